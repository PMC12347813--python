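"""Independent brute-force oracles shared by the test suite."""

import numpy as np

from depnet.preprocess import epoch_taper


def brute_force_cross_spectrum(epochs, fs):
    """O(n^2) direct DFT evaluation of the tapered, epoch-averaged
    cross-spectrum (independent of the FFT implementation path)."""
    epochs = np.asarray(epochs)
    n_ep, n_series, n = epochs.shape
    w = epoch_taper(n)
    freqs = np.arange(n // 2 + 1) * fs / n
    S = np.zeros((len(freqs), n_series, n_series), dtype=complex)
    for e in range(n_ep):
        X = np.zeros((n_series, len(freqs)), dtype=complex)
        for s in range(n_series):
            xw = epochs[e, s] * w
            for ki in range(n // 2 + 1):
                X[s, ki] = np.sum(
                    xw * np.exp(-2j * np.pi * ki * np.arange(n) / n)
                )
        for ki in range(len(freqs)):
            S[ki] += np.outer(X[:, ki], np.conj(X[:, ki]))
    return freqs, S / (n_ep * n * np.sum(w**2))


def brute_force_llc(epochs, fs, lo, hi):
    """Band-mean lagged linear connectivity between the first two series,
    evaluated from the brute-force cross-spectrum with explicit loops."""
    freqs, S = brute_force_cross_spectrum(epochs, fs)
    vals = []
    for ki, f in enumerate(freqs):
        if not (lo - 1e-9 <= f <= hi + 1e-9):
            continue
        sxx = S[ki, 0, 0].real
        syy = S[ki, 1, 1].real
        sxy = S[ki, 0, 1]
        if sxx * syy <= 0:
            continue
        denom = sxx * syy - sxy.real**2
        if denom > 1e-12 * sxx * syy:
            vals.append(sxy.imag**2 / denom)
        else:
            vals.append(0.0)
    return float(np.mean(vals))
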