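"""Lagged linear connectivity (lagged coherence) between ROI time series.

For ROI series x and y with epoch-averaged cross-spectrum S_xy(f), the
lagged linear connectivity at a frequency bin is

    LLC_xy(f) = Im(S_xy)^2 / (S_xx * S_yy - Re(S_xy)^2)

i.e. the share of the linear dependence that survives after removing the
instantaneous (zero-lag, real) part.  Because |S_xy|^2 <= S_xx * S_yy
(Cauchy-Schwarz), LLC lies in [0, 1]; identical or purely instantaneously
mixed series give exactly 0, which is what makes the measure robust to
volume conduction.  Band values are the arithmetic mean of the per-bin
LLC over in-band bins; bins whose denominator is numerically degenerate
(zero-power ROI pairs) are excluded from the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from depnet.preprocess import BandDefinition, DEFAULT_BANDS, band_bins, epoch_taper


@dataclass
class CrossSpectrum:
    """Epoch-averaged Hermitian cross-spectral matrices per frequency bin."""

    freqs: np.ndarray  # (n_bins,)
    S: np.ndarray  # (n_bins, n_series, n_series) complex
    n_epochs: int


@dataclass
class BandConnectivity:
    """Per-participant symmetric LLC matrix for one band (zero diagonal)."""

    participant_id: str
    band: str
    matrix: np.ndarray  # (n_rois, n_rois), NaN where undefined
    n_epochs: int


def cross_spectrum(
    roi_epochs: np.ndarray,
    sampling_rate: float,
    cosine_fraction: float = 0.1,
    freq_mask: np.ndarray | None = None,
) -> CrossSpectrum:
    """Epoch-averaged cross-spectra of (n_epochs, n_series, n_samples) data.

    Each epoch is tapered (10%-cosine Tukey window) and Fourier transformed;
    S_xy(f) is the epoch mean of X(f) * conj(Y(f)), normalised by the taper
    power.  ``freq_mask`` restricts the output to selected bins (saves the
    memory of full 18 x 18 matrices at every bin).
    """
    roi_epochs = np.asarray(roi_epochs)
    if roi_epochs.ndim != 3:
        raise ValueError("roi_epochs must be (n_epochs, n_series, n_samples)")
    n_ep, _, n = roi_epochs.shape
    if n_ep < 2:
        raise ValueError("need at least two epochs to estimate cross-spectra")
    w = epoch_taper(n, cosine_fraction)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    X = np.fft.rfft(roi_epochs * w[None, None, :], axis=2)
    if freq_mask is not None:
        freqs = freqs[freq_mask]
        X = X[:, :, freq_mask]
    # S[f] = mean_e X_e(f) X_e(f)^H, taper-power normalised
    S = np.einsum("eif,ejf->fij", X, np.conj(X)) / (n_ep * n * np.sum(w**2))
    return CrossSpectrum(freqs=freqs, S=S, n_epochs=n_ep)


def lagged_connectivity(
    cs: CrossSpectrum, band: BandDefinition, denom_rtol: float = 1e-12
) -> np.ndarray:
    """Band-mean LLC matrix (symmetric, zero diagonal, NaN where undefined).

    Per-bin LLC is averaged over the band's bins.  Bins where the
    denominator ``S_xx S_yy - Re(S_xy)^2`` is below ``denom_rtol`` times the
    pair's power scale carry no usable lagged information and are excluded;
    a pair with no usable bin at all (degenerate, zero-power ROI) is NaN.
    """
    mask = band_bins(cs.freqs, band)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band.name}")
    S = cs.S[mask]
    P = np.real(np.einsum("fii->fi", S))  # (n_bins, n_series) auto-spectra
    num = np.imag(S) ** 2
    scale = P[:, :, None] * P[:, None, :]
    denom = scale - np.real(S) ** 2
    power_ok = scale > 0
    denom_ok = denom > denom_rtol * scale
    # three regimes per bin: regular ratio; perfect instantaneous coherence
    # (denominator collapses, lagged share is zero by definition); no power
    # at all (undefined)
    llc_bins = np.where(
        power_ok & denom_ok,
        num / np.where(denom_ok, denom, 1.0),
        np.where(power_ok, 0.0, np.nan),
    )
    with np.errstate(invalid="ignore"):
        defined = ~np.isnan(llc_bins)
        n_def = defined.sum(axis=0)
        llc = np.where(
            n_def > 0, np.nansum(llc_bins, axis=0) / np.maximum(n_def, 1), np.nan
        )
    llc = 0.5 * (llc + llc.T)  # enforce exact symmetry against rounding
    np.fill_diagonal(llc, 0.0)
    return llc


def participant_connectivity(
    roi_epochs: np.ndarray,
    sampling_rate: float,
    participant_id: str = "",
    bands=DEFAULT_BANDS,
    cosine_fraction: float = 0.1,
) -> dict[str, BandConnectivity]:
    """LLC matrices for all requested bands from one participant's ROI epochs."""
    mask = None
    n = np.asarray(roi_epochs).shape[2]
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    mask = np.zeros(freqs.size, dtype=bool)
    for b in bands:
        mask |= band_bins(freqs, b)
    cs = cross_spectrum(roi_epochs, sampling_rate, cosine_fraction, freq_mask=mask)
    return {
        b.name: BandConnectivity(
            participant_id=participant_id,
            band=b.name,
            matrix=lagged_connectivity(cs, b),
            n_epochs=cs.n_epochs,
        )
        for b in bands
    }


def edge_index(n_rois: int = 18) -> list[tuple[int, int]]:
    """Unique upper-triangle ROI pairs (i < j, 0-based): 153 edges for 18 ROIs."""
    return [(i, j) for i in range(n_rois) for j in range(i + 1, n_rois)]


def edge_vector(matrix: np.ndarray) -> np.ndarray:
    """Upper-triangle values of a symmetric connectivity matrix."""
    n = matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    return matrix[iu]
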