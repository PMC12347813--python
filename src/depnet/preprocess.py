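"""EEG preprocessing: filtering, 4-s epoching, rejection, band power.

The processing chain mirrors a conventional resting-state pipeline:

1. zero-phase filtering -- 1 Hz high-pass (2 Hz transition), 30 Hz low-pass
   (8 Hz transition), 50 Hz notch (1.5 Hz transition) with harmonics, and a
   50 Hz band-stop of 10 Hz width (5 Hz transitions), also with harmonics;
2. back-to-back non-overlapping 4-s epochs (trailing remainder discarded);
3. per-epoch baseline correction (whole epoch as baseline) and rejection of
   any epoch whose residual exceeds +/-50 uV on any channel;
4. participants with fewer than 75% artifact-free epochs are excluded;
5. FFT power spectra per epoch (Tukey taper with 10% cosine fraction),
   averaged across kept epochs, summed within the alpha (8-12.9 Hz) and
   beta (13-18 Hz) bands.

Filters are realised by multiplying the signal's real FFT with a designed
magnitude response (exact zero phase, exact nulls at the notch centres).
Each transition is a raised cosine of the stated width with full attenuation
at the printed cutoff and the transition rising on the passband side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal.windows import tukey

EPOCH_SECONDS = 4.0
REJECT_UV = 50.0
MIN_KEEP_FRACTION = 0.75


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with inclusive edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")


ALPHA = BandDefinition("alpha", 8.0, 12.9)
BETA = BandDefinition("beta", 13.0, 18.0)
DEFAULT_BANDS = (ALPHA, BETA)


@dataclass
class EEGRecording:
    """Multichannel EEG: channels x samples in microvolts."""

    channel_labels: tuple[str, ...]
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("samples must be (n_channels, n_samples) matching labels")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


@dataclass
class EpochSet:
    """Contiguous 4-s segments with a keep mask and rejection provenance."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples_per_epoch)
    sampling_rate: float
    keep_mask: np.ndarray
    rejection_reasons: dict[int, str] = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())

    @property
    def keep_fraction(self) -> float:
        return self.n_kept / self.n_epochs if self.n_epochs else 0.0

    def kept(self) -> np.ndarray:
        return self.epochs[self.keep_mask]


@dataclass(frozen=True)
class FilterConfig:
    """Cutoffs in Hz; transition ("slope") widths in Hz; switchable stages."""

    highpass: float = 1.0
    highpass_width: float = 2.0
    lowpass: float = 30.0
    lowpass_width: float = 8.0
    notch: float | None = 50.0
    notch_width: float = 1.5
    bandstop: float | None = 50.0
    bandstop_halfwidth: float = 5.0
    bandstop_transition: float = 5.0
    harmonics: bool = True


def _raised_cosine_rise(f: np.ndarray, start: float, width: float) -> np.ndarray:
    """0 below ``start``, raised-cosine rise to 1 over ``width`` Hz."""
    x = np.clip((f - start) / width, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def filter_response(freqs: np.ndarray, config: FilterConfig, nyquist: float) -> np.ndarray:
    """Designed magnitude response of the full chain on the given frequency grid."""
    f = np.asarray(freqs, dtype=float)
    H = np.ones_like(f)
    # high-pass: zero at/below the cutoff, rising into the passband
    H *= _raised_cosine_rise(f, config.highpass, config.highpass_width)
    # low-pass: unity at/below the cutoff, falling above it
    H *= 1.0 - _raised_cosine_rise(f, config.lowpass, config.lowpass_width)

    def stop_centres(f0: float):
        k = 1
        while k * f0 < nyquist + 1e-9:
            yield k * f0
            k += 1
            if not config.harmonics:
                return

    if config.notch is not None:
        for fc in stop_centres(config.notch):
            d = np.abs(f - fc)
            # unity outside, cosine dip to an exact zero at the centre
            H *= _raised_cosine_rise(d, 0.0, config.notch_width)
    if config.bandstop is not None:
        for fc in stop_centres(config.bandstop):
            d = np.abs(f - fc)
            # zero across the stated width, cosine transitions on either side
            H *= _raised_cosine_rise(d, config.bandstop_halfwidth, config.bandstop_transition)
    return H


def filter_chain(rec: EEGRecording, config: FilterConfig | None = None) -> EEGRecording:
    """Apply the zero-phase filter chain to a recording."""
    if config is None:
        config = FilterConfig()
    nyq = rec.sampling_rate / 2.0
    highest_edge = max(config.highpass + config.highpass_width, config.lowpass + config.lowpass_width)
    if rec.sampling_rate < 2.0 * highest_edge:
        raise ValueError(
            f"sampling rate {rec.sampling_rate} Hz too low for filter edges up to {highest_edge} Hz"
        )
    n = rec.samples.shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.sampling_rate)
    H = filter_response(freqs, config, nyq)
    spectra = np.fft.rfft(rec.samples, axis=1)
    filtered = np.fft.irfft(spectra * H[None, :], n=n, axis=1)
    return replace(rec, samples=filtered.astype(rec.samples.dtype, copy=False))


def make_epochs(rec: EEGRecording, epoch_seconds: float = EPOCH_SECONDS) -> EpochSet:
    """Cut back-to-back non-overlapping epochs; trailing remainder discarded."""
    spe = int(round(epoch_seconds * rec.sampling_rate))
    n_epochs = rec.samples.shape[1] // spe
    if n_epochs < 1:
        raise ValueError(f"recording shorter than one {epoch_seconds}-s epoch")
    trimmed = rec.samples[:, : n_epochs * spe]
    epochs = trimmed.reshape(rec.samples.shape[0], n_epochs, spe).transpose(1, 0, 2)
    return EpochSet(
        epochs=np.ascontiguousarray(epochs),
        sampling_rate=rec.sampling_rate,
        keep_mask=np.ones(n_epochs, dtype=bool),
    )


def reject_epochs(eset: EpochSet, threshold_uv: float = REJECT_UV) -> EpochSet:
    """Baseline-correct each epoch (whole-epoch mean) and reject on amplitude.

    An epoch is rejected when any sample on any channel exceeds
    ``threshold_uv`` in absolute value after per-channel demeaning.
    Already-rejected epochs keep their original reason (idempotent).
    """
    if eset.n_epochs == 0:
        raise ValueError("no epochs to reject")
    demeaned = eset.epochs - eset.epochs.mean(axis=2, keepdims=True)
    peak = np.abs(demeaned).max(axis=(1, 2))
    keep = peak <= threshold_uv
    reasons = dict(eset.rejection_reasons)
    for i in np.nonzero(~keep)[0]:
        reasons.setdefault(
            int(i), f"amplitude {peak[i]:.1f} uV exceeds +/-{threshold_uv:.0f} uV after baseline correction"
        )
    return EpochSet(
        epochs=eset.epochs,
        sampling_rate=eset.sampling_rate,
        keep_mask=eset.keep_mask & keep,
        rejection_reasons=reasons,
    )


def exclude_participants(
    keep_fractions: Mapping[str, float], min_fraction: float = MIN_KEEP_FRACTION
) -> tuple[list[str], list[str]]:
    """Split participant ids into (kept, excluded) by the 75% rule.

    A participant is excluded iff their artifact-free epoch fraction is
    strictly below ``min_fraction``.
    """
    kept, excluded = [], []
    for pid, frac in keep_fractions.items():
        (excluded if frac < min_fraction else kept).append(pid)
    return kept, excluded


def epoch_taper(n_samples: int, cosine_fraction: float = 0.1, full_hann: bool = False) -> np.ndarray:
    """Per-epoch taper: 10%-cosine Tukey window by default, full Hann optionally."""
    if full_hann:
        return np.hanning(n_samples)
    return tukey(n_samples, alpha=cosine_fraction)


def power_spectrum(eset: EpochSet, cosine_fraction: float = 0.1, full_hann: bool = False):
    """Epoch-averaged power per FFT bin: (freqs, power[channel, bin]).

    Normalised so that the sum of bin powers equals the mean-square signal
    amplitude (Parseval), i.e. an in-band sinusoid of amplitude A contributes
    A^2/2 to its band total, independent of the taper.
    """
    kept = eset.kept()
    if kept.shape[0] < 1:
        raise ValueError("no kept epochs")
    n = kept.shape[2]
    w = epoch_taper(n, cosine_fraction, full_hann)
    freqs = np.fft.rfftfreq(n, d=1.0 / eset.sampling_rate)
    X = np.fft.rfft(kept * w[None, None, :], axis=2)
    scale = np.full(freqs.shape, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    P = (np.abs(X) ** 2 * scale[None, None, :]) / (n * np.sum(w**2))
    return freqs, P.mean(axis=0)


def band_bins(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Boolean mask of bins with lo <= f <= hi (inclusive of available edges)."""
    return (freqs >= band.lo - 1e-9) & (freqs <= band.hi + 1e-9)


def band_power(
    eset: EpochSet,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    cosine_fraction: float = 0.1,
    full_hann: bool = False,
) -> dict[str, np.ndarray]:
    """Total power per band and channel (uV^2): {band name: (n_channels,)}."""
    freqs, P = power_spectrum(eset, cosine_fraction, full_hann)
    return {b.name: P[:, band_bins(freqs, b)].sum(axis=1) for b in bands}
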