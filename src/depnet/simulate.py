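"""Synthetic cohorts and forward-modelled EEG with known ground truth.

Two generators make the whole analysis chain testable without any
participant data:

* :func:`gen_sds_cohort` draws correlated subtype severities from a
  one-general-factor latent model (severity_s = loading * G + specific
  noise), then emits ordinal 1-4 item responses by thresholding the
  severity plus item noise.  Defaults are calibrated so that a cohort of
  100 reproduces the descriptive statistics of a community sample:
  subtype mean scores around 1.6-2.2 and inter-subtype score correlations
  in the 0.6-0.85 range.

* :func:`gen_sources` / :func:`forward_project` / :func:`inject_artifacts`
  build per-participant scalp EEG: each of the 18 ROI sources carries a
  1/f background plus narrowband alpha and beta oscillations; designated
  coupling edges add a *time-lagged* copy of the sender's band component
  to the receiver (lag strictly positive -- instantaneous mixing carries
  no lagged connectivity), with the coupling strength scaled up for
  members of the designated depressed group.  Sources are projected
  through the three-shell spherical leadfield, sensor noise is added, and
  blinks / electrode pops / muscle bursts are injected at Poisson rates.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from depnet import headmodel
from depnet.preprocess import EEGRecording
from depnet.sds import SDSRecord, SUBTYPES, REVERSE_KEYED_ITEMS, SUBTYPE_ITEMS, DEPRESSED, NON_DEPRESSED

# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortSpec:
    """Latent model for four correlated subtype severities and ordinal items.

    ``general_factor_loading`` is the loading of every subtype severity on a
    shared general depression factor; ``subtype_specific_sd`` the standard
    deviation of the subtype-specific part.  ``ordinal_thresholds`` are the
    three increasing cut points mapping (severity + item noise) onto the
    1-4 symptom-frequency scale.
    """

    n_participants: int = 100
    general_factor_loading: float = 0.9
    subtype_specific_sd: float = 0.45
    item_noise_sd: float = 0.6
    ordinal_thresholds: tuple[float, float, float] = (-0.15, 0.95, 1.9)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.general_factor_loading <= 1.0:
            raise ValueError("general_factor_loading must be in [0, 1]")
        t = self.ordinal_thresholds
        if not (t[0] < t[1] < t[2]):
            raise ValueError("ordinal thresholds must be strictly increasing")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")


@dataclass
class GroundTruth:
    """Generator-side truth: latent severities and per-subtype group labels."""

    severities: pd.DataFrame  # participant_id + one column per subtype
    labels: pd.DataFrame  # participant_id + one {depressed, non_depressed} column per subtype
    coupled_edges: list = field(default_factory=list)
    eeg_group: dict[str, str] = field(default_factory=dict)  # participant -> label used for EEG


def gen_sds_cohort(spec: CohortSpec) -> tuple[list[SDSRecord], GroundTruth]:
    """Generate SDS records plus ground truth from a latent severity model.

    Reverse-worded items are emitted on the raw questionnaire scale, i.e.
    a *high* symptom level produces a *low* raw response on those items, so
    downstream scoring must reverse-key them.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    lam = spec.general_factor_loading
    G = rng.normal(size=n)
    sev = {
        s: lam * G + spec.subtype_specific_sd * rng.normal(size=n) for s in SUBTYPES
    }
    # age/sex independent of severity (the study found no association)
    ages = np.round(rng.uniform(18, 75, size=n), 1)
    sexes = rng.choice(["F", "M"], size=n)

    item_subtype = {i: s for s, items in SUBTYPE_ITEMS.items() for i in items}
    # items outside every subtype grouping (2 of the 20) load on the general factor
    records = []
    thresholds = np.asarray(spec.ordinal_thresholds)
    for p in range(n):
        responses: dict[int, int] = {}
        for item in range(1, 21):
            base = sev[item_subtype[item]][p] if item in item_subtype else lam * G[p]
            latent = base + spec.item_noise_sd * rng.normal()
            level = 1 + int(np.searchsorted(thresholds, latent))
            responses[item] = (5 - level) if item in REVERSE_KEYED_ITEMS else level
        records.append(
            SDSRecord(
                participant_id=f"P{p:03d}",
                raw_responses=responses,
                age=float(ages[p]),
                sex=str(sexes[p]),
            )
        )

    ids = [r.participant_id for r in records]
    sev_df = pd.DataFrame({"participant_id": ids, **{s: sev[s] for s in SUBTYPES}})
    labels = {
        s: np.where(sev[s] >= sev[s].mean(), DEPRESSED, NON_DEPRESSED) for s in SUBTYPES
    }
    lab_df = pd.DataFrame({"participant_id": ids, **labels})
    return records, GroundTruth(severities=sev_df, labels=lab_df)


# ---------------------------------------------------------------------------
# EEG generation


@dataclass(frozen=True)
class CouplingEdge:
    """Directed lagged coupling between two ROI sources (1-based indices)."""

    roi_i: int
    roi_j: int
    band: str  # 'alpha' or 'beta'
    lag_ms: float = 25.0
    strength: float = 0.4
    group_contrast: float = 0.5

    def validate(self, n_rois: int = 18, allow_zero_lag: bool = False) -> None:
        for idx in (self.roi_i, self.roi_j):
            if not 1 <= idx <= n_rois:
                raise ValueError(f"roi index {idx} outside 1..{n_rois}")
        if self.roi_i == self.roi_j:
            raise ValueError("coupling edge must join two distinct ROIs")
        if self.band not in ("alpha", "beta"):
            raise ValueError(f"unknown band {self.band!r}")
        if self.lag_ms <= 0 and not allow_zero_lag:
            raise ValueError("coupling lag must be strictly positive")


@dataclass(frozen=True)
class SimEEGSpec:
    """Generation parameters for one cohort's EEG recordings."""

    n_channels: int = 24
    sampling_rate: float = 1000.0
    duration: float = 180.0
    n_rois: int = 18
    alpha_freq: float = 10.0
    beta_freq: float = 15.0
    alpha_bandwidth: float = 1.5
    beta_bandwidth: float = 2.0
    alpha_amplitude: float = 1.0
    beta_amplitude: float = 0.6
    background_amplitude: float = 0.8
    one_over_f_exponent: float = 1.0
    amplitude_jitter: float = 0.3  # lognormal sigma of per-participant amplitude variation
    source_scale: float = 0.025  # source moment scale; gives ~6.5 uV median channel std
    sensor_noise_uv: float = 2.0
    coupling_edges: tuple[CouplingEdge, ...] = ()
    blink_rate_per_min: float = 0.7
    pop_rate_per_min: float = 0.1
    burst_rate_per_min: float = 0.2
    blink_amplitude_uv: float = 200.0
    pop_amplitude_uv: float = 100.0
    burst_amplitude_uv: float = 60.0
    seed: int = 0

    def validate(self, allow_zero_lag: bool = False) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        for e in self.coupling_edges:
            e.validate(self.n_rois, allow_zero_lag=allow_zero_lag)


def _unit_variance_amplitudes(amp: np.ndarray, n: int) -> np.ndarray:
    """Scale rfft bin amplitudes so the synthesised series has unit variance.

    For coefficients ``c_k = a_k (xi + i zeta)`` with standard-normal xi,
    zeta, Parseval gives an expected time-domain variance of
    ``4 sum(a_k^2) / n^2``.
    """
    s = 2.0 * np.sqrt(np.sum(amp**2)) / n
    return amp / s if s > 0 else amp


def gen_sources(
    spec: SimEEGSpec,
    group_label: str = NON_DEPRESSED,
    seed: int | np.random.Generator | None = None,
    _allow_zero_lag: bool = False,
) -> np.ndarray:
    """One participant's ROI source series (n_rois x n_samples).

    ``group_label`` selects the coupling strength: members of the depressed
    group get each edge's ``strength * (1 + group_contrast)``, others the
    base ``strength``.  ``_allow_zero_lag`` is a test hook for the defining
    property of the lagged measure (zero-lag mixing must yield none).

    Sources are assembled in the frequency domain (random-phase spectra for
    the 1/f background and the Gaussian-bump alpha/beta components; lagged
    coupling enters as an ``exp(-2 pi i f lag)`` phase factor on the
    sender's band component) and synthesised with one inverse FFT per ROI.
    Generation is restricted to bins below 45 Hz -- the processing chain's
    30 Hz low-pass removes faster content anyway.
    """
    spec.validate(allow_zero_lag=_allow_zero_lag)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = int(round(spec.duration * spec.sampling_rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sampling_rate)
    gen = (freqs > 0) & (freqs <= min(45.0, 0.95 * spec.sampling_rate / 2.0))
    f = freqs[gen]
    nb = f.size

    a_alpha = _unit_variance_amplitudes(
        np.exp(-0.5 * ((f - spec.alpha_freq) / spec.alpha_bandwidth) ** 2), n
    )
    a_beta = _unit_variance_amplitudes(
        np.exp(-0.5 * ((f - spec.beta_freq) / spec.beta_bandwidth) ** 2), n
    )
    a_bg = _unit_variance_amplitudes(
        np.where(f > 0.5, f ** (-spec.one_over_f_exponent / 2.0), 0.0), n
    )

    def draw(amp: np.ndarray, scale: float) -> np.ndarray:
        jitter = float(np.exp(rng.normal(0.0, spec.amplitude_jitter)))
        noise = rng.standard_normal(nb) + 1j * rng.standard_normal(nb)
        return (scale * jitter) * amp * noise

    alpha_spec = np.empty((spec.n_rois, nb), dtype=complex)
    beta_spec = np.empty_like(alpha_spec)
    total = np.zeros((spec.n_rois, freqs.size), dtype=complex)
    for r in range(spec.n_rois):
        alpha_spec[r] = draw(a_alpha, spec.alpha_amplitude)
        beta_spec[r] = draw(a_beta, spec.beta_amplitude)
        total[r, gen] = alpha_spec[r] + beta_spec[r] + draw(a_bg, spec.background_amplitude)

    depressed = group_label == DEPRESSED
    for e in spec.coupling_edges:
        comp = alpha_spec if e.band == "alpha" else beta_spec
        w = e.strength * (1.0 + e.group_contrast) if depressed else e.strength
        w = min(w, 0.95)
        delay = np.exp(-2j * np.pi * f * (e.lag_ms / 1000.0))
        # variance-preserving mixing: the receiver's own band component shrinks
        # by sqrt(1 - w^2) so the group contrast lives in the *lagged
        # dependence*, not in band power
        total[e.roi_j - 1, gen] += (
            (np.sqrt(1.0 - w**2) - 1.0) * comp[e.roi_j - 1]
            + w * delay * comp[e.roi_i - 1]
        )

    sources = np.fft.irfft(total, n=n, axis=1)
    return sources * spec.source_scale


def forward_project(
    sources: np.ndarray,
    leadfield: headmodel.Leadfield,
    noise_uv: float = 2.0,
    source_indices: Sequence[int] | None = None,
    seed: int | np.random.Generator | None = None,
    channel_labels: tuple[str, ...] | None = None,
    sampling_rate: float = 1000.0,
) -> EEGRecording:
    """Scalp EEG = gain . sources + white sensor noise (uV).

    ``source_indices`` selects which leadfield columns the source rows
    occupy (default: the first ``n_sources`` grid nodes, which
    :func:`depnet.headmodel.build_source_grid` reserves for ROI centres).
    """
    sources = np.asarray(sources)
    n_src = sources.shape[0]
    if source_indices is None:
        source_indices = range(n_src)
    G = leadfield.gain[:, list(source_indices)]
    if G.shape[1] != n_src:
        raise ValueError("source_indices length must match source rows")
    rng = np.random.default_rng(seed)
    eeg = G @ sources
    if noise_uv > 0:
        eeg = eeg + rng.normal(0.0, noise_uv, size=eeg.shape)
    labels = channel_labels or leadfield.channel_labels
    return EEGRecording(channel_labels=tuple(labels), samples=eeg, sampling_rate=sampling_rate)


@dataclass
class ArtifactLog:
    """Placement bookkeeping: (kind, start_s, duration_s, channel or -1)."""

    events: list[tuple[str, float, float, int]] = field(default_factory=list)

    def contaminated_epochs(self, epoch_seconds: float, n_epochs: int) -> set[int]:
        """Indices of epochs overlapping any artifact window."""
        hit: set[int] = set()
        for _, start, dur, _ in self.events:
            first = int(start // epoch_seconds)
            last = int((start + dur) // epoch_seconds)
            for k in range(first, last + 1):
                if 0 <= k < n_epochs:
                    hit.add(k)
        return hit


def inject_artifacts(
    rec: EEGRecording,
    spec: SimEEGSpec,
    channel_positions: np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> tuple[EEGRecording, ArtifactLog]:
    """Add blinks, electrode pops and muscle bursts; return the placement log.

    Blinks are 400 ms frontal-weighted raised-cosine deflections; pops are
    step discontinuities on a single channel; bursts are 25 Hz transients
    on a random channel pair.  Event counts are Poisson in the stated
    per-minute rates; placements are uniform.
    """
    rng = np.random.default_rng(seed)
    fs = rec.sampling_rate
    n = rec.samples.shape[1]
    minutes = n / fs / 60.0
    eeg = rec.samples.copy()
    log = ArtifactLog()

    # frontal weighting from electrode geometry (+y is anterior)
    y = channel_positions[:, 1] / np.linalg.norm(channel_positions, axis=1)
    frontal = np.clip(y, 0.0, None) ** 2
    if frontal.max() > 0:
        frontal = frontal / frontal.max()

    for _ in range(rng.poisson(spec.blink_rate_per_min * minutes)):
        dur = 0.4
        width = int(dur * fs)
        start = rng.integers(0, max(1, n - width))
        pulse = spec.blink_amplitude_uv * 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
        eeg[:, start : start + width] += frontal[:, None] * pulse[None, :]
        log.events.append(("blink", start / fs, dur, -1))

    for _ in range(rng.poisson(spec.pop_rate_per_min * minutes)):
        ch = int(rng.integers(0, eeg.shape[0]))
        start = int(rng.integers(0, n))
        step = spec.pop_amplitude_uv * rng.choice([-1.0, 1.0])
        eeg[ch, start:] += step
        log.events.append(("pop", start / fs, 0.5, ch))

    for _ in range(rng.poisson(spec.burst_rate_per_min * minutes)):
        dur = 0.5
        width = int(dur * fs)
        start = rng.integers(0, max(1, n - width))
        ch = int(rng.integers(0, eeg.shape[0]))
        t = np.arange(width) / fs
        envelope = np.exp(-0.5 * ((t - dur / 2) / (dur / 6)) ** 2)
        burst = spec.burst_amplitude_uv * envelope * np.sin(2 * np.pi * 25.0 * t)
        for c in {ch, min(ch + 1, eeg.shape[0] - 1)}:
            eeg[c, start : start + width] += burst
        log.events.append(("burst", start / fs, dur, ch))

    return replace(rec, samples=eeg), log


# ---------------------------------------------------------------------------
# file output (numeric matrix + JSON header; cohort CSV; ground truth JSON)


def save_recording(rec: EEGRecording, stem: Path) -> None:
    """Write ``<stem>.npy`` (channels x samples, uV) + ``<stem>.json`` header."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), rec.samples)
    header = {
        "channel_labels": list(rec.channel_labels),
        "sampling_rate": rec.sampling_rate,
        "units": "uV",
    }
    stem.with_suffix(".json").write_text(json.dumps(header, indent=1))


def load_recording(stem: Path) -> EEGRecording:
    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    samples = np.load(stem.with_suffix(".npy"))
    return EEGRecording(
        channel_labels=tuple(header["channel_labels"]),
        samples=samples,
        sampling_rate=float(header["sampling_rate"]),
    )


def cohort_to_csv(records: Sequence[SDSRecord], path: Path) -> None:
    rows = []
    for r in records:
        row = {"participant_id": r.participant_id, "age": r.age, "sex": r.sex}
        row.update({f"item_{i}": r.raw_responses[i] for i in range(1, 21)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
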