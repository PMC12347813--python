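"""Analytic three-shell spherical head model and leadfield construction.

The head is modelled as three concentric spheres (brain, skull, scalp) with
piecewise-constant conductivity.  Sources are current dipoles with fixed
radial orientation on a grid of positions inside the brain compartment;
electrodes sit on the scalp sphere.  For each spherical-harmonic degree
``n`` the potential in shell ``i`` is ``(A_i r^n + B_i r^-(n+1)) P_n(cos g)``
and the shell coefficients follow from continuity of potential and radial
current at the two interfaces plus a no-current condition at the scalp
surface; the per-degree 5x5 systems are solved once and reused for every
source-electrode pair.  The series is truncated at a degree where the
eccentricity term ``(b/R)^(n-1)`` has decayed below ~1e-10.

Electrode positions for the 24-site montage used throughout the analyses
are taken from MNE's packaged standard 10-10 montage and projected onto the
scalp sphere.  Source positions are given in MNI-style millimetres and are
mapped into the sphere frame by subtracting a fixed head-centre offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: default shell radii, mm (brain, skull, scalp)
DEFAULT_RADII = (87.0, 92.0, 100.0)
#: default conductivities, S/m (brain, skull, scalp)
DEFAULT_CONDUCTIVITIES = (0.33, 0.0042, 0.33)
#: approximate head-sphere centre in MNI coordinates, mm
MNI_SPHERE_CENTER = np.array([0.0, -15.0, 10.0])

#: the 24 recording sites (10-10 names), frontal through occipital
CHANNELS_24: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "F7", "F8", "FT7", "FT8", "FC3", "FC4",
    "T7", "T8", "TP7", "TP8", "C3", "C4",
    "P3", "P4", "P7", "P8", "CP3", "CP4",
    "O1", "O2",
)


class HeadModelError(ValueError):
    """Raised for degenerate head-model geometry."""


@dataclass
class Leadfield:
    """Gain matrix (channels x sources) plus geometry.

    ``gain`` maps radial dipole moments (nA*m scale is arbitrary; the model
    is linear) at ``source_positions`` (MNI-style mm) to scalp potentials at
    ``channel_positions`` (sphere-frame mm).  ``full_column_rank`` records
    whether the gain columns are linearly independent (they generally are
    not once sources outnumber channels; underdetermined is the normal
    case for EEG).
    """

    gain: np.ndarray
    source_positions: np.ndarray
    channel_labels: tuple[str, ...]
    channel_positions: np.ndarray
    radii: tuple[float, float, float] = DEFAULT_RADII
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES
    full_column_rank: bool = field(default=False)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.gain)):
            raise HeadModelError("gain matrix contains non-finite values")
        norms = np.linalg.norm(self.gain, axis=0)
        if np.any(norms == 0):
            raise HeadModelError("gain matrix has an all-zero column")


def montage_positions(labels: tuple[str, ...] = CHANNELS_24, scalp_radius: float = DEFAULT_RADII[2]) -> np.ndarray:
    """Electrode positions (mm) on the scalp sphere for standard 10-10 labels.

    Directions come from MNE's packaged montage (best-fit sphere centre
    removed); each electrode is then placed on the scalp sphere.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    ch_pos = montage.get_positions()["ch_pos"]
    by_upper = {name.upper(): np.asarray(p) for name, p in ch_pos.items()}
    missing = [l for l in labels if l.upper() not in by_upper]
    if missing:
        raise HeadModelError(f"montage lacks channels: {missing}")
    pts = np.array([by_upper[l.upper()] for l in labels])
    # best-fit sphere centre of the full montage (least squares)
    allpts = np.array(list(ch_pos.values()))
    A = np.c_[2 * allpts, np.ones(len(allpts))]
    b = (allpts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    dirs = pts - center
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs * scalp_radius


def _shell_transfer(n_max: int, radii, conductivities) -> np.ndarray:
    """Scalp-surface response g_n per unit source term, degrees 1..n_max.

    Works in radii normalised by the scalp radius.  For degree n the source
    adds ``S r^-(n+1)`` to the brain-shell potential with ``S = 1`` here;
    the returned ``g_n`` is the scalp-surface coefficient
    ``A3 + B3`` (at r = 1) of the solved shell system.
    """
    r1, r2, r3 = radii
    s1, s2, s3 = conductivities
    u1, u2 = r1 / r3, r2 / r3
    if not (0 < u1 < u2 < 1.0 + 1e-12):
        raise HeadModelError(f"radii must be strictly increasing: {radii}")
    if min(conductivities) <= 0:
        raise HeadModelError("conductivities must be positive")
    g = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        # unknowns: A1, A2, B2, A3, B3
        M = np.zeros((5, 5))
        rhs = np.zeros(5)
        # continuity of V at u1
        M[0] = [u1**n, -(u1**n), -(u1 ** -(n + 1)), 0, 0]
        rhs[0] = -(u1 ** -(n + 1))
        # continuity of sigma dV/dr at u1
        M[1] = [
            s1 * n * u1 ** (n - 1),
            -s2 * n * u1 ** (n - 1),
            s2 * (n + 1) * u1 ** -(n + 2),
            0,
            0,
        ]
        rhs[1] = s1 * (n + 1) * u1 ** -(n + 2)
        # continuity of V at u2
        M[2] = [0, u2**n, u2 ** -(n + 1), -(u2**n), -(u2 ** -(n + 1))]
        # continuity of sigma dV/dr at u2
        M[3] = [
            0,
            s2 * n * u2 ** (n - 1),
            -s2 * (n + 1) * u2 ** -(n + 2),
            -s3 * n * u2 ** (n - 1),
            s3 * (n + 1) * u2 ** -(n + 2),
        ]
        # no radial current at the scalp surface (u = 1)
        M[4] = [0, 0, 0, n, -(n + 1)]
        try:
            sol = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise HeadModelError(f"degenerate shell system at degree {n}") from err
        g[n] = sol[3] + sol[4]
    return g


def radial_dipole_potentials(
    source_positions_mm: np.ndarray,
    electrode_positions_mm: np.ndarray,
    radii=DEFAULT_RADII,
    conductivities=DEFAULT_CONDUCTIVITIES,
    n_terms: int = 120,
) -> np.ndarray:
    """Scalp potentials of unit radial dipoles: (n_electrodes, n_sources).

    Positions are in the sphere frame (mm, origin at the sphere centre).
    Every source must lie strictly inside the brain shell and off-centre
    (a radial orientation is undefined at the origin).
    """
    src = np.atleast_2d(np.asarray(source_positions_mm, dtype=float))
    ele = np.atleast_2d(np.asarray(electrode_positions_mm, dtype=float))
    r1, _, r3 = radii
    b = np.linalg.norm(src, axis=1)
    if np.any(b < 1e-6):
        raise HeadModelError("source at the sphere centre has no radial orientation")
    if np.any(b >= r1):
        raise HeadModelError("sources must lie strictly inside the brain shell")
    e_norm = np.linalg.norm(ele, axis=1)
    if np.any(np.abs(e_norm - r3) > 1e-6 * r3):
        raise HeadModelError("electrodes must lie on the scalp sphere")

    g = _shell_transfer(n_terms, radii, conductivities)  # degrees 0..n_terms
    cosg = (ele / e_norm[:, None]) @ (src / b[:, None]).T
    cosg = np.clip(cosg, -1.0, 1.0)

    bu = b / r3  # normalised eccentricities
    sigma1 = conductivities[0]
    # Legendre recurrence accumulated over degrees; term_n = g_n * n * bu^(n-1) * P_n
    V = np.zeros((ele.shape[0], src.shape[0]))
    P_prev = np.ones_like(cosg)  # P_0
    P_curr = cosg.copy()  # P_1
    for n in range(1, n_terms + 1):
        coeff = g[n] * n * bu ** (n - 1)  # per source
        V += coeff[None, :] * P_curr
        # advance recurrence to P_{n+1}
        P_next = ((2 * n + 1) * cosg * P_curr - n * P_prev) / (n + 1)
        P_prev, P_curr = P_curr, P_next
    V /= 4.0 * np.pi * sigma1 * (r3 * 1e-3) ** 2  # SI scaling (r3 in metres)
    return V


def build_source_grid(
    roi_positions_mm: np.ndarray,
    n_extra: int = 30,
    seed: int | np.random.Generator = 0,
    min_radius: float = 25.0,
    max_radius: float = 78.0,
    min_separation: float = 12.0,
) -> np.ndarray:
    """Source grid: the ROI centres plus ``n_extra`` random interior nodes.

    Extra nodes are rejection-sampled in the upper part of the brain shell
    (z > -30 mm, sphere frame) at least ``min_separation`` mm from every
    existing node, emulating a sparse cortical grid.  Positions returned in
    MNI-style mm (same frame as the ROI table).
    """
    rng = np.random.default_rng(seed)
    pts = [np.atleast_2d(np.asarray(roi_positions_mm, dtype=float))]
    centred = pts[0] - MNI_SPHERE_CENTER
    existing = list(centred)
    added = 0
    tries = 0
    while added < n_extra and tries < 20000:
        tries += 1
        p = rng.uniform(-max_radius, max_radius, size=3)
        r = np.linalg.norm(p)
        if not (min_radius <= r <= max_radius) or p[2] < -30.0:
            continue
        if existing and np.min(np.linalg.norm(np.array(existing) - p, axis=1)) < min_separation:
            continue
        existing.append(p)
        pts.append((p + MNI_SPHERE_CENTER)[None, :])
        added += 1
    return np.vstack(pts)


def gen_leadfield(
    source_positions_mm: np.ndarray,
    channel_labels: tuple[str, ...] = CHANNELS_24,
    radii=DEFAULT_RADII,
    conductivities=DEFAULT_CONDUCTIVITIES,
    n_terms: int = 120,
) -> Leadfield:
    """Three-shell spherical leadfield for radial dipoles at the given positions.

    ``source_positions_mm`` are MNI-style coordinates; they are shifted into
    the sphere frame by :data:`MNI_SPHERE_CENTER` before evaluation.
    """
    src = np.atleast_2d(np.asarray(source_positions_mm, dtype=float))
    ele = montage_positions(channel_labels, scalp_radius=radii[2])
    gain = radial_dipole_potentials(
        src - MNI_SPHERE_CENTER, ele, radii=radii, conductivities=conductivities, n_terms=n_terms
    )
    lf = Leadfield(
        gain=gain,
        source_positions=src,
        channel_labels=tuple(channel_labels),
        channel_positions=ele,
        radii=tuple(radii),
        conductivities=tuple(conductivities),
        full_column_rank=bool(np.linalg.matrix_rank(gain) == src.shape[0]),
    )
    lf.validate()
    return lf
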