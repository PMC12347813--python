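"""Group comparison of connectivity: effect-size screening with exclusivity.

For every ROI pair (edge) and band, depressed vs non-depressed LLC values
(groups defined per SDS subtype) are compared with a pooled-variance
two-sample t test; the effect size is Cohen's d with pooled n-1 standard
deviation, signed depressed - non_depressed.  Edges with |d| >= 0.2 are
flagged as candidate differences; an edge flagged under two or more
subtypes in the same band is discarded everywhere (cross-subtype
exclusivity), so each surviving edge characterises exactly one subtype.
Counts per subtype x band x direction form the headline table; signed
18 x 18 indicator matrices and their DMN/ECN/SAL network-pair aggregates
mirror the connectivity figures.  Family-wise corrected p values come from
a max-|t| label permutation (add-one convention) and are reported as
adjunct evidence, not the screening criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

D_THRESHOLD = 0.2
D_GT_ND = "D_gt_ND"
D_LT_ND = "D_lt_ND"


@dataclass(frozen=True)
class EdgeComparison:
    """One edge's group comparison under one subtype and band."""

    subtype: str
    band: str
    edge: tuple[int, int]  # 0-based ROI indices, i < j
    mean_depressed: float
    mean_non_depressed: float
    t_statistic: float
    p_value: float
    cohens_d: float
    direction: str | None
    flagged: bool


def edge_ttest(values_depressed: np.ndarray, values_non_depressed: np.ndarray):
    """Pooled-variance Student t, two-tailed p, and signed Cohen's d.

    Returns ``(t, p, d)``; all NaN when the pooled variance is zero
    (comparison undefined).  Requires at least two values per group.
    """
    x = np.asarray(values_depressed, dtype=float)
    y = np.asarray(values_non_depressed, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two values per group")
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 <= 0:
        return float("nan"), float("nan"), float("nan")
    diff = x.mean() - y.mean()
    t = diff / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * stats.t.sf(abs(t), nx + ny - 2)
    d = diff / np.sqrt(sp2)
    return float(t), float(p), float(d)


def _edges(n_rois: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n_rois) for j in range(i + 1, n_rois)]


def compare_edges(
    edge_values: np.ndarray,
    depressed_mask: np.ndarray,
    subtype: str,
    band: str,
    n_rois: int = 18,
    d_threshold: float = D_THRESHOLD,
) -> list[EdgeComparison]:
    """Compare all edges for one subtype and band.

    ``edge_values`` is (n_participants, n_edges) in upper-triangle order;
    ``depressed_mask`` a boolean participant vector.  Edges with missing
    (NaN) values for any participant are reported undefined and unflagged.
    """
    V = np.asarray(edge_values, dtype=float)
    dep = np.asarray(depressed_mask, dtype=bool)
    if dep.sum() < 2 or (~dep).sum() < 2:
        raise ValueError("need at least two participants per group")
    edges = _edges(n_rois)
    if V.shape[1] != len(edges):
        raise ValueError(f"expected {len(edges)} edge columns, got {V.shape[1]}")
    out = []
    for k, edge in enumerate(edges):
        col = V[:, k]
        if np.isnan(col).any():
            out.append(
                EdgeComparison(subtype, band, edge, float("nan"), float("nan"),
                               float("nan"), float("nan"), float("nan"), None, False)
            )
            continue
        t, p, d = edge_ttest(col[dep], col[~dep])
        if np.isnan(d):
            direction, flagged = None, False
        else:
            direction = D_GT_ND if d > 0 else D_LT_ND
            flagged = abs(d) >= d_threshold
        out.append(
            EdgeComparison(subtype, band, edge, float(col[dep].mean()),
                           float(col[~dep].mean()), t, p, d, direction, flagged)
        )
    return out


def flag_edges(comparisons: Sequence[EdgeComparison], d_threshold: float = D_THRESHOLD):
    """Flagged (edge, direction) pairs at |d| >= threshold ("at least 0.2")."""
    out = []
    for c in comparisons:
        if not np.isnan(c.cohens_d) and abs(c.cohens_d) >= d_threshold:
            out.append((c.edge, D_GT_ND if c.cohens_d > 0 else D_LT_ND))
    return out


@dataclass
class ExclusiveEdgeSet:
    """Survivors of the exclusivity cross-check: subtype -> [(edge, direction)]."""

    band: str
    by_subtype: dict[str, list[tuple[tuple[int, int], str]]] = field(default_factory=dict)


def exclusivity_filter(
    flagged_by_subtype: Mapping[str, Sequence[tuple[tuple[int, int], str]]], band: str
) -> ExclusiveEdgeSet:
    """Keep only edges flagged under exactly one subtype (per band).

    The identity cross-checked is the (edge, band) instance -- direction is
    *not* part of it, so an edge flagged in two subtypes with opposite
    directions is still removed from both.
    """
    counts: dict[tuple[int, int], int] = {}
    for flags in flagged_by_subtype.values():
        for edge, _ in flags:
            counts[edge] = counts.get(edge, 0) + 1
    result = ExclusiveEdgeSet(band=band)
    for subtype, flags in flagged_by_subtype.items():
        result.by_subtype[subtype] = [
            (edge, direction) for edge, direction in flags if counts[edge] == 1
        ]
    return result


@dataclass
class CountTable:
    """Per subtype x band counts of exclusive edges by direction + best p."""

    table: pd.DataFrame  # index: direction; columns: (subtype, band)


def count_and_matrices(
    exclusive: Mapping[str, ExclusiveEdgeSet],
    rois,
    best_p: Mapping[tuple[str, str], float] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], np.ndarray], pd.DataFrame]:
    """Count table, signed 18x18 indicator matrices, and network aggregates.

    ``exclusive`` maps band name -> :class:`ExclusiveEdgeSet`.  Returns
    ``(counts, matrices, network_counts)`` where ``matrices[(subtype, band)]``
    holds +1 for depressed > non-depressed, -1 for the reverse, and
    ``network_counts`` aggregates signed edges over DMN/ECN/SAL pairs.
    """
    n_rois = len(rois)
    families = [r.network_family for r in rois]
    subtypes = sorted({s for es in exclusive.values() for s in es.by_subtype})
    rows = []
    matrices: dict[tuple[str, str], np.ndarray] = {}
    net_rows = []
    for band, es in exclusive.items():
        for subtype in subtypes:
            flags = es.by_subtype.get(subtype, [])
            mat = np.zeros((n_rois, n_rois), dtype=int)
            for (i, j), direction in flags:
                sign = 1 if direction == D_GT_ND else -1
                mat[i, j] = sign
                mat[j, i] = sign
            matrices[(subtype, band)] = mat
            n_gt = sum(1 for _, d in flags if d == D_GT_ND)
            n_lt = sum(1 for _, d in flags if d == D_LT_ND)
            row = {"subtype": subtype, "band": band, "D_gt_ND": n_gt, "D_lt_ND": n_lt}
            if best_p is not None and (subtype, band) in best_p:
                row["best_p"] = best_p[(subtype, band)]
            rows.append(row)
            for fam_a, fam_b in combinations_with_self(("DMN", "ECN", "SAL")):
                cnt_gt = cnt_lt = 0
                for (i, j), direction in flags:
                    pair = tuple(sorted((families[i], families[j])))
                    if pair == tuple(sorted((fam_a, fam_b))):
                        if direction == D_GT_ND:
                            cnt_gt += 1
                        else:
                            cnt_lt += 1
                net_rows.append(
                    {"subtype": subtype, "band": band, "network_a": fam_a,
                     "network_b": fam_b, "D_gt_ND": cnt_gt, "D_lt_ND": cnt_lt}
                )
    counts = pd.DataFrame(rows)
    network_counts = pd.DataFrame(net_rows)
    return counts, matrices, network_counts


def combinations_with_self(items):
    for i, a in enumerate(items):
        for b in items[i:]:
            yield a, b


def permutation_threshold(
    edge_values: np.ndarray,
    depressed_mask: np.ndarray,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, float]:
    """Max-|t| permutation-corrected p per edge and the best (minimum) p.

    Group labels are permuted ``n_perm`` times; the null distribution is
    the maximum |t| over all edges per permutation, and each edge's
    corrected p is ``(1 + #{max|t|_perm >= |t|_obs}) / (n_perm + 1)``
    (add-one convention, so p is never zero).  Edges with undefined t
    (NaN columns) receive corrected p = NaN.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    V = np.asarray(edge_values, dtype=float)
    dep = np.asarray(depressed_mask, dtype=bool)
    n = V.shape[0]
    n1, n2 = int(dep.sum()), int((~dep).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("degenerate group labels for permutation test")
    rng = np.random.default_rng(seed)

    def tstats(mask: np.ndarray) -> np.ndarray:
        g1 = V[mask]
        g2 = V[~mask]
        m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
        v1 = g1.var(axis=0, ddof=1)
        v2 = g2.var(axis=0, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))

    t_obs = np.abs(tstats(dep))
    max_null = np.empty(n_perm)
    idx = np.arange(n)
    for b in range(n_perm):
        perm = rng.permutation(idx)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n1]] = True
        with np.errstate(invalid="ignore"):
            max_null[b] = np.nanmax(np.abs(tstats(mask)))
    with np.errstate(invalid="ignore"):
        exceed = (max_null[None, :] >= t_obs[:, None]).sum(axis=1)
    p_corr = (1.0 + exceed) / (n_perm + 1.0)
    p_corr = np.where(np.isnan(t_obs), np.nan, p_corr)
    best = float(np.nanmin(p_corr)) if np.isfinite(p_corr).any() else float("nan")
    return p_corr, best


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(F * df1 / (F * df1 + df2))


def t_to_p(t: float, df: float) -> float:
    """Two-tailed p from a t statistic."""
    if df <= 0:
        raise ValueError("df must be positive")
    return float(2.0 * stats.t.sf(abs(t), df))


def comparisons_frame(comparisons: Sequence[EdgeComparison], rois=None) -> pd.DataFrame:
    """Edge comparisons as a tidy long table."""
    rows = []
    for c in comparisons:
        row = {
            "subtype": c.subtype, "band": c.band,
            "roi_i": c.edge[0], "roi_j": c.edge[1],
            "mean_depressed": c.mean_depressed,
            "mean_non_depressed": c.mean_non_depressed,
            "t": c.t_statistic, "p": c.p_value, "cohens_d": c.cohens_d,
            "direction": c.direction, "flagged": c.flagged,
        }
        if rois is not None:
            row["roi_i_label"] = rois[c.edge[0]].network
            row["roi_j_label"] = rois[c.edge[1]].network
        rows.append(row)
    return pd.DataFrame(rows)
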