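"""Zung Self-Rating Depression Scale (SDS) scoring and subtype grouping.

The SDS has 20 items rated 1-4 for symptom frequency ("None or a little of
the time" = 1 ... "Most or all of the time" = 4).  Ten items are positively
worded and reverse-keyed (scored ``5 - raw``), so the scored total runs from
20 (no symptoms) to 80 (maximal symptoms); a total of 40 or above is the
conventional cutoff for clinically significant depression.

Four symptom subtypes are scored as the *mean* of their scored items, so
that subtypes with different item counts are comparable:

========== ============================
subtype    SDS items
========== ============================
mood       1, 3, 14, 15, 17, 19
anhedonia  5, 6, 18, 20
cognitive  11, 12, 16
somatic    4, 7, 8, 9, 10, 13
========== ============================

Participants are split into depressed / non-depressed groups *per subtype*
by comparing each subtype mean score with its cohort-mean cutoff; ties land
on the depressed side, mirroring the "40 or above" convention for the full
scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

N_ITEMS = 20

#: Positively worded items, reverse-keyed (standard instrument convention).
REVERSE_KEYED_ITEMS: frozenset[int] = frozenset({2, 5, 6, 11, 12, 14, 16, 17, 18, 20})

#: Item membership of the four symptom subtypes.
SUBTYPE_ITEMS: dict[str, tuple[int, ...]] = {
    "mood": (1, 3, 14, 15, 17, 19),
    "anhedonia": (5, 6, 18, 20),
    "cognitive": (11, 12, 16),
    "somatic": (4, 7, 8, 9, 10, 13),
}

SUBTYPES: tuple[str, ...] = tuple(SUBTYPE_ITEMS)

DEPRESSED = "depressed"
NON_DEPRESSED = "non_depressed"


class SDSValidationError(ValueError):
    """Raised for malformed SDS responses (missing items, out-of-range values)."""


@dataclass(frozen=True)
class SDSRecord:
    """One participant's raw item responses plus demographics.

    ``raw_responses`` maps item number (1-20) to the raw 1-4 response, on the
    questionnaire scale, i.e. *before* reverse-keying.
    """

    participant_id: str
    raw_responses: Mapping[int, int]
    age: float | None = None
    sex: str | None = None

    def validate(self) -> None:
        items = set(self.raw_responses)
        missing = set(range(1, N_ITEMS + 1)) - items
        if missing:
            raise SDSValidationError(
                f"participant {self.participant_id}: missing items {sorted(missing)}"
            )
        extra = items - set(range(1, N_ITEMS + 1))
        if extra:
            raise SDSValidationError(
                f"participant {self.participant_id}: unexpected items {sorted(extra)}"
            )
        for item, value in self.raw_responses.items():
            if value not in (1, 2, 3, 4):
                raise SDSValidationError(
                    f"participant {self.participant_id}: item {item} response {value!r} "
                    "outside {1, 2, 3, 4}"
                )


@dataclass(frozen=True)
class SDSScore:
    """Scored SDS: per-item scored values, total, and the four subtype means."""

    participant_id: str
    scored_items: Mapping[int, int]
    total: int
    subtype_means: Mapping[str, float]


@dataclass(frozen=True)
class GroupAssignment:
    """Per-subtype depressed / non-depressed labels for one participant."""

    participant_id: str
    labels: Mapping[str, str]
    cutoffs_used: Mapping[str, float]


def default_keying() -> dict[int, str]:
    """Item -> {'direct', 'reverse'} map under the standard SDS convention."""
    return {
        i: ("reverse" if i in REVERSE_KEYED_ITEMS else "direct")
        for i in range(1, N_ITEMS + 1)
    }


def score_sds(record: SDSRecord, keying: Mapping[int, str] | None = None) -> SDSScore:
    """Score one SDS record: reverse-key, total, and subtype means.

    Reverse-keyed items are scored ``5 - raw``; direct items keep their raw
    value.  No imputation is performed: a missing or out-of-range response
    raises :class:`SDSValidationError`.
    """
    record.validate()
    if keying is None:
        keying = default_keying()
    if set(keying) != set(range(1, N_ITEMS + 1)):
        raise SDSValidationError("keying must cover items 1..20 exactly")
    n_reverse = sum(1 for v in keying.values() if v == "reverse")
    if n_reverse != 10:
        raise SDSValidationError(
            f"keying must mark exactly ten reverse-keyed items, got {n_reverse}"
        )
    scored: dict[int, int] = {}
    for item in range(1, N_ITEMS + 1):
        raw = record.raw_responses[item]
        scored[item] = 5 - raw if keying[item] == "reverse" else raw
    total = int(sum(scored.values()))
    subtype_means = {
        name: float(np.mean([scored[i] for i in items]))
        for name, items in SUBTYPE_ITEMS.items()
    }
    return SDSScore(
        participant_id=record.participant_id,
        scored_items=scored,
        total=total,
        subtype_means=subtype_means,
    )


def score_cohort(
    records: Iterable[SDSRecord], keying: Mapping[int, str] | None = None
) -> list[SDSScore]:
    """Score every record, dropping (with a warning) any invalid record."""
    scores = []
    for rec in records:
        try:
            scores.append(score_sds(rec, keying))
        except SDSValidationError as err:
            logger.warning("excluding record: %s", err)
    return scores


def assign_groups(scores: Sequence[SDSScore]) -> list[GroupAssignment]:
    """Split the cohort at the subtype-mean cutoffs, independently per subtype.

    For each subtype the cutoff is the cohort mean of that subtype's mean
    scores; a participant is labelled depressed iff their subtype mean is
    greater than *or equal to* the cutoff.
    """
    if len(scores) < 2:
        raise ValueError("need at least two participants to form groups")
    cutoffs = {
        name: float(np.mean([s.subtype_means[name] for s in scores]))
        for name in SUBTYPES
    }
    assignments = []
    for s in scores:
        labels = {
            name: (DEPRESSED if s.subtype_means[name] >= cutoffs[name] else NON_DEPRESSED)
            for name in SUBTYPES
        }
        assignments.append(
            GroupAssignment(participant_id=s.participant_id, labels=labels, cutoffs_used=cutoffs)
        )
    return assignments


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha for a participants x items matrix of scored responses.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(total score)),
    with unbiased (n-1) variances.  Raises ``ValueError`` when the total
    score has zero variance (alpha undefined).
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 participants and 2 items")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def demographic_screen(
    scores: Sequence[SDSScore],
    age: Sequence[float],
    sex: Sequence[str],
    extra_columns: Mapping[str, Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Spearman correlations of age and sex against SDS scores (and extras).

    ``sex`` is coded 0/1 in the order the category labels first appear.
    Returns a tidy frame with columns ``covariate, variable, rho, p``;
    correlations against a constant column are reported as NaN.
    """
    n = len(scores)
    if len(age) != n or len(sex) != n:
        raise ValueError("age and sex must match the number of scored participants")
    sex_levels: dict[str, int] = {}
    sex_coded = np.array([sex_levels.setdefault(s, len(sex_levels)) for s in sex], dtype=float)
    if len(sex_levels) > 2:
        raise ValueError(f"sex has more than two levels: {sorted(sex_levels)}")
    age_arr = np.asarray(age, dtype=float)

    variables: dict[str, np.ndarray] = {
        "sds_total": np.array([s.total for s in scores], dtype=float)
    }
    for name in SUBTYPES:
        variables[f"sds_{name}"] = np.array([s.subtype_means[name] for s in scores])
    if extra_columns:
        for name, col in extra_columns.items():
            variables[name] = np.asarray(col, dtype=float)

    rows = []
    for cov_name, cov in (("age", age_arr), ("sex", sex_coded)):
        for var_name, var in variables.items():
            rho, p = _spearman(cov, var)
            rows.append({"covariate": cov_name, "variable": var_name, "rho": rho, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delimited-table I/O

def read_sds_table(path) -> list[SDSRecord]:
    """Read a CSV/TSV with columns participant_id, item_1..item_20, age, sex."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"participant_id", *{f"item_{i}" for i in range(1, N_ITEMS + 1)}}
    missing = required - set(df.columns)
    if missing:
        raise SDSValidationError(f"missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        responses = {i: int(row[f"item_{i}"]) for i in range(1, N_ITEMS + 1)}
        records.append(
            SDSRecord(
                participant_id=str(row["participant_id"]),
                raw_responses=responses,
                age=float(row["age"]) if "age" in df.columns else None,
                sex=str(row["sex"]) if "sex" in df.columns else None,
            )
        )
    return records


def scores_frame(scores: Sequence[SDSScore]) -> pd.DataFrame:
    """Scores as a tidy table (one row per participant)."""
    rows = []
    for s in scores:
        row = {"participant_id": s.participant_id, "sds_total": s.total}
        row.update({f"sds_{k}": v for k, v in s.subtype_means.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def assignments_frame(assignments: Sequence[GroupAssignment]) -> pd.DataFrame:
    """Group labels as a tidy table (one row per participant)."""
    rows = []
    for a in assignments:
        row = {"participant_id": a.participant_id}
        row.update({f"group_{k}": v for k, v in a.labels.items()})
        rows.append(row)
    return pd.DataFrame(rows)
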