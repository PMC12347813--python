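"""SDS scoring, subtype means, group cutoffs, reliability, demographics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from depnet import sds
from depnet.sds import (
    DEPRESSED,
    NON_DEPRESSED,
    REVERSE_KEYED_ITEMS,
    SDSRecord,
    SDSScore,
    SDSValidationError,
    SUBTYPE_ITEMS,
    SUBTYPES,
)


def make_record(level_fn, pid="p"):
    """Build a record whose *symptom level* per item is level_fn(item); the
    raw response is inverted for reverse-keyed (positively worded) items."""
    responses = {
        i: (5 - level_fn(i) if i in REVERSE_KEYED_ITEMS else level_fn(i))
        for i in range(1, 21)
    }
    return SDSRecord(participant_id=pid, raw_responses=responses)


class TestScoring:
    @pytest.mark.parametrize(
        "level, total, mean",
        [(1, 20, 1.0), (4, 80, 4.0), (2, 40, 2.0), (3, 60, 3.0)],
    )
    def test_uniform_symptom_levels(self, level, total, mean):
        score = sds.score_sds(make_record(lambda i: level))
        assert score.total == total
        assert all(m == pytest.approx(mean) for m in score.subtype_means.values())

    def test_hand_tally_mixed_profile(self):
        # raw 2 on negatively worded items, raw 3 on positively worded items:
        # every item scores 2 after reverse-keying
        raw = {i: (3 if i in REVERSE_KEYED_ITEMS else 2) for i in range(1, 21)}
        score = sds.score_sds(SDSRecord("p", raw))
        assert score.total == 40
        assert all(m == pytest.approx(2.0) for m in score.subtype_means.values())

    def test_subtype_means_follow_item_groups(self):
        # symptom level = 4 on mood items only, 1 elsewhere
        score = sds.score_sds(make_record(lambda i: 4 if i in SUBTYPE_ITEMS["mood"] else 1))
        assert score.subtype_means["mood"] == pytest.approx(4.0)
        for other in ("anhedonia", "cognitive", "somatic"):
            assert score.subtype_means[other] == pytest.approx(1.0)

    def test_missing_item_rejected_without_imputation(self):
        responses = {i: 2 for i in range(1, 20)}  # item 20 missing
        with pytest.raises(SDSValidationError, match="missing items"):
            sds.score_sds(SDSRecord("p", responses))

    def test_out_of_range_response_rejected(self):
        responses = {i: 2 for i in range(1, 21)}
        responses[7] = 5
        with pytest.raises(SDSValidationError, match="outside"):
            sds.score_sds(SDSRecord("p", responses))

    def test_keying_must_have_ten_reverse_items(self):
        keying = {i: "direct" for i in range(1, 21)}
        with pytest.raises(SDSValidationError, match="ten reverse"):
            sds.score_sds(make_record(lambda i: 2), keying)

    @given(
        st.lists(st.integers(min_value=1, max_value=4), min_size=20, max_size=20)
    )
    def test_bounds_invariants(self, levels):
        responses = dict(zip(range(1, 21), levels))
        score = sds.score_sds(SDSRecord("p", responses))
        assert 20 <= score.total <= 80
        assert score.total == sum(score.scored_items.values())
        for m in score.subtype_means.values():
            assert 1.0 <= m <= 4.0

    @given(st.lists(st.integers(min_value=1, max_value=4), min_size=20, max_size=20))
    def test_total_invariant_under_item_order(self, levels):
        responses = dict(zip(range(1, 21), levels))
        shuffled = dict(sorted(responses.items(), key=lambda kv: -kv[0]))
        a = sds.score_sds(SDSRecord("p", responses))
        b = sds.score_sds(SDSRecord("p", shuffled))
        assert a.total == b.total and a.subtype_means == b.subtype_means


def fake_score(pid, value):
    return SDSScore(pid, {i: 2 for i in range(1, 21)}, 40,
                    {s: value for s in SUBTYPES})


class TestGroupAssignment:
    def test_tie_lands_depressed(self):
        scores = [fake_score(f"p{k}", v) for k, v in enumerate([1.0, 2.0, 3.0])]
        labels = [a.labels["mood"] for a in sds.assign_groups(scores)]
        assert labels == [NON_DEPRESSED, DEPRESSED, DEPRESSED]

    def test_identical_cohort_all_depressed(self):
        scores = [fake_score(f"p{k}", 2.5) for k in range(5)]
        assignments = sds.assign_groups(scores)
        assert all(a.labels[s] == DEPRESSED for a in assignments for s in SUBTYPES)

    def test_shift_equivariance(self):
        vals = [1.1, 1.9, 2.4, 3.0, 1.4]
        base = sds.assign_groups([fake_score(f"p{k}", v) for k, v in enumerate(vals)])
        shifted = sds.assign_groups(
            [fake_score(f"p{k}", v + 0.7) for k, v in enumerate(vals)]
        )
        assert [a.labels for a in base] == [a.labels for a in shifted]

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            sds.assign_groups([fake_score("p0", 2.0)])

    def test_two_component_mixture_split_recovered(self, rng):
        # 60 low-severity and 40 high-severity participants; the cohort-mean
        # cutoff should land between the modes and recover the mixture split
        truth = np.array([0] * 60 + [1] * 40)
        scores = []
        for k, hi in enumerate(truth):
            base = 3 if hi else 1
            level = lambda i: int(np.clip(base + rng.integers(-1, 2), 1, 4))
            scores.append(sds.score_sds(make_record(level, pid=f"p{k}")))
        n_dep = sum(
            a.labels["mood"] == DEPRESSED for a in sds.assign_groups(scores)
        )
        assert abs(n_dep - 40) <= 5


class TestCronbachAlpha:
    def test_perfectly_correlated_items(self):
        x = np.arange(10.0)
        assert sds.cronbach_alpha(np.c_[x, x]) == pytest.approx(1.0)

    def test_independent_items_near_zero(self, rng):
        X = rng.normal(size=(10000, 20))
        assert abs(sds.cronbach_alpha(X)) < 0.05

    def test_matches_direct_formula_on_toy_matrix(self):
        X = np.array([[1, 2, 3], [2, 4, 5], [3, 5, 7], [4, 4, 8]], dtype=float)
        # independent spreadsheet-style evaluation
        k = 3
        item_vars = [np.var(X[:, j], ddof=1) for j in range(k)]
        total_var = np.var(X.sum(axis=1), ddof=1)
        expected = k / (k - 1) * (1 - sum(item_vars) / total_var)
        assert sds.cronbach_alpha(X) == pytest.approx(expected, abs=1e-12)

    def test_zero_total_variance_signalled(self):
        X = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])  # totals constant
        with pytest.raises(ValueError, match="alpha undefined"):
            sds.cronbach_alpha(X)


class TestDemographicScreen:
    def _scores(self, totals):
        return [
            SDSScore(f"p{k}", {i: 2 for i in range(1, 21)}, int(t),
                     {s: 2.0 for s in SUBTYPES})
            for k, t in enumerate(totals)
        ]

    def test_age_identical_to_total(self):
        totals = [25, 30, 40, 55, 60]
        df = sds.demographic_screen(self._scores(totals), totals, ["F", "M", "F", "M", "F"])
        row = df[(df.covariate == "age") & (df.variable == "sds_total")].iloc[0]
        assert row.rho == pytest.approx(1.0)

    def test_reversed_ranks(self):
        totals = [25, 30, 40, 55, 60]
        df = sds.demographic_screen(self._scores(totals), totals[::-1],
                                    ["F", "M", "F", "M", "F"])
        row = df[(df.covariate == "age") & (df.variable == "sds_total")].iloc[0]
        assert row.rho == pytest.approx(-1.0)

    def test_independent_age_small_rho(self, rng):
        totals = rng.integers(20, 80, size=1000)
        ages = rng.uniform(18, 75, size=1000)
        sexes = rng.choice(["F", "M"], size=1000)
        df = sds.demographic_screen(self._scores(totals), ages, list(sexes))
        row = df[(df.covariate == "age") & (df.variable == "sds_total")].iloc[0]
        assert abs(row.rho) < 0.08 and row.p > 0.001

    def test_constant_column_reported_nan(self):
        totals = [30, 30, 30, 30]
        df = sds.demographic_screen(self._scores(totals), [40, 50, 60, 70],
                                    ["F", "F", "M", "M"])
        row = df[(df.covariate == "age") & (df.variable == "sds_total")].iloc[0]
        assert np.isnan(row.rho)


def test_table_roundtrip(tmp_path):
    from depnet import simulate

    records, _ = simulate.gen_sds_cohort(simulate.CohortSpec(n_participants=7, seed=3))
    path = tmp_path / "cohort.csv"
    simulate.cohort_to_csv(records, path)
    back = sds.read_sds_table(path)
    assert [r.raw_responses for r in back] == [r.raw_responses for r in records]
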