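"""Synthetic cohort and EEG generators: calibration, geometry, bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from depnet import connectivity, headmodel, inverse, preprocess, sds, simulate
from depnet.simulate import CohortSpec, CouplingEdge, SimEEGSpec


def subtype_score_matrix(records):
    scores = sds.score_cohort(records)
    return np.array(
        [[s.subtype_means[name] for name in sds.SUBTYPES] for s in scores]
    )


class TestCohortGenerator:
    def test_pure_general_factor_gives_identical_rankings(self):
        spec = CohortSpec(n_participants=200, general_factor_loading=1.0,
                          subtype_specific_sd=1e-12, item_noise_sd=1e-12, seed=1)
        M = subtype_score_matrix(simulate.gen_sds_cohort(spec)[0])
        for a in range(4):
            for b in range(a + 1, 4):
                rho = stats.spearmanr(M[:, a], M[:, b]).statistic
                assert rho == pytest.approx(1.0)

    def test_no_general_factor_gives_uncorrelated_subtypes(self):
        spec = CohortSpec(n_participants=5000, general_factor_loading=0.0, seed=2)
        M = subtype_score_matrix(simulate.gen_sds_cohort(spec)[0])
        C = np.corrcoef(M.T)
        off = C[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.05)

    def test_default_calibration_matches_observed_range(self):
        # packaged defaults must land inter-subtype correlations in the
        # range reported for community samples (0.55-0.90 at n=100)
        spec = CohortSpec(n_participants=100, seed=3)
        M = subtype_score_matrix(simulate.gen_sds_cohort(spec)[0])
        off = np.corrcoef(M.T)[np.triu_indices(4, 1)]
        assert np.all((off > 0.55) & (off < 0.90))

    def test_same_seed_reproduces_cohort_exactly(self):
        a, ta = simulate.gen_sds_cohort(CohortSpec(n_participants=20, seed=9))
        b, tb = simulate.gen_sds_cohort(CohortSpec(n_participants=20, seed=9))
        assert [r.raw_responses for r in a] == [r.raw_responses for r in b]
        assert ta.severities.equals(tb.severities)

    def test_nonincreasing_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            simulate.gen_sds_cohort(
                CohortSpec(ordinal_thresholds=(0.5, 0.5, 1.0))
            )

    def test_truth_labels_split_at_severity_mean(self):
        records, truth = simulate.gen_sds_cohort(CohortSpec(n_participants=50, seed=4))
        sev = truth.severities["mood"].to_numpy()
        labels = truth.labels["mood"].to_numpy()
        assert np.array_equal(labels == sds.DEPRESSED, sev >= sev.mean())


class TestLeadfield:
    def test_matches_homogeneous_sphere_closed_form(self, rng):
        # with equal shell conductivities the model must reduce to the
        # single-sphere textbook series V = q/(4 pi sigma R^2)
        #   * sum (2n+1)(b/R)^(n-1) P_n(cos gamma)
        from numpy.polynomial.legendre import legval

        R, sigma = 100.0, 0.33
        src = rng.normal(size=(5, 3))
        src *= (rng.uniform(30, 70, 5) / np.linalg.norm(src, axis=1))[:, None]
        ele = rng.normal(size=(5, 3))
        ele *= (R / np.linalg.norm(ele, axis=1))[:, None]
        V = headmodel.radial_dipole_potentials(
            src, ele, radii=(87, 92, R), conductivities=(sigma, sigma, sigma),
            n_terms=150,
        )
        b = np.linalg.norm(src, axis=1)
        cosg = (ele / R) @ (src / b[:, None]).T
        Vo = np.zeros((5, 5))
        for n in range(1, 151):
            c = np.zeros(n + 1)
            c[n] = 1
            Vo += (2 * n + 1) * (b / R) ** (n - 1) * legval(cosg, c)
        Vo /= 4 * np.pi * sigma * (R * 1e-3) ** 2
        assert np.max(np.abs(V - Vo)) < 1e-9 * np.max(np.abs(Vo))

    def test_sensor_over_radial_source_sees_largest_gain(self):
        ele = headmodel.montage_positions()
        # place the source 30 mm beneath the O1 electrode
        direction = ele[22] / np.linalg.norm(ele[22])
        V = headmodel.radial_dipole_potentials(direction[None, :] * 70.0, ele)
        assert headmodel.CHANNELS_24[int(np.argmax(np.abs(V[:, 0])))] == "O1"

    def test_gain_is_linear_in_source_moment(self, leadfield50, rng):
        s = rng.normal(size=(50, 100))
        eeg1 = leadfield50.gain @ s
        eeg2 = leadfield50.gain @ (2 * s)
        assert np.allclose(eeg2, 2 * eeg1)

    def test_grid_contains_roi_centres(self, grid50, rois):
        assert np.allclose(grid50[:18], inverse.roi_positions(rois))

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(headmodel.HeadModelError):
            headmodel.radial_dipole_potentials(
                np.array([[0, 0, 50.0]]), np.array([[0, 0, 100.0]]),
                radii=(92, 87, 100),
            )
        with pytest.raises(headmodel.HeadModelError, match="centre"):
            headmodel.radial_dipole_potentials(
                np.array([[0.0, 0, 0]]), np.array([[0, 0, 100.0]])
            )

    def test_underdetermined_rank_reported(self, leadfield50):
        assert leadfield50.gain.shape == (24, 50)
        assert leadfield50.full_column_rank is False  # 50 sources, 24 channels


def source_llc(spec, seed, band="alpha", label=sds.NON_DEPRESSED, allow_zero_lag=False):
    """LLC matrix computed directly on generated source series (no scalp)."""
    src = simulate.gen_sources(spec, group_label=label, seed=seed,
                               _allow_zero_lag=allow_zero_lag)
    n_ep = int(spec.duration // 4)
    epochs = src[:, : n_ep * 4000].reshape(src.shape[0], n_ep, 4000).transpose(1, 0, 2)
    conn = connectivity.participant_connectivity(epochs, spec.sampling_rate)
    return conn[band].matrix


class TestSourceGenerator:
    def test_uncoupled_sources_have_negligible_llc(self):
        spec = SimEEGSpec(duration=180.0)
        llc = source_llc(spec, seed=11)
        vals = llc[np.triu_indices(18, 1)]
        assert np.nanmax(vals) < 0.05

    def test_coupled_alpha_pair_tops_all_uncoupled_pairs(self):
        spec = SimEEGSpec(
            coupling_edges=(CouplingEdge(roi_i=3, roi_j=12, band="alpha",
                                         lag_ms=25.0, strength=0.7),)
        )
        llc = source_llc(spec, seed=12)
        vals = llc[np.triu_indices(18, 1)]
        assert llc[2, 11] == np.nanmax(vals)
        # faithfulness: no elevation in the other band
        llc_beta = source_llc(spec, seed=12, band="beta")
        assert llc_beta[2, 11] < 0.05

    def test_zero_lag_coupling_yields_no_lagged_connectivity(self):
        spec = SimEEGSpec(
            coupling_edges=(CouplingEdge(roi_i=3, roi_j=12, band="alpha",
                                         lag_ms=0.0, strength=0.9),)
        )
        llc = source_llc(spec, seed=13, allow_zero_lag=True)
        assert llc[2, 11] < 0.05  # high ordinary coherence, no lagged share

    def test_zero_lag_rejected_without_hook(self):
        spec = SimEEGSpec(
            coupling_edges=(CouplingEdge(roi_i=1, roi_j=2, band="alpha", lag_ms=0.0),)
        )
        with pytest.raises(ValueError, match="lag"):
            simulate.gen_sources(spec, seed=1)

    def test_same_seed_identical_sources(self):
        spec = SimEEGSpec(duration=8.0)
        a = simulate.gen_sources(spec, seed=5)
        b = simulate.gen_sources(spec, seed=5)
        assert np.array_equal(a, b)

    def test_depressed_group_gets_stronger_lagged_coupling(self):
        spec = SimEEGSpec(
            coupling_edges=(CouplingEdge(roi_i=1, roi_j=10, band="alpha",
                                         strength=0.4, group_contrast=0.5),)
        )
        # paired on the same seed: identical spectra, only the mixing weight
        # differs, so the depressed member's lagged coupling must be higher
        for s in range(40, 44):
            dep = source_llc(spec, seed=s, label=sds.DEPRESSED)[0, 9]
            non = source_llc(spec, seed=s, label=sds.NON_DEPRESSED)[0, 9]
            assert dep > non


class TestForwardAndArtifacts:
    def test_zero_sources_zero_noise_gives_zero_eeg(self, leadfield50):
        rec = simulate.forward_project(
            np.zeros((18, 1000)), leadfield50, noise_uv=0.0,
            source_indices=range(18),
        )
        assert not rec.samples.any()

    def test_planted_blinks_drive_epoch_rejection_bookkeeping(self, leadfield50):
        # quiet brain: the only +/-50 uV breaches are the planted blinks, so
        # rejected epochs must be exactly the artifact-contaminated windows
        spec = SimEEGSpec(duration=60.0, source_scale=0.002,
                          sensor_noise_uv=0.5, blink_rate_per_min=3.0,
                          pop_rate_per_min=0.0, burst_rate_per_min=0.0)
        src = simulate.gen_sources(spec, seed=21)
        rec = simulate.forward_project(src, leadfield50, noise_uv=spec.sensor_noise_uv,
                                       source_indices=range(18), seed=21)
        rec, log = simulate.inject_artifacts(rec, spec, leadfield50.channel_positions,
                                             seed=22)
        rec = preprocess.filter_chain(rec)
        eset = preprocess.reject_epochs(preprocess.make_epochs(rec))
        rejected = set(np.nonzero(~eset.keep_mask)[0])
        assert len(log.events) > 0
        assert rejected == log.contaminated_epochs(4.0, eset.n_epochs)

    def test_same_seed_identical_artifact_placement(self, leadfield50):
        spec = SimEEGSpec(duration=30.0)
        rec = preprocess.EEGRecording(
            channel_labels=headmodel.CHANNELS_24,
            samples=np.zeros((24, 30000)), sampling_rate=1000.0,
        )
        a, la = simulate.inject_artifacts(rec, spec, leadfield50.channel_positions, seed=8)
        b, lb = simulate.inject_artifacts(rec, spec, leadfield50.channel_positions, seed=8)
        assert np.array_equal(a.samples, b.samples)
        assert la.events == lb.events

    def test_blinks_are_frontal_weighted(self, leadfield50):
        spec = SimEEGSpec(duration=30.0, blink_rate_per_min=4.0,
                          pop_rate_per_min=0.0, burst_rate_per_min=0.0)
        rec = preprocess.EEGRecording(
            channel_labels=headmodel.CHANNELS_24,
            samples=np.zeros((24, 30000)), sampling_rate=1000.0,
        )
        out, log = simulate.inject_artifacts(rec, spec, leadfield50.channel_positions,
                                             seed=9)
        assert log.events
        amp = np.abs(out.samples).max(axis=1)
        frontal = [headmodel.CHANNELS_24.index(c) for c in ("FP1", "FP2")]
        occipital = [headmodel.CHANNELS_24.index(c) for c in ("O1", "O2")]
        assert amp[frontal].min() > 10 * max(amp[occipital].max(), 1e-9)


def test_recording_roundtrip(tmp_path, rng):
    rec = preprocess.EEGRecording(
        channel_labels=headmodel.CHANNELS_24,
        samples=rng.normal(size=(24, 500)), sampling_rate=1000.0,
    )
    simulate.save_recording(rec, tmp_path / "r")
    back = simulate.load_recording(tmp_path / "r")
    assert np.array_equal(back.samples, rec.samples)
    assert back.channel_labels == rec.channel_labels
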