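"""Synthetic cohort generator: determinism, ground truths, generative model."""

import math

import numpy as np
import pytest

from vectsick import scales, synthetic
from vectsick.beliefs import likelihoods_from_report
from vectsick.oculomotor import count_head_movements, spev
from vectsick.stats import logit_outcome
from vectsick.synthetic import (
    SyntheticCohortConfig,
    allocate_ssq_items,
    generate_beliefs,
    generate_cohort,
    generate_cohort_features,
    generate_head_trace,
    generate_okn_trace,
    generate_outcomes,
    generate_vection_trace,
)
from vectsick.vection import vection_features


class TestVectionGeneration:
    def test_infinite_full_dwell_pins_trace(self):
        cfg = SyntheticCohortConfig(duration_s=60.0, dwell_full_s=math.inf,
                                    knob_noise_sd=0.0)
        rng = np.random.default_rng(6)  # first draw starts in 'full'
        for _ in range(10):
            tr = generate_vection_trace(cfg, rng)
            f = vection_features(tr)
            if f.full_vection_pct == 100.0:
                return
        raise AssertionError("no trace started and stayed in full vection")

    def test_symmetric_dwells_split_time_evenly(self):
        cfg = SyntheticCohortConfig(
            duration_s=1200.0,
            dwell_full_s=40.0,
            dwell_no_s=40.0,
            dwell_partial_s=5.0,
            vection_heterogeneity=0.0,
            knob_noise_sd=0.0,
        )
        fv = [
            vection_features(generate_vection_trace(cfg, seed)).full_vection_pct
            for seed in range(12)
        ]
        # renewal expectation: dwell_full / (dwell_full + dwell_no + partials)
        expect = 100 * 40.0 / (40 + 40 + 2 * 5 + 4 * cfg.ramp_s)
        assert np.mean(fv) == pytest.approx(expect, abs=6.0)

    def test_seeded_reproducibility(self):
        cfg = SyntheticCohortConfig(duration_s=30.0)
        a = generate_vection_trace(cfg, 77)
        b = generate_vection_trace(cfg, 77)
        assert np.array_equal(a.ratings, b.ratings)


class TestOknGeneration:
    def test_gain_recoverable_through_pipeline(self):
        cfg = SyntheticCohortConfig(duration_s=60.0, okn_gain=0.9, eye_noise_sd=0.0)
        trace, _ = generate_okn_trace(cfg, 15)
        assert spev(trace).median_spev == pytest.approx(54.0, abs=1.0)

    def test_zero_saccade_rate_gives_pure_ramp(self):
        cfg = SyntheticCohortConfig(duration_s=10.0, saccade_rate_hz=0.0,
                                    eye_noise_sd=0.0)
        trace, truth = generate_okn_trace(cfg, 1)
        assert truth == ()
        v = np.diff(trace.horizontal_position) * cfg.eye_sample_rate
        assert np.allclose(v, cfg.okn_gain * 60.0, atol=1e-6)

    def test_truth_intervals_cover_programmed_resets(self):
        cfg = SyntheticCohortConfig(duration_s=30.0, eye_noise_sd=0.0)
        trace, truth = generate_okn_trace(cfg, 22)
        v = np.diff(trace.horizontal_position) * cfg.eye_sample_rate
        opposing = np.flatnonzero(v < 0)  # resets run against the slow phase
        covered = np.zeros(trace.times.size, bool)
        for s, e in truth:
            covered[s:e] = True
        assert covered[opposing].all()

    def test_seeded_reproducibility(self):
        cfg = SyntheticCohortConfig(duration_s=20.0)
        a, ta = generate_okn_trace(cfg, 4)
        b, tb = generate_okn_trace(cfg, 4)
        assert np.array_equal(a.horizontal_position, b.horizontal_position)
        assert ta == tb


class TestHeadGeneration:
    def test_no_transients_no_counts(self):
        cfg = SyntheticCohortConfig(duration_s=60.0, head_transient_count=0)
        trace, k = generate_head_trace(cfg, 2)
        assert k == 0
        assert count_head_movements(trace) == 0

    def test_injected_count_matches(self):
        cfg = SyntheticCohortConfig(duration_s=120.0, head_transient_count=4)
        trace, k = generate_head_trace(cfg, 3)
        assert k == 4
        assert count_head_movements(trace) == 4


class TestOutcomes:
    def test_noiseless_outcome_is_deterministic(self):
        cfg = SyntheticCohortConfig(residual_sd=0.0)
        out = generate_outcomes(cfg, 1, mssq=20.0, conflict=0.5)
        eta = -1.64 + 0.02 * 20.0 + 2.15 * 0.5
        target = 235.62 / (1 + math.exp(-eta))
        assert out["ssq_ts"] == pytest.approx(target, abs=scales.SSQ_TS_FACTOR / 2)

    @pytest.mark.parametrize("target", [5.0, 37.0, 79.0, 161.0, 230.0])
    def test_allocated_items_rescore_to_target(self, target):
        resp = allocate_ssq_items(target)
        ts = scales.score_ssq(resp).total_score
        assert abs(ts - target) <= scales.SSQ_TS_FACTOR / 2 + 1e-9

    def test_fms_respects_stop_rule(self):
        cfg = SyntheticCohortConfig()
        for seed in range(20):
            out = generate_outcomes(cfg, seed, mssq=45.0, conflict=0.9)
            s = out["fms_series"]
            hits = [i for i, v in enumerate(s.scores) if v >= 15]
            if hits:
                assert hits[0] == len(s.scores) - 1

    def test_null_conflict_recovers_zero(self):
        """With beta_conflict = 0 the fitted conflict coefficient is centred
        on zero across replicates."""
        from vectsick.stats import fit_conflict_model

        cfg = SyntheticCohortConfig(beta_conflict=0.0)
        est = []
        for rep in range(40):
            df = generate_cohort_features(cfg, n=200, seed=900 + rep)
            est.append(
                fit_conflict_model(df).coefficients.loc["conflict_pb", "estimate"]
            )
        est = np.array(est)
        assert abs(est.mean()) < 3 * est.std(ddof=1) / math.sqrt(est.size)


class TestCohort:
    def test_cohort_determinism(self):
        cfg = SyntheticCohortConfig(seed=42, duration_s=20.0, n_participants=3)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.vection_trace.ratings, rb.vection_trace.ratings)
            assert np.array_equal(
                ra.eye_trace.horizontal_position, rb.eye_trace.horizontal_position
            )
            assert ra.ssq_response.ratings == rb.ssq_response.ratings
            assert ra.belief_report == rb.belief_report

    def test_belief_coupling_is_negative(self):
        from scipy.stats import spearmanr

        cfg = SyntheticCohortConfig()
        rng = np.random.default_rng(0)
        z = rng.standard_normal(400)
        rl = np.array(
            [
                likelihoods_from_report(generate_beliefs(cfg, s, zi)).rl_chair
                for s, zi in enumerate(z)
            ]
        )
        rho = spearmanr(z, rl).statistic
        assert rho == pytest.approx(-0.58, abs=0.12)

    def test_feature_cohort_matches_study_margins(self):
        df = generate_cohort_features(SyntheticCohortConfig(), n=4000, seed=5)
        assert df["full_vection_pct"].mean() == pytest.approx(44.0, abs=2.0)
        assert df["full_vection_pct"].std() == pytest.approx(21.0, abs=3.0)
        assert df["mssq"].mean() == pytest.approx(16.6, abs=1.0)
        assert (df["ssq_ts"] > 0).all() and (df["ssq_ts"] < 235.62).all()

    def test_outcome_model_is_the_stated_logit_form(self):
        cfg = SyntheticCohortConfig(residual_sd=0.0)
        df = generate_cohort_features(cfg, n=50, seed=9)
        eta = logit_outcome(df["ssq_ts"].to_numpy())
        lin = -1.64 + 0.02 * df["mssq"] + 2.15 * df["conflict_pb"]
        assert np.allclose(eta, lin, atol=1e-9)
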