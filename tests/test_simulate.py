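import hashlib

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from cueweight.design import standard_design
from cueweight.observer import belief_trajectories
from cueweight.preprocess import filter_trials
from cueweight.response import ResponseParams, fit_weighting
from cueweight.simulate import (
    GroundTruth,
    recovery_experiment,
    simulate_cohort,
    simulate_subject,
    uniform_w_sampler,
)

from conftest import make_labeled_subject


def table_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


class TestSimulateSubject:
    def test_same_seed_identical_tables(self, exp3_design, study_params):
        truth = GroundTruth("S00", 0.8, study_params)
        a = simulate_subject(exp3_design, truth, seed=9)
        b = simulate_subject(exp3_design, truth, seed=9)
        assert table_hash(a) == table_hash(b)
        c = simulate_subject(exp3_design, truth, seed=10)
        assert table_hash(a) != table_hash(c)

    def test_trial_counts_match_design(self, exp1_design, study_params):
        truth = GroundTruth("S00", 0.8, study_params)
        df = simulate_subject(exp1_design, truth, seed=1)
        assert len(df) == 480
        assert df.groupby("block").size().tolist() == [80] * 6
        assert (df.groupby(["block", "modality"]).size() == 40).all()

    def test_zero_slopes_remove_predictability_effect(self, exp3_design):
        params = ResponseParams(2.2, 0.0, 2.0, 0.0, 1e-6)
        truth = GroundTruth("S00", 1.0, params)
        df = simulate_subject(exp3_design, truth, seed=2)
        rs = 1000.0 / df["rt_ms"]
        by_cond = rs.groupby([df["block"], df["validity"]]).mean().unstack()
        # valid - invalid gap is the intercept difference in every block
        assert np.allclose(by_cond["valid"] - by_cond["invalid"], 0.2, atol=1e-4)

    def test_noiseless_round_trip_recovers_w(self, exp3_design, noiseless_params):
        labeled = make_labeled_subject(exp3_design, w=1.0, params=noiseless_params)
        kept = labeled[labeled["exclusion_reason"] == "kept"]
        unit = kept[(kept["block"] == 0) & (kept["modality"] == "visual")]
        fit = fit_weighting(unit)
        assert fit.w_hat == pytest.approx(1.0, abs=0.01)

    def test_pathological_parameters_rejected(self, exp3_design):
        params = ResponseParams(-5.0, 0.5, -5.0, 0.5, 0.1)
        with pytest.raises(ValueError, match="RS"):
            simulate_subject(exp3_design, GroundTruth("S00", 0.8, params), seed=1)

    def test_error_rate_marks_incorrect_trials(self, exp3_design, study_params):
        truth = GroundTruth("S00", 0.8, study_params)
        df = simulate_subject(exp3_design, truth, seed=3, error_rate=0.2)
        frac_wrong = 1.0 - df["correct"].mean()
        assert 0.1 < frac_wrong < 0.3
        wrong = df[~df["correct"]]
        assert (wrong["response"] != wrong["elevation"]).all()


class TestSimulateCohort:
    def test_default_cohort_dimensions(self, exp3_design):
        cohort, truths = simulate_cohort(exp3_design, seed=0)
        assert len(truths) == 21
        assert cohort["subject_id"].nunique() == 21
        assert (cohort.groupby("subject_id").size() == 320).all()

    def test_shared_sequence_across_subjects(self, exp3_design):
        cohort, _ = simulate_cohort(exp3_design, n_subjects=3, seed=0)
        cols = ["block", "trial_index", "modality", "validity", "cue_side"]
        seqs = [g[cols].reset_index(drop=True) for _, g in cohort.groupby("subject_id")]
        assert all(s.equals(seqs[0]) for s in seqs[1:])

    def test_point_mass_truth_sampler(self, exp3_design, study_params):
        def sampler(rng, sid, design):
            return GroundTruth(sid, 0.75, study_params)

        _, truths = simulate_cohort(
            exp3_design, n_subjects=4, truth_sampler=sampler, seed=1
        )
        assert {t.w for t in truths} == {0.75}

    def test_master_seed_reproducible_and_seed_sensitive(self, exp3_design):
        a, _ = simulate_cohort(exp3_design, n_subjects=3, seed=5)
        b, _ = simulate_cohort(exp3_design, n_subjects=3, seed=5)
        c, _ = simulate_cohort(exp3_design, n_subjects=3, seed=6)
        assert table_hash(a) == table_hash(b)
        assert table_hash(a) != table_hash(c)
        # different data, same structure: mean RS within sampling error
        rs_a, rs_c = 1000.0 / a["rt_ms"], 1000.0 / c["rt_ms"]
        assert abs(rs_a.mean() - rs_c.mean()) < 0.05

    def test_constant_sampler_draws_decoupled_levels(self, exp3_design):
        sampler = uniform_w_sampler(generating_model="constant")
        _, truths = simulate_cohort(
            exp3_design, n_subjects=2, truth_sampler=sampler, seed=2
        )
        for t in truths:
            assert t.generating_model == "constant"
            assert len(t.p_const) == 8  # 4 blocks x 2 modalities
            assert all(0.1 <= v <= 0.9 for v in t.p_const.values())


class TestValidityEffect:
    def test_rs_cost_tracks_predictability_when_separate(self, exp1_design):
        """With fully separate processing and no noise, the valid-invalid
        RS gap increases with the block's own-modality predictability."""
        params = ResponseParams(2.2, 0.5, 2.0, 0.5, 1e-6)
        truth = GroundTruth("S00", 1.0, params)
        df = simulate_subject(exp1_design, truth, seed=4)
        rs = 1000.0 / df["rt_ms"]
        design = exp1_design
        for modality in ("visual", "tactile"):
            effects = {}
            for block in design.blocks:
                sub = df[(df["block"] == block.block_index) & (df["modality"] == modality)]
                gap = (
                    rs[sub.index][sub["validity"] == "valid"].mean()
                    - rs[sub.index][sub["validity"] == "invalid"].mean()
                )
                effects.setdefault(block.p_valid(modality), []).append(gap)
            # average over blocks sharing a level, then check the ordering
            levels = sorted(effects)
            mean_gap = [np.mean(effects[lv]) for lv in levels]
            rho = spearmanr(levels, mean_gap).statistic
            assert rho == pytest.approx(1.0)


class TestRecoveryExperiment:
    def test_noiseless_recovery_at_grid_resolution(self, exp3_design):
        report = recovery_experiment(
            exp3_design, w_values=(0.6, 0.9), n_subjects=4, sigma=1e-6, seed=8
        )
        usable = report.units[report.units["ok"]]
        assert (np.abs(usable["w_hat"] - usable["w_true"]) <= 0.011).all()
        assert report.median_abs_error <= 0.011

    def test_flagged_units_tabulated_not_dropped(self, exp3_design):
        report = recovery_experiment(
            exp3_design, w_values=(0.7,), n_subjects=3, sigma=0.2, seed=9,
            unit="block",
        )
        assert len(report.units) == 3 * 4 * 2
        assert {"w_true", "w_hat", "ok", "flags"} <= set(report.units.columns)
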