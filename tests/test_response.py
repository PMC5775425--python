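import math

import numpy as np
import pandas as pd
import pytest

from cueweight.design import standard_design
from cueweight.observer import belief_trajectories
from cueweight.response import (
    ResponseParams,
    fit_bayesian_concatenated,
    fit_constant_model,
    fit_weighting,
    gaussian_loglik,
    log_evidence,
    optimal_p_const,
    predicted_rs,
)
from cueweight.simulate import GroundTruth, simulate_subject

from conftest import make_labeled_subject


def kept_unit(labeled, block, modality):
    kept = labeled[labeled["exclusion_reason"] == "kept"]
    if block is None:
        return kept[kept["modality"] == modality]
    return kept[(kept["block"] == block) & (kept["modality"] == modality)]


class TestPredictedRS:
    def test_valid_and_invalid_branches(self):
        params = ResponseParams(2.0, 0.5, 2.0, 0.5, 0.1)
        assert predicted_rs(0.8, "valid", params) == pytest.approx(2.4)
        assert predicted_rs(0.8, "invalid", params) == pytest.approx(2.1)

    def test_intercept_limit(self):
        params = ResponseParams(2.2, 0.7, 1.9, 0.3, 0.1)
        assert predicted_rs(0.0, "valid", params) == pytest.approx(2.2)

    def test_probability_outside_unit_interval_rejected(self):
        params = ResponseParams(2.0, 0.5, 2.0, 0.5, 0.1)
        with pytest.raises(ValueError):
            predicted_rs(1.2, "valid", params)


class TestGaussianLoglik:
    def test_zero_residuals_closed_form(self):
        ll = gaussian_loglik([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], sigma=1.0)
        assert ll == pytest.approx(-1.5 * math.log(2 * math.pi))

    def test_unit_residuals_closed_form(self):
        ll = gaussian_loglik([1.0, -1.0], [0.0, 0.0], sigma=1.0)
        assert ll == pytest.approx(-math.log(2 * math.pi) - 1.0)

    def test_doubling_sigma_costs_n_log_two(self):
        y = [1.0, 2.0, 3.0, 4.0]
        assert gaussian_loglik(y, y, 1.0) - gaussian_loglik(y, y, 2.0) == pytest.approx(
            4 * math.log(2)
        )

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_loglik([1.0], [1.0], sigma=0.0)


class TestLogEvidence:
    def test_bic_formula(self):
        assert log_evidence(-10.0, 6, 40, "bic") == pytest.approx(
            -10.0 - 3.0 * math.log(40)
        )

    def test_zero_parameters_no_penalty(self):
        assert log_evidence(-10.0, 0, 40, "bic") == pytest.approx(-10.0)

    def test_penalty_monotone_in_k(self):
        evs = [log_evidence(-10.0, k, 40, "bic") for k in range(5)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_laplace_with_identity_hessian(self):
        # H = I: evidence = ll + (k/2) ln 2*pi
        ev = log_evidence(-10.0, 2, 40, "laplace", hessian=np.eye(2))
        assert ev == pytest.approx(-10.0 + math.log(2 * math.pi))

    def test_laplace_singular_hessian_falls_back_to_bic(self):
        ev = log_evidence(-10.0, 2, 40, "laplace", hessian=np.zeros((2, 2)))
        assert ev == pytest.approx(log_evidence(-10.0, 2, 40, "bic"))


class TestFitWeighting:
    def test_profiled_zetas_match_regression_oracle(self, exp3_design, study_params):
        labeled = make_labeled_subject(exp3_design, w=0.8, params=study_params)
        unit = kept_unit(labeled, block=1, modality="visual")
        w0 = 0.37
        fit = fit_weighting(unit, w_bounds=(w0, w0), evidence="bic")
        p_own = unit["p_vis_prior"].to_numpy()
        p_other = unit["p_tac_prior"].to_numpy()
        p_int = w0 * p_own + (1 - w0) * p_other
        valid = (unit["validity"] == "valid").to_numpy()
        rs = unit["rs"].to_numpy()
        slope_v, icept_v = np.polyfit(p_int[valid], rs[valid], 1)
        slope_i, icept_i = np.polyfit(1 - p_int[~valid], rs[~valid], 1)
        assert fit.params.zeta1_valid == pytest.approx(icept_v, abs=1e-10)
        assert fit.params.zeta2_valid == pytest.approx(slope_v, abs=1e-10)
        assert fit.params.zeta1_invalid == pytest.approx(icept_i, abs=1e-10)
        assert fit.params.zeta2_invalid == pytest.approx(slope_i, abs=1e-10)

    @pytest.mark.parametrize("w_true", [1.0, 0.5])
    def test_noiseless_identifiability(self, exp3_design, noiseless_params, w_true):
        labeled = make_labeled_subject(exp3_design, w=w_true, params=noiseless_params)
        unit = kept_unit(labeled, block=0, modality="visual")  # (90, 10) block
        fit = fit_weighting(unit, grid_step=0.01)
        assert fit.w_hat == pytest.approx(w_true, abs=0.01)
        assert fit.ok

    def test_constant_rs_flags_w_unidentified(self, exp3_design):
        # zero slopes: w enters the likelihood only through zeta2 * p_int
        params = ResponseParams(2.2, 0.0, 2.0, 0.0, 1e-6)
        labeled = make_labeled_subject(exp3_design, w=0.7, params=params)
        unit = kept_unit(labeled, block=0, modality="visual").copy()
        unit["rs"] = np.where(unit["validity"] == "valid", 2.2, 2.0)
        fit = fit_weighting(unit)
        assert "w_unidentified" in fit.flags
        assert fit.w_hat == 0.5

    def test_too_few_trials_flagged_not_raised(self, exp3_design, study_params):
        labeled = make_labeled_subject(exp3_design, w=0.8, params=study_params)
        unit = kept_unit(labeled, block=0, modality="visual").head(4)
        fit = fit_weighting(unit)
        assert not fit.ok
        assert "too_few_trials" in fit.flags
        assert math.isnan(fit.w_hat)

    def test_sparse_condition_slope_fixed_to_zero(self, exp3_design, study_params):
        labeled = make_labeled_subject(exp3_design, w=0.8, params=study_params)
        unit = kept_unit(labeled, block=0, modality="visual")
        invalid = unit[unit["validity"] == "invalid"].head(2)
        sparse = pd.concat([unit[unit["validity"] == "valid"], invalid])
        fit = fit_weighting(sparse)
        assert fit.params.zeta2_invalid == 0.0

    def test_likelihood_location_equivariant(self, exp3_design, study_params):
        labeled = make_labeled_subject(exp3_design, w=0.9, params=study_params)
        unit = kept_unit(labeled, block=1, modality="tactile")
        shifted = unit.copy()
        shifted["rs"] = shifted["rs"] + 3.0
        a = fit_weighting(unit)
        b = fit_weighting(shifted)
        assert b.w_hat == pytest.approx(a.w_hat, abs=1e-6)
        assert b.log_likelihood == pytest.approx(a.log_likelihood, abs=1e-6)
        assert b.params.zeta2_valid == pytest.approx(a.params.zeta2_valid, abs=1e-6)

    def test_evidence_penalized_below_likelihood(self, exp3_design, study_params):
        labeled = make_labeled_subject(exp3_design, w=0.8, params=study_params)
        unit = kept_unit(labeled, block=2, modality="visual")
        for method in ("marginal", "bic"):
            fit = fit_weighting(unit, evidence=method)
            assert fit.log_evidence <= fit.log_likelihood


class TestConcatenatedFit:
    def test_single_block_reduces_to_blockwise_fit(self, exp3_design, study_params):
        labeled = make_labeled_subject(exp3_design, w=0.8, params=study_params)
        unit = kept_unit(labeled, block=0, modality="visual")
        a = fit_weighting(unit)
        b = fit_bayesian_concatenated(unit)
        assert b.w_hat == pytest.approx(a.w_hat)
        assert b.log_likelihood == pytest.approx(a.log_likelihood)

    def test_block_order_irrelevant(self, exp3_design, study_params):
        labeled = make_labeled_subject(exp3_design, w=0.7, params=study_params)
        unit = kept_unit(labeled, block=None, modality="visual")
        permuted = pd.concat(
            [unit[unit["block"] == b] for b in [2, 0, 3, 1]]
        )
        a = fit_bayesian_concatenated(unit)
        b = fit_bayesian_concatenated(permuted)
        assert b.w_hat == pytest.approx(a.w_hat)
        assert b.log_likelihood == pytest.approx(a.log_likelihood)

    def test_subject_level_recovery_mixed_design(self, exp1_design, study_params):
        """Concatenated estimates track subject-level truth on the
        mixed-predictability design at study noise."""
        from cueweight.simulate import recovery_experiment

        report = recovery_experiment(
            exp1_design, w_values=(0.5, 0.7, 0.9), sigma=0.2, seed=11
        )
        assert report.median_abs_error <= 0.1
        assert report.correlation >= 0.8


class TestConstantModel:
    def test_p_const_closed_form_matches_grid_oracle(self, exp3_design, study_params):
        labeled = make_labeled_subject(
            exp3_design, w=0.5, params=study_params,
            generating_model="constant",
            p_const={(b, m): p for b, p in zip(range(4), [0.2, 0.8, 0.4, 0.6])
                     for m in ("visual", "tactile")},
        )
        unit = kept_unit(labeled, block=1, modality="visual")
        valid = (unit["validity"] == "valid").to_numpy()
        rs = unit["rs"].to_numpy()
        zetas = ResponseParams(2.1, 0.4, 1.9, 0.6, 0.2)
        closed = optimal_p_const(zetas, valid, rs)

        def sse(p):
            pred = np.where(
                valid,
                zetas.zeta1_valid + zetas.zeta2_valid * p,
                zetas.zeta1_invalid + zetas.zeta2_invalid * (1 - p),
            )
            return np.sum((rs - pred) ** 2)

        grid = np.linspace(0, 1, 20001)
        oracle = grid[int(np.argmin([sse(p) for p in grid]))]
        assert closed == pytest.approx(oracle, abs=1e-4)

    def test_p_unidentified_when_slopes_vanish(self):
        zetas = ResponseParams(2.0, 0.0, 2.0, 0.0, 0.2)
        assert optimal_p_const(zetas, np.array([True, False]), np.array([2.0, 2.0])) is None

    def test_single_noiseless_block_saturated(self, exp3_design, noiseless_params):
        labeled = make_labeled_subject(
            exp3_design, w=0.5, params=noiseless_params,
            generating_model="constant",
            p_const={(b, m): 0.7 for b in range(4) for m in ("visual", "tactile")},
        )
        unit = kept_unit(labeled, block=0, modality="visual")
        fit = fit_constant_model(unit)
        # both cell means are exactly reproduced: residual variance ~ 0
        assert fit.params.sigma < 1e-4

    def test_recovers_generating_levels(self, exp3_design, study_params):
        p_true = {(b, m): p for b, p in zip(range(4), [0.15, 0.85, 0.35, 0.65])
                  for m in ("visual", "tactile")}
        labeled = make_labeled_subject(
            exp3_design, w=0.5, params=study_params,
            generating_model="constant", p_const=p_true,
        )
        unit = kept_unit(labeled, block=None, modality="visual")
        fit = fit_constant_model(unit)
        assert fit.converged
        estimated = np.array([fit.p_const[b] for b in range(4)])
        truth = np.array([p_true[(b, "visual")] for b in range(4)])
        # the model is invariant under (p, zeta2) -> (1-p, -zeta2)
        err_direct = np.abs(estimated - truth).mean()
        err_mirror = np.abs((1 - estimated) - truth).mean()
        assert min(err_direct, err_mirror) < 0.15

    def test_learning_model_beats_constant_on_learner_data(
        self, exp1_design, study_params
    ):
        labeled = make_labeled_subject(exp1_design, w=0.9, params=study_params)
        unit = kept_unit(labeled, block=None, modality="visual")
        bayes = fit_bayesian_concatenated(unit)
        const = fit_constant_model(unit)
        assert bayes.n_trials_used == const.n_trials_used
        assert bayes.log_evidence > const.log_evidence
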