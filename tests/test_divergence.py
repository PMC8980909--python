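"""Threshold (divergence-age) model: basis, design, CV selection, predictions."""

import numpy as np
import pytest

from divage import (
    DivergenceModelSpec,
    PhenotypeSpec,
    SimulationConfig,
    ThresholdGrid,
    build_design,
    cv_mspe,
    divergence_basis,
    predict_trajectory,
    select_threshold,
    simulate_cohort,
)
from divage.cohort import phenotype_mean
from divage.divergence import _fold_assignment, refit_with_grs_main

from conftest import normal_equation_beta


def brute_force_cv_mspe(cohort, spec, threshold):
    """Independent re-implementation: explicit fold loop with the
    normal-equation oracle on raw training rows."""
    data = build_design(cohort, spec, threshold)
    fold_ids = _fold_assignment(data.n, spec.cv_folds, spec.fold_seed)
    total = 0.0
    for f in range(spec.cv_folds):
        test = fold_ids == f
        beta = normal_equation_beta(data.X[~test], data.y[~test])
        resid = data.y[test] - data.X[test] @ beta
        total += float(resid @ resid)
    return total / data.n


class TestDivergenceBasis:
    def test_zero_below_threshold(self):
        assert divergence_basis(50.0, 3.0, 55.0, 3) == 0.0

    def test_two_decades_cubed(self):
        assert divergence_basis(75.0, 1.0, 55.0, 3) == pytest.approx(8.0)

    def test_zero_score_zero_everywhere(self):
        ages = np.linspace(40, 70, 31)
        np.testing.assert_array_equal(divergence_basis(ages, 0.0, 50.0, 3), 0.0)

    def test_exactly_zero_at_threshold(self):
        assert divergence_basis(50.0, 2.5, 50.0, 2) == 0.0


class TestBuildDesign:
    def test_column_count_quadratic_base_plus_covariates(self, divergent_cohort):
        cohort, _, _ = divergent_cohort
        spec = DivergenceModelSpec(
            "cognition",
            covariates=("sex", "assay") + tuple(f"pc{i}" for i in range(1, 11)),
        )
        data = build_design(cohort, spec, 50.0)
        assert data.X.shape[1] == 4 + 12  # intercept, t, t^2, divergence + 12
        assert data.names[:4] == ["intercept", "t", "t^2", "divergence"]
        assert "grs_main" not in data.names  # constrained to zero below threshold

    def test_threshold_at_max_age_drops_divergence_column(self, divergent_cohort):
        cohort, _, _ = divergent_cohort
        spec = DivergenceModelSpec("cognition")
        with pytest.warns(UserWarning, match="not estimable"):
            data = build_design(cohort, spec, 70.0)
        assert not data.b3_estimable
        assert "divergence" not in data.names

    def test_matches_hand_built_matrix_on_five_rows(self):
        import pandas as pd

        cohort = pd.DataFrame(
            {
                "age": [42.0, 50.0, 57.5, 63.0, 70.0],
                "grs_z": [1.0, -0.5, 0.0, 2.0, -1.0],
                "cognition": [1.0, 2.0, 3.0, 4.0, 5.0],
                "sex": [0.0, 1.0, 0.0, 1.0, 1.0],
            }
        )
        spec = DivergenceModelSpec("cognition", covariates=("sex",))
        data = build_design(cohort, spec, 55.0)
        t = (cohort["age"].to_numpy() - 40.0) / 10.0
        z = cohort["grs_z"].to_numpy()
        hand = np.column_stack(
            [
                np.ones(5),
                t,
                t**2,
                z * np.maximum(0.0, t - 1.5) ** 3,
                cohort["sex"].to_numpy(),
            ]
        )
        np.testing.assert_allclose(data.X, hand, atol=0)

    def test_divergence_order_must_be_base_plus_one(self):
        with pytest.raises(ValueError, match="base_order"):
            DivergenceModelSpec("y", base_order=2, divergence_order=4)


class TestCvMspe:
    def test_matches_brute_force_loop(self, divergent_cohort):
        cohort, _, _ = divergent_cohort
        sub = cohort.iloc[:300].reset_index(drop=True)
        spec = DivergenceModelSpec("cognition", covariates=("sex",), cv_folds=5,
                                   fold_seed=4)
        for threshold in (45.0, 50.0, 60.0):
            assert cv_mspe(sub, spec, threshold) == pytest.approx(
                brute_force_cv_mspe(sub, spec, threshold), abs=1e-10
            )

    def test_noise_free_minimum_at_true_threshold(self):
        spec_p = PhenotypeSpec(
            name="y",
            base_coefs=(0.0, -0.25, -0.05),
            true_threshold_age=50.0,
            divergence_coef=-0.3,
        )
        cfg = SimulationConfig(n_participants=3000, seed=6, phenotype_specs=(spec_p,))
        cohort = simulate_cohort(cfg)
        cohort["y"] = np.asarray(
            [phenotype_mean(spec_p, a, z) for a, z in zip(cohort.age, cohort.grs_z)]
        )
        spec = DivergenceModelSpec("y", fold_seed=1)
        mspe_true = cv_mspe(cohort, spec, 50.0)
        for threshold in (42.0, 46.0, 54.0, 60.0, 66.0):
            assert mspe_true <= cv_mspe(cohort, spec, threshold)

    def test_null_phenotype_mspe_flat_near_variance(self):
        rng = np.random.default_rng(3)
        spec_p = PhenotypeSpec(name="y", base_coefs=(0.0, 0.0, 0.0), residual_sd=1.0)
        cfg = SimulationConfig(n_participants=5000, seed=8, phenotype_specs=(spec_p,))
        cohort = simulate_cohort(cfg)
        spec = DivergenceModelSpec("y", fold_seed=2)
        values = [cv_mspe(cohort, spec, thr) for thr in (40.0, 50.0, 60.0, 69.0)]
        for v in values:
            assert v == pytest.approx(1.0, rel=0.08)  # ~ Var(y), Monte-Carlo slack

    def test_too_many_folds_rejected(self, divergent_cohort):
        cohort, _, _ = divergent_cohort
        tiny = cohort.iloc[:24].reset_index(drop=True)
        spec = DivergenceModelSpec("cognition", cv_folds=10)
        with pytest.raises(ValueError, match="fewer folds"):
            cv_mspe(tiny, spec, 50.0)


class TestSelectThreshold:
    def test_recovers_strong_divergence(self, divergent_cohort):
        cohort, _, _ = divergent_cohort
        spec = DivergenceModelSpec("cognition", covariates=("sex",), fold_seed=3)
        fit = select_threshold(cohort, spec)
        assert abs(fit.selected_threshold - 50.0) <= 3.0
        assert fit.boundary_flag == "interior"
        assert fit.selected_threshold == min(
            fit.mspe_by_threshold, key=fit.mspe_by_threshold.get
        )

    def test_grid_order_invariance(self, divergent_cohort):
        """Evaluating the grid in any order yields the same MSPE map."""
        cohort, _, _ = divergent_cohort
        sub = cohort.iloc[:1500].reset_index(drop=True)
        grid = ThresholdGrid((45.0, 50.0, 55.0, 60.0))
        spec = DivergenceModelSpec("cognition", grid=grid, fold_seed=7)
        fit = select_threshold(sub, spec)
        reversed_map = {
            thr: cv_mspe(sub, spec, thr) for thr in reversed(grid.ages)
        }
        for thr, v in fit.mspe_by_threshold.items():
            assert v == pytest.approx(reversed_map[thr], abs=1e-14)

    def test_tie_break_prefers_largest_threshold(self, divergent_cohort):
        """Thresholds at/above the max age yield identical models; the
        reported argmin must be the largest of the tied candidates."""
        cohort, _, _ = divergent_cohort
        sub = cohort.iloc[:800].reset_index(drop=True)
        top = float(np.ceil(sub["age"].max()))
        null_spec = DivergenceModelSpec("cognition", grid=ThresholdGrid((top, top + 1.0)),
                                        fold_seed=5)
        with pytest.warns(UserWarning, match="not estimable"):
            null_fit = select_threshold(sub, null_spec)
        # both candidates drop the divergence column -> identical MSPE -> tie
        vals = list(null_fit.mspe_by_threshold.values())
        assert vals[0] == vals[1]
        assert null_fit.selected_threshold == top + 1.0
        assert null_fit.boundary_flag == "at_max"

    def test_full_data_refit_matches_normal_equation_oracle(self, divergent_cohort):
        cohort, _, _ = divergent_cohort
        sub = cohort.iloc[:500].reset_index(drop=True)
        spec = DivergenceModelSpec("cognition", covariates=("sex",), fold_seed=9)
        fit = select_threshold(sub, spec)
        data = build_design(sub, spec, fit.selected_threshold)
        beta = normal_equation_beta(data.X, data.y)
        for name, value in zip(data.names, beta):
            assert fit.coefficients[name] == pytest.approx(value, abs=1e-10)

    def test_noise_free_exact_coefficient_recovery(self):
        """Correctly specified model on a noise-free cohort: coefficients to 1e-6."""
        spec_p = PhenotypeSpec(
            name="y",
            base_coefs=(1.5, -0.25, -0.05),
            true_threshold_age=50.0,
            divergence_coef=-0.08,
        )
        cfg = SimulationConfig(n_participants=4000, seed=13, phenotype_specs=(spec_p,))
        cohort = simulate_cohort(cfg)
        cohort["y"] = np.asarray(
            [phenotype_mean(spec_p, a, z) for a, z in zip(cohort.age, cohort.grs_z)]
        )
        fit = select_threshold(cohort, DivergenceModelSpec("y", fold_seed=2))
        assert fit.selected_threshold == 50.0
        assert fit.coefficients["intercept"] == pytest.approx(1.5, abs=1e-6)
        assert fit.coefficients["t"] == pytest.approx(-0.25, abs=1e-6)
        assert fit.coefficients["t^2"] == pytest.approx(-0.05, abs=1e-6)
        assert fit.coefficients["divergence"] == pytest.approx(-0.08, abs=1e-6)


@pytest.fixture(scope="module")
def fitted(divergent_cohort):
    cohort, _, _ = divergent_cohort
    spec = DivergenceModelSpec("cognition", covariates=("sex",), fold_seed=3)
    return select_threshold(cohort, spec)


class TestPredictTrajectory:
    def test_published_percentile_scores_identical_below_threshold(self, fitted):
        """The 95th/5th percentile score exemplars (1.76 / -1.22) predict the
        same mean at every age at or below the selected threshold."""
        ages = np.arange(40.0, fitted.selected_threshold + 0.5, 1.0)
        hi = predict_trajectory(fitted, 1.76, {"sex": 1.0}, ages)
        lo = predict_trajectory(fitted, -1.22, {"sex": 1.0}, ages)
        np.testing.assert_array_equal(hi, lo)

    def test_diverges_above_threshold(self, fitted):
        age = np.array([fitted.selected_threshold + 10.0])
        hi = predict_trajectory(fitted, 1.76, {}, age)
        lo = predict_trajectory(fitted, -1.22, {}, age)
        assert hi[0] != lo[0]

    def test_grs_gradient_zero_below_threshold_exactly(self, fitted):
        ages = np.linspace(40.0, fitted.selected_threshold, 30)
        for z in (-3.0, -1.0, 0.5, 2.0):
            np.testing.assert_array_equal(
                predict_trajectory(fitted, z, {}, ages),
                predict_trajectory(fitted, 0.0, {}, ages),
            )

    def test_c2_continuity_at_threshold(self, fitted):
        """Cubic divergence: value, first and second derivative continuous
        at the knot (numerical mesh, tolerance 1e-8 per unit coefficient)."""
        b3 = abs(fitted.coefficients["divergence"])
        h = 1e-3  # years
        thr = fitted.selected_threshold
        ages = np.array([thr - 2 * h, thr - h, thr, thr + h, thr + 2 * h])
        vals = predict_trajectory(fitted, 2.0, {}, ages) - predict_trajectory(
            fitted, 0.0, {}, ages
        )
        # the score-dependent part and its first two finite differences vanish
        assert abs(vals[2]) <= 1e-8 * max(b3, 1.0)
        d1 = (vals[3] - vals[1]) / (2 * h)
        d2 = (vals[3] - 2 * vals[2] + vals[1]) / h**2
        assert abs(d1) <= 1e-8 * max(b3, 1.0)
        assert abs(d2) <= 1e-6 * max(b3, 1.0)  # second difference amplifies fp noise

    def test_hand_computed_mean_on_toy_fit(self, fitted):
        age = 66.0
        t = (age - 40.0) / 10.0
        c = fitted.coefficients
        expected = (
            c["intercept"]
            + c["t"] * t
            + c["t^2"] * t**2
            + c["divergence"] * 1.5 * max(0.0, t - (fitted.selected_threshold - 40) / 10) ** 3
            + c["sex"] * 1.0
        )
        got = predict_trajectory(fitted, 1.5, {"sex": 1.0}, [age])[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_extrapolation_warns(self, fitted):
        with pytest.warns(UserWarning, match="extrapolat"):
            predict_trajectory(fitted, 0.0, {}, [80.0])

    def test_unestimable_divergence_gives_flat_difference(self, divergent_cohort):
        cohort, _, _ = divergent_cohort
        sub = cohort.iloc[:600].reset_index(drop=True)
        top = float(np.ceil(sub["age"].max()))
        spec = DivergenceModelSpec(
            "cognition", grid=ThresholdGrid((top, top + 1.0)), fold_seed=1
        )
        with pytest.warns(UserWarning, match="not estimable"):
            fit = select_threshold(sub, spec)
        ages = np.linspace(40, 70, 7)
        with pytest.warns(UserWarning, match="extrapolat"):
            hi = predict_trajectory(fit, 2.0, {}, ages)
            lo = predict_trajectory(fit, -2.0, {}, ages)
        np.testing.assert_array_equal(hi, lo)


class TestDiagnostics:
    def test_grs_main_refit_exposes_constraint(self, divergent_cohort):
        """The diagnostic refit adds a score main effect; on data generated
        with no below-threshold score association it stays near zero."""
        cohort, _, _ = divergent_cohort
        spec = DivergenceModelSpec("cognition", covariates=("sex",))
        coefs = refit_with_grs_main(cohort, spec, 50.0)
        assert "grs_main" in coefs
        assert abs(coefs["grs_main"]) < 0.1

    def test_noise_covariates_cannot_cut_mse_below_noise_floor(self):
        """In-sample MSE with junk covariates stays near residual_sd^2."""
        spec_p = PhenotypeSpec(name="y", base_coefs=(0.0, -0.2, -0.02), residual_sd=1.0)
        cfg = SimulationConfig(
            n_participants=4000, seed=19, phenotype_specs=(spec_p,), n_pcs=10
        )
        cohort = simulate_cohort(cfg)
        spec = DivergenceModelSpec(
            "y", covariates=tuple(f"pc{i}" for i in range(1, 11)), fold_seed=3
        )
        data = build_design(cohort, spec, 50.0)
        beta = np.linalg.lstsq(data.X, data.y, rcond=None)[0]
        mse = float(np.mean((data.y - data.X @ beta) ** 2))
        p = data.X.shape[1]
        # E[MSE] = sigma^2 (1 - p/n); allow 4 SD of the chi^2 fluctuation
        assert mse > 1.0 * (1 - p / 4000) - 4 * np.sqrt(2 / 4000)
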