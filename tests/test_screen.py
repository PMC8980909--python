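"""Interaction screen: fits, percent ratios, Bonferroni selection, invariants."""

import numpy as np
import pandas as pd
import pytest

from divage import (
    PhenotypeSpec,
    ScreenModelSpec,
    SimulationConfig,
    bonferroni_threshold,
    fit_interaction_model,
    harmonize_direction,
    percent_ratio,
    screen_all,
    simulate_cohort,
)
from divage.reference import (
    N_SCREENED_MEASURES,
    PERCENT_CONSISTENT_ROWS,
    REFERENCE_SCREEN_ESTIMATES,
)
from divage.screen import _screen_design

from conftest import normal_equation_beta


class TestHarmonizeDirection:
    def test_lower_better_negated(self):
        np.testing.assert_array_equal(
            harmonize_direction([100.0, 200.0], "lower_better"), [-100.0, -200.0]
        )

    def test_higher_better_unchanged(self):
        np.testing.assert_array_equal(
            harmonize_direction([5.0, 7.0], "higher_better"), [5.0, 7.0]
        )

    def test_involution(self):
        col = np.array([3.0, -1.0, 8.0])
        twice = harmonize_direction(
            harmonize_direction(col, "lower_better"), "lower_better"
        )
        np.testing.assert_array_equal(twice, col)


class TestPercentRatio:
    @pytest.mark.parametrize(
        "age_slope, interaction, printed",
        [REFERENCE_SCREEN_ESTIMATES[name][:3] for name in PERCENT_CONSISTENT_ROWS],
    )
    def test_published_worked_examples(self, age_slope, interaction, printed):
        """Rounded published coefficients reproduce the printed percentage."""
        assert round(percent_ratio(age_slope, interaction), 1) == printed

    def test_zero_interaction_gives_zero(self):
        assert percent_ratio(-0.35, 0.0) == 0.0

    def test_zero_age_slope_flagged_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(percent_ratio(0.0, -0.01))

    def test_same_sign_is_positive(self):
        assert percent_ratio(-0.2, -0.01) > 0


class TestBonferroni:
    def test_published_family_size(self):
        assert bonferroni_threshold(0.05, N_SCREENED_MEASURES) == pytest.approx(
            1.5625e-3
        )

    @pytest.mark.parametrize("alpha, m, expected", [(0.05, 1, 0.05), (0.01, 10, 0.001)])
    def test_simple_cases(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def _linear_cohort(n=4000, seed=3, **kwargs):
    spec = PhenotypeSpec(
        name="y",
        base_coefs=kwargs.pop("base_coefs", (1.0, -0.09, 0.0)),
        true_threshold_age=40.0,
        divergence_coef=kwargs.pop("divergence_coef", -0.007),
        divergence_order=1,
        residual_sd=kwargs.pop("residual_sd", 1.0),
    )
    cfg = SimulationConfig(n_participants=n, seed=seed, phenotype_specs=(spec,))
    return simulate_cohort(cfg), spec


class TestFitInteractionModel:
    def test_noise_free_recovery_to_1e6(self):
        from divage.cohort import phenotype_mean

        cohort, spec = _linear_cohort()
        cohort["y"] = np.asarray(
            [phenotype_mean(spec, a, z) for a, z in zip(cohort.age, cohort.grs_z)]
        )
        res = fit_interaction_model(cohort, ScreenModelSpec("y"))
        assert res.age_slope_per_decade == pytest.approx(-0.09, abs=1e-6)
        assert res.interaction_per_decade == pytest.approx(-0.007, abs=1e-6)

    def test_constant_phenotype_no_evidence(self):
        cohort, _ = _linear_cohort(n=500)
        cohort["y"] = 3.0
        res = fit_interaction_model(cohort, ScreenModelSpec("y"))
        assert res.age_slope_per_decade == pytest.approx(0.0, abs=1e-10)
        assert res.interaction_per_decade == pytest.approx(0.0, abs=1e-10)
        assert res.p_interaction == pytest.approx(1.0)

    def test_matches_normal_equation_oracle_on_toy(self, toy_cohort):
        spec = ScreenModelSpec("score", covariates=("sex", "assay", "pc1", "pc2"))
        res = fit_interaction_model(toy_cohort, spec)
        X, y, names, n = _screen_design(toy_cohort, spec)
        beta = normal_equation_beta(X, y)
        assert res.age_slope_per_decade == pytest.approx(
            beta[names.index("age_main")], abs=1e-10
        )
        assert res.interaction_per_decade == pytest.approx(
            beta[names.index("interaction")], abs=1e-10
        )

    def test_complete_cases_define_n(self):
        cohort, _ = _linear_cohort(n=2000)
        cohort.loc[cohort.index[:300], "y"] = np.nan
        res = fit_interaction_model(cohort, ScreenModelSpec("y"))
        assert res.n == 1700

    def test_negating_phenotype_flips_slopes_only(self):
        cohort, _ = _linear_cohort(n=3000)
        a = fit_interaction_model(cohort, ScreenModelSpec("y"))
        flipped = cohort.copy()
        flipped["y"] = -flipped["y"]
        b = fit_interaction_model(flipped, ScreenModelSpec("y"))
        assert b.age_slope_per_decade == pytest.approx(-a.age_slope_per_decade)
        assert b.interaction_per_decade == pytest.approx(-a.interaction_per_decade)
        assert b.p_interaction == pytest.approx(a.p_interaction, rel=1e-9)
        assert b.percent_ratio == pytest.approx(a.percent_ratio, rel=1e-9)

    def test_lower_better_direction_equals_manual_negation(self):
        cohort, _ = _linear_cohort(n=1000)
        auto = fit_interaction_model(
            cohort, ScreenModelSpec("y", direction="lower_better")
        )
        manual = cohort.copy()
        manual["y"] = -manual["y"]
        ref = fit_interaction_model(manual, ScreenModelSpec("y"))
        assert auto.age_slope_per_decade == ref.age_slope_per_decade

    def test_age_unit_rescaling_invariance(self):
        """Years vs decades: slopes reported per decade either way, and the
        interaction t-statistic (hence p) is unchanged to 1e-10."""
        cohort, _ = _linear_cohort(n=2500)
        dec = fit_interaction_model(cohort, ScreenModelSpec("y", age_unit="decades"))
        yrs = fit_interaction_model(cohort, ScreenModelSpec("y", age_unit="years"))
        assert yrs.age_slope_per_decade == pytest.approx(
            dec.age_slope_per_decade, abs=1e-10
        )
        assert yrs.interaction_per_decade == pytest.approx(
            dec.interaction_per_decade, abs=1e-10
        )
        assert yrs.p_interaction == pytest.approx(dec.p_interaction, abs=1e-10)

    def test_collinear_design_named_in_error(self):
        cohort, _ = _linear_cohort(n=500)
        cohort["pc1"] = cohort["pc2"] * 2.0  # exact collinearity
        with pytest.raises(np.linalg.LinAlgError, match="pc"):
            fit_interaction_model(
                cohort, ScreenModelSpec("y", covariates=("pc1", "pc2"))
            )

    def test_logit_link_on_binary_phenotype(self):
        spec = PhenotypeSpec(
            name="b",
            scale="binary",
            base_coefs=(0.5, -0.4, 0.0),
            true_threshold_age=40.0,
            divergence_coef=-0.3,
            divergence_order=1,
        )
        cfg = SimulationConfig(n_participants=20_000, seed=9, phenotype_specs=(spec,))
        cohort = simulate_cohort(cfg)
        res = fit_interaction_model(cohort, ScreenModelSpec("b", link="logit"))
        assert res.link == "logit"
        assert res.age_slope_per_decade == pytest.approx(-0.4, abs=0.15)
        assert res.interaction_per_decade == pytest.approx(-0.3, abs=0.15)


class TestScreenAll:
    def test_powered_phenotypes_selected(self):
        """5 of 32 phenotypes carry interactions sized >= 5 SE; exactly those
        survive Bonferroni."""
        n = 20_000
        # the interaction regressor z*t has residual variance ~0.75 after
        # partialling out {1, t, z}, so SE ~ 1/sqrt(0.75 n) ~ 0.008; use ~6 SE
        strong = 0.05
        specs = []
        for i in range(32):
            coef = strong if i < 5 else 0.0
            specs.append(
                PhenotypeSpec(
                    name=f"p{i:02d}",
                    base_coefs=(0.0, -0.2, 0.0),
                    true_threshold_age=40.0 if coef else None,
                    divergence_coef=-coef,
                    divergence_order=1,
                    residual_sd=1.0,
                )
            )
        cfg = SimulationConfig(n_participants=n, seed=17, phenotype_specs=tuple(specs))
        cohort = simulate_cohort(cfg)
        outcome = screen_all(
            cohort, [ScreenModelSpec(s.name) for s in specs], alpha=0.05
        )
        assert outcome.m == 32
        assert sorted(outcome.selected) == [f"p{i:02d}" for i in range(5)]

    def test_single_phenotype_threshold_is_alpha(self):
        cohort, _ = _linear_cohort(n=500)
        outcome = screen_all(cohort, [ScreenModelSpec("y")], alpha=0.05)
        assert outcome.threshold == pytest.approx(0.05)

    def test_results_sorted_by_percent_ratio_magnitude(self):
        cohort, _ = _linear_cohort(n=2000)
        cohort["y2"] = cohort["y"] + np.linspace(0, 1, len(cohort))
        outcome = screen_all(
            cohort, [ScreenModelSpec("y"), ScreenModelSpec("y2")], alpha=0.05
        )
        ratios = [abs(r.percent_ratio) for r in outcome.results]
        assert ratios == sorted(ratios, reverse=True)

    def test_failures_recorded_and_count_toward_m(self):
        cohort, _ = _linear_cohort(n=500)
        cohort["bad"] = np.nan  # no complete cases at all
        with pytest.warns(UserWarning, match="failed"):
            outcome = screen_all(
                cohort, [ScreenModelSpec("y"), ScreenModelSpec("bad")], alpha=0.05
            )
        assert "bad" in outcome.failures
        assert outcome.m == 2
        assert outcome.threshold == pytest.approx(0.025)
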