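"""Seeded Monte-Carlo experiments characterizing the two-stage procedure.

These harnesses define the simulation study the test suite and the
reproduction script both run: threshold recovery when a true divergence age
exists, null behavior of the threshold search and of the Bonferroni screen,
and boundary behavior when divergence is active at the youngest observed
age.

Study conditions (module constants): cohorts of 100 000 participants aged
uniformly 40-70, residual SD 1, a quadratic age trend with a cubic
divergence term of -0.02 per decade^3 per SD of the risk score (a magnitude
inside the range of interaction slopes reported for the cognitive measures
that survive screening), sex/assay/10-PC covariates, 20 replicates for the
threshold experiments and 200 for the screen's family-wise error rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import PhenotypeSpec, SimulationConfig, simulate_cohort
from .divergence import DivergenceModelSpec, ThresholdGrid, select_threshold
from .screen import ScreenModelSpec, screen_all

__all__ = [
    "STUDY_N",
    "STUDY_DIVERGENCE_COEF",
    "STUDY_COVARIATES",
    "make_study_cohort",
    "ThresholdExperimentResult",
    "threshold_experiment",
    "null_screen_fwer",
]

STUDY_N = 100_000
STUDY_DIVERGENCE_COEF = -0.02  # per decade^3 per SD of the score
STUDY_COVARIATES: tuple[str, ...] = ("sex", "assay") + tuple(
    f"pc{i}" for i in range(1, 11)
)
#: quadratic age trend typical of the screened cognitive measures
STUDY_BASE_COEFS = (0.0, -0.25, -0.05)


def study_phenotype_spec(
    true_threshold: float | None,
    divergence_coef: float = STUDY_DIVERGENCE_COEF,
    name: str = "cognition",
) -> PhenotypeSpec:
    return PhenotypeSpec(
        name=name,
        scale="continuous",
        direction="higher_better",
        base_coefs=STUDY_BASE_COEFS,
        true_threshold_age=true_threshold,
        divergence_coef=divergence_coef if true_threshold is not None else 0.0,
        divergence_order=3,
        covariate_effects={"sex": 0.1, "pc1": 0.05},
        residual_sd=1.0,
    )


def make_study_cohort(
    seed: int,
    true_threshold: float | None,
    divergence_coef: float = STUDY_DIVERGENCE_COEF,
    n: int = STUDY_N,
    n_phenotypes: int = 1,
):
    """One simulated cohort under the study conditions.

    With ``n_phenotypes > 1`` the cohort carries that many independent
    copies (used for the null screen), all sharing the same generative
    parameters.
    """
    specs = tuple(
        study_phenotype_spec(
            true_threshold, divergence_coef, name=f"cognition_{i}" if n_phenotypes > 1 else "cognition"
        )
        for i in range(n_phenotypes)
    )
    config = SimulationConfig(
        n_participants=n,
        seed=seed,
        phenotype_specs=specs,
        n_centers=1,  # center dummies excluded from the study covariate set
    )
    return simulate_cohort(config), config


@dataclass
class ThresholdExperimentResult:
    selected_thresholds: list[float]
    boundary_flags: list[str]

    def recovery_rate(self, true_threshold: float, tol_years: float = 3.0) -> float:
        hits = [
            abs(t - true_threshold) <= tol_years for t in self.selected_thresholds
        ]
        return float(np.mean(hits))

    def median_threshold(self) -> float:
        return float(np.median(self.selected_thresholds))

    def boundary_rate(self, flag: str) -> float:
        return float(np.mean([f == flag for f in self.boundary_flags]))


def threshold_experiment(
    true_threshold: float | None,
    n_replicates: int = 20,
    base_seed: int = 0,
    divergence_coef: float = STUDY_DIVERGENCE_COEF,
    n: int = STUDY_N,
) -> ThresholdExperimentResult:
    """Replicate cohorts and run the threshold search on each.

    ``true_threshold=None`` simulates the null (no divergence at any age).
    Seeds are derived deterministically from ``base_seed``.
    """
    selected: list[float] = []
    flags: list[str] = []
    for rep in range(n_replicates):
        seed = (base_seed * 100_003 + rep) % (2**31 - 1)
        cohort, _ = make_study_cohort(seed, true_threshold, divergence_coef, n=n)
        spec = DivergenceModelSpec(
            phenotype="cognition",
            covariates=STUDY_COVARIATES,
            grid=ThresholdGrid(),
            cv_folds=10,
            fold_seed=seed + 1,
        )
        fit = select_threshold(cohort, spec)
        selected.append(fit.selected_threshold)
        flags.append(fit.boundary_flag)
    return ThresholdExperimentResult(selected, flags)


def null_screen_fwer(
    n_replicates: int = 200,
    n_phenotypes: int = 32,
    alpha: float = 0.05,
    base_seed: int = 0,
    n: int = STUDY_N,
) -> float:
    """Family-wise error rate of the Bonferroni screen under the global null.

    Each replicate simulates a cohort with ``n_phenotypes`` independent
    null phenotypes (no score-age interaction anywhere) and runs the full
    screen; the FWER is the fraction of replicates selecting at least one
    phenotype at the alpha/m threshold.
    """
    rejections = 0
    for rep in range(n_replicates):
        seed = (base_seed * 100_003 + 50_000 + rep) % (2**31 - 1)
        cohort, config = make_study_cohort(
            seed, true_threshold=None, n=n, n_phenotypes=n_phenotypes
        )
        specs = [
            ScreenModelSpec(phenotype=s.name, covariates=STUDY_COVARIATES)
            for s in config.phenotype_specs
        ]
        outcome = screen_all(cohort, specs, alpha=alpha)
        if outcome.selected:
            rejections += 1
    return rejections / n_replicates
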