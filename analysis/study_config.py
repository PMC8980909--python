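"""Shared configuration of the synthetic study the analysis scripts run.

One cohort of 20 000 participants aged 40-70 carrying a 12-measure cognitive
battery built to mirror the structure of a large biobank battery: counts,
times (lower is better) and a binary pass/fail measure; six measures with a
true risk-score divergence age between 48 and 62; heavy and very uneven
per-test missingness so per-measure analytic samples range from ~3000 to
~19 000.  All scripts regenerate the cohort deterministically from the same
seed, so they can be run independently and in any order.
"""

from pathlib import Path

from divage import PhenotypeSpec, SimulationConfig
from divage.divergence import ThresholdGrid

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

STUDY_SEED = 20_220_404
COVARIATES = ("sex", "assay", "center") + tuple(f"pc{i}" for i in range(1, 11))
GRID = ThresholdGrid()  # integer ages 40..70
FOLD_SEED = 7
ALPHA = 0.05

#: the synthetic cognitive battery; coefficient scales follow each measure's
#: native units (counts, seconds), age in decades since 40
BATTERY = (
    PhenotypeSpec(
        name="pairs_match_correct_r1", scale="count", direction="higher_better",
        base_coefs=(10.0, -0.4, -0.08), true_threshold_age=48.0,
        divergence_coef=-0.12, residual_sd=1.6, missing_frac=0.10,
        covariate_effects={"sex": 0.2, "pc1": 0.1},
    ),
    PhenotypeSpec(
        name="pairs_match_time_r1", scale="continuous", direction="lower_better",
        base_coefs=(32.0, 2.5, 0.5), true_threshold_age=50.0,
        divergence_coef=0.6, residual_sd=6.0, missing_frac=0.10,
        covariate_effects={"sex": -0.5},
    ),
    PhenotypeSpec(
        name="pairs_match_incorrect_r1", scale="count", direction="lower_better",
        base_coefs=(4.0, 0.6, 0.1), true_threshold_age=52.0,
        divergence_coef=0.25, residual_sd=2.2, missing_frac=0.15,
    ),
    PhenotypeSpec(
        name="symbol_digit_correct", scale="count", direction="higher_better",
        base_coefs=(24.0, -1.4, -0.2), true_threshold_age=55.0,
        divergence_coef=-0.45, residual_sd=4.5, missing_frac=0.60,
        covariate_effects={"practice": 0.8},
    ),
    PhenotypeSpec(
        name="symbol_digit_time", scale="continuous", direction="lower_better",
        base_coefs=(55.0, 4.0, 0.8), true_threshold_age=55.0,
        divergence_coef=1.0, residual_sd=9.0, missing_frac=0.60,
    ),
    PhenotypeSpec(
        name="numeric_memory_max_digits", scale="count", direction="higher_better",
        base_coefs=(7.0, -0.3, -0.05), true_threshold_age=58.0,
        divergence_coef=-0.18, residual_sd=1.4, missing_frac=0.70,
    ),
    PhenotypeSpec(
        name="fluid_intelligence_correct", scale="count", direction="higher_better",
        base_coefs=(6.5, -0.25, -0.04), residual_sd=2.0, missing_frac=0.50,
        covariate_effects={"pc2": -0.1},
    ),
    PhenotypeSpec(
        name="prospective_memory_first_try", scale="binary", direction="higher_better",
        base_coefs=(1.6, -0.35, 0.0), missing_frac=0.40,
    ),
    PhenotypeSpec(
        name="reaction_time_mean", scale="continuous", direction="lower_better",
        base_coefs=(540.0, 25.0, 4.0), residual_sd=90.0, missing_frac=0.05,
    ),
    PhenotypeSpec(
        name="trail_making_b_time", scale="continuous", direction="lower_better",
        base_coefs=(60.0, 8.0, 1.5), true_threshold_age=62.0,
        divergence_coef=2.0, residual_sd=22.0, missing_frac=0.80,
    ),
    PhenotypeSpec(
        name="matrix_completion_correct", scale="count", direction="higher_better",
        base_coefs=(8.0, -0.3, -0.05), residual_sd=2.4, missing_frac=0.85,
    ),
    PhenotypeSpec(
        name="paired_associate_learning", scale="count", direction="higher_better",
        base_coefs=(6.0, -0.5, -0.08), residual_sd=2.1, missing_frac=0.75,
    ),
)


def build_simulation_config(n: int = 20_000, seed: int = STUDY_SEED) -> SimulationConfig:
    return SimulationConfig(
        n_participants=n,
        seed=seed,
        prop_female=0.54,
        n_centers=10,
        prop_assay_b=0.33,
        n_pcs=10,
        phenotype_specs=BATTERY,
    )


def ensure_dirs() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
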