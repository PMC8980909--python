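"""Synthetic cohort generation for gene-by-age analyses of cognitive decline.

Emulates a midlife population cohort (ages 40-70 at testing) carrying a
standardized polygenic risk score, standard epidemiological covariates
(sex, assessment center, genotyping assay, practice indicator, 10 ancestry
principal components) and a battery of cognitive phenotypes whose population
mean is quadratic in age, with a risk-score-dependent divergence term that
switches on above a configurable threshold age:

    E[Y | t, z, W] = b0 + b1*t + b2*t^2 + g*z + c*z*max(0, t - t_thr)^p + W'b

with t age in decades since 40, z the z-scored risk score, c the divergence
coefficient and p the divergence order (cubic by default, so the mean is C^2
at the threshold).  Binary phenotypes pass this linear predictor through a
logistic link; count phenotypes are rounded and floored at zero.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grs import VariantWeight, DosageMatrix, zscore_values

__all__ = [
    "PhenotypeSpec",
    "SimulationConfig",
    "phenotype_mean",
    "simulate_cohort",
    "simulate_genotypes",
    "write_cohort",
    "read_cohort",
]

AGE_CENTER_YEARS = 40.0
DECADE_YEARS = 10.0

#: numeric covariate columns a PhenotypeSpec may attach effects to
_EFFECT_COLUMNS = ("sex", "assay", "practice") + tuple(f"pc{i}" for i in range(1, 21))


@dataclass(frozen=True)
class PhenotypeSpec:
    """Generative description of one cognitive phenotype.

    Parameters
    ----------
    name:
        Column name in the simulated cohort.
    scale:
        ``"continuous"``, ``"binary"`` or ``"count"``.  Count outcomes are
        rounded, zero-floored continuous draws (the analysis treats ordinal
        measures with an identity link, so a full count GLM is not needed).
    direction:
        ``"higher_better"`` or ``"lower_better"`` -- recorded so the screen
        can harmonize signs (times/error counts are lower-is-better).
    base_coefs:
        (b0, b1, b2): intercept, age and age^2 coefficients on the linear
        predictor scale, age in decades since 40.
    true_threshold_age:
        Years at which the risk-score divergence activates, or ``None`` for
        a null phenotype (mean independent of the score at all ages).
    divergence_coef:
        Coefficient on z * max(0, t - t_thr)^order, per decade^order.
    divergence_order:
        Power of the truncated age term (default 3, cubic).
    grs_main_effect:
        Age-constant score effect on the linear predictor (default 0: below
        the threshold the mean does not depend on the score).
    covariate_effects:
        Map of covariate column -> additive effect on the linear predictor.
    residual_sd:
        Gaussian residual SD (continuous and count scales).
    missing_frac:
        Completely-at-random missingness fraction for this phenotype.
    missing_age_slope:
        Optional increase in missingness probability per decade of age above
        the cohort midpoint (healthy-volunteer-style dropout); default 0.
    """

    name: str
    scale: str = "continuous"
    direction: str = "higher_better"
    base_coefs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    true_threshold_age: float | None = None
    divergence_coef: float = 0.0
    divergence_order: int = 3
    grs_main_effect: float = 0.0
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    residual_sd: float = 1.0
    missing_frac: float = 0.0
    missing_age_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.scale not in {"continuous", "binary", "count"}:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.direction not in {"higher_better", "lower_better"}:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.divergence_order < 1:
            raise ValueError("divergence_order must be >= 1")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if not 0.0 <= self.missing_frac <= 1.0:
            raise ValueError("missing_frac must lie in [0, 1]")
        for key in self.covariate_effects:
            if key not in _EFFECT_COLUMNS:
                raise ValueError(
                    f"covariate_effects key {key!r} is not a numeric covariate "
                    f"column (expected one of sex/assay/practice/pc*)"
                )


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters."""

    n_participants: int
    seed: int
    age_range: tuple[float, float] = (40.0, 70.0)
    prop_female: float = 0.54
    n_centers: int = 22
    prop_assay_b: float = 0.5
    prop_practice: float = 0.3
    n_pcs: int = 10
    grs_mean: float = 0.0
    grs_sd: float = 1.0
    phenotype_specs: tuple[PhenotypeSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be a positive integer")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range must be increasing, got {self.age_range}")
        for name, value in (
            ("prop_female", self.prop_female),
            ("prop_assay_b", self.prop_assay_b),
            ("prop_practice", self.prop_practice),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_centers < 1:
            raise ValueError("n_centers must be positive")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be non-negative")
        if self.grs_sd <= 0:
            raise ValueError("grs_sd must be positive")
        names = [s.name for s in self.phenotype_specs]
        if len(set(names)) != len(names):
            raise ValueError("phenotype names must be unique")
        object.__setattr__(self, "phenotype_specs", tuple(self.phenotype_specs))


def _age_decades(age: np.ndarray | float) -> np.ndarray | float:
    return (np.asarray(age, dtype=float) - AGE_CENTER_YEARS) / DECADE_YEARS


def divergence_term(
    age: np.ndarray | float,
    grs_z: np.ndarray | float,
    threshold_age: float,
    order: int,
) -> np.ndarray | float:
    """z * max(0, t - t_thr)^order with t, t_thr in decades since 40."""
    t = _age_decades(age)
    t_thr = (threshold_age - AGE_CENTER_YEARS) / DECADE_YEARS
    return np.asarray(grs_z, dtype=float) * np.maximum(0.0, t - t_thr) ** order


def phenotype_mean(
    spec: PhenotypeSpec,
    age: np.ndarray | float,
    grs_z: np.ndarray | float,
    covariates: Mapping[str, float] | None = None,
) -> np.ndarray | float:
    """Population mean of a phenotype at given age / score / covariates.

    Returns the linear-predictor mean for continuous and count scales and
    the logistic-transformed probability for the binary scale.
    """
    t = _age_decades(age)
    b0, b1, b2 = spec.base_coefs
    lp = b0 + b1 * t + b2 * t**2 + spec.grs_main_effect * np.asarray(grs_z, float)
    if spec.true_threshold_age is not None and spec.divergence_coef != 0.0:
        lp = lp + spec.divergence_coef * divergence_term(
            age, grs_z, spec.true_threshold_age, spec.divergence_order
        )
    if covariates:
        for key, effect in spec.covariate_effects.items():
            lp = lp + effect * float(covariates.get(key, 0.0))
    if spec.scale == "binary":
        return 1.0 / (1.0 + np.exp(-lp))
    return lp


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw a cohort table with covariates, z-scored risk score and phenotypes.

    Ages are uniform on ``config.age_range``; the raw score is
    Normal(grs_mean, grs_sd) and is z-scored against the sample itself, as a
    real analysis standardizes against the full scored sample.  Identical
    config (including seed) yields a bit-identical table.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    lo, hi = config.age_range

    table = pd.DataFrame(
        {
            "participant_id": [f"P{i:07d}" for i in range(n)],
            "age": rng.uniform(lo, hi, size=n),
            "sex": (rng.random(n) < config.prop_female).astype(np.int64),
            "center": rng.integers(0, config.n_centers, size=n),
            "assay": (rng.random(n) < config.prop_assay_b).astype(np.int64),
            "practice": (rng.random(n) < config.prop_practice).astype(np.int64),
        }
    )
    for i in range(1, config.n_pcs + 1):
        table[f"pc{i}"] = rng.standard_normal(n)

    raw = config.grs_mean + config.grs_sd * rng.standard_normal(n)
    table["grs_raw"] = raw
    table["grs_z"] = zscore_values(raw) if n >= 2 else np.zeros(n)

    mid_age = 0.5 * (lo + hi)
    for spec in config.phenotype_specs:
        cov = {
            key: table[key].to_numpy(dtype=float)
            for key in spec.covariate_effects
            if key in table.columns
        }
        lp = phenotype_mean_array(spec, table["age"].to_numpy(), table["grs_z"].to_numpy(), cov)
        if spec.scale == "binary":
            prob = 1.0 / (1.0 + np.exp(-lp))
            values = (rng.random(n) < prob).astype(float)
        else:
            values = lp + spec.residual_sd * rng.standard_normal(n)
            if spec.scale == "count":
                values = np.maximum(0.0, np.rint(values))
        p_miss = spec.missing_frac + spec.missing_age_slope * (
            (table["age"].to_numpy() - mid_age) / DECADE_YEARS
        )
        p_miss = np.clip(p_miss, 0.0, 1.0)
        if np.any(p_miss > 0):
            values = np.where(rng.random(n) < p_miss, np.nan, values)
        table[spec.name] = values
    return table


def phenotype_mean_array(
    spec: PhenotypeSpec,
    age: np.ndarray,
    grs_z: np.ndarray,
    covariate_columns: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Vectorized linear predictor used by the generator (identity scale)."""
    t = _age_decades(age)
    b0, b1, b2 = spec.base_coefs
    lp = b0 + b1 * t + b2 * t**2 + spec.grs_main_effect * grs_z
    if spec.true_threshold_age is not None and spec.divergence_coef != 0.0:
        lp = lp + spec.divergence_coef * divergence_term(
            age, grs_z, spec.true_threshold_age, spec.divergence_order
        )
    if covariate_columns:
        for key, effect in spec.covariate_effects.items():
            if key in covariate_columns:
                lp = lp + effect * covariate_columns[key]
    return lp


def simulate_genotypes(
    weights: Sequence[VariantWeight],
    n: int,
    allele_freqs: Sequence[float],
    seed: int,
    missing_frac: float = 0.0,
) -> DosageMatrix:
    """Hardy-Weinberg effect-allele dosages for a set of weighted variants.

    Each participant's dosage at variant *j* is Binomial(2, allele_freqs[j]).
    The returned matrix counts each variant's effect allele.
    """
    if len(allele_freqs) != len(weights):
        raise ValueError("one allele frequency per variant weight is required")
    freqs = np.asarray(allele_freqs, dtype=float)
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    if n < 1:
        raise ValueError("n must be positive")
    if not 0.0 <= missing_frac < 1.0:
        raise ValueError("missing_frac must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, freqs, size=(n, len(weights))).astype(float)
    if missing_frac > 0.0:
        dosages[rng.random(dosages.shape) < missing_frac] = np.nan
    return DosageMatrix(
        participant_ids=tuple(f"P{i:07d}" for i in range(n)),
        snv_ids=tuple(w.snv_id for w in weights),
        dosages=dosages,
        counted_alleles={w.snv_id: w.effect_allele for w in weights},
        positions={w.snv_id: (w.chrom, w.pos) for w in weights},
        alleles={w.snv_id: (w.effect_allele, w.other_allele) for w in weights},
    )


# ---------------------------------------------------------------------------
# cohort I/O: tab-delimited table + JSON sidecar with column roles and truth


def write_cohort(table: pd.DataFrame, config: SimulationConfig, path: str | Path) -> Path:
    """Write the cohort as TSV plus a ``<path>.meta.json`` sidecar.

    The sidecar records column roles, per-phenotype direction conventions
    and the true generative parameters, so recovery tests can be run against
    the file alone.
    """
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
    meta = {
        "column_roles": {
            "id": "participant_id",
            "age": "age",
            "covariates": ["sex", "center", "assay", "practice"]
            + [f"pc{i}" for i in range(1, config.n_pcs + 1)],
            "grs_raw": "grs_raw",
            "grs_z": "grs_z",
            "phenotypes": [s.name for s in config.phenotype_specs],
        },
        "directions": {s.name: s.direction for s in config.phenotype_specs},
        "scales": {s.name: s.scale for s in config.phenotype_specs},
        "true_parameters": [asdict(s) for s in config.phenotype_specs],
        "config": {
            k: v for k, v in asdict(config).items() if k != "phenotype_specs"
        },
    }
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, default=_jsonable))
    return sidecar


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a cohort TSV and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        warnings.warn(f"no sidecar metadata found at {sidecar}")
    return table, meta
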