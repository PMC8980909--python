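"""Earliest age at which the high-vs-low risk-score gap is detectable.

After the divergence model fixes the age at which modeled mean cognition
begins to separate by risk-score level, this module asks a different
question: at what age does that separation first become *statistically
detectable* with a one-sided two-sample t-test (high-score group performing
worse) at P <= alpha?

For each candidate age a, the modeled mean difference between the
high-score group (default: above the sample's 95th percentile of the
z-scored GRS) and the low-score group (below the 5th percentile) at
reference covariates is combined with the fitted model's residual SD and
with the observed group sizes -- cohort participants whose age falls in
[a - step/2, a + step/2) and whose score lies in the respective tail -- to
form the t statistic.  Detection can therefore never precede the model's
divergence age (below it the mean difference is exactly zero), and the gap
between the two ages reflects residual noise and tail-group sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .divergence import DivergenceFit, predict_trajectory

__all__ = [
    "DetectionSpec",
    "DetectionResult",
    "earliest_detectable_age",
    "detection_report_frame",
    "arrow_summary",
]


@dataclass(frozen=True)
class DetectionSpec:
    """Configuration of the detectability scan.

    ``grs_high`` / ``grs_low`` default to the cohort's 95th / 5th
    percentiles of the z-scored score; group membership is strictly above /
    below those cut points.  ``reference_covariates`` (default: all zero,
    i.e. reference category and median-zero principal components) shift both
    groups equally and cancel from the difference.
    """

    grs_high: float | None = None
    grs_low: float | None = None
    alpha: float = 0.05
    age_step: float = 1.0
    reference_covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.age_step <= 0:
            raise ValueError("age_step must be positive")
        if (
            self.grs_high is not None
            and self.grs_low is not None
            and not self.grs_high > self.grs_low
        ):
            raise ValueError("grs_high must exceed grs_low")


@dataclass
class DetectionResult:
    phenotype: str
    divergence_threshold: float
    earliest_detectable_age: float | None
    p_by_age: dict[float, float]
    grs_high: float
    grs_low: float
    alpha: float


def earliest_detectable_age(
    fit: DivergenceFit,
    cohort: pd.DataFrame,
    spec: DetectionSpec | None = None,
) -> DetectionResult:
    """Scan ages for the first one-sided t-test detection of the score gap.

    At each age on the fit's grid (stepped by ``age_step``), the modeled
    mean difference low-minus-high (harmonized so positive means the
    high-score group performs worse) is tested against zero with

        t = (mu_low - mu_high) / (s * sqrt(1/n_high + 1/n_low)),

    s the fitted model's residual SD and n the tail-group counts in that
    age bin.  Ages with an empty tail group are skipped with a warning.
    Returns the youngest age with p <= alpha, or None.
    """
    spec = spec or DetectionSpec()
    grs = cohort["grs_z"].to_numpy(dtype=float)
    grs = grs[np.isfinite(grs)]
    z_hi = spec.grs_high if spec.grs_high is not None else float(np.percentile(grs, 95))
    z_lo = spec.grs_low if spec.grs_low is not None else float(np.percentile(grs, 5))
    if not z_hi > z_lo:
        raise ValueError("high-score cut point must exceed low-score cut point")

    age_col = cohort["age"].to_numpy(dtype=float)
    grs_col = cohort["grs_z"].to_numpy(dtype=float)
    ages = np.arange(fit.grid[0], fit.grid[-1] + spec.age_step / 2, spec.age_step)

    mean_hi = predict_trajectory(fit, z_hi, spec.reference_covariates, ages)
    mean_lo = predict_trajectory(fit, z_lo, spec.reference_covariates, ages)
    delta = mean_lo - mean_hi  # positive when the high-score group is worse

    p_by_age: dict[float, float] = {}
    earliest: float | None = None
    for a, d in zip(ages, delta):
        in_bin = (age_col >= a - spec.age_step / 2) & (age_col < a + spec.age_step / 2)
        n_hi = int(np.sum(in_bin & (grs_col > z_hi)))
        n_lo = int(np.sum(in_bin & (grs_col < z_lo)))
        if n_hi == 0 or n_lo == 0:
            warnings.warn(f"age {a:g}: empty tail group (n_high={n_hi}, "
                          f"n_low={n_lo}); age skipped")
            p_by_age[float(a)] = float("nan")
            continue
        se = fit.residual_sd * np.sqrt(1.0 / n_hi + 1.0 / n_lo)
        tstat = d / se
        p = float(stats.t.sf(tstat, df=n_hi + n_lo - 2))
        p_by_age[float(a)] = p
        if earliest is None and p <= spec.alpha:
            earliest = float(a)

    if earliest is not None and earliest < fit.selected_threshold:
        raise AssertionError(
            "detection age precedes the model's divergence age; the modeled "
            "difference below the threshold must be zero"
        )
    return DetectionResult(
        phenotype=fit.phenotype,
        divergence_threshold=fit.selected_threshold,
        earliest_detectable_age=earliest,
        p_by_age=p_by_age,
        grs_high=z_hi,
        grs_low=z_lo,
        alpha=spec.alpha,
    )


def detection_report_frame(results: Sequence[DetectionResult]) -> pd.DataFrame:
    """Tidy table: one row per (phenotype, age) with the scan p-value."""
    rows = []
    for r in results:
        for age, p in sorted(r.p_by_age.items()):
            rows.append(
                {
                    "phenotype": r.phenotype,
                    "age": age,
                    "p_one_sided": p,
                    "divergence_threshold": r.divergence_threshold,
                    "earliest_detectable_age": r.earliest_detectable_age,
                }
            )
    return pd.DataFrame(rows)


def arrow_summary(results: Sequence[DetectionResult]) -> str:
    """Text rendering of divergence vs detection ages, one line per phenotype."""
    lines = []
    for r in sorted(results, key=lambda r: r.divergence_threshold):
        det = (
            f"detectable from {r.earliest_detectable_age:.0f}"
            if r.earliest_detectable_age is not None
            else "not detectable in range"
        )
        lines.append(
            f"{r.phenotype:<32s} diverges {r.divergence_threshold:>4.0f} --> {det}"
        )
    return "\n".join(lines)
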