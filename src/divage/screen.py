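"""Stage 1: age x risk-score interaction screen over cognitive phenotypes.

For each phenotype Y the model

    Y ~ link(b_age * Age + b_grs * GRSz + b_int * GRSz x Age + covariates)

is fit by ordinary least squares (identity link; continuous and ordinal
measures) or maximum-likelihood logistic regression (logit link; binary
measures) on complete cases.  The screen reports, per phenotype, the age
slope for a person with mean risk score, the interaction slope (both per
decade of age, with Wald 95% CIs), the interaction's percentage of the age
slope (100 x b_int / b_age, the effect-size metric used to rank phenotypes)
and a Bonferroni significance flag at alpha / (number of phenotypes).

Coefficients are named by role (age_main, grs_main, interaction), never by
index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .design import covariate_columns, complete_case_mask

__all__ = [
    "ScreenModelSpec",
    "ScreenResult",
    "ScreenOutcome",
    "harmonize_direction",
    "fit_interaction_model",
    "percent_ratio",
    "bonferroni_threshold",
    "screen_all",
    "screen_report_frame",
]

_Z95 = 1.959963984540054  # standard-normal 97.5% quantile for Wald CIs


@dataclass(frozen=True)
class ScreenModelSpec:
    """Per-phenotype screen configuration.

    ``age_unit`` sets the unit of the age regressor actually entered in the
    model ("years" or "decades"); reported slopes are always per decade.
    ``direction`` triggers sign harmonization so that larger values always
    mean better performance (times and error counts are lower-is-better).
    """

    phenotype: str
    link: str = "identity"
    covariates: tuple[str, ...] = ()
    age_center: float = 40.0
    age_unit: str = "decades"
    direction: str = "higher_better"

    def __post_init__(self) -> None:
        if self.link not in {"identity", "logit"}:
            raise ValueError(f"unknown link {self.link!r}")
        if self.age_unit not in {"years", "decades"}:
            raise ValueError(f"unknown age_unit {self.age_unit!r}")
        if self.direction not in {"higher_better", "lower_better"}:
            raise ValueError(f"unknown direction {self.direction!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass
class ScreenResult:
    """Per-phenotype screen estimates, reported per decade of age."""

    phenotype: str
    n: int
    age_slope_per_decade: float
    age_slope_ci: tuple[float, float]
    interaction_per_decade: float
    interaction_ci: tuple[float, float]
    p_interaction: float
    percent_ratio: float
    significant: bool = False
    grs_main: float = float("nan")
    link: str = "identity"
    direction: str = "higher_better"


@dataclass
class ScreenOutcome:
    """All screen results plus the Bonferroni selection."""

    results: list[ScreenResult]
    selected: list[str]
    m: int
    alpha: float
    threshold: float
    failures: dict[str, str] = field(default_factory=dict)


def harmonize_direction(values: np.ndarray | pd.Series, direction: str) -> np.ndarray:
    """Recode a phenotype so larger values mean better performance.

    lower_better columns (times, error counts) are negated; higher_better
    columns are returned unchanged.  Applying the transformation twice with
    ``lower_better`` returns the original values.
    """
    arr = np.asarray(values, dtype=float)
    if direction == "higher_better":
        return arr.copy()
    if direction == "lower_better":
        return -arr
    raise ValueError(f"unknown direction {direction!r}")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise corrected per-test threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be a positive integer, got {m}")
    return alpha / m


def percent_ratio(age_slope: float, interaction: float) -> float:
    """Interaction slope as a percentage of the age slope: 100 x b_int / b_age.

    Same-signed inputs give a positive percentage, read as a faster
    age-related change for a 1-SD higher risk score.  A zero age slope makes
    the ratio undefined; NaN is returned with a warning.
    """
    if interaction == 0.0:
        return 0.0
    if age_slope == 0.0:
        warnings.warn("percent ratio undefined: age slope is zero")
        return float("nan")
    return 100.0 * interaction / age_slope


def _screen_design(
    cohort: pd.DataFrame, spec: ScreenModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Complete-case (X, y, column names, n) for one screen model."""
    needed = [spec.phenotype, "age", "grs_z", *spec.covariates]
    mask = complete_case_mask(cohort, needed)
    sub = cohort[needed] if mask.all() else cohort.loc[mask, needed]
    n = len(sub)

    scale = 1.0 if spec.age_unit == "years" else 10.0
    age = (sub["age"].to_numpy(dtype=float) - spec.age_center) / scale
    grs = sub["grs_z"].to_numpy(dtype=float)
    cov_pairs = covariate_columns(sub, spec.covariates)

    # Fortran order: LAPACK's QR then factors the matrix without a transpose
    X = np.empty((n, 4 + len(cov_pairs)), order="F")
    X[:, 0] = 1.0
    X[:, 1] = age
    X[:, 2] = grs
    X[:, 3] = age * grs
    for j, (_, col) in enumerate(cov_pairs):
        X[:, 4 + j] = col
    names = ["intercept", "age_main", "grs_main", "interaction"] + [
        name for name, _ in cov_pairs
    ]
    y = harmonize_direction(sub[spec.phenotype], spec.direction)
    return X, y, names, n


@dataclass
class _OLSFactor:
    """QR factorization of one screen design, reusable across outcomes."""

    X: np.ndarray
    R: np.ndarray
    names: list[str]
    n: int
    xtx_inv_diag: np.ndarray


def _ols_factor(X: np.ndarray, names: list[str], phenotype: str) -> _OLSFactor:
    """Factor the design once: least squares goes through the triangular R
    of X's QR decomposition, never through an explicit (X'X)^-1 X'y product."""
    from scipy.linalg import qr, solve_triangular

    n, p = X.shape
    R = qr(X, mode="r", check_finite=False)[0][:p]
    diag = np.abs(np.diag(R))
    if np.any(diag <= np.max(diag) * n * np.finfo(float).eps):
        _check_full_rank(X, names, phenotype)  # raises, naming columns
    rinv = solve_triangular(R, np.eye(p), check_finite=False)
    return _OLSFactor(X=X, R=R, names=names, n=n, xtx_inv_diag=np.sum(rinv**2, axis=1))


def _ols_wald(
    factor: _OLSFactor, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficients, SEs and two-sided t p-values for one outcome.

    A constant outcome (zero residual variance) carries no evidence about
    any slope: SEs are zeroed and p-values set to 1 rather than left 0/0.
    """
    from scipy.linalg import solve_triangular
    from scipy import stats as _stats

    X, R = factor.X, factor.R
    n, p = X.shape
    xty = X.T @ y
    params = solve_triangular(
        R, solve_triangular(R, xty, trans="T", check_finite=False), check_finite=False
    )
    resid = y - X @ params
    ssr = float(resid @ resid)
    if ssr <= 1e-14 * max(float(y @ y), 1e-300):
        return params, np.zeros(p), np.ones(p)
    sigma2 = ssr / (n - p)
    bse = np.sqrt(sigma2 * factor.xtx_inv_diag)
    tvals = params / bse
    pvalues = 2.0 * _stats.t.sf(np.abs(tvals), df=n - p)
    return params, bse, pvalues


def _fit_logit(
    X: np.ndarray, y: np.ndarray, names: list[str], phenotype: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    _check_full_rank(X, names, phenotype)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError, RuntimeWarning) as exc:
        raise RuntimeError(
            f"{phenotype}: logistic fit failed ({exc}); check for separation "
            f"or a degenerate outcome"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"{phenotype}: logistic fit did not converge")
    return res.params, res.bse, res.pvalues


def _result_from_estimates(
    spec: ScreenModelSpec,
    names: list[str],
    n: int,
    params: np.ndarray,
    bse: np.ndarray,
    pvalues: np.ndarray,
) -> ScreenResult:
    # report per decade whatever unit the age regressor used
    rescale = 10.0 if spec.age_unit == "years" else 1.0
    i_age, i_int = names.index("age_main"), names.index("interaction")
    age_slope = params[i_age] * rescale
    age_se = bse[i_age] * rescale
    inter = params[i_int] * rescale
    inter_se = bse[i_int] * rescale
    return ScreenResult(
        phenotype=spec.phenotype,
        n=n,
        age_slope_per_decade=float(age_slope),
        age_slope_ci=(float(age_slope - _Z95 * age_se), float(age_slope + _Z95 * age_se)),
        interaction_per_decade=float(inter),
        interaction_ci=(float(inter - _Z95 * inter_se), float(inter + _Z95 * inter_se)),
        p_interaction=float(min(max(pvalues[i_int], np.nextafter(0, 1)), 1.0)),
        percent_ratio=percent_ratio(float(age_slope), float(inter)),
        grs_main=float(params[names.index("grs_main")]),
        link=spec.link,
        direction=spec.direction,
    )


def fit_interaction_model(cohort: pd.DataFrame, spec: ScreenModelSpec) -> ScreenResult:
    """Fit one phenotype's age x risk-score interaction model.

    QR-based least squares for the identity link, maximum likelihood for
    the logit link, on complete cases; Wald 95% CIs (estimate +/- 1.96 SE).
    Slopes are rescaled to per-decade for reporting regardless of
    ``age_unit``.  Non-convergence or perfect separation raises rather than
    returning silently wrong estimates; a rank-deficient design raises an
    error naming the collinear columns.
    """
    X, y, names, n = _screen_design(cohort, spec)
    if n < X.shape[1]:
        raise ValueError(
            f"{spec.phenotype}: {n} complete cases for {X.shape[1]} parameters"
        )
    if spec.link == "identity":
        params, bse, pvalues = _ols_wald(_ols_factor(X, names, spec.phenotype), y)
    else:
        params, bse, pvalues = _fit_logit(X, y, names, spec.phenotype)
    return _result_from_estimates(spec, names, n, params, bse, pvalues)


def _check_full_rank(X: np.ndarray, names: list[str], phenotype: str) -> None:
    """Raise, naming collinear columns, if the design is rank deficient."""
    xtx = X.T @ X
    rank = np.linalg.matrix_rank(xtx, hermitian=True)
    if rank == X.shape[1]:
        return
    # identify offending columns from the near-null eigenvectors
    eigvals, eigvecs = np.linalg.eigh(xtx)
    tol = eigvals[-1] * X.shape[1] * np.finfo(float).eps
    bad: set[str] = set()
    for k in range(X.shape[1]):
        if eigvals[k] <= tol:
            involved = np.where(np.abs(eigvecs[:, k]) > 1e-8)[0]
            bad.update(names[j] for j in involved)
    raise np.linalg.LinAlgError(
        f"{phenotype}: design matrix is rank deficient "
        f"(rank {rank} < {X.shape[1]}); collinear columns: {sorted(bad)}"
    )


def screen_all(
    cohort: pd.DataFrame,
    specs: Sequence[ScreenModelSpec],
    alpha: float = 0.05,
    count_failures_in_m: bool = True,
) -> ScreenOutcome:
    """Screen every phenotype and apply the Bonferroni selection rule.

    ``m`` defaults to the number of phenotypes *attempted* (failed fits
    still count toward the correction, the conservative choice); results
    are sorted by |percent ratio| descending for reporting.
    """
    if not specs:
        raise ValueError("at least one phenotype spec is required")
    results: list[ScreenResult] = []
    failures: dict[str, str] = {}
    # identity-link phenotypes sharing covariates, age coding and the same
    # complete-case rows also share the design matrix; factor it only once
    factor_cache: dict[tuple, _OLSFactor] = {}
    for spec in specs:
        try:
            if spec.link != "identity":
                results.append(fit_interaction_model(cohort, spec))
                continue
            mask = complete_case_mask(
                cohort, [spec.phenotype, "age", "grs_z", *spec.covariates]
            )
            key = (spec.covariates, spec.age_center, spec.age_unit, mask.tobytes())
            factor = factor_cache.get(key)
            if factor is None:
                X, y, names, n = _screen_design(cohort, spec)
                if n < X.shape[1]:
                    raise ValueError(
                        f"{spec.phenotype}: {n} complete cases for "
                        f"{X.shape[1]} parameters"
                    )
                factor = _ols_factor(X, names, spec.phenotype)
                factor_cache[key] = factor
            else:
                sub = cohort if mask.all() else cohort.loc[mask]
                y = harmonize_direction(sub[spec.phenotype], spec.direction)
            params, bse, pvalues = _ols_wald(factor, y)
            results.append(
                _result_from_estimates(
                    spec, factor.names, factor.n, params, bse, pvalues
                )
            )
        except Exception as exc:  # recorded, never silently swallowed
            failures[spec.phenotype] = str(exc)
            warnings.warn(f"screen fit failed for {spec.phenotype}: {exc}")

    m = len(specs) if count_failures_in_m else len(results)
    if m == 0:
        raise ValueError("no phenotype could be fit")
    threshold = bonferroni_threshold(alpha, m)
    results = [
        replace(r, significant=bool(r.p_interaction < threshold)) for r in results
    ]
    results.sort(
        key=lambda r: (np.isnan(r.percent_ratio), -abs(r.percent_ratio))
    )
    selected = [r.phenotype for r in results if r.significant]
    return ScreenOutcome(
        results=results,
        selected=selected,
        m=m,
        alpha=alpha,
        threshold=threshold,
        failures=failures,
    )


def screen_report_frame(outcome: ScreenOutcome) -> pd.DataFrame:
    """Tidy report table: one row per phenotype, estimates with CI bounds."""
    rows = []
    for r in outcome.results:
        rows.append(
            {
                "phenotype": r.phenotype,
                "n": r.n,
                "age_slope_per_decade": r.age_slope_per_decade,
                "age_slope_ci_low": r.age_slope_ci[0],
                "age_slope_ci_high": r.age_slope_ci[1],
                "interaction_per_decade": r.interaction_per_decade,
                "interaction_ci_low": r.interaction_ci[0],
                "interaction_ci_high": r.interaction_ci[1],
                "p_interaction": r.p_interaction,
                "percent_ratio": r.percent_ratio,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
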