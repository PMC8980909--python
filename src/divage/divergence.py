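"""Stage 2: cross-validated divergence-age (threshold) model.

For a phenotype that survived the interaction screen, the model

    Y ~ link( b0 + b1*t + ... + b_q*t^q
              + b_div * GRSz * max(0, t - t_thr)^(q+1) + covariates )

is fit for every candidate threshold age t_thr on a grid (default integer
ages 40..70), with t age in decades since 40.  Below the threshold the
risk-score association is constrained to zero (no GRS main-effect column),
so the population mean is a single age curve; above it, mean cognition
diverges smoothly by risk-score level through a truncated power term whose
order is one above the base polynomial (quadratic base + cubic divergence by
default, giving a C^2 mean at the knot; linear+quadratic and cubic+quartic
are the rigid and flexible sensitivity forms).

The threshold is selected by minimum mean squared prediction error in a
k-fold cross-validation that reuses one fold partition for every candidate,
so that partition noise cancels out of the comparison.  A selected
threshold at the grid minimum means risk-score-specific curves fit best at
all observed ages; at the maximum, a single curve suffices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import covariate_design, complete_case_mask
from .screen import harmonize_direction

__all__ = [
    "ThresholdGrid",
    "DivergenceModelSpec",
    "DivergenceFit",
    "divergence_basis",
    "build_design",
    "cv_mspe",
    "select_threshold",
    "predict_trajectory",
    "refit_with_grs_main",
    "fit_to_dict",
    "write_fit_json",
    "mspe_long_frame",
]

AGE_CENTER_YEARS = 40.0
DECADE_YEARS = 10.0


@dataclass(frozen=True)
class ThresholdGrid:
    """Ordered candidate threshold ages in years."""

    ages: tuple[float, ...] = tuple(float(a) for a in range(40, 71))

    def __post_init__(self) -> None:
        ages = tuple(float(a) for a in self.ages)
        if not ages:
            raise ValueError("threshold grid is empty")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("threshold grid must be strictly increasing")
        object.__setattr__(self, "ages", ages)

    @classmethod
    def from_range(cls, lo: float, hi: float, step: float = 1.0) -> "ThresholdGrid":
        return cls(tuple(np.arange(lo, hi + step / 2, step)))


@dataclass(frozen=True)
class DivergenceModelSpec:
    """Configuration of one phenotype's threshold model.

    ``divergence_order`` must be ``base_order + 1`` so the modeled mean stays
    C^(base_order) at the knot; ``None`` derives it.
    """

    phenotype: str
    link: str = "identity"
    base_order: int = 2
    divergence_order: int | None = None
    age_center: float = AGE_CENTER_YEARS
    covariates: tuple[str, ...] = ()
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    cv_folds: int = 10
    fold_seed: int = 0
    direction: str = "higher_better"

    def __post_init__(self) -> None:
        if self.link not in {"identity", "logit"}:
            raise ValueError(f"unknown link {self.link!r}")
        if self.base_order not in {1, 2, 3}:
            raise ValueError("base_order must be 1, 2 or 3")
        expected = self.base_order + 1
        if self.divergence_order is None:
            object.__setattr__(self, "divergence_order", expected)
        elif self.divergence_order != expected:
            raise ValueError(
                f"divergence_order must equal base_order + 1 = {expected} "
                f"(got {self.divergence_order})"
            )
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.link == "logit":
            warnings.warn(
                "logit-link threshold selection squares errors on predicted "
                "probabilities; this path is experimental"
            )
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass
class DivergenceFit:
    """Selected threshold, per-threshold CV-MSPE map and refit coefficients."""

    phenotype: str
    grid: tuple[float, ...]
    mspe_by_threshold: dict[float, float]
    selected_threshold: float
    coefficients: dict[str, float]
    boundary_flag: str  # interior | at_min | at_max
    b3_estimable: bool
    residual_sd: float
    n: int
    link: str
    base_order: int
    divergence_order: int
    age_center: float
    cv_folds: int
    fold_seed: int
    direction: str = "higher_better"


def divergence_basis(
    age: np.ndarray | float,
    grs_z: np.ndarray | float,
    threshold: float,
    order: int,
) -> np.ndarray | float:
    """Truncated power interaction grs_z * max(0, t - t_thr)^order.

    t and t_thr are in decades since age 40; the term is identically zero at
    and below the threshold age.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    t = (np.asarray(age, dtype=float) - AGE_CENTER_YEARS) / DECADE_YEARS
    t_thr = (threshold - AGE_CENTER_YEARS) / DECADE_YEARS
    return np.asarray(grs_z, dtype=float) * np.maximum(0.0, t - t_thr) ** order


@dataclass
class _DesignData:
    """Materialized complete-case data for one threshold model."""

    X: np.ndarray
    y: np.ndarray
    names: list[str]
    b3_estimable: bool
    divergence_index: int | None
    n: int


def build_design(
    cohort: pd.DataFrame, spec: DivergenceModelSpec, threshold: float
) -> _DesignData:
    """Design matrix for one candidate threshold on complete cases.

    Columns: intercept, t, ..., t^base_order, divergence term, covariates.
    There is deliberately NO risk-score main-effect column: the model
    constrains the score's association with the outcome to zero below the
    threshold.  If the divergence column is identically zero (threshold at
    or above the oldest observed age) it is dropped, the fit proceeds, and
    the divergence coefficient is recorded as not estimable.
    """
    needed = [spec.phenotype, "age", "grs_z", *spec.covariates]
    mask = complete_case_mask(cohort, needed)
    sub = cohort[needed] if mask.all() else cohort.loc[mask, needed]
    n = len(sub)
    age = sub["age"].to_numpy(dtype=float)
    t = (age - spec.age_center) / DECADE_YEARS
    grs = sub["grs_z"].to_numpy(dtype=float)

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for k in range(1, spec.base_order + 1):
        cols.append(t**k)
        names.append("t" if k == 1 else f"t^{k}")

    div = divergence_basis(age, grs, threshold, spec.divergence_order)
    b3_estimable = bool(np.any(div != 0.0))
    div_index: int | None = None
    if b3_estimable:
        div_index = len(cols)
        cols.append(div)
        names.append("divergence")
    else:
        warnings.warn(
            f"threshold {threshold} leaves no participant above it; divergence "
            f"coefficient not estimable, column dropped"
        )

    cov, cov_names = covariate_design(sub, spec.covariates)
    if cov.size:
        cols.extend(cov.T)
        names.extend(cov_names)

    y = harmonize_direction(sub[spec.phenotype], spec.direction)
    return _DesignData(
        X=np.column_stack(cols),
        y=y,
        names=names,
        b3_estimable=b3_estimable,
        divergence_index=div_index,
        n=n,
    )


def _fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    """Deterministic balanced fold labels 0..folds-1 for n rows."""
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=np.int64)
    labels[rng.permutation(n)] = np.arange(n) % folds
    return labels


def _cv_mspe_identity(X: np.ndarray, y: np.ndarray, fold_ids: np.ndarray) -> float:
    """Held-out squared error of per-fold least-squares fits.

    Per-fold training cross-products are obtained by subtracting the fold's
    block from the full-data Gram matrix, which is orders of magnitude
    cheaper than refitting from raw rows and numerically equivalent for the
    well-conditioned decade-scaled designs used here.
    """
    folds = int(fold_ids.max()) + 1
    p = X.shape[1]
    order = np.argsort(fold_ids, kind="stable")
    Xs, ys = X[order], y[order]
    bounds = np.searchsorted(fold_ids[order], np.arange(folds + 1))

    gram_f = np.empty((folds, p, p))
    xty_f = np.empty((folds, p))
    for f in range(folds):
        blk = slice(bounds[f], bounds[f + 1])
        gram_f[f] = Xs[blk].T @ Xs[blk]
        xty_f[f] = Xs[blk].T @ ys[blk]
    gram = gram_f.sum(axis=0)
    xty = xty_f.sum(axis=0)

    total = 0.0
    for f in range(folds):
        blk = slice(bounds[f], bounds[f + 1])
        if bounds[f + 1] - bounds[f] == 0:
            continue
        g_train = gram - gram_f[f]
        c_train = xty - xty_f[f]
        try:
            beta = np.linalg.solve(g_train, c_train)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(g_train, c_train, rcond=None)[0]
        resid = ys[blk] - Xs[blk] @ beta
        total += float(resid @ resid)
    return total / len(y)


def _cv_mspe_logit(X: np.ndarray, y: np.ndarray, fold_ids: np.ndarray) -> float:
    import statsmodels.api as sm

    folds = int(fold_ids.max()) + 1
    total = 0.0
    for f in range(folds):
        test = fold_ids == f
        res = sm.Logit(y[~test], X[~test]).fit(disp=0, maxiter=200)
        prob = 1.0 / (1.0 + np.exp(-(X[test] @ res.params)))
        total += float(np.sum((y[test] - prob) ** 2))
    return total / len(y)


def cv_mspe(
    cohort: pd.DataFrame, spec: DivergenceModelSpec, threshold: float
) -> float:
    """k-fold cross-validated mean squared prediction error at one threshold.

    The fold partition is a deterministic function of (n, cv_folds,
    fold_seed), so every candidate threshold is scored against the same
    partition.  MSPE averages (observed - out-of-fold prediction)^2 over all
    complete cases; for the logit link the prediction is the probability.
    """
    data = build_design(cohort, spec, threshold)
    if data.n // spec.cv_folds < data.X.shape[1]:
        raise ValueError(
            f"folds of ~{data.n // spec.cv_folds} rows are smaller than the "
            f"{data.X.shape[1]}-parameter model; use fewer folds"
        )
    fold_ids = _fold_assignment(data.n, spec.cv_folds, spec.fold_seed)
    if spec.link == "identity":
        return _cv_mspe_identity(data.X, data.y, fold_ids)
    return _cv_mspe_logit(data.X, data.y, fold_ids)


def select_threshold(cohort: pd.DataFrame, spec: DivergenceModelSpec) -> DivergenceFit:
    """Grid-search the divergence age by minimum cross-validated MSPE.

    Every candidate is scored with the same fold partition; the argmin wins,
    with exact ties broken toward the LARGEST threshold (the most
    conservative claim about early divergence).  Coefficients are then refit
    on all complete cases at the selected threshold.
    """
    mspe_map: dict[float, float] = {}
    errors: dict[float, str] = {}
    for threshold in spec.grid.ages:
        try:
            mspe_map[threshold] = cv_mspe(cohort, spec, threshold)
        except ValueError:
            raise
        except Exception as exc:  # logit non-convergence etc.
            errors[threshold] = str(exc)
    if not mspe_map:
        raise RuntimeError(f"every candidate threshold failed: {errors}")

    values = np.array([mspe_map[a] for a in spec.grid.ages if a in mspe_map])
    ages = [a for a in spec.grid.ages if a in mspe_map]
    best = values.min()
    selected = max(a for a, v in zip(ages, values) if v == best)

    data = build_design(cohort, spec, selected)
    if spec.link == "identity":
        beta, _, rank, _ = np.linalg.lstsq(data.X, data.y, rcond=None)
        resid = data.y - data.X @ beta
        dof = max(data.n - int(rank), 1)
        residual_sd = float(np.sqrt(resid @ resid / dof))
    else:
        import statsmodels.api as sm

        res = sm.Logit(data.y, data.X).fit(disp=0, maxiter=200)
        beta = res.params
        prob = 1.0 / (1.0 + np.exp(-(data.X @ beta)))
        residual_sd = float(np.sqrt(np.mean((data.y - prob) ** 2)))

    coefficients = dict(zip(data.names, (float(b) for b in beta)))
    if selected == spec.grid.ages[0]:
        boundary = "at_min"
    elif selected == spec.grid.ages[-1]:
        boundary = "at_max"
    else:
        boundary = "interior"

    return DivergenceFit(
        phenotype=spec.phenotype,
        grid=spec.grid.ages,
        mspe_by_threshold=mspe_map,
        selected_threshold=float(selected),
        coefficients=coefficients,
        boundary_flag=boundary,
        b3_estimable=data.b3_estimable,
        residual_sd=residual_sd,
        n=data.n,
        link=spec.link,
        base_order=spec.base_order,
        divergence_order=spec.divergence_order,
        age_center=spec.age_center,
        cv_folds=spec.cv_folds,
        fold_seed=spec.fold_seed,
        direction=spec.direction,
    )


def predict_trajectory(
    fit: DivergenceFit,
    grs_z: float,
    covariates: Mapping[str, float] | None = None,
    ages: Sequence[float] | np.ndarray = (),
) -> np.ndarray:
    """Modeled mean cognition across ages for a fixed score and covariates.

    Below the selected threshold the prediction does not depend on
    ``grs_z`` at all -- the defining property of the model.  Covariate
    values default to zero (reference center, median-zero PCs).  Ages
    outside the threshold grid draw an extrapolation warning.
    """
    ages_arr = np.asarray(ages, dtype=float)
    if ages_arr.size and (
        ages_arr.min() < fit.grid[0] or ages_arr.max() > fit.grid[-1]
    ):
        warnings.warn("predicting outside the threshold grid extrapolates the fit")
    t = (ages_arr - fit.age_center) / DECADE_YEARS
    mean = np.full(ages_arr.shape, fit.coefficients.get("intercept", 0.0))
    for k in range(1, fit.base_order + 1):
        name = "t" if k == 1 else f"t^{k}"
        mean = mean + fit.coefficients.get(name, 0.0) * t**k
    if fit.b3_estimable and "divergence" in fit.coefficients:
        mean = mean + fit.coefficients["divergence"] * divergence_basis(
            ages_arr, grs_z, fit.selected_threshold, fit.divergence_order
        )
    if covariates:
        for name, value in covariates.items():
            if name in fit.coefficients and name not in {"intercept", "divergence"}:
                mean = mean + fit.coefficients[name] * float(value)
    if fit.link == "logit":
        return 1.0 / (1.0 + np.exp(-mean))
    return mean


def refit_with_grs_main(
    cohort: pd.DataFrame, spec: DivergenceModelSpec, threshold: float
) -> dict[str, float]:
    """Diagnostic refit that ADDS a score main-effect column.

    Relaxes the below-threshold zero-association constraint so the
    constraint itself can be inspected; never used for threshold selection.
    """
    data = build_design(cohort, spec, threshold)
    mask = complete_case_mask(cohort, [spec.phenotype, "age", "grs_z", *spec.covariates])
    grs = cohort.loc[mask, "grs_z"].to_numpy(dtype=float)
    X = np.column_stack([data.X, grs])
    names = data.names + ["grs_main"]
    beta = np.linalg.lstsq(X, data.y, rcond=None)[0]
    return dict(zip(names, (float(b) for b in beta)))


# ---------------------------------------------------------------------------
# serialization


def fit_to_dict(fit: DivergenceFit) -> dict:
    return {
        "phenotype": fit.phenotype,
        "grid": list(fit.grid),
        "mspe_by_threshold": {str(k): v for k, v in fit.mspe_by_threshold.items()},
        "selected_threshold": fit.selected_threshold,
        "coefficients": fit.coefficients,
        "boundary_flag": fit.boundary_flag,
        "b3_estimable": fit.b3_estimable,
        "residual_sd": fit.residual_sd,
        "n": fit.n,
        "link": fit.link,
        "base_order": fit.base_order,
        "divergence_order": fit.divergence_order,
        "age_center": fit.age_center,
        "cv_folds": fit.cv_folds,
        "fold_seed": fit.fold_seed,
        "direction": fit.direction,
    }


def fit_from_dict(d: dict) -> DivergenceFit:
    """Inverse of :func:`fit_to_dict` (JSON round-trip)."""
    return DivergenceFit(
        phenotype=d["phenotype"],
        grid=tuple(d["grid"]),
        mspe_by_threshold={float(k): v for k, v in d["mspe_by_threshold"].items()},
        selected_threshold=d["selected_threshold"],
        coefficients=d["coefficients"],
        boundary_flag=d["boundary_flag"],
        b3_estimable=d["b3_estimable"],
        residual_sd=d["residual_sd"],
        n=d["n"],
        link=d["link"],
        base_order=d["base_order"],
        divergence_order=d["divergence_order"],
        age_center=d["age_center"],
        cv_folds=d["cv_folds"],
        fold_seed=d["fold_seed"],
        direction=d.get("direction", "higher_better"),
    )


def write_fit_json(fit: DivergenceFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2, sort_keys=True))


def mspe_long_frame(fits: Sequence[DivergenceFit]) -> pd.DataFrame:
    """Tidy long table (phenotype, threshold_age, mspe, selected)."""
    rows = []
    for fit in fits:
        for age, mspe in sorted(fit.mspe_by_threshold.items()):
            rows.append(
                {
                    "phenotype": fit.phenotype,
                    "threshold_age": age,
                    "mspe": mspe,
                    "selected": age == fit.selected_threshold,
                }
            )
    return pd.DataFrame(rows)
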