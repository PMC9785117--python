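"""Missing-value imputation, Box-Cox transformation and train-anchored scaling.

Missing cells (rare: the emulated cohorts carry <2% missingness, median two
cells per variable) are filled by Gibbs-style conditional-normal multiple
imputation: each incomplete variable is regressed on its most-correlated
companions, missing entries are drawn from the conditional normal, and the
sweep is iterated to convergence; several completed data sets are averaged
into one analysis table.  Imputation of positive-valued variables runs on the
log scale so imputed concentrations stay positive.  Age is never imputed.

Every continuous variable is then Box-Cox transformed with a lambda grid
search over [-10, 10].  The selection criterion is the smallest standard
deviation of the geometric-mean-scaled transform

    z(lambda) = (y^lambda - 1) / (lambda * GM^(lambda - 1)),   lambda != 0
    z(0)      = GM * ln(y)

where GM is the geometric mean of the variable.  The GM scaling makes SDs
comparable across lambda (the raw-transform SD shrinks without bound as
|lambda| grows, which would make the criterion degenerate); minimizing this
scaled SD is equivalent to maximizing the Box-Cox profile likelihood.  A flag
restores the literal unscaled criterion.  Lambda, the geometric mean and the
standardization constants are always fitted on the training arm only and
replayed verbatim on the test arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .synthdata import CohortTable

__all__ = [
    "ImputationSpec",
    "BoxCoxSpec",
    "impute",
    "boxcox_fit",
    "boxcox_apply",
    "shapiro_check",
    "fit_transform_cohort",
]


@dataclass
class ImputationSpec:
    n_imputations: int = 5
    max_iterations: int = 20
    seed: int = 0
    # convergence: change of the conditional means between sweeps, relative to
    # each column's observed SD (draws themselves never settle)
    tol: float = 0.05
    max_predictors: int = 15  # companion variables used per conditional model

    def validate(self) -> None:
        if self.n_imputations < 1:
            raise ConfigurationError("n_imputations: must be >= 1")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations: must be >= 1")


@dataclass
class BoxCoxSpec:
    """Replayable per-variable transform: shift, lambda, GM and train stats."""

    variable: str
    lam: float
    shift: float = 0.0
    gm: float = 1.0
    train_mean: float = 0.0
    train_sd: float = 1.0
    scaled: bool = True


def _conditional_models(
    X: np.ndarray, miss: np.ndarray, target_cols: list[int], max_predictors: int
) -> dict[int, np.ndarray]:
    """Pick the most-correlated predictor columns for each incomplete column."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    predictors: dict[int, np.ndarray] = {}
    for j in target_cols:
        order = np.argsort(-np.abs(corr[j]))
        cand = [k for k in order if k != j][:max_predictors]
        predictors[j] = np.asarray(cand, dtype=int)
    return predictors


def _gibbs_chain(
    X0: np.ndarray,
    miss: np.ndarray,
    target_cols: list[int],
    spec: ImputationSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """One imputation chain; returns the completed matrix and convergence flag."""
    X = X0.copy()
    # initialize missing cells at column means of observed values
    for j in target_cols:
        mj = miss[:, j]
        X[mj, j] = np.nanmean(X0[~mj, j]) if (~mj).any() else 0.0
    predictors = _conditional_models(X, miss, target_cols, spec.max_predictors)
    obs_sd = {
        j: max(float(np.nanstd(X0[~miss[:, j], j], ddof=1)), 1e-12) for j in target_cols
    }
    prev_pred: dict[int, np.ndarray] = {}
    converged = False
    for _ in range(spec.max_iterations):
        delta = 0.0
        for j in target_cols:
            mj = miss[:, j]
            cols = predictors[j]
            A = np.column_stack([np.ones(X.shape[0]), X[:, cols]])
            obs = ~mj
            beta, *_ = np.linalg.lstsq(A[obs], X[obs, j], rcond=None)
            resid = X[obs, j] - A[obs] @ beta
            dof = max(int(obs.sum()) - len(beta), 1)
            sigma = float(np.sqrt(np.maximum((resid @ resid) / dof, 0.0)))
            pred = A[mj] @ beta
            if j in prev_pred:
                shift = float(np.max(np.abs(pred - prev_pred[j]), initial=0.0))
                delta = max(delta, shift / obs_sd[j])
            else:
                delta = np.inf  # first sweep: no reference yet
            prev_pred[j] = pred
            X[mj, j] = pred + rng.normal(0.0, sigma, size=int(mj.sum()))
        if delta < spec.tol:
            converged = True
            break
    return X, converged


def impute(table: CohortTable, spec: ImputationSpec) -> CohortTable:
    """Fill missing cells; observed cells are returned bit-identical.

    Strictly positive variables are imputed on the log scale and
    exponentiated back, keeping concentrations positive.  The
    ``spec.n_imputations`` completed data sets are averaged into a single
    analysis table.  Non-convergent chains are used at their last sweep and
    reported via the table's ``attrs['imputation_warnings']``.
    """
    spec.validate()
    cols = table.variables("clinical", "metabolite", "bmi")
    data = table.data
    for c in cols:
        n_obs = int(data[c].notna().sum())
        if n_obs == 0:
            raise DataError(f"variable {c}: entirely missing, cannot impute")
        if n_obs < 2:
            raise DataError(f"variable {c}: fewer than 2 observed values")
        if data[c].isna().mean() >= 0.5:
            raise DataError(f"variable {c}: missing fraction >= 0.5")

    if not data[cols].isna().any().any():
        return table.copy()

    # log-scale for strictly positive variables
    vals = data[cols].to_numpy(dtype=float)
    positive = np.array([np.nanmin(vals[:, j]) > 0 for j in range(vals.shape[1])])
    W = vals.copy()
    W[:, positive] = np.log(W[:, positive])
    miss = np.isnan(W)
    target_cols = [j for j in range(W.shape[1]) if miss[:, j].any()]

    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_imputations)
    stacks = []
    n_bad = 0
    for child in children:
        chain, ok = _gibbs_chain(W, miss, target_cols, spec, np.random.default_rng(child))
        if not ok:
            n_bad += 1
        stacks.append(chain)
    mean_W = np.mean(np.stack(stacks), axis=0)
    mean_W[~miss] = W[~miss]  # observed cells exactly unchanged
    filled = mean_W.copy()
    filled[:, positive] = np.exp(filled[:, positive])
    filled[~miss] = vals[~miss]

    out = table.copy()
    out.data[cols] = filled
    out.data.attrs["imputation_warnings"] = (
        [f"{n_bad} chain(s) did not converge in {spec.max_iterations} sweeps"]
        if n_bad
        else []
    )
    return out


def _boxcox_transform(y: np.ndarray, lam: float, gm: float, scaled: bool) -> np.ndarray:
    # expm1 keeps y^lam - 1 accurate when y^lam is close to 1
    denom = lam * gm ** (lam - 1.0) if scaled else lam
    if lam == 0.0:
        return (gm if scaled else 1.0) * np.log(y)
    return np.expm1(lam * np.log(y)) / denom


def _boxcox_sd(y: np.ndarray, lam: float, gm: float, scaled: bool) -> float:
    """SD of the transform across y; the constant -1 shift drops out, so this
    stays exact even where y^lam underflows relative to 1."""
    if lam == 0.0:
        z = np.log(y)
        scale = gm if scaled else 1.0
    else:
        logy = lam * np.log(y)
        z = np.exp(logy - logy.max())  # rescale before SD; constant factor restored below
        scale = np.exp(logy.max()) / (abs(lam) * gm ** (lam - 1.0) if scaled else abs(lam))
    return float(np.std(z, ddof=1) * scale)


def boxcox_fit(
    values: np.ndarray | pd.Series,
    grid_step: float = 0.1,
    variable: str = "",
    lam_bounds: tuple[float, float] = (-10.0, 10.0),
    scaled: bool = True,
) -> BoxCoxSpec:
    """Grid-search lambda over ``lam_bounds`` minimizing the transform SD.

    Ties are broken toward the lambda closest to 1, then toward smaller
    |lambda|.  Values must be strictly positive after the shift (a shift is
    applied automatically only when non-positive values are present, moving
    the minimum to 1% of the observed spread above zero).  Standardization
    constants (mean/SD of the chosen transform) are stored for train-anchored
    replay.
    """
    y = np.asarray(values, dtype=float)
    y = y[~np.isnan(y)]
    if len(y) < 3:
        raise DataError("boxcox_fit: need at least 3 observed values")
    if grid_step <= 0:
        raise ConfigurationError("grid_step: must be positive")
    shift = 0.0
    if np.min(y) <= 0:
        spread = np.max(y) - np.min(y)
        shift = -np.min(y) + (0.01 * spread if spread > 0 else 1.0)
    ys = y + shift
    if np.min(ys) <= 0:
        raise DataError("boxcox_fit: non-positive value after shift")
    if np.ptp(ys) == 0:
        raise DataError("boxcox_fit: zero-variance input")

    gm = float(np.exp(np.mean(np.log(ys))))
    lo, hi = lam_bounds
    n_steps = int(round((hi - lo) / grid_step))
    grid = np.round(lo + grid_step * np.arange(n_steps + 1), 12)
    # snap near-zero grid points to exactly 0 so the log branch is used
    grid[np.isclose(grid, 0.0, atol=1e-12)] = 0.0

    best = None
    for lam in grid:
        sd = _boxcox_sd(ys, float(lam), gm, scaled)
        key = (sd, abs(lam - 1.0), abs(lam))
        if best is None or key < best[0]:
            best = (key, float(lam))
    lam = best[1]
    z = _boxcox_transform(ys, lam, gm, scaled)
    sd = _boxcox_sd(ys, lam, gm, scaled)
    if sd <= 0:
        raise DataError("boxcox_fit: transformed values have zero variance")
    return BoxCoxSpec(
        variable=variable,
        lam=lam,
        shift=shift,
        gm=gm,
        train_mean=float(np.mean(z)),
        train_sd=sd,
        scaled=scaled,
    )


def boxcox_apply(values: np.ndarray | pd.Series, spec: BoxCoxSpec) -> np.ndarray:
    """Transform with the fitted lambda and standardize with the train stats.

    Strictly monotone in the input for every lambda.  NaNs pass through.
    """
    y = np.asarray(values, dtype=float) + spec.shift
    out = np.full(y.shape, np.nan)
    obs = ~np.isnan(y)
    if np.any(y[obs] <= 0):
        raise DataError(f"boxcox_apply[{spec.variable}]: non-positive value after shift")
    z = _boxcox_transform(y[obs], spec.lam, spec.gm, spec.scaled)
    out[obs] = (z - spec.train_mean) / spec.train_sd
    return out


def shapiro_check(values: np.ndarray | pd.Series) -> tuple[float, float]:
    """Shapiro-Wilk normality check; returns (W, p). Informational, not a gate."""
    y = np.asarray(values, dtype=float)
    y = y[~np.isnan(y)]
    if not 3 <= len(y) <= 5000:
        raise DataError("shapiro_check: n must be in [3, 5000]")
    res = stats.shapiro(y)
    return float(res.statistic), float(res.pvalue)


def fit_transform_cohort(
    table: CohortTable,
    grid_step: float = 0.1,
    scaled: bool = True,
) -> tuple[CohortTable, dict[str, BoxCoxSpec], pd.DataFrame]:
    """Box-Cox + standardize every continuous variable, train-anchored.

    Specs (lambda, shift, GM, mean, SD) are fitted on the training arm only
    and applied to all subjects; sex is left untouched (categorical), age is
    transformed like any other continuous variable so that correlations are
    computed on comparably normalized scales.  Returns the transformed table,
    the per-variable specs, and a normality report (Shapiro-Wilk W and p,
    before and after transform, computed on the training arm).
    """
    if table.split is None:
        raise DataError("cohort has no split labels; run split_cohort first")
    cols = table.variables("age", "bmi", "clinical", "metabolite")
    train = table.data.loc[table.split == "train"]
    out = table.copy()
    # keep untransformed age (years) for the prediction model's target scale
    out.data["age_years"] = table.data["age"]
    out.roles["age_years"] = "raw_age"
    out.mask["age_years"] = True
    specs: dict[str, BoxCoxSpec] = {}
    report_rows = []
    for c in cols:
        spec = boxcox_fit(train[c], grid_step=grid_step, variable=c, scaled=scaled)
        specs[c] = spec
        w0, p0 = shapiro_check(train[c])
        out.data[c] = boxcox_apply(table.data[c], spec)
        w1, p1 = shapiro_check(out.data.loc[table.split == "train", c])
        report_rows.append(
            {
                "variable": c,
                "lambda": spec.lam,
                "shapiro_w_raw": w0,
                "shapiro_p_raw": p0,
                "shapiro_w_transformed": w1,
                "shapiro_p_transformed": p1,
            }
        )
    report = pd.DataFrame(report_rows).set_index("variable")
    return out, specs, report
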