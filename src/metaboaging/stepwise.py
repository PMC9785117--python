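"""Forward stepwise multiple linear regression of age on metabolites.

BMI is forced into the model as a covariate and never competes for entry.
Starting from the forced-only model, each step adds the candidate with the
smallest partial-F p-value (equivalently the largest |t| for its coefficient
in the augmented model) provided it falls below ``p_enter``; selection stops
when no candidate qualifies.  There is no removal step (pure forward
selection).  The fitted model reports standardized coefficients (the inputs
are Box-Cox transformed and train-standardized, so betas are in years per SD),
multiple correlation, adjusted R^2 and per-variable variance inflation
factors, and can be evaluated on a held-out test arm transformed with the
train-anchored specs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .synthdata import CohortTable

__all__ = ["StepwiseModel", "forward_stepwise", "evaluate_on_test", "compute_vif"]


@dataclass
class StepwiseModel:
    selected: list[str]
    forced: list[str]
    coefficients: dict[str, float]  # per-predictor, standardized-input scale
    intercept: float  # years
    r_multiple: float
    r2: float
    r2_adjusted: float
    vif: dict[str, float]
    entry_p: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    @property
    def predictors(self) -> list[str]:
        return self.forced + self.selected


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least squares with intercept prepended; returns (beta, resid, rss)."""
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return beta, resid, float(resid @ resid)


def _coef_t_p(X: np.ndarray, y: np.ndarray, j: int) -> tuple[float, float]:
    """t statistic and two-sided p for coefficient j (0-based among columns of X)."""
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    dof = n - p - 1
    if dof < 1:
        raise DataError("forward_stepwise: not enough degrees of freedom")
    AtA = A.T @ A
    if np.linalg.matrix_rank(AtA) < A.shape[1]:
        raise DataError("singular design")
    beta = np.linalg.solve(AtA, A.T @ y)
    resid = y - A @ beta
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(AtA)
    se = np.sqrt(cov[j + 1, j + 1])
    if se == 0:
        return np.inf, 0.0
    t = float(beta[j + 1] / se)
    return t, float(2.0 * stats.t.sf(abs(t), dof))


def compute_vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor 1/(1 - R^2_j) per column of the design.

    Exactly collinear columns are reported as ``inf``.
    """
    if design.shape[1] < 2:
        raise DataError("compute_vif: need at least 2 columns")
    X = design.to_numpy(dtype=float)
    out: dict[str, float] = {}
    for j, name in enumerate(design.columns):
        others = np.delete(X, j, axis=1)
        y = X[:, j]
        _, resid, rss = _ols(others, y)
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss <= 0:
            raise DataError(f"compute_vif: column {name} has zero variance")
        r2 = 1.0 - rss / tss
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def forward_stepwise(
    table: CohortTable,
    candidates: list[str],
    target: str = "age",
    forced: tuple[str, ...] = ("bmi",),
    p_enter: float = 0.05,
) -> StepwiseModel:
    """Forward selection over ``candidates`` with ``forced`` always in.

    Deterministic: ties on entry p are broken by larger |t|, then variable
    name.  Candidates producing a singular design are skipped with a warning.
    With no qualifying candidate the forced-only model is returned.
    """
    if not 0.0 < p_enter < 1.0:
        raise DataError("forward_stepwise: p_enter must be in (0, 1)")
    df = table.data
    for c in list(forced) + list(candidates) + [target]:
        if c not in df.columns:
            raise DataError(f"forward_stepwise: column {c!r} missing")
    y = df[target].to_numpy(dtype=float)
    selected: list[str] = []
    entry_p: dict[str, float] = {}
    warnings: list[str] = []
    remaining = sorted(set(candidates) - set(forced))

    while remaining:
        scores = []
        for c in remaining:
            cols = list(forced) + selected + [c]
            X = df[cols].to_numpy(dtype=float)
            try:
                t, p = _coef_t_p(X, y, j=len(cols) - 1)
            except DataError:
                warnings.append(f"candidate {c} skipped: singular design")
                remaining = [r for r in remaining if r != c]
                continue
            scores.append((p, -abs(t), c))
        if not scores:
            break
        scores.sort()
        p_best, _, best = scores[0]
        if p_best >= p_enter:
            break
        selected.append(best)
        entry_p[best] = p_best
        remaining = [r for r in remaining if r != best]

    cols = list(forced) + selected
    X = df[cols].to_numpy(dtype=float)
    beta, resid, rss = _ols(X, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    n, p = X.shape
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else np.nan
    vif = compute_vif(df[cols]) if len(cols) >= 2 else {c: 1.0 for c in cols}
    return StepwiseModel(
        selected=selected,
        forced=list(forced),
        coefficients={c: float(b) for c, b in zip(cols, beta[1:])},
        intercept=float(beta[0]),
        r_multiple=float(np.sqrt(max(r2, 0.0))),
        r2=float(r2),
        r2_adjusted=float(r2_adj),
        vif=vif,
        entry_p=entry_p,
        warnings=warnings,
    )


def evaluate_on_test(model: StepwiseModel, test: CohortTable, target: str = "age") -> float:
    """Multiple correlation of the fitted model on a held-out arm.

    The test table must be transformed with the train-anchored Box-Cox specs;
    returns the Pearson correlation between predicted and observed target.
    """
    df = test.data
    missing = [c for c in model.predictors if c not in df.columns]
    if missing:
        raise DataError(f"evaluate_on_test: model variables missing from test: {missing}")
    pred = model.intercept + sum(
        model.coefficients[c] * df[c].to_numpy(dtype=float) for c in model.predictors
    )
    obs = df[target].to_numpy(dtype=float)
    if np.std(pred) == 0 or np.std(obs) == 0:
        raise DataError("evaluate_on_test: zero variance in predictions or target")
    return float(np.corrcoef(pred, obs)[0, 1])
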