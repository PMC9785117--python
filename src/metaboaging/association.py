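"""BMI-adjusted partial-correlation screening with a dual significance rule.

Covariate selection regresses age on BMI and sex; covariates whose
coefficient reaches p < 0.05 are retained (in cohorts of this structure that
keeps BMI and drops sex).  Each clinical marker and metabolite is then tested
against age by partial Pearson correlation controlling for the retained
covariates — the correlation of the two sets of OLS residuals — with
two-sided p from t = r sqrt(df / (1 - r^2)), df = n - 2 - k.  Significance
uses a dual rule: Benjamini-Hochberg step-up rejection at FDR q = 0.2 AND raw
p < 0.05.  The alpha cap only ever shrinks the BH rejection set, so the false
discovery rate stays controlled at q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .synthdata import CohortTable

__all__ = [
    "select_covariates",
    "partial_correlation",
    "bh_screen",
    "screen_cohort",
]


def select_covariates(table: CohortTable, alpha: float = 0.05) -> list[str]:
    """OLS of age on BMI and sex; return covariates with coefficient p < alpha."""
    df = table.data
    X = sm.add_constant(df[["bmi", "sex"]])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DataError("singular design in covariate-selection regression")
    fit = sm.OLS(df["age"], X).fit()
    return [c for c in ("bmi", "sex") if fit.pvalues[c] < alpha]


def _residuals(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), Z]) if Z.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_correlation(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> tuple[float, float, int]:
    """Partial Pearson correlation of x and y controlling for covariates.

    Returns ``(r, p, df)`` with ``df = n - 2 - k`` and a two-sided p-value
    from the exact t reference distribution.  With no covariates this is the
    plain Pearson correlation with df = n - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((len(x), 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    if len(x) != len(y) or len(x) != Z.shape[0]:
        raise DataError("partial_correlation: length mismatch")
    k = Z.shape[1]
    n = len(x)
    if n < k + 4:
        raise DataError("partial_correlation: need n >= k + 4")
    if k and np.linalg.matrix_rank(np.column_stack([np.ones(n), Z])) < k + 1:
        raise DataError("partial_correlation: covariates not full rank")
    rx = _residuals(x, Z)
    ry = _residuals(y, Z)
    sx = rx.std(ddof=1)
    sy = ry.std(ddof=1)
    tol_x = 1e-10 * max(float(np.abs(x).max()), 1.0)
    tol_y = 1e-10 * max(float(np.abs(y).max()), 1.0)
    if sx <= tol_x or sy <= tol_y:
        raise DataError("partial_correlation: zero residual variance")
    r = float(np.dot(rx - rx.mean(), ry - ry.mean()) / ((n - 1) * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p, df


@dataclass
class BHResult:
    significant: np.ndarray  # final dual-rule flags
    bh_rejected: np.ndarray  # BH step-up rejection set at level q
    critical: np.ndarray  # per-test critical value rank*q/m


def bh_screen(
    p_values: np.ndarray | list[float],
    q: float = 0.2,
    alpha: float = 0.05,
    rule: str = "stepup",
) -> BHResult:
    """Dual significance rule: BH rejection at FDR q AND raw p < alpha.

    ``rule="stepup"`` (default) uses the standard Benjamini-Hochberg step-up
    rejection set.  ``rule="per_rank"`` instead flags tests whose p-value
    falls below its own rank's critical value i*q/m without the step-up
    closure (an alternative literal reading of "p < FDR-corrected p-value").
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        z = np.zeros(0, dtype=bool)
        return BHResult(significant=z, bh_rejected=z, critical=np.zeros(0))
    if np.any((p < 0) | (p > 1)):
        raise DataError("bh_screen: p-values outside [0, 1]")
    if not 0.0 < q < 1.0:
        raise DataError("bh_screen: q must be in (0, 1)")
    m = p.size
    ranks = stats.rankdata(p, method="ordinal")
    critical = ranks * q / m
    if rule == "stepup":
        rejected = multipletests(p, alpha=q, method="fdr_bh")[0]
    elif rule == "per_rank":
        rejected = p <= critical
    else:
        raise DataError("bh_screen: rule must be 'stepup' or 'per_rank'")
    significant = rejected & (p < alpha)
    return BHResult(significant=significant, bh_rejected=rejected, critical=critical)


def screen_cohort(
    table: CohortTable,
    covariates: list[str] | None = None,
    q: float = 0.2,
    alpha: float = 0.05,
    rule: str = "stepup",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen every clinical marker and metabolite against age.

    Returns ``(records, corr_matrix)``: one row per variable with the partial
    r, df, raw p, BH critical value and the dual-rule significance flag
    (sorted by raw p), plus the full symmetric Pearson correlation matrix of
    age + covariates + all screened variables for heatmap output.  The table
    must already be imputed and transformed.
    """
    if covariates is None:
        covariates = select_covariates(table)
    variables = table.variables("clinical", "metabolite")
    if not variables:
        raise DataError("screen_cohort: no clinical/metabolite variables")
    df = table.data
    if df[variables].isna().any().any():
        raise DataError("screen_cohort: table contains missing values; impute first")

    age = df["age"].to_numpy(dtype=float)
    Z = df[covariates].to_numpy(dtype=float) if covariates else None

    rows = []
    for v in variables:
        r, p, dof = partial_correlation(age, df[v], Z)
        rows.append({"variable": v, "partial_r": r, "df": dof, "p_raw": p})
    records = pd.DataFrame(rows).set_index("variable")
    res = bh_screen(records["p_raw"].to_numpy(), q=q, alpha=alpha, rule=rule)
    records["bh_critical"] = res.critical
    records["bh_rejected"] = res.bh_rejected
    records["significant"] = res.significant
    records = records.sort_values(["p_raw", "variable"], kind="mergesort")

    heat_cols = ["age"] + covariates + variables
    corr = df[heat_cols].corr(method="pearson")
    return records, corr
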