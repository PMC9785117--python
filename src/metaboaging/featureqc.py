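"""LC-HRMS feature-inclusion filters and QC-anchored LOESS drift correction.

Three inclusion rules are applied per feature, mirroring standard untargeted
LC-MS practice: a blank-contamination rule (mean blank signal must stay below
5% of the mean experimental-sample signal), a technical-repeatability rule
(CV% across QC injections, averaging each QC triplicate first, below 20%) and
a detection rule (fewer than 10% missing cells among experimental samples).
Retained features are then normalized against instrumental drift by fitting a
LOESS curve to QC intensity versus injection order and dividing every
injection by the curve relative to the feature's median QC intensity, so QC
medians are preserved and smooth sensitivity drift is removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ConfigurationError, DataError
from .synthdata import FeatureTable

__all__ = ["filter_features", "loess_normalize", "apply_filter"]


def _qc_triplet_means(values: np.ndarray) -> np.ndarray:
    """Mean of each consecutive QC triplicate, NaNs excluded.

    QC samples are injected in triplicate; replicate means are taken before
    the CV so that within-triplet injection noise does not inflate it.
    """
    n_groups = len(values) // 3
    means = []
    for g in range(n_groups):
        chunk = values[3 * g : 3 * g + 3]
        if np.all(np.isnan(chunk)):
            continue
        means.append(np.nanmean(chunk))
    # trailing partial group, if any
    rest = values[3 * n_groups :]
    if rest.size and not np.all(np.isnan(rest)):
        means.append(np.nanmean(rest))
    return np.asarray(means, dtype=float)


def filter_features(
    table: FeatureTable,
    blank_threshold: float = 0.05,
    cv_threshold: float = 20.0,
    missing_threshold: float = 0.10,
    blank_rule: str = "contaminant",
) -> pd.DataFrame:
    """Apply the three inclusion rules; return a per-feature report.

    Parameters
    ----------
    blank_threshold
        Proportion of the mean sample signal that the mean blank signal must
        stay below (default 0.05).
    cv_threshold
        CV% bound across QC triplicate means (default 20).
    missing_threshold
        Maximum missing fraction among experimental samples (default 0.10).
    blank_rule
        ``"contaminant"`` (default): retain when mean blank < threshold x
        mean sample — blank signal is treated as contamination.
        ``"presence"``: retain when mean sample exceeds the mean blank by more
        than the threshold fraction (a signal-presence reading of the same
        5% rule).

    Returns a DataFrame indexed by feature with columns ``blank_ratio``,
    ``qc_cv`` (percent), ``missing_fraction``, the three pass flags and
    ``retained`` (the conjunction).
    """
    if not 0.0 < blank_threshold < 1.0:
        raise ConfigurationError("blank_threshold: must be in (0, 1)")
    if not 0.0 < cv_threshold < 100.0:
        raise ConfigurationError("cv_threshold: must be in (0, 100)")
    if not 0.0 < missing_threshold < 1.0:
        raise ConfigurationError("missing_threshold: must be in (0, 1)")
    if blank_rule not in ("contaminant", "presence"):
        raise ConfigurationError("blank_rule: must be 'contaminant' or 'presence'")
    table.validate()

    is_sample = (table.injection_class == "sample").to_numpy()
    is_blank = (table.injection_class == "blank").to_numpy()
    is_qc = (table.injection_class == "qc").to_numpy()
    if not is_blank.any():
        raise DataError("no blank injections: blank rule cannot be applied")
    if not is_qc.any():
        raise DataError("no QC injections: CV rule cannot be applied")

    rows = []
    for fid, row in table.intensities.iterrows():
        vals = row.to_numpy(dtype=float)
        sample_vals = vals[is_sample]
        mean_sample = np.nanmean(sample_vals) if not np.all(np.isnan(sample_vals)) else np.nan
        blank_vals = vals[is_blank]
        mean_blank = np.nanmean(blank_vals) if not np.all(np.isnan(blank_vals)) else 0.0
        blank_ratio = mean_blank / mean_sample if mean_sample and mean_sample > 0 else np.inf

        if blank_rule == "contaminant":
            passed_blank = blank_ratio < blank_threshold
        else:
            passed_blank = mean_sample > (1.0 + blank_threshold) * mean_blank

        qc_means = _qc_triplet_means(vals[is_qc])
        if qc_means.size >= 2 and np.mean(qc_means) > 0:
            qc_cv = 100.0 * np.std(qc_means, ddof=1) / np.mean(qc_means)
        elif qc_means.size == 1:
            qc_cv = 0.0
        else:
            qc_cv = np.nan
        passed_cv = bool(qc_cv < cv_threshold) if np.isfinite(qc_cv) else False

        missing_fraction = float(np.isnan(sample_vals).mean())
        passed_missing = missing_fraction < missing_threshold

        rows.append(
            {
                "feature_id": fid,
                "blank_ratio": blank_ratio,
                "qc_cv": qc_cv,
                "missing_fraction": missing_fraction,
                "passed_blank": bool(passed_blank),
                "passed_cv": bool(passed_cv),
                "passed_missing": bool(passed_missing),
            }
        )
    report = pd.DataFrame(rows).set_index("feature_id")
    report["retained"] = report.passed_blank & report.passed_cv & report.passed_missing
    return report


def apply_filter(table: FeatureTable, report: pd.DataFrame) -> FeatureTable:
    """Subset a feature table to the retained features of a filter report."""
    keep = report.index[report["retained"]]
    return FeatureTable(
        intensities=table.intensities.loc[keep].copy(),
        injection_class=table.injection_class.copy(),
        injection_order=table.injection_order.copy(),
        true_retained=table.true_retained,
    )


def loess_normalize(table: FeatureTable, span: float = 0.75) -> tuple[FeatureTable, list[str]]:
    """Remove smooth intensity drift using the QC injections as anchors.

    Per feature, a degree-1 LOESS curve is fit to QC intensity versus
    injection order and evaluated at every injection by linear interpolation
    (held constant beyond the outermost QCs).  Each intensity is divided by
    ``curve / median(QC)``, so QC medians are preserved exactly and the
    missingness pattern is untouched.  Features whose fitted curve is not
    strictly positive anywhere are left unnormalized and returned in the
    warning list.
    """
    if not 0.0 < span <= 1.0:
        raise ConfigurationError("span: must be in (0, 1]")
    table.validate()
    is_qc = (table.injection_class == "qc").to_numpy()
    order = table.injection_order.to_numpy(dtype=float)
    X = table.intensities.to_numpy(dtype=float).copy()
    warnings: list[str] = []

    for i, fid in enumerate(table.intensities.index):
        qc_vals = X[i, is_qc]
        qc_ord = order[is_qc]
        obs = ~np.isnan(qc_vals)
        if obs.sum() < 4:
            raise DataError(f"feature {fid}: fewer than 4 observed QC injections")
        fitted = lowess(qc_vals[obs], qc_ord[obs], frac=span, it=0, return_sorted=True)
        curve = np.interp(order, fitted[:, 0], fitted[:, 1])
        if np.any(curve <= 0):
            warnings.append(fid)
            continue
        median_qc = float(np.nanmedian(qc_vals))
        X[i, :] = X[i, :] * (median_qc / curve)

    out = FeatureTable(
        intensities=pd.DataFrame(
            X, index=table.intensities.index, columns=table.intensities.columns
        ),
        injection_class=table.injection_class.copy(),
        injection_order=table.injection_order.copy(),
        true_retained=table.true_retained,
    )
    return out, warnings
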