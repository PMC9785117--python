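"""Tab-separated and JSON persistence for pipeline artifacts.

Cohorts travel as a pair of files: the data TSV (subjects x columns, NaN for
missing, a ``split`` column when assigned) and a sidecar metadata TSV with
one row per column (variable, role, units).  Feature tables use a features x
injections TSV plus a sidecar with injection class and order.  All writers
are deterministic: fixed column order, fixed float formatting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .preprocess import BoxCoxSpec
from .synthdata import CohortTable, FeatureTable

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_feature_table",
    "read_feature_table",
    "write_boxcox_specs",
    "read_boxcox_specs",
    "write_json",
]

_ROLE_UNITS = {
    "age": "years",
    "raw_age": "years",
    "sex": "binary (1 = male)",
    "bmi": "kg/m^2",
    "clinical": "mg/dL",
    "metabolite": "mmol/L",
}


def write_cohort(table: CohortTable, data_path: str | Path, meta_path: str | Path) -> None:
    df = table.data.copy()
    if table.split is not None:
        df["split"] = table.split
    df.to_csv(data_path, sep="\t", float_format="%.17g")
    meta = pd.DataFrame(
        {
            "variable": list(table.roles),
            "role": [table.roles[c] for c in table.roles],
            "units": [_ROLE_UNITS.get(table.roles[c], "") for c in table.roles],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def read_cohort(data_path: str | Path, meta_path: str | Path) -> CohortTable:
    data_path, meta_path = Path(data_path), Path(meta_path)
    if not data_path.exists() or not meta_path.exists():
        raise DataError(f"cohort files not found: {data_path}, {meta_path}")
    df = pd.read_csv(data_path, sep="\t", index_col=0, float_precision="round_trip")
    meta = pd.read_csv(meta_path, sep="\t")
    roles = dict(zip(meta["variable"], meta["role"]))
    split = None
    if "split" in df.columns:
        split = df.pop("split")
        split.name = "split"
    df = df.astype(float)
    missing_roles = [c for c in df.columns if c not in roles]
    if missing_roles:
        raise DataError(f"columns without role metadata: {missing_roles}")
    mask = df.notna()
    return CohortTable(data=df, roles=roles, mask=mask, split=split)


def write_feature_table(table: FeatureTable, data_path: str | Path, meta_path: str | Path) -> None:
    table.intensities.to_csv(data_path, sep="\t", float_format="%.17g", index_label="feature_id")
    meta = pd.DataFrame(
        {
            "injection": table.injection_class.index,
            "class": table.injection_class.to_numpy(),
            "order": table.injection_order.to_numpy(),
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def read_feature_table(data_path: str | Path, meta_path: str | Path) -> FeatureTable:
    data_path, meta_path = Path(data_path), Path(meta_path)
    if not data_path.exists() or not meta_path.exists():
        raise DataError(f"feature table files not found: {data_path}, {meta_path}")
    intensities = pd.read_csv(data_path, sep="\t", index_col=0, float_precision="round_trip")
    meta = pd.read_csv(meta_path, sep="\t")
    table = FeatureTable(
        intensities=intensities,
        injection_class=pd.Series(
            meta["class"].to_numpy(), index=meta["injection"], name="injection_class"
        ),
        injection_order=pd.Series(
            meta["order"].to_numpy(), index=meta["injection"], name="injection_order"
        ),
    )
    table.validate()
    return table


def write_boxcox_specs(specs: dict[str, BoxCoxSpec], path: str | Path) -> None:
    rows = [
        {
            "variable": s.variable,
            "lambda": s.lam,
            "shift": s.shift,
            "gm": s.gm,
            "mean": s.train_mean,
            "sd": s.train_sd,
            "scaled": s.scaled,
        }
        for s in specs.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_boxcox_specs(path: str | Path) -> dict[str, BoxCoxSpec]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"Box-Cox spec table not found: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return {
        row["variable"]: BoxCoxSpec(
            variable=row["variable"],
            lam=float(row["lambda"]),
            shift=float(row["shift"]),
            gm=float(row["gm"]),
            train_mean=float(row["mean"]),
            train_sd=float(row["sd"]),
            scaled=bool(row["scaled"]),
        )
        for _, row in df.iterrows()
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, no timestamps, trailing newline."""
    with Path(path).open("w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
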