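"""Readers and writers for the pipeline's tabular and JSON artifacts.

All tabular data are CSV with fixed, validated schemas (units: cm for
diameter/height, m/degrees for topography); fits and reports are JSON.
Round trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CENSUS_COLUMNS",
    "PLOTS_COLUMNS",
    "read_census_csv",
    "write_census_csv",
    "read_plots_csv",
    "write_plots_csv",
    "write_json",
    "read_json",
    "load_yaml",
]

CENSUS_COLUMNS = {
    "plot_id": str,
    "tree_id": str,
    "row": int,
    "col": int,
    "species_id": str,
    "role": str,
    "census_year": int,
    "D_cm": float,
    "H_cm": float,
    "alive": bool,
}

PLOTS_COLUMNS = {
    "plot_id": str,
    "richness": int,
    "composition_id": str,
    "elevation_m": float,
    "slope_deg": float,
    "northness": float,
}


def _validate(df: pd.DataFrame, schema: dict, what: str) -> pd.DataFrame:
    unknown = [c for c in df.columns if c not in schema]
    if unknown:
        raise ValueError(f"unknown columns in {what}: {unknown}")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns in {what}: {missing}")
    return df[list(schema)]


def write_census_csv(census: pd.DataFrame, path: str | Path) -> None:
    _validate(census, CENSUS_COLUMNS, "census table")
    census[list(CENSUS_COLUMNS)].to_csv(path, index=False)


def read_census_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plot_id": str, "tree_id": str, "species_id": str, "role": str})
    df = _validate(df, CENSUS_COLUMNS, "census table")
    if len(df) == 0:
        return df
    d = df["D_cm"].to_numpy(dtype=float)
    bad = np.where(np.nan_to_num(d, nan=0.0) < 0)[0]
    if bad.size:
        raise ValueError(
            f"negative diameter in census table at row(s) {bad[:5].tolist()}"
        )
    bad_h = np.where(np.nan_to_num(df["H_cm"].to_numpy(dtype=float), nan=0.0) < 0)[0]
    if bad_h.size:
        raise ValueError(
            f"negative height in census table at row(s) {bad_h[:5].tolist()}"
        )
    df["alive"] = df["alive"].astype(bool)
    return df


def write_plots_csv(plots: pd.DataFrame, path: str | Path) -> None:
    _validate(plots, PLOTS_COLUMNS, "plot metadata")
    plots[list(PLOTS_COLUMNS)].to_csv(path, index=False)


def read_plots_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plot_id": str, "composition_id": str})
    return _validate(df, PLOTS_COLUMNS, "plot metadata")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
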