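"""Tree volumes, annual growth and neighbourhood indices.

Wood volume treats the stem as a cylinder scaled by a form factor
(V = pi D^2/4 * H * f, default f = 0.5 for young subtropical trees); annual
growth is the volume difference over the census interval.  For each focal
tree the (up to eight) occupants of the surrounding grid cells — the Moore
neighbourhood on the planting grid — define three indices:

NCI   neighbourhood competition index, the summed basal area (cm^2) of
      neighbours; the size-asymmetric variant counts only neighbours with a
      strictly larger stem diameter than the focal tree, the symmetric
      variant counts all neighbours.
CND   conspecific neighbour density, the count of same-species neighbours.
NSR   neighbourhood species richness, the count of distinct heterospecific
      neighbour species.

Neighbours dead at a census are omitted from that census's indices, and
indices are averaged over the censuses of the study period so that they
reflect the neighbourhood actually experienced by the focal tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "wood_volume",
    "annual_growth",
    "filter_negative_growth",
    "extract_neighbours",
    "neighbourhood_indices",
    "average_over_period",
    "grid_neighbourhood_indices",
    "compute_features",
    "NeighbourhoodFeatures",
]

#: the eight (row, col) offsets of the Moore neighbourhood
MOORE_OFFSETS = [
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
]


def wood_volume(d_cm, h_cm, form_factor: float = 0.5):
    """Stem wood volume in cm^3 from diameter and height in cm."""
    if not 0 < form_factor <= 1:
        raise ValueError("form factor must be in (0, 1]")
    d = np.asarray(d_cm, dtype=float)
    h = np.asarray(h_cm, dtype=float)
    if np.any(d < 0) or np.any(h < 0):
        raise ValueError("diameter and height must be non-negative")
    v = math.pi * d**2 / 4.0 * h * form_factor
    return float(v) if np.isscalar(d_cm) and np.isscalar(h_cm) else v


def annual_growth(v1, v2, t1, t2):
    """Annual wood volume growth (cm^3 year^-1) between censuses t1 < t2."""
    if t2 <= t1:
        raise ValueError(f"census interval must be positive, got t1={t1}, t2={t2}")
    return (np.asarray(v2, float) - np.asarray(v1, float)) / (t2 - t1)


def filter_negative_growth(records: pd.DataFrame, growth_col: str = "G"):
    """Drop trees with negative growth (measurement artefacts).

    Returns (kept, report); the report lists excluded tree ids and the
    excluded fraction.
    """
    g = np.asarray(records[growth_col], dtype=float)
    bad = g < 0
    excluded = records.loc[bad]
    kept = records.loc[~bad]
    report = {
        "n_input": int(len(records)),
        "n_excluded": int(bad.sum()),
        "fraction_excluded": float(bad.mean()) if len(records) else 0.0,
        "excluded_ids": excluded["tree_id"].tolist() if "tree_id" in records else [],
    }
    if len(kept) == 0 and len(records) > 0:
        import warnings

        warnings.warn("all records had negative growth; empty output", RuntimeWarning)
    return kept, report


@dataclass
class NeighbourhoodFeatures:
    """Per-focal-tree neighbourhood summary (single census or period mean)."""

    tree_id: object
    nci_asym: float
    nci_sym: float
    cnd: float
    nsr: float
    n_neighbours: float
    averaged: bool = False


def extract_neighbours(
    census: pd.DataFrame, plot_id, row: int, col: int, census_year
) -> pd.DataFrame:
    """The <= 8 alive occupants of the Moore neighbourhood of a grid position."""
    plot = census[(census["plot_id"] == plot_id) & (census["census_year"] == census_year)]
    if not ((plot["row"] == row) & (plot["col"] == col)).any():
        raise KeyError(f"no tree at ({row}, {col}) in plot {plot_id!r}")
    wanted = {(row + dr, col + dc) for dr, dc in MOORE_OFFSETS}
    mask = [
        (r, c) in wanted for r, c in zip(plot["row"], plot["col"])
    ]
    nb = plot.loc[mask]
    return nb[nb["alive"].astype(bool)]


def neighbourhood_indices(
    focal_d: float, focal_species, neighbours: pd.DataFrame, tree_id=None
) -> NeighbourhoodFeatures:
    """Single-census indices from a focal tree and its neighbour records."""
    d = np.asarray(neighbours["D_cm"], dtype=float)
    sp = np.asarray(neighbours["species_id"])
    ba = math.pi * d**2 / 4.0
    nci_sym = float(ba.sum())
    nci_asym = float(ba[d > focal_d].sum())
    cnd = int((sp == focal_species).sum())
    nsr = int(len(set(sp[sp != focal_species])))
    return NeighbourhoodFeatures(
        tree_id=tree_id,
        nci_asym=nci_asym,
        nci_sym=nci_sym,
        cnd=cnd,
        nsr=nsr,
        n_neighbours=int(len(neighbours)),
    )


def average_over_period(
    per_census: Sequence[NeighbourhoodFeatures],
) -> NeighbourhoodFeatures:
    """Arithmetic mean of per-census indices over the study period."""
    if not per_census:
        raise ValueError("no censuses to average over")
    return NeighbourhoodFeatures(
        tree_id=per_census[0].tree_id,
        nci_asym=float(np.mean([f.nci_asym for f in per_census])),
        nci_sym=float(np.mean([f.nci_sym for f in per_census])),
        cnd=float(np.mean([f.cnd for f in per_census])),
        nsr=float(np.mean([f.nsr for f in per_census])),
        n_neighbours=float(np.mean([f.n_neighbours for f in per_census])),
        averaged=True,
    )


def grid_neighbourhood_indices(
    species: np.ndarray, diameter: np.ndarray, alive: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorised per-cell indices for one plot grid at one census.

    `species` is an integer grid (codes >= 0), `diameter` in cm, `alive`
    boolean; dead cells contribute nothing as neighbours.  Returns arrays of
    the grid's shape.
    """
    sp = np.asarray(species)
    d = np.asarray(diameter, dtype=float)
    al = np.asarray(alive, dtype=bool)
    nrow, ncol = sp.shape
    spp = np.full((nrow + 2, ncol + 2), -1, dtype=sp.dtype)
    spp[1:-1, 1:-1] = np.where(al, sp, -1)
    dp = np.zeros((nrow + 2, ncol + 2))
    dp[1:-1, 1:-1] = np.where(al, d, 0.0)
    nsp = np.stack(
        [spp[1 + dr : 1 + dr + nrow, 1 + dc : 1 + dc + ncol] for dr, dc in MOORE_OFFSETS]
    )
    nd = np.stack(
        [dp[1 + dr : 1 + dr + nrow, 1 + dc : 1 + dc + ncol] for dr, dc in MOORE_OFFSETS]
    )
    valid = nsp >= 0
    ba = math.pi * nd**2 / 4.0
    nci_sym = (ba * valid).sum(axis=0)
    nci_asym = (ba * (valid & (nd > d))).sum(axis=0)
    cnd = (valid & (nsp == sp)).sum(axis=0)
    het = np.where(valid & (nsp != sp), nsp, -1)
    het_sorted = np.sort(het, axis=0)
    first = np.full((1, nrow, ncol), -1, dtype=het_sorted.dtype)
    changes = np.diff(np.concatenate([first, het_sorted], axis=0), axis=0) != 0
    nsr = ((het_sorted >= 0) & changes).sum(axis=0)
    return {
        "nci_asym": nci_asym,
        "nci_sym": nci_sym,
        "cnd": cnd,
        "nsr": nsr,
        "n_neighbours": valid.sum(axis=0),
    }


def compute_features(
    census: pd.DataFrame,
    *,
    form_factor: float = 0.5,
    index_censuses: str | Sequence = "all",
) -> pd.DataFrame:
    """Per-tree growth and period-averaged neighbourhood indices.

    `census` is the long table (one row per tree per census) with columns
    plot_id, tree_id, row, col, species_id, role, census_year, D_cm, H_cm,
    alive.  Growth uses the first and last census; indices are averaged over
    `index_censuses` ("all", or an explicit list of census years).  Trees
    dead at the final census get no growth record (G = NaN).
    """
    years = sorted(census["census_year"].unique())
    if len(years) < 1:
        raise ValueError("census table is empty")
    t1, t2 = years[0], years[-1]
    if index_censuses == "all":
        idx_years = years
    else:
        idx_years = [y for y in years if y in set(index_censuses)]
        if not idx_years:
            raise ValueError("index_censuses matches no census year")

    sp_codes, sp_levels = pd.factorize(census["species_id"], sort=True)
    census = census.assign(_sp_code=sp_codes)

    base = (
        census[census["census_year"] == t1]
        .set_index("tree_id")[["plot_id", "row", "col", "species_id", "role", "_sp_code"]]
    )

    # pivot per-census grids per plot, accumulate index sums per tree
    sums: dict[str, np.ndarray] = {}
    n_tracked = len(base)
    order = {tid: i for i, tid in enumerate(base.index)}
    acc = {k: np.zeros(n_tracked) for k in ("nci_asym", "nci_sym", "cnd", "nsr", "n_neighbours")}
    for year in idx_years:
        snap = census[census["census_year"] == year]
        for plot_id, grp in snap.groupby("plot_id", sort=False):
            nrow = int(grp["row"].max()) + 1
            ncol = int(grp["col"].max()) + 1
            sp = np.full((nrow, ncol), -1, dtype=int)
            d = np.zeros((nrow, ncol))
            al = np.zeros((nrow, ncol), dtype=bool)
            r = grp["row"].to_numpy()
            c = grp["col"].to_numpy()
            sp[r, c] = grp["_sp_code"].to_numpy()
            dvals = grp["D_cm"].to_numpy(dtype=float)
            d[r, c] = np.nan_to_num(dvals, nan=0.0)
            al[r, c] = grp["alive"].to_numpy(dtype=bool)
            res = grid_neighbourhood_indices(sp, d, al)
            rows_idx = np.fromiter(
                (order[t] for t in grp["tree_id"]), dtype=int, count=len(grp)
            )
            for k in acc:
                acc[k][rows_idx] += res[k][r, c]
    for k in acc:
        sums[k] = acc[k] / len(idx_years)

    wide_d = census.pivot_table(index="tree_id", columns="census_year", values="D_cm", aggfunc="first")
    wide_h = census.pivot_table(index="tree_id", columns="census_year", values="H_cm", aggfunc="first")
    wide_a = census.pivot(index="tree_id", columns="census_year", values="alive")

    out = base.copy()
    d1 = wide_d[t1].reindex(base.index)
    h1 = wide_h[t1].reindex(base.index)
    out["V1"] = wood_volume(d1.fillna(0.0), h1.fillna(0.0), form_factor)
    alive_end = wide_a[t2].reindex(base.index).fillna(False).astype(bool)
    if t2 != t1:
        d2 = wide_d[t2].reindex(base.index)
        h2 = wide_h[t2].reindex(base.index)
        v2 = wood_volume(d2.fillna(0.0), h2.fillna(0.0), form_factor)
        v2 = np.where(alive_end, v2, np.nan)
        out["V2"] = v2
        out["G"] = (out["V2"] - out["V1"]) / (t2 - t1)
    else:
        out["V2"] = np.nan
        out["G"] = np.nan
    out["alive_end"] = alive_end.to_numpy()
    for k, v in sums.items():
        out[k] = v
    out = out.drop(columns=["_sp_code"]).reset_index()
    return out
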