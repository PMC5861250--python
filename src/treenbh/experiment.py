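"""Synthetic planted tree-diversity experiments with known ground truth.

Emulates the layout of a large biodiversity-ecosystem functioning planting
trial: square plots of 20 x 20 trees at 1.29 m spacing, a richness gradient
{1, 2, 4, 8, 16, 24} drawn from a 40-species pool, species randomly
assigned to planting positions with equal per-species frequency, and a
central block of focal trees surrounded by a ring of neighbour-only trees.

Initial sizes follow a lognormal stem diameter with a power-law
diameter-height allometry whose noise is calibrated analytically so that
the log D - log H correlation matches a configured target (0.91 by
default).  Growth is generated from the neighbourhood growth model itself —
log10 of annual wood-volume growth is a linear function of standardised
log10 initial volume, log10(NCI+1), CND and NSR (plus optional interaction
terms), with crossed Gaussian random intercepts for species, neighbourhood
species composition, neighbour density and plot, and a Gaussian residual —
so every downstream estimator can be checked against known coefficients.
Mortality is a single Bernoulli draw per tree per period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import grid_neighbourhood_indices, wood_volume

__all__ = [
    "PlotDesign",
    "ExperimentDesign",
    "AllometryParams",
    "GrowthModelParams",
    "SimulationTruth",
    "generate_design",
    "simulate_initial_state",
    "simulate_growth_and_mortality",
    "simulate_site",
]

RICHNESS_LEVELS = (1, 2, 4, 8, 16, 24)

#: per-site plot counts per richness level used in the reference trial
SITE_A_PLOTS = {1: 76, 2: 68, 4: 46, 8: 26, 16: 19, 24: 5}
SITE_B_PLOTS = {1: 74, 2: 66, 4: 45, 8: 26, 16: 18, 24: 5}


@dataclass
class PlotDesign:
    plot_id: str
    richness: int
    composition_id: str
    species: tuple[str, ...]
    planting: np.ndarray  # (grid_dim, grid_dim) array of species ids (str)
    focal_block: int
    elevation_m: float
    slope_deg: float
    northness: float

    def roles(self) -> np.ndarray:
        """Grid of roles: focal centre block, neighbour-only ring, edge buffer."""
        g = self.planting.shape[0]
        roles = np.full((g, g), "edge", dtype=object)
        f = self.focal_block
        lo = (g - f) // 2
        hi = lo + f
        roles[max(lo - 1, 0) : min(hi + 1, g), max(lo - 1, 0) : min(hi + 1, g)] = "neighbour_only"
        roles[lo:hi, lo:hi] = "focal"
        return roles


@dataclass
class ExperimentDesign:
    site_id: str
    plots: list[PlotDesign]
    species_pool: tuple[str, ...]
    spacing_m: float = 1.29
    grid_dim: int = 20


@dataclass
class AllometryParams:
    """Initial-size distribution: D ~ lognormal, H = a D^b * lognormal noise."""

    d_median_cm: float = 1.5
    d_sigma_log: float = 0.25  # sd of natural-log diameter (same-age cohort)
    h_coef: float = 60.0  # cm at D = 1 cm
    h_exp: float = 0.9
    dh_corr: float = 0.91  # target Pearson correlation of log D, log H

    def h_noise_sd(self) -> float:
        """Natural-log H noise sd implied by the target log D - log H correlation.

        corr = b s_D / sqrt(b^2 s_D^2 + s_e^2)  =>  s_e = b s_D sqrt(1/r^2 - 1).
        """
        r = self.dh_corr
        if not 0 < r <= 1:
            raise ValueError("dh_corr must be in (0, 1]")
        if r == 1.0:
            return 0.0
        return abs(self.h_exp) * self.d_sigma_log * math.sqrt(1.0 / r**2 - 1.0)


@dataclass
class GrowthModelParams:
    """Ground-truth coefficients of the generative neighbourhood growth model.

    Slopes act on standardised predictors (divided by the site population
    sd); the intercept is log10 growth (cm^3 year^-1) at zero predictors.
    """

    alpha: float = -1.3
    beta_logv: float = 0.35
    beta_nci: float = -0.15
    beta_cnd: float = 0.0
    beta_nsr: float = 0.15
    beta_logv_nci: float = 0.0
    beta_logv_nsr: float = -0.01
    beta_nci_nsr: float = -0.01
    beta_logv_nci_nsr: float = 0.005
    sd_species: float = 0.25
    sd_composition: float = 0.10
    sd_density: float = 0.05
    sd_plot: float = 0.06
    sd_resid: float = 0.30

    def __post_init__(self):
        for name in ("sd_species", "sd_composition", "sd_density", "sd_plot", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def fixed_part(self, zv, znci, zcnd, znsr):
        """Fixed linear predictor on standardised covariates (vectorised)."""
        return (
            self.alpha
            + self.beta_logv * zv
            + self.beta_nci * znci
            + self.beta_cnd * zcnd
            + self.beta_nsr * znsr
            + self.beta_logv_nci * zv * znci
            + self.beta_logv_nsr * zv * znsr
            + self.beta_nci_nsr * znci * znsr
            + self.beta_logv_nci_nsr * zv * znci * znsr
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationTruth:
    """Ground truth recorded by the generator for estimator checks."""

    params: GrowthModelParams
    divisors: dict[str, float]  # population sd used to standardise each predictor
    random_effects: dict[str, dict]
    predictors: pd.DataFrame = None  # per-tree standardised covariates + logG


def _topography(rng: np.random.Generator) -> tuple[float, float, float]:
    return (
        float(rng.uniform(100.0, 300.0)),
        float(rng.uniform(15.0, 40.0)),
        float(rng.uniform(-1.0, 1.0)),
    )


def generate_design(
    n_plots_per_level: Mapping[int, int],
    *,
    species_pool_size: int = 40,
    grid_dim: int = 20,
    spacing_m: float = 1.29,
    seed: int | np.random.SeedSequence = 0,
    site_id: str = "A",
    focal_block: int = 4,
    large_focal_fraction: float = 0.0,
    large_focal_block: int = 10,
    compositions_per_level: Mapping[int, int] | None = None,
) -> ExperimentDesign:
    """Randomised plot designs for one experimental site.

    Each plot draws a species set of its richness level uniformly from the
    site pool and assigns individuals to grid positions at equal per-species
    frequency (remainders round-robin).  Species compositions are memoised
    into a limited set per richness level so that the composition grouping
    factor has repeated levels.  Plots at richness >= 4 are upgraded to a
    larger focal block with probability `large_focal_fraction`.
    """
    rng = np.random.default_rng(seed)
    pool = tuple(f"{site_id}_sp{i:02d}" for i in range(species_pool_size))
    for r, count in n_plots_per_level.items():
        if r > species_pool_size:
            raise ValueError(
                f"richness {r} exceeds species pool size {species_pool_size}"
            )
        if count < 0:
            raise ValueError("plot counts must be non-negative")
    if focal_block + 4 > grid_dim or large_focal_block + 4 > grid_dim:
        raise ValueError("focal block too large for grid (needs 2-row border)")

    plots: list[PlotDesign] = []
    n_cells = grid_dim * grid_dim
    for r in sorted(n_plots_per_level):
        count = n_plots_per_level[r]
        if count == 0:
            continue
        if compositions_per_level and r in compositions_per_level:
            n_comp = max(1, compositions_per_level[r])
        elif r == 1:
            n_comp = min(count, species_pool_size)
        else:
            n_comp = max(1, math.ceil(count / 3))
        n_comp = min(n_comp, count)
        comps = []
        seen = set()
        attempts = 0
        while len(comps) < n_comp and attempts < 1000 * n_comp:
            attempts += 1
            s = tuple(sorted(rng.choice(species_pool_size, size=r, replace=False)))
            if s not in seen:
                seen.add(s)
                comps.append(s)
        assignment = rng.permutation(
            np.resize(np.arange(len(comps)), count)
        )
        for i in range(count):
            comp_idx = assignment[i]
            comp = comps[comp_idx]
            species = tuple(pool[j] for j in comp)
            base = n_cells // r
            counts = np.full(r, base)
            extra = rng.permutation(r)[: n_cells - base * r]
            counts[extra] += 1
            flat = np.repeat(np.arange(r), counts)
            flat = flat[rng.permutation(n_cells)]
            planting = np.array([species[k] for k in flat], dtype=object).reshape(
                grid_dim, grid_dim
            )
            fblock = focal_block
            if r >= 4 and rng.random() < large_focal_fraction:
                fblock = large_focal_block
            elev, slope, north = _topography(rng)
            plots.append(
                PlotDesign(
                    plot_id=f"{site_id}_r{r:02d}_p{i:03d}",
                    richness=r,
                    composition_id=f"{site_id}_c{r:02d}_{comp_idx:03d}",
                    species=species,
                    planting=planting,
                    focal_block=fblock,
                    elevation_m=elev,
                    slope_deg=slope,
                    northness=north,
                )
            )
    return ExperimentDesign(
        site_id=site_id,
        plots=plots,
        species_pool=pool,
        spacing_m=spacing_m,
        grid_dim=grid_dim,
    )


def plots_table(design: ExperimentDesign) -> pd.DataFrame:
    """Plot metadata table (one row per plot)."""
    return pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in design.plots],
            "richness": [p.richness for p in design.plots],
            "composition_id": [p.composition_id for p in design.plots],
            "elevation_m": [p.elevation_m for p in design.plots],
            "slope_deg": [p.slope_deg for p in design.plots],
            "northness": [p.northness for p in design.plots],
        }
    )


def simulate_initial_state(
    design: ExperimentDesign,
    allometry: AllometryParams | None = None,
    *,
    seed: int | np.random.SeedSequence = 0,
    census_year: int = 2011,
) -> pd.DataFrame:
    """First-census tree table: every planted tree alive with D and H (cm)."""
    allometry = allometry or AllometryParams()
    rng = np.random.default_rng(seed)
    frames = []
    g = design.grid_dim
    rows_idx, cols_idx = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    for plot in design.plots:
        n = g * g
        d = allometry.d_median_cm * np.exp(
            rng.normal(0.0, allometry.d_sigma_log, size=n)
        )
        noise = rng.normal(0.0, allometry.h_noise_sd(), size=n)
        h = allometry.h_coef * d**allometry.h_exp * np.exp(noise)
        roles = plot.roles()
        frames.append(
            pd.DataFrame(
                {
                    "plot_id": plot.plot_id,
                    "tree_id": [
                        f"{plot.plot_id}_t{r:02d}{c:02d}"
                        for r, c in zip(rows_idx.ravel(), cols_idx.ravel())
                    ],
                    "row": rows_idx.ravel(),
                    "col": cols_idx.ravel(),
                    "species_id": plot.planting.ravel(),
                    "role": roles.ravel(),
                    "census_year": census_year,
                    "D_cm": d,
                    "H_cm": h,
                    "alive": True,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _draw_effects(levels: Sequence, sd: float, rng: np.random.Generator) -> dict:
    levels = sorted(set(levels))
    draws = rng.normal(0.0, sd, size=len(levels))
    return dict(zip(levels, draws))


def simulate_growth_and_mortality(
    trees: pd.DataFrame,
    design: ExperimentDesign,
    params: GrowthModelParams | None = None,
    *,
    mortality_rate: float = 0.17,
    negative_growth_rate: float = 0.0,
    n_years: int = 5,
    form_factor: float = 0.5,
    seed: int | np.random.SeedSequence = 0,
    divisors: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Append a final census generated from the neighbourhood growth model.

    Every tree's log10 annual growth is its fixed linear predictor (on
    census-1 standardised covariates) plus its four random intercepts and a
    Gaussian residual; final volume is V1 + G * n_years, back-solved to
    (D, H) holding the tree's height/diameter ratio fixed.  Death is an
    independent Bernoulli per tree; a `negative_growth_rate` fraction of
    survivors get a slightly shrunken remeasured volume, emulating the
    measurement artefacts that the growth filter later removes.

    Returns the full two-census long table and a :class:`SimulationTruth`
    with the divisors, random-effect draws and per-tree predictors.
    """
    params = params or GrowthModelParams()
    if not 0 <= mortality_rate < 1:
        raise ValueError("mortality_rate must be in [0, 1)")
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)

    trees = trees.sort_values(["plot_id", "row", "col"]).reset_index(drop=True)
    t1 = int(trees["census_year"].iloc[0])
    t2 = t1 + n_years

    # census-1 neighbourhood indices for every tree, plot by plot
    sp_codes, _ = pd.factorize(trees["species_id"], sort=True)
    trees = trees.assign(_sp=sp_codes)
    nci = np.empty(len(trees))
    cnd = np.empty(len(trees))
    nsr = np.empty(len(trees))
    nnb = np.empty(len(trees))
    g = design.grid_dim
    for plot_id, grp in trees.groupby("plot_id", sort=False):
        sp = np.full((g, g), -1, dtype=int)
        d = np.zeros((g, g))
        r = grp["row"].to_numpy()
        c = grp["col"].to_numpy()
        sp[r, c] = grp["_sp"].to_numpy()
        d[r, c] = grp["D_cm"].to_numpy(dtype=float)
        res = grid_neighbourhood_indices(sp, d, np.ones((g, g), dtype=bool))
        idx = grp.index.to_numpy()
        nci[idx] = res["nci_asym"][r, c]
        cnd[idx] = res["cnd"][r, c]
        nsr[idx] = res["nsr"][r, c]
        nnb[idx] = res["n_neighbours"][r, c]

    v1 = wood_volume(trees["D_cm"].to_numpy(), trees["H_cm"].to_numpy(), form_factor)
    logv = np.log10(v1)
    lognci = np.log10(nci + 1.0)

    if divisors is None:
        divisors = {
            "logV": float(np.std(logv, ddof=1)),
            "logNCI": float(max(np.std(lognci, ddof=1), 1e-12)),
            "CND": float(max(np.std(cnd, ddof=1), 1e-12)),
            "NSR": float(max(np.std(nsr, ddof=1), 1e-12)),
        }
    else:
        divisors = dict(divisors)
    zv = logv / divisors["logV"]
    znci = lognci / divisors["logNCI"]
    zcnd = cnd / divisors["CND"]
    znsr = nsr / divisors["NSR"]

    plot_meta = {p.plot_id: p for p in design.plots}
    comp_of_plot = {pid: p.composition_id for pid, p in plot_meta.items()}
    comp_ids = trees["plot_id"].map(comp_of_plot)
    density_id = nnb.astype(int)

    re_species = _draw_effects(trees["species_id"], params.sd_species, rng)
    re_comp = _draw_effects(comp_ids, params.sd_composition, rng)
    re_density = _draw_effects(density_id, params.sd_density, rng)
    re_plot = _draw_effects(trees["plot_id"], params.sd_plot, rng)

    eta = params.fixed_part(zv, znci, zcnd, znsr)
    logg = (
        eta
        + trees["species_id"].map(re_species).to_numpy()
        + comp_ids.map(re_comp).to_numpy()
        + pd.Series(density_id).map(re_density).to_numpy()
        + trees["plot_id"].map(re_plot).to_numpy()
        + rng.normal(0.0, params.sd_resid, size=len(trees))
    )
    growth = np.power(10.0, logg)
    v2 = v1 + growth * n_years

    dead = rng.random(len(trees)) < mortality_rate
    if negative_growth_rate > 0:
        shrink = (~dead) & (rng.random(len(trees)) < negative_growth_rate)
        v2 = np.where(shrink, v1 * (1.0 - rng.uniform(0.005, 0.05, size=len(trees))), v2)

    # back-solve (D2, H2) from V2 with the tree's H/D ratio held fixed:
    # V = pi f c / 4 * D^3 with c = H1/D1
    c_ratio = trees["H_cm"].to_numpy() / trees["D_cm"].to_numpy()
    d2 = np.cbrt(4.0 * v2 / (math.pi * form_factor * c_ratio))
    h2 = c_ratio * d2

    final = trees.drop(columns=["_sp"]).copy()
    final["census_year"] = t2
    final["D_cm"] = np.where(dead, np.nan, d2)
    final["H_cm"] = np.where(dead, np.nan, h2)
    final["alive"] = ~dead

    census = pd.concat(
        [trees.drop(columns=["_sp"]), final], ignore_index=True
    )
    truth = SimulationTruth(
        params=params,
        divisors=divisors,
        random_effects={
            "species_id": re_species,
            "composition_id": re_comp,
            "density_id": re_density,
            "plot_id": re_plot,
        },
        predictors=pd.DataFrame(
            {
                "tree_id": trees["tree_id"],
                "plot_id": trees["plot_id"],
                "zv": zv,
                "znci": znci,
                "zcnd": zcnd,
                "znsr": znsr,
                "logG_true": logg,
                "dead": dead,
            }
        ),
    )
    return census, truth


def simulate_site(
    n_plots_per_level: Mapping[int, int] | None = None,
    *,
    site_id: str = "A",
    seed: int | np.random.SeedSequence = 0,
    params: GrowthModelParams | None = None,
    allometry: AllometryParams | None = None,
    mortality_rate: float = 0.17,
    negative_growth_rate: float = 0.017,
    large_focal_fraction: float = 0.25,
    divisors: Mapping[str, float] | None = None,
    **design_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, ExperimentDesign, SimulationTruth]:
    """Convenience wrapper: design + initial state + growth for one site.

    Returns (census table, plot metadata table, design, truth); all
    randomness derives from `seed` via spawned child streams.
    """
    if n_plots_per_level is None:
        n_plots_per_level = SITE_A_PLOTS if site_id == "A" else SITE_B_PLOTS
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    s_design, s_init, s_growth = ss.spawn(3)
    design = generate_design(
        n_plots_per_level,
        site_id=site_id,
        seed=s_design,
        large_focal_fraction=large_focal_fraction,
        **design_kwargs,
    )
    trees = simulate_initial_state(design, allometry, seed=s_init)
    census, truth = simulate_growth_and_mortality(
        trees,
        design,
        params,
        mortality_rate=mortality_rate,
        negative_growth_rate=negative_growth_rate,
        seed=s_growth,
        divisors=divisors,
    )
    return census, plots_table(design), design, truth
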