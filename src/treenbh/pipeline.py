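"""End-to-end pipeline: simulate two sites, fit the neighbourhood model at
site A, scale predictions up to site-B community productivity, and
partition the community-model variance.

The two sites are generated independently with disjoint species pools by
default, so the neighbourhood model fitted at site A is transferred to
site B through its fixed effects only — species identity never enters the
cross-site prediction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, experiment, io, lmm, neighbourhood
from .experiment import AllometryParams, GrowthModelParams

__all__ = ["SiteConfig", "RunConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger("treenbh")


@dataclass
class SiteConfig:
    site_id: str
    n_plots_per_level: dict[int, int]
    mortality_rate: float = 0.17
    negative_growth_rate: float = 0.017
    species_pool_size: int = 40
    grid_dim: int = 20
    focal_block: int = 4
    large_focal_fraction: float = 0.25
    large_focal_block: int = 10


@dataclass
class RunConfig:
    seed: int
    site_a: SiteConfig = field(
        default_factory=lambda: SiteConfig("A", dict(experiment.SITE_A_PLOTS))
    )
    site_b: SiteConfig = field(
        default_factory=lambda: SiteConfig(
            "B", dict(experiment.SITE_B_PLOTS), mortality_rate=0.23,
            negative_growth_rate=0.021,
        )
    )
    growth: GrowthModelParams = field(default_factory=GrowthModelParams)
    allometry: AllometryParams = field(default_factory=AllometryParams)
    nci_mode: str = "asym"  # 'asym', 'sym' or 'both' (both runs the comparison)
    index_censuses: str | list = "all"
    form_factor: float = 0.5
    selection_alpha: float = 0.05
    cnd_baseline: str = "mean"
    richness_groups: tuple = community.DEFAULT_RICHNESS_GROUPS
    output_dir: str | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.nci_mode not in ("asym", "sym", "both"):
            raise ValueError("nci_mode must be 'asym', 'sym' or 'both'")
        for sc in (self.site_a, self.site_b):
            if sum(sc.n_plots_per_level.values()) == 0:
                raise ValueError(f"site {sc.site_id}: no plots configured")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, klass in (("site_a", SiteConfig), ("site_b", SiteConfig)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if "n_plots_per_level" in sub:
                    sub["n_plots_per_level"] = {
                        int(k): int(v) for k, v in sub["n_plots_per_level"].items()
                    }
                d[key] = klass(**sub)
        if "growth" in d and isinstance(d["growth"], dict):
            d["growth"] = GrowthModelParams(**d["growth"])
        if "allometry" in d and isinstance(d["allometry"], dict):
            d["allometry"] = AllometryParams(**d["allometry"])
        if "richness_groups" in d:
            d["richness_groups"] = tuple(tuple(g) for g in d["richness_groups"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io.load_yaml(path))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["richness_groups"] = [list(g) for g in self.richness_groups]
        return d

    def hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # scientific config only, not artifact paths
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": self.stages,
            "warnings": self.warnings,
        }


def _simulate_site(cfg: RunConfig, sc: SiteConfig, ss: np.random.SeedSequence):
    return experiment.simulate_site(
        sc.n_plots_per_level,
        site_id=sc.site_id,
        seed=ss,
        params=cfg.growth,
        allometry=cfg.allometry,
        mortality_rate=sc.mortality_rate,
        negative_growth_rate=sc.negative_growth_rate,
        species_pool_size=sc.species_pool_size,
        grid_dim=sc.grid_dim,
        focal_block=sc.focal_block,
        large_focal_fraction=sc.large_focal_fraction,
        large_focal_block=sc.large_focal_block,
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all pipeline stages; artifacts go to ``config.output_dir``."""
    t_start = time.time()
    report = RunReport(config_hash=config.hash(), seed=config.seed)
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    ss_a, ss_b = ss.spawn(2)
    caught: list[str] = []

    def stage(name):
        logger.info("stage %s", name)
        return time.time()

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        # -- simulate ------------------------------------------------------
        t = stage("simulate")
        census_a, plots_a, design_a, truth_a = _simulate_site(config, config.site_a, ss_a)
        census_b, plots_b, design_b, truth_b = _simulate_site(config, config.site_b, ss_b)
        for label, census, truth in (("site_a", census_a, truth_a), ("site_b", census_b, truth_b)):
            final = census[census["census_year"] == census["census_year"].max()]
            report.stages.setdefault("simulate", {})[label] = {
                "n_trees": int(final.shape[0]),
                "realized_mortality": float(1.0 - final["alive"].mean()),
            }
        report.stages["simulate"]["elapsed_s"] = round(time.time() - t, 2)
        if outdir:
            io.write_census_csv(census_a, outdir / "census_site_a.csv")
            io.write_census_csv(census_b, outdir / "census_site_b.csv")
            io.write_plots_csv(plots_a, outdir / "plots_site_a.csv")
            io.write_plots_csv(plots_b, outdir / "plots_site_b.csv")

        # -- metrics + focal datasets -------------------------------------
        t = stage("metrics")
        mode = "asym" if config.nci_mode == "both" else config.nci_mode
        ds_a = neighbourhood.build_focal_dataset(
            census_a, plots_a, nci_mode=mode,
            index_censuses=config.index_censuses, form_factor=config.form_factor,
        )
        ds_b = neighbourhood.build_focal_dataset(
            census_b, plots_b, nci_mode=mode,
            index_censuses=config.index_censuses, form_factor=config.form_factor,
        )
        report.stages["metrics"] = {
            "site_a": {"n_focal": ds_a.n_focal, **ds_a.exclusions},
            "site_b": {"n_focal": ds_b.n_focal, **ds_b.exclusions},
            "elapsed_s": round(time.time() - t, 2),
        }

        # -- neighbourhood model (site A) ----------------------------------
        t = stage("fit-neighbourhood")
        sel = neighbourhood.select_neighbourhood_model(ds_a, alpha=config.selection_alpha)
        r2m, r2c = lmm.r2_nakagawa(sel.best_fit)
        report.stages["neighbourhood_model"] = {
            "terms": [lmm.term_label(t_) for t_ in sel.terms],
            "aic": sel.best_fit.aic,
            "r2_marginal": r2m,
            "r2_conditional": r2c,
            "random_slope_test": sel.random_slope_test,
            "n_candidates": int(len(sel.candidate_table)),
            "elapsed_s": round(time.time() - t, 2),
        }
        if outdir:
            (outdir / "neighbourhood_fit.json").write_text(sel.best_fit.to_json())
            sel.candidate_table.to_csv(outdir / "candidate_models.csv")

        # -- NE surface -----------------------------------------------------
        t = stage("ne-surface")
        surface = neighbourhood.ne_nbh_surface(
            sel.best_fit, ds_a, cnd_baseline=config.cnd_baseline
        )
        report.stages["ne_surface"] = {
            "n_cells": int(len(surface)),
            "max_ne_percent": float(surface["ne_percent"].max()),
            "elapsed_s": round(time.time() - t, 2),
        }
        if outdir:
            surface.to_csv(outdir / "ne_surface.csv", index=False)

        # -- NCI mode sensitivity ------------------------------------------
        if config.nci_mode == "both":
            t = stage("nci-comparison")
            cmp_res = neighbourhood.nci_mode_comparison(ds_a, sel.terms)
            cmp_res["elapsed_s"] = round(time.time() - t, 2)
            report.stages["nci_comparison"] = cmp_res

        # -- cross-predict + community model --------------------------------
        t = stage("community")
        g_nbh = community.cross_predict_growth(sel.best_fit, ds_a.record, ds_b)
        records = community.build_community_records(ds_b, plots_b, g_nbh)
        cm = community.fit_community_model(records, alpha=config.selection_alpha)
        part = community.variance_partition(cm["fit"], cm["data"])
        r2_groups = community.r2_by_richness(records, config.richness_groups)
        nsr_csr = community.nsr_csr_relation(ds_b, plots_b)
        r2m_c, r2c_c = lmm.r2_nakagawa(cm["fit"])
        report.stages["community_model"] = {
            "n_plots": int(len(records)),
            "terms": [lmm.term_label(t_) for t_ in cm["fit"].spec.fixed],
            "vif_max": float(cm["vif"].max()) if len(cm["vif"]) else None,
            "r2_marginal": r2m_c,
            "r2_conditional": r2c_c,
            "variance_partition": part.to_dict(),
            "r2_by_richness": r2_groups.to_dict(orient="records"),
            "nsr_csr": nsr_csr,
            "elapsed_s": round(time.time() - t, 2),
        }
        if outdir:
            records.to_csv(outdir / "community_records.csv", index=False)
            io.write_json(part.to_dict(), outdir / "variance_partition.json")
            r2_groups.to_csv(outdir / "r2_by_richness.csv", index=False)
            (outdir / "community_fit.json").write_text(cm["fit"].to_json())

        caught = sorted({str(w.message) for w in wlist})

    report.warnings = caught
    report.stages["total_elapsed_s"] = round(time.time() - t_start, 2)
    if outdir:
        io.write_json(report.to_dict(), outdir / "run_report.json")
    return report
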