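"""Stage 2: community productivity, its drivers, and variance partitioning.

Plot-level standardised aboveground wood productivity (AWP, cm^3 cm^-3
year^-1) weights each focal tree's annual growth by its initial wood volume
and divides by the summed period-mean wood volume:

    AWP = sum_i(G_i * V_i) / sum_i(Vbar_i)

The same aggregation serves the observed growth rates (AWP_obs) and the
growth rates predicted by the neighbourhood model fitted at the other site
(AWP_nbh), which carries the aggregated net effect of local neighbourhood
interactions across sites.  The community model regresses log10 AWP_obs on
standardised log10 community species richness (CSR), log10 AWP_nbh and
topography (elevation, slope, northness), with a random intercept for the
planted species composition (CSC); its variance is partitioned into
per-predictor, per-random-factor and residual fractions that sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import lmm
from .lmm import ModelFit, ModelSpec, RandomTerm, StandardizationRecord
from .neighbourhood import FocalDataset

__all__ = [
    "awp",
    "plot_awp",
    "cross_predict_growth",
    "build_community_records",
    "fit_community_model",
    "variance_partition",
    "VariancePartitionResult",
    "r2_by_richness",
    "nsr_csr_relation",
    "simulate_community_records",
    "DEFAULT_RICHNESS_GROUPS",
]

COMMUNITY_PREDICTORS = ("logAWPnbh", "logCSR", "elevation_m", "slope_deg", "northness")
DEFAULT_RICHNESS_GROUPS = ((1,), (2,), (4, 8), (16, 24))


def awp(growth: np.ndarray, v_initial: np.ndarray, v_mean: np.ndarray) -> float:
    """Standardised aboveground wood productivity of one plot.

    ``sum(G_i * V_i) / sum(Vbar_i)`` — growth weighted by initial volume,
    normalised by the summed period-mean volume.
    """
    g = np.asarray(growth, dtype=float)
    vi = np.asarray(v_initial, dtype=float)
    vm = np.asarray(v_mean, dtype=float)
    if g.size == 0:
        raise ValueError("empty plot: no focal trees to aggregate")
    if not (g.shape == vi.shape == vm.shape):
        raise ValueError("growth and volume vectors must be aligned")
    denom = float(vm.sum())
    if denom <= 0:
        raise ValueError("summed mean wood volume must be positive")
    return float((g * vi).sum() / denom)


def plot_awp(features: pd.DataFrame, growth_col: str = "G") -> pd.Series:
    """Per-plot AWP from a focal-tree feature table (V1, V2, growth column).

    The period-mean volume of each tree is the mean of its per-census
    volumes ((V1+V2)/2 in the two-census default).
    """
    def _one(grp: pd.DataFrame) -> float:
        vmean = (grp["V1"] + grp["V2"]) / 2.0
        return awp(grp[growth_col].to_numpy(), grp["V1"].to_numpy(), vmean.to_numpy())

    return features.groupby("plot_id").apply(_one, include_groups=False)


def cross_predict_growth(
    fit: ModelFit,
    record: StandardizationRecord,
    dataset: FocalDataset,
) -> np.ndarray:
    """Fixed-effects growth predictions (cm^3 year^-1) for another site.

    Covariates are taken on the raw log scale and standardised with the
    *training* site's record; random effects are at zero, so predictions
    transfer across sites whose species pools differ.
    """
    raw = pd.DataFrame(
        {
            "logV": dataset.data["logV_raw"],
            "logNCI": dataset.data["logNCI_raw"],
            "CND": dataset.data["CND_raw"],
            "NSR": dataset.data["NSR_raw"],
        }
    )
    return lmm.predict_fixed(fit, record, raw, back_transform=True)


def build_community_records(
    dataset: FocalDataset,
    plots: pd.DataFrame,
    g_nbh: np.ndarray,
) -> pd.DataFrame:
    """Per-plot community records: observed and predicted productivity.

    ``dataset`` is the focal dataset of the prediction site (its ``data``
    holds per-tree observed G, V1, V2); ``g_nbh`` is the per-tree predicted
    growth aligned with ``dataset.data``.
    """
    df = dataset.data.copy()
    df["G_nbh"] = np.asarray(g_nbh, dtype=float)
    obs = plot_awp(df, "G")
    nbh = plot_awp(df, "G_nbh")
    n_focal = df.groupby("plot_id").size()
    meta = plots.set_index("plot_id")
    rec = pd.DataFrame(
        {
            "AWP_obs": obs,
            "AWP_nbh": nbh,
            "n_focal": n_focal,
        }
    ).join(meta[["richness", "composition_id", "elevation_m", "slope_deg", "northness"]])
    rec = rec.rename(columns={"richness": "CSR", "composition_id": "CSC"})
    bad = (rec["AWP_obs"] <= 0) | (rec["AWP_nbh"] <= 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} plots with non-positive AWP dropped (no log)",
            RuntimeWarning,
        )
        rec = rec[~bad]
    return rec.reset_index()


def _prepare_community_data(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, StandardizationRecord, list[str], list[str]]:
    data = records.copy()
    data["logAWPobs"] = np.log10(data["AWP_obs"])
    data["logAWPnbh"] = np.log10(data["AWP_nbh"])
    data["logCSR"] = np.log10(data["CSR"].astype(float))
    predictors, dropped = [], []
    for col in COMMUNITY_PREDICTORS:
        x = np.asarray(data[col], dtype=float)
        if np.std(x, ddof=1) > 1e-12:
            predictors.append(col)
        else:
            dropped.append(col)
    data, record = lmm.standardize(data, predictors)
    return data, record, predictors, dropped


def fit_community_model(
    records: pd.DataFrame,
    *,
    alpha: float = 0.05,
    backward: bool = True,
) -> dict:
    """Fit and select the community biodiversity-productivity model.

    ML backward elimination over the five main effects (constant predictors
    are dropped up front with a notice), REML refit of the result, plus a
    collinearity check (VIF) on the retained predictors.
    """
    data, record, predictors, dropped = _prepare_community_data(records)
    notices = [f"dropped constant predictor {c}" for c in dropped]
    if data["CSC"].nunique() < 2:
        raise ValueError("need >= 2 species-composition levels")
    random = (RandomTerm("CSC"),)
    terms = tuple((p,) for p in predictors)
    current_fit = lmm.fit_lmm(data, ModelSpec("logAWPobs", terms, random, "ML"))
    trace = []
    if backward:
        while len(current_fit.spec.fixed) > 1:
            tests = []
            for t in current_fit.spec.fixed:
                reduced = tuple(x for x in current_fit.spec.fixed if x != t)
                red_fit = lmm.fit_lmm(
                    data,
                    ModelSpec("logAWPobs", reduced, random, "ML"),
                    theta0=current_fit.theta,
                )
                chi2, df, p = lmm.lr_test(red_fit, current_fit)
                tests.append((p, chi2, df, t, red_fit))
            tests = [x for x in tests if x[0] > alpha]
            if not tests:
                break
            p, chi2, df, t, red_fit = max(tests, key=lambda x: x[0])
            trace.append({"dropped": lmm.term_label(t), "chi2": chi2, "df": df, "p": p})
            current_fit = red_fit
    final = lmm.fit_lmm(
        data,
        ModelSpec("logAWPobs", current_fit.spec.fixed, random, "REML"),
        theta0=current_fit.theta,
        standardization=record,
    )
    kept = [t[0] for t in final.spec.fixed]
    vifs = lmm.vif(data, kept) if len(kept) >= 2 else pd.Series(dtype=float)
    return {
        "fit": final,
        "data": data,
        "record": record,
        "elimination": trace,
        "notices": notices,
        "vif": vifs,
    }


@dataclass
class VariancePartitionResult:
    """Fractions of response-model variance; they sum to one."""

    fixed: dict[str, float]
    random: dict[str, float]
    residual: float
    order: list[str] = field(default_factory=list)

    def total(self) -> float:
        return sum(self.fixed.values()) + sum(self.random.values()) + self.residual

    def to_dict(self) -> dict:
        return {
            "fixed": dict(self.fixed),
            "random": dict(self.random),
            "residual": self.residual,
            "order": list(self.order),
        }


def variance_partition(
    fit: ModelFit, data: pd.DataFrame, order: list[str] | None = None
) -> VariancePartitionResult:
    """Partition model variance into per-term, per-factor and residual shares.

    Each fixed term's share is the variance of its partial linear predictor
    after sequential orthogonalisation against the terms preceding it in
    `order` (default: the model's term order); random shares are variance
    components, and the residual closes the sum to one.  The attribution
    convention for correlated predictors is therefore sequential and is
    reported in ``order``.
    """
    labels = [lmm.term_label(t) for t in fit.spec.fixed]
    X = lmm.build_fixed_matrix(data, fit.spec.fixed)
    contrib = X[:, 1:] * fit.beta[1:]  # per-term partial predictors
    if order is None:
        order = labels
    idx = [labels.index(l) for l in order if l in labels]
    n = X.shape[0]
    total_fixed = fit.var_fixed
    denom = total_fixed + fit.total_random_variance() + fit.resid_var
    fixed_frac: dict[str, float] = {}
    if contrib.shape[1] and n > 1:
        C = contrib[:, idx] - contrib[:, idx].mean(axis=0)
        eta = C.sum(axis=1)
        Q, R = np.linalg.qr(C)
        # guard rank deficiency: zero out directions with negligible scale
        keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
        proj = Q.T @ eta
        shares = np.where(keep, proj**2 / (n - 1), 0.0)
        for j, col in enumerate(idx):
            fixed_frac[labels[col]] = float(shares[j] / denom) if denom > 0 else 0.0
    else:
        for l in labels:
            fixed_frac[l] = 0.0
    random_frac = {
        k: float(v / denom) if denom > 0 else 0.0 for k, v in fit.ranef_var.items()
    }
    resid_frac = (
        1.0 - sum(fixed_frac.values()) - sum(random_frac.values())
        if denom > 0
        else 1.0
    )
    return VariancePartitionResult(
        fixed=fixed_frac, random=random_frac, residual=float(resid_frac),
        order=[labels[i] for i in idx],
    )


def r2_by_richness(
    records: pd.DataFrame,
    groups: tuple[tuple[int, ...], ...] = DEFAULT_RICHNESS_GROUPS,
    *,
    min_plots: int = 3,
) -> pd.DataFrame:
    """Marginal r² of AWP_obs ~ AWP_nbh within richness-level groups."""
    rows = []
    for group in groups:
        sub = records[records["CSR"].isin(group)]
        label = "/".join(str(g) for g in group)
        if len(sub) < min_plots:
            rows.append(
                {"group": label, "n_plots": len(sub), "r2_marginal": np.nan,
                 "note": "skipped: too few plots"}
            )
            continue
        data = sub.copy()
        data["logAWPobs"] = np.log10(data["AWP_obs"])
        data["logAWPnbh"] = np.log10(data["AWP_nbh"])
        if np.std(data["logAWPnbh"], ddof=1) <= 1e-12:
            rows.append(
                {"group": label, "n_plots": len(sub), "r2_marginal": np.nan,
                 "note": "skipped: constant predictor"}
            )
            continue
        data, _ = lmm.standardize(data, ["logAWPnbh"])
        random = (RandomTerm("CSC"),) if data["CSC"].nunique() >= 2 else ()
        note = "" if random else "single composition level: no random effect"
        fit = lmm.fit_lmm(
            data, ModelSpec("logAWPobs", (("logAWPnbh",),), random, "REML")
        )
        r2m, _ = lmm.r2_nakagawa(fit)
        rows.append(
            {"group": label, "n_plots": len(sub), "r2_marginal": r2m, "note": note}
        )
    return pd.DataFrame(rows)


def nsr_csr_relation(dataset: FocalDataset, plots: pd.DataFrame) -> dict:
    """Plot-mean neighbourhood species richness against log10 community richness."""
    mean_nsr = dataset.data.groupby("plot_id")["NSR_raw"].mean()
    meta = plots.set_index("plot_id")["richness"]
    joined = pd.DataFrame({"mean_NSR": mean_nsr}).join(meta).dropna()
    if joined["richness"].nunique() < 2 or np.std(joined["mean_NSR"], ddof=0) <= 1e-12:
        return {"degenerate": True, "n_plots": len(joined)}
    res = stats.linregress(np.log10(joined["richness"].astype(float)), joined["mean_NSR"])
    return {
        "degenerate": False,
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n_plots": len(joined),
    }


def simulate_community_records(
    n_plots_per_level: dict[int, int],
    *,
    beta_nbh: float = np.sqrt(0.5),
    beta_csr: float = np.sqrt(0.05),
    sd_csc: float = 0.5,
    sd_resid: float = np.sqrt(0.2),
    nbh_signal_sd: float | dict[int, float] = 1.0,
    compositions_per_level: int = 8,
    awp_scale: float = -2.0,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Directly simulated plot records with known variance shares.

    log10 AWP_obs = awp_scale + beta_nbh * x + beta_csr * z_CSR + u_CSC + e,
    where x = log10 AWP_nbh deviation with per-level sd `nbh_signal_sd`
    (a dict allows the neighbourhood signal to strengthen with richness),
    z_CSR is standardised log richness and u_CSC a composition intercept.
    The default shares of response variance are 0.5 (AWP_nbh), 0.05 (CSR),
    0.25 (CSC) and 0.2 (residual).  Used for calibration tests of the
    community model and the variance partition.
    """
    rng = np.random.default_rng(seed)
    rows = []
    levels = sorted(n_plots_per_level)
    lev_arr = np.log10(np.array(levels, dtype=float))
    lsd = np.std(
        np.repeat(lev_arr, [n_plots_per_level[l] for l in levels]), ddof=1
    )
    lsd = lsd if lsd > 0 else 1.0
    csc_effects: dict[str, float] = {}
    for level in levels:
        for i in range(n_plots_per_level[level]):
            comp = f"c{level}_{i % compositions_per_level}"
            if comp not in csc_effects:
                csc_effects[comp] = rng.normal(0.0, sd_csc)
            sd_x = (
                nbh_signal_sd[level]
                if isinstance(nbh_signal_sd, dict)
                else nbh_signal_sd
            )
            x = rng.normal(0.0, sd_x)
            z_csr = np.log10(level) / lsd
            y = (
                awp_scale
                + beta_nbh * x
                + beta_csr * z_csr
                + csc_effects[comp]
                + rng.normal(0.0, sd_resid)
            )
            rows.append(
                {
                    "plot_id": f"p{level}_{i}",
                    "CSR": level,
                    "CSC": comp,
                    "AWP_obs": 10.0**y,
                    "AWP_nbh": 10.0 ** (awp_scale + x),
                    "elevation_m": rng.uniform(100, 300),
                    "slope_deg": rng.uniform(15, 40),
                    "northness": rng.uniform(-1, 1),
                    "n_focal": 16,
                }
            )
    return pd.DataFrame(rows)
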