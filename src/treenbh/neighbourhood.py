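"""Stage 1: focal-tree dataset, growth-model selection and the net
biodiversity-effect surface.

The focal dataset joins annual growth with period-averaged neighbourhood
indices, log10-transforms growth, initial volume and NCI (+1 offset), and
standardises the predictors by dividing by their sample standard deviation.
Model selection follows a two-stage convention: the random structure is
assessed under REML with the full fixed part (including a test for a
species-specific NSR random slope), then the fixed structure is chosen
under ML by AIC over a hierarchical candidate set and backward-eliminated
by likelihood-ratio tests; the final model is refitted by REML.

The net biodiversity effect at the neighbourhood scale, NE_nbh, is the
percent change in predicted growth of a focal tree in a heterospecific
neighbourhood (NSR = 1..7) relative to a fully conspecific one (NSR = 0),
evaluated on a grid of focal-tree size and competition quantiles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lmm
from .lmm import ModelFit, ModelSpec, RandomTerm, StandardizationRecord
from .metrics import compute_features, filter_negative_growth

__all__ = [
    "FocalDataset",
    "SelectionResult",
    "build_focal_dataset",
    "enumerate_candidates",
    "select_neighbourhood_model",
    "nci_mode_comparison",
    "ne_nbh",
    "ne_nbh_surface",
    "DEFAULT_RANDOM",
]

MAIN_EFFECTS = ("logV", "logNCI", "CND", "NSR")
INTERACTIONS = (
    ("logV", "logNCI"),
    ("logV", "NSR"),
    ("logNCI", "NSR"),
    ("logV", "logNCI", "NSR"),
)
FULL_FIXED = tuple((m,) for m in MAIN_EFFECTS) + INTERACTIONS

DEFAULT_RANDOM = (
    RandomTerm("species_id"),
    RandomTerm("composition_id"),
    RandomTerm("density_id"),
    RandomTerm("plot_id"),
)


@dataclass
class FocalDataset:
    """Model-ready per-focal-tree data with its standardisation record.

    `data` holds the response ``logG``, standardised predictors (``logV``,
    ``logNCI`` = active NCI mode, ``logNCI_asym``, ``logNCI_sym``, ``CND``,
    ``NSR``), raw log-scale covariates with ``_raw`` suffix, and the four
    grouping factors.
    """

    data: pd.DataFrame
    record: StandardizationRecord
    nci_mode: str
    exclusions: dict = field(default_factory=dict)

    @property
    def n_focal(self) -> int:
        return len(self.data)


def build_focal_dataset(
    census: pd.DataFrame,
    plots: pd.DataFrame,
    *,
    nci_mode: str = "asym",
    index_censuses: str | list = "all",
    form_factor: float = 0.5,
) -> FocalDataset:
    """Build the standardised focal-tree dataset from census tables."""
    if nci_mode not in ("asym", "sym"):
        raise ValueError("nci_mode must be 'asym' or 'sym'")
    if len(census) == 0:
        return FocalDataset(
            data=pd.DataFrame(), record=StandardizationRecord({}), nci_mode=nci_mode,
            exclusions={"n_input": 0, "n_excluded": 0, "fraction_excluded": 0.0},
        )
    feats = compute_features(
        census, form_factor=form_factor, index_censuses=index_censuses
    )
    focal = feats[(feats["role"] == "focal") & feats["alive_end"]].copy()
    focal = focal[np.isfinite(focal["G"])]
    kept, report = filter_negative_growth(focal)
    kept = kept[kept["G"] > 0].copy()  # G = 0 has no log; measure-zero in practice

    meta = plots.set_index("plot_id")
    kept["composition_id"] = kept["plot_id"].map(meta["composition_id"])
    missing = kept["composition_id"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} focal trees lack plot metadata; dropped",
            RuntimeWarning,
        )
        kept = kept[~missing]

    kept["logG"] = np.log10(kept["G"])
    kept["logV_raw"] = np.log10(kept["V1"])
    kept["logNCI_asym_raw"] = np.log10(kept["nci_asym"] + 1.0)
    kept["logNCI_sym_raw"] = np.log10(kept["nci_sym"] + 1.0)
    kept["CND_raw"] = kept["cnd"].astype(float)
    kept["NSR_raw"] = kept["nsr"].astype(float)
    kept["density_id"] = kept["n_neighbours"].round().astype(int)

    raw_cols = {
        "logV": "logV_raw",
        "logNCI_asym": "logNCI_asym_raw",
        "logNCI_sym": "logNCI_sym_raw",
        "CND": "CND_raw",
        "NSR": "NSR_raw",
    }
    for std_name, raw_name in raw_cols.items():
        kept[std_name] = kept[raw_name]
    kept = kept.reset_index(drop=True)
    scalable = [
        c for c in raw_cols if np.std(kept[c].to_numpy(dtype=float), ddof=1) > 1e-12
    ]
    degenerate = sorted(set(raw_cols) - set(scalable))
    if degenerate:
        warnings.warn(
            f"constant predictors left unscaled (divisor 1): {degenerate}",
            RuntimeWarning,
        )
    data, record = lmm.standardize(kept, scalable)
    for c in degenerate:
        record.divisors[c] = 1.0
        x = kept[c].to_numpy(dtype=float)
        record.ranges[c] = (float(x.min()), float(x.max())) if len(x) else (0.0, 0.0)
    # the active NCI column and a record keyed by the model's covariate names
    data["logNCI"] = data[f"logNCI_{nci_mode}"]
    data["logNCI_raw"] = data[f"logNCI_{nci_mode}_raw"]
    record.divisors["logNCI"] = record.divisors[f"logNCI_{nci_mode}"]
    record.ranges["logNCI"] = record.ranges[f"logNCI_{nci_mode}"]
    return FocalDataset(data=data, record=record, nci_mode=nci_mode, exclusions=report)


def enumerate_candidates() -> list[tuple[tuple[str, ...], ...]]:
    """Hierarchical candidate set for the fixed structure.

    Initial volume (logV) is always present; NCI, CND and NSR main effects
    vary; interaction terms require all their main effects, and the
    three-way term requires all three constituent two-way terms.
    """
    candidates = []
    others = ("logNCI", "CND", "NSR")
    for included in itertools.chain.from_iterable(
        itertools.combinations(others, k) for k in range(len(others) + 1)
    ):
        mains = ("logV",) + included
        main_set = set(mains)
        allowed_two = [t for t in INTERACTIONS[:3] if set(t) <= main_set]
        for k in range(len(allowed_two) + 1):
            for combo in itertools.combinations(allowed_two, k):
                terms = tuple((m,) for m in mains) + combo
                candidates.append(terms)
                if len(combo) == 3:  # all two-ways present -> three-way allowed
                    candidates.append(terms + (INTERACTIONS[3],))
    return candidates


def _contains(term: tuple, other: tuple) -> bool:
    return set(term) < set(other)


def usable_random(
    dataset: FocalDataset, random: tuple[RandomTerm, ...] = DEFAULT_RANDOM
) -> tuple[RandomTerm, ...]:
    """Drop random factors with fewer than two levels (untestable varcomp)."""
    kept = []
    for term in random:
        if dataset.data[term.factor].nunique() >= 2:
            kept.append(term)
        else:
            warnings.warn(
                f"random factor {term.factor!r} has a single level; dropped",
                RuntimeWarning,
            )
    return tuple(kept)


@dataclass
class SelectionResult:
    best_fit: ModelFit  # REML refit of the final fixed structure
    candidate_table: pd.DataFrame
    elimination: list[dict]
    random_slope_test: dict
    dataset: FocalDataset

    @property
    def terms(self) -> tuple:
        return self.best_fit.spec.fixed


def select_neighbourhood_model(
    dataset: FocalDataset,
    *,
    alpha: float = 0.05,
    random: tuple[RandomTerm, ...] = DEFAULT_RANDOM,
    response: str = "logG",
) -> SelectionResult:
    """Two-stage model selection for the neighbourhood growth model."""
    data = dataset.data
    random = usable_random(dataset, random)
    # -- stage 1 (REML, full fixed part): random structure.  The four crossed
    # intercepts are retained a priori; the species random slope on NSR is
    # tested by a REML likelihood-ratio test (slope variance + correlation,
    # 2 df) and kept only if significant.
    full_spec = ModelSpec(response, FULL_FIXED, random, "REML")
    reml_full = lmm.fit_lmm(data, full_spec)
    slope_random = tuple(
        RandomTerm(r.factor, "NSR") if r.factor == "species_id" else r for r in random
    )
    reml_slope = lmm.fit_lmm(
        data, ModelSpec(response, FULL_FIXED, slope_random, "REML")
    )
    chi2, df, p = lmm.lr_test(reml_full, reml_slope)
    random_slope_test = {"chi2": chi2, "df": df, "p": p, "kept": p < alpha}
    if random_slope_test["kept"]:
        random = slope_random

    # -- stage 2 (ML): AIC over the hierarchical candidate set, warm-started
    # from the full model's variance parameters.
    ml_full = lmm.fit_lmm(data, ModelSpec(response, FULL_FIXED, random, "ML"))
    theta0 = ml_full.theta
    fits: dict[tuple, ModelFit] = {FULL_FIXED: ml_full}
    labels = []
    fit_list = []
    for terms in enumerate_candidates():
        if terms not in fits:
            try:
                fits[terms] = lmm.fit_lmm(
                    data, ModelSpec(response, terms, random, "ML"),
                    theta0=theta0, n_starts=1,
                )
            except Exception as exc:  # non-convergence: record, exclude
                warnings.warn(f"candidate {terms} failed: {exc}", RuntimeWarning)
                continue
        label = " + ".join(lmm.term_label(t) for t in terms)
        labels.append(label)
        fit_list.append(fits[terms])
    table = lmm.akaike_compare(fit_list, labels)
    best_label = table.index[0]
    best_terms = next(
        t for t, f in fits.items()
        if " + ".join(lmm.term_label(x) for x in t) == best_label
    )

    # -- backward elimination by ML likelihood-ratio tests: drop the least
    # significant droppable term (largest p > alpha); a term is droppable
    # only if no retained higher-order term contains it.
    current = best_terms
    current_fit = fits[current]
    trace: list[dict] = []
    while True:
        droppable = [
            t for t in current if not any(_contains(t, o) for o in current if o != t)
        ]
        droppable = [t for t in droppable if t != ("logV",) or len(current) == 1]
        tests = []
        for t in droppable:
            reduced = tuple(x for x in current if x != t)
            if not reduced:
                continue
            key = tuple(sorted(reduced))
            red_fit = fits.get(reduced)
            if red_fit is None:
                red_fit = lmm.fit_lmm(
                    data, ModelSpec(response, reduced, random, "ML"),
                    theta0=theta0, n_starts=1,
                )
                fits[reduced] = red_fit
            chi2_t, df_t, p_t = lmm.lr_test(red_fit, current_fit)
            tests.append((p_t, chi2_t, df_t, t, reduced, red_fit))
        tests = [x for x in tests if x[0] > alpha]
        if not tests:
            break
        p_t, chi2_t, df_t, t, reduced, red_fit = max(tests, key=lambda x: x[0])
        trace.append(
            {"dropped": lmm.term_label(t), "chi2": chi2_t, "df": df_t, "p": p_t}
        )
        current, current_fit = reduced, red_fit

    best_reml = lmm.fit_lmm(
        data,
        ModelSpec(response, current, random, "REML"),
        theta0=current_fit.theta,
        standardization=dataset.record,
    )
    return SelectionResult(
        best_fit=best_reml,
        candidate_table=table,
        elimination=trace,
        random_slope_test=random_slope_test,
        dataset=dataset,
    )


def nci_mode_comparison(
    dataset: FocalDataset,
    terms: tuple = FULL_FIXED,
    *,
    random: tuple[RandomTerm, ...] = DEFAULT_RANDOM,
) -> dict:
    """Size-asymmetric vs size-symmetric competition (ML-AIC comparison).

    Positive ``delta_aic`` means the asymmetric index fits better.
    """
    data = dataset.data.copy()
    fits = {}
    for mode in ("asym", "sym"):
        data["logNCI"] = data[f"logNCI_{mode}"]
        fits[mode] = lmm.fit_lmm(data, ModelSpec("logG", terms, random, "ML"))
    delta = fits["sym"].aic - fits["asym"].aic
    w = np.exp(-0.5 * np.array([0.0, abs(delta)]))
    w /= w.sum()
    better = "asym" if delta >= 0 else "sym"
    return {
        "aic_asym": fits["asym"].aic,
        "aic_sym": fits["sym"].aic,
        "delta_aic": delta,
        "winner": better,
        "weight_winner": float(w[0]),
        "weight_loser": float(w[1]),
    }


def _baseline_cnd(dataset: FocalDataset, baseline: str) -> float:
    raw = dataset.data["CND_raw"]
    if baseline == "mean":
        return float(raw.mean())
    if baseline == "max":
        return float(raw.max())
    raise ValueError("cnd_baseline must be 'mean' or 'max'")


SIZE_QUANTILES = (0.20, 0.50, 0.80)
NCI_QUANTILES = (0.20, 0.50, 0.80)
NSR_LEVELS = tuple(range(8))


def ne_nbh(
    fit: ModelFit,
    dataset: FocalDataset,
    size_q: float,
    nci_q: float,
    nsr: int,
    *,
    cnd_baseline: str = "mean",
) -> float:
    """Net biodiversity effect (%) at one (size, competition, NSR) cell.

    Predicted growth with `nsr` heterospecific neighbour species relative to
    a conspecific neighbourhood (NSR = 0), with focal size and NCI fixed at
    empirical quantiles of their log10-transformed distributions and CND
    held at its baseline.
    """
    if not 0 <= nsr <= 7:
        raise ValueError("nsr must be in 0..7")
    data = dataset.data
    v = float(np.quantile(data["logV_raw"], size_q))
    c = float(np.quantile(data["logNCI_raw"], nci_q))
    cnd0 = _baseline_cnd(dataset, cnd_baseline)
    rows = pd.DataFrame(
        {
            "logV": [v, v],
            "logNCI": [c, c],
            "CND": [cnd0, cnd0],
            "NSR": [float(nsr), 0.0],
        }
    )
    g_h, g_c = lmm.predict_fixed(fit, dataset.record, rows)
    return float(100.0 * (g_h - g_c) / g_c)


def ne_nbh_surface(
    fit: ModelFit, dataset: FocalDataset, *, cnd_baseline: str = "mean"
) -> pd.DataFrame:
    """Full 3 x 3 x 8 NE_nbh grid (size x NCI quantiles x NSR 0..7)."""
    rows = []
    for sq, cq, nsr in itertools.product(SIZE_QUANTILES, NCI_QUANTILES, NSR_LEVELS):
        rows.append(
            {
                "size_q": sq,
                "nci_q": cq,
                "nsr": nsr,
                "ne_percent": ne_nbh(
                    fit, dataset, sq, cq, nsr, cnd_baseline=cnd_baseline
                ),
            }
        )
    return pd.DataFrame(rows)
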