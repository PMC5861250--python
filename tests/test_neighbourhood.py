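"""Focal dataset construction, candidate enumeration, and the net
biodiversity-effect surface."""

import numpy as np
import pandas as pd
import pytest

from treenbh.lmm import ModelFit, ModelSpec, StandardizationRecord, term_label
from treenbh.neighbourhood import (
    FULL_FIXED,
    build_focal_dataset,
    enumerate_candidates,
    nci_mode_comparison,
    ne_nbh,
    ne_nbh_surface,
)


class TestBuildFocalDataset:
    def test_empty_input_no_crash(self):
        ds = build_focal_dataset(pd.DataFrame(), pd.DataFrame())
        assert ds.n_focal == 0

    def test_focal_counts_and_columns(self, small_site, small_dataset):
        census, plots, design, _ = small_site
        ds = small_dataset
        n_plots = len(design.plots)
        assert 0 < ds.n_focal <= 16 * n_plots
        for col in (
            "logG", "logV", "logNCI", "logNCI_asym", "logNCI_sym", "CND", "NSR",
            "species_id", "composition_id", "density_id", "plot_id",
        ):
            assert col in ds.data.columns
        assert not ds.data[["logG", "logV", "logNCI", "CND", "NSR"]].isna().any().any()

    def test_predictors_standardized_not_centred(self, small_dataset):
        for col in ("logV", "logNCI", "CND", "NSR"):
            assert np.std(small_dataset.data[col], ddof=1) == pytest.approx(1.0)
        assert small_dataset.data["logV"].mean() > 0.5  # no centring

    def test_divisors_recorded(self, small_dataset):
        rec = small_dataset.record
        assert set(rec.divisors) >= {"logV", "logNCI", "CND", "NSR"}
        assert all(v > 0 for v in rec.divisors.values())

    def test_negative_growth_excluded(self, small_site, small_dataset):
        assert small_dataset.exclusions["n_excluded"] >= 0
        assert (small_dataset.data["G"] > 0).all()

    def test_invalid_nci_mode(self, small_site):
        census, plots, *_ = small_site
        with pytest.raises(ValueError):
            build_focal_dataset(census, plots, nci_mode="bogus")


class TestCandidateEnumeration:
    def test_candidate_count_and_uniqueness(self):
        cands = enumerate_candidates()
        assert len(cands) == len(set(cands)) == 28

    def test_hierarchy_respected(self):
        for terms in enumerate_candidates():
            term_set = set(terms)
            mains = {t[0] for t in terms if len(t) == 1}
            for t in terms:
                if len(t) > 1:
                    assert set(t) <= mains  # all main effects present
                if len(t) == 3:
                    for pair in [(t[0], t[1]), (t[0], t[2]), (t[1], t[2])]:
                        assert pair in term_set

    def test_logv_always_included(self):
        assert all(("logV",) in terms for terms in enumerate_candidates())


def _manual_fit(terms, beta, record=None):
    """Hand-constructed fit for analytic surface checks."""
    spec = ModelSpec("logG", terms, (), "REML")
    beta = np.asarray(beta, dtype=float)
    return ModelFit(
        spec=spec, fixed_names=spec.fixed_labels(), beta=beta,
        se=np.ones_like(beta), varcomps={}, resid_var=0.1, theta=np.empty(0),
        loglik=0.0, aic=0.0, n_obs=100, n_params=len(beta) + 1, converged=True,
        singular=False, var_fixed=1.0, ranef_var={}, standardization=record,
    )


class TestNeSurface:
    def test_baseline_is_exactly_zero(self, medium_selection):
        sel, ds, _ = medium_selection
        surface = ne_nbh_surface(sel.best_fit, ds)
        base = surface[surface["nsr"] == 0]
        assert len(base) == 9
        assert (base["ne_percent"] == 0.0).all()

    def test_surface_has_72_cells(self, medium_selection):
        sel, ds, _ = medium_selection
        surface = ne_nbh_surface(sel.best_fit, ds)
        assert len(surface) == 72
        assert surface.groupby(["size_q", "nci_q"]).size().eq(8).all()

    def test_surface_deterministic_through_serialization(self, medium_selection):
        sel, ds, _ = medium_selection
        s1 = ne_nbh_surface(sel.best_fit, ds)
        clone = ModelFit.from_json(sel.best_fit.to_json())
        s2 = ne_nbh_surface(clone, ds)
        pd.testing.assert_frame_equal(s1, s2)

    def test_nsr_out_of_range_rejected(self, medium_selection):
        sel, ds, _ = medium_selection
        with pytest.raises(ValueError):
            ne_nbh(sel.best_fit, ds, 0.5, 0.5, 8)

    def test_all_zero_betas_give_flat_surface(self, medium_selection):
        _, ds, _ = medium_selection
        fit = _manual_fit(FULL_FIXED, np.zeros(len(FULL_FIXED) + 1), ds.record)
        surface = ne_nbh_surface(fit, ds)
        assert np.allclose(surface["ne_percent"], 0.0)

    def test_pure_nsr_effect_uniform_and_increasing(self, medium_selection):
        """With only a positive NSR slope the effect is identical across
        size/NCI cells and strictly increasing in NSR, matching the
        closed-form 100*(10^(b*z) - 1)."""
        _, ds, _ = medium_selection
        terms = (("logV",), ("logNCI",), ("CND",), ("NSR",))
        b = 0.1
        fit = _manual_fit(terms, [2.0, 0.0, 0.0, 0.0, b], ds.record)
        surface = ne_nbh_surface(fit, ds)
        for nsr in range(8):
            vals = surface[surface["nsr"] == nsr]["ne_percent"]
            z = nsr / ds.record.divisors["NSR"]
            expected = 100.0 * (10.0 ** (b * z) - 1.0)
            assert np.allclose(vals, expected, atol=1e-9)
        means = surface.groupby("nsr")["ne_percent"].mean()
        assert means.is_monotonic_increasing

    def test_negative_nci_nsr_interaction_dampens_high_competition(
        self, medium_selection
    ):
        """A negative NCI x NSR interaction makes the biodiversity benefit
        smaller under high competition (sign analysis of the predictor)."""
        _, ds, _ = medium_selection
        terms = (("logV",), ("logNCI",), ("CND",), ("NSR",), ("logNCI", "NSR"))
        fit = _manual_fit(terms, [2.0, 0.0, 0.0, 0.0, 0.15, -0.08], ds.record)
        surface = ne_nbh_surface(fit, ds)
        small = surface[surface["size_q"] == 0.20]
        high = small[(small["nci_q"] == 0.80) & (small["nsr"] == 5)]["ne_percent"].item()
        low = small[(small["nci_q"] == 0.20) & (small["nsr"] == 5)]["ne_percent"].item()
        assert high < low

    def test_sign_matches_log_scale_contribution(self, medium_selection):
        """Percent change and the log-scale NSR contribution share their
        sign (monotone back-transform)."""
        sel, ds, _ = medium_selection
        fit = sel.best_fit
        for nsr in (1, 4, 7):
            ne = ne_nbh(fit, ds, 0.5, 0.5, nsr)
            eta = _eta_contribution(fit, ds, 0.5, 0.5, nsr)
            assert np.sign(np.round(ne, 10)) == np.sign(np.round(eta, 10))


def _eta_contribution(fit, ds, size_q, nci_q, nsr):
    from treenbh.lmm import predict_fixed

    v = float(np.quantile(ds.data["logV_raw"], size_q))
    c = float(np.quantile(ds.data["logNCI_raw"], nci_q))
    cnd = float(ds.data["CND_raw"].mean())
    rows = pd.DataFrame(
        {"logV": [v, v], "logNCI": [c, c], "CND": [cnd, cnd], "NSR": [float(nsr), 0.0]}
    )
    eta = predict_fixed(fit, ds.record, rows, back_transform=False)
    return eta[0] - eta[1]


class TestSelection:
    def test_selected_model_contains_size_and_nsr(self, medium_selection):
        sel, _, truth = medium_selection
        labels = [term_label(t) for t in sel.terms]
        assert "logV" in labels
        assert "NSR" in labels  # true NSR effect present in the generator
        assert sel.best_fit.method == "REML"

    def test_candidate_table_weights_sum_to_one(self, medium_selection):
        sel, *_ = medium_selection
        assert sel.candidate_table["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_random_slope_test_has_two_df(self, medium_selection):
        sel, *_ = medium_selection
        assert sel.random_slope_test["df"] == 2

    def test_elimination_never_drops_supported_main(self, medium_selection):
        sel, *_ = medium_selection
        labels = {term_label(t) for t in sel.terms}
        for t in sel.terms:
            if len(t) > 1:
                for name in t:
                    assert name in {x for x in labels if ":" not in x}


class TestNciModeComparison:
    def test_identical_columns_give_zero_delta(self, small_dataset):
        ds = small_dataset
        data = ds.data.copy()
        data["logNCI_sym"] = data["logNCI_asym"]
        ds2 = type(ds)(data=data, record=ds.record, nci_mode="asym")
        res = nci_mode_comparison(ds2, (("logV",), ("logNCI",), ("NSR",)))
        assert res["delta_aic"] == pytest.approx(0.0, abs=1e-4)

    def test_asym_truth_prefers_asym_index(self, small_dataset):
        res = nci_mode_comparison(small_dataset)
        assert res["winner"] == "asym"
        assert res["delta_aic"] > 0
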