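"""Summaries, worked percent comparisons, model selection and Moran's I."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoflux import (
    fit_bef_models,
    knn_weights,
    morans_i,
    percent_change,
    summarize_by_system,
)


def test_summarize_by_system_matches_group_means(default_study):
    out = summarize_by_system(
        default_study.site_totals, ["total_flux_kg_ha_yr", "biomass_kg_ha"]
    )
    g = default_study.site_totals.groupby("system")
    assert np.allclose(out["total_flux_kg_ha_yr_mean"], g["total_flux_kg_ha_yr"].mean())
    assert np.allclose(out["total_flux_kg_ha_yr_se"], g["total_flux_kg_ha_yr"].sem())
    assert (out["n"] == 8).all()


def test_summary_se_edge_cases():
    df = pd.DataFrame({"system": ["a", "b", "b"], "y": [1.0, 2.0, 2.0]})
    out = summarize_by_system(df, ["y"])
    assert np.isnan(out.loc["a", "y_se"])  # single site: s.e. undefined
    assert out.loc["b", "y_se"] == 0.0  # identical sites


def test_percent_change_modes_and_rounding():
    assert percent_change(0.424, 1.664, "ratio") == 25
    assert percent_change(30.697, 66.816, "ratio") == 46
    assert percent_change(0.767, 0.629, "ratio") == 122
    assert percent_change(32.531, 61.900, "loss") == 47
    assert percent_change(5.0, 5.0, "ratio") == 100
    assert percent_change(5.0, 5.0, "loss") == 0
    assert percent_change(0.125, 1.0, "ratio") == 13  # half-up at 12.5
    assert percent_change(0.125, 1.0, "loss") == 88  # half-up at 87.5
    with pytest.raises(ZeroDivisionError):
        percent_change(1.0, 0.0)
    with pytest.raises(ValueError):
        percent_change(1.0, 1.0, "delta")


@given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
@settings(max_examples=100, deadline=None)
def test_ratio_and_loss_sum_to_100(value, reference):
    total = percent_change(value, reference, "ratio") + percent_change(value, reference, "loss")
    assert abs(total - 100) <= 1  # exact up to opposing half-up rounding


def _simulated_sites(slopes, noise_sd, seed, n_rep=8):
    """Site table with a known richness->response structure."""
    rng = np.random.default_rng(seed)
    rows = []
    for system, slope in slopes.items():
        for landscape in ("L1", "L2"):
            for r in range(n_rep):
                richness = rng.integers(40, 220)
                y = slope * np.log10(richness) + rng.normal(0, noise_sd)
                rows.append(
                    {"system": system, "landscape": landscape, "S_obs": richness,
                     "response": y}
                )
    return pd.DataFrame(rows)


def test_zero_effect_selects_null_model():
    df = _simulated_sites(
        {"forest": 0.0, "jungle_rubber": 0.0, "rubber": 0.0, "oil_palm": 0.0},
        noise_sd=1.0, seed=2,
    )
    fit = fit_bef_models(df, response="response")
    assert fit.selected == "null"
    assert fit.slopes is None


def test_large_interaction_effect_selects_interaction_model():
    df = _simulated_sites(
        {"forest": 10.0, "jungle_rubber": 60.0, "rubber": 25.0, "oil_palm": 90.0},
        noise_sd=0.5, seed=3,
    )
    fit = fit_bef_models(df, response="response")
    assert fit.selected == "interaction"
    # recovered per-system slopes close to the generating ones
    for system, truth in {"forest": 10.0, "jungle_rubber": 60.0,
                          "rubber": 25.0, "oil_palm": 90.0}.items():
        assert fit.slopes[system] == pytest.approx(truth, rel=0.1)


def test_common_slope_selects_additive_or_simpler_not_interaction():
    df = _simulated_sites(
        {"forest": 50.0, "jungle_rubber": 50.0, "rubber": 50.0, "oil_palm": 50.0},
        noise_sd=0.5, seed=4,
    )
    fit = fit_bef_models(df, response="response")
    assert fit.selected in ("richness_only", "additive")
    assert fit.slopes["forest"] == pytest.approx(50.0, rel=0.05)


def test_selection_deterministic_given_data():
    df = _simulated_sites({"forest": 5.0, "jungle_rubber": 5.0, "rubber": 5.0,
                           "oil_palm": 5.0}, noise_sd=2.0, seed=5)
    a = fit_bef_models(df, response="response")
    b = fit_bef_models(df, response="response")
    assert a.selected == b.selected
    pd.testing.assert_frame_equal(a.aic_table, b.aic_table)


def test_alternative_response_families(default_study):
    st_tot = default_study.site_totals
    # overdispersed richness counts on a negative binomial GLM
    nb = fit_bef_models(st_tot, response="S_obs", richness_col="n_individuals",
                        family="negative_binomial")
    assert nb.selected in nb.aic_table.index
    assert np.isfinite(nb.aic_table["aic"]).all()
    # right-skewed biomass modelled on a log10 scale
    lg = fit_bef_models(st_tot, response="biomass_kg_ha", family="log10_gaussian")
    assert np.isfinite(lg.aic_table["aic"]).all()
    with pytest.raises(ValueError, match="unknown family"):
        fit_bef_models(st_tot, family="poisson")


def test_single_landscape_falls_back_with_warning():
    df = _simulated_sites({"forest": 5.0, "oil_palm": 5.0}, noise_sd=0.5, seed=6)
    df = df[df["landscape"] == "L1"]
    with pytest.warns(UserWarning, match="single landscape"):
        fit = fit_bef_models(df, response="response")
    assert not fit.mixed


# ---------------------------------------------------------------------------
# Moran's I


def chain_weights(n):
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return w / w.sum(axis=1, keepdims=True)


def test_alternating_residuals_on_chain_give_negative_I():
    resid = 5.0 + np.array([1.0, -1.0] * 5)
    out = morans_i(resid, weights=chain_weights(10))
    assert out.I < 0


def test_small_instance_matches_bruteforce_double_sum():
    rng = np.random.default_rng(7)
    z = rng.normal(size=4)
    w = np.array(
        [[0, 0.5, 0.5, 0], [0.3, 0, 0.3, 0.4], [0.5, 0.5, 0, 0], [0, 1.0, 0, 0]]
    )
    out = morans_i(z, weights=w)
    zc = z - z.mean()
    num = sum(w[i, j] * zc[i] * zc[j] for i in range(4) for j in range(4))
    brute = (4 / w.sum()) * num / (zc @ zc)
    assert out.I == pytest.approx(brute, rel=1e-12)
    assert out.expected == pytest.approx(-1 / 3)


def test_null_mean_approaches_expectation():
    rng = np.random.default_rng(8)
    n = 25
    coords = rng.uniform(0, 100, size=(n, 2))
    w = knn_weights(coords, k=4)
    vals = [morans_i(rng.normal(size=n), weights=w).I for _ in range(600)]
    assert np.mean(vals) == pytest.approx(-1 / (n - 1), abs=0.02)


def test_morans_invariances_and_errors():
    rng = np.random.default_rng(9)
    z = rng.normal(size=12)
    w = chain_weights(12)
    base = morans_i(z, weights=w)
    shifted = morans_i(z + 100.0, weights=w)
    scaled = morans_i(z * 3.5, weights=w)
    assert shifted.I == pytest.approx(base.I, rel=1e-12)
    assert scaled.I == pytest.approx(base.I, rel=1e-12)
    with pytest.raises(ValueError, match="identical"):
        morans_i(np.ones(5), weights=chain_weights(5))
    with pytest.raises(ValueError):
        morans_i(z[:2], weights=chain_weights(2))


def test_study_residuals_show_no_spatial_autocorrelation(default_study):
    st_tot = default_study.site_totals
    fit = fit_bef_models(st_tot)
    sel = fit.results[fit.selected]
    resid = st_tot["total_flux_kg_ha_yr"].to_numpy() - np.asarray(sel.fittedvalues)
    out = morans_i(resid, coords=st_tot[["x", "y"]].to_numpy())
    assert np.isfinite(out.pvalue)
    assert 0 <= out.pvalue <= 1
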