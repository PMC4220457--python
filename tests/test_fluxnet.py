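"""Diet matrices, the flux balance solver and unit conversions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoflux import (
    GUILDS,
    NODES,
    AssimilationTable,
    DietMatrix,
    FluxError,
    build_diet_matrix,
    effective_assimilation,
    mass_to_energy_flux,
    sensitivity_compare,
    solve_fluxes,
    to_mass_flux,
)


def fixed_point_fluxes(x, diet, e, n_iter=20_000):
    """Independent oracle: iterate F <- (X + L(F)) / e from F = X / e."""
    wcc = diet.consumer_block()
    xv = np.array([x[g] for g in GUILDS])
    ev = np.array([e[g] for g in GUILDS])
    f = xv / ev
    for _ in range(n_iter):
        loss = wcc @ f
        f_new = (xv + loss) / ev
        if np.allclose(f_new, f, rtol=1e-14, atol=0):
            break
        f = f_new
    return dict(zip(GUILDS, f))


def test_null_model_diet_columns():
    diet = build_diet_matrix("null_model")
    w = diet.W
    pred = w["predator"]
    assert pred[["omnivore", "detritivore", "herbivore"]].tolist() == pytest.approx([1 / 3] * 3)
    omn = w["omnivore"]
    assert omn[["predator", "detritivore", "herbivore"]].tolist() == [0.25, 0.25, 0.25]
    assert omn["plant"] == omn["detritus"] == 0.125
    assert w.loc["detritus", "detritivore"] == 1.0
    assert w.loc["plant", "herbivore"] == 1.0
    for c in GUILDS:
        assert w[c].sum() == pytest.approx(1.0, abs=1e-15)


def test_sensitivity_variant_omnivore_column():
    w = build_diet_matrix("no_animal_omnivory").W
    assert w.loc["plant", "omnivore"] == 0.5
    assert w.loc["detritus", "omnivore"] == 0.5
    assert w.loc[list(GUILDS), "omnivore"].sum() == 0.0
    # every other column identical to the null model
    null = build_diet_matrix("null_model").W
    for c in ("predator", "detritivore", "herbivore"):
        pd.testing.assert_series_equal(w[c], null[c])
    with pytest.raises(ValueError, match="unknown diet model"):
        build_diet_matrix("gut_content")


def test_effective_assimilation_weighted_mean():
    table = AssimilationTable(e_animal=0.9, e_plant=0.5, e_detritus=0.2)
    diet = build_diet_matrix("null_model")
    assert effective_assimilation("detritivore", diet, table) == 0.2
    assert effective_assimilation("herbivore", diet, table) == 0.5
    assert effective_assimilation("omnivore", diet, table) == pytest.approx(
        0.75 * 0.9 + 0.125 * 0.5 + 0.125 * 0.2
    )
    assert effective_assimilation("predator", diet, table) == pytest.approx(0.9)


def _diet_from(entries):
    w = pd.DataFrame(0.0, index=list(NODES), columns=list(NODES))
    for (r, c), v in entries.items():
        w.loc[r, c] = v
    return DietMatrix(w)


def test_single_node_and_chain_closed_forms():
    # lone detritivore: F = X when e = 1 and nothing eats it
    diet = _diet_from({
        ("detritus", "detritivore"): 1.0, ("plant", "herbivore"): 1.0,
        ("detritivore", "predator"): 1.0, ("plant", "omnivore"): 1.0,
    })
    e = {"predator": 1.0, "omnivore": 1.0, "detritivore": 1.0, "herbivore": 1.0}
    x = {"predator": 0.0, "omnivore": 0.0, "detritivore": 10.0, "herbivore": 0.0}
    net = solve_fluxes(x, diet, e_eff=e)
    assert net.F["detritivore"] == pytest.approx(10.0)

    # two-node chain: predator (e=1, X=2) on detritivore (e=0.5, X=10)
    e = {"predator": 1.0, "omnivore": 1.0, "detritivore": 0.5, "herbivore": 1.0}
    x = {"predator": 2.0, "omnivore": 0.0, "detritivore": 10.0, "herbivore": 0.0}
    net = solve_fluxes(x, diet, e_eff=e)
    assert net.F["predator"] == pytest.approx(2.0)
    assert net.L["detritivore"] == pytest.approx(2.0)
    assert net.F["detritivore"] == pytest.approx((10.0 + 2.0) / 0.5)


def test_predator_omnivore_cycle_closed_form():
    # predator eats only omnivore (weight 0.25 of omnivore's input comes back):
    # F_p = 1 + 0.25 F_o, F_o = 1 + F_p  ->  F_p = 5/3, F_o = 8/3
    diet = _diet_from({
        ("omnivore", "predator"): 1.0,
        ("predator", "omnivore"): 0.25, ("plant", "omnivore"): 0.75,
        ("detritus", "detritivore"): 1.0, ("plant", "herbivore"): 1.0,
    })
    e = {g: 1.0 for g in GUILDS}
    x = {"predator": 1.0, "omnivore": 1.0, "detritivore": 0.0, "herbivore": 0.0}
    net = solve_fluxes(x, diet, e_eff=e)
    assert net.F["predator"] == pytest.approx(5 / 3)
    assert net.F["omnivore"] == pytest.approx(8 / 3)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=60, deadline=None)
def test_solver_equals_fixed_point_oracle(seed):
    rng = np.random.default_rng(seed)
    diet = build_diet_matrix(rng.choice(["null_model", "no_animal_omnivory"]))
    x = {g: float(rng.uniform(0, 50)) for g in GUILDS}
    table = AssimilationTable(
        e_animal=float(rng.uniform(0.7, 1.0)),
        e_plant=float(rng.uniform(0.3, 0.7)),
        e_detritus=float(rng.uniform(0.1, 0.3)),
    )
    net = solve_fluxes(x, diet, table)
    oracle = fixed_point_fluxes(x, diet, {g: net.e_eff[g] for g in GUILDS})
    for g in GUILDS:
        assert net.F[g] == pytest.approx(oracle[g], rel=1e-9)
    # balance holds at every node
    assert np.all(np.abs(net.balance_residual().to_numpy()) <= 1e-9 * np.maximum(net.X + net.L, 1.0))


def test_monotonicity_in_demand_and_efficiency():
    diet = build_diet_matrix("null_model")
    table = AssimilationTable()
    x = {"predator": 5.0, "omnivore": 4.0, "detritivore": 10.0, "herbivore": 3.0}
    base = solve_fluxes(x, diet, table)
    bumped = solve_fluxes({**x, "omnivore": 6.0}, diet, table)
    assert np.all(bumped.F.to_numpy() >= base.F.to_numpy() - 1e-12)
    # lowering one node's efficiency raises that node's flux
    e = {g: base.e_eff[g] for g in GUILDS}
    lowered = solve_fluxes(x, diet, e_eff={**e, "detritivore": e["detritivore"] / 2})
    assert lowered.F["detritivore"] > base.F["detritivore"]


def test_acyclic_case_equals_topdown_substitution():
    """With the omnivore's animal diet zeroed the network is acyclic and the
    solution matches explicit top-down substitution."""
    diet = build_diet_matrix("no_animal_omnivory")
    table = AssimilationTable(e_animal=0.9, e_plant=0.5, e_detritus=0.2)
    x = {"predator": 2.0, "omnivore": 3.0, "detritivore": 8.0, "herbivore": 1.5}
    net = solve_fluxes(x, diet, table)
    f_pred = x["predator"] / 0.9
    e_omn = 0.5 * 0.5 + 0.5 * 0.2
    f_omn = (x["omnivore"] + f_pred / 3) / e_omn
    f_det = (x["detritivore"] + f_pred / 3) / 0.2
    f_herb = (x["herbivore"] + f_pred / 3) / 0.5
    assert net.F["predator"] == pytest.approx(f_pred)
    assert net.F["omnivore"] == pytest.approx(f_omn)
    assert net.F["detritivore"] == pytest.approx(f_det)
    assert net.F["herbivore"] == pytest.approx(f_herb)


def test_infeasible_system_raises_named_error():
    diet = _diet_from({
        ("omnivore", "predator"): 1.0, ("predator", "omnivore"): 1.0,
        ("detritus", "detritivore"): 1.0, ("plant", "herbivore"): 1.0,
    })
    # pure predator<->omnivore loop with e=1: singular (diag(e) - Wcc loses rank)
    x = {"predator": 1.0, "omnivore": 1.0, "detritivore": 0.0, "herbivore": 0.0}
    with pytest.raises(FluxError):
        solve_fluxes(x, diet, e_eff={g: 1.0 for g in GUILDS})


def test_mass_flux_conversion_and_round_trip():
    assert to_mass_flux(0.0) == 0.0
    assert to_mass_flux(1.0, energy_per_gram=7000.0) == pytest.approx(8760e4 / 7e6)
    f = 3.7
    assert mass_to_energy_flux(to_mass_flux(f)) == pytest.approx(f, rel=1e-12)
    with pytest.raises(ValueError):
        to_mass_flux(1.0, energy_per_gram=0.0)


def test_sensitivity_compare_identities():
    base = pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(8)],
            "system": ["forest"] * 2 + ["rubber"] * 3 + ["oil_palm"] * 3,
            "total_flux_kg_ha_yr": [10.0, 12.0, 6.0, 7.0, 8.0, 4.0, 5.0, 6.0],
        }
    )
    same = sensitivity_compare(base, base.copy())
    assert (same["disparity"] == 0).all()
    # global rescaling leaves relative losses unchanged
    scaled = base.assign(total_flux_kg_ha_yr=base["total_flux_kg_ha_yr"] * 3.7)
    comp = sensitivity_compare(base, scaled)
    assert np.allclose(comp["disparity"], 0.0, atol=1e-12)
    with pytest.raises(ValueError, match="reference system"):
        sensitivity_compare(base[base.system != "forest"], base)


def test_sensitivity_matches_bruteforce_on_study(default_study, alt_study):
    comp = sensitivity_compare(default_study.site_totals, alt_study.site_totals)
    null_m = default_study.site_totals.groupby("system")["total_flux_kg_ha_yr"].mean()
    alt_m = alt_study.site_totals.groupby("system")["total_flux_kg_ha_yr"].mean()
    for s in comp.index:
        ln = 1 - null_m[s] / null_m["forest"]
        la = 1 - alt_m[s] / alt_m["forest"]
        assert comp.loc[s, "disparity"] == pytest.approx(abs(ln - la), rel=1e-12)
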