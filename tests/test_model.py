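"""Rate-law and stoichiometry checks for the core reaction network.

The oracle below re-codes every printed rate law independently of the
package (plain Python expressions on intensive values) and compares the
package's flux vector against it at random states.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ironblock import Model, default_config
from ironblock.model import (IDX, IRON_ATOMS, REACTIONS, RIDX, SPECIES,
                             STOICHIOMETRY)
from conftest import random_states


def oracle_fluxes(model, amounts):
    """Independent direct evaluation of the 19 printed rate laws."""
    p = model.config.rates
    sz = model.sizes
    x = {s: max(amounts[IDX[s]], 0.0) / model.species_size[IDX[s]]
         for s in SPECIES}
    lip, dfp, core, ft = x["LIP"], x["DFP"], x["core"], x["FT"]
    out = {}

    q = p["dmt1_endocytosis_free"]
    out["dmt1_endocytosis_free"] = q["k_cat"] * x["DMT1_active"]
    q = p["dmt1_endocytosis_lip"]
    out["dmt1_endocytosis_lip"] = (
        q["k_cat"] * x["DMT1_active"]
        * lip ** q["n"] / (q["K_m"] ** q["n"] + lip ** q["n"]))
    out["dmt1_fusion"] = p["dmt1_fusion"]["k_cat"] * x["DMT1_cytoplasm"]
    q = p["dmt1_iron_transport"]
    out["dmt1_iron_transport"] = (q["k_cat"] * x["DMT1_active"]
                                  * x["Fe_lumen"] / (q["K_m"] + x["Fe_lumen"]))

    q = p["oxidation"]
    out["oxidation"] = (q["k_cat"] * (q["H"] + q["rO"]) / (24 + q["rO"]) * ft
                        * lip ** q["n"] / (q["K_m"] ** q["n"] + lip ** q["n"]))
    out["reduction"] = p["reduction"]["k_deg"] * dfp
    q = p["nucleation"]
    out["nucleation"] = (q["k_cat"] * dfp ** 2 * ft
                         * (q["L"] + q["rN"]) / (24 + q["rN"])
                         * q["K_i"] ** q["n"] / (q["K_i"] ** q["n"] + core ** q["n"]))
    q = p["mineralization"]
    apc = min(core / ft, q["capacity"]) if ft > 0 else 0.0
    out["mineralization"] = (
        q["k_cat"] * core * dfp / (q["K_m"] + dfp)
        * q["K_i"] ** q["n"] / (q["K_i"] ** q["n"] + core ** q["n"])
        * (q["capacity"] ** q["m"] - apc ** q["m"]) / q["capacity"] ** q["m"])
    out["ft_core_release"] = p["ft_core_release"]["k_deg"] * core
    out["ft_degradation"] = p["ft_degradation"]["k_deg"] * ft

    q = p["fpn_inactivation"]
    feb = x["Fe_blood"]
    out["fpn_inactivation"] = (
        q["k_cat"] * x["FPN_active"]
        * feb ** q["n"] / (q["K_m"] ** q["n"] + feb ** q["n"]))
    out["fpn_activation"] = p["fpn_activation"]["k_cat"] * x["FPN_inactive"]
    q = p["fpn_iron_transport"]
    out["fpn_iron_transport"] = (q["k_cat"] * x["FPN_active"]
                                 * lip / (q["K_m"] + lip))

    out["irps_inactivation"] = (p["irps_inactivation"]["k_cat"]
                                * x["IRPs_active"] * lip)
    out["irps_activation"] = (p["irps_activation"]["k_cat"]
                              * x["IRPs_inactive"])
    q = p["ft_expression"]
    ia = x["IRPs_active"]
    out["ft_expression"] = q["k_cat"] * (
        1.0 - ia ** q["n"] / (q["K_m"] ** q["n"] + ia ** q["n"]))

    out["body_sequestration"] = (p["body_sequestration"]["k_cat"]
                                 * x["Fe_blood"])
    out["basal_uptake"] = p["basal_uptake"]["k_cat"] * x["Fe_blood"]
    q = p["paracellular"]
    out["paracellular"] = (q["k_for"] * x["Fe_lumen"] * sz["lumen"]
                           - q["k_rev"] * x["Fe_blood"] * sz["blood"])

    scale = {
        "dmt1_endocytosis_free": sz["apical_membrane"],
        "dmt1_endocytosis_lip": sz["apical_membrane"],
        "dmt1_fusion": sz["cytoplasm"],
        "dmt1_iron_transport": sz["apical_membrane"],
        "oxidation": sz["cytoplasm"], "reduction": sz["cytoplasm"],
        "nucleation": sz["cytoplasm"], "mineralization": sz["cytoplasm"],
        "ft_core_release": sz["cytoplasm"], "ft_degradation": sz["cytoplasm"],
        "fpn_inactivation": sz["basal_membrane"],
        "fpn_activation": sz["cytoplasm"],
        "fpn_iron_transport": sz["basal_membrane"],
        "irps_inactivation": sz["cytoplasm"], "irps_activation": sz["cytoplasm"],
        "ft_expression": sz["cytoplasm"],
        "body_sequestration": sz["blood"], "basal_uptake": sz["blood"],
        "paracellular": 1.0,
    }
    return np.array([out[r] * scale[r] for r in REACTIONS])


def test_fluxes_match_independent_oracle(model):
    """Each of the 19 fluxes equals a direct evaluation of its printed
    formula at 120 random states (relative error < 1e-12)."""
    for x in random_states(model, 120, seed=42):
        v = model.fluxes(x)
        w = oracle_fluxes(model, x)
        denom = np.maximum(np.abs(w), 1e-300)
        assert np.all(np.abs(v - w) / denom < 1e-12)


def _state_with(model, **intensive):
    x = model.initial_amounts()
    for s, val in intensive.items():
        x[IDX[s]] = val * model.species_size[IDX[s]]
    return x


@pytest.mark.parametrize("species,zeroed_reactions", [
    ("Fe_lumen", ["dmt1_iron_transport"]),
    ("LIP", ["oxidation", "fpn_iron_transport", "irps_inactivation"]),
    ("DFP", ["reduction", "nucleation", "mineralization"]),
    ("Fe_blood", ["fpn_inactivation", "body_sequestration", "basal_uptake"]),
])
def test_zero_substrate_gives_zero_flux(model, species, zeroed_reactions):
    x = _state_with(model, **{species: 0.0})
    v = model.fluxes(x)
    for r in zeroed_reactions:
        assert v[RIDX[r]] == 0.0


def test_transport_at_half_saturation(model):
    """Fe_lumen = K_m gives half the maximal DMT1 transport rate."""
    km = model.config.get_rate("dmt1_iron_transport.K_m")
    kcat = model.config.get_rate("dmt1_iron_transport.k_cat")
    x = _state_with(model, Fe_lumen=km)
    d_act = x[IDX["DMT1_active"]] / model.species_size[IDX["DMT1_active"]]
    expected = 0.5 * kcat * d_act * model.sizes["apical_membrane"]
    assert model.fluxes(x)[RIDX["dmt1_iron_transport"]] == pytest.approx(expected)


def test_fpn_export_at_half_saturation(model):
    """LIP = K_m (2.31 uM) gives export rate k_cat x [FPN_active] / 2."""
    km = model.config.get_rate("fpn_iron_transport.K_m")
    assert km == pytest.approx(2.31e-6)
    x = _state_with(model, LIP=km)
    f_act = x[IDX["FPN_active"]] / model.species_size[IDX["FPN_active"]]
    expected = 0.5 * 1.88 * f_act * model.sizes["basal_membrane"]
    assert model.fluxes(x)[RIDX["fpn_iron_transport"]] == pytest.approx(expected)


def test_ft_expression_repression_limits(model):
    """IRPs_active = 0 -> full rate; = K_m -> half; large -> repressed."""
    kcat = model.config.get_rate("ft_expression.k_cat")
    km = model.config.get_rate("ft_expression.K_m")
    v_cyt = model.sizes["cytoplasm"]
    r = RIDX["ft_expression"]
    assert model.fluxes(_state_with(model, IRPs_active=0.0))[r] == \
        pytest.approx(kcat * v_cyt)
    assert model.fluxes(_state_with(model, IRPs_active=km))[r] == \
        pytest.approx(0.5 * kcat * v_cyt)
    high = model.fluxes(_state_with(model, IRPs_active=1e6 * km))[r]
    assert high < 1e-5 * kcat * v_cyt


def test_core_release_is_kdeg_times_core_for_any_ft(model):
    """k_deg (core/FT) FT reduces to k_deg core, including at FT = 0."""
    kdeg = model.config.get_rate("ft_core_release.k_deg")
    core = 0.368e-6
    for ft in (2.38e-9, 1e-15, 0.0):
        x = _state_with(model, core=core, FT=ft)
        expected = kdeg * core * model.sizes["cytoplasm"]
        assert model.fluxes(x)[RIDX["ft_core_release"]] == pytest.approx(expected)


def test_mineralization_vanishes_at_capacity(model):
    """A full ferritin cage (apc = 4300) admits no further mineralization."""
    ft = 2.38e-9
    x = _state_with(model, FT=ft, core=4300 * ft, DFP=1e-9)
    assert model.fluxes(x)[RIDX["mineralization"]] == pytest.approx(0.0, abs=1e-40)


def test_apc_clipped_and_zero_without_ft(model):
    x = _state_with(model, FT=2e-9, core=5e-5)   # would exceed capacity
    assert model.atoms_per_core(x) == 4300
    x = _state_with(model, FT=0.0, core=1e-6)
    assert model.atoms_per_core(x) == 0.0


def test_paracellular_equilibrium(model):
    """k_for Fe_lumen V_lum = k_rev Fe_blood V_blood -> zero net flux."""
    kf = model.config.get_rate("paracellular.k_for")
    kr = model.config.get_rate("paracellular.k_rev")
    fe_lum = 1e-6
    fe_blood = (kf * fe_lum * model.sizes["lumen"]
                / (kr * model.sizes["blood"]))
    x = _state_with(model, Fe_lumen=fe_lum, Fe_blood=fe_blood)
    assert model.fluxes(x)[RIDX["paracellular"]] == pytest.approx(0.0, abs=1e-40)


def test_moiety_columns_conserve_transporters():
    """No reaction changes the total DMT1, FPN or IRPs amounts."""
    for group in (("DMT1_active", "DMT1_cytoplasm"),
                  ("FPN_active", "FPN_inactive"),
                  ("IRPs_active", "IRPs_inactive")):
        rows = STOICHIOMETRY[[IDX[s] for s in group], :]
        assert np.all(rows.sum(axis=0) == 0)


def test_ft_is_not_conserved():
    row = STOICHIOMETRY[IDX["FT"], :]
    assert row[RIDX["ft_expression"]] == 1
    assert row[RIDX["ft_degradation"]] == -1


def test_rhs_conserves_iron_at_random_states(model):
    """d(total iron)/dt = 0 at any state of the closed system (DFP counted
    as two atoms), because every iron reaction only moves or repackages
    atoms."""
    w = np.array([IRON_ATOMS[s] for s in SPECIES], dtype=float)
    for x in random_states(model, 50, seed=7):
        dx = model.rhs(0.0, x)
        total_rate = float(w @ dx)
        scale = float(np.abs(model.fluxes(x)).max())
        assert abs(total_rate) <= 1e-10 * max(scale, 1e-300)


def test_rhs_zero_iron_stays_zero(model):
    x = model.initial_amounts()
    for s in SPECIES:
        if IRON_ATOMS[s]:
            x[IDX[s]] = 0.0
    dx = model.rhs(0.0, x)
    for s in SPECIES:
        if IRON_ATOMS[s]:
            assert dx[IDX[s]] == 0.0


def test_clamped_species_have_zero_derivative(model):
    mask = np.zeros(len(SPECIES), dtype=bool)
    mask[IDX["Fe_lumen"]] = mask[IDX["FT"]] = True
    dx = model.rhs(0.0, model.initial_amounts(), mask)
    assert dx[IDX["Fe_lumen"]] == 0.0 and dx[IDX["FT"]] == 0.0


def test_non_finite_flux_reports_reaction(model):
    x = model.initial_amounts()
    x[IDX["LIP"]] = np.inf
    with pytest.raises(Exception, match="irps_inactivation"):
        model.rhs(0.0, x)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_fluxes_nonnegative_and_finite_property(seed):
    """All unidirectional fluxes are non-negative and finite at random
    states (paracellular is the single signed net flux)."""
    model = Model(default_config())
    x = next(iter(random_states(model, 1, seed=seed)))
    v = model.fluxes(x)
    assert np.all(np.isfinite(v))
    signed = RIDX["paracellular"]
    assert np.all(np.delete(v, signed) >= 0.0)
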