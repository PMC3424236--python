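"""Solver correctness against closed forms, brute force, and conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from siderocalc.chem import Condition, ModelError, load_model
from siderocalc.equilibrium import (
    predominant_species,
    solve_equilibrium,
    speciation_diagram,
)

from conftest import quadratic_bound


def _species_conc_from_free(model, state, ph=None):
    """Recompute species concentrations directly from the returned free
    concentrations and the declared constants (independent of solver internals)."""
    out = {}
    for sp in model.species:
        logc = sp.log_beta
        for name, nu in sp.stoich.items():
            free = state.free[name]
            if free == 0.0:
                logc = -np.inf
                break
            logc += nu * np.log10(free)
        out[sp.label] = 0.0 if logc == -np.inf else 10.0 ** logc
    return out


def _check_mass_balance(model, state, condition, tol=1e-9):
    conc = _species_conc_from_free(model, state)
    proton = model.proton
    for comp in model.components:
        if condition.ph is not None and proton and comp.name == proton.name:
            continue
        total = condition.totals.get(comp.name, 0.0)
        lhs = state.free[comp.name] + sum(
            sp.stoich.get(comp.name, 0) * conc[sp.label] for sp in model.species
        )
        if proton and comp.name == proton.name:
            lhs -= 10.0 ** model.kw / max(state.free[comp.name], 1e-300)
        scale = max(total, state.free[comp.name] + sum(
            abs(sp.stoich.get(comp.name, 0)) * conc[sp.label] for sp in model.species
        ), 1e-30)
        assert abs(lhs - total) / scale <= 5 * tol, comp.name


def test_identity_no_species():
    m = load_model({"components": [{"name": "Fe", "role": "metal"}], "species": []})
    st_ = solve_equilibrium(m, Condition({"Fe": 1e-6}))
    assert st_.converged
    assert st_.free["Fe"] == pytest.approx(1e-6, rel=1e-9)


def test_one_to_one_binding_matches_quadratic():
    """[PL] equals the closed-form root of the 1:1 quadratic binding equation."""
    m = load_model(
        {
            "components": [{"name": "P", "role": "protein"}, {"name": "L", "role": "ligand"}],
            "species": [{"label": "PL", "stoich": {"P": 1, "L": 1}, "log_beta": 6.0,
                         "provenance": "test"}],
        }
    )
    st_ = solve_equilibrium(m, Condition({"P": 1e-6, "L": 1e-6}))
    expected = quadratic_bound(1e-6, 1e-6, 1e6)
    assert expected == pytest.approx(0.382e-6, abs=5e-10)  # frozen oracle value
    assert st_.converged
    assert st_.species_conc["PL"] == pytest.approx(expected, rel=1e-9)


def test_diprotic_acid_matches_henderson_hasselbalch():
    """Fixed-pH speciation of a diprotic acid equals the closed-form fractions."""
    b1, b2 = 9.5, 13.2
    m = load_model(
        {
            "components": [{"name": "L", "role": "ligand"}, {"name": "H", "role": "proton"}],
            "species": [
                {"label": "LH", "stoich": {"L": 1, "H": 1}, "log_beta": b1, "provenance": "t"},
                {"label": "LH2", "stoich": {"L": 1, "H": 2}, "log_beta": b2, "provenance": "t"},
            ],
        }
    )
    for ph in (3.0, 7.2, 9.5, 12.0):
        st_ = solve_equilibrium(m, Condition({"L": 1e-4}, ph=ph))
        assert st_.converged
        h = 10.0 ** -ph
        denom = 1 + 10.0 ** b1 * h + 10.0 ** b2 * h * h
        assert st_.free["L"] == pytest.approx(1e-4 / denom, rel=1e-9)
        assert st_.species_conc["LH"] == pytest.approx(1e-4 * 10 ** b1 * h / denom, rel=1e-9)
        assert st_.species_conc["LH2"] == pytest.approx(1e-4 * 10 ** b2 * h * h / denom, rel=1e-9)


def test_two_component_system_matches_grid_search():
    """Solver agrees with an exhaustive log-spaced grid search over free space."""
    m = load_model(
        {
            "components": [{"name": "Fe", "role": "metal"}, {"name": "L", "role": "ligand"}],
            "species": [
                {"label": "FeL", "stoich": {"Fe": 1, "L": 1}, "log_beta": 6.2, "provenance": "t"},
                {"label": "FeL2", "stoich": {"Fe": 1, "L": 2}, "log_beta": 11.0, "provenance": "t"},
            ],
        }
    )
    totals = {"Fe": 2e-5, "L": 6e-5}
    st_ = solve_equilibrium(m, Condition(totals))
    assert st_.converged

    # brute-force oracle: nested refinement of a log-spaced grid minimising the
    # worst relative mass-balance residual
    lo = np.array([-12.0, -12.0])
    hi = np.array([-3.0, -3.0])
    best = None
    for _ in range(6):
        g0 = np.linspace(lo[0], hi[0], 60)
        g1 = np.linspace(lo[1], hi[1], 60)
        fe, l = np.meshgrid(10.0 ** g0, 10.0 ** g1, indexing="ij")
        fel = 10.0 ** 6.2 * fe * l
        fel2 = 10.0 ** 11.0 * fe * l * l
        r0 = np.abs(fe + fel + fel2 - totals["Fe"]) / totals["Fe"]
        r1 = np.abs(l + fel + 2 * fel2 - totals["L"]) / totals["L"]
        resid = np.maximum(r0, r1)
        i, j = np.unravel_index(np.argmin(resid), resid.shape)
        best = (g0[i], g1[j])
        span0 = (hi[0] - lo[0]) / 59
        span1 = (hi[1] - lo[1]) / 59
        lo = np.array([best[0] - 2 * span0, best[1] - 2 * span1])
        hi = np.array([best[0] + 2 * span0, best[1] + 2 * span1])
    grid_fe, grid_l = 10.0 ** best[0], 10.0 ** best[1]
    assert st_.free["Fe"] == pytest.approx(grid_fe, rel=1e-4)
    assert st_.free["L"] == pytest.approx(grid_l, rel=1e-4)


def test_negative_totals_raise_not_flag():
    with pytest.raises(ModelError):
        Condition({"Fe": -1.0})


def test_warm_start_equals_cold_start(dhba_model):
    """Warm-started pH-grid solve equals cold-start solve point by point."""
    totals = {"Fe": 20e-6, "L": 60e-6}
    table = speciation_diagram(dhba_model, totals, (3.0, 9.0), 31)
    assert table.ok.all()
    for k, ph in enumerate(table.ph_grid):
        cold = solve_equilibrium(dhba_model, Condition(totals, ph=float(ph)))
        assert cold.converged
        for lab in table.fractions.index:
            warm_frac = float(table.fractions.iloc[list(table.fractions.index).index(lab), k])
            if lab == "Fe":
                cold_frac = cold.free["Fe"] / totals["Fe"]
            else:
                sp = dhba_model.species_by_label(lab)
                cold_frac = sp.stoich["Fe"] * cold.species_conc[lab] / totals["Fe"]
            assert warm_frac == pytest.approx(cold_frac, rel=1e-6, abs=1e-12)


def test_speciation_columns_sum_to_one(dhba_model):
    table = speciation_diagram(dhba_model, {"Fe": 20e-6, "L": 60e-6}, (2, 10), 41)
    sums = table.fractions.sum(axis=0).to_numpy()
    assert np.all(np.abs(sums[table.ok] - 1.0) <= 1e-6)
    vals = table.fractions.to_numpy()
    assert np.nanmin(vals) >= -1e-12 and np.nanmax(vals) <= 1 + 1e-9


def test_hydrolysis_only_free_fraction_at_low_ph():
    """As pH -> 0 hydrolysis is suppressed and free Fe3+ fraction -> 1."""
    m = load_model(
        {
            "components": [{"name": "Fe", "role": "metal"}, {"name": "H", "role": "proton"}],
            "species": [
                {"label": "FeOH", "stoich": {"Fe": 1, "H": -1}, "log_beta": -2.19, "provenance": "t"},
                {"label": "FeOH2", "stoich": {"Fe": 1, "H": -2}, "log_beta": -5.67, "provenance": "t"},
            ],
        }
    )
    table = speciation_diagram(m, {"Fe": 1e-6}, (0.5, 6.0), 12)
    frac_free = table.fractions.loc["Fe"].to_numpy()
    assert frac_free[0] > 0.97
    assert np.all(np.diff(frac_free) <= 1e-9)  # free fraction falls as pH rises


def test_monotone_complexation_in_ligand_total(dhba_model):
    """At fixed pH, total complexed metal fraction is non-decreasing in ligand total."""
    fracs = []
    for lt in np.linspace(0.0, 120e-6, 9):
        st_ = solve_equilibrium(dhba_model, Condition({"Fe": 20e-6, "L": lt}, ph=5.5))
        assert st_.converged
        bound = sum(
            sp.stoich.get("Fe", 0) * st_.species_conc[sp.label]
            for sp in dhba_model.species
            if sp.stoich.get("Fe", 0) > 0 and sp.stoich.get("L", 0) > 0
        )
        fracs.append(bound / 20e-6)
    assert np.all(np.diff(fracs) >= -1e-9)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    logb1=st.floats(min_value=2, max_value=12),
    logb2=st.floats(min_value=4, max_value=18),
    t_m=st.floats(min_value=1e-8, max_value=1e-3),
    t_l=st.floats(min_value=1e-8, max_value=1e-3),
)
def test_mass_conservation_property(logb1, logb2, t_m, t_l):
    """Mass balance holds at every converged state of randomised 2-component models."""
    m = load_model(
        {
            "components": [{"name": "M", "role": "metal"}, {"name": "L", "role": "ligand"}],
            "species": [
                {"label": "ML", "stoich": {"M": 1, "L": 1}, "log_beta": logb1, "provenance": "p"},
                {"label": "ML2", "stoich": {"M": 1, "L": 2}, "log_beta": logb2, "provenance": "p"},
            ],
        }
    )
    cond = Condition({"M": t_m, "L": t_l})
    st_ = solve_equilibrium(m, cond)
    assert st_.converged
    _check_mass_balance(m, st_, cond)


def test_predominant_species_basic(dhba_model):
    table = speciation_diagram(dhba_model, {"Fe": 20e-6, "L": 60e-6}, (2, 10), 81)
    labs = predominant_species(table, 7.2, threshold=0.1)
    assert "FeL" in labs
    # descending order of fraction
    at = table.fractions_at(7.2)
    fr = [at[l] for l in labs]
    assert fr == sorted(fr, reverse=True)


def test_predominant_species_single_dominant(minimal_pl_model):
    table = speciation_diagram(
        minimal_pl_model, {"P": 1e-6, "L": 1e-3}, (4, 8), 5, reference_component="P"
    )
    labs = predominant_species(table, 7.2, threshold=0.1)
    assert labs == ["PL"]  # one species holds ~all the protein


def test_predominant_species_empty_table_errors(dhba_model):
    table = speciation_diagram(dhba_model, {"Fe": 20e-6, "L": 60e-6}, (2, 10), 5)
    table.fractions = table.fractions.iloc[0:0]
    with pytest.raises(ModelError):
        predominant_species(table, 7.2)


def test_nonconvergence_is_flagged_not_raised():
    """A hopeless iteration budget yields a flagged state, not an exception."""
    m = load_model(
        {
            "components": [{"name": "Fe", "role": "metal"}, {"name": "L", "role": "ligand"}],
            "species": [
                {"label": "FeL", "stoich": {"Fe": 1, "L": 1}, "log_beta": 25.0, "provenance": "t"},
            ],
        }
    )
    st_ = solve_equilibrium(m, Condition({"Fe": 1e-4, "L": 1e-4}), max_iter=1)
    assert isinstance(st_.converged, bool)
    if not st_.converged:
        assert any(abs(v) > 0 for v in st_.residuals.values())
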