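"""Quench forward model, K_D refinement, model selection and dilution correction."""

import numpy as np
import pytest

from siderocalc.chem import ModelError, add_protein_binding, load_model, packaged_model
from siderocalc.synthetic import GeneratorSpec, default_schedule, generate_titration, scenario_spec
from siderocalc.titration import (
    QuenchModel,
    TitrationDataset,
    TitrationPoint,
    apply_dilution_correction,
    estimate_noise,
    fit_kd,
    read_titration_csv,
    select_species_model,
    simulate_quench,
    write_titration_csv,
)

from conftest import quadratic_bound

PL = ("PL", {"P": 1, "L": 1})
PL2 = ("PL2", {"P": 1, "L": 2})
PL3 = ("PL3", {"P": 1, "L": 3})


def _quench(candidates=(PL,), coeffs=None):
    return QuenchModel(
        fluorescent_coeffs=dict(coeffs or {}),
        candidate_bound_species=list(candidates),
    )


def test_zero_ligand_is_exactly_one(bare_plh_model):
    f = simulate_quench(
        bare_plh_model, _quench(), [(0.0, 1e-7, 7.2), (0.0, 1e-6, 7.2)], log_k_assoc=[8.0]
    )
    assert np.allclose(f, 1.0)


def test_no_binding_means_no_quench(bare_plh_model):
    """A vanishing association constant leaves fluorescence flat at 1."""
    sched = default_schedule()
    f = simulate_quench(bare_plh_model, _quench(), sched, log_k_assoc=[-5.0])
    assert np.allclose(f, 1.0, atol=1e-6)


def test_quench_matches_quadratic_oracle(bare_plh_model):
    """1:1 quench curves equal 1 - [PL]/P_T from the closed-form quadratic."""
    log_k = 7.0
    pt = 1e-6
    sched = [(lt, pt, 7.2) for lt in (0.0, 2e-7, 5e-7, 1e-6, 2e-6, 1e-5)]
    f = simulate_quench(bare_plh_model, _quench(), sched, log_k_assoc=[log_k])
    for (lt, _, _), fi in zip(sched, f):
        bound = quadratic_bound(pt, lt, 10.0 ** log_k) if lt > 0 else 0.0
        assert fi == pytest.approx(1.0 - bound / pt, abs=1e-7)


def test_stoichiometric_titration_limit(bare_plh_model):
    """At K*P_T >> 1 and coeff 0, quench is piecewise linear with its breakpoint
    at ligand_total = protein_total."""
    pt = 1e-6
    sched = [(x * pt, pt, 7.2) for x in (0.0, 0.25, 0.5, 0.75, 1.5, 3.0)]
    f = simulate_quench(bare_plh_model, _quench(), sched, log_k_assoc=[12.0])
    expected = [1.0, 0.75, 0.5, 0.25, 0.0, 0.0]
    assert np.allclose(f, expected, atol=2e-3)


def test_noiseless_round_trip_recovers_parameters(bare_plh_model):
    """fit_kd on data simulated by the same forward model returns the truth."""
    spec = GeneratorSpec(
        model=bare_plh_model, bound_species=[PL], true_log_k=[6.0],
        quench_coeffs=[0.1], noise_sd=0.0, n_replicates=1, seed=3,
    )
    ds = generate_titration(spec)
    res = fit_kd(ds, bare_plh_model, _quench())
    assert res.identifiable and res.converged
    assert res.log_k_assoc[0] == pytest.approx(6.0, abs=1e-4)
    assert res.coeffs[0] == pytest.approx(0.1, abs=1e-3)
    assert res.kd[0] == pytest.approx(1e-6, rel=1e-3)


def test_flat_dataset_flagged_unidentifiable(bare_plh_model):
    """GA-like flat titrations get a K_D lower bound, not a point estimate."""
    rng = np.random.default_rng(11)
    sched = default_schedule()
    datasets = []
    for r in range(3):
        pts = [
            TitrationPoint(lt, pt, ph, float(1.0 + rng.normal(0, 0.01)), sigma=0.01)
            for lt, pt, ph in sched
        ]
        datasets.append(TitrationDataset(points=pts, metadata={"replicate": r}))
    res = fit_kd(datasets, bare_plh_model, _quench())
    assert not res.identifiable
    assert np.isnan(res.kd).all()
    assert res.kd_lower_bound > 10 * 0.40e-6  # far beyond the fittable sub-uM scale
    assert "unidentifiable" in res.message


def test_joint_fit_uses_all_replicates(bare_plh_model):
    spec = GeneratorSpec(
        model=bare_plh_model, bound_species=[PL], true_log_k=[6.398],
        quench_coeffs=[0.05], noise_sd=0.01, n_replicates=3, seed=7,
    )
    ds = generate_titration(spec)
    res = fit_kd(ds, bare_plh_model, _quench())
    assert res.n_titrations == 3
    assert res.n_points == 60
    assert res.identifiable
    assert abs(res.log_k_assoc[0] - 6.398) < 4 * res.se_log_k[0]
    assert len(res.scales) == 3 and np.all(np.abs(res.scales - 1) < 0.05)


def test_aic_selects_generating_stoichiometry(bare_plh_model):
    spec = GeneratorSpec(
        model=bare_plh_model, bound_species=[PL], true_log_k=[6.398],
        quench_coeffs=[0.05], noise_sd=0.01, n_replicates=3, seed=21,
    )
    ds = generate_titration(spec)
    res = select_species_model(
        ds, bare_plh_model, [_quench([c]) for c in (PL, PL2, PL3)], restrict=False
    )
    assert res.selected_model[0][0] == "PL"
    assert res.candidate_results is not None and len(res.candidate_results) == 3


def test_candidate_restriction_keeps_predominant_core():
    """For the ferric 2,3-DHBA system the 1:1 Fe:L core survives restriction."""
    model = packaged_model("dhba23")
    spec = scenario_spec("dhba23_ferric", seed=5)
    ds = generate_titration(spec)
    cands = [
        _quench([("PFeL", {"P": 1, "Fe": 1, "L": 1})]),
        _quench([("PFeL3", {"P": 1, "Fe": 1, "L": 3})]),
    ]
    res = select_species_model(
        ds, model, cands, restrict=True,
        speciation_totals={"Fe": 20e-6, "L": 60e-6}, assay_ph=7.2,
    )
    # FeL3 is not predominant at pH 7.2, so the 1:1 core must be the survivor
    assert res.selected_model[0][0] == "PFeL"
    assert res.identifiable
    assert res.log_k_assoc[0] == pytest.approx(9.996, abs=0.1)


def test_all_candidates_unidentifiable_aggregate_flag(bare_plh_model):
    sched = default_schedule()
    pts = [TitrationPoint(lt, pt, ph, 1.0, sigma=0.01) for lt, pt, ph in sched]
    ds = [TitrationDataset(points=pts, metadata={"replicate": 0})]
    res = select_species_model(ds, bare_plh_model, [_quench([PL]), _quench([PL2])],
                               restrict=False)
    assert not res.identifiable
    assert "unidentifiable" in res.message


def test_dilution_correction_cases():
    raw = np.array([100.0, 90.0, 80.0])
    assert np.allclose(apply_dilution_correction(raw, 1.0, []), raw)
    one = apply_dilution_correction(np.array([100.0]), 1.0, [0.1])
    assert one[0] == pytest.approx(110.0)
    with pytest.raises(ModelError):
        apply_dilution_correction(raw, 0.0, [0.1, 0.1])
    with pytest.raises(ModelError):
        apply_dilution_correction(raw, 1.0, [0.1, -0.1])


def test_dilution_correction_round_trip(bare_plh_model):
    """Diluting a simulated concentration series and correcting it back matches
    the directly simulated normalised curve."""
    sched = default_schedule(n_points=8)
    f_true = simulate_quench(bare_plh_model, _quench(), sched, log_k_assoc=[6.5])
    additions = np.full(len(sched) - 1, 0.004)
    v0 = 1.0
    factors = (v0 + np.concatenate([[0.0], np.cumsum(additions)])) / v0
    measured = f_true / factors  # dilution attenuates the raw signal
    corrected = apply_dilution_correction(measured, v0, additions)
    assert np.allclose(corrected, f_true, rtol=1e-12)


def test_csv_round_trip(tmp_path, bare_plh_model):
    spec = GeneratorSpec(
        model=bare_plh_model, bound_species=[PL], true_log_k=[6.0],
        quench_coeffs=[0.2], noise_sd=0.01, n_replicates=2, seed=9,
    )
    ds = generate_titration(spec)
    path = tmp_path / "t.csv"
    write_titration_csv(ds, path)
    back = read_titration_csv(path)
    assert len(back) == 2
    for a, b in zip(ds, back):
        for p, q in zip(a.points, b.points):
            assert q.ligand_total == pytest.approx(p.ligand_total, rel=1e-10)
            assert q.f_norm == pytest.approx(p.f_norm, rel=1e-10)
            assert q.sigma == pytest.approx(p.sigma, rel=1e-10)


def test_estimate_noise_from_replicates(bare_plh_model):
    spec = GeneratorSpec(
        model=bare_plh_model, bound_species=[PL], true_log_k=[6.0],
        quench_coeffs=[0.0], noise_sd=0.02, n_replicates=6, seed=13,
    )
    ds = generate_titration(spec)
    for d in ds:  # force the replicate-scatter path
        d.points = [TitrationPoint(p.ligand_total, p.protein_total, p.ph, p.f_norm)
                    for p in d.points]
    est = estimate_noise(ds)
    assert est == pytest.approx(0.02, rel=0.35)


def test_titration_dataset_ordering_enforced():
    with pytest.raises(ModelError):
        TitrationDataset(points=[
            TitrationPoint(1e-6, 1e-7, 7.2, 0.9),
            TitrationPoint(5e-7, 1e-7, 7.2, 0.95),
        ])
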