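"""The desk-scale annealing engine."""

import numpy as np
import pytest

from adrpipe.refine import (AnnealConfig, REFERENCE_ANNEAL, EnergyModel,
                            Topology, anneal, backbone_rmsd, pseudo_energy,
                            restraint_energy, rmsd_to_reference,
                            _dihedrals_grad, _model_to_flat, minimize_energy)
from adrpipe.restraints import (AmbiguousDistanceRestraint, AssignmentOption,
                                HBOND_BOUNDS, HBondRestraint,
                                TorsionRestraint)
from adrpipe.structures import Model, StructureEnsemble
from adrpipe.geometry import dihedral


def test_reference_parameters_on_record():
    # the full-scale schedule is stored unchanged; the engine runs scaled
    assert REFERENCE_ANNEAL["tad_high_temperature_K"] == 20000.0
    assert REFERENCE_ANNEAL["refine_steps"] == 8000
    cfg = AnnealConfig()
    assert cfg.high_temperature < REFERENCE_ANNEAL["cartesian_high_temperature_K"]
    assert cfg.cool_steps < REFERENCE_ANNEAL["cool1_steps"]


def test_dihedral_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 2, (8, 3))
    quads = np.array([[0, 1, 2, 3], [2, 4, 5, 6]])
    phi, grad = _dihedrals_grad(x, quads)
    for m, q in enumerate(quads):
        assert phi[m] == pytest.approx(dihedral(*x[q]), abs=1e-9)
        for col in range(4):
            for d in range(3):
                xp = x.copy(); xp[q[col], d] += 1e-6
                xm = x.copy(); xm[q[col], d] -= 1e-6
                fd = ((dihedral(*xp[q]) - dihedral(*xm[q]) + 180) % 360 - 180) / 2e-6
                assert grad[m, col, d] == pytest.approx(fd, abs=1e-4)


def test_total_energy_gradient_consistent():
    rng = np.random.default_rng(1)
    top = Topology("VTYLS")
    adr = AmbiguousDistanceRestraint(
        [AssignmentOption((1, "H"), (4, "H")),
         AssignmentOption((2, "H"), (5, "H"))], 1.0, 3.5)
    tors = [TorsionRestraint(2, "phi", -139, 20)]
    em = EnergyModel(top, [adr], tors)
    x = rng.normal(0, 3, (top.n_atoms, 3)).ravel()
    em.refresh_neighbors(x.reshape(-1, 3))
    e, g = em.energy_grad(x)
    for i in rng.choice(len(x), size=25, replace=False):
        xp = x.copy(); xp[i] += 1e-6
        xm = x.copy(); xm[i] -= 1e-6
        fd = (em.energy_grad(xp)[0] - em.energy_grad(xm)[0]) / 2e-6
        assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)


def test_pseudo_energy_zero_when_satisfied(small_sheet):
    m = small_sheet.models[0]
    adrs = [AmbiguousDistanceRestraint(
        [AssignmentOption((a, "H"), (b, "H"))], 1.0, 5.5)
        for a, b in small_sheet.provenance["facing_couples"]]
    assert restraint_energy(m, adrs) == pytest.approx(0.0, abs=1e-9)


def test_restraint_term_quadratic_in_violation(small_sheet):
    m = small_sheet.models[0]
    a, b = small_sheet.provenance["facing_couples"][0]
    d = m.distance(a, "H", b, "H")  # ~3.3
    upper = d - 1.0                 # violated by exactly 1.0
    cfg = AnnealConfig()
    adr = AmbiguousDistanceRestraint(
        [AssignmentOption((a, "H"), (b, "H"))], 1.0, upper)
    e = restraint_energy(m, [adr], config=cfg)
    assert e == pytest.approx(cfg.k_distance * 1.0 ** 2, rel=1e-6)


def test_two_residue_toy_restraint_satisfied():
    ens = anneal("VT",
                 [AmbiguousDistanceRestraint(
                     [AssignmentOption((1, "H"), (2, "H"))], 3.0, 3.5)],
                 config=AnnealConfig(n_models=2, seed=4))
    for m in ens.models:
        d = m.distance(1, "H", 2, "H")
        assert 3.0 - 0.2 <= d <= 3.5 + 0.2


def test_same_seed_identical_ensemble():
    adr = AmbiguousDistanceRestraint(
        [AssignmentOption((1, "H"), (3, "H"))], 3.0, 4.0)
    cfg = AnnealConfig(n_models=2, seed=7)
    a = anneal("VTY", [adr], config=cfg)
    b = anneal("VTY", [adr], config=cfg)
    for ma, mb in zip(a.models, b.models):
        assert np.allclose(np.nan_to_num(ma.coords), np.nan_to_num(mb.coords))
        assert ma.pseudo_energy == mb.pseudo_energy


def test_zero_restraints_returns_regularized_chain():
    ens = anneal("VTYLS", [], config=AnnealConfig(n_models=1, seed=0))
    assert len(ens) == 1
    m = ens.models[0]
    # covalent geometry near ideal after regularization
    assert np.linalg.norm(m.position(2, "N") - m.position(2, "CA")) == \
        pytest.approx(1.458, abs=0.02)


def test_energy_sorting_stable():
    models = []
    rng = np.random.default_rng(0)
    for e in (3.0, 1.0, 3.0, 2.0):
        coords = rng.normal(size=(2, 6, 3))
        models.append(Model(coords, "VT", np.array([1, 2]), pseudo_energy=e))
    ens = StructureEnsemble("VT", np.array([1, 2]), models)
    s = ens.sorted_by_energy()
    assert [m.pseudo_energy for m in s.models] == [1.0, 2.0, 3.0, 3.0]
    # ties keep input order (stable)
    assert s.models[2] is models[0]


def test_backbone_rmsd_duplicate_model_zero(small_sheet):
    m = small_sheet.models[0]
    ens = StructureEnsemble(small_sheet.sequence, small_sheet.resnums, [m, m])
    mean, sd = backbone_rmsd(ens)
    assert mean == pytest.approx(0.0, abs=1e-9)


def test_backbone_rmsd_translation_invariant(small_sheet):
    m = small_sheet.models[0]
    shifted = Model(m.coords + 5.0, m.sequence, m.resnums, pseudo_energy=1.0)
    ens = StructureEnsemble(small_sheet.sequence, small_sheet.resnums,
                            [m, shifted])
    mean, _ = backbone_rmsd(ens)
    assert mean == pytest.approx(0.0, abs=1e-9)


def test_backbone_rmsd_empty_subset_raises(small_sheet):
    m = small_sheet.models[0]
    ens = StructureEnsemble(small_sheet.sequence, small_sheet.resnums, [m, m])
    with pytest.raises(ValueError):
        backbone_rmsd(ens, [])


def test_quench_energy_never_increases(small_sheet):
    """A quench from a perturbed state ends at or below its starting
    pseudo-energy (monotone over the final quench)."""
    m = small_sheet.models[0]
    top = Topology(m.sequence)
    adrs = [AmbiguousDistanceRestraint(
        [AssignmentOption((a, "H"), (b, "H"))], 1.0, 3.5)
        for a, b in small_sheet.provenance["facing_couples"]]
    em = EnergyModel(top, adrs, ())
    rng = np.random.default_rng(2)
    x = _model_to_flat(m, top) + rng.normal(0, 0.3, (top.n_atoms, 3))
    em.refresh_neighbors(x)
    e0 = em.energy(x)
    _, e1 = minimize_energy(em, x, 300)
    assert e1 <= e0


def test_recovery_from_true_restraints(small_sheet):
    """Annealing against noise-free restraints derived from the generator
    truth recovers the sheet to well under 2 A backbone RMSD."""
    m = small_sheet.models[0]
    strand_res = sorted(small_sheet.provenance["strand_of"])
    adrs = []
    hbonds = []
    for a, b in small_sheet.provenance["facing_couples"]:
        adrs.append(AmbiguousDistanceRestraint(
            [AssignmentOption((a, "H"), (b, "H"))], 1.0, 3.5))
        for da, ac in ((a, b), (b, a)):
            hbonds.append(HBondRestraint(da, ac, "H_O", *HBOND_BOUNDS["H_O"]))
            hbonds.append(HBondRestraint(da, ac, "N_O", *HBOND_BOUNDS["N_O"]))
    for r in strand_res:
        if r + 1 in strand_res:
            adrs.append(AmbiguousDistanceRestraint(
                [AssignmentOption((r, "H"), (r + 1, "H"))], 1.0, 5.5))
    from adrpipe.restraints import emit_torsion_restraints
    from adrpipe.synth import talos_from_truth
    tors = emit_torsion_restraints(talos_from_truth(small_sheet))
    ens = anneal(small_sheet.sequence, adrs, tors, hbonds,
                 AnnealConfig(n_models=4, seed=11))
    best = ens.sorted_by_energy().models[:2]
    sel = StructureEnsemble(ens.sequence, ens.resnums, best)
    assert rmsd_to_reference(sel, m, strand_res) < 2.0
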