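"""Ideal-sheet geometry and the synthetic data generator."""

import numpy as np
import pytest

from adrpipe import geometry
from adrpipe.io_nmr import spectrum_darr, spectrum_hnhh, spectrum_hnhhnh
from adrpipe.labeling import build_labeling_scheme
from adrpipe.restraints import match_peaks_h
from adrpipe.synth import (PeakSimConfig, SheetSpec, build_ideal_sheet,
                           inject_overlap, simulate_peaks, simulate_shifts,
                           talos_from_truth)


def _central_facing_distance(truth):
    spec = truth.provenance["spec"]
    m = truth.models[0]
    mid = spec.strand_start(0) + (spec.residues_per_strand - 1) / 2.0
    couples = truth.provenance["facing_couples"]
    a, b = min(couples, key=lambda c: abs(c[0] - mid))
    return m.distance(a, "H", b, "H")


def test_backbone_builder_reproduces_torsions():
    phi = np.full(6, geometry.BETA_PHI)
    psi = np.full(6, geometry.BETA_PSI)
    bb = geometry.build_backbone(phi, psi)
    got_phi = geometry.dihedral(bb["C"][1], bb["N"][2], bb["CA"][2], bb["C"][2])
    got_psi = geometry.dihedral(bb["N"][2], bb["CA"][2], bb["C"][2], bb["N"][3])
    assert got_phi == pytest.approx(geometry.BETA_PHI, abs=1e-6)
    assert got_psi == pytest.approx(geometry.BETA_PSI, abs=1e-6)


def test_superposed_rmsd_identity_and_translation():
    rng = np.random.default_rng(0)
    P = rng.normal(size=(12, 3))
    assert geometry.superposed_rmsd(P, P) == pytest.approx(0.0, abs=1e-9)
    assert geometry.superposed_rmsd(P + [3.0, -1.0, 7.0], P) == pytest.approx(0.0, abs=1e-9)


def test_superposed_rmsd_hand_computed_toy():
    # one atom displaced by 0.6 after optimal alignment of the other two:
    # verify against a brute-force grid of rigid transforms
    P = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0]])
    Q = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 3.6, 0]])
    got = geometry.superposed_rmsd(P, Q)
    from scipy.optimize import minimize as _min
    from scipy.spatial.transform import Rotation

    def loss(p):
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        return np.sqrt(((P @ R.T + p[3:] - Q) ** 2).sum() / 3)

    best = min(_min(loss, np.concatenate([rv, [0, 0, 0.0]])).fun
               for rv in ([0, 0, 0], [0.1, -0.1, 0.2]))
    assert got == pytest.approx(best, abs=1e-5)


def test_facing_hn_hn_is_3_3(small_sheet):
    assert round(_central_facing_distance(small_sheet), 1) == 3.3


def test_sequential_hn_hn_near_4_3(small_sheet):
    m = small_sheet.models[0]
    d = m.distance(3, "H", 4, "H")
    assert abs(d - 4.3) <= 0.2  # ideal-strand value


def test_single_strand_has_no_cross_contacts():
    truth = build_ideal_sheet(SheetSpec(n_strands=1, residues_per_strand=6))
    assert truth.provenance["facing_couples"] == []


def test_barrel_needs_even_strand_count():
    with pytest.raises(ValueError):
        SheetSpec(n_strands=5, barrel=True)


def test_loop_residues_are_unassigned(small_sheet, small_shifts):
    loops = set(small_sheet.provenance["loop_residues"])
    assigned = {e.residue_number for e in small_shifts.entries}
    assert loops
    assert not loops & assigned


def test_disorder_range_omitted_from_shifts(small_sheet):
    sl = simulate_shifts(small_sheet, seed=1, disorder={2, 3, 4, 5, 6})
    assigned = {e.residue_number for e in sl.entries}
    assert not assigned & {2, 3, 4, 5, 6}


def test_shifts_deterministic_per_seed(small_sheet):
    a = simulate_shifts(small_sheet, seed=9)
    b = simulate_shifts(small_sheet, seed=9)
    assert [e.shift for e in a.entries] == [e.shift for e in b.entries]


def test_amide_h_shifts_in_window(small_sheet):
    sl = simulate_shifts(small_sheet, seed=1, jitter_sd={"H": 0.3})
    for e in sl.by_atom("H"):
        assert 5.0 <= e.shift <= 12.0


def test_four_cross_peaks_for_visible_pair(small_sheet, small_shifts):
    cfg = PeakSimConfig(seed=3)
    pls = [simulate_peaks(small_sheet, small_shifts, sp, cfg)
           for sp in (spectrum_hnhh(), spectrum_hnhhnh())]
    a, b = small_sheet.provenance["facing_couples"][0]
    sh = small_shifts
    count = 0
    for pl in pls:
        for p in pl.peaks:
            for (i, j) in ((a, b), (b, a)):
                expect = tuple(
                    sh.get(i if role == "origin" else j, "N" if nuc == "N" else "H")
                    for nuc, role in zip(pl.spectrum.dimension_nuclei,
                                         pl.spectrum.dimension_roles))
                if p.positions == pytest.approx(expect):
                    count += 1
    assert count == 4


def test_intensity_monotonic_in_distance(small_sheet, small_shifts):
    cfg = PeakSimConfig(seed=3)
    pl = simulate_peaks(small_sheet, small_shifts, spectrum_hnhh(), cfg)
    m = small_sheet.models[0]
    sh = small_shifts

    def peak_for(i, j):
        pos = (sh.get(i, "N"), sh.get(i, "H"), sh.get(j, "H"))
        for p in pl.peaks:
            if p.positions == pytest.approx(pos):
                return p
        return None

    a, b = small_sheet.provenance["facing_couples"][0]  # ~3.3 A
    seq = peak_for(a, a + 1)                             # ~4.3 A
    cross = peak_for(a, b)
    assert cross is not None and seq is not None
    assert cross.intensity > seq.intensity


def test_pair_beyond_cutoff_gives_no_peak(small_sheet, small_shifts):
    cfg = PeakSimConfig(seed=3)
    pl = simulate_peaks(small_sheet, small_shifts, spectrum_hnhh(), cfg)
    m = small_sheet.models[0]
    sh = small_shifts
    # residues at opposite chain ends are far apart
    assert m.distance(1, "H", 15, "H") > cfg.distance_cutoff["rfdr_2ms"]
    pos = (sh.get(1, "N"), sh.get(1, "H"), sh.get(15, "H"))
    assert all(p.positions != pytest.approx(pos) for p in pl.peaks)


def test_peaks_bit_reproducible(small_sheet, small_shifts):
    cfg = PeakSimConfig(seed=5, noise_sd=0.1)
    a = simulate_peaks(small_sheet, small_shifts, spectrum_hnhh(), cfg)
    b = simulate_peaks(small_sheet, small_shifts, spectrum_hnhh(), cfg)
    assert [(p.positions, p.intensity) for p in a.peaks] == \
           [(p.positions, p.intensity) for p in b.peaks]


def test_unsupported_spectrum_type_raises(small_sheet, small_shifts):
    from adrpipe.io_nmr import SpectrumDef
    bad = SpectrumDef("NC", ("N", "C"), ("origin", "destination"),
                      (0.4, 0.4), "darr_long")
    with pytest.raises(ValueError):
        simulate_peaks(small_sheet, small_shifts, bad, PeakSimConfig())


def test_matching_recovers_true_pairs(small_sheet, small_shifts):
    """Noise-free peaks: virtually every emitted contact appears among the
    options of some restraint (recovery >= 95%)."""
    cfg = PeakSimConfig(seed=3)
    pls = [simulate_peaks(small_sheet, small_shifts, sp, cfg)
           for sp in (spectrum_hnhh(), spectrum_hnhhnh())]
    adrs = []
    for pl in pls:
        adrs += match_peaks_h(pl, small_shifts)
    m = small_sheet.models[0]
    assigned = sorted({e.residue_number for e in small_shifts.by_atom("H")})
    contacts = set()
    cutoff = cfg.distance_cutoff["rfdr_2ms"]
    for pl in pls:
        for p in pl.peaks:
            pass
    for i in assigned:
        for j in assigned:
            if i < j and m.distance(i, "H", j, "H") <= cutoff:
                contacts.add((i, j))
    option_pairs = {o.residue_pair for a in adrs for o in a.options}
    recovered = sum(c in option_pairs for c in contacts)
    assert recovered / len(contacts) >= 0.95


def test_overlap_injection_increases_ambiguity(small_sheet, small_shifts):
    cfg = PeakSimConfig(seed=3)
    def mean_ambiguity(shifts):
        pl = simulate_peaks(small_sheet, shifts, spectrum_hnhh(), cfg)
        adrs = match_peaks_h(pl, shifts)
        return np.mean([a.ambiguity for a in adrs])
    base = mean_ambiguity(small_shifts)
    overlapped = inject_overlap(small_shifts, count=3, seed=1)
    assert mean_ambiguity(overlapped) > base


def test_talos_table_marks_loops_unreliable(small_sheet):
    df = talos_from_truth(small_sheet)
    loops = set(small_sheet.provenance["loop_residues"])
    for _, row in df.iterrows():
        if row.RESID in loops:
            assert row.CLASS == "None"
    good = df[df.CLASS == "Good"]
    assert len(good) > 0
    # measured torsions of strand interiors are near the ideal values
    inner = good[(good.RESID > 1) & (good.RESID < 6)]
    assert np.allclose(inner.PHI, geometry.BETA_PHI, atol=1.0)
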