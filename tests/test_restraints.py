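"""Restraint generation: matching, redundancy, classes, gates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrpipe.io_nmr import (Peak, PeakList, ShiftEntry, ShiftList,
                            spectrum_darr, spectrum_hnhh, spectrum_hnhhnh)
from adrpipe.labeling import build_labeling_scheme
from adrpipe.restraints import (AmbiguousDistanceRestraint, AssignmentOption,
                                CoupleEvidence, H_CLASS_REGULAR,
                                H_CLASS_STRONG, HBondRestraint,
                                classify_h_bounds, count_support,
                                emit_hbond_restraints,
                                emit_torsion_restraints,
                                exclude_intra_and_region, match_peaks_c,
                                match_peaks_h, redundancy_filter)


# -------------------------------------------------------------- 1H matching

def test_match_within_tolerances_single_option(tiny_shifts):
    # N 115.2 vs 115.4 (0.2 <= 0.4), H_ind 8.31 vs 8.25 (0.06 <= 0.1),
    # H_dir 9.02 vs 9.20 (0.18 <= 0.7) -> the 75 <-> 87 option
    pl = PeakList(spectrum_hnhh(), [Peak((115.2, 8.31, 9.02), 50.0, 0)])
    adrs = match_peaks_h(pl, tiny_shifts)
    assert len(adrs) == 1
    assert adrs[0].options[0].residue_pair == (75, 87)


def test_auto_correlation_peak_dropped(tiny_shifts):
    pl = PeakList(spectrum_hnhh(), [Peak((115.4, 8.25, 8.25), 400.0, 0)])
    assert match_peaks_h(pl, tiny_shifts) == []


def test_unmatched_peak_excluded(tiny_shifts, caplog):
    pl = PeakList(spectrum_hnhh(), [Peak((150.0, 3.0, 3.0), 10.0, 0)])
    import logging
    with caplog.at_level(logging.WARNING, logger="adrpipe.restraints"):
        assert match_peaks_h(pl, tiny_shifts) == []
    assert "matched nothing" in caplog.text


def test_empty_shift_list_raises():
    pl = PeakList(spectrum_hnhh(), [])
    with pytest.raises(ValueError):
        match_peaks_h(pl, ShiftList([]))


def test_carbon_only_shift_list_rejected():
    sl = ShiftList([ShiftEntry(1, "A", "CA", 52.5)])
    pl = PeakList(spectrum_hnhh(), [])
    with pytest.raises(ValueError, match="amide"):
        match_peaks_h(pl, sl)


def test_matching_boundary_inclusive(tiny_shifts):
    # exactly at tolerance in every dimension still matches
    pl = PeakList(spectrum_hnhh(), [Peak((115.4 + 0.4, 8.25 + 0.1, 9.20 + 0.7),
                                         10.0, 0)])
    adrs = match_peaks_h(pl, tiny_shifts)
    assert len(adrs) == 1
    assert adrs[0].options[0].residue_pair == (75, 87)


# ----------------------------------------------------------- redundancy rule

def _adr_with_supports(supports):
    opts = [AssignmentOption((1, "H"), (10 + k, "H"), support_count=s)
            for k, s in enumerate(supports)]
    return AmbiguousDistanceRestraint(opts, 1.0, 5.5)


@pytest.mark.parametrize("supports,kept", [
    ([4, 2, 1], [4]),          # four-peak rule removes 1- and 2-supported
    ([3, 1, 2], [3, 2]),       # three-peak rule removes only 1-supported
    ([2, 2], [2, 2]),          # no rule fires
    ([4, 3, 2, 1], [4, 3]),
    ([1], [1]),
])
def test_redundancy_rule_micro_cases(supports, kept):
    adr = _adr_with_supports(supports)
    redundancy_filter([adr])
    assert sorted(o.support_count for o in adr.options) == sorted(kept)


def test_redundancy_never_removes_best_option():
    # exhaustive over all support patterns up to 4 options
    from itertools import product
    for n in range(1, 5):
        for supports in product(range(1, 5), repeat=n):
            adr = _adr_with_supports(list(supports))
            redundancy_filter([adr])
            assert max(supports) in [o.support_count for o in adr.options]
            assert adr.active


def test_four_fold_support_micro_fixture(amide_spectra):
    # two residues with well-separated shifts and the full reciprocal peak
    # pattern across the paired spectra: support is exactly four
    from adrpipe.restraints import amide_pair_support
    sl = ShiftList([
        ShiftEntry(75, "Y", "N", 115.4), ShiftEntry(75, "Y", "H", 6.55),
        ShiftEntry(87, "L", "N", 121.3), ShiftEntry(87, "L", "H", 9.20),
    ])
    hnhh, hnhhnh = amide_spectra
    pls = [
        PeakList(hnhh, [Peak((115.4, 6.55, 9.20), 10.0, 0),
                        Peak((121.3, 9.20, 6.55), 10.0, 1)]),
        PeakList(hnhhnh, [Peak((115.4, 121.3, 9.20), 10.0, 0),
                          Peak((121.3, 115.4, 6.55), 10.0, 1)]),
    ]
    assert amide_pair_support(75, 87, pls, sl) == 4
    # remove one direction in one spectrum: support drops to three
    pls[0] = PeakList(hnhh, pls[0].peaks[:1])
    assert amide_pair_support(75, 87, pls, sl) == 3


# ----------------------------------------------------------- distance classes

def _peak_adrs(intensities, sequential_flags):
    peaks, adrs = [], []
    for k, (inten, seq) in enumerate(zip(intensities, sequential_flags)):
        peaks.append(Peak((110.0 + k, 8.0, 9.0), inten, k))
        partner = 1 if seq else 10
        adrs.append(AmbiguousDistanceRestraint(
            [AssignmentOption((1, "H"), (1 + partner, "H"))], 1.0, 5.5,
            source_peaks=[k]))
    return PeakList(spectrum_hnhh(), peaks), adrs


def test_intensity_classes_split_at_first_sequential():
    # threshold = 5.0 (most intense sequential peak); 9.0 > 5.0 -> strong,
    # 5.0 and 2.0 stay regular
    pl, adrs = _peak_adrs([9.0, 5.0, 2.0], [False, True, False])
    classify_h_bounds(adrs, pl)
    assert (adrs[0].lower, adrs[0].upper) == H_CLASS_STRONG
    assert (adrs[1].lower, adrs[1].upper) == H_CLASS_REGULAR
    assert (adrs[2].lower, adrs[2].upper) == H_CLASS_REGULAR


def test_equal_intensity_stays_regular():
    pl, adrs = _peak_adrs([5.0, 5.0], [True, False])
    classify_h_bounds(adrs, pl)
    assert (adrs[1].lower, adrs[1].upper) == H_CLASS_REGULAR


def test_no_sequential_peak_conservative():
    pl, adrs = _peak_adrs([9.0, 5.0], [False, False])
    with pytest.warns(UserWarning, match="sequential"):
        classify_h_bounds(adrs, pl)
    assert all((a.lower, a.upper) == H_CLASS_REGULAR for a in adrs)


def test_classification_partitions_into_the_two_classes(small_sheet,
                                                        small_shifts,
                                                        amide_spectra):
    from adrpipe.synth import PeakSimConfig, simulate_peaks
    cfg = PeakSimConfig(seed=3)
    pl = simulate_peaks(small_sheet, small_shifts, amide_spectra[0], cfg)
    adrs = match_peaks_h(pl, small_shifts)
    classify_h_bounds(adrs, pl)
    assert {(a.lower, a.upper) for a in adrs} <= {H_CLASS_STRONG, H_CLASS_REGULAR}


def test_empty_adr_list_passthrough():
    assert classify_h_bounds([], PeakList(spectrum_hnhh(), [])) == []


# ----------------------------------------------------------- 13C matching

@pytest.fixture
def carbon_shifts():
    return ShiftList([
        ShiftEntry(5, "A", "CA", 55.2), ShiftEntry(5, "A", "CB", 18.9),
        ShiftEntry(9, "V", "CA", 55.3), ShiftEntry(9, "V", "CB", 24.8),
        ShiftEntry(9, "V", "N", 120.0),
    ])


def test_labeling_filter_keeps_only_observable_pair(carbon_shifts):
    # A-CA at 0.9-ish enrichment vs V-CB 0.07: only the strong product stays
    scheme = build_labeling_scheme({
        "kind": "uniform",
        "enrichment_overrides": {"A": {"CA": 0.9}, "V": {"CA": 0.07, "CB": 1.0}}})
    pl = PeakList(spectrum_darr("darr_long", scheme),
                  [Peak((55.2, 24.8), 10.0, 0)])
    adrs = match_peaks_c(pl, carbon_shifts, scheme=scheme)
    assert len(adrs) == 1
    assert [o.residue_pair for o in adrs[0].options] == [(5, 9)]
    assert adrs[0].options[0].labeling_product == pytest.approx(0.9)


def test_intra_residue_candidates_excluded(carbon_shifts):
    scheme = build_labeling_scheme({"kind": "uniform"})
    pl = PeakList(spectrum_darr("darr_long", scheme),
                  [Peak((55.3, 24.8), 10.0, 0)])
    adrs = match_peaks_c(pl, carbon_shifts, scheme=scheme)
    # (9, CA)-(9, CB) would fit the positions but is intra-residue; only the
    # inter-residue (5, CA)-(9, CB) option may remain
    for a in adrs:
        for o in a.options:
            assert o.atom_a[0] != o.atom_b[0]


def test_unmatchable_carbon_peak_dropped(carbon_shifts):
    scheme = build_labeling_scheme({"kind": "forward", "labeled": "G"})
    pl = PeakList(spectrum_darr("darr_long", scheme),
                  [Peak((55.2, 24.8), 10.0, 0)])
    assert match_peaks_c(pl, carbon_shifts, scheme=scheme) == []


def test_missing_scheme_raises(carbon_shifts):
    pl = PeakList(spectrum_darr("darr_long", None), [Peak((55.2, 24.8), 1.0, 0)])
    with pytest.raises(ValueError, match="scheme"):
        match_peaks_c(pl, carbon_shifts)


def test_c_class_modes(carbon_shifts):
    scheme = build_labeling_scheme({"kind": "uniform"})
    pl = PeakList(spectrum_darr("darr_long", scheme), [Peak((55.2, 24.8), 1.0, 0)])
    single = match_peaks_c(pl, carbon_shifts, scheme=scheme, class_mode="single")
    two = match_peaks_c(pl, carbon_shifts, scheme=scheme, class_mode="by_mixing")
    assert (single[0].lower, single[0].upper) == (1.5, 8.0)
    assert (two[0].lower, two[0].upper) == (1.5, 7.0)


def test_exclude_intra_and_region():
    scheme = build_labeling_scheme({"kind": "uniform"})
    long_mix = PeakList(spectrum_darr("darr_long", scheme), [
        Peak((55.0, 24.8), 5.0, 0),    # matches a short-mix peak -> removed
        Peak((60.0, 30.0), 5.0, 1),    # genuine long-mix peak -> kept
        Peak((175.1, 55.0), 5.0, 2),   # outside aliphatic region -> removed
    ])
    short_mix = PeakList(spectrum_darr("darr_short", scheme),
                         [Peak((55.2, 24.9), 50.0, 0)])
    kept = exclude_intra_and_region(long_mix, short_mix)
    assert [p.id for p in kept.peaks] == [1]


# ----------------------------------------------------- hydrogen bonds, torsions

def test_qualifying_couple_emits_colinear_pair():
    ev = {(75, 87): CoupleEvidence(True, True, 4)}
    hb, rejected = emit_hbond_restraints([(75, 87)], ev)
    assert rejected == []
    assert len(hb) == 2
    kinds = {r.kind: (r.lower, r.upper) for r in hb}
    assert kinds["H_O"] == (1.73, 2.70)
    assert kinds["N_O"] == (2.52, 3.93)


def test_92_couples_yield_184_restraints():
    couples = [(i, i + 40) for i in range(1, 93)]
    ev = {c: CoupleEvidence(True, True, 4) for c in couples}
    hb, rejected = emit_hbond_restraints(couples, ev)
    assert len(hb) == 184
    assert rejected == []


def test_incomplete_cross_peak_pattern_rejected():
    ev = {(75, 87): CoupleEvidence(True, True, 3)}
    hb, rejected = emit_hbond_restraints([(75, 87)], ev)
    assert hb == []
    assert rejected[0][1] == "incomplete cross-peak pattern"


def test_non_beta_couple_rejected():
    ev = {(75, 87): CoupleEvidence(True, False, 4)}
    hb, rejected = emit_hbond_restraints([(75, 87)], ev)
    assert hb == []
    assert "beta" in rejected[0][1]


def test_duplicate_couple_raises():
    ev = {(75, 87): CoupleEvidence(True, True, 4)}
    with pytest.raises(ValueError, match="duplicate"):
        emit_hbond_restraints([(75, 87), (87, 75)], ev)


def _talos_table(n_reliable, n_unreliable=0):
    rows = []
    for k in range(n_reliable):
        rows.append(dict(RESID=k + 1, RESNAME="V", PHI=-139.0, PSI=135.0,
                         DPHI=15.0, DPSI=18.0, CLASS="Good"))
    for k in range(n_unreliable):
        rows.append(dict(RESID=500 + k, RESNAME="A", PHI=9999.0, PSI=9999.0,
                         DPHI=0.0, DPSI=0.0, CLASS="None"))
    return pd.DataFrame(rows)


def test_128_reliable_rows_give_256_restraints():
    out = emit_torsion_restraints(_talos_table(128, n_unreliable=10))
    assert len(out) == 256
    assert {t.angle for t in out} == {"phi", "psi"}


def test_unreliable_rows_skipped():
    assert emit_torsion_restraints(_talos_table(0, n_unreliable=5)) == []


def test_empty_table_gives_empty_list():
    assert emit_torsion_restraints(pd.DataFrame(
        columns=["RESID", "RESNAME", "PHI", "PSI", "DPHI", "DPSI", "CLASS"])) == []


def test_malformed_row_reports_index():
    df = _talos_table(2)
    df.loc[1, "PHI"] = np.nan
    with pytest.raises(ValueError, match="row 1"):
        emit_torsion_restraints(df)


def test_torsion_centers_copied_from_table():
    out = emit_torsion_restraints(_talos_table(1))
    phi = next(t for t in out if t.angle == "phi")
    assert phi.center == pytest.approx(-139.0)
    assert phi.half_width == pytest.approx(15.0)


# ----------------------------------------------------------- invariants

@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_every_emitted_option_is_inter_residue(seed):
    rng = np.random.default_rng(seed)
    sl = ShiftList([e for r in range(1, 6) for e in (
        ShiftEntry(r, "V", "N", float(105 + rng.uniform(0, 30))),
        ShiftEntry(r, "V", "H", float(6 + rng.uniform(0, 4))))])
    pl = PeakList(spectrum_hnhh(), [
        Peak((float(rng.uniform(105, 135)), float(rng.uniform(6, 10)),
              float(rng.uniform(6, 10))), 1.0, k) for k in range(6)])
    for adr in match_peaks_h(pl, sl):
        for o in adr.options:
            assert o.atom_a[0] != o.atom_b[0]
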