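"""Iterative-protocol operations: effective distances, violation analysis,
pruning, combination, merging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrpipe.protocol import (ProtocolConfig, combine_restraints,
                              effective_distance, merge_equivalent,
                              prune_options, violation_analysis)
from adrpipe.restraints import AmbiguousDistanceRestraint, AssignmentOption
from adrpipe.structures import Model, StructureEnsemble


def _line_model(distances, energy=0.0):
    """Residues with amide protons placed on the x axis.

    ``distances[k]`` is the distance of residue k+2's H from residue 1's H.
    """
    n = len(distances) + 1
    coords = np.full((n, 6, 3), np.nan)
    xs = [0.0] + list(distances)
    for i in range(n):
        coords[i, 1] = [xs[i], 0.0, 0.0]          # H
        coords[i, 0] = [xs[i], 1.0, 0.0]          # N (unused but present)
    return Model(coords, "V" * n, np.arange(1, n + 1), pseudo_energy=energy)


def _adr(pairs, lower=1.0, upper=5.5):
    opts = [AssignmentOption((1, "H"), (k, "H")) for k in pairs]
    return AmbiguousDistanceRestraint(opts, lower, upper)


def test_effective_distance_single_option_is_plain_distance():
    m = _line_model([3.0])
    assert effective_distance(m, _adr([2])) == pytest.approx(3.0)


def test_effective_distance_two_options_closed_form():
    m = _line_model([3.0, 6.0])
    expect = (3.0 ** -6 + 6.0 ** -6) ** (-1 / 6)
    assert effective_distance(m, _adr([2, 3])) == pytest.approx(expect)
    assert expect == pytest.approx(2.992, abs=5e-4)


def test_effective_distance_degenerate_options():
    m = _line_model([4.0, 4.0])
    assert effective_distance(m, _adr([2, 3])) == pytest.approx(4.0 * 2 ** (-1 / 6))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(ds=st.lists(st.floats(1.5, 12.0), min_size=1, max_size=6))
def test_effective_distance_oracle_equivalence(ds):
    """r^-6 pooling matches the independent closed form to 1e-9 and never
    exceeds the shortest option distance."""
    m = _line_model(ds)
    adr = _adr(list(range(2, len(ds) + 2)))
    got = effective_distance(m, adr)
    oracle = sum(d ** -6 for d in ds) ** (-1 / 6)
    assert got == pytest.approx(oracle, abs=1e-9)
    assert got <= min(ds) + 1e-12


# ----------------------------------------------------------- violation rule

def _ensemble(satisfied_count, n_models=15, dist_ok=3.0, dist_bad=9.0):
    models = []
    for k in range(n_models):
        d = dist_ok if k < satisfied_count else dist_bad
        models.append(_line_model([d], energy=float(k)))
    return StructureEnsemble("VV", np.array([1, 2]), models)


@pytest.mark.parametrize("sat", range(16))
def test_at_least_half_rule_all_counts(sat):
    """Enumerate every satisfied count for the 15-model selection: kept iff
    satisfied in at least ceil(0.5 x 15) = 8 models."""
    cfg = ProtocolConfig(n_structures=15, n_select=15,
                         violation_tolerance=(0.0,))
    adr = _adr([2])
    report = violation_analysis([adr], _ensemble(sat), cfg, iteration=0)
    expected = "kept" if sat >= 8 else "rejected"
    assert report.records[0].decision == expected
    assert adr.active == (expected == "kept")


def test_rejected_restraint_is_soft_deleted():
    cfg = ProtocolConfig(n_structures=15, n_select=15,
                         violation_tolerance=(0.0,))
    adr = _adr([2])
    violation_analysis([adr], _ensemble(0), cfg, 0)
    assert not adr.active
    assert adr.options  # options survive the soft delete


def test_violation_tolerance_widens_bounds():
    cfg = ProtocolConfig(n_structures=15, n_select=15,
                         violation_tolerance=(4.0,))
    adr = _adr([2])  # bad distance 9.0 <= 5.5 + 4.0
    report = violation_analysis([adr], _ensemble(0), cfg, 0)
    assert report.records[0].decision == "kept"


def test_empty_ensemble_raises():
    cfg = ProtocolConfig()
    with pytest.raises(ValueError):
        violation_analysis([_adr([2])], StructureEnsemble("V", np.array([1])), cfg)


def test_perfect_ensemble_keeps_true_rejects_decoys(small_sheet):
    """With the generator's truth as the ensemble, restraints built from
    true contacts are all kept and a planted far decoy is rejected."""
    cfg = ProtocolConfig(n_structures=1, n_select=1, violation_tolerance=(0.1,))
    m = small_sheet.models[0]
    true_adrs = [AmbiguousDistanceRestraint(
        [AssignmentOption((a, "H"), (b, "H"))], 1.0, 5.5)
        for a, b in small_sheet.provenance["facing_couples"]]
    decoy = AmbiguousDistanceRestraint(
        [AssignmentOption((1, "H"), (15, "H"))], 1.0, 3.5)  # chain ends, far
    assert m.distance(1, "H", 15, "H") > 3.6
    ens = StructureEnsemble(small_sheet.sequence, small_sheet.resnums, [m])
    report = violation_analysis(true_adrs + [decoy], ens, cfg, 0)
    decisions = [r.decision for r in report.records]
    assert decisions[:-1] == ["kept"] * len(true_adrs)
    assert decisions[-1] == "rejected"


# ----------------------------------------------------------- pruning

def test_prune_keeps_dominant_weight_prefix():
    # distances 3, 6, 7 -> weights ~0.985, 0.015, ...; cutoff 0.8 keeps one
    m = _line_model([3.0, 6.0, 7.0])
    ens = StructureEnsemble("VVVV", np.arange(1, 5), [m])
    adr = _adr([2, 3, 4])
    prune_options(adr, ens, 0.8)
    assert [o.atom_b[0] for o in adr.options] == [2]


def test_prune_cutoff_one_keeps_everything():
    m = _line_model([3.0, 6.0, 7.0])
    ens = StructureEnsemble("VVVV", np.arange(1, 5), [m])
    adr = _adr([2, 3, 4])
    prune_options(adr, ens, 1.0)
    assert adr.ambiguity == 3


def test_prune_single_option_unchanged():
    m = _line_model([3.0])
    ens = StructureEnsemble("VV", np.arange(1, 3), [m])
    adr = _adr([2])
    prune_options(adr, ens, 0.5)
    assert adr.ambiguity == 1


# ----------------------------------------------------------- combination

def _singles(n, lower=1.5, upper=8.0):
    return [AmbiguousDistanceRestraint(
        [AssignmentOption((k, "CA"), (k + 5, "CA"))], lower, upper)
        for k in range(1, n + 1)]


def test_combine_eight_singles_into_two_groups():
    out = combine_restraints(_singles(8), arity=4, rng=0)
    assert len(out) == 2
    assert all(r.ambiguity == 4 for r in out)


def test_combine_leftover_passthrough():
    out = combine_restraints(_singles(5), arity=4, rng=0)
    assert sorted(r.ambiguity for r in out) == [1, 4]


def test_combine_seed_reproducible():
    a = combine_restraints(_singles(12), rng=42)
    b = combine_restraints(_singles(12), rng=42)
    assert [r.option_keys() for r in a] == [r.option_keys() for r in b]


def test_combine_takes_widest_bounds():
    adrs = _singles(3) + [AmbiguousDistanceRestraint(
        [AssignmentOption((20, "CA"), (30, "CA"))], 1.0, 5.5)]
    out = combine_restraints(adrs, arity=4, rng=1)
    assert len(out) == 1
    assert out[0].lower == 1.0 and out[0].upper == 8.0


def test_combine_arity_below_two_raises():
    with pytest.raises(ValueError):
        combine_restraints(_singles(4), arity=1)


# ----------------------------------------------------------- merging

def test_merge_equivalent_keeps_tighter_upper():
    a = AmbiguousDistanceRestraint([AssignmentOption((75, "H"), (87, "H"))],
                                   1.0, 3.5, source_peaks=[1])
    b = AmbiguousDistanceRestraint([AssignmentOption((75, "H"), (87, "H"))],
                                   1.0, 5.5, source_peaks=[2])
    out = merge_equivalent([a, b])
    assert len(out) == 1
    assert out[0].upper == 3.5
    assert sorted(out[0].source_peaks) == [1, 2]


def test_merge_disjoint_sets_unchanged():
    a = _adr([2])
    b = _adr([3])
    assert len(merge_equivalent([a, b])) == 2


def test_merge_empty_input():
    assert merge_equivalent([]) == []
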