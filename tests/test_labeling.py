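"""Labeling schemes and the pair-observability filter."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrpipe.labeling import (RESIDUE_TYPES, build_labeling_scheme,
                              bundled_schemes, carbon_atoms,
                              glycerol_pattern_table, pair_observability,
                              pair_observable)


@pytest.fixture(scope="module")
def forward_gavls():
    return build_labeling_scheme({"name": "GAVLS(W)", "kind": "forward",
                                  "labeled": "GAVLS", "accidental": "W"})


def test_forward_scheme_labels_listed_residues(forward_gavls):
    assert forward_gavls.carbon_fraction("L", "CA") == 1.0
    assert forward_gavls.carbon_fraction("V", "CB") == 1.0


def test_forward_scheme_zero_for_unlisted_residues(forward_gavls):
    assert forward_gavls.carbon_fraction("F", "CA") == 0.0
    assert forward_gavls.carbon_fraction("K", "CB") == 0.0


def test_accidental_residue_gets_reduced_fraction(forward_gavls):
    assert forward_gavls.carbon_fraction("W", "CA") == pytest.approx(0.3)


def test_glycerol_scheme_reads_pattern_table():
    scheme = build_labeling_scheme({"kind": "glycerol_2"})
    table = glycerol_pattern_table()["glycerol_2"]
    assert scheme.carbon_fraction("A", "CA") == pytest.approx(table["A"]["CA"])
    assert scheme.carbon_fraction("A", "CB") == pytest.approx(table["A"]["CB"])


def test_scheme_covers_all_residue_types():
    scheme = build_labeling_scheme({"kind": "glycerol_1_3"})
    for res in RESIDUE_TYPES:
        for atom in carbon_atoms(res):
            assert 0.0 <= scheme.carbon_fraction(res, atom) <= 1.0


def test_unknown_residue_code_raises():
    with pytest.raises(ValueError):
        build_labeling_scheme({"kind": "forward", "labeled": "GAXZ"})


def test_non_carbon_query_raises(forward_gavls):
    with pytest.raises(ValueError):
        forward_gavls.carbon_fraction("L", "N")


def test_bundled_schemes_build():
    schemes = bundled_schemes()
    assert "GAVLS(W)" in schemes
    assert "2-TEMPQANDSG" in schemes
    # reverse scheme: name-giving residues carry the glycerol pattern,
    # others are unlabeled
    rev = schemes["2-TEMPQANDSG"]
    assert rev.carbon_fraction("T", "CA") > 0.0
    assert rev.carbon_fraction("W", "CA") == 0.0


@pytest.mark.parametrize("fa,fb,kept", [
    (1.0, 1.0, True),    # fully labeled pair
    (0.5, 0.15, False),  # 0.075 fails the strict 10% rule
    (0.4, 0.3, True),    # 0.12 passes
    (1.0, 0.10, False),  # exactly 0.10 is NOT "exceeded"
])
def test_ten_percent_product_rule(fa, fb, kept):
    scheme = build_labeling_scheme({
        "kind": "uniform",
        "enrichment_overrides": {"A": {"CA": fa}, "V": {"CB": fb}}})
    assert pair_observability(scheme, ("A", "CA"), ("V", "CB")) == pytest.approx(fa * fb)
    assert pair_observable(scheme, ("A", "CA"), ("V", "CB")) is kept


@settings(max_examples=30, deadline=None, derandomize=True)
@given(res_a=st.sampled_from(RESIDUE_TYPES), res_b=st.sampled_from(RESIDUE_TYPES))
def test_pair_observability_symmetric(res_a, res_b):
    scheme = build_labeling_scheme({"kind": "glycerol_2"})
    a = (res_a, "CA")
    b = (res_b, "CB" if res_b != "G" else "CA")
    assert pair_observability(scheme, a, b) == pytest.approx(
        pair_observability(scheme, b, a))


def test_uniform_scheme_every_pair_observable():
    scheme = build_labeling_scheme({"kind": "uniform"})
    for res in ("A", "L", "K", "W"):
        assert pair_observable(scheme, (res, "CA"), ("V", "CB"))


def test_forward_unlabeled_pair_filtered(forward_gavls):
    # any pair involving an unlabeled, non-accidental residue drops out
    assert not pair_observable(forward_gavls, ("F", "CA"), ("L", "CA"))
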