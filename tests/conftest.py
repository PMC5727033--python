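import numpy as np
import pytest

from adrpipe.io_nmr import ShiftEntry, ShiftList, spectrum_hnhh, spectrum_hnhhnh
from adrpipe.synth import PeakSimConfig, SheetSpec, build_ideal_sheet, simulate_shifts


@pytest.fixture(scope="session")
def small_sheet():
    """Two antiparallel strands of six residues with a 3-residue loop."""
    spec = SheetSpec(n_strands=2, residues_per_strand=6, loop_length=3, seed=3)
    return build_ideal_sheet(spec)


@pytest.fixture(scope="session")
def small_shifts(small_sheet):
    return simulate_shifts(small_sheet, seed=3)


@pytest.fixture(scope="session")
def amide_spectra():
    return [spectrum_hnhh(), spectrum_hnhhnh()]


@pytest.fixture
def tiny_shifts():
    """Hand-written shift list for matching micro-cases."""
    return ShiftList([
        ShiftEntry(75, "Y", "N", 115.4),
        ShiftEntry(75, "Y", "H", 8.25),
        ShiftEntry(87, "L", "N", 121.3),
        ShiftEntry(87, "L", "H", 9.20),
        ShiftEntry(12, "V", "N", 109.0),
        ShiftEntry(12, "V", "H", 7.10),
    ])
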