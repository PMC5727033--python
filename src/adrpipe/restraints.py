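"""Restraint generation from peak lists, shift lists and labeling schemes.

The central object is the ambiguous distance restraint (ADR): a pair of
distance bounds attached to every atom-pair assignment compatible with the
peak position within per-dimension chemical-shift tolerances.  Amide-amide
ADRs from the paired 3D 1H-detected spectra are sharpened by the four-fold
cross-peak redundancy of that spectrum pair; 13C-13C ADRs are pre-filtered
by the sample's labeling scheme.  Hydrogen-bond and torsion restraints are
emitted from derived evidence and a TALOS-style prediction table.

Matching is boundary-inclusive: a shift matches a peak position when
``|delta| <= tolerance``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_nmr import PeakList, ShiftList, SpectrumDef
from .labeling import LabelingScheme, pair_observability

logger = logging.getLogger(__name__)

#: distance classes for 1H-1H restraints (strong / regular), Angstrom
H_CLASS_STRONG = (1.0, 3.5)
H_CLASS_REGULAR = (1.0, 5.5)
#: single distance class for 13C-13C restraints
C_CLASS_SINGLE = (1.5, 8.0)
#: two-class alternative keyed by mixing time
C_CLASS_BY_MIXING = {"darr_short": (1.5, 5.5), "darr_medium": (1.5, 5.5),
                     "darr_long": (1.5, 7.0)}

#: labeling-product cutoff: keep an option iff product > this (strict)
MIN_LABELING_PRODUCT = 0.10

#: default aliphatic 13C window in ppm (both dimensions)
ALIPHATIC_REGION = (5.0, 75.0)

#: hydrogen-bond restraint bounds, Angstrom
HBOND_BOUNDS = {"H_O": (1.73, 2.70), "N_O": (2.52, 3.93)}

#: TALOS classes accepted as reliable predictions
RELIABLE_TALOS_CLASSES = frozenset({"Good", "Strong"})


@dataclass
class AssignmentOption:
    """One candidate atom pair explaining a cross peak."""

    atom_a: tuple[int, str]  # (residue_number, atom_name)
    atom_b: tuple[int, str]
    labeling_product: float = 1.0
    support_count: int = 1

    def __post_init__(self) -> None:
        if self.atom_a == self.atom_b:
            raise ValueError("assignment option with identical atoms")
        if self.atom_a[0] == self.atom_b[0]:
            raise ValueError("assignment option must be inter-residue")

    @property
    def key(self) -> tuple:
        return tuple(sorted((self.atom_a, self.atom_b)))

    @property
    def residue_pair(self) -> tuple[int, int]:
        return tuple(sorted((self.atom_a[0], self.atom_b[0])))

    @property
    def sequential(self) -> bool:
        return abs(self.atom_a[0] - self.atom_b[0]) == 1


@dataclass
class AmbiguousDistanceRestraint:
    options: list[AssignmentOption]
    lower: float
    upper: float
    source_peaks: list[int] = field(default_factory=list)
    spectrum: SpectrumDef | None = None
    active: bool = True
    #: evidence-complete option list the iterative loop may re-select from;
    #: ``options`` is the currently selected working subset
    full_options: list[AssignmentOption] | None = None

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"lower bound {self.lower} must be below upper {self.upper}")
        if self.active and not self.options:
            raise ValueError("active restraint with empty option set")

    @property
    def ambiguity(self) -> int:
        return len(self.options)

    def option_keys(self) -> frozenset:
        return frozenset(o.key for o in self.options)


@dataclass(frozen=True)
class HBondRestraint:
    donor_residue: int
    acceptor_residue: int
    kind: str  # "H_O" or "N_O"
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.kind not in HBOND_BOUNDS:
            raise ValueError(f"unknown hydrogen-bond restraint kind {self.kind!r}")
        if (self.lower, self.upper) != HBOND_BOUNDS[self.kind]:
            raise ValueError(f"{self.kind} bounds must be {HBOND_BOUNDS[self.kind]}")


@dataclass(frozen=True)
class TorsionRestraint:
    residue: int
    angle: str  # "phi" or "psi"
    center: float  # degrees
    half_width: float

    def __post_init__(self) -> None:
        if self.angle not in ("phi", "psi"):
            raise ValueError(f"unknown torsion angle {self.angle!r}")
        if not -180.0 < self.center <= 180.0:
            raise ValueError("torsion center must lie in (-180, 180]")
        if self.half_width <= 0:
            raise ValueError("torsion half-width must be positive")


# --------------------------------------------------------------------------
# 1H-1H matching
# --------------------------------------------------------------------------

def _amide_residues(shifts: ShiftList) -> list[int]:
    withN = {e.residue_number for e in shifts.by_atom("N")}
    withH = {e.residue_number for e in shifts.by_atom("H")}
    return sorted(withN & withH)


def _amide_dim_matches(peak_pos: float, nucleus: str, tol: float,
                       shifts: ShiftList, residues: list[int]) -> set[int]:
    atom = "N" if nucleus == "N" else "H"
    out = set()
    for r in residues:
        s = shifts.get(r, atom)
        if s is not None and abs(peak_pos - s) <= tol + 1e-9:
            out.add(r)
    return out


def match_peaks_h(peaks: PeakList, shifts: ShiftList,
                  spectrum: SpectrumDef | None = None) -> list[AmbiguousDistanceRestraint]:
    """Shift-match amide-amide peaks of one 3D 1H-detected spectrum.

    Every combination of residues consistent with the peak position in all
    dimensions becomes an assignment option between the two amide protons;
    auto-correlation matches (same residue on both sides) are discarded.
    Peaks matching nothing are logged and yield no restraint.  Bounds start
    in the regular class; :func:`classify_h_bounds` re-classifies by
    intensity.
    """
    spectrum = spectrum or peaks.spectrum
    if len(shifts) == 0:
        raise ValueError("empty shift list")
    residues = _amide_residues(shifts)
    if not residues:
        raise ValueError("shift list carries no amide N/H entries; wrong shift "
                         "list for a 1H-detected spectrum")
    if "C" in spectrum.dimension_nuclei:
        raise ValueError(f"{spectrum.name} is not an amide-amide spectrum")

    lower, upper = H_CLASS_REGULAR
    adrs = []
    for peak in peaks.peaks:
        origin: set[int] | None = None
        dest: set[int] | None = None
        for pos, nuc, role, tol in zip(peak.positions, spectrum.dimension_nuclei,
                                       spectrum.dimension_roles, spectrum.tolerances):
            cand = _amide_dim_matches(pos, nuc, tol, shifts, residues)
            if role == "origin":
                origin = cand if origin is None else origin & cand
            else:
                dest = cand if dest is None else dest & cand
        origin = origin or set()
        dest = dest or set()
        if origin & dest:
            # explainable as an auto-correlation peak: discarded, since the
            # diagonal assignment always dominates a chance cross match
            continue
        options = []
        for i in sorted(origin):
            for j in sorted(dest):
                options.append(AssignmentOption((i, "H"), (j, "H")))
        # the same amide pair may appear from both (i,j) and (j,i); keep one
        seen = {}
        for o in options:
            seen.setdefault(o.key, o)
        options = list(seen.values())
        if not options:
            logger.warning("peak %d of %s matched nothing within tolerance",
                           peak.id, spectrum.name)
            continue
        adrs.append(AmbiguousDistanceRestraint(options, lower, upper,
                                               source_peaks=[peak.id],
                                               spectrum=spectrum))
    return adrs


def peak_supports_direction(peak, spectrum: SpectrumDef, shifts: ShiftList,
                            res_origin: int, res_dest: int) -> bool:
    """True if the peak is consistent with magnetization flowing from
    ``res_origin`` to ``res_dest``, using the spectrum's own tolerances."""
    for pos, nuc, role, tol in zip(peak.positions, spectrum.dimension_nuclei,
                                   spectrum.dimension_roles, spectrum.tolerances):
        res = res_origin if role == "origin" else res_dest
        atom = "N" if nuc == "N" else "H"
        s = shifts.get(res, atom)
        if s is None or abs(pos - s) > tol + 1e-9:
            return False
    return True


def _cross_peaks(pl: PeakList, shifts: ShiftList) -> list:
    """Peaks that cannot be explained as an auto-correlation.

    A peak consistent with (a -> a) for any residue a is treated as
    diagonal and carries no cross-peak evidence; only the remaining peaks
    may support an assignment option.
    """
    residues = _amide_residues(shifts)
    out = []
    for p in pl.peaks:
        if any(peak_supports_direction(p, pl.spectrum, shifts, a, a)
               for a in residues):
            continue
        out.append(p)
    return out


def amide_pair_support(res_i: int, res_j: int, peaklists: list[PeakList],
                       shifts: ShiftList, cross_only: dict | None = None) -> int:
    """Cross-peak support for one amide pair across the paired 3D spectra.

    Counts the (spectrum, transfer direction) slots in which at least one
    non-diagonal peak is consistent with the pair, so a fully visible pair
    scores the maximal four (two directions x two spectra) and shift
    overlap cannot inflate the count beyond that.
    """
    count = 0
    for pl in peaklists:
        peaks = (cross_only[id(pl)] if cross_only is not None
                 else _cross_peaks(pl, shifts))
        for a, b in ((res_i, res_j), (res_j, res_i)):
            if any(peak_supports_direction(p, pl.spectrum, shifts, a, b)
                   for p in peaks):
                count += 1
    return count


def count_support(adrs: list[AmbiguousDistanceRestraint],
                  peaklists: list[PeakList], shifts: ShiftList) -> None:
    """Fill ``support_count`` of every option by counting consistent peaks
    across the paired spectra (in place on the options)."""
    cross = {id(pl): _cross_peaks(pl, shifts) for pl in peaklists}
    cache: dict[tuple[int, int], int] = {}
    for adr in adrs:
        for opt in adr.options:
            pair = opt.residue_pair
            if pair not in cache:
                cache[pair] = amide_pair_support(pair[0], pair[1], peaklists,
                                                 shifts, cross)
            # the peak an option was generated from always supports it
            opt.support_count = max(cache[pair], 1)


def redundancy_filter(adrs: list[AmbiguousDistanceRestraint]
                      ) -> list[AmbiguousDistanceRestraint]:
    """Prune options using the four-fold redundancy of the paired spectra.

    If the best option of a restraint is supported by four peaks, options
    supported by only one or two are removed; if the best support is three,
    options supported by a single peak are removed.  Support counts must
    already be present (:func:`count_support`).  Restraints are modified in
    place and returned; a restraint whose option list empties is deactivated.
    """
    for adr in adrs:
        if not adr.options:
            continue
        best = max(o.support_count for o in adr.options)
        if best >= 4:
            kept = [o for o in adr.options if o.support_count not in (1, 2)]
        elif best == 3:
            kept = [o for o in adr.options if o.support_count != 1]
        else:
            kept = list(adr.options)
        adr.options = kept
        if not adr.options:
            adr.active = False
    return adrs


def classify_h_bounds(adrs: list[AmbiguousDistanceRestraint],
                      peaks: PeakList) -> list[AmbiguousDistanceRestraint]:
    """Assign the two 1H-1H distance classes by intensity sorting.

    The threshold is the intensity of the most intense peak whose restraint
    carries a sequential (|i-j| = 1) assignment option.  Peaks strictly
    stronger go to the strong class (1.0-3.5 A); peaks less or equally
    intense stay in the regular class (1.0-5.5 A).  Without any sequential
    peak everything stays regular (conservative) with a warning.
    """
    if not adrs:
        return adrs
    by_peak = {}
    for adr in adrs:
        for pid in adr.source_peaks:
            by_peak[pid] = adr
    threshold = None
    for peak in sorted(peaks.peaks, key=lambda p: p.intensity, reverse=True):
        adr = by_peak.get(peak.id)
        if adr is not None and any(o.sequential for o in adr.options):
            threshold = peak.intensity
            break
    if threshold is None:
        warnings.warn("no peak with a sequential assignment option; all "
                      "restraints kept in the 1.0-5.5 A class", stacklevel=2)
        for adr in adrs:
            adr.lower, adr.upper = H_CLASS_REGULAR
        return adrs
    intensity_of = {p.id: p.intensity for p in peaks.peaks}
    for adr in adrs:
        inten = max(intensity_of[pid] for pid in adr.source_peaks)
        adr.lower, adr.upper = (H_CLASS_STRONG if inten > threshold
                                else H_CLASS_REGULAR)
    return adrs


# --------------------------------------------------------------------------
# 13C-13C matching
# --------------------------------------------------------------------------

def exclude_intra_and_region(long_mix: PeakList, short_mix: PeakList | None,
                             region: tuple[tuple[float, float], tuple[float, float]]
                             = (ALIPHATIC_REGION, ALIPHATIC_REGION),
                             tol: tuple[float, float] | None = None) -> PeakList:
    """Drop long-mixing peaks that also appear at short mixing (intra-residue
    signals) and peaks outside the aliphatic window."""
    if tol is None:
        tol = tuple(long_mix.spectrum.tolerances)
    kept = []
    for p in long_mix.peaks:
        if not all(lo <= x <= hi for x, (lo, hi) in zip(p.positions, region)):
            continue
        if short_mix is not None and any(
                all(abs(x - y) <= t for x, y, t in zip(p.positions, q.positions, tol))
                for q in short_mix.peaks):
            continue
        kept.append(p)
    return PeakList(long_mix.spectrum, kept)


def match_peaks_c(peaks: PeakList, shifts: ShiftList,
                  spectrum: SpectrumDef | None = None,
                  scheme: LabelingScheme | None = None, *,
                  min_product: float = MIN_LABELING_PRODUCT,
                  class_mode: str = "single",
                  region: tuple[tuple[float, float], tuple[float, float]]
                  = (ALIPHATIC_REGION, ALIPHATIC_REGION)
                  ) -> list[AmbiguousDistanceRestraint]:
    """Shift-match aliphatic 13C-13C peaks under a labeling scheme.

    Intra-residue candidate pairs are excluded; an option survives only when
    the product of the two 13C enrichment fractions exceeds ``min_product``
    (strict).  ``class_mode`` picks the bounds: "single" puts every
    restraint at 1.5-8.0 A, "by_mixing" uses 1.5-5.5 / 1.5-7.0 A for
    medium / long DARR mixing.
    """
    spectrum = spectrum or peaks.spectrum
    scheme = scheme or spectrum.sample
    if scheme is None:
        raise ValueError("13C-13C matching needs a labeling scheme")
    if len(shifts) == 0:
        raise ValueError("empty shift list")
    if class_mode == "single":
        lower, upper = C_CLASS_SINGLE
    elif class_mode == "by_mixing":
        lower, upper = C_CLASS_BY_MIXING.get(spectrum.mixing_class, C_CLASS_SINGLE)
    else:
        raise ValueError(f"unknown class_mode {class_mode!r}")

    carbons = [e for e in shifts.carbons()
               if region[0][0] <= e.shift <= region[0][1]]
    adrs = []
    for peak in peaks.peaks:
        cands = []
        for pos, tolppm in zip(peak.positions, spectrum.tolerances):
            cands.append([e for e in carbons if abs(pos - e.shift) <= tolppm + 1e-9])
        options = {}
        for ea in cands[0]:
            for eb in cands[1]:
                if ea.residue_number == eb.residue_number:
                    continue  # intra-residue option excluded
                product = pair_observability(
                    scheme, (ea.residue_type, ea.atom_name),
                    (eb.residue_type, eb.atom_name))
                if product <= min_product:
                    continue
                opt = AssignmentOption((ea.residue_number, ea.atom_name),
                                       (eb.residue_number, eb.atom_name),
                                       labeling_product=product)
                options.setdefault(opt.key, opt)
        if not options:
            logger.warning("13C peak %d of %s left no labeling-consistent "
                           "inter-residue option", peak.id, spectrum.name)
            continue
        adrs.append(AmbiguousDistanceRestraint(list(options.values()), lower, upper,
                                               source_peaks=[peak.id],
                                               spectrum=spectrum))
    return adrs


# --------------------------------------------------------------------------
# hydrogen-bond and torsion restraints
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CoupleEvidence:
    """Gate evidence for one candidate hydrogen-bonded residue couple."""

    beta_a: bool  # TALOS beta-sheet classification of the first residue
    beta_b: bool
    support_count: int  # amide cross peaks across the paired 3D spectra


def emit_hbond_restraints(couples: list[tuple[int, int]],
                          evidence: dict[tuple[int, int], CoupleEvidence]
                          ) -> tuple[list[HBondRestraint], list[tuple[tuple[int, int], str]]]:
    """Emit co-linear hydrogen-bond restraints for qualifying couples.

    A couple qualifies when both residues are classified beta-sheet and the
    full four-peak amide cross-peak pattern is present.  Each qualifying
    couple yields exactly two restraints: H-O at 1.73-2.70 A and N-O at
    2.52-3.93 A.  Returns (restraints, rejected couples with reasons).
    """
    seen = set()
    restraints = []
    rejected = []
    for couple in couples:
        key = tuple(sorted(couple))
        if key in seen:
            raise ValueError(f"duplicate hydrogen-bond couple {couple}")
        seen.add(key)
        ev = evidence.get(couple) or evidence.get((couple[1], couple[0]))
        if ev is None:
            rejected.append((couple, "no evidence"))
            continue
        if not (ev.beta_a and ev.beta_b):
            rejected.append((couple, "not beta-sheet in torsion prediction"))
            continue
        if ev.support_count < 4:
            rejected.append((couple, "incomplete cross-peak pattern"))
            continue
        donor, acceptor = couple
        restraints.append(HBondRestraint(donor, acceptor, "H_O", *HBOND_BOUNDS["H_O"]))
        restraints.append(HBondRestraint(donor, acceptor, "N_O", *HBOND_BOUNDS["N_O"]))
    return restraints, rejected


def is_beta(phi: float, psi: float) -> bool:
    """Coarse beta-region test on predicted torsions."""
    return -180.0 <= phi <= -80.0 and 90.0 <= psi <= 180.0


def emit_torsion_restraints(talos_table: pd.DataFrame,
                            reliable_classes=RELIABLE_TALOS_CLASSES
                            ) -> list[TorsionRestraint]:
    """Two restraints (phi and psi) per reliably predicted residue."""
    out = []
    for idx, row in talos_table.iterrows():
        try:
            resid = int(row["RESID"])
            phi, psi = float(row["PHI"]), float(row["PSI"])
            dphi, dpsi = float(row["DPHI"]), float(row["DPSI"])
            cls = str(row["CLASS"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed TALOS row {idx}: {exc}") from None
        if not all(np.isfinite(v) for v in (phi, psi, dphi, dpsi)):
            raise ValueError(f"malformed TALOS row {idx}: non-finite angles")
        if cls not in reliable_classes:
            continue
        out.append(TorsionRestraint(resid, "phi", phi, dphi))
        out.append(TorsionRestraint(resid, "psi", psi, dpsi))
    return out
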