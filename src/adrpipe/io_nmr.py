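"""Readers and writers for every format the pipeline touches.

Shift lists (simple tabular or an NMR-STAR subset), Sparky-style peak
lists, TALOS-style torsion prediction tables, CNS-style ``.tbl`` restraint
files, and PDB coordinates.  All readers/writers round-trip and none
mutates its input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

from .structures import AA1, AA3, ATOM_ORDER, Model, StructureEnsemble, model_from_backbone

_ATOM_ALIASES = {"HN": "H", "CO": "C", "C'": "C", "15N": "N", "NH": "N"}


def normalize_atom(name: str) -> str:
    name = name.strip().upper()
    return _ATOM_ALIASES.get(name, name)


# --------------------------------------------------------------------------
# shift lists
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftEntry:
    residue_number: int
    residue_type: str  # 1-letter code
    atom_name: str
    shift: float


@dataclass
class ShiftList:
    """Assigned chemical shifts, unique per (residue_number, atom_name)."""

    entries: list[ShiftEntry] = field(default_factory=list)
    deuterated_variant: bool = False

    def __post_init__(self) -> None:
        seen: dict[tuple[int, str], ShiftEntry] = {}
        dups = []
        for e in self.entries:
            key = (e.residue_number, e.atom_name)
            if key in seen:
                dups.append(key)
            seen[key] = e
            if not np.isfinite(e.shift):
                raise ValueError(f"non-finite shift for residue {e.residue_number} {e.atom_name}")
        if dups:
            raise ValueError("duplicate (residue, atom) shift entries: "
                             + ", ".join(f"{r}/{a}" for r, a in dups))
        self._index = seen
        self._sanity_check()

    def _sanity_check(self) -> None:
        for e in self.entries:
            if e.atom_name == "N" and not 90.0 <= e.shift <= 140.0:
                warnings.warn(f"15N shift {e.shift} ppm of residue {e.residue_number} "
                              "outside 90-140 ppm", stacklevel=3)
            if e.atom_name == "H" and not 5.0 <= e.shift <= 12.0:
                warnings.warn(f"amide 1H shift {e.shift} ppm of residue {e.residue_number} "
                              "outside 5-12 ppm", stacklevel=3)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, residue_number: int, atom_name: str) -> float | None:
        e = self._index.get((residue_number, atom_name))
        return None if e is None else e.shift

    def residue_type(self, residue_number: int) -> str | None:
        for e in self.entries:
            if e.residue_number == residue_number:
                return e.residue_type
        return None

    def by_atom(self, atom_name: str) -> list[ShiftEntry]:
        return [e for e in self.entries if e.atom_name == atom_name]

    def carbons(self) -> list[ShiftEntry]:
        return [e for e in self.entries if e.atom_name.startswith("C")]


def load_shift_list(path, dialect: str = "tabular", *,
                    deuterated_variant: bool = False) -> ShiftList:
    """Read a shift list.

    ``tabular``: whitespace-separated columns ``residue_number residue_type
    atom_name shift`` ('#' comments allowed).  ``nmrstar-subset``: a minimal
    NMR-STAR reader that understands the ``_Atom_chem_shift`` loop columns
    Seq_ID / Comp_ID / Atom_ID / Val.
    """
    if dialect == "tabular":
        return _load_shift_tabular(path, deuterated_variant)
    if dialect == "nmrstar-subset":
        return _load_shift_nmrstar(path, deuterated_variant)
    raise ValueError(f"unknown shift-list dialect {dialect!r}")


def _load_shift_tabular(path, deuterated: bool) -> ShiftList:
    entries = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
            resnum, restype, atom, shift = parts
            try:
                entries.append(ShiftEntry(int(resnum), restype.upper(),
                                          normalize_atom(atom), float(shift)))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed row ({exc})") from None
    return ShiftList(entries, deuterated_variant=deuterated)


def _load_shift_nmrstar(path, deuterated: bool) -> ShiftList:
    """Tiny NMR-STAR subset reader for one _Atom_chem_shift loop."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    entries = []
    i = 0
    while i < len(lines):
        if lines[i] == "loop_":
            tags = []
            i += 1
            while i < len(lines) and lines[i].startswith("_"):
                tags.append(lines[i])
                i += 1
            if any(t.startswith("_Atom_chem_shift.") for t in tags):
                cols = {t.split(".", 1)[1]: k for k, t in enumerate(tags)}
                for need in ("Seq_ID", "Comp_ID", "Atom_ID", "Val"):
                    if need not in cols:
                        raise ValueError(f"NMR-STAR loop lacks _Atom_chem_shift.{need}")
                while i < len(lines) and lines[i] not in ("stop_",):
                    if lines[i] and not lines[i].startswith("#"):
                        vals = lines[i].split()
                        comp = vals[cols["Comp_ID"]].upper()
                        restype = AA1.get(comp, comp[:1])
                        entries.append(ShiftEntry(int(vals[cols["Seq_ID"]]), restype,
                                                  normalize_atom(vals[cols["Atom_ID"]]),
                                                  float(vals[cols["Val"]])))
                    i += 1
        i += 1
    return ShiftList(entries, deuterated_variant=deuterated)


def write_shift_list(shifts: ShiftList, path) -> None:
    with open(path, "w") as fh:
        fh.write("# residue_number residue_type atom_name shift_ppm\n")
        for e in shifts.entries:
            fh.write(f"{e.residue_number:5d} {e.residue_type} {e.atom_name:<4s} {e.shift:9.3f}\n")


# --------------------------------------------------------------------------
# spectra and peak lists
# --------------------------------------------------------------------------

MIXING_CLASSES = ("rfdr_2ms", "darr_short", "darr_medium", "darr_long")

#: default distance class (lower, upper) in Angstrom per mixing class;
#: rfdr peaks are split into two classes later by intensity sorting
DEFAULT_DISTANCE_CLASS = {
    "rfdr_2ms": (1.0, 5.5),
    "darr_short": (1.5, 5.5),
    "darr_medium": (1.5, 5.5),
    "darr_long": (1.5, 7.0),
}


@dataclass(frozen=True)
class SpectrumDef:
    """Geometry and matching metadata of one spectrum type.

    ``dimension_nuclei`` entries are drawn from {H_direct, H_indirect, N, C};
    ``dimension_roles`` say which residue of the mixed pair each dimension
    reports: "origin" (the residue whose magnetization starts the mixing)
    or "destination".
    """

    name: str
    dimension_nuclei: tuple[str, ...]
    dimension_roles: tuple[str, ...]
    tolerances: tuple[float, ...]  # ppm, per dimension
    mixing_class: str
    sample: object | None = None  # LabelingScheme for 13C spectra

    def __post_init__(self) -> None:
        if not (len(self.dimension_nuclei) == len(self.dimension_roles)
                == len(self.tolerances)):
            raise ValueError("dimension metadata lengths differ")
        for nuc in self.dimension_nuclei:
            if nuc not in ("H_direct", "H_indirect", "N", "C"):
                raise ValueError(f"unknown dimension nucleus {nuc!r}")
        for role in self.dimension_roles:
            if role not in ("origin", "destination"):
                raise ValueError(f"unknown dimension role {role!r}")
        for tol in self.tolerances:
            if tol <= 0:
                raise ValueError("tolerances must be positive")
        if self.mixing_class not in MIXING_CLASSES:
            raise ValueError(f"unknown mixing class {self.mixing_class!r}")

    @property
    def ndim(self) -> int:
        return len(self.dimension_nuclei)

    def distance_class(self) -> tuple[float, float]:
        return DEFAULT_DISTANCE_CLASS[self.mixing_class]


# Paper-default matching tolerances: 0.4 ppm for 15N, 0.1 ppm for the
# indirect 1H dimension, 0.7 ppm for the directly detected 1H dimension,
# 0.4 ppm for 13C.
TOL_N = 0.4
TOL_H_INDIRECT = 0.1
TOL_H_DIRECT = 0.7
TOL_C = 0.4


def spectrum_hnhh(*, tol_n: float = TOL_N, tol_h_ind: float = TOL_H_INDIRECT,
                  tol_h_dir: float = TOL_H_DIRECT) -> SpectrumDef:
    """(H)NHH: N(i), H(i) indirect, H(j) direct after 1H-1H mixing."""
    return SpectrumDef("HNHH", ("N", "H_indirect", "H_direct"),
                       ("origin", "origin", "destination"),
                       (tol_n, tol_h_ind, tol_h_dir), "rfdr_2ms")


def spectrum_hnhhnh(*, tol_n: float = TOL_N, tol_h_dir: float = TOL_H_DIRECT) -> SpectrumDef:
    """(H)N(HH)NH: N(i), N(j), H(j) direct; mixing happens between the Ns."""
    return SpectrumDef("HNHHNH", ("N", "N", "H_direct"),
                       ("origin", "destination", "destination"),
                       (tol_n, tol_n, tol_h_dir), "rfdr_2ms")


def spectrum_darr(mixing_class: str = "darr_medium", sample=None, *,
                  tol_c: float = TOL_C, name: str | None = None) -> SpectrumDef:
    """2D 13C-13C DARR spectrum bound to a labeling scheme."""
    return SpectrumDef(name or f"DARR_{mixing_class}", ("C", "C"),
                       ("origin", "destination"), (tol_c, tol_c),
                       mixing_class, sample)


@dataclass(frozen=True)
class Peak:
    positions: tuple[float, ...]  # ppm per dimension
    intensity: float
    id: int


@dataclass
class PeakList:
    spectrum: SpectrumDef
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in self.peaks:
            if len(p.positions) != self.spectrum.ndim:
                raise ValueError(f"peak {p.id} dimensionality {len(p.positions)} "
                                 f"!= spectrum {self.spectrum.ndim}")
            if not np.isfinite(p.intensity):
                raise ValueError(f"peak {p.id} has non-finite intensity")

    def __len__(self) -> int:
        return len(self.peaks)


def load_peak_list(path, spectrum_def: SpectrumDef) -> PeakList:
    """Read a peak list: one position column per dimension plus intensity.

    Sparky-style headers ("Assignment w1 w2 ... Data Height") and a leading
    non-numeric assignment column are tolerated.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0].lower() in ("assignment",) or parts[0].startswith("w1"):
                continue  # Sparky header
            rows.append(parts)
    peaks = []
    nd = spectrum_def.ndim
    for k, parts in enumerate(rows):
        cols = parts
        try:
            float(cols[0])
        except ValueError:
            cols = cols[1:]  # Sparky assignment label
        if len(cols) != nd + 1:
            raise ValueError(f"{path}: row {k + 1} has {len(cols)} numeric columns, "
                             f"expected {nd + 1} for a {nd}D spectrum")
        vals = [float(x) for x in cols]
        peaks.append(Peak(tuple(vals[:nd]), vals[nd], id=k))
    return PeakList(spectrum_def, peaks)


def write_peak_list(peaklist: PeakList, path) -> None:
    nd = peaklist.spectrum.ndim
    with open(path, "w") as fh:
        fh.write("# " + " ".join(f"w{i + 1}" for i in range(nd)) + " intensity\n")
        for p in peaklist.peaks:
            fh.write(" ".join(f"{x:10.3f}" for x in p.positions)
                     + f" {p.intensity:14.6g}\n")


# --------------------------------------------------------------------------
# TALOS-style torsion prediction tables
# --------------------------------------------------------------------------

TALOS_COLUMNS = ["RESID", "RESNAME", "PHI", "PSI", "DPHI", "DPSI", "CLASS"]


def load_talos(path) -> pd.DataFrame:
    """Read a TALOS-style prediction table (VARS/FORMAT header optional)."""
    rows = []
    cols = TALOS_COLUMNS
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("REMARK", "DATA", "FORMAT", "#")):
                continue
            if s.startswith("VARS"):
                cols = s.split()[1:]
                continue
            parts = s.split()
            if len(parts) != len(cols):
                raise ValueError(f"{path}:{ln}: expected {len(cols)} fields, got {len(parts)}")
            row = dict(zip(cols, parts))
            try:
                rows.append({
                    "RESID": int(row["RESID"]),
                    "RESNAME": row["RESNAME"],
                    "PHI": float(row["PHI"]),
                    "PSI": float(row["PSI"]),
                    "DPHI": float(row["DPHI"]),
                    "DPSI": float(row["DPSI"]),
                    "CLASS": row["CLASS"],
                })
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{ln}: malformed row ({exc})") from None
    return pd.DataFrame(rows, columns=TALOS_COLUMNS)


def write_talos(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("VARS " + " ".join(TALOS_COLUMNS) + "\n")
        fh.write("FORMAT %4d %s %8.3f %8.3f %8.3f %8.3f %s\n")
        for _, r in table.iterrows():
            fh.write(f"{int(r.RESID):4d} {r.RESNAME} {r.PHI:8.3f} {r.PSI:8.3f} "
                     f"{r.DPHI:8.3f} {r.DPSI:8.3f} {r.CLASS}\n")


# --------------------------------------------------------------------------
# restraint files
# --------------------------------------------------------------------------

def write_restraints(restraints, path, dialect: str = "cns_tbl") -> None:
    """Serialize distance restraints.

    ``cns_tbl``: one ``assign`` statement per restraint with OR continuation
    lines for extra assignment options; bounds are emitted as
    ``d dminus dplus`` with ``d = upper``, ``dminus = upper - lower`` and
    ``dplus = 0`` so the asymmetric distance classes survive exactly.
    ``tabular``: one line per option with bounds and support counts.
    """
    if dialect == "cns_tbl":
        _write_cns(restraints, path)
    elif dialect == "tabular":
        _write_tabular(restraints, path)
    else:
        raise ValueError(f"unknown restraint dialect {dialect!r}")


def _sel(res: int, atom: str) -> str:
    return f"(resid {res:d} and name {atom})"


def _write_cns(restraints, path) -> None:
    with open(path, "w") as fh:
        for r in restraints:
            if not r.options:
                raise ValueError("restraint with empty assignment option set")
            d = r.upper
            dminus = r.upper - r.lower
            first, *rest = r.options
            fh.write(f"assign {_sel(*first.atom_a)} {_sel(*first.atom_b)} "
                     f"{d:.2f} {dminus:.2f} 0.00\n")
            for opt in rest:
                fh.write(f"  or {_sel(*opt.atom_a)} {_sel(*opt.atom_b)}\n")


def _write_tabular(restraints, path) -> None:
    with open(path, "w") as fh:
        fh.write("# restraint option res_a atom_a res_b atom_b lower upper "
                 "support labeling_product active spectrum\n")
        for i, r in enumerate(restraints):
            if not r.options:
                raise ValueError("restraint with empty assignment option set")
            spec = r.spectrum.name if r.spectrum is not None else "-"
            for k, opt in enumerate(r.options):
                fh.write(f"{i:5d} {k:3d} {opt.atom_a[0]:5d} {opt.atom_a[1]:<4s} "
                         f"{opt.atom_b[0]:5d} {opt.atom_b[1]:<4s} "
                         f"{r.lower:6.2f} {r.upper:6.2f} {opt.support_count:3d} "
                         f"{opt.labeling_product:8.4f} {int(r.active):d} {spec}\n")


def read_restraints(path, dialect: str = "cns_tbl"):
    """Read distance restraints written by :func:`write_restraints`."""
    from .restraints import AmbiguousDistanceRestraint, AssignmentOption

    out = []
    if dialect == "cns_tbl":
        import re
        pat = re.compile(r"\(resid\s+(-?\d+)\s+and\s+name\s+(\S+)\)")
        with open(path) as fh:
            for line in fh:
                s = line.strip()
                if not s or s.startswith("!"):
                    continue
                atoms = [(int(r), a.upper()) for r, a in pat.findall(s)]
                if s.startswith("assign"):
                    nums = [float(x) for x in s.replace(")", ") ").split()[-3:]]
                    d, dminus, _ = nums
                    out.append(AmbiguousDistanceRestraint(
                        options=[AssignmentOption(atoms[0], atoms[1])],
                        lower=d - dminus, upper=d))
                elif s.startswith("or"):
                    out[-1].options.append(AssignmentOption(atoms[0], atoms[1]))
                else:
                    raise ValueError(f"unrecognized line in {path}: {s!r}")
        return out
    if dialect == "tabular":
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                         names=["restraint", "option", "res_a", "atom_a", "res_b",
                                "atom_b", "lower", "upper", "support", "product",
                                "active", "spectrum"])
        for _, grp in df.groupby("restraint", sort=True):
            opts = [AssignmentOption((int(g.res_a), g.atom_a), (int(g.res_b), g.atom_b),
                                     labeling_product=float(g.product),
                                     support_count=int(g.support))
                    for g in grp.itertuples()]
            first = grp.iloc[0]
            out.append(AmbiguousDistanceRestraint(
                options=opts, lower=float(first.lower), upper=float(first.upper),
                active=bool(first.active)))
        return out
    raise ValueError(f"unknown restraint dialect {dialect!r}")


def write_hbond_restraints(restraints, path) -> None:
    with open(path, "w") as fh:
        for r in restraints:
            atom_d = "H" if r.kind == "H_O" else "N"
            fh.write(f"assign (resid {r.donor_residue} and name {atom_d}) "
                     f"(resid {r.acceptor_residue} and name O) "
                     f"{r.upper:.2f} {r.upper - r.lower:.2f} 0.00\n")


def write_torsion_restraints(restraints, path) -> None:
    with open(path, "w") as fh:
        fh.write("# residue angle center_deg half_width_deg\n")
        for r in restraints:
            fh.write(f"{r.residue:5d} {r.angle:<3s} {r.center:8.2f} {r.half_width:7.2f}\n")


# --------------------------------------------------------------------------
# coordinates
# --------------------------------------------------------------------------

def read_structure(path) -> StructureEnsemble:
    """Read PDB coordinates into a backbone ensemble.

    Missing amide protons are rebuilt from N/CA/C geometry and the ensemble
    is flagged ``h_reconstructed``.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    models = []
    sequence = None
    resnums = None
    any_h_missing = False
    for gm in st:
        if len(gm) == 0:
            raise ValueError(f"{path}: model without chains")
        chain = gm[0]
        seq = []
        nums = []
        coords = []
        for res in chain:
            one = AA1.get(res.name.upper())
            if one is None:
                continue
            seq.append(one)
            nums.append(res.seqid.num)
            row = np.full((6, 3), np.nan)
            for atom in res:
                name = normalize_atom(atom.name)
                if name in ATOM_ORDER:
                    i = ATOM_ORDER.index(name)
                    row[i] = [atom.pos.x, atom.pos.y, atom.pos.z]
            coords.append(row)
        if not coords:
            raise ValueError(f"{path}: chain without standard residues")
        coords = np.array(coords)
        seq = "".join(seq)
        hs = coords[:, ATOM_ORDER.index("H"), :]
        need_h = np.any(np.isnan(hs).all(axis=1) & np.array([a != "P" for a in seq]))
        if need_h:
            any_h_missing = True
            H = geometry_rebuild_h(coords, seq)
            coords[:, ATOM_ORDER.index("H"), :] = H
        m = Model(coords, seq, np.array(nums))
        models.append(m)
        if sequence is None:
            sequence, resnums = seq, np.array(nums)
    ens = StructureEnsemble(sequence, resnums, models,
                            provenance={"source": str(path)},
                            h_reconstructed=any_h_missing)
    return ens


def geometry_rebuild_h(coords: np.ndarray, sequence: str) -> np.ndarray:
    from . import geometry
    N = coords[:, ATOM_ORDER.index("N"), :]
    CA = coords[:, ATOM_ORDER.index("CA"), :]
    C = coords[:, ATOM_ORDER.index("C"), :]
    H = geometry.add_amide_hydrogens(N, CA, C)
    for i, aa in enumerate(sequence):
        if aa == "P":
            H[i] = np.nan
    return H


def write_structure(ensemble: StructureEnsemble, path) -> None:
    st = gemmi.Structure()
    st.name = "adrpipe"
    for k, m in enumerate(ensemble.models):
        gm = gemmi.Model(k + 1)
        chain = gemmi.Chain("A")
        for i, aa in enumerate(m.sequence):
            res = gemmi.Residue()
            res.name = AA3[aa]
            res.seqid = gemmi.SeqId(int(m.resnums[i]), " ")
            for j, atom_name in enumerate(ATOM_ORDER):
                xyz = m.coords[i, j]
                if np.any(np.isnan(xyz)):
                    continue
                at = gemmi.Atom()
                at.name = atom_name
                at.element = gemmi.Element(atom_name[0])
                at.pos = gemmi.Position(*xyz)
                res.add_atom(at)
            chain.add_residue(res)
        gm.add_chain(chain)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
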