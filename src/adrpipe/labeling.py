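"""Isotope labeling schemes and pair observability.

Amino-acid-type selective 13C labeling decides which carbon-carbon
correlations a DARR spectrum can show at all: an assignment option for a
cross peak is only physical if *both* carbons are substantially enriched in
the sample.  The pipeline models a sample as a :class:`LabelingScheme`
mapping ``(residue_type, atom_name)`` to an enrichment fraction and keeps an
option when the product of the two fractions exceeds a threshold (default
0.10, strict).

Scheme kinds
------------
``forward``
    A set of 13C,15N-labeled amino acids added to unlabeled medium: listed
    residue types are enriched at the nominal level (optionally on a subset
    of carbons), everything else is at zero except "accidental" residues
    that pick up label through active biosynthetic pathways.
``reverse``
    Growth on [2-13C]- or [1,3-13C]-glycerol with the complement of the
    target set added in unlabeled form: the name-giving residues carry the
    glycerol pattern.
``uniform``
    Every carbon at the nominal enrichment.
``glycerol_2`` / ``glycerol_1_3``
    All residue types carry the corresponding glycerol pattern (see
    ``data/glycerol_13c_patterns.yaml``; the per-atom values come from the
    labeling literature, not from a measurement made here, and can be
    overridden per descriptor).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

VALID_KINDS = {"forward", "reverse", "uniform", "glycerol_1_3", "glycerol_2"}

# carbons the enrichment map is defined over, per residue type
_SIDECHAIN_CARBONS = {
    "A": ["CB"], "R": ["CB", "CG", "CD", "CZ"], "N": ["CB", "CG"],
    "D": ["CB", "CG"], "C": ["CB"], "Q": ["CB", "CG", "CD"],
    "E": ["CB", "CG", "CD"], "G": [], "H": ["CB", "CG"],
    "I": ["CB", "CG1", "CG2", "CD1"], "L": ["CB", "CG", "CD1", "CD2"],
    "K": ["CB", "CG", "CD", "CE"], "M": ["CB", "CG", "CE"],
    "F": ["CB", "CG", "CD1", "CD2", "CZ"], "P": ["CB", "CG", "CD"],
    "S": ["CB"], "T": ["CB", "CG2"], "W": ["CB", "CG"],
    "Y": ["CB", "CG", "CD1", "CD2", "CZ"], "V": ["CB", "CG1", "CG2"],
}
RESIDUE_TYPES = sorted(_SIDECHAIN_CARBONS)

_CARBON_ATOMS = {res: ["CA", "C"] + side for res, side in _SIDECHAIN_CARBONS.items()}


def carbon_atoms(residue_type: str) -> list[str]:
    """Carbons covered by the enrichment map for one residue type."""
    try:
        return list(_CARBON_ATOMS[residue_type])
    except KeyError:
        raise ValueError(f"unknown residue code {residue_type!r}") from None


def _load_yaml(name: str) -> dict:
    path = importlib.resources.files("adrpipe.data") / name
    with path.open() as fh:
        return yaml.safe_load(fh)


_GLYCEROL_PATTERNS: dict | None = None


def glycerol_pattern_table() -> dict:
    """The versioned [2-13C]/[1,3-13C]-glycerol enrichment table."""
    global _GLYCEROL_PATTERNS
    if _GLYCEROL_PATTERNS is None:
        _GLYCEROL_PATTERNS = _load_yaml("glycerol_13c_patterns.yaml")
    return _GLYCEROL_PATTERNS


@dataclass
class LabelingScheme:
    """Per-residue-type, per-atom isotope enrichment for one sample."""

    name: str
    kind: str
    enrichment: dict[tuple[str, str], float] = field(default_factory=dict)
    nitrogen_enrichment: dict[str, float] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        for key, frac in self.enrichment.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"enrichment fraction out of [0,1] for {key}: {frac}")
        for res, frac in self.nitrogen_enrichment.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"15N fraction out of [0,1] for {res}: {frac}")

    def carbon_fraction(self, residue_type: str, atom_name: str) -> float:
        """13C enrichment for one carbon; errors on non-carbons and unknowns."""
        if residue_type not in _CARBON_ATOMS:
            raise ValueError(f"unknown residue code {residue_type!r}")
        if not atom_name.startswith("C"):
            raise ValueError(f"{atom_name!r} is not a carbon atom")
        try:
            return self.enrichment[(residue_type, atom_name)]
        except KeyError:
            raise KeyError(
                f"no enrichment entry for ({residue_type}, {atom_name}) in "
                f"scheme {self.name!r}"
            ) from None


def _glycerol_fractions(base: str, residue_type: str) -> dict[str, float]:
    table = glycerol_pattern_table()
    try:
        per_res = table[base]
    except KeyError:
        raise ValueError(f"no glycerol pattern table for {base!r}") from None
    if residue_type not in per_res:
        raise ValueError(f"glycerol table {base!r} has no entry for residue {residue_type!r}")
    row = per_res[residue_type]
    out = {}
    for atom in _CARBON_ATOMS[residue_type]:
        if atom not in row:
            raise ValueError(
                f"glycerol pattern table {base!r} is missing atom {atom} of "
                f"residue {residue_type}"
            )
        out[atom] = float(row[atom])
    return out


def build_labeling_scheme(spec: dict, *, accidental_fraction: float = 0.3,
                          nominal: float = 1.0) -> LabelingScheme:
    """Build a complete enrichment map from a scheme descriptor.

    ``spec`` is a mapping with at least ``kind`` (and usually ``name``);
    forward/reverse kinds take ``labeled`` (one-letter residue string),
    optional ``accidental``, optional per-residue ``atom_subset``, reverse
    additionally ``base`` in {glycerol_2, glycerol_1_3}.  Arbitrary per-atom
    values can be forced via ``enrichment_overrides`` entries of the form
    ``{residue: {atom: fraction}}``.

    The result covers all 20 residue types over backbone and principal
    side-chain carbons; the map is deterministic for a given descriptor.
    """
    kind = spec.get("kind")
    if kind not in VALID_KINDS:
        raise ValueError(f"descriptor must name a valid kind, got {kind!r}")
    name = spec.get("name", kind)
    labeled = spec.get("labeled", "") or ""
    accidental = spec.get("accidental", "") or ""
    for code in labeled + accidental:
        if code not in _CARBON_ATOMS:
            raise ValueError(f"unknown residue code {code!r} in descriptor {name!r}")
    atom_subset = spec.get("atom_subset", {}) or {}
    acc_frac = float(spec.get("accidental_fraction", accidental_fraction))
    nom = float(spec.get("nominal", nominal))

    enrichment: dict[tuple[str, str], float] = {}
    for res in RESIDUE_TYPES:
        atoms = _CARBON_ATOMS[res]
        if kind == "uniform":
            fracs = {a: nom for a in atoms}
        elif kind in ("glycerol_2", "glycerol_1_3"):
            fracs = _glycerol_fractions(kind, res)
        elif kind == "forward":
            if res in labeled:
                subset = atom_subset.get(res)
                fracs = {a: (nom if subset is None or a in subset else 0.0)
                         for a in atoms}
            elif res in accidental:
                subset = atom_subset.get(res)
                fracs = {a: (acc_frac if subset is None or a in subset else 0.0)
                         for a in atoms}
            else:
                fracs = {a: 0.0 for a in atoms}
        else:  # reverse
            base = spec.get("base")
            if base not in ("glycerol_2", "glycerol_1_3"):
                raise ValueError(f"reverse descriptor {name!r} needs base glycerol kind")
            if res in labeled:
                fracs = _glycerol_fractions(base, res)
            elif res in accidental:
                fracs = {a: acc_frac * f for a, f in _glycerol_fractions(base, res).items()}
            else:
                fracs = {a: 0.0 for a in atoms}
        for a, f in fracs.items():
            enrichment[(res, a)] = f

    for res, atom_fracs in (spec.get("enrichment_overrides") or {}).items():
        for a, f in atom_fracs.items():
            if res not in _CARBON_ATOMS or a not in _CARBON_ATOMS[res]:
                raise ValueError(f"override targets unknown atom ({res}, {a})")
            enrichment[(res, a)] = float(f)

    nitrogen = {res: 1.0 for res in RESIDUE_TYPES}  # 15N medium in all preparations
    notes = spec.get("notes", "")
    if accidental:
        notes = (notes + f" accidental: {accidental} at {acc_frac}").strip()
    return LabelingScheme(name=name, kind=kind, enrichment=enrichment,
                          nitrogen_enrichment=nitrogen, notes=notes)


def bundled_schemes(**kwargs) -> dict[str, LabelingScheme]:
    """The study's scheme descriptors, built into full schemes."""
    raw = _load_yaml("labeling_schemes.yaml")["schemes"]
    return {d["name"]: build_labeling_scheme(d, **kwargs) for d in raw}


def pair_observability(scheme: LabelingScheme, atom_a: tuple[str, str],
                       atom_b: tuple[str, str]) -> float:
    """Probability that both carbons of a candidate pair are 13C.

    ``atom_a``/``atom_b`` are ``(residue_type, atom_name)``.  Returns the
    product of the two enrichment fractions; symmetric in its arguments.
    """
    fa = scheme.carbon_fraction(*atom_a)
    fb = scheme.carbon_fraction(*atom_b)
    return fa * fb


def pair_observable(scheme: LabelingScheme, atom_a: tuple[str, str],
                    atom_b: tuple[str, str], *, min_product: float = 0.10) -> bool:
    """Keep an assignment option iff the labeling product exceeds the cutoff
    (strict inequality)."""
    return pair_observability(scheme, atom_a, atom_b) > min_product
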