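"""End-to-end orchestration of the restraint pipeline.

Glues the stages together the way the study ran them: shift-match the
paired amide spectra, sharpen by four-fold redundancy, classify bounds by
intensity, shift-match the carbon spectra under the labeling scheme, run
the iterative disambiguation protocol, then derive co-linear hydrogen-bond
restraints from the converged ensemble (full cross-peak pattern, beta-sheet
torsion prediction, and hydrogen-bond geometry realized in the bundle) and
compute a final ensemble with them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_nmr import PeakList, ShiftList
from .protocol import ProtocolConfig, ProtocolState, merge_equivalent, run_protocol
from .refine import AnnealConfig, anneal
from .restraints import (CoupleEvidence, amide_pair_support, classify_h_bounds,
                         count_support, emit_hbond_restraints,
                         emit_torsion_restraints, exclude_intra_and_region,
                         is_beta, match_peaks_c, match_peaks_h,
                         redundancy_filter)
from .structures import StructureEnsemble

logger = logging.getLogger(__name__)


def build_h_restraints(peaklists: list[PeakList], shifts: ShiftList):
    """Amide-amide ADRs from the paired 3D spectra: match, count the
    four-fold redundancy, prune, and classify bounds per spectrum."""
    adrs = []
    per_spectrum = []
    for pl in peaklists:
        a = match_peaks_h(pl, shifts)
        per_spectrum.append((a, pl))
        adrs.extend(a)
    count_support(adrs, peaklists, shifts)
    redundancy_filter(adrs)
    for a, pl in per_spectrum:
        classify_h_bounds(a, pl)
    return adrs


def build_c_restraints(long_mix: PeakList, short_mix: PeakList | None,
                       shifts: ShiftList, scheme=None,
                       class_mode: str = "by_mixing", **kwargs):
    """Aliphatic 13C-13C ADRs: intra-residue/region exclusion, labeling
    filter, and merging of equivalent restraints.

    The default two-class bounds (1.5-5.5 A medium / 1.5-7.0 A long
    mixing) carry more structural information than the single 1.5-8.0 A
    class; pass ``class_mode="single"`` for the latter.
    """
    peaks = exclude_intra_and_region(long_mix, short_mix)
    adrs = match_peaks_c(peaks, shifts, long_mix.spectrum, scheme,
                         class_mode=class_mode, **kwargs)
    return merge_equivalent(adrs)


def beta_residues(talos) -> set[int]:
    """Residues reliably predicted in the beta region."""
    out = set()
    for _, row in talos.iterrows():
        if row.CLASS in ("Good", "Strong") and is_beta(row.PHI, row.PSI):
            out.add(int(row.RESID))
    return out


def _beta_strand_runs(beta: set[int], min_len: int = 3) -> list[list[int]]:
    runs = []
    cur: list[int] = []
    for r in sorted(beta):
        if cur and r == cur[-1] + 1:
            cur.append(r)
        else:
            if len(cur) >= min_len:
                runs.append(cur)
            cur = [r]
    if len(cur) >= min_len:
        runs.append(cur)
    return runs


def derive_hbond_couples(h_adrs, peaklists, shifts, beta: set[int],
                         ensemble: StructureEnsemble, n_select: int = 5,
                         min_registry_score: float = 4.0,
                         min_separation: int = 3):
    """Hydrogen-bonded residue couples read off the disambiguated data.

    In an antiparallel sheet every couple between two strands shares one
    residue-number sum (the registry offset), and the mutually
    hydrogen-bonded ("narrow") couples occupy alternating lattice
    positions of that offset.  The derivation therefore (i) lets the
    selected assignment options between two beta-strand runs vote for an
    offset, weighted by restraint ambiguity, and (ii) picks the offset and
    parity whose lattice carries the strongest disambiguated peak
    intensity - narrow couples sit at ~3.3 A and give the dominant cross
    peaks.  Strand pairs whose vote never reaches ``min_registry_score``
    are not hydrogen-bond partners.  The four-peak support and beta
    prediction of every couple are returned as gate evidence.
    """
    strands = _beta_strand_runs(beta)
    strand_of = {r: k for k, run in enumerate(strands) for r in run}
    strand_sets = [set(run) for run in strands]
    models = ensemble.lowest(n_select)

    votes: dict[tuple[int, int], dict[int, float]] = {}
    assigned_intensity: dict[tuple[int, int], float] = {}
    intensity_of = {}
    for pl in peaklists:
        intensity_of[pl.spectrum.name] = {p.id: p.intensity for p in pl.peaks}
    for adr in h_adrs:
        if not adr.active or not adr.options:
            continue
        peak_int = 0.0
        if adr.spectrum is not None and adr.spectrum.name in intensity_of:
            peak_int = max(intensity_of[adr.spectrum.name].get(pid, 0.0)
                           for pid in adr.source_peaks)
        for o in adr.options:
            pair = o.residue_pair
            assigned_intensity[pair] = max(assigned_intensity.get(pair, 0.0),
                                           peak_int / adr.ambiguity)
            i, j = pair
            if abs(i - j) < min_separation:
                continue
            ka, kb = strand_of.get(i), strand_of.get(j)
            if ka is None or kb is None or ka == kb:
                continue
            key = (min(ka, kb), max(ka, kb))
            votes.setdefault(key, {}).setdefault(i + j, 0.0)
            votes[key][i + j] += 1.0 / adr.ambiguity

    def median_hn(pair):
        try:
            return float(np.median([m.distance(pair[0], "H", pair[1], "H")
                                    for m in models]))
        except KeyError:
            return np.inf

    raw_peaks = {id(pl): pl.peaks for pl in peaklists}
    couples = []
    evidence = {}
    for (ka, kb), offs in sorted(votes.items()):
        ranked = sorted(offs.items(), key=lambda kv: -kv[1])
        if ranked[0][1] < min_registry_score:
            continue
        classes = []
        for off, score in ranked[:2]:
            if score < 0.5 * ranked[0][1]:
                continue
            lattice = [(i, off - i) for i in strands[ka]
                       if off - i in strand_sets[kb]]
            for parity in (0, 1):
                cls = [p for p in lattice if p[0] % 2 == parity]
                if len(cls) < 2:
                    continue
                strength = float(np.mean(
                    [assigned_intensity.get(tuple(sorted(p)), 0.0) for p in cls]))
                classes.append((strength, off, cls))
        if not classes:
            continue
        classes.sort(key=lambda c: -c[0])
        _, _, cls = classes[0]
        for pair in cls:
            i, j = pair
            key = (min(i, j), max(i, j))
            if key in evidence or median_hn(pair) > 6.0:
                continue
            support = amide_pair_support(i, j, peaklists, shifts, raw_peaks)
            couples.append(key)
            evidence[key] = CoupleEvidence(i in beta, j in beta, support)
    return sorted(couples), evidence


@dataclass
class PipelineResult:
    h_adrs: list
    c_adrs: list
    torsions: list
    hbonds: list
    rejected_couples: list
    state: ProtocolState
    final_ensemble: StructureEnsemble


def run_pipeline(sequence: str, amide_peaklists, shifts, talos,
                 darr_pairs=(),
                 protocol_config: ProtocolConfig | None = None,
                 anneal_config: AnnealConfig | None = None,
                 chain_breaks=()) -> PipelineResult:
    """The whole analysis on one set of inputs.

    ``darr_pairs`` holds (long-mixing, short-mixing) peak-list pairs, one
    per carbon-detected sample; each long-mixing spectrum carries its
    labeling scheme.  Runs the iterative protocol on the amide and carbon
    ADRs plus torsion restraints, then derives hydrogen-bond restraints
    from the converged bundle and computes a final ensemble with them.
    """
    protocol_config = protocol_config or ProtocolConfig.desk_scale()
    h_adrs = build_h_restraints(list(amide_peaklists), shifts)
    c_adrs = []
    for darr_long, darr_short in darr_pairs:
        c_adrs.extend(build_c_restraints(darr_long, darr_short, shifts,
                                         darr_long.spectrum.sample))
    c_adrs = merge_equivalent(c_adrs)
    torsions = emit_torsion_restraints(talos)
    state = run_protocol(sequence, h_adrs, c_adrs, torsions, (),
                         config=protocol_config, anneal_config=anneal_config,
                         chain_breaks=chain_breaks, final_run=False)
    beta = beta_residues(talos)
    couples, evidence = derive_hbond_couples(
        [a for a in state.h_adrs if a.active], list(amide_peaklists), shifts,
        beta, state.final_ensemble, n_select=protocol_config.n_select)
    hbonds, rejected = emit_hbond_restraints(couples, evidence)
    final = state.final_ensemble
    if hbonds:
        # the subsequent full calculation: the complete (freshly matched)
        # restraint lists re-enter together with the hydrogen bonds, and
        # the final bundle is the converged subset of the new ensemble
        import dataclasses

        from .refine import select_converged

        acfg = dataclasses.replace(anneal_config or AnnealConfig(),
                                   n_models=protocol_config.n_structures,
                                   seed=protocol_config.seed * 1009 + 777)
        full = anneal(sequence, h_adrs + c_adrs, torsions, hbonds, acfg,
                      chain_breaks)
        core = sorted({t.residue for t in torsions})
        final = select_converged(full, core or None,
                                 n_select=protocol_config.n_select)
    return PipelineResult(state.h_adrs, state.c_adrs, torsions, hbonds,
                          rejected, state, final)
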