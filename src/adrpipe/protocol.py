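"""ARIA-style iterative disambiguation loop.

Restraints enter on a schedule (amide-amide restraints and torsions from
the start, the more ambiguous carbon-carbon restraints later), each
iteration refines an ensemble against the active restraints, and the
lowest-pseudo-energy models drive violation analysis (restraints not
satisfiable in at least half of the selected models are deactivated, never
deleted) and option pruning (the smallest weight-ordered prefix of options
reaching the ambiguity cutoff survives).  Carbon restraints are combined
4-to-4 during their first iterations; equivalent restraints are merged
afterwards.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .refine import AnnealConfig, anneal
from .restraints import AmbiguousDistanceRestraint
from .structures import Model, StructureEnsemble

logger = logging.getLogger(__name__)


@dataclass
class ProtocolConfig:
    """Schedule of the iterative protocol.

    Defaults mirror the full-scale reference protocol: nine iterations
    (numbered 0-8), 200 structures per iteration of which the 15
    lowest-energy drive disambiguation, amide restraints from iteration 0,
    carbon restraints from iteration 4, 4-to-4 combination of the carbon
    restraints in iterations 4-6, and rejection of restraints unsatisfied
    in at least half of the selected models.  ``desk_scale`` gives the
    reduced schedule used for end-to-end runs on one CPU.
    """

    n_iterations: int = 9
    n_structures: int = 200
    n_select: int = 15
    h_from_iteration: int = 0
    c_from_iteration: int = 4
    combine_iterations: tuple[int, int] = (4, 6)  # inclusive range
    combine_arity: int = 4
    # per-iteration violation tolerance (A); first iteration effectively
    # unfiltered, mirroring common ARIA schedules (not printed in any paper)
    violation_tolerance: tuple[float, ...] = (1000.0, 5.0, 3.0, 1.0, 1.0,
                                              1.0, 0.1, 0.1, 0.1)
    satisfied_fraction: float = 0.5
    # ambiguity cutoff schedule: fraction of summed option weight retained
    ambiguity_cutoff: tuple[float, ...] = (1.0, 0.99, 0.98, 0.96, 0.93,
                                           0.90, 0.85, 0.80, 0.80)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_select > self.n_structures:
            raise ValueError("n_select cannot exceed n_structures")
        lo, hi = self.combine_iterations
        if not (0 <= lo <= hi < max(self.n_iterations, 1)):
            raise ValueError("combine_iterations must lie within the protocol")

    def tolerance(self, iteration: int) -> float:
        sched = self.violation_tolerance
        return sched[min(iteration, len(sched) - 1)]

    def cutoff(self, iteration: int) -> float:
        sched = self.ambiguity_cutoff
        return sched[min(iteration, len(sched) - 1)]

    def min_satisfied(self) -> int:
        # "at least half" with an odd selection size rounds up
        return math.ceil(self.satisfied_fraction * self.n_select)

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "ProtocolConfig":
        """Five-iteration schedule with 20 structures/iteration."""
        return cls(n_iterations=5, n_structures=20, n_select=5,
                   c_from_iteration=2, combine_iterations=(2, 3),
                   violation_tolerance=(1000.0, 3.0, 2.0, 1.0, 0.5),
                   ambiguity_cutoff=(1.0, 0.97, 0.92, 0.86, 0.80),
                   seed=seed)


@dataclass
class ViolationRecord:
    restraint_index: int
    satisfied_count: int
    effective_distances: list[float]
    decision: str  # "kept" | "rejected"


@dataclass
class ViolationReport:
    iteration: int
    tolerance: float
    n_select: int
    records: list[ViolationRecord] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return sum(r.decision == "rejected" for r in self.records)


def effective_distance(model: Model, adr: AmbiguousDistanceRestraint) -> float:
    """r^-6-pooled distance over the restraint's assignment options.

    Equals the plain distance for a single option and is never longer than
    the shortest option distance.
    """
    if not adr.options:
        raise ValueError("restraint has no assignment options")
    total = 0.0
    for o in adr.options:
        d = model.distance(o.atom_a[0], o.atom_a[1], o.atom_b[0], o.atom_b[1])
        total += d ** -6
    return total ** (-1.0 / 6.0)


def violation_analysis(adrs: list[AmbiguousDistanceRestraint],
                       ensemble: StructureEnsemble, config: ProtocolConfig,
                       iteration: int = 0) -> ViolationReport:
    """Deactivate restraints unsatisfied in too many selected models.

    A restraint is satisfied in a model iff
    ``lower - tol <= effective_distance <= upper + tol``; it is kept iff
    satisfied in at least ``ceil(satisfied_fraction * n_select)`` of the
    ``n_select`` lowest-energy models.  Rejected restraints are flagged
    inactive (soft delete), never removed from the list.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    models = ensemble.lowest(config.n_select)
    tol = config.tolerance(iteration)
    need = config.min_satisfied()
    report = ViolationReport(iteration, tol, len(models))
    for idx, adr in enumerate(adrs):
        if not adr.active:
            continue
        dists = [effective_distance(m, adr) for m in models]
        sat = sum(adr.lower - tol <= d <= adr.upper + tol for d in dists)
        decision = "kept" if sat >= need else "rejected"
        if decision == "rejected":
            adr.active = False
        report.records.append(ViolationRecord(idx, sat, dists, decision))
    return report


def prune_options(adr: AmbiguousDistanceRestraint, ensemble: StructureEnsemble,
                  ambiguity_cutoff: float, n_select: int | None = None
                  ) -> AmbiguousDistanceRestraint:
    """Re-select the smallest weight-ordered option prefix reaching the
    cutoff.

    Option weights are the mean r^-6 contributions over the selected
    models, normalized to unit sum.  Pruning is cumulative across
    iterations (the selection only ever contracts), which acts as a
    consistency annealing: the surviving option sets must jointly explain
    the ensembles of every iteration so far.  With cutoff 1.0 every option
    survives.  Modified in place and returned.
    """
    base = adr.options
    if len(base) <= 1:
        return adr
    models = ensemble.lowest(n_select) if n_select else ensemble.models
    weights = []
    for o in base:
        try:
            contrib = [m.distance(o.atom_a[0], o.atom_a[1],
                                  o.atom_b[0], o.atom_b[1]) ** -6
                       for m in models]
        except KeyError:
            contrib = [0.0]
        weights.append(np.mean(contrib))
    weights = np.array(weights)
    total = weights.sum()
    if total <= 0:
        return adr
    weights = weights / total
    order = np.argsort(weights, kind="stable")[::-1]
    cum = 0.0
    kept = []
    for k in order:
        kept.append(k)
        cum += weights[k]
        if cum >= ambiguity_cutoff - 1e-12:
            break
    kept = kept[:max(len(adr.options), 1)]  # ambiguity never grows
    kept = sorted(kept)
    adr.options = [base[k] for k in kept]
    return adr


def combine_restraints(adrs: list[AmbiguousDistanceRestraint], arity: int = 4,
                       rng: np.random.Generator | int | None = None
                       ) -> list[AmbiguousDistanceRestraint]:
    """Merge random groups of ``arity`` restraints into one wider ADR each.

    The combined restraint carries the union of the options and the widest
    bounds of its group; leftover restraints (fewer than ``arity``) pass
    through unchanged.  Grouping is reproducible for a seeded generator.
    """
    if arity < 2:
        raise ValueError("combination arity must be at least 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    active = [r for r in adrs if r.active]
    inactive = [r for r in adrs if not r.active]
    order = rng.permutation(len(active))
    out = []
    for start in range(0, len(active) - len(active) % arity, arity):
        group = [active[k] for k in order[start:start + arity]]
        options = {}
        peaks: list[int] = []
        for r in group:
            for o in r.options:
                options.setdefault(o.key, o)
            peaks.extend(r.source_peaks)
        out.append(AmbiguousDistanceRestraint(
            list(options.values()),
            lower=min(r.lower for r in group),
            upper=max(r.upper for r in group),
            source_peaks=peaks, spectrum=group[0].spectrum))
    leftover = [active[k] for k in order[len(active) - len(active) % arity:]]
    return out + leftover + inactive


def merge_equivalent(adrs: list[AmbiguousDistanceRestraint]
                     ) -> list[AmbiguousDistanceRestraint]:
    """Merge restraints with identical option sets (order-insensitive),
    keeping the tighter upper bound and pooling source peaks."""
    by_key: dict[frozenset, AmbiguousDistanceRestraint] = {}
    out = []
    for r in adrs:
        if not r.active:
            out.append(r)
            continue
        key = r.option_keys()
        prev = by_key.get(key)
        if prev is None:
            r = copy.copy(r)
            r.source_peaks = list(r.source_peaks)
            by_key[key] = r
            out.append(r)
        else:
            prev.upper = min(prev.upper, r.upper)
            prev.lower = max(prev.lower, r.lower)
            prev.source_peaks.extend(r.source_peaks)
    return out


# --------------------------------------------------------------------------
# the loop
# --------------------------------------------------------------------------

@dataclass
class IterationRecord:
    iteration: int
    n_active_h: int
    n_active_c: int
    n_restraints_used: int
    mean_ambiguity: float
    n_rejected: int
    best_energy: float


@dataclass
class ProtocolState:
    config: ProtocolConfig
    history: list[IterationRecord] = field(default_factory=list)
    reports: list[ViolationReport] = field(default_factory=list)
    final_ensemble: StructureEnsemble | None = None
    h_adrs: list = field(default_factory=list)
    c_adrs: list = field(default_factory=list)

    def audit_rows(self) -> list[dict]:
        return [vars(r) for r in self.history]


def _mean_ambiguity(adrs) -> float:
    active = [r for r in adrs if r.active]
    if not active:
        return 0.0
    return float(np.mean([r.ambiguity for r in active]))


def run_protocol(sequence: str, h_adrs, c_adrs=(), torsions=(), hbonds=(),
                 config: ProtocolConfig | None = None,
                 anneal_config: AnnealConfig | None = None,
                 refiner=anneal, chain_breaks=(), final_run: bool = True
                 ) -> ProtocolState:
    """Run the iterative disambiguation protocol.

    Iterations before ``c_from_iteration`` use only the amide-amide
    restraints (plus torsions); carbon restraints join afterwards, combined
    4-to-4 during the configured iterations.  After each iteration the
    selected lowest-energy models drive violation analysis and option
    pruning.  When ``final_run`` is set and hydrogen-bond restraints are
    supplied, one more ensemble is computed with them included.

    The refiner must accept ``(sequence, distance_restraints, torsions,
    hbonds, config, chain_breaks)`` and return a
    :class:`~adrpipe.structures.StructureEnsemble` with pseudo-energies.
    """
    config = config or ProtocolConfig.desk_scale()
    base_anneal = anneal_config or AnnealConfig()
    state = ProtocolState(config=config,
                          h_adrs=[copy.deepcopy(r) for r in h_adrs],
                          c_adrs=[copy.deepcopy(r) for r in c_adrs])
    for adr in state.h_adrs + state.c_adrs:
        if adr.full_options is None:
            adr.full_options = list(adr.options)
    ensemble = None
    for it in range(config.n_iterations):
        pool = [r for r in state.h_adrs if r.active]
        use_c = it >= config.c_from_iteration
        c_pool = [r for r in state.c_adrs if r.active] if use_c else []
        lo, hi = config.combine_iterations
        if use_c and lo <= it <= hi and c_pool:
            rng = np.random.default_rng(config.seed + 1000 + it)
            c_pool = merge_equivalent(combine_restraints(
                c_pool, config.combine_arity, rng))
        restraints = pool + c_pool
        if not restraints:
            raise RuntimeError(f"iteration {it}: no active restraints")
        acfg = dataclasses.replace(base_anneal, n_models=config.n_structures,
                            seed=config.seed * 1009 + it)
        try:
            ensemble = refiner(sequence, restraints, torsions, (),
                               acfg, chain_breaks)
        except Exception:
            logger.exception("refiner failed at iteration %d; state dump: %s",
                             it, state.audit_rows())
            raise
        report = violation_analysis(state.h_adrs + (state.c_adrs if use_c else []),
                                    ensemble, config, it)
        cutoff = config.cutoff(it)
        for adr in state.h_adrs + (state.c_adrs if use_c else []):
            if adr.active:
                prune_options(adr, ensemble, cutoff, config.n_select)
        state.reports.append(report)
        state.history.append(IterationRecord(
            iteration=it,
            n_active_h=sum(r.active for r in state.h_adrs),
            n_active_c=sum(r.active for r in state.c_adrs) if use_c else 0,
            n_restraints_used=len(restraints),
            mean_ambiguity=_mean_ambiguity(state.h_adrs + state.c_adrs),
            n_rejected=report.n_rejected,
            best_energy=float(np.min(ensemble.pseudo_energies)),
        ))
        logger.info("iteration %d: %d restraints, %d rejected, mean ambiguity %.2f",
                    it, len(restraints), report.n_rejected,
                    state.history[-1].mean_ambiguity)
    if final_run and hbonds:
        pool = [r for r in state.h_adrs if r.active] + \
               [r for r in state.c_adrs if r.active]
        acfg = dataclasses.replace(base_anneal, n_models=config.n_structures,
                            seed=config.seed * 1009 + config.n_iterations)
        ensemble = refiner(sequence, pool, torsions, tuple(hbonds),
                           acfg, chain_breaks)
    state.final_ensemble = ensemble
    return state
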