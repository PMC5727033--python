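# Methods

## The problem

Magic-angle-spinning (MAS) NMR of a membrane protein in lipid bilayers
yields cross peaks whose positions are pairs (or triples) of chemical
shifts, not atom identities. Within a matching tolerance, many atom pairs
can explain each peak. The standard answer is the ambiguous distance
restraint (ADR): a distance bound attached to *every* compatible
assignment, interpreted during structure calculation through
r⁻⁶-pooled effective distances, and sharpened iteratively against the
evolving structure ensemble. `adrpipe` implements this restraint-generation
and iterative-disambiguation machinery for β-barrel membrane proteins and
exercises it end to end on synthetic data.

## Restraint generation

**Amide–amide restraints.** The paired 3D (H)NHH and (H)N(HH)NH spectra
(2 ms RFDR ¹H–¹H mixing) are shift-matched with 0.4 ppm tolerance in the
¹⁵N dimension(s), 0.1 ppm in the indirectly detected ¹H dimension and
0.7 ppm in the directly detected ¹H dimension (boundary-inclusive,
|Δ| ≤ tol). Every residue pair consistent with a peak in all dimensions
becomes an assignment option between the two amide protons. A peak whose
origin and destination candidate sets intersect is explainable as an
auto-correlation (diagonal) peak and is discarded.

A spatially close amide pair produces up to four cross peaks: two transfer
directions in each of the two spectra. An option's *support* is the number
of (spectrum × direction) slots that contain at least one consistent
non-diagonal peak, so support is at most four and cannot be inflated by
shift overlap; the option's own source peak always counts, so support is
at least one. The redundancy rule then prunes: if a restraint's best
option has support four, options with support one or two are removed; if
the best support is three, options with support one are removed.

Restraints are divided into two distance classes by intensity sorting per
spectrum: the threshold is the most intense peak that carries a sequential
(|Δresidue| = 1) assignment option; strictly stronger peaks are classified
1.0–3.5 Å, the rest 1.0–5.5 Å. Without any sequential peak everything
stays at 1.0–5.5 Å (conservative).

**Carbon–carbon restraints.** 2D DARR peak lists are restricted to the
aliphatic window (5–75 ppm default); peaks reproduced in a short-mixing
spectrum are removed as intra-residue signals. Matching uses 0.4 ppm in
both ¹³C dimensions, excludes intra-residue candidates, and keeps an
option only when the product of the two ¹³C enrichment fractions of the
sample's labeling scheme *exceeds* 10% (strict). Bounds are either a
single 1.5–8.0 Å class or, by default in the pipeline, two classes keyed
to the mixing time (1.5–5.5 Å medium, 1.5–7.0 Å long); the two-class mode
carries visibly more structural information and both modes are selectable.

**Labeling schemes.** A scheme maps (residue type, atom) to a ¹³C
enrichment fraction. Forward schemes enrich a listed amino-acid set at the
nominal level (optionally on a carbon subset, e.g. Phe/Tyr Cα/Cβ only);
residues picked up through active biosynthetic pathways ("accidental")
default to fraction 0.3 — the experiments report only "labeled to a lower
degree", so this is a configurable package choice. Reverse schemes give
the name-giving residues the [2-¹³C]- or [1,3-¹³C]-glycerol pattern. The
glycerol per-atom fractions are **not** measured here: they are an encoded
approximation of the metabolic-labeling literature (clean single positions
for the glycolytic family, ½ and ¼ fractions for residues drawn from the
citric-acid cycle), stored as a versioned data table and overridable per
descriptor. Scrambling is modeled only through the accidental fractions,
not as a pathway simulation.

**Hydrogen bonds and torsions.** Reliable rows of a TALOS-style prediction
table yield two torsion restraints (φ, ψ) with centers and half-widths
copied from the table. Co-linear hydrogen-bond restraints are emitted for
residue couples that pass two gates — β-sheet torsion prediction for both
residues and the complete four-peak amide pattern — as fixed pairs:
H–O 1.73–2.70 Å and N–O 2.52–3.93 Å.

The candidate couples are read off the converged bundle by *registry
inference*: in an antiparallel sheet every couple between two strands
shares one residue-number sum (the registry offset), and the mutually
hydrogen-bonded ("narrow") couples occupy alternating positions of that
offset. Selected assignment options between two β-strand runs vote for an
offset (weighted by 1/ambiguity); among candidate offsets and parities the
lattice carrying the strongest disambiguated peak intensity wins, since
narrow couples sit at ~3.3 Å and produce the dominant cross peaks. This
formalizes what is otherwise a manual inspection of the hydrogen-bonding
restraint pattern.

## The iterative protocol

The reference schedule is nine iterations (numbered 0–8) of 200 structures
each, with the 15 lowest-pseudo-energy models driving disambiguation;
amide restraints and torsions from iteration 0, carbon restraints from
iteration 4, 4-to-4 random combination of the carbon restraints in
iterations 4–6 followed by merging of restraints with identical option
sets (tighter upper bound wins). The desk-scale variant used throughout
the tests is five iterations of 20 structures with 5 selected, carbon
restraints from iteration 2 and combination in iterations 2–3.

*Violation analysis*: a restraint is satisfied in a model iff
lower − tol ≤ d_eff ≤ upper + tol with the per-iteration tolerance
schedule (effectively unfiltered in iteration 0, mirroring common
practice; the exact schedules of full-scale runs are not published, so the
defaults here are package choices). A restraint is kept iff satisfied in
at least ceil(0.5 · n_select) of the selected models — "at least half"
rounds up for odd selections. Rejection is a soft delete; the restraint
and its options remain for audit and the per-iteration history
reconstructs every decision.

*Option pruning*: option weights are the mean r⁻⁶ contributions over the
selected models, normalized; the smallest weight-ordered prefix reaching
the ambiguity cutoff survives (cutoff schedule decreasing from 1.0 to
0.8). Pruning is cumulative — the selection only contracts — which acts as
a consistency annealing: surviving options must jointly explain the
ensembles of all iterations so far. A re-selecting variant (recomputing
from the full option list each iteration) was evaluated and tracked decoy
ensembles instead of converging; the evidence-complete option list is kept
on each restraint (`full_options`) but the working selection never grows.

After the iterations, hydrogen-bond restraints are derived as above and a
*subsequent full calculation* yields the final structure: the complete,
freshly matched restraint lists re-enter together with the hydrogen bonds
(the loop's pruned selections are kept for reporting but are not imposed
on the final run, so an option mis-pruned against an early ensemble
cannot poison the final structure), and one more ensemble is computed.
The final bundle is the *converged subset* of that ensemble: networks
with residual false restraints (e.g. from degenerate auto-correlation
peaks) admit a few competing minima whose pseudo-energies overlap, but
converged models agree with each other while decoys scatter, so the
bundle is the cluster around the model with the most neighbours within
2 Å backbone RMSD over the torsion-restrained core, taking its
lowest-energy members.

## The refinement engine

The engine is a desk-scale restraint-satisfaction annealer, *not* a
molecular-dynamics code: no torsion-angle dynamics, no empirical force
field, no solvent refinement, no Ramachandran potential. The full-scale
annealing parameters (20,000 K torsion-angle high temperature, two
100,000-step cooling stages, 8,000 refinement steps, …) are stored for
provenance and executed scaled down (temperatures ÷ 10, step counts ÷ 100,
refinement ÷ 10).

The pseudo-energy is a sum of harmonic covalent terms (bonds plus
angle-equivalent 1–3 distances), smooth periodic wells for the peptide
plane (ω and the O–C–N–H improper) and the Cβ chirality improper
(1 − cos form: no derivative kink at the anti-target ridge), flat-bottom
torsion terms, flat-bottom distance terms over r⁻⁶-pooled effective
distances (zero inside [lower, upper], quadratic outside, force constant
25 Å⁻² by default), and a soft-sphere repulsion (minimum 1.8 Å, below the
hydrogen-bond H···O contact). All gradients are analytic and
finite-difference-verified; the soft-sphere neighbor list is frozen within
each quench chunk so the energy stays smooth through every line search —
rebuilding it mid-line-search makes L-BFGS abort, which was the single
largest convergence obstacle found during development.

Model generation depends on how informative the network is:

* **Embedding path** (used when hydrogen-bond restraints are present and
  the unambiguous network is dense enough): bound-smoothed metric-matrix
  distance geometry over the unambiguous restraints, covalent terms and
  torsion-derived 1–4 distances; a random distance matrix within the
  smoothed bounds is embedded (classical MDS), refined by a smooth stress
  minimization, mirror-corrected via the Cβ impropers, and then
  *regularized*: the rigid torsion-seeded template of each chain segment
  is Kabsch-fitted onto the embedded coordinates of its restrained core.
  This keeps the embedded global fold but restores clean local geometry —
  embeddings otherwise carry cis-peptides, local tangles and loop knots
  that plain descent cannot repair. Remaining cis-ω or D-center defects
  are fixed directly (mirror the Cβ through the backbone plane; rotate the
  downstream stretch about the peptide bond) before the final quench.
* **Assembly path** (early iterations, ambiguous networks): the chain is
  split at the centres of torsionally unrestrained runs (the unassigned
  loops); each segment is built from its restrained torsions, placed by a
  random walk, assembled by rigid-body annealing (noisy gradient descent
  on segment poses with capped steps), optionally seeded by rigid
  least-squares docking on the unambiguous short-restraint graph, then
  relaxed through perturbation/quench cycles of decreasing amplitude.

Pseudo-energies rank the models; sorting is stable, so ties keep input
order.

## The synthetic generator

The generator emulates the statistical structure of the real experiments,
not their physics (no cross-polarization dynamics, relaxation or spin
diffusion build-up):

* **Geometry.** Strands use ideal β torsions (φ = −139°, ψ = +135°) and
  Engh/Huber-style covalent parameters, amide H built 1.02 Å along the
  anti-bisector. An antiparallel partner strand is placed by rigid least
  squares onto canonical hydrogen-bond registry targets (H···O 1.98 Å,
  N···O 2.98 Å, facing HN–HN 3.30 Å), weighted toward the strand centre;
  the registry offset is forced even so mutually hydrogen-bonded couples
  share index parity. Central facing HN–HN distances come out at 3.30 Å
  and sequential HN–HN at 4.35 Å (the ideal-strand value; standard tables
  quote 4.3 Å). Flat sheets repeat the fitted pair transform; barrels use
  a dihedral-symmetric placement (n/2-fold rotation plus in-plane two-fold
  flips) fitted to the same registry targets, so closure is exact. An
  unsheared rigid barrel of eight strands cannot simultaneously satisfy
  hydrogen bonds and avoid wall contacts — real barrels relieve this with
  strand tilt (shear), which this generator deliberately omits — so the
  assembled barrel is relaxed as a whole against covalent terms, soft
  spheres, hydrogen-bond registry restraints and β torsions, giving a
  self-consistent, clash-free ground truth (facing HN–HN ≈ 3.0–3.2 Å).
  Strands are connected by flexible loops (default 3 residues) initialized
  on an outward-bulged arc and relaxed with the strand atoms fixed; loops
  are left unassigned, emulating the mobile loop residues missing from
  real CP-based spectra, and covalently pin the strand order — a meander
  with free-floating strands would leave the topology undetermined.
* **Shifts.** Residue-type-typical random-coil means (versioned data
  table) plus seeded Gaussian jitter, sd 4.5 ppm (¹⁵N), 1.3 ppm (¹H_N),
  1.8 ppm (¹³Cα/β) — sized to reproduce the dispersion of a β-sheet
  membrane protein (amide ¹H roughly 6.5–10.5 ppm). Disordered ranges and
  loops are omitted from the list. `inject_overlap` makes chosen amide
  pairs nearly degenerate to study ambiguity growth.
* **Peaks.** Every visible ordered pair yields peaks at the positions
  dictated by the spectrum's dimension roles, with intensities ∝ r⁻⁶
  (times the labeling product for DARR) and optional multiplicative
  log-normal noise; auto-correlation peaks are emitted for the amide
  spectra. Visibility is per-residue: each amide shows cross peaks to its
  `max_partners` (default 2) closest partners, symmetrized so a visible
  pair always yields the full four-peak redundancy — matching the
  observed pattern of one large cross-strand peak and one or two weaker
  sequential ones per residue, and the density of ~2 cross peaks per
  assigned residue. Sampling depths: RFDR 4.6 Å, DARR 2.5/4.5/7.0 Å
  (short/medium/long) — long-mixing peaks under the picking threshold are
  the reason the formal 7–8 Å restraint bounds exceed the sampled reach.
  The default carbon-detected sample set mirrors the selective-labeling
  strategy: [2-¹³C]- and [1,3-¹³C]-glycerol plus two forward-labeled
  samples, each contributing a short-mixing (intra-residue reference) and
  a long-mixing spectrum.
* **Torsion predictions.** The truth's measured φ/ψ with ±20° widths and
  class "Good" for assigned strand residues; loops, disordered ranges and
  chain termini get class "None" (skipped downstream).

All generator outputs are bit-reproducible per seed.

What passing tests show — and what they do not: the synthetic data carry
realistic shift overlap, restraint ambiguity, false restraints from
degenerate auto-correlation peaks, unassigned regions, and labeling-scheme
structure, so the disambiguation machinery is genuinely exercised. They do
not carry assignment errors, spinning sidebands, intensity distortions
from relaxation or spin-diffusion saturation, or sample-to-sample
perturbations between differently labeled preparations; conclusions about
real-data performance are correspondingly limited.

## Problem sizes and numerical choices

The end-to-end recovery test uses an 8-strand × 8-residue barrel with
3-residue loops (85 residues), 20 structures per iteration over 5
iterations plus the final hydrogen-bond run — sizes chosen so the full
loop runs on a single CPU in minutes. Matching is boundary-inclusive with
a 1 × 10⁻⁹ ppm guard against floating-point edge effects. Effective
distances use exact r⁻⁶ pooling (verified against the closed form to
1 × 10⁻⁹ Å). Combination partitions are drawn without replacement from a
seeded generator. Degenerate inputs: empty peak files give empty lists;
peaks matching nothing are logged and skipped; restraints whose option
lists empty are deactivated, never deleted.

## Known limitations

* The refiner is a restraint-satisfaction engine; its pseudo-energies are
  not comparable to molecular-mechanics energies, and no solvent or
  Ramachandran refinement stage exists.
* The barrel generator has no shear number; its barrels are slightly
  wider-waisted than real ones and rely on a relaxation step for
  self-consistency.
* Registry inference assumes antiparallel topology (true for the systems
  this pipeline targets); parallel sheets are not generated or inferred.
* The glycerol enrichment table is an approximation; quantitative
  labeling-product values near the 10% cutoff should not be
  over-interpreted.
* With heavily overlapped shifts the ensemble bundles converge to a few
  Å before hydrogen bonds are available; precision beyond that relies on
  the hydrogen-bond stage, as it does in practice.
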