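# adrpipe

Ambiguous distance restraints and iterative disambiguation for
magic-angle-spinning (MAS) NMR structure determination of β-barrel
membrane proteins.

## The problem

Solid-state NMR of a membrane protein in lipid bilayers produces cross
peaks whose positions are chemical shifts, not atom identities: within the
matching tolerances, many atom pairs can explain each peak, and mobile
loop residues are often not assigned at all. The field's answer is the
ambiguous distance restraint (ADR) — a distance bound attached to every
compatible atom-pair assignment, evaluated through the r⁻⁶-pooled
effective distance

    d_eff = ( Σ_options d_o⁻⁶ )^(−1/6)

and sharpened iteratively: ensembles of structures are computed, the
lowest-pseudo-energy models are used to reject restraints that cannot be
satisfied ("violation analysis": a restraint survives only if satisfied in
at least half of the selected models) and to prune unlikely assignment
options, and the cycle repeats.

`adrpipe` implements this machinery for the data of a ¹H- and ¹³C-detected
MAS NMR study of a β-barrel:

* **labeling** — forward/reverse/glycerol isotope labeling schemes and the
  10% labeling-product filter that decides which carbon-pair assignments a
  selectively labeled sample can show;
* **io_nmr** — shift lists (tabular / NMR-STAR subset), Sparky-style peak
  lists, TALOS-style torsion tables, CNS-style `.tbl` restraint files with
  OR-groups, and PDB coordinates;
* **restraints** — shift matching of the paired 3D amide spectra
  (tolerances 0.4 / 0.1 / 0.7 ppm for ¹⁵N / indirect ¹H / direct ¹H) with
  the four-fold cross-peak redundancy filter, intensity-based distance
  classes (1.0–3.5 / 1.0–5.5 Å), aliphatic ¹³C–¹³C matching (0.4 ppm,
  classes 1.5–5.5 / 1.5–7.0 Å by mixing time or a single 1.5–8.0 Å class),
  co-linear hydrogen-bond restraints (H–O 1.73–2.70 Å, N–O 2.52–3.93 Å)
  and torsion restraints;
* **protocol** — the iterative loop: schedules, violation analysis,
  option pruning, 4-to-4 restraint combination, merging;
* **refine** — a desk-scale restraint-satisfaction annealer (distance
  geometry + simulated annealing on backbone coordinates) standing in for
  a full structure-calculation package;
* **synth** — synthetic β-sheets and barrels with realistic shift
  dispersion, peak redundancy, unassigned loops and labeling structure,
  so everything is testable without any experimental download.

See `docs/methods.md` for the models, parameter choices and limitations,
and `examples/` for narrative scripts, one per capability.

## A worked example

```python
from adrpipe.pipeline import build_h_restraints
from adrpipe.synth import SheetSpec, simulate_dataset

data = simulate_dataset(SheetSpec(n_strands=4, residues_per_strand=8,
                                  barrel=False, seed=2))
adrs = build_h_restraints([data["peaks"]["hnhh"], data["peaks"]["hnhhnh"]],
                          data["shifts"])
```

Running `python examples/02_match_amide_peaks.py` (which executes exactly
this and prints a summary) gives

```
232 peaks -> 140 ambiguous distance restraints
mean ambiguity after the redundancy filter: 2.21 (51 unambiguous)
distance classes: 50 strong (1.0-3.5 A), 90 regular (1.0-5.5 A)
```

Each of the 140 restraints came from one cross peak of the paired 3D
amide spectra; on average it still lists ~2 candidate amide pairs after
the four-peak redundancy filter, 51 are already unique, and the 50
strongest peaks were placed in the short 1.0–3.5 Å class because they are
more intense than the first peak with a sequential assignment. The iterative
protocol (`examples/04_iterative_protocol.py`) then resolves the remaining
ambiguity against the evolving ensemble, reads the hydrogen-bond registry
off the converged bundle and computes a final ensemble with the
hydrogen-bond restraints included.

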