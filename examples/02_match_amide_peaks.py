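"""Amide-amide restraints from the paired 3D spectra.

Shift-matches the (H)NHH / (H)N(HH)NH peak lists against the assigned
shifts (tolerances 0.4 ppm 15N, 0.1 ppm indirect 1H, 0.7 ppm direct 1H),
counts the four-fold cross-peak redundancy, prunes options with the
four-peak/three-peak rule, and classifies each restraint into the
1.0-3.5 A or 1.0-5.5 A distance class by intensity sorting.
"""

import numpy as np

from adrpipe.pipeline import build_h_restraints
from adrpipe.synth import SheetSpec, simulate_dataset

data = simulate_dataset(SheetSpec(n_strands=4, residues_per_strand=8,
                                  barrel=False, seed=2))
peaklists = [data["peaks"]["hnhh"], data["peaks"]["hnhhnh"]]
adrs = build_h_restraints(peaklists, data["shifts"])

ambig = [a.ambiguity for a in adrs]
strong = sum(a.upper == 3.5 for a in adrs)
print(f"{sum(len(p) for p in peaklists)} peaks -> {len(adrs)} ambiguous "
      "distance restraints")
print(f"mean ambiguity after the redundancy filter: {np.mean(ambig):.2f} "
      f"({sum(a == 1 for a in ambig)} unambiguous)")
print(f"distance classes: {strong} strong (1.0-3.5 A), "
      f"{len(adrs) - strong} regular (1.0-5.5 A)")

adr = max(adrs, key=lambda a: a.ambiguity)
print(f"\nmost ambiguous restraint ({adr.ambiguity} options, "
      f"bounds {adr.lower}-{adr.upper} A):")
for o in adr.options:
    print(f"  H{o.atom_a[0]} <-> H{o.atom_b[0]}  (supported by "
          f"{o.support_count} cross peaks)")
print("\nthe iterative protocol resolves such restraints against the "
      "evolving structure ensemble.")
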