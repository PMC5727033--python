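# Per-atom 13C enrichment fractions for proteins expressed on [2-13C]- or
# [1,3-13C]-glycerol as sole carbon source (E. coli).
#
# version: 1
#
# These values are NOT measured here.  They are an encoded approximation of
# the enrichment patterns reported in the metabolic-labeling literature
# (LeMaster & Kushlan-style glycerol labeling of E. coli proteins): amino
# acids made through glycolysis inherit clean single-position patterns from
# pyruvate / 3-phosphoglycerate, while amino acids drawn from citric-acid
# -cycle intermediates show fractional enrichment because of the symmetry of
# fumarate/succinate and multiple cycle turns.  Fractional values below are
# rounded to the conventional 1/2 and 1/4 scrambling levels.  Every value can
# be overridden from a scheme descriptor (``enrichment_overrides``); treat
# this table as a starting point, not ground truth.
#
# Atom coverage: backbone C (carbonyl), CA, CB and the principal side-chain
# carbons used for aliphatic-region restraint generation.

glycerol_2:
  # pyruvate C2 / 3-phosphoglycerate C2 labeled -> CA of glycolytic residues
  G: {CA: 1.0, C: 0.0}
  A: {CA: 1.0, CB: 0.0, C: 0.0}
  S: {CA: 1.0, CB: 0.0, C: 0.0}
  C: {CA: 1.0, CB: 0.0, C: 0.0}
  V: {CA: 1.0, CB: 1.0, CG1: 0.0, CG2: 0.0, C: 0.0}
  L: {CA: 0.0, CB: 1.0, CG: 1.0, CD1: 0.0, CD2: 0.0, C: 0.5}
  I: {CA: 0.5, CB: 1.0, CG1: 0.0, CG2: 0.0, CD1: 0.0, C: 0.25}
  F: {CA: 1.0, CB: 0.0, CG: 0.5, CD1: 0.5, CD2: 0.5, CZ: 1.0, C: 0.0}
  Y: {CA: 1.0, CB: 0.0, CG: 0.5, CD1: 0.5, CD2: 0.5, CZ: 1.0, C: 0.0}
  W: {CA: 1.0, CB: 0.0, CG: 0.5, C: 0.0}
  H: {CA: 1.0, CB: 0.0, CG: 0.5, C: 0.0}
  # citric-acid-cycle family: oxaloacetate / 2-oxoglutarate derived,
  # fractional through fumarate symmetry and repeated cycle turns
  D: {CA: 0.5, CB: 0.25, CG: 0.25, C: 0.25}
  N: {CA: 0.5, CB: 0.25, CG: 0.25, C: 0.25}
  T: {CA: 0.5, CB: 0.25, CG2: 0.0, C: 0.25}
  M: {CA: 0.5, CB: 0.25, CG: 0.25, CE: 0.0, C: 0.25}
  K: {CA: 0.5, CB: 0.25, CG: 0.25, CD: 0.25, CE: 0.5, C: 0.25}
  E: {CA: 0.5, CB: 0.5, CG: 0.25, CD: 0.25, C: 0.25}
  Q: {CA: 0.5, CB: 0.5, CG: 0.25, CD: 0.25, C: 0.25}
  P: {CA: 0.5, CB: 0.5, CG: 0.25, CD: 0.25, C: 0.25}
  R: {CA: 0.5, CB: 0.5, CG: 0.25, CD: 0.25, CZ: 0.0, C: 0.25}

glycerol_1_3:
  # glycerol C1/C3 -> pyruvate C1 (carboxyl) and C3 (methyl); complementary
  # to the [2-13C] pattern for the glycolytic family
  G: {CA: 0.0, C: 1.0}
  A: {CA: 0.0, CB: 1.0, C: 1.0}
  S: {CA: 0.0, CB: 1.0, C: 1.0}
  C: {CA: 0.0, CB: 1.0, C: 1.0}
  V: {CA: 0.0, CB: 0.0, CG1: 1.0, CG2: 1.0, C: 1.0}
  L: {CA: 1.0, CB: 0.0, CG: 0.0, CD1: 1.0, CD2: 1.0, C: 0.5}
  I: {CA: 0.5, CB: 0.0, CG1: 1.0, CG2: 1.0, CD1: 1.0, C: 0.75}
  F: {CA: 0.0, CB: 1.0, CG: 0.5, CD1: 0.5, CD2: 0.5, CZ: 1.0, C: 1.0}
  Y: {CA: 0.0, CB: 1.0, CG: 0.5, CD1: 0.5, CD2: 0.5, CZ: 1.0, C: 1.0}
  W: {CA: 0.0, CB: 1.0, CG: 0.5, C: 1.0}
  H: {CA: 0.0, CB: 1.0, CG: 0.5, C: 1.0}
  D: {CA: 0.5, CB: 0.75, CG: 0.75, C: 0.75}
  N: {CA: 0.5, CB: 0.75, CG: 0.75, C: 0.75}
  T: {CA: 0.5, CB: 0.75, CG2: 1.0, C: 0.75}
  M: {CA: 0.5, CB: 0.75, CG: 0.75, CE: 1.0, C: 0.75}
  K: {CA: 0.5, CB: 0.75, CG: 0.75, CD: 0.75, CE: 0.5, C: 0.75}
  E: {CA: 0.5, CB: 0.5, CG: 0.75, CD: 0.75, C: 0.75}
  Q: {CA: 0.5, CB: 0.5, CG: 0.75, CD: 0.75, C: 0.75}
  P: {CA: 0.5, CB: 0.5, CG: 0.75, CD: 0.75, C: 0.75}
  R: {CA: 0.5, CB: 0.5, CG: 0.75, CD: 0.75, CZ: 0.0, C: 0.75}
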