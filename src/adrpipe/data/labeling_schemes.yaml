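# Descriptors for amino-acid-type selective 13C labeling schemes of the kind
# used for beta-barrel membrane proteins.  Forward schemes add 13C,15N amino acids to
# otherwise unlabeled medium; reverse schemes grow on [2-13C]- or
# [1,3-13C]-glycerol and add the residues to *exclude* in unlabeled (15N-only)
# form, so the name-giving residues carry the glycerol pattern.
#
# "accidental" residues were labeled to a lower degree through active
# biosynthetic pathways (scrambling); they default to the fraction given by
# ``accidental_fraction`` when building the scheme.
#
# "atom_subset" restricts labeling of a residue type to the listed carbons
# (e.g. Phe/Tyr labeled on CA and CB only).

schemes:
  - name: GAFY(S)
    kind: forward
    labeled: GAFY
    accidental: S
    atom_subset:
      F: [CA, CB]
      Y: [CA, CB]
  - name: GAVLS(W)
    kind: forward
    labeled: GAVLS
    accidental: W
    atom_subset:
      W: [CA, CB, CG]
  - name: RIGA(S)
    kind: forward
    labeled: RIGA
    accidental: S
  - name: GANDSH(LV)
    kind: forward
    labeled: GANDSH
    accidental: LV
  - name: GENDQPASR
    kind: forward
    labeled: GENDQPASR
    accidental: ""
  - name: GAFYSHVL
    kind: forward
    labeled: GAFYSHVL
    accidental: ""
    atom_subset:
      F: [CA, CB]
      Y: [CA, CB]
  - name: 2-uniform
    kind: glycerol_2
  - name: 1,3-uniform
    kind: glycerol_1_3
  - name: 2-TEMPQANDSG
    kind: reverse
    base: glycerol_2
    labeled: TEMPQANDSG
  - name: 1,3-TEMPQANDSG
    kind: reverse
    base: glycerol_1_3
    labeled: TEMPQANDSG
  - name: 2-SHLYGWAFV(QENDT)
    kind: reverse
    base: glycerol_2
    labeled: SHLYGWAFV
    accidental: QENDT
  - name: 1,3-MKINDT
    kind: reverse
    base: glycerol_1_3
    labeled: MKINDT
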