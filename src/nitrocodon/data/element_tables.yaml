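# Elemental cost tables used throughout the package.
#
# per_nucleotide: nitrogen atoms in the base of each ribo/deoxyribonucleotide
#   (purines A/G carry 5, cytosine 3, thymine/uracil 2).
# per_basepair:   nitrogen atoms in a double-stranded base pair
#   (must equal the sum of the paired bases: A+T = 7, G+C = 8).
# per_sidechain:  nitrogen atoms in the amino-acid side chain (backbone amide
#   nitrogen excluded); standard chemistry.
#
# Swap this file (or pass an alternative path to nitrogen.load_element_tables)
# to account for a different element, e.g. carbon.
element: nitrogen
per_nucleotide:
  A: 5
  G: 5
  C: 3
  T: 2
  U: 2
per_basepair:
  AT: 7
  GC: 8
per_sidechain:
  A: 0
  C: 0
  D: 0
  E: 0
  F: 0
  G: 0
  H: 2
  I: 0
  K: 1
  L: 0
  M: 0
  N: 1
  P: 0
  Q: 1
  R: 3
  S: 0
  T: 0
  V: 0
  W: 1
  Y: 0
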