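# Selective constraints s_ij on codon-anticodon coupling efficiency used in
# the tRNA adaptation index, omega(C) = sum_j (1 - s_ij) * tGCN_ij.
# One row per pairing class between the codon third base and the anticodon
# first (wobble, position 34) base; "I" denotes inosine derived from A34.
# Values are the standard optimised constraints of dos Reis et al. (2004),
# as adopted by Tuller et al. (2010). Edit to supply alternative constraints.
pair	s
A:T	0.0
G:C	0.0
T:A	0.0
C:G	0.0
G:T	0.41
I:C	0.28
I:A	0.9999
T:G	0.68
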