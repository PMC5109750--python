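# nitrocodon

Nitrogen-aware modelling of synonymous codon usage.

Organisms that live on nitrogen-poor diets (for example plant-colonising
microbial parasites) can spell the same proteins with cheaper codons:
purines (A, G) carry 5 nitrogen atoms per base, cytosine 3, and thymine or
uracil only 2, so synonymous substitutions change the nitrogen cost of an
mRNA without touching the protein.  `nitrocodon` is a toolkit for
quantifying this effect in comparative genomic data and for asking whether
it reflects selection rather than mutation bias alone.  It is aimed at
researchers working on codon usage, stoichiogenomics / elemental sparing,
and the comparative genomics of parasites and other diet-restricted
microbes.

## The model

Within each synonymous codon family the probability of codon *C* is

```
p(C | θ) ∝ α(C) · β(C) · η(C)
```

with

* **selection on nitrogen content** α(C) = exp(2N_g·s · N_mRNA(C)), where
  N_mRNA(C) is the codon's nitrogen atom count and 2N_g·s is a composite
  selection bias (negative values favour nitrogen-poor codons);
* **mutation bias toward AT** β(C) = δ^AT (1−δ)^GC with δ = m/(m+1), where
  m is the equilibrium AT:GC odds and AT/GC are the codon's base counts;
* **translational selection** η(C) = exp(2N_g·σ · ω(C)), where ω(C) is the
  codon's tRNA adaptation index computed from tRNA gene copy numbers under
  standard wobble rules.

Any subset of the three pressures defines a model variant.  The likelihood
of a set of coding sequences is ℒ(θ|X) = Π_C p(C|θ)^{N_C} over pooled
sense-codon counts; parameters are estimated by a deterministic brute-force
grid search with one zoom refinement, variants are compared by AIC, and the
reality of nitrogen selection is tested by refitting after globally
shuffling the nitrogen values assigned to codons (Monte-Carlo p-value).
Fitted group models can then classify a new species' dietary-nitrogen group
from its raw CDS by maximum likelihood.

Around the model the package provides: codon counting with explicit
validation policy, nitrogen accounting for mRNA, double-stranded DNA,
amino-acid side chains and whole rRNA molecules, single-copy orthogroup
filtering, codon-aware back-translation of protein alignments, paired
per-gene nitrogen comparisons (Wilcoxon signed-rank), per-gene selection
versus mRNA abundance, and a fully seeded synthetic-data generator for
end-to-end validation.

## Worked example

Simulate a nitrogen-starved bacterial-style species (selection bias
2N_g·s = −0.24, mutation bias m = 3.5), refit the model and test the
selection signal:

```python
import numpy as np
import nitrocodon as nc

table = nc.codon_probs(nc.ModelParams("selection_mutation", sel_n=-0.24, mut_m=3.5))
counts = nc.sample_codon_counts(table, 100_000, np.random.default_rng(1))

res = nc.fit(counts, "selection_mutation")
print(f"sel_n = {res.params.sel_n:+.3f}   m = {res.params.mut_m:.3f}")
print(f"loglik = {res.loglik:.1f}   AIC = {res.aic:.1f}")

emp = nc.empirical_probs(counts)
print(f"R2 = {nc.model_accuracy(res.probs, emp):.3f}")

perm = nc.permutation_test_selection(counts, n_perm=199, rng=np.random.default_rng(2))
print(f"permutation p = {perm.p_value:.3f}")
```

prints

```
sel_n = -0.240   m = 3.477
loglik = -78061.7   AIC = 156127.4
R2 = 1.000
permutation p = 0.005
```

The fit recovers the generating parameters (a negative `sel_n` means
selection is removing nitrogen from the transcriptome; `m` near 3.5 means a
site is 3.5 times more likely to be A/T than G/C at mutational
equilibrium), the fitted table explains the empirical codon-use percentages
essentially perfectly on the model's own data, and no shuffled assignment
of nitrogen values to codons fits as well as the real one (p = 1/200, the
smallest value 199 permutations can produce).

The same analysis is scriptable from the shell:

```bash
nitrocodon synth --seed 5 --out data/           # synthetic 3-group study
nitrocodon pipeline --cds-dir data/ \
    --orthogroups data/orthogroups.tsv \
    --groups data/groups.tsv --out results/     # paired nitrogen comparison
nitrocodon fit --counts pooled_counts.tsv --variant selection_mutation --out fit/
```

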