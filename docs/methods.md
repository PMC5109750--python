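# Methods

## Model

Synonymous codon use is modelled within each synonymous family (the set of
sense codons encoding one amino acid under the active translation table).
The weight of codon *C* is the product of up to three biases:

* selection on nitrogen content, `α(C) = exp(sel_n · N_mRNA(C))`, where
  `N_mRNA(C)` is the number of nitrogen atoms in the codon's bases
  (A/G = 5, C = 3, T/U = 2; range 6–15 per codon) and `sel_n` is the
  composite parameter 2N_g·s — the per-atom selection coefficient scaled by
  the effective number of genes.  Only the composite is identifiable.
* mutation bias toward AT, `β(C) = δ^AT (1−δ)^GC` with `δ = m/(m+1)`.
  `m` is the equilibrium odds that a site is A/T rather than G/C; the model
  assumes compositional equilibrium and site independence.
* translational selection, `η(C) = exp(sel_tai · ω(C))`, with `ω(C)` the
  unnormalised tRNA adaptation index: `ω(C) = Σ_j (1−s_ij)·tGCN_ij` over the
  isoacceptors recognising *C* by Watson–Crick or single wobble pairing at
  the anticodon 34 position.  ω is deliberately not rescaled to max = 1
  because the selection term exponentiates the absolute value.

Probabilities are the weights normalised within each family, so the law of
total probability holds per family by construction (unit tests require the
deviation to stay below 1e-12).  Six variants — each non-empty subset of
{selection, mutation, translation} that the analysis uses — are supported;
parameters absent from a variant are pinned at their neutral values
(sel_n = 0, m = 1, sel_tai = 0), which makes the variants exactly nested:
the joint model with sel_n = 0 coincides with the mutation-only model, and
with m = 1 with the selection-only model.

The likelihood of a sequence set X is `ℒ(θ|X) = Π_C p(C|θ)^{N_C}` over
pooled sense-codon counts `N_C`; genes only matter through their pooled
counts, and single-codon families (Met, Trp under the standard table)
contribute nothing.  Group-level estimates pool counts across the species
of a group; per-species fits are also available, and run configurations
record which was used.

## Genetic codes and validation policy

Translation tables 1 (standard; 61 sense codons) and 4 (TGA → Trp, as in
Mollicutes; 62 sense codons) are supported, via Biopython's codon tables.
CDS validation: length must be a positive multiple of 3; a terminal stop is
discarded; an internal stop drops the gene (logged, not fatal); codons with
ambiguity characters are skipped individually.  This keeps every count
defined over sense codons.  U is normalised to T at parse time.

## Fitting

Estimation is a deterministic brute-force grid search, chosen because the
models have at most three free parameters and the likelihood surface is
cheap to evaluate exactly on a grid (gradient-based optimisers are suitable
only as a cross-check).  Defaults:

* `sel_n ∈ [−1, 1]`, step 0.01 (201 points);
* `m` log-spaced over [0.05, 20] with 201 points.  The symmetric 201-point
  log grid contains the neutral point m = 1 exactly, mirroring the sel_n
  grid containing 0; the log-step is ≈ 0.030.
* `sel_tai ∈ [−1, 1]`, step 0.01.

These ranges bracket every group estimate the model is intended for
(|sel_n| ≤ ~0.25, m from ~0.3 to ~4) with wide margin.  One zoom pass
re-evaluates a 10×-finer grid one coarse step either side of the coarse
optimum (clipped to the bounds), giving refinement steps of 0.001 for the
linear parameters and ≈ 0.003 in log m.  Exact ties on the grid are broken
toward the neutral point (smallest |sel_n|, then m closest to 1, then
smallest |sel_tai|) — conservative with respect to claiming selection.
AIC = 2k − 2 lnℒ with k the variant's free-parameter count.

Noise-free counts exactly proportional to a model table are refitted to
within one refinement step of the generating parameters; at 1e5 multinomial
codons the sampling standard error (~0.005 on sel_n) dominates the grid
resolution, and the mean absolute error across a grid of true parameter
values stays below twice the coarse step.

Per-gene selection estimates hold m fixed at the genome-wide value
(mutation bias is a genome-level process) and skip genes with fewer than
100 counted codons by default.

## tAI inputs

ω uses tRNA gene copy numbers keyed by anticodon plus wobble-class
constraints s_ij shipped as an editable TSV (`data/wobble_constraints.tsv`)
with the standard optimised values (Watson–Crick pairs 0; G:U 0.41; I:C
0.28; I:A 0.9999; U:G 0.68).  Codons recognised by no tRNA get ω = 0 and
are flagged.  Lineage-specific anticodon modifications (e.g. lysidine
tRNA-Ile2 reading ATA in many bacteria) are not modelled.

## Significance testing

* **Paired Wilcoxon signed-rank** compares per-gene mean nitrogen between
  groups; orthologous single-copy genes are paired observations.  Two-tailed;
  zero differences dropped; all-zero differences raise a named error.
* **Permutation test for nitrogen selection**: the nitrogen values of all
  sense codons are globally shuffled (not within families), the model is
  refit, and the maximised log-likelihood recorded;
  p = (1 + #{perm ≥ observed}) / (n_perm + 1).  The plus-one convention
  avoids p = 0 and makes the null distribution of p uniform on
  {1/(N+1), …, 1}.  Permutation refits use a coarser default grid
  (sel_n step 0.02, 81 log-spaced m points, same zoom pass) than headline
  fits; because the observed and every permuted dataset are fitted on the
  identical grid, exchangeability — and therefore the validity of p — is
  unaffected, while a 1000-shuffle test stays interactive.
* **Model accuracy** is the squared Pearson correlation (R²) between model
  and empirical codon-use percentages over all sense codons.
* **Classification** evaluates a species' pooled counts under each group's
  fitted parameters and assigns the argmax; exact ties are flagged, never
  silently resolved.
* **Expression correlation** reports Spearman's ρ and the OLS slope of
  per-gene sel_n on log10 mRNA abundance.
* A one-way ANOVA helper summarises per-species sel_n distributions by
  group.

## Orthology pipeline

Orthogroups are retained only if every represented species contributes
exactly one gene and each nitrogen-availability group has at least three
species (configurable).  CDS are threaded back through aligned proteins
codon-by-codon (gaps become `---`; any translation mismatch is an error
naming species and position).  Columns are kept only if gap-free in every
row and their score strictly exceeds 0.75.  External per-column alignment
scores are consumed when available; otherwise a fallback score — the
fraction of rows matching the modal residue — is computed.  The fallback is
not equivalent to an alignment-ensemble column score and is labelled as
such.  Alignment columns are 0-based half-open internally, 1-based in
reports.  The paired table reports both the kept-column total and the
columns × species observation count, since "orthologous codons compared"
can be read either way.  rRNA totals per ribosome sum nitrogen over a named
molecule set; a species missing any molecule is flagged NF rather than
failing the run.

## Synthetic data

The generator emulates a three-group comparative study at desk scale.
Defaults are the bacterial-style study conditions: selection biases −0.24
(L_N), −0.15 (M_N) and −0.13 (H_N) with mutation bias m = 3.5 for all
groups (group-level mutation bias is reported in the motivating analyses
only as "greater than 3.5"), four species per group, 300 single-copy
orthogroups, log-normal gene lengths with mean 630 codons (log-sd 0.35),
and uniform amino-acid frequencies (overridable by an empirical table).
Every orthogroup draws one shared protein; each species' CDS is simulated
independently under its group's codon table, so orthology is exact and
indel-free.  All randomness flows from a single recorded seed.

What the generator does *not* emulate: phylogenetic non-independence among
species, indels and alignment error, gene-specific selective pressures
(mRNA structure, splice sites, expression-dependent bias), and non-uniform
amino-acid composition.  Passing tests therefore demonstrate correctness of
the estimation and comparison machinery under the model's own assumptions,
not that real genomes satisfy those assumptions.

## Numerical and scale choices

* Probability normalisation is exact per family; weights stay within
  float64 range for the default grids (|log weight| ≤ ~25).
* Density summaries use a Gaussian KDE on a padded 512-point grid and are
  checked to integrate to 1 ± 0.01; constant input is rejected rather than
  producing a spike.
* Zero-count families get uniform empirical probabilities with a warning.
* Test and validation problem sizes: parameter-recovery fits use 1e5–1e6
  codons; permutation calibration uses 50 seeds × 199 shuffles at 2e4
  codons; classification checks use 1e6-codon training pools and 40
  1e5-codon test species; the end-to-end synthetic study uses the full
  default (3 × 4 species × 300 orthogroups ≈ 2.3 M codons).

## Known limitations

* Selection acts only on codon nitrogen content; biased gene conversion
  and other strand- or context-dependent forces are outside the model.
* The grid bounds clip estimates with |sel_n| > 1 or m outside [0.05, 20];
  such data are outside the model's intended regime.
* The classifier compares only the candidate groups supplied; it cannot
  signal "none of the above".
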