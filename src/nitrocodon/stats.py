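"""Significance testing, model comparison, classification and savings summaries.

The permutation test asks whether the real assignment of nitrogen values to
codons explains codon use better than chance: the per-codon nitrogen
contents are globally shuffled across all sense codons, the model is refit,
and the maximised log-likelihood recorded; p = (1 + #{perm ≥ observed}) /
(n_perm + 1), the standard Monte-Carlo convention that avoids p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .counting import CodonCounts, CodonProbTable
from .errors import DegenerateDataError, EmptyInputError, NitrocodonError
from .model import (
    FitResult,
    GridSpec,
    PERMUTATION_GRID,
    VARIANTS,
    canonical_variant,
    fit,
    log_likelihood,
)
from .nitrogen import GeneticCode, STANDARD_CODE, nitrogen_mrna
from .tai import TaiTable


def paired_wilcoxon(pairs: Sequence[tuple[float, float]]):
    """Two-tailed Wilcoxon signed-rank test on paired per-gene means.

    Zero differences are dropped (Wilcoxon's convention); if none remain the
    data are degenerate and a named error is raised.
    """
    a = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)
    if a.size == 0:
        raise EmptyInputError("no pairs supplied")
    if np.all(a == b):
        raise DegenerateDataError("all paired differences are zero")
    res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass
class PermutationResult:
    p_value: float
    observed_loglik: float
    null_logliks: np.ndarray
    n_perm: int


def permutation_test_selection(
    counts,
    variant: str = "selection_mutation",
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    code: GeneticCode = STANDARD_CODE,
    grid: GridSpec | None = None,
    tai: TaiTable | None = None,
) -> PermutationResult:
    """Permutation test of selection on codon nitrogen content.

    Each permutation globally shuffles the nitrogen values assigned to the
    sense codons, refits the model on the same grid, and records the maximum
    log-likelihood.
    """
    variant = canonical_variant(variant)
    if "sel_n" not in VARIANTS[variant]:
        raise NitrocodonError("the permutation test requires a variant with selection on nitrogen")
    if n_perm < 1:
        raise NitrocodonError(f"n_perm must be >= 1, got {n_perm}")
    rng = rng or np.random.default_rng()
    grid = grid or PERMUTATION_GRID
    observed = fit(counts, variant=variant, code=code, grid=grid, tai=tai).loglik
    nvec = np.array([nitrogen_mrna(c) for c in code.sense_codons], dtype=float)
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = rng.permutation(nvec)
        null[i] = fit(
            counts, variant=variant, code=code, grid=grid, tai=tai, nitrogen_values=shuffled
        ).loglik
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return PermutationResult(
        p_value=float(p), observed_loglik=observed, null_logliks=null, n_perm=n_perm
    )


def model_accuracy(model: CodonProbTable, empirical: CodonProbTable) -> float:
    """R²: squared Pearson correlation of paired codon-use percentages."""
    if set(model.probs) != set(empirical.probs):
        raise NitrocodonError("codon sets of the two probability tables differ")
    codons = sorted(model.probs)
    x = np.array([100.0 * model.probs[c] for c in codons])
    y = np.array([100.0 * empirical.probs[c] for c in codons])
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


@dataclass
class ClassificationResult:
    """Log-likelihood of a species' counts under each candidate group's fit."""

    logliks: dict[str, float]
    assigned: str
    tie: bool


def classify_species(
    counts,
    group_fits: Mapping[str, FitResult],
    code: GeneticCode = STANDARD_CODE,
    tai: TaiTable | None = None,
) -> ClassificationResult:
    """Assign a species to the nitrogen-availability group whose fitted
    parameters give its pooled codon counts the highest likelihood."""
    if len(group_fits) < 2:
        raise NitrocodonError("need at least two candidate groups")
    pooled = counts.pooled if isinstance(counts, CodonCounts) else dict(counts)
    if not pooled or sum(pooled.values()) == 0:
        raise EmptyInputError("empty codon counts")
    lls = {
        g: log_likelihood(f.params, pooled, code=code, tai=tai) for g, f in group_fits.items()
    }
    best = max(lls.values())
    winners = sorted(g for g, v in lls.items() if v == best)
    return ClassificationResult(logliks=lls, assigned=winners[0], tie=len(winners) > 1)


def per_gene_selection(
    counts: CodonCounts,
    mut_m: float,
    code: GeneticCode = STANDARD_CODE,
    grid: GridSpec | None = None,
    min_codons: int = 100,
) -> tuple[dict[str, float], list[str]]:
    """Per-gene ML selection bias with mutation bias held at the genome-wide
    estimate (mutation is a genome-level process).

    Genes with fewer than ``min_codons`` counted codons are skipped and
    returned in the second element.
    """
    base = grid or GridSpec()
    pinned = GridSpec(
        sel_n=base.sel_n,
        m_range=base.m_range,
        m_points=base.m_points,
        sel_tai=base.sel_tai,
        zoom=base.zoom,
        zoom_halfwidth=base.zoom_halfwidth,
        fixed={**dict(base.fixed), "mut_m": float(mut_m)},
    )
    out: dict[str, float] = {}
    skipped: list[str] = []
    for gene, gcounts in counts.per_gene.items():
        if sum(gcounts.values()) < min_codons:
            skipped.append(gene)
            continue
        res = fit(gcounts, variant="selection_mutation", code=code, grid=pinned)
        out[gene] = res.params.sel_n
    if not out:
        raise DegenerateDataError(f"all {len(skipped)} genes fall below {min_codons} codons")
    return out, skipped


@dataclass
class ExpressionCorrelation:
    spearman_rho: float
    spearman_p: float
    slope: float  # OLS slope of sel_n on log10 abundance
    n_genes: int


def expression_correlation(
    per_gene_sel: Mapping[str, float], abundance: Mapping[str, float]
) -> ExpressionCorrelation:
    """Rank correlation and regression slope of per-gene selection bias on
    log10 mRNA abundance, matching genes by id."""
    genes = sorted(set(per_gene_sel) & set(abundance))
    if len(genes) < 3:
        raise EmptyInputError(f"only {len(genes)} genes matched; need >= 3")
    sel = np.array([per_gene_sel[g] for g in genes])
    ab = np.array([float(abundance[g]) for g in genes])
    if np.any(ab <= 0):
        raise NitrocodonError("abundances must be positive for a log10 transform")
    if np.ptp(ab) == 0:
        raise DegenerateDataError("constant abundance: correlation undefined")
    logab = np.log10(ab)
    rho, p = sps.spearmanr(sel, logab)
    slope = float(np.polyfit(logab, sel, 1)[0])
    return ExpressionCorrelation(
        spearman_rho=float(rho), spearman_p=float(p), slope=slope, n_genes=len(genes)
    )


@dataclass
class NitrogenSavings:
    """Savings of the low-nitrogen mean over the high-nitrogen mean."""

    difference: float            # atoms/codon saved (mean_b - mean_a)
    codons_per_atom: float | None
    percent: float | None
    has_saving: bool


def nitrogen_savings_summary(mean_a: float, mean_b: float) -> NitrogenSavings:
    """Summarise the saving of *mean_a* (cheaper) relative to *mean_b*.

    ``codons_per_atom`` = 1/(mean_b − mean_a) is the number of codons over
    which one whole nitrogen atom is saved; ``percent`` the relative saving.
    If mean_b ≤ mean_a there is no saving and both are None.
    """
    diff = float(mean_b) - float(mean_a)
    if diff <= 0:
        return NitrogenSavings(difference=diff, codons_per_atom=None, percent=None, has_saving=False)
    return NitrogenSavings(
        difference=diff,
        codons_per_atom=1.0 / diff,
        percent=100.0 * diff / float(mean_b),
        has_saving=True,
    )


def transcriptome_nitrogen_saving(
    n_transcripts: float, mean_length_codons: float, codons_per_atom: float
) -> float:
    """Whole-transcriptome atoms saved: n_transcripts × length / codons-per-atom."""
    return n_transcripts * mean_length_codons / codons_per_atom


def protein_equivalents(atoms: float, mean_protein_length: float) -> float:
    """Number of average-sized proteins buildable from *atoms* backbone
    nitrogens (one amide nitrogen per residue)."""
    return atoms / mean_protein_length


def per_gene_dsdna_saving(mean_length_codons: float, codons_per_atom: float) -> float:
    """Atoms saved per gene in double-stranded DNA at the given rate."""
    return mean_length_codons / codons_per_atom


def genome_nitrogen_saving(n_genes: float, atoms_per_gene: float, ploidy: int = 2) -> float:
    """Genome-wide atoms saved: ploidy × gene count × per-gene saving."""
    return ploidy * n_genes * atoms_per_gene


def anova_species_selection(groups: Mapping[str, Sequence[float]]):
    """One-way ANOVA over per-species selection-bias distributions by group."""
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(samples) < 2:
        raise NitrocodonError("need at least two groups for ANOVA")
    f, p = sps.f_oneway(*samples)
    return float(f), float(p)
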