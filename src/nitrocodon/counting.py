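"""Codon tallies from CDS records and the empirical codon-use probabilities.

Validation policy: a gene must be length-divisible by 3; a terminal stop is
discarded; a gene with an internal stop is dropped (logged, not fatal);
individual codons containing characters outside ACGT are skipped.  Counts are
therefore defined over the sense codons of the active genetic code only.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import DegenerateDataError, EmptyInputError
from .nitrogen import GeneticCode, STANDARD_CODE, nitrogen_dsdna, nitrogen_mrna


@dataclass
class CodonCounts:
    """Per-gene and pooled sense-codon counts for one species (or pool)."""

    species_id: str
    per_gene: dict[str, dict[str, int]]
    pooled: dict[str, int]
    n_genes: int

    @classmethod
    def from_pooled(cls, pooled: Mapping[str, float], species_id: str = "pooled") -> "CodonCounts":
        pooled = dict(pooled)
        return cls(species_id=species_id, per_gene={"pooled": dict(pooled)}, pooled=pooled, n_genes=1)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (gene, codon, n)
            for gene, counts in self.per_gene.items()
            for codon, n in sorted(counts.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "codon", "count"])


@dataclass
class CountSummary:
    """Bookkeeping from a counting run: genes kept/dropped and codons skipped."""

    kept: int = 0
    dropped: dict[str, str] = field(default_factory=dict)
    codons_skipped: int = 0


@dataclass(frozen=True)
class CodonProbTable:
    """Codon-use probabilities normalised within each synonymous family."""

    probs: Mapping[str, float]
    code: GeneticCode

    def family_sums(self) -> dict[str, float]:
        return {
            aa: sum(self.probs[c] for c in fam) for aa, fam in self.code.families.items()
        }

    def as_percentages(self) -> dict[str, float]:
        return {c: 100.0 * p for c, p in self.probs.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.code.codon_to_aa[c], c, self.probs[c]) for c in self.code.sense_codons
        ]
        return pd.DataFrame(rows, columns=["amino_acid", "codon", "probability"])


def _iter_records(cds_records) -> Iterable[tuple[str, str]]:
    for rec in cds_records:
        if isinstance(rec, tuple):
            yield str(rec[0]), str(rec[1])
        else:  # Bio.SeqRecord
            yield rec.id, str(rec.seq)


def count_codons(
    cds_records,
    code: GeneticCode = STANDARD_CODE,
    species_id: str = "species",
) -> tuple[CodonCounts, CountSummary]:
    """Tally sense codons per gene from CDS records.

    Parameters
    ----------
    cds_records
        Iterable of ``(gene_id, sequence)`` pairs or Biopython ``SeqRecord``s.
    code
        Active genetic code; names the validation policy's stop codons.

    Returns
    -------
    (CodonCounts, CountSummary)
        Counts over sense codons plus a summary of genes kept/dropped and
        codons skipped.
    """
    stops = {c for c, aa in code.codon_to_aa.items() if aa == "*"}
    per_gene: dict[str, dict[str, int]] = {}
    pooled: Counter = Counter()
    summary = CountSummary()
    n_records = 0
    for gene_id, raw in _iter_records(cds_records):
        n_records += 1
        seq = raw.upper().replace("U", "T")
        if len(seq) == 0 or len(seq) % 3:
            summary.dropped[gene_id] = f"length {len(seq)} not a positive multiple of 3"
            continue
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons[-1] in stops:
            codons = codons[:-1]
        clean: list[str] = []
        internal_stop = False
        skipped = 0
        for codon in codons:
            if codon in stops:
                internal_stop = True
                break
            if any(b not in "ACGT" for b in codon):
                skipped += 1
                continue
            clean.append(codon)
        if internal_stop:
            summary.dropped[gene_id] = f"internal stop codon (table {code.table_id})"
            continue
        summary.codons_skipped += skipped
        counts = dict(Counter(clean))
        per_gene[gene_id] = counts
        pooled.update(counts)
        summary.kept += 1
    if n_records == 0:
        raise EmptyInputError("no CDS records supplied")
    return (
        CodonCounts(
            species_id=species_id,
            per_gene=per_gene,
            pooled=dict(pooled),
            n_genes=len(per_gene),
        ),
        summary,
    )


def count_codons_fasta(path, code: GeneticCode = STANDARD_CODE, species_id: str | None = None):
    """`count_codons` over a multi-FASTA of CDS (ids taken up to first whitespace)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    return count_codons(records, code=code, species_id=species_id or str(path))


def empirical_probs(counts: CodonCounts | Mapping[str, float], code: GeneticCode = STANDARD_CODE) -> CodonProbTable:
    """Per-family empirical codon-use probabilities from pooled counts.

    Families with zero total count receive uniform probabilities and a
    warning (degenerate-input policy for small fixtures).
    """
    pooled = counts.pooled if isinstance(counts, CodonCounts) else dict(counts)
    probs: dict[str, float] = {}
    for aa, fam in code.families.items():
        total = sum(pooled.get(c, 0) for c in fam)
        if total == 0:
            warnings.warn(f"family {aa} has zero total count; using uniform probabilities")
            for c in fam:
                probs[c] = 1.0 / len(fam)
        else:
            for c in fam:
                probs[c] = pooled.get(c, 0) / total
    return CodonProbTable(probs=probs, code=code)


def mean_nitrogen_per_codon(codons: Sequence[str], mode: str = "mRNA") -> float:
    """Arithmetic mean nitrogen per codon over a gene's (filtered) codons.

    ``mode`` selects single-stranded ("mRNA") or double-stranded ("dsDNA")
    accounting.
    """
    if len(codons) == 0:
        raise DegenerateDataError("cannot average nitrogen over an empty codon list")
    fn = {"mRNA": nitrogen_mrna, "dsDNA": nitrogen_dsdna}.get(mode)
    if fn is None:
        raise ValueError(f"mode must be 'mRNA' or 'dsDNA', got {mode!r}")
    return sum(fn(c) for c in codons) / len(codons)
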