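"""Orthogroup filtering, codon-aware back-translation and the paired
per-gene nitrogen comparison, plus whole-ribosome rRNA nitrogen totals.

Filtering follows the comparative-study rules: an orthogroup is retained
only if every represented species contributes exactly one gene and every
nitrogen-availability group is represented by at least ``min_per_group``
species; alignment columns are kept only if gap-free in every row and their
column score strictly exceeds the threshold (default 0.75).  When no
external column scores are supplied, a fallback score — the fraction of rows
matching the modal residue — is computed; it is *not* equivalent to an
alignment-ensemble (MergeAlign-style) column score.

Alignment columns are 0-based half-open internally and 1-based in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    EmptyInputError,
    NitrocodonError,
    ScoreLengthError,
    TranslationMismatchError,
    UnknownSpeciesError,
)
from .nitrogen import (
    GeneticCode,
    STANDARD_CODE,
    nitrogen_dsdna,
    nitrogen_mrna,
    rna_total_nitrogen,
)

# -- vectorised codon-index machinery (hot paths over large alignments) ------

_BASE_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_LUT[ord(_b)] = _i
_BASE_LUT[ord("U")] = 3

_ALL_CODONS = ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_N_MRNA64 = np.array([nitrogen_mrna(c) for c in _ALL_CODONS], dtype=float)
_N_DSDNA64 = np.array([nitrogen_dsdna(c) for c in _ALL_CODONS], dtype=float)


def _row_codon_indices(row: str) -> np.ndarray:
    """Codon row -> per-column codon index in [0, 64); -1 for gaps/ambiguity."""
    raw = np.frombuffer(row.upper().encode(), dtype=np.uint8)
    bases = _BASE_LUT[raw].reshape(-1, 3)
    idx = bases[:, 0] * 16 + bases[:, 1] * 4 + bases[:, 2]
    idx[(bases < 0).any(axis=1)] = -1
    return idx


def _aa_codes(code: GeneticCode) -> np.ndarray:
    """Codon index -> amino-acid letter as uint8 ('*' for stops)."""
    return np.array([ord(code.codon_to_aa[c]) for c in _ALL_CODONS], dtype=np.int64)


@dataclass
class OrthogroupAlignment:
    """Codon-space alignment of one orthogroup with a per-column keep mask."""

    orthogroup_id: str
    rows: dict[str, str]                 # species -> aligned codon row (gaps as '---')
    keep_mask: np.ndarray | None = None  # per amino-acid column, after filtering
    scores: np.ndarray | None = None
    gene_ids: dict[str, str] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        any_row = next(iter(self.rows.values()))
        return len(any_row) // 3

    def column(self, idx: int) -> dict[str, str]:
        return {sp: row[3 * idx : 3 * idx + 3] for sp, row in self.rows.items()}

    def kept_codons(self, species: str) -> list[str]:
        if self.keep_mask is None:
            raise NitrocodonError("alignment has not been column-filtered yet")
        row = self.rows[species]
        return [row[3 * i : 3 * i + 3] for i in np.flatnonzero(self.keep_mask)]


def filter_orthogroups(
    membership: pd.DataFrame,
    groups: Mapping[str, str],
    min_per_group: int = 3,
) -> list[str]:
    """Retain single-copy orthogroups covered by ≥ *min_per_group* species in
    every group.

    ``membership`` must have columns orthogroup_id, species_id, gene_id.
    """
    required = {"orthogroup_id", "species_id", "gene_id"}
    if not required.issubset(membership.columns):
        raise NitrocodonError(f"membership table needs columns {sorted(required)}")
    unknown = set(membership["species_id"]) - set(groups)
    if unknown:
        raise UnknownSpeciesError(f"species without group assignment: {sorted(unknown)}")
    all_labels = sorted(set(groups.values()))
    retained = []
    for og_id, sub in membership.groupby("orthogroup_id", sort=True):
        per_species = sub.groupby("species_id")["gene_id"].nunique()
        if (per_species != 1).any():
            continue  # single-copy rule
        cover = {g: 0 for g in all_labels}
        for sp in per_species.index:
            cover[groups[sp]] += 1
        if all(cover[g] >= min_per_group for g in all_labels):
            retained.append(og_id)
    return retained


def backtranslate_alignment(
    protein_rows: Mapping[str, str],
    cds: Mapping[str, str],
    code: GeneticCode = STANDARD_CODE,
    orthogroup_id: str = "OG",
    gene_ids: Mapping[str, str] | None = None,
) -> OrthogroupAlignment:
    """Thread each species' CDS back through its aligned protein row.

    Each residue becomes its source codon; protein gaps become '---'.  The
    ungapped protein must translate exactly from the CDS (a terminal stop on
    the CDS is tolerated), otherwise a mismatch error names the species,
    1-based position and residues involved.
    """
    widths = {len(r) for r in protein_rows.values()}
    if len(widths) != 1:
        raise NitrocodonError(f"{orthogroup_id}: aligned protein rows differ in length")
    rows: dict[str, str] = {}
    for species, prot_row in protein_rows.items():
        seq = str(cds[species]).upper().replace("U", "T")
        if len(seq) % 3:
            raise TranslationMismatchError(
                f"{orthogroup_id}/{species}: CDS length {len(seq)} not a multiple of 3"
            )
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and code.codon_to_aa.get(codons[-1]) == "*":
            codons = codons[:-1]
        ungapped = prot_row.replace("-", "").upper()
        if len(codons) != len(ungapped):
            raise TranslationMismatchError(
                f"{orthogroup_id}/{species}: CDS has {len(codons)} codons but the "
                f"protein row has {len(ungapped)} residues"
            )
        seq_nostop = "".join(codons)
        idx = _row_codon_indices(seq_nostop)
        aa64 = _aa_codes(code)
        observed = np.where(idx >= 0, aa64[np.clip(idx, 0, 63)], ord("X"))
        expected = np.frombuffer(ungapped.encode(), dtype=np.uint8).astype(np.int64)
        mismatch = np.flatnonzero(observed != expected)
        if mismatch.size:
            j = int(mismatch[0])
            raise TranslationMismatchError(
                f"{orthogroup_id}/{species}: residue mismatch at position {j + 1}: "
                f"expected {ungapped[j]!r}, CDS codon {codons[j]} encodes "
                f"{chr(int(observed[j]))!r}"
            )
        if "-" not in prot_row:
            rows[species] = seq_nostop
        else:
            gap_cols = [i for i, ch in enumerate(prot_row) if ch == "-"]
            pieces = np.empty(len(prot_row), dtype=object)
            pieces[gap_cols] = "---"
            pieces[[i for i, ch in enumerate(prot_row) if ch != "-"]] = codons
            rows[species] = "".join(pieces)
    return OrthogroupAlignment(
        orthogroup_id=orthogroup_id,
        rows=rows,
        gene_ids=dict(gene_ids or {}),
    )


def modal_residue_scores(aln: OrthogroupAlignment, code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """Fallback per-column score: fraction of rows matching the modal residue.

    A stand-in used only when no external alignment-ensemble column scores
    are provided; documented as non-equivalent to them.
    """
    aa64 = _aa_codes(code)
    idx = np.stack([_row_codon_indices(row) for row in aln.rows.values()])
    aas = np.where(idx >= 0, aa64[np.clip(idx, 0, 63)], -1)  # (R, C)
    # modal count per column among non-gap rows
    match = (aas[:, None, :] == aas[None, :, :]) & (aas[None, :, :] >= 0) & (aas[:, None, :] >= 0)
    modal = match.sum(axis=0).max(axis=0)
    return modal / len(aln.rows)


def filter_columns(
    aln: OrthogroupAlignment,
    scores: Sequence[float] | None = None,
    threshold: float = 0.75,
    code: GeneticCode = STANDARD_CODE,
) -> OrthogroupAlignment:
    """Keep columns that are gap-free in every row AND score strictly above
    the threshold; idempotent and row-order invariant."""
    ncol = aln.n_columns
    if scores is None:
        score_vec = modal_residue_scores(aln, code=code)
    else:
        score_vec = np.asarray(list(scores), dtype=float)
        if score_vec.shape != (ncol,):
            raise ScoreLengthError(
                f"{aln.orthogroup_id}: {len(score_vec)} scores for {ncol} columns"
            )
    idx = np.stack([_row_codon_indices(row) for row in aln.rows.values()])
    gap_free = (idx >= 0).all(axis=0)
    keep = gap_free & (score_vec > threshold)
    if aln.keep_mask is not None:
        keep = keep & aln.keep_mask
    return OrthogroupAlignment(
        orthogroup_id=aln.orthogroup_id,
        rows=dict(aln.rows),
        keep_mask=keep,
        scores=score_vec,
        gene_ids=dict(aln.gene_ids),
    )


@dataclass
class PairedNitrogenTable:
    """Per gene × species nitrogen means over kept columns, plus totals."""

    table: pd.DataFrame  # orthogroup_id, species_id, group, n_codons, mean_n_mrna, mean_n_dsdna
    n_columns_total: int          # kept codon columns summed over orthogroups
    n_codon_observations: int     # kept columns × species (summed)
    excluded: list[str] = field(default_factory=list)

    def group_means_by_orthogroup(self, mode: str = "mRNA") -> pd.DataFrame:
        """Per-orthogroup mean of the per-gene means within each group: the
        paired observations for the between-group Wilcoxon tests."""
        col = {"mRNA": "mean_n_mrna", "dsDNA": "mean_n_dsdna"}[mode]
        return self.table.pivot_table(
            index="orthogroup_id", columns="group", values=col, aggfunc="mean"
        )


def paired_nitrogen_table(
    alignments: Sequence[OrthogroupAlignment],
    groups: Mapping[str, str],
) -> PairedNitrogenTable:
    """Assemble the paired per-gene nitrogen comparison from filtered
    alignments; orthogroups with zero kept columns are excluded (logged)."""
    rows = []
    excluded: list[str] = []
    ncols_total = 0
    nobs = 0
    for aln in alignments:
        if aln.keep_mask is None:
            raise NitrocodonError(f"{aln.orthogroup_id}: run filter_columns first")
        kept = int(aln.keep_mask.sum())
        if kept == 0:
            excluded.append(aln.orthogroup_id)
            continue
        ncols_total += kept
        keep = np.asarray(aln.keep_mask, dtype=bool)
        for species, row in aln.rows.items():
            if species not in groups:
                raise UnknownSpeciesError(f"species {species!r} has no group assignment")
            idx = _row_codon_indices(row)[keep]
            if (idx < 0).any():  # kept columns are gap-free by construction
                raise NitrocodonError(f"{aln.orthogroup_id}/{species}: gap in a kept column")
            nobs += len(idx)
            rows.append(
                (
                    aln.orthogroup_id,
                    species,
                    groups[species],
                    len(idx),
                    float(_N_MRNA64[idx].mean()),
                    float(_N_DSDNA64[idx].mean()),
                )
            )
    if not rows:
        raise EmptyInputError("no orthogroup retained any columns")
    table = pd.DataFrame(
        rows,
        columns=["orthogroup_id", "species_id", "group", "n_codons", "mean_n_mrna", "mean_n_dsdna"],
    )
    return PairedNitrogenTable(
        table=table,
        n_columns_total=ncols_total,
        n_codon_observations=nobs,
        excluded=excluded,
    )


@dataclass
class RibosomeNitrogen:
    """Total rRNA nitrogen per ribosome, or NF when a molecule is missing."""

    total: int | None
    missing: tuple[str, ...]

    @property
    def nf(self) -> bool:
        return bool(self.missing)


def ribosome_nitrogen(
    rrna: Mapping[str, str],
    molecule_set: Sequence[str],
) -> RibosomeNitrogen:
    """Sum rRNA nitrogen over the named molecules of one ribosome.

    A species missing any molecule is flagged NF ("not found") rather than
    raising, since incomplete rDNA assemblies are routine.
    """
    missing = tuple(m for m in molecule_set if m not in rrna or not rrna[m])
    if missing:
        return RibosomeNitrogen(total=None, missing=missing)
    return RibosomeNitrogen(
        total=sum(rna_total_nitrogen(rrna[m]) for m in molecule_set), missing=()
    )


def read_fasta_map(path) -> dict[str, str]:
    """id → sequence from a FASTA file (ids up to first whitespace)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_paired_pipeline(
    cds_by_species: Mapping[str, Mapping[str, str]],
    membership: pd.DataFrame,
    groups: Mapping[str, str],
    code: GeneticCode = STANDARD_CODE,
    protein_msas: Mapping[str, Mapping[str, str]] | None = None,
    column_scores: Mapping[str, Sequence[float]] | None = None,
    min_per_group: int = 3,
    score_threshold: float = 0.75,
) -> PairedNitrogenTable:
    """End-to-end paired comparison: filter orthogroups, back-translate,
    filter columns, assemble the nitrogen table.

    When ``protein_msas`` is omitted the proteins are translated from the CDS
    and must be indel-free (equal length across species) — the situation for
    the synthetic datasets; real data should supply aligned proteins.
    """
    retained = filter_orthogroups(membership, groups, min_per_group=min_per_group)
    gene_of = {
        (r.orthogroup_id, r.species_id): r.gene_id for r in membership.itertuples()
    }
    species_of_og = {
        og: sorted(sub["species_id"].unique())
        for og, sub in membership.groupby("orthogroup_id")
    }
    alignments = []
    for og_id in retained:
        species = species_of_og[og_id]
        cds = {sp: cds_by_species[sp][gene_of[(og_id, sp)]] for sp in species}
        if protein_msas is not None:
            prot_rows = dict(protein_msas[og_id])
        else:
            prot_rows = {}
            for sp, seq in cds.items():
                prot = code.translate(seq)
                if prot.endswith("*"):
                    prot = prot[:-1]
                prot_rows[sp] = prot
            if len({len(p) for p in prot_rows.values()}) != 1:
                raise NitrocodonError(
                    f"{og_id}: unaligned proteins differ in length; supply protein MSAs"
                )
        aln = backtranslate_alignment(
            prot_rows,
            cds,
            code=code,
            orthogroup_id=og_id,
            gene_ids={sp: gene_of[(og_id, sp)] for sp in species},
        )
        scores = None if column_scores is None else column_scores.get(og_id)
        alignments.append(filter_columns(aln, scores=scores, threshold=score_threshold, code=code))
    return paired_nitrogen_table(alignments, groups)
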