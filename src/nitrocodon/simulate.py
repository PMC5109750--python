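"""Sequence simulation and synthetic multi-species datasets.

``simulate_cds`` draws each residue's codon independently from its
synonymous family's probabilities, so the translation of the output always
equals the input protein.  ``generate_synthetic_dataset`` emulates a desk-
scale comparative study: orthogroups share one amino-acid sequence across
species (single-copy, indel-free), and each species' CDS is simulated under
its nitrogen-availability group's model parameters.  Phylogenetic
non-independence, indels and alignment error are deliberately not simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .counting import CodonProbTable
from .errors import DegenerateDataError, EmptyInputError, InvalidResidueError
from .model import ModelParams, codon_probs
from .nitrogen import GeneticCode
from .tai import TaiTable

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def simulate_cds(aa_sequence: str, probs: CodonProbTable, rng: np.random.Generator) -> str:
    """Simulate an in-frame CDS encoding *aa_sequence* from a codon table.

    Each residue's codon is drawn independently from its family's
    probabilities; deterministic given the generator state.
    """
    code = probs.code
    aa_seq = str(aa_sequence).upper()
    for aa in set(aa_seq):
        if aa not in code.families:
            raise InvalidResidueError(f"residue {aa!r} has no codon family in table {code.table_id}")
    # draw per amino acid in bulk, then place codons back in sequence order
    out = [""] * len(aa_seq)
    positions: dict[str, list[int]] = {}
    for i, aa in enumerate(aa_seq):
        positions.setdefault(aa, []).append(i)
    for aa in sorted(positions):
        fam = code.families[aa]
        p = np.array([probs.probs[c] for c in fam])
        p = p / p.sum()
        draws = rng.choice(len(fam), size=len(positions[aa]), p=p)
        for i, d in zip(positions[aa], draws):
            out[i] = fam[d]
    return "".join(out)


@dataclass
class SyntheticTruth:
    """Generator configuration plus the ground-truth model parameters.

    Defaults emulate the bacterial (Mollicute-style) study conditions: three
    nitrogen-availability groups with selection biases −0.24 (L_N), −0.15
    (M_N) and −0.13 (H_N) and a strong AT mutation bias m = 3.5; four species
    per group; 300 single-copy orthogroups with log-normal gene lengths
    averaging 630 codons; uniform amino-acid frequencies.
    """

    groups: Mapping[str, ModelParams] = field(
        default_factory=lambda: {
            "L_N": ModelParams(variant="selection_mutation", sel_n=-0.24, mut_m=3.5),
            "M_N": ModelParams(variant="selection_mutation", sel_n=-0.15, mut_m=3.5),
            "H_N": ModelParams(variant="selection_mutation", sel_n=-0.13, mut_m=3.5),
        }
    )
    n_species_per_group: int = 4
    n_orthogroups: int = 300
    mean_gene_length: float = 630.0  # codons
    length_log_sd: float = 0.35
    aa_frequencies: Mapping[str, float] = field(
        default_factory=lambda: {aa: 1.0 / 20.0 for aa in _AA20}
    )
    seed: int = 0
    table_id: int = 1

    def __post_init__(self):
        total = sum(self.aa_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"aa_frequencies must sum to 1, got {total}")
        if self.n_orthogroups < 1:
            raise EmptyInputError("n_orthogroups must be >= 1")
        if self.mean_gene_length < 1:
            raise ValueError("mean_gene_length must be >= 1 codon")

    def to_dict(self) -> dict:
        return {
            "groups": {
                g: {"variant": p.variant, "sel_n": p.sel_n, "mut_m": p.mut_m, "sel_tai": p.sel_tai}
                for g, p in self.groups.items()
            },
            "n_species_per_group": self.n_species_per_group,
            "n_orthogroups": self.n_orthogroups,
            "mean_gene_length": self.mean_gene_length,
            "length_log_sd": self.length_log_sd,
            "aa_frequencies": dict(self.aa_frequencies),
            "seed": self.seed,
            "table_id": self.table_id,
        }


@dataclass
class SyntheticDataset:
    """In-memory synthetic study: per-species CDS, membership and grouping."""

    truth: SyntheticTruth
    cds: dict[str, dict[str, str]]          # species -> gene_id -> CDS
    orthogroups: pd.DataFrame               # orthogroup_id, species_id, gene_id
    groups: dict[str, str]                  # species_id -> group label
    proteins: dict[str, str]                # orthogroup_id -> shared protein

    def write(self, outdir: str | Path) -> None:
        """Write per-species FASTA, membership/group TSVs and truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for species, genes in self.cds.items():
            with open(outdir / f"{species}.cds.fasta", "w") as fh:
                for gene_id, seq in genes.items():
                    fh.write(f">{gene_id}\n{seq}\n")
        self.orthogroups.to_csv(outdir / "orthogroups.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.groups.items()), columns=["species_id", "group"]
        ).to_csv(outdir / "groups.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth.to_dict(), fh, indent=2)


def generate_synthetic_dataset(
    truth: SyntheticTruth,
    code: GeneticCode | None = None,
    tai: TaiTable | None = None,
) -> SyntheticDataset:
    """Generate a complete multi-species dataset with known ground truth.

    For each orthogroup one shared amino-acid sequence is drawn (length from
    the log-normal distribution, residues i.i.d. from ``aa_frequencies``);
    each species' CDS is then simulated under its group's parameters.  All
    randomness flows from ``truth.seed``.
    """
    code = code or GeneticCode.from_table_id(truth.table_id)
    rng = np.random.default_rng(truth.seed)
    aas = sorted(truth.aa_frequencies)
    aa_p = np.array([truth.aa_frequencies[a] for a in aas])
    mu = np.log(truth.mean_gene_length) - truth.length_log_sd**2 / 2.0

    tables = {
        g: codon_probs(p, code=code, tai=tai) for g, p in truth.groups.items()
    }
    species_of_group = {
        g: [f"{g}_sp{i + 1}" for i in range(truth.n_species_per_group)]
        for g in truth.groups
    }
    groups = {sp: g for g, sps in species_of_group.items() for sp in sps}

    proteins: dict[str, str] = {}
    cds: dict[str, dict[str, str]] = {sp: {} for sp in groups}
    membership = []
    for og in range(truth.n_orthogroups):
        og_id = f"OG{og:05d}"
        length = max(1, int(round(rng.lognormal(mu, truth.length_log_sd))))
        protein = "".join(np.array(list(aas))[rng.choice(len(aas), size=length, p=aa_p)])
        proteins[og_id] = protein
        for g, sps in species_of_group.items():
            for sp in sps:
                gene_id = f"{sp}_{og_id}"
                cds[sp][gene_id] = simulate_cds(protein, tables[g], rng)
                membership.append((og_id, sp, gene_id))
    return SyntheticDataset(
        truth=truth,
        cds=cds,
        orthogroups=pd.DataFrame(membership, columns=["orthogroup_id", "species_id", "gene_id"]),
        groups=groups,
        proteins=proteins,
    )


def _codon_weights(probs: CodonProbTable, aa_frequencies: Mapping[str, float] | None):
    code = probs.code
    if aa_frequencies is None:
        aa_frequencies = {aa: 1.0 / len(code.families) for aa in code.families}
    codons = code.sense_codons
    w = np.array([aa_frequencies.get(code.codon_to_aa[c], 0.0) * probs.probs[c] for c in codons])
    return codons, w / w.sum()


def expected_codon_counts(
    probs: CodonProbTable,
    n_codons: float,
    aa_frequencies: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Noise-free counts exactly proportional to the generating table,
    scaled to *n_codons* total (amino acids weighted by ``aa_frequencies``,
    uniform over families by default)."""
    codons, w = _codon_weights(probs, aa_frequencies)
    return dict(zip(codons, n_codons * w))


def sample_codon_counts(
    probs: CodonProbTable,
    n_codons: int,
    rng: np.random.Generator,
    aa_frequencies: Mapping[str, float] | None = None,
) -> dict[str, int]:
    """Multinomial pooled codon counts from the generating table."""
    codons, w = _codon_weights(probs, aa_frequencies)
    draws = rng.multinomial(int(n_codons), w)
    return {c: int(n) for c, n in zip(codons, draws)}


def nitrogen_density_summary(values, grid_points: int = 512):
    """Gaussian kernel density of per-gene nitrogen means on an explicit grid.

    Returns ``(grid, density)``; the density integrates to 1 within 0.01 over
    the padded grid.  Constant input (zero spread) is rejected.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise DegenerateDataError("need at least two values for a density estimate")
    if np.ptp(arr) == 0:
        raise DegenerateDataError("constant input has no density estimate (degenerate spike)")
    kde = stats.gaussian_kde(arr)
    pad = 3.0 * arr.std(ddof=1)
    grid = np.linspace(arr.min() - pad, arr.max() + pad, grid_points)
    return grid, kde(grid)
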