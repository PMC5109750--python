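"""Nitrogen bookkeeping for nucleotide and protein sequences.

Purine bases (A, G) carry five nitrogen atoms, cytosine three and
thymine/uracil two, so an mRNA codon costs between 6 (TTT) and 15 (e.g. GGG)
nitrogen atoms while a double-stranded codon costs between 21 (three A·T
pairs, 7 each) and 24 (three G·C pairs, 8 each).  These per-base costs are
the currency of every comparison in the package; they are loaded from a
machine-readable YAML config so an alternative element table (e.g. carbon)
can be swapped in.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import yaml
from Bio.Data import CodonTable

from .errors import InvalidCodonError, InvalidResidueError, InvalidSequenceError

_NUCLEOTIDES = frozenset("ACGTU")
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def load_element_tables(path: str | None = None) -> dict:
    """Load the per-nucleotide / per-basepair / per-sidechain atom tables.

    Parameters
    ----------
    path
        Optional path to an alternative YAML config with the same keys as the
        shipped ``data/element_tables.yaml``; by default the packaged nitrogen
        table is loaded.
    """
    if path is None:
        ref = importlib.resources.files("nitrocodon").joinpath("data/element_tables.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    tables = yaml.safe_load(text)
    for key in ("per_nucleotide", "per_basepair", "per_sidechain"):
        if key not in tables:
            raise KeyError(f"element table config missing '{key}'")
    return tables


_TABLES = load_element_tables()

#: Nitrogen atoms per nucleotide base (A/G = 5, C = 3, T/U = 2).
NITROGEN_PER_NUCLEOTIDE: Mapping[str, int] = dict(_TABLES["per_nucleotide"])

#: Nitrogen atoms per double-stranded base pair (A·T = 7, G·C = 8).
NITROGEN_PER_BASEPAIR: Mapping[str, int] = dict(_TABLES["per_basepair"])

#: Nitrogen atoms in each amino acid's side chain.
SIDECHAIN_NITROGEN: Mapping[str, int] = dict(_TABLES["per_sidechain"])


def normalize_codon(codon: str) -> str:
    """Uppercase a codon and map U to T; raise on anything else.

    Raises
    ------
    InvalidCodonError
        If the codon is not three characters over {A, C, G, T, U}.
    """
    c = str(codon).upper().replace("U", "T")
    if len(c) != 3 or any(b not in _COMPLEMENT for b in c):
        raise InvalidCodonError(f"invalid codon {codon!r}")
    return c


def reverse_complement(codon: str) -> str:
    c = normalize_codon(codon)
    return "".join(_COMPLEMENT[b] for b in reversed(c))


def nitrogen_mrna(codon: str) -> int:
    """Nitrogen atoms in the single-stranded (mRNA) form of *codon*.

    T and U are equivalent; the result lies in [6, 15].
    """
    c = normalize_codon(codon)
    return sum(NITROGEN_PER_NUCLEOTIDE[b] for b in c)


def nitrogen_dsdna(codon: str) -> int:
    """Nitrogen atoms in both strands of the codon's three base pairs.

    Each A or T position contributes an A·T pair (7 atoms), each G or C
    position a G·C pair (8 atoms); the result lies in [21, 24].
    """
    c = normalize_codon(codon)
    at = sum(1 for b in c if b in "AT")
    return NITROGEN_PER_BASEPAIR["AT"] * at + NITROGEN_PER_BASEPAIR["GC"] * (3 - at)


def nitrogen_sidechain(aa: str) -> int:
    """Side-chain nitrogen atoms of a one-letter amino acid code."""
    key = str(aa).upper()
    try:
        return SIDECHAIN_NITROGEN[key]
    except KeyError:
        raise InvalidResidueError(f"unknown amino acid {aa!r}") from None


def rna_total_nitrogen(sequence: str) -> int:
    """Total nitrogen atoms in an RNA/DNA sequence; gaps ('-') are ignored.

    Additive over concatenation, so a per-ribosome total is the sum over the
    constituent rRNA molecules.
    """
    total = 0
    for pos, base in enumerate(str(sequence).upper()):
        if base == "-":
            continue
        if base not in _NUCLEOTIDES:
            raise InvalidSequenceError(f"invalid character {base!r} at position {pos}")
        total += NITROGEN_PER_NUCLEOTIDE[base]
    return total


@dataclass(frozen=True)
class GeneticCode:
    """A translation table: codon → amino acid, plus the synonymous families.

    ``sense_codons`` excludes stops; under the standard table (1) there are 61
    sense codons, under the Mollicute table (4, TGA → Trp) there are 62.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    sense_codons: tuple[str, ...]
    families: Mapping[str, tuple[str, ...]] = field(repr=False)

    @classmethod
    def from_table_id(cls, table_id: int = 1) -> "GeneticCode":
        try:
            table = CodonTable.unambiguous_dna_by_id[int(table_id)]
        except KeyError:
            raise ValueError(f"unknown translation table id {table_id}") from None
        codon_to_aa: dict[str, str] = {}
        for c1 in "TCAG":
            for c2 in "TCAG":
                for c3 in "TCAG":
                    codon = c1 + c2 + c3
                    codon_to_aa[codon] = (
                        "*" if codon in table.stop_codons else table.forward_table[codon]
                    )
        sense = tuple(c for c, aa in codon_to_aa.items() if aa != "*")
        families: dict[str, list[str]] = {}
        for codon in sense:
            families.setdefault(codon_to_aa[codon], []).append(codon)
        return cls(
            table_id=int(table_id),
            codon_to_aa=codon_to_aa,
            sense_codons=sense,
            families={aa: tuple(sorted(cs)) for aa, cs in families.items()},
        )

    def family_of(self, codon: str) -> tuple[str, ...]:
        """The synonymous family (tuple of codons) containing *codon*."""
        c = normalize_codon(codon)
        aa = self.codon_to_aa[c]
        if aa == "*":
            raise InvalidCodonError(f"{c} is a stop codon under table {self.table_id}")
        return self.families[aa]

    def translate(self, cds: str) -> str:
        """Translate an in-frame CDS (no stops allowed mid-sequence)."""
        seq = str(cds).upper().replace("U", "T")
        if len(seq) % 3:
            raise InvalidSequenceError(f"CDS length {len(seq)} is not a multiple of 3")
        return "".join(self.codon_to_aa[seq[i : i + 3]] for i in range(0, len(seq), 3))


#: The standard genetic code (table 1), the package default.
STANDARD_CODE = GeneticCode.from_table_id(1)

#: The Mollicute/mycoplasma code (table 4): TGA encodes tryptophan.
MOLLICUTE_CODE = GeneticCode.from_table_id(4)
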