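"""tRNA adaptation index: per-codon absolute adaptiveness ω.

ω(C) = Σ_j (1 − s_ij) · tGCN_ij, summed over the tRNA isoacceptors that
recognise codon C through Watson–Crick or wobble pairing at the anticodon
first (34) position.  tGCN is the tRNA gene copy number keyed by anticodon
(5'→3'), and s_ij is the selective constraint on coupling efficiency for
each pairing class.  ω is used unnormalised (no rescaling to max = 1)
because the translational-selection bias exponentiates it directly.

Limitations: the generic wobble rules below do not model bacterial
lysidine-modified tRNA-Ile2 reading of ATA, nor other lineage-specific
anticodon modifications.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import NitrocodonError
from .nitrogen import GeneticCode, STANDARD_CODE, reverse_complement

# codon third base -> [(anticodon wobble base actually encoded, s_ij key)];
# "I" keys denote inosine derived from a genomically encoded A34.
_WOBBLE_RULES = {
    "T": [("A", "A:T"), ("G", "G:T")],
    "C": [("G", "G:C"), ("A", "I:C")],
    "A": [("T", "T:A"), ("A", "I:A")],
    "G": [("C", "C:G"), ("T", "T:G")],
}


def load_wobble_constraints(path: str | None = None) -> dict[str, float]:
    """Read the s_ij config TSV (columns ``pair``, ``s``); package default if no path."""
    if path is None:
        ref = importlib.resources.files("nitrocodon").joinpath("data/wobble_constraints.tsv")
        with ref.open("rb") as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["pair"], df["s"].astype(float)))


@dataclass(frozen=True)
class TaiTable:
    """Per-codon adaptiveness ω plus provenance of the tGCN and s_ij inputs."""

    omega: Mapping[str, float]
    provenance: str
    unrecognized: tuple[str, ...] = ()  # sense codons with no recognising tRNA (ω = 0)


def tai_omega(
    tgcn: Mapping[str, int],
    sij: Mapping[str, float] | None = None,
    code: GeneticCode = STANDARD_CODE,
    provenance: str = "user tGCN table; packaged s_ij defaults",
) -> TaiTable:
    """Compute ω for every sense codon from anticodon gene copy numbers.

    Parameters
    ----------
    tgcn
        tRNA gene copy number per anticodon (5'→3' trinucleotide over ACGT).
    sij
        Pairing-class constraints; defaults to the packaged config.
    """
    if sij is None:
        sij = load_wobble_constraints()
    tgcn_norm: dict[str, int] = {}
    for anti, n in tgcn.items():
        n = int(n)
        if n < 0:
            raise NitrocodonError(f"negative tRNA gene copy number for anticodon {anti!r}")
        tgcn_norm[str(anti).upper().replace("U", "T")] = n
    omega: dict[str, float] = {}
    missing: list[str] = []
    for codon in code.sense_codons:
        tail = reverse_complement(codon)[1:]
        total = 0.0
        for wobble_base, key in _WOBBLE_RULES[codon[2]]:
            anticodon = wobble_base + tail
            copies = tgcn_norm.get(anticodon, 0)
            if copies:
                total += (1.0 - float(sij.get(key, 0.0))) * copies
        omega[codon] = total
        if total == 0.0:
            missing.append(codon)
    return TaiTable(omega=omega, provenance=provenance, unrecognized=tuple(missing))
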