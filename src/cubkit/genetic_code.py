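"""Genetic-code tables used throughout the package.

The standard nuclear code (NCBI translation table 1) is the default; any
NCBI table id can be plugged in for organisms with a non-standard code.
Synonymous *families* — the sets of codons translated to one amino acid —
are the unit every RSCU computation works over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

STOP = "*"

#: DNA alphabet accepted in coding sequences (N = ambiguity from assembly).
DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class GeneticCodeTable:
    """A codon → amino-acid map plus its synonymous-family structure.

    Attributes
    ----------
    table_id : NCBI translation table id.
    codon_to_aa : map from each of the 64 DNA codons to a one-letter amino
        acid, with ``"*"`` for stop.
    families : map amino acid → tuple of its synonymous codons (sorted).
    """

    table_id: int
    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]] = field(repr=False)

    @property
    def family_size(self) -> dict[str, int]:
        return {aa: len(c) for aa, c in self.families.items()}

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa != STOP))

    @property
    def single_codon_aas(self) -> frozenset[str]:
        """Amino acids with exactly one codon (Met, Trp under table 1)."""
        return frozenset(aa for aa, cs in self.families.items() if len(cs) == 1)

    @property
    def rscu_codons(self) -> tuple[str, ...]:
        """Codons that carry an RSCU value: sense codons in families of
        size ≥ 2 (59 codons under the standard code)."""
        return tuple(
            sorted(
                c
                for aa, cs in self.families.items()
                if len(cs) >= 2
                for c in cs
            )
        )

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"expected 64 codons, got {len(self.codon_to_aa)}")
        n_sense = sum(len(c) for c in self.families.values())
        if n_sense + len(self.stop_codons) != 64:
            raise ValueError("families and stop codons do not partition the code")


@lru_cache(maxsize=None)
def standard_code(table_id: int = 1) -> GeneticCodeTable:
    """Build a :class:`GeneticCodeTable` from an NCBI translation table."""
    bt = CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = dict(bt.forward_table)
    for c in bt.stop_codons:
        codon_to_aa[c] = STOP
    families: dict[str, list[str]] = {}
    for codon, aa in codon_to_aa.items():
        if aa != STOP:
            families.setdefault(aa, []).append(codon)
    fam = {aa: tuple(sorted(cs)) for aa, cs in sorted(families.items())}
    return GeneticCodeTable(table_id=table_id, codon_to_aa=codon_to_aa, families=fam)
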