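"""Codon counting, %GC, RSCU, and preferred-codon classification.

RSCU (relative synonymous codon usage) for codon *i* in a synonymous family
of size *k* with family total *n_fam* is ``n_i / (n_fam / k)``: the observed
count over the count expected if all synonyms were used equally.  RSCU = 1
means no preference; codons with RSCU ≥ 1.5 in the most highly expressed
ORFs (RPKM > 1,000) are called *preferred codons*.

Conventions: stop codons never enter counts or denominators; the
single-codon families ATG (Met) and TGG (Trp) carry no RSCU and cannot be
preferred, but they do count in the preferred-content denominator; a family
absent from a sequence has MISSING (NaN) RSCU for all its codons, whereas a
codon absent from a *present* family has a true RSCU of 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genetic_code import DNA_ALPHABET, GeneticCodeTable, standard_code

PREFERRED_THRESHOLD_DEFAULT = 1.5


class FrameError(ValueError):
    """Sequence length is not a multiple of 3 with frame checking on."""


class EmptyInputError(ValueError):
    pass


class UndefinedGCError(ValueError):
    """%GC is undefined (no unambiguous bases)."""


class UndefinedPreferredSetError(ValueError):
    """Preferred-codon set is UNDEFINED (no L5 ORFs), so content cannot be scored."""


@dataclass
class CodonCountVector:
    """Per-codon counts for one ORF or one pooled count set.

    ``counts`` holds sense codons only; stop codons are tallied separately
    in ``stop_tally`` and codons containing N are counted in ``skipped``.
    """

    counts: dict[str, int]
    source: str = ""
    stop_tally: dict[str, int] = field(default_factory=dict)
    skipped: int = 0

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountVector") -> "CodonCountVector":
        counts = dict(self.counts)
        for c, n in other.counts.items():
            counts[c] = counts.get(c, 0) + n
        stops = dict(self.stop_tally)
        for c, n in other.stop_tally.items():
            stops[c] = stops.get(c, 0) + n
        return CodonCountVector(
            counts=counts,
            source=f"{self.source}+{other.source}",
            stop_tally=stops,
            skipped=self.skipped + other.skipped,
        )


@dataclass
class RscuVector:
    """RSCU values for every codon in a multi-codon family.

    ``values[codon]`` is NaN (MISSING) when the codon's whole family has
    zero occurrences; a 0.0 is a real value (family present, codon unused).
    """

    values: dict[str, float]
    scope: str = "per-orf"

    def is_missing(self, codon: str) -> bool:
        return math.isnan(self.values[codon])

    def as_array(self, codon_order: tuple[str, ...]) -> np.ndarray:
        return np.array([self.values[c] for c in codon_order], dtype=float)


@dataclass
class PreferredCodonSet:
    """Codons called preferred for one yeast from its L5 RSCU."""

    yeast_id: str
    codons: frozenset[str]
    rscu_source: str = "pooled-L5"
    threshold: float = PREFERRED_THRESHOLD_DEFAULT
    undefined: bool = False  # True when the yeast had no L5 ORFs


def count_codons(
    seq: str,
    frame_check: bool = True,
    code: GeneticCodeTable | None = None,
    source: str = "",
) -> CodonCountVector:
    """Count codons in frame 0 of a coding sequence.

    Codons containing N are skipped (assembled contigs carry ambiguity
    characters); stop codons go to a side tally, not into ``counts``.
    """
    code = code or standard_code()
    if not seq:
        raise EmptyInputError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    if frame_check and len(seq) % 3 != 0:
        raise FrameError(f"length {len(seq)} is not a multiple of 3")
    counts: dict[str, int] = {}
    stops: dict[str, int] = {}
    skipped = 0
    stop_codons = code.stop_codons
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            skipped += 1
        elif codon in stop_codons:
            stops[codon] = stops.get(codon, 0) + 1
        else:
            counts[codon] = counts.get(codon, 0) + 1
    return CodonCountVector(counts=counts, source=source, stop_tally=stops, skipped=skipped)


def gc_percent(seq: str) -> float:
    """%GC of a sequence, with N excluded from both numerator and denominator."""
    if not seq:
        raise EmptyInputError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    gc = seq.count("G") + seq.count("C")
    acgt = len(seq) - seq.count("N")
    if acgt == 0:
        raise UndefinedGCError("all-N sequence has undefined %GC")
    return 100.0 * gc / acgt


def rscu(counts: CodonCountVector, code: GeneticCodeTable | None = None) -> RscuVector:
    """RSCU for every codon in a multi-codon family.

    Families with zero total count get NaN for all member codons; within a
    present family the values sum to the family size k.
    """
    code = code or standard_code()
    values: dict[str, float] = {}
    for aa, fam in code.families.items():
        k = len(fam)
        if k < 2:
            continue
        n_fam = sum(counts.counts.get(c, 0) for c in fam)
        if n_fam == 0:
            for c in fam:
                values[c] = math.nan
        else:
            expected = n_fam / k
            for c in fam:
                values[c] = counts.counts.get(c, 0) / expected
    return RscuVector(values=values, scope="per-orf")


def pooled_rscu(
    orfs: list[CodonCountVector], code: GeneticCodeTable | None = None
) -> RscuVector:
    """RSCU of counts summed across ORFs (the pooled codon-usage profile)."""
    if not orfs:
        raise EmptyInputError("no count vectors to pool")
    code = code or standard_code()
    pooled: dict[str, int] = {}
    for cv in orfs:
        for c, n in cv.counts.items():
            pooled[c] = pooled.get(c, 0) + n
    out = rscu(CodonCountVector(counts=pooled, source="POOLED"), code)
    out.scope = "pooled"
    return out


def call_preferred(
    pooled_l5: RscuVector | None,
    threshold: float = PREFERRED_THRESHOLD_DEFAULT,
    yeast_id: str = "",
    rscu_source: str = "pooled-L5",
) -> PreferredCodonSet:
    """Classify codons with RSCU ≥ threshold in the L5 profile as preferred.

    ``pooled_l5=None`` signals a yeast without any L5 ORF: the set is
    flagged UNDEFINED rather than returned empty.
    """
    if pooled_l5 is None:
        return PreferredCodonSet(
            yeast_id=yeast_id, codons=frozenset(), threshold=threshold,
            rscu_source=rscu_source, undefined=True,
        )
    members = frozenset(
        c for c, v in pooled_l5.values.items() if not math.isnan(v) and v >= threshold
    )
    return PreferredCodonSet(
        yeast_id=yeast_id, codons=members, threshold=threshold, rscu_source=rscu_source
    )


def preferred_content(counts: CodonCountVector, pref: PreferredCodonSet) -> float:
    """Percentage of an ORF's (sense) codons that are preferred.

    The denominator is all counted sense codons, including ATG and TGG,
    which can never be in the numerator.
    """
    if pref.undefined:
        raise UndefinedPreferredSetError(
            f"preferred set for {pref.yeast_id!r} is undefined (no L5 ORFs)"
        )
    total = counts.n_codons
    if total == 0:
        raise EmptyInputError("count vector has no codons")
    hit = sum(n for c, n in counts.counts.items() if c in pref.codons)
    return 100.0 * hit / total
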