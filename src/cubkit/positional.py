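"""Positional preferred-codon content: 30-nt segments, the 5′ ramp, and
structure/localization-coding segments.

ORFs are fragmented 5′→3′ into non-overlapping 30-nt segments (10 codons,
frame 0; a trailing partial segment is dropped).  The ramp summary is the
median over ORFs of the content difference between a segment and each of
its downstream segments, for the first 20 positions — negative values at
the 5′ end are the ramp signature.  Structure/localization content scores
each ORF's codons under one per-residue label category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import group_stats
from .codons import CodonCountVector, PreferredCodonSet, preferred_content
from .dataset import (
    LOCALIZATION_CATEGORIES,
    STRUCTURE_CATEGORIES,
    OrfRecord,
    YeastDataset,
    assign_expression_group,
)
from .group_stats import ALPHA_DEFAULT

logger = logging.getLogger(__name__)

SEGMENT_NT = 30
CODONS_PER_SEGMENT = SEGMENT_NT // 3
RAMP_WINDOW = 20        # first 5′ segments considered
RAMP_OFFSETS = 20       # downstream offsets per segment
RAMP_CELL_FLOOR = 10    # minimum ORFs contributing to a delta cell


@dataclass
class SegmentProfile:
    orf_id: str
    segment_percents: list[float]

    @property
    def n_segments(self) -> int:
        return len(self.segment_percents)


def fragment_orf(orf: OrfRecord, pref: PreferredCodonSet) -> SegmentProfile | None:
    """Per-segment preferred-codon percentages for one ORF.

    Returns None (logged) for ORFs shorter than one segment.
    """
    if orf.length_nt < SEGMENT_NT:
        logger.warning("ORF %s shorter than one segment; skipped", orf.orf_id)
        return None
    codons = orf.codons()
    n_seg = len(codons) // CODONS_PER_SEGMENT
    percents = []
    for s in range(n_seg):
        chunk = codons[s * CODONS_PER_SEGMENT : (s + 1) * CODONS_PER_SEGMENT]
        counts: dict[str, int] = {}
        for c in chunk:
            counts[c] = counts.get(c, 0) + 1
        cv = CodonCountVector(counts=counts, source=f"{orf.orf_id}:seg{s + 1}")
        percents.append(preferred_content(cv, pref))
    return SegmentProfile(orf_id=orf.orf_id, segment_percents=percents)


def _segment_matrix(profiles: list[SegmentProfile], max_segments: int) -> np.ndarray:
    mat = np.full((len(profiles), max_segments), np.nan)
    for i, p in enumerate(profiles):
        upto = min(p.n_segments, max_segments)
        mat[i, :upto] = p.segment_percents[:upto]
    return mat


def ramp_summary(
    profiles: list[SegmentProfile],
    groups: pd.Series | None = None,
    window: int = RAMP_WINDOW,
    offsets: int = RAMP_OFFSETS,
    floor: int = RAMP_CELL_FLOOR,
) -> dict[str, pd.DataFrame]:
    """Median content difference, segment s minus segment s+j.

    Returns one (window × offsets) delta matrix per expression group plus
    "ALL"; cells supported by fewer than ``floor`` ORFs are NaN (MISSING).
    ``groups`` maps orf_id → expression group; when None only "ALL" is
    computed.
    """
    by_group: dict[str, list[SegmentProfile]] = {"ALL": profiles}
    if groups is not None:
        for p in profiles:
            g = groups.get(p.orf_id)
            if g is not None:
                by_group.setdefault(g, []).append(p)

    out: dict[str, pd.DataFrame] = {}
    max_needed = window + offsets
    for gname, plist in sorted(by_group.items()):
        mat = _segment_matrix(plist, max_needed)
        delta = np.full((window, offsets), np.nan)
        for s in range(window):
            for j in range(1, offsets + 1):
                t = s + j
                if t >= max_needed:
                    continue
                diff = mat[:, s] - mat[:, t]
                diff = diff[~np.isnan(diff)]
                if len(diff) >= floor:
                    delta[s, j - 1] = float(np.median(diff))
        out[gname] = pd.DataFrame(
            delta,
            index=pd.Index(range(1, window + 1), name="segment"),
            columns=[f"+{j}" for j in range(1, offsets + 1)],
        )
    return out


def structure_content(
    yeast: YeastDataset,
    pref: PreferredCodonSet,
    scheme: str = "structure",
    alpha: float = ALPHA_DEFAULT,
    adjust: str = "bonferroni",
    by_expression_group: bool = True,
) -> dict[str, pd.DataFrame]:
    """Preferred-codon content of category-coding segments.

    ``scheme="structure"`` uses per-residue H/E/T/C labels (helix, strand,
    turn, coil); ``scheme="localization"`` uses c/e/t (cytoplasmic,
    extracellular, transmembrane).  Per ORF and category, content is
    computed over exactly the codons whose residue carries that label;
    categories are then compared all-pairs per expression group.
    """
    if scheme == "structure":
        categories = STRUCTURE_CATEGORIES
        attr = "structure_labels"
    elif scheme == "localization":
        categories = LOCALIZATION_CATEGORIES
        attr = "localization_labels"
    else:
        raise ValueError("scheme must be 'structure' or 'localization'")

    rows = []
    for orf in yeast.orfs:
        labels = getattr(orf, attr)
        if labels is None:
            continue
        codons = orf.codons()
        if len(labels) != len(codons):
            raise ValueError(
                f"{orf.orf_id}: {scheme} labels ({len(labels)}) do not match "
                f"codon count ({len(codons)})"
            )
        unknown = set(labels) - set(categories)
        if unknown:
            raise ValueError(f"{orf.orf_id}: unknown {scheme} labels {sorted(unknown)}")
        group = assign_expression_group(orf.rpkm)
        for sym, name in categories.items():
            sub = [c for c, l in zip(codons, labels) if l == sym]
            if not sub:
                continue
            counts: dict[str, int] = {}
            for c in sub:
                counts[c] = counts.get(c, 0) + 1
            cv = CodonCountVector(counts=counts, source=orf.orf_id)
            rows.append(
                {"orf_id": orf.orf_id, "yeast_id": yeast.yeast_id, "group": group,
                 "category": name, "n_codons": len(sub),
                 "content": preferred_content(cv, pref)}
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError(f"no ORF carries {scheme} labels")

    comp_rows = []
    strata = table.groupby("group") if by_expression_group else [("ALL", table)]
    for gname, sub in strata:
        cats = {c: s["content"].to_numpy() for c, s in sub.groupby("category")}
        cats = {c: v for c, v in cats.items() if len(v) >= group_stats.MIN_GROUP_N}
        if len(cats) < 2:
            continue
        for r in group_stats.kw_dunn(cats, alpha=alpha, adjust=adjust,
                                     unit=f"{scheme}-content"):
            d = r.__dict__ | {"expression_group": gname, "yeast_id": yeast.yeast_id}
            comp_rows.append(d)
    return {"content": table, "comparisons": pd.DataFrame(comp_rows)}
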