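"""Shared tabular builders: per-ORF RSCU tables and group summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codons import PreferredCodonSet, preferred_content, pooled_rscu, rscu
from .dataset import EXPRESSION_GROUPS, YeastDataset, assign_expression_group
from .genetic_code import GeneticCodeTable, standard_code


def orf_rscu_table(
    yeast: YeastDataset, code: GeneticCodeTable | None = None
) -> pd.DataFrame:
    """Per-ORF RSCU table: rows = ORFs, columns = the fixed 59-codon index,
    NaN where the codon's family is absent from the ORF."""
    code = code or standard_code()
    order = code.rscu_codons
    data = np.empty((len(yeast.orfs), len(order)), dtype=float)
    ids = []
    for i, orf in enumerate(yeast.orfs):
        vec = rscu(orf.codon_counts(code), code)
        data[i] = vec.as_array(order)
        ids.append(orf.orf_id)
    return pd.DataFrame(data, index=pd.Index(ids, name="orf_id"), columns=list(order))


def pooled_group_rscu(
    yeast: YeastDataset,
    group: str = "L5",
    code: GeneticCodeTable | None = None,
):
    """Pooled RSCU over the ORFs of one expression group, or None if the
    group is empty (e.g. a yeast without L5 ORFs)."""
    code = code or standard_code()
    members = [o for o in yeast.orfs if assign_expression_group(o.rpkm) == group]
    if not members:
        return None
    return pooled_rscu([o.codon_counts(code) for o in members], code)


def group_rscu_summary(
    datasets: dict[str, YeastDataset],
    stat: str = "median",
    code: GeneticCodeTable | None = None,
) -> pd.DataFrame:
    """Per-yeast, per-expression-group, per-codon summary of per-ORF RSCU.

    The default summary is the median (matching the nonparametric framing);
    ``stat="mean"`` is selectable.  Rows are a (yeast_id, group)
    MultiIndex; empty groups are absent.
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    code = code or standard_code()
    rows = []
    index = []
    for yid in sorted(datasets):
        yeast = datasets[yid]
        table = orf_rscu_table(yeast, code)
        labels = pd.Series(
            [assign_expression_group(o.rpkm) for o in yeast.orfs], index=table.index
        )
        for g in EXPRESSION_GROUPS:
            sub = table.loc[labels == g]
            if sub.empty:
                continue
            rows.append(sub.median() if stat == "median" else sub.mean())
            index.append((yid, g))
    if not rows:
        raise ValueError("no (yeast, group) combination has ORFs")
    out = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["yeast_id", "group"]))
    return out


def content_table(yeast: YeastDataset, pref: PreferredCodonSet) -> pd.DataFrame:
    """Per-ORF preferred-codon content with expression group and annotations."""
    rows = []
    for orf in yeast.orfs:
        rows.append(
            {
                "orf_id": orf.orf_id,
                "yeast_id": yeast.yeast_id,
                "group": assign_expression_group(orf.rpkm),
                "content": preferred_content(orf.codon_counts(), pref),
                "pathway": orf.pathway,
                "log2fc": orf.log2fc,
            }
        )
    return pd.DataFrame(rows)
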