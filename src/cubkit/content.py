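"""Preferred-codon content across cellular pathways and regulated ORF sets.

The per-ORF preferred-codon percentage is compared (i) across the 22
cellular-pathway categories within each yeast, and (ii) between
up-regulated (log2FC ≥ 1) and down-regulated (log2FC ≤ −1) ORF sets,
overall and per pathway.  All comparisons use the Kruskal–Wallis + Dunn
machinery of :mod:`cubkit.group_stats`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import group_stats
from .codons import PreferredCodonSet
from .dataset import YeastDataset
from .group_stats import ALPHA_DEFAULT, InsufficientGroupsError
from .tables import content_table

logger = logging.getLogger(__name__)

#: The 22 cellular-pathway categories and their abbreviations.
PATHWAYS: dict[str, str] = {
    "Amino acid metabolism": "Aam",
    "Biosynthesis of other secondary metabolites": "Boosm",
    "Carbohydrate metabolism": "Cmet",
    "Cell growth and death": "Cgad",
    "Cell motility": "Cmom",
    "Cellular community - eukaryotes": "Cc-e",
    "Energy metabolism": "Em",
    "Folding, sorting, and degradation": "Fsad",
    "Glycan biosynthesis and metabolism": "Gbam",
    "Lipid metabolism": "Lm",
    "Membrane transport": "Mt",
    "Metabolism of cofactors and vitamins": "Mocav",
    "Metabolism of other amino acids": "Mooaa",
    "Metabolism of terpenoids and polyketides": "Motap",
    "Nucleotide metabolism": "Nm",
    "Replication and repair": "Rar",
    "Signal transduction": "St",
    "Signaling molecules and interaction": "Smai",
    "Transcription": "Transc",
    "Translation": "Transl",
    "Transport and catabolism": "Tac",
    "Xenobiotics biodegradation and metabolism": "Xbam",
}

PATHWAY_ABBREVIATIONS: tuple[str, ...] = tuple(sorted(PATHWAYS.values()))

UP_THRESHOLD = 1.0      # log2FC ≥ 1  → up-regulated (closed bound)
DOWN_THRESHOLD = -1.0   # log2FC ≤ −1 → down-regulated (closed bound)

MIN_PATHWAY_N = 2


class UnknownPathwayError(ValueError):
    pass


def validate_pathway(label: str) -> str:
    if label not in PATHWAY_ABBREVIATIONS:
        raise UnknownPathwayError(
            f"unknown pathway {label!r}; allowed abbreviations: "
            f"{', '.join(PATHWAY_ABBREVIATIONS)}"
        )
    return label


def regulation_direction(log2fc: float) -> str | None:
    """'up' for log2FC ≥ 1, 'down' for ≤ −1, else None (both bounds closed)."""
    if log2fc >= UP_THRESHOLD:
        return "up"
    if log2fc <= DOWN_THRESHOLD:
        return "down"
    return None


def pathway_content(
    yeast: YeastDataset,
    pref: PreferredCodonSet,
    alpha: float = ALPHA_DEFAULT,
    adjust: str = "bonferroni",
) -> dict[str, pd.DataFrame]:
    """Preferred-codon content per pathway with all-pairs comparisons.

    Returns the per-pathway distribution summary, the long pairwise
    comparison table (median differences are the pathway-vs-pathway
    quantity), and the count of significant pathway pairs.
    """
    table = content_table(yeast, pref).dropna(subset=["pathway"])
    for p in table["pathway"].unique():
        validate_pathway(p)
    sizes = table.groupby("pathway").size()
    keep = sizes[sizes >= MIN_PATHWAY_N].index
    for p in sizes[sizes < MIN_PATHWAY_N].index:
        logger.warning("pathway %s dropped (n=%d)", p, sizes[p])
    table = table[table["pathway"].isin(keep)]
    if table["pathway"].nunique() < 2:
        raise InsufficientGroupsError("need ≥ 2 pathways with ≥ 2 annotated ORFs")

    summary = (
        table.groupby("pathway")["content"]
        .agg(n_orfs="size", median="median", q1=lambda s: s.quantile(0.25),
             q3=lambda s: s.quantile(0.75))
        .reset_index()
        .assign(yeast_id=yeast.yeast_id)
    )
    groups = {p: sub["content"].to_numpy() for p, sub in table.groupby("pathway")}
    results = group_stats.results_to_frame(
        group_stats.kw_dunn(groups, alpha=alpha, adjust=adjust, unit="pathway-content")
    ).assign(yeast_id=yeast.yeast_id)
    n_sig = int(results["significant"].sum())
    return {"summary": summary, "comparisons": results,
            "n_significant_pairs": pd.Series({"n_significant_pairs": n_sig})}


def regulation_content(
    yeast: YeastDataset,
    pref: PreferredCodonSet,
    alpha: float = ALPHA_DEFAULT,
    by_pathway: bool = False,
    adjust: str = "bonferroni",
) -> dict[str, pd.DataFrame]:
    """Up- vs down-regulated preferred-codon content, overall and per pathway.

    The per-pathway pass emits the "% up-down" median difference for each
    pathway whose up/down distributions differ significantly.
    """
    table = content_table(yeast, pref).dropna(subset=["log2fc"])
    table = table.assign(direction=table["log2fc"].map(regulation_direction))
    table = table.dropna(subset=["direction"])
    summary = (
        table.groupby("direction")["content"]
        .agg(n_orfs="size", median="median")
        .reset_index()
        .assign(yeast_id=yeast.yeast_id)
    )
    out: dict[str, pd.DataFrame] = {"summary": summary}

    counts = table["direction"].value_counts()
    if counts.get("up", 0) < 2 or counts.get("down", 0) < 2:
        logger.warning("yeast %s: a regulation direction is (nearly) empty; "
                       "overall comparison skipped", yeast.yeast_id)
        out["comparison"] = pd.DataFrame()
    else:
        res = group_stats.kw_dunn(
            {"up": table.loc[table["direction"] == "up", "content"].to_numpy(),
             "down": table.loc[table["direction"] == "down", "content"].to_numpy()},
            alpha=alpha, adjust=adjust, unit="regulation-content",
        )
        out["comparison"] = group_stats.results_to_frame(res).assign(
            yeast_id=yeast.yeast_id
        )

    if by_pathway:
        rows = []
        for pathway, sub in table.dropna(subset=["pathway"]).groupby("pathway"):
            validate_pathway(pathway)
            up = sub.loc[sub["direction"] == "up", "content"].to_numpy()
            down = sub.loc[sub["direction"] == "down", "content"].to_numpy()
            if len(up) < 2 or len(down) < 2:
                continue
            res = group_stats.kw_dunn({"up": up, "down": down}, alpha=alpha,
                                      adjust=adjust, unit=pathway)[0]
            rows.append(
                {"yeast_id": yeast.yeast_id, "pathway": pathway,
                 "pct_up_minus_down": float(np.median(up) - np.median(down)),
                 "dunn_p_adj": res.dunn_p_adj, "significant": res.significant,
                 "n_up": len(up), "n_down": len(down)}
            )
        out["per_pathway"] = pd.DataFrame(rows)
    return out
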