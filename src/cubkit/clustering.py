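"""Hierarchical clustering of yeasts on their L5 codon-usage profiles.

Each yeast is represented by the pooled RSCU of its most highly expressed
ORFs (L5, RPKM > 1,000) over the fixed 59-codon index.  Yeasts are
agglomeratively clustered — correlation distance (1 − Pearson r between
profiles) with average linkage by default, Euclidean/Ward selectable —
and the tree is cut into k main groups (default 9) whose OTG
distributions are summarized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from skbio import TreeNode

from .dataset import YeastDataset
from .genetic_code import GeneticCodeTable, standard_code
from .tables import pooled_group_rscu

logger = logging.getLogger(__name__)

DEFAULT_DISTANCE = "correlation"
DEFAULT_LINKAGE = "average"
DEFAULT_K = 9


@dataclass
class ClusterResult:
    linkage: np.ndarray
    yeast_ids: list[str]
    groups: dict[str, int]
    group_otg: pd.DataFrame
    newick: str

    @property
    def k(self) -> int:
        return len(set(self.groups.values()))


def yeast_profile(
    yeast: YeastDataset, code: GeneticCodeTable | None = None
) -> pd.Series | None:
    """Pooled L5 RSCU profile over the fixed 59-codon index, or None when
    the yeast has no L5 ORF (it is then excluded from clustering)."""
    code = code or standard_code()
    pooled = pooled_group_rscu(yeast, "L5", code)
    if pooled is None:
        logger.warning("yeast %s has no L5 ORFs; excluded from clustering",
                       yeast.yeast_id)
        return None
    return pd.Series(pooled.as_array(code.rscu_codons), index=list(code.rscu_codons),
                     name=yeast.yeast_id)


def profile_matrix(
    datasets: dict[str, YeastDataset], code: GeneticCodeTable | None = None
) -> pd.DataFrame:
    """Stack per-yeast L5 profiles; codons missing in one yeast are imputed
    with the cross-yeast median (flagged in the log) so a single sparse
    yeast cannot drop a codon for everyone."""
    rows = []
    for yid in sorted(datasets):
        prof = yeast_profile(datasets[yid], code)
        if prof is not None:
            rows.append(prof)
    if len(rows) < 3:
        raise ValueError("need at least three yeasts with L5 profiles")
    mat = pd.DataFrame(rows)
    if mat.isna().any().any():
        n = int(mat.isna().sum().sum())
        logger.warning("imputing %d missing profile entries with cross-yeast medians", n)
        mat = mat.fillna(mat.median())
    return mat


def cluster_yeasts(
    profiles: pd.DataFrame,
    otg: pd.Series | None = None,
    distance: str = DEFAULT_DISTANCE,
    linkage: str = DEFAULT_LINKAGE,
    k: int = DEFAULT_K,
) -> ClusterResult:
    """Agglomerative clustering of yeast profiles cut into k groups.

    Profiles are sorted by yeast id before distance computation so equal
    merge heights resolve deterministically.  Group indices are renumbered
    1..k in order of first appearance down the sorted id list.
    """
    profiles = profiles.sort_index()
    n = len(profiles)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} yeasts available")
    x = profiles.to_numpy(dtype=float)
    if distance == "correlation" and np.any(np.ptp(x, axis=1) == 0):
        # correlation distance is undefined for flat profiles (e.g. the
        # all-identical corner case); fall back to Euclidean there
        logger.warning("flat profile encountered; using euclidean distance")
        distance = "euclidean"
    dists = pdist(x, metric=distance)
    if np.allclose(dists, 0.0):
        logger.warning("all yeast profiles identical; every cut is arbitrary")
    if linkage == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    z = hierarchy.linkage(dists, method=linkage)
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    groups: dict[str, int] = {}
    for yid, g in zip(profiles.index, raw):
        if g not in remap:
            remap[g] = len(remap) + 1
        groups[yid] = remap[g]

    if otg is not None:
        rows = []
        for g in sorted(set(groups.values())):
            members = [y for y, gg in groups.items() if gg == g]
            vals = otg.reindex(members).dropna()
            rows.append(
                {"group": g, "n_yeasts": len(members),
                 "otg_median": float(vals.median()) if len(vals) else np.nan,
                 "otg_min": float(vals.min()) if len(vals) else np.nan,
                 "otg_max": float(vals.max()) if len(vals) else np.nan}
            )
        group_otg = pd.DataFrame(rows)
    else:
        group_otg = pd.DataFrame(columns=["group", "n_yeasts", "otg_median",
                                          "otg_min", "otg_max"])

    tree = TreeNode.from_linkage_matrix(z, list(profiles.index))
    newick = str(tree).strip()
    return ClusterResult(linkage=z, yeast_ids=list(profiles.index), groups=groups,
                         group_otg=group_otg, newick=newick)
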