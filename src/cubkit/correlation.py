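"""Difference-matrix correlations of codon usage with growth temperature
and expression level.

The procedure builds, for every codon, a matrix of paired differences over
all combinations of yeast strains and expression-level groups: the
difference in the group-summary RSCU (median per codon across the group's
ORFs), the difference in optimal growth temperature (OTG, °C), and the
difference in expression-group rank (L1=1 … L5=5).  Per-codon correlations
of the RSCU differences against OTG differences (between yeasts) or
expression-rank differences (within yeasts) are then screened at the
reporting thresholds |rho| ≥ 0.4 (OTG) and |rho| ≥ 0.5 (expression).

Spearman is the default correlation (the data reject normality);
Pearson is selectable.  A PCA of the difference matrix is an auxiliary
output.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

OTG_REPORTING_THRESHOLD = 0.4
EXPRESSION_REPORTING_THRESHOLD = 0.5
MIN_RECORDS = 5

GROUP_RANK = {"L1": 1, "L2": 2, "L3": 3, "L4": 4, "L5": 5}

META_COLUMNS = [
    "context", "yeast_a", "yeast_b", "group_a", "group_b", "d_otg", "d_expr",
]


def build_difference_matrix(
    group_summaries: pd.DataFrame, otg: pd.Series
) -> pd.DataFrame:
    """All pairwise difference records (first minus second).

    ``group_summaries``: (yeast_id, group) MultiIndex × codon columns, as
    produced by :func:`cubkit.tables.group_rscu_summary`. ``otg``: yeast_id
    → OTG in °C.  Between-yeast records cover every yeast pair × every
    (group-of-a, group-of-b) combination, same or different; within-yeast
    records cover every group pair inside each yeast and have d_otg = 0.
    """
    codons = list(group_summaries.columns)
    yeasts = sorted(group_summaries.index.get_level_values("yeast_id").unique())
    groups_of = {
        y: sorted(
            group_summaries.loc[y].index, key=lambda g: GROUP_RANK[g]
        )
        for y in yeasts
    }
    meta_rows: list[tuple] = []
    data_rows: list[np.ndarray] = []

    for ya, yb in itertools.combinations(yeasts, 2):
        d_otg = float(otg[ya] - otg[yb])
        for ga in groups_of[ya]:
            va = group_summaries.loc[(ya, ga)].to_numpy()
            for gb in groups_of[yb]:
                vb = group_summaries.loc[(yb, gb)].to_numpy()
                meta_rows.append(
                    ("between", ya, yb, ga, gb, d_otg,
                     GROUP_RANK[ga] - GROUP_RANK[gb])
                )
                data_rows.append(va - vb)

    for y in yeasts:
        for ga, gb in itertools.combinations(groups_of[y], 2):
            va = group_summaries.loc[(y, ga)].to_numpy()
            vb = group_summaries.loc[(y, gb)].to_numpy()
            meta_rows.append(
                ("within", y, y, ga, gb, 0.0, GROUP_RANK[ga] - GROUP_RANK[gb])
            )
            data_rows.append(va - vb)

    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    data = pd.DataFrame(np.vstack(data_rows) if data_rows else
                        np.empty((0, len(codons))), columns=codons)
    return pd.concat([meta, data], axis=1)


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        rho = stats.spearmanr(x, y).statistic
    elif method == "pearson":
        rho = stats.pearsonr(x, y).statistic
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(rho)


def correlate(
    differences: pd.DataFrame,
    target: str,
    method: str = "spearman",
    threshold: float | None = None,
    min_n: int = MIN_RECORDS,
) -> dict[str, pd.DataFrame | pd.Series]:
    """Per-codon correlation of RSCU differences against a target.

    ``target="otg"`` correlates d_rscu with d_otg on the between-yeast
    records; ``target="expression"`` correlates d_rscu with d_expr, both
    pooled and per yeast on the within-yeast records (the per-yeast pass
    yields, per codon, the count of yeasts reaching the threshold).
    Records where either side has zero variance are skipped with a reason.
    """
    if target == "otg":
        threshold = OTG_REPORTING_THRESHOLD if threshold is None else threshold
        contexts = {"between": differences[differences["context"] == "between"]}
        axis = "d_otg"
    elif target == "expression":
        threshold = EXPRESSION_REPORTING_THRESHOLD if threshold is None else threshold
        contexts = {
            "within-pooled": differences[differences["context"] == "within"],
            "between": differences[differences["context"] == "between"],
        }
        axis = "d_expr"
    else:
        raise ValueError("target must be 'otg' or 'expression'")

    codons = [c for c in differences.columns if c not in META_COLUMNS]
    rows = []
    for ctx_name, sub in contexts.items():
        for codon in codons:
            pair = sub[[axis, codon]].dropna()
            if len(pair) < min_n:
                continue
            x = pair[axis].to_numpy()
            y = pair[codon].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.info("codon %s in %s skipped: zero variance", codon, ctx_name)
                continue
            rho = _corr(x, y, method)
            rows.append(
                {"codon": codon, "context": ctx_name, "target": target,
                 "rho": rho, "n": len(pair), "reported": abs(rho) >= threshold}
            )
    results = pd.DataFrame(rows)

    out: dict[str, pd.DataFrame | pd.Series] = {"results": results}
    if target == "expression":
        within = differences[differences["context"] == "within"]
        per_yeast_rows = []
        for yeast, sub in within.groupby("yeast_a"):
            for codon in codons:
                pair = sub[["d_expr", codon]].dropna()
                if len(pair) < min_n:
                    continue
                x = pair["d_expr"].to_numpy()
                y = pair[codon].to_numpy()
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
                per_yeast_rows.append(
                    {"yeast_id": yeast, "codon": codon,
                     "rho": _corr(x, y, method), "n": len(pair)}
                )
        per_yeast = pd.DataFrame(per_yeast_rows)
        out["per_yeast"] = per_yeast
        if not per_yeast.empty:
            out["yeast_counts"] = (
                per_yeast.assign(hit=per_yeast["rho"].abs() >= threshold)
                .groupby("codon")["hit"].sum().astype(int)
            )
        else:
            out["yeast_counts"] = pd.Series(dtype=int)
    return out


def pca_difference_matrix(
    differences: pd.DataFrame, n_components: int | None = None
) -> dict[str, pd.DataFrame | np.ndarray]:
    """Centered (unscaled) PCA of the codon-difference matrix; auxiliary.

    Rows with any missing codon difference are dropped (complete-case),
    with a log line; rank deficiency simply reduces the component count.
    """
    codons = [c for c in differences.columns if c not in META_COLUMNS]
    matrix = differences[codons].dropna()
    dropped = len(differences) - len(matrix)
    if dropped:
        logger.info("PCA: %d incomplete rows dropped", dropped)
    x = matrix.to_numpy()
    max_rank = min(x.shape[0] - 1, x.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(x)
    return {
        "scores": pd.DataFrame(scores, index=matrix.index,
                               columns=[f"PC{i+1}" for i in range(k)]),
        "loadings": pd.DataFrame(pca.components_.T, index=codons,
                                 columns=[f"PC{i+1}" for i in range(k)]),
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }
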