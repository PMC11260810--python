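"""Kruskal–Wallis + Dunn comparison machinery and its summary matrices.

All group comparisons in the pipeline are nonparametric (the per-ORF RSCU
distributions are heavily non-normal, as the normality battery confirms):
a Kruskal–Wallis omnibus test across groups, followed by Dunn's pairwise
z-tests on mean ranks with tie correction, adjusted within each omnibus
family (Bonferroni by default; Holm and Benjamini–Hochberg selectable).

Dunn's statistic for groups a, b out of pooled N observations:

    z = (R̄_a − R̄_b) / sqrt( (N(N+1)/12 − T/(12(N−1))) (1/n_a + 1/n_b) )

with T = Σ (t³ − t) over tie groups; two-sided p from the normal.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05
MIN_GROUP_N = 2

ADJUSTMENTS = ("bonferroni", "holm", "fdr_bh", "none")


class InsufficientGroupsError(ValueError):
    pass


@dataclass
class ComparisonResult:
    """Outcome of one unit × group-pair Dunn comparison."""

    unit: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    kw_h: float
    kw_p: float
    dunn_z: float
    dunn_p: float
    dunn_p_adj: float
    significant: bool
    median_diff: float


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    if method == "none" or len(pvals) <= 1:
        return np.clip(pvals, 0.0, 1.0)
    if method == "bonferroni":
        return np.clip(pvals * len(pvals), 0.0, 1.0)
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method=method)[1]


def kw_dunn(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    alpha: float = ALPHA_DEFAULT,
    adjust: str = "bonferroni",
    unit: str = "",
    min_n: int = MIN_GROUP_N,
) -> list[ComparisonResult]:
    """Kruskal–Wallis omnibus plus Dunn's all-pairs post-hoc comparisons.

    Groups with fewer than ``min_n`` observations are dropped with a
    warning; fewer than two retained groups is an error.
    """
    if adjust not in ADJUSTMENTS:
        raise ValueError(f"unknown adjustment {adjust!r}")
    if isinstance(groups, list):
        groups = {f"g{i + 1}": g for i, g in enumerate(groups)}
    clean: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        if len(arr) < min_n:
            logger.warning("group %r dropped (n=%d < %d)", name, len(arr), min_n)
            continue
        clean[name] = arr
    if len(clean) < 2:
        raise InsufficientGroupsError(
            f"need ≥ 2 groups with ≥ {min_n} observations, got {len(clean)}"
        )

    names = list(clean)
    pooled = np.concatenate([clean[n] for n in names])
    n_total = len(pooled)
    if np.all(pooled == pooled[0]):
        kw_h, kw_p = 0.0, 1.0
    else:
        kw_h, kw_p = stats.kruskal(*[clean[n] for n in names])

    ranks = stats.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for n in names:
        n_i = len(clean[n])
        mean_rank[n] = float(ranks[start : start + n_i].mean())
        start += n_i
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_base -= tie_term / (12.0 * (n_total - 1))

    pairs = list(itertools.combinations(names, 2))
    zs, ps = [], []
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / len(clean[a]) + 1.0 / len(clean[b])))
        z = 0.0 if se == 0.0 else (mean_rank[a] - mean_rank[b]) / se
        zs.append(z)
        ps.append(2.0 * stats.norm.sf(abs(z)))
    p_adj = _adjust(np.array(ps), adjust)

    results = []
    for (a, b), z, p, pa in zip(pairs, zs, ps, p_adj):
        results.append(
            ComparisonResult(
                unit=unit,
                group_a=a,
                group_b=b,
                n_a=len(clean[a]),
                n_b=len(clean[b]),
                kw_h=float(kw_h),
                kw_p=float(kw_p),
                dunn_z=float(z),
                dunn_p=float(p),
                dunn_p_adj=float(pa),
                significant=bool(pa <= alpha),
                median_diff=float(np.median(clean[a]) - np.median(clean[b])),
            )
        )
    return results


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def pairwise_yeast_codon_matrix(
    rscu_per_orf: dict[str, pd.DataFrame],
    alpha: float = ALPHA_DEFAULT,
    adjust: str = "bonferroni",
) -> dict[str, pd.DataFrame | pd.Series]:
    """Count, per yeast pair, codons whose per-ORF RSCU distributions differ.

    ``rscu_per_orf`` maps yeast id → per-ORF RSCU table (ORFs × codons,
    NaN = missing family).  Returns the pair × pair significant-codon count
    matrix, the per-codon percentage of significant pairs, the long result
    table, and a count-distribution summary (median, IQR).
    """
    yeasts = sorted(rscu_per_orf)
    if len(yeasts) < 2:
        raise InsufficientGroupsError("need at least two yeasts")
    codons = list(rscu_per_orf[yeasts[0]].columns)
    matrix = pd.DataFrame(0, index=yeasts, columns=yeasts, dtype=int)
    sig_pairs_per_codon = {c: 0 for c in codons}
    rows: list[ComparisonResult] = []
    n_pairs = 0
    for ya, yb in itertools.combinations(yeasts, 2):
        n_pairs += 1
        n_sig = 0
        for codon in codons:
            a = rscu_per_orf[ya][codon].dropna().to_numpy()
            b = rscu_per_orf[yb][codon].dropna().to_numpy()
            if len(a) < MIN_GROUP_N or len(b) < MIN_GROUP_N:
                continue  # codon untestable for this pair
            res = kw_dunn({ya: a, yb: b}, alpha=alpha, adjust=adjust, unit=codon)
            rows.extend(res)
            if res[0].significant:
                n_sig += 1
                sig_pairs_per_codon[codon] += 1
        matrix.loc[ya, yb] = matrix.loc[yb, ya] = n_sig
    counts = np.array(
        [matrix.loc[a, b] for a, b in itertools.combinations(yeasts, 2)], dtype=float
    )
    summary = pd.Series(
        {
            "n_pairs": float(n_pairs),
            "median": float(np.median(counts)),
            "iqr": float(np.subtract(*np.percentile(counts, [75, 25]))),
        }
    )
    percent = pd.Series(
        {c: 100.0 * k / n_pairs for c, k in sig_pairs_per_codon.items()}, name="percent"
    )
    return {
        "matrix": matrix,
        "percent_per_codon": percent,
        "results": results_to_frame(rows),
        "summary": summary,
    }


def within_yeast_group_comparison(
    orf_rscu: pd.DataFrame,
    group_labels: pd.Series,
    alpha: float = ALPHA_DEFAULT,
    adjust: str = "bonferroni",
) -> dict[str, pd.DataFrame]:
    """Per-codon KW + Dunn across a grouping scheme within one yeast.

    ``orf_rscu``: ORFs × codons RSCU table; ``group_labels``: group label
    per ORF (same index).  Returns the long result table and a group-pair
    summary counting significant codons.
    """
    labels = group_labels.reindex(orf_rscu.index)
    present = sorted(labels.dropna().unique())
    if len(present) < 2:
        raise InsufficientGroupsError("fewer than two groups present")
    rows: list[ComparisonResult] = []
    for codon in orf_rscu.columns:
        groups = {
            g: orf_rscu.loc[labels == g, codon].dropna().to_numpy() for g in present
        }
        groups = {g: v for g, v in groups.items() if len(v) >= MIN_GROUP_N}
        if len(groups) < 2:
            continue
        rows.extend(kw_dunn(groups, alpha=alpha, adjust=adjust, unit=codon))
    frame = results_to_frame(rows)
    if frame.empty:
        raise InsufficientGroupsError("no codon was testable across the groups")
    summary = (
        frame.groupby(["group_a", "group_b"])["significant"]
        .sum()
        .astype(int)
        .reset_index()
        .rename(columns={"significant": "n_significant_codons"})
    )
    return {"results": frame, "summary": summary}


def normality_battery(sample: np.ndarray, alpha: float = ALPHA_DEFAULT) -> pd.Series:
    """Diagnostic battery: Lilliefors, Kolmogorov–Smirnov, Anderson–Darling,
    and D'Agostino K² p-values.  The pipeline stays nonparametric whatever
    the outcome; this only documents why.
    """
    x = np.asarray(sample, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 8:
        logger.warning("normality battery skipped (n=%d < 8)", len(x))
        return pd.Series(dtype=float)
    if np.all(x == x[0]):
        logger.warning("normality battery on constant sample; tests degenerate")
        return pd.Series(
            {"lilliefors": np.nan, "ks": np.nan, "anderson_darling": np.nan,
             "dagostino_k2": np.nan}
        )
    from statsmodels.stats.diagnostic import lilliefors

    _, p_lf = lilliefors(x, dist="norm")
    z = (x - x.mean()) / x.std(ddof=1)
    _, p_ks = stats.kstest(z, "norm")
    p_ad = _anderson_darling_p(x)
    _, p_k2 = stats.normaltest(x)
    return pd.Series(
        {"lilliefors": p_lf, "ks": p_ks, "anderson_darling": p_ad,
         "dagostino_k2": p_k2}
    )


def _anderson_darling_p(x: np.ndarray) -> float:
    """Approximate p-value for the Anderson–Darling normality statistic
    (case with estimated mean and variance; Stephens' approximation)."""
    import warnings

    n = len(x)
    with warnings.catch_warnings():
        # only the statistic is consumed; the p-value comes from Stephens'
        # approximation below, so scipy's method-selection notice is moot
        warnings.simplefilter("ignore", FutureWarning)
        a2 = stats.anderson(x, dist="norm").statistic
    a2_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2_star >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2_star + 0.0186 * a2_star**2)
    elif a2_star >= 0.34:
        p = math.exp(0.9177 - 4.279 * a2_star - 1.38 * a2_star**2)
    elif a2_star >= 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a2_star - 59.938 * a2_star**2)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a2_star - 223.73 * a2_star**2)
    return float(min(max(p, 0.0), 1.0))
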