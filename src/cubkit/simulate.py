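"""Synthetic multi-yeast ORF corpora with planted, recoverable effects.

The generator emulates the statistical structure the pipeline assumes:
per-yeast synonymous-codon preference profiles (per-family Dirichlet draws
or explicit archetypes), heavy-tailed RPKM values spanning the L1–L5
ranges, %GC variation (a by-product of the profiles), per-yeast optimal
growth temperatures, and per-ORF pathway / regulation / per-residue
structure and localization labels.

Every effect the downstream analyses look for can be planted with a known
magnitude and is recorded in a ground-truth ledger:

* preferred codons — per-family probability mass concentrated on one codon
  (ground truth: codons whose expected RSCU, probability × family size,
  clears the calling threshold);
* an RSCU–OTG coupling — per-codon log-linear slope of the family profile
  in OTG;
* an RSCU–expression coupling — per-codon slope over the group rank
  (L1=1 … L5=5);
* a 5′ ramp — a depletion of top-ranked codons over the first segments,
  in percentage points of preferred content, optionally restricted to
  chosen expression groups;
* structure / pathway biases — odds multipliers on the top-ranked codon
  for residues of one category or ORFs of one pathway;
* regulation offsets — additive content shifts for up/down-regulated ORFs.

Amino-acid sequences are drawn i.i.d. from a fixed proteome-like
composition; the synonymous-codon choice at each position is what carries
all planted signal.  A fixed seed fully determines the corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .content import PATHWAY_ABBREVIATIONS
from .dataset import EXPRESSION_GROUPS, OrfRecord, YeastDataset
from .genetic_code import GeneticCodeTable, standard_code
from .positional import CODONS_PER_SEGMENT

#: Average yeast-proteome-like amino-acid composition (normalized in code).
AA_COMPOSITION: dict[str, float] = {
    "A": 0.055, "R": 0.044, "N": 0.061, "D": 0.058, "C": 0.013,
    "Q": 0.039, "E": 0.065, "G": 0.050, "H": 0.022, "I": 0.066,
    "L": 0.096, "K": 0.073, "M": 0.021, "F": 0.045, "P": 0.044,
    "S": 0.090, "T": 0.059, "W": 0.010, "Y": 0.034, "V": 0.056,
}

#: RPKM range represented by each expression group (L5 capped for sampling).
GROUP_RPKM_RANGES = {
    "L1": (10.0, 100.0), "L2": (100.0, 300.0), "L3": (300.0, 500.0),
    "L4": (500.0, 1000.0), "L5": (1000.0, 20000.0),
}

STRUCTURE_RUN_PROBS = {"H": 0.32, "E": 0.21, "T": 0.12, "C": 0.35}
LOCALIZATION_RUN_PROBS = {"c": 0.75, "e": 0.10, "t": 0.15}
STRUCTURE_RUN_MEAN = 6.0
LOCALIZATION_RUN_MEAN = 20.0


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic corpus.

    Defaults give a neutral corpus (random per-yeast preference profiles,
    no planted couplings) at a desk scale of 10 yeasts × 200 ORFs.
    """

    n_yeasts: int = 10
    n_orfs_per_yeast: int = 200
    seed: int = 0

    # ORF length (nt): lognormal over residues, clipped, forced to 3·residues
    length_log_mean: float = math.log(450.0)
    length_log_sd: float = 0.35
    min_length_nt: int = 210
    max_length_nt: int = 3000

    # expression: lognormal truncated at the RPKM ≥ 10 filter, or explicit
    # per-group proportions with log-uniform RPKM inside each group range
    rpkm_log_mean: float = math.log(120.0)
    rpkm_log_sd: float = 1.3
    group_proportions: dict[str, float] | None = None

    # per-yeast codon-preference profiles
    profile_alpha: float = 0.6
    planted_preferred_mass: float | None = None   # mass on one codon per family
    n_archetypes: int | None = None               # shared profile archetypes
    archetype_noise: float = 0.05                 # lognormal sd around archetype

    # OTG (°C) and planted couplings
    otg_values: list[float] | None = None
    otg_range: tuple[float, float] = (10.0, 30.0)
    otg_coupling: list[tuple[str, float]] = field(default_factory=list)
    expression_coupling: list[tuple[str, float]] = field(default_factory=list)

    # 5′ ramp: depth in percentage points over the first `span` segments
    ramp_depth: float = 0.0
    ramp_span: int = 3
    ramp_groups: list[str] | None = None          # None = all groups

    # category / pathway / regulation effects
    structure_bias: dict[str, float] = field(default_factory=dict)
    pathway_bias: dict[str, float] = field(default_factory=dict)
    frac_up: float = 0.1
    frac_down: float = 0.1
    regulation_offset: dict[str, float] = field(default_factory=dict)

    with_pathways: bool = True
    with_regulation: bool = True
    with_labels: bool = True
    preferred_threshold: float = 1.5

    def validate(self) -> None:
        if self.n_yeasts < 1 or self.n_orfs_per_yeast < 1:
            raise ConfigError("need at least one yeast and one ORF")
        if self.min_length_nt < 210 or self.min_length_nt % 3:
            raise ConfigError("minimum ORF length must be ≥ 210 and a multiple of 3")
        if self.group_proportions is not None:
            if set(self.group_proportions) - set(EXPRESSION_GROUPS):
                raise ConfigError("group_proportions keys must be L1..L5")
            if abs(sum(self.group_proportions.values()) - 1.0) > 1e-9:
                raise ConfigError("group_proportions must sum to 1")
        for m in list(self.structure_bias.values()) + list(self.pathway_bias.values()):
            if m <= 0:
                raise ConfigError("bias multipliers must be positive")
        if self.frac_up + self.frac_down > 1.0:
            raise ConfigError("frac_up + frac_down exceeds 1")
        if self.planted_preferred_mass is not None and not (
            0.0 < self.planted_preferred_mass < 1.0
        ):
            raise ConfigError("planted_preferred_mass must be in (0, 1)")


@dataclass
class GroundTruth:
    """Planted effects, recorded for recovery tests."""

    preferred: dict[str, frozenset[str]]          # yeast → expected-RSCU≥thr codons
    profiles: dict[str, dict[str, np.ndarray]]    # yeast → aa → family profile
    archetype_of: dict[str, int]                  # yeast → archetype index (or 0)
    otg: dict[str, float]
    otg_coupling: list[tuple[str, float]]
    expression_coupling: list[tuple[str, float]]
    ramp: tuple[float, int, tuple[str, ...] | None]
    structure_bias: dict[str, float]
    pathway_bias: dict[str, float]
    regulation_offset: dict[str, float]


def _normalize(p: np.ndarray) -> np.ndarray:
    return p / p.sum()


def _runs(rng: np.random.Generator, n: int, probs: dict[str, float],
          mean_len: float) -> str:
    """Label string of length n built from geometric-length category runs."""
    cats = list(probs)
    weights = _normalize(np.array([probs[c] for c in cats]))
    out: list[str] = []
    while len(out) < n:
        c = cats[rng.choice(len(cats), p=weights)]
        run = 1 + rng.geometric(1.0 / mean_len)
        out.extend(c * run)
    return "".join(out[:n])


def _sample_rpkm(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    if cfg.group_proportions is not None:
        groups = sorted(cfg.group_proportions)
        probs = _normalize(np.array([cfg.group_proportions[g] for g in groups]))
        g = groups[rng.choice(len(groups), p=probs)]
        lo, hi = GROUP_RPKM_RANGES[g]
        # nudge off the exact bounds so the half-open bins are unambiguous
        return float(math.exp(rng.uniform(math.log(lo + 1e-6), math.log(hi))))
    while True:
        v = float(rng.lognormal(cfg.rpkm_log_mean, cfg.rpkm_log_sd))
        if v >= 10.0:
            return v


def _base_profiles(
    rng: np.random.Generator, cfg: SimulationConfig, code: GeneticCodeTable,
    archetypes: dict[int, dict[str, np.ndarray]] | None, arch_idx: int,
    otg: float,
) -> dict[str, np.ndarray]:
    """Per-family codon probability vectors for one yeast."""
    profiles: dict[str, np.ndarray] = {}
    for aa, fam in code.families.items():
        k = len(fam)
        if k == 1:
            profiles[aa] = np.array([1.0])
            continue
        if archetypes is not None:
            base = archetypes[arch_idx][aa]
            noise = rng.lognormal(0.0, cfg.archetype_noise, size=k)
            p = _normalize(base * noise)
        elif cfg.planted_preferred_mass is not None:
            j = int(rng.integers(k))
            p = np.full(k, (1.0 - cfg.planted_preferred_mass) / (k - 1))
            p[j] = cfg.planted_preferred_mass
        else:
            p = rng.dirichlet(np.full(k, cfg.profile_alpha))
        profiles[aa] = p
    # OTG coupling: log-linear tilt of the target codon's mass in OTG
    for codon, slope in cfg.otg_coupling:
        aa = code.codon_to_aa[codon]
        fam = code.families[aa]
        if len(fam) < 2:
            raise ConfigError(f"OTG coupling on single-codon family {codon}")
        p = profiles[aa].copy()
        j = fam.index(codon)
        p[j] *= math.exp(slope * (otg - 20.0))
        profiles[aa] = _normalize(p)
    return profiles


def _expected_preferred(
    profiles: dict[str, np.ndarray], code: GeneticCodeTable,
    expression_coupling: list[tuple[str, float]], threshold: float,
) -> frozenset[str]:
    """Codons whose expected RSCU (at L5, rank 5) clears the threshold."""
    prefs = []
    for aa, fam in code.families.items():
        k = len(fam)
        if k < 2:
            continue
        p = profiles[aa].copy()
        for codon, slope in expression_coupling:
            if codon in fam:
                p[fam.index(codon)] *= math.exp(slope * (5 - 3))
        p = _normalize(p)
        for j, codon in enumerate(fam):
            if p[j] * k >= threshold:
                prefs.append(codon)
    return frozenset(prefs)


def _effective_profile(
    p: np.ndarray,
    expr_terms: list[tuple[int, float]], rank: int,
    odds_mult: float, add_points: float,
) -> np.ndarray:
    """Apply expression coupling, odds multiplier, and additive content
    shift (percentage points on the top codon) to one family profile."""
    p = p.copy()
    for j, slope in expr_terms:
        p[j] *= math.exp(slope * (rank - 3))
    p = _normalize(p)
    top = int(np.argmax(p))
    q = p[top]
    if odds_mult != 1.0:
        q_new = odds_mult * q / (odds_mult * q + (1.0 - q))
        scale = (1.0 - q_new) / (1.0 - q) if q < 1.0 else 0.0
        p = p * scale
        p[top] = q_new
        q = q_new
    if add_points < 0.0 and q > 0.0:
        w = min(1.0, -add_points / 100.0 / q)
        mix = np.full(len(p), 1.0 / (len(p) - 1)) if len(p) > 1 else np.ones(1)
        if len(p) > 1:
            mix[top] = 0.0
        p = (1.0 - w) * p + w * mix
    elif add_points > 0.0 and q < 1.0:
        w = min(1.0, add_points / 100.0 / (1.0 - q))
        mix = np.zeros(len(p))
        mix[top] = 1.0
        p = (1.0 - w) * p + w * mix
    return _normalize(p)


def simulate_corpus(
    config: SimulationConfig, code: GeneticCodeTable | None = None
) -> tuple[dict[str, YeastDataset], GroundTruth]:
    """Generate a corpus of per-yeast ORF collections plus its truth ledger."""
    config.validate()
    code = code or standard_code()
    rng = np.random.default_rng(config.seed)
    aas = sorted(AA_COMPOSITION)
    aa_probs = _normalize(np.array([AA_COMPOSITION[a] for a in aas]))
    rank_of = {g: i + 1 for i, g in enumerate(EXPRESSION_GROUPS)}

    archetypes = None
    if config.n_archetypes:
        archetypes = {}
        for a in range(config.n_archetypes):
            archetypes[a] = {
                aa: (rng.dirichlet(np.full(len(fam), config.profile_alpha))
                     if len(fam) > 1 else np.array([1.0]))
                for aa, fam in code.families.items()
            }

    struct_mult = {sym: config.structure_bias.get(name, 1.0)
                   for sym, name in
                   {"H": "helix", "E": "strand", "T": "turn", "C": "coil"}.items()}
    loc_mult = {sym: config.structure_bias.get(name, 1.0)
                for sym, name in
                {"c": "cyto", "e": "extra", "t": "trans"}.items()}

    datasets: dict[str, YeastDataset] = {}
    truth_pref: dict[str, frozenset[str]] = {}
    truth_prof: dict[str, dict[str, np.ndarray]] = {}
    truth_arch: dict[str, int] = {}
    truth_otg: dict[str, float] = {}

    for yi in range(config.n_yeasts):
        yid = f"yeast{yi + 1:03d}"
        if config.otg_values is not None:
            otg = float(config.otg_values[yi % len(config.otg_values)])
        else:
            otg = float(rng.uniform(*config.otg_range))
        arch_idx = yi % config.n_archetypes if config.n_archetypes else 0
        profiles = _base_profiles(rng, config, code, archetypes, arch_idx, otg)
        truth_prof[yid] = profiles
        truth_arch[yid] = arch_idx
        truth_otg[yid] = otg
        truth_pref[yid] = _expected_preferred(
            profiles, code, config.expression_coupling, config.preferred_threshold
        )
        expr_terms_by_aa: dict[str, list[tuple[int, float]]] = {}
        for codon, slope in config.expression_coupling:
            aa = code.codon_to_aa[codon]
            fam = code.families[aa]
            expr_terms_by_aa.setdefault(aa, []).append((fam.index(codon), slope))

        orfs: list[OrfRecord] = []
        for oi in range(config.n_orfs_per_yeast):
            oid = f"{yid}.orf{oi + 1:04d}"
            n_res = int(round(rng.lognormal(config.length_log_mean,
                                            config.length_log_sd) / 3.0))
            n_res = int(np.clip(n_res, config.min_length_nt // 3,
                                config.max_length_nt // 3))
            rpkm = _sample_rpkm(rng, config)
            group = next(
                (g for g, (lo, hi) in GROUP_RPKM_RANGES.items()
                 if (lo <= rpkm <= hi if g == "L1" else lo < rpkm <= hi)),
                "L5",
            )
            rank = rank_of[group]
            pathway = (
                PATHWAY_ABBREVIATIONS[int(rng.integers(len(PATHWAY_ABBREVIATIONS)))]
                if config.with_pathways else None
            )
            if config.with_regulation:
                u = rng.random()
                if u < config.frac_up:
                    log2fc = float(rng.uniform(1.0, 3.0))
                    direction = "up"
                elif u < config.frac_up + config.frac_down:
                    log2fc = float(rng.uniform(-3.0, -1.0))
                    direction = "down"
                else:
                    log2fc = float(rng.uniform(-0.95, 0.95))
                    direction = None
            else:
                log2fc, direction = None, None
            structure = (_runs(rng, n_res, STRUCTURE_RUN_PROBS, STRUCTURE_RUN_MEAN)
                         if config.with_labels else None)
            localization = (_runs(rng, n_res, LOCALIZATION_RUN_PROBS,
                                  LOCALIZATION_RUN_MEAN)
                            if config.with_labels else None)

            aa_seq = ["M"] + [aas[j] for j in
                              rng.choice(len(aas), size=n_res - 1, p=aa_probs)]
            ramp_on = config.ramp_depth != 0.0 and (
                config.ramp_groups is None or group in config.ramp_groups
            )
            reg_points = (config.regulation_offset.get(direction, 0.0)
                          if direction else 0.0)
            path_mult = config.pathway_bias.get(pathway, 1.0) if pathway else 1.0

            # group positions by (aa, ramp-zone, structure label) and draw
            # each context's codons in one vectorized call
            keys: dict[tuple, list[int]] = {}
            for pos, aa in enumerate(aa_seq):
                in_ramp = ramp_on and pos // CODONS_PER_SEGMENT < config.ramp_span
                sym = structure[pos] if (structure and config.structure_bias) else ""
                lsym = (localization[pos]
                        if (localization and config.structure_bias) else "")
                keys.setdefault((aa, in_ramp, sym, lsym), []).append(pos)
            codon_at: list[str | None] = [None] * n_res
            for (aa, in_ramp, sym, lsym), positions in keys.items():
                fam = code.families[aa]
                if len(fam) == 1:
                    for pos in positions:
                        codon_at[pos] = fam[0]
                    continue
                mult = path_mult
                if sym:
                    mult *= struct_mult.get(sym, 1.0)
                if lsym:
                    mult *= loc_mult.get(lsym, 1.0)
                add = reg_points - (config.ramp_depth if in_ramp else 0.0)
                p_eff = _effective_profile(
                    profiles[aa], expr_terms_by_aa.get(aa, []), rank, mult, add,
                )
                draws = rng.choice(len(fam), size=len(positions), p=p_eff)
                for pos, d in zip(positions, draws):
                    codon_at[pos] = fam[int(d)]
            seq = "".join(codon_at)  # type: ignore[arg-type]
            orfs.append(OrfRecord(
                orf_id=oid, yeast_id=yid, seq=seq, rpkm=rpkm, pathway=pathway,
                log2fc=log2fc, structure_labels=structure,
                localization_labels=localization,
            ))
        datasets[yid] = YeastDataset(yeast_id=yid, otg_c=otg, orfs=orfs)

    truth = GroundTruth(
        preferred=truth_pref, profiles=truth_prof, archetype_of=truth_arch,
        otg=truth_otg, otg_coupling=list(config.otg_coupling),
        expression_coupling=list(config.expression_coupling),
        ramp=(config.ramp_depth, config.ramp_span,
              tuple(config.ramp_groups) if config.ramp_groups else None),
        structure_bias=dict(config.structure_bias),
        pathway_bias=dict(config.pathway_bias),
        regulation_offset=dict(config.regulation_offset),
    )
    return datasets, truth


def simulate_null(
    config: SimulationConfig, code: GeneticCodeTable | None = None
) -> tuple[dict[str, YeastDataset], GroundTruth]:
    """Same machinery with every planted effect disabled (type-I calibration)."""
    null_cfg = replace(
        config, otg_coupling=[], expression_coupling=[], ramp_depth=0.0,
        structure_bias={}, pathway_bias={}, regulation_offset={},
    )
    return simulate_corpus(null_cfg, code)


# ---------------------------------------------------------------------------
# On-disk corpus in the exact input formats of :mod:`cubkit.dataset`


def write_corpus(
    datasets: dict[str, YeastDataset], outdir, truth: GroundTruth | None = None
) -> None:
    """Write FASTA + TSV inputs (and optionally the truth ledger) to a dir."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_lines: list[str] = []
    expr_rows, meta_rows, ann_rows, lab_rows = [], [], [], []
    for yid in sorted(datasets):
        y = datasets[yid]
        meta_rows.append({"yeast_id": yid, "otg_c": y.otg_c})
        for o in sorted(y.orfs, key=lambda r: r.orf_id):
            fasta_lines.append(f">{o.orf_id}")
            fasta_lines.extend(o.seq[i:i + 70] for i in range(0, len(o.seq), 70))
            expr_rows.append({"orf_id": o.orf_id, "yeast_id": yid, "rpkm": o.rpkm})
            if o.pathway is not None or o.log2fc is not None:
                ann_rows.append({"orf_id": o.orf_id, "pathway": o.pathway,
                                 "log2fc": o.log2fc})
            if o.structure_labels is not None or o.localization_labels is not None:
                lab_rows.append({
                    "orf_id": o.orf_id,
                    "structure_labels": o.structure_labels,
                    "localization_labels": o.localization_labels,
                })
    (outdir / "orfs.fasta").write_text("\n".join(fasta_lines) + "\n")
    pd.DataFrame(expr_rows).to_csv(outdir / "expression.tsv", sep="\t",
                                   index=False, float_format="%.6g")
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.tsv", sep="\t",
                                   index=False, float_format="%.6g")
    if ann_rows:
        pd.DataFrame(ann_rows).to_csv(outdir / "annotations.tsv", sep="\t",
                                      index=False, float_format="%.6g")
    if lab_rows:
        pd.DataFrame(lab_rows).to_csv(outdir / "labels.tsv", sep="\t", index=False)
    if truth is not None:
        rows = [{"yeast_id": yid, "preferred_codons": ",".join(sorted(cset)),
                 "otg_c": truth.otg[yid], "archetype": truth.archetype_of[yid]}
                for yid, cset in sorted(truth.preferred.items())]
        pd.DataFrame(rows).to_csv(outdir / "truth.tsv", sep="\t", index=False,
                                  float_format="%.6g")
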