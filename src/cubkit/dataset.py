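"""ORF records, RPKM, inclusion filters, and expression/%GC stratification.

The pipeline consumes ORF nucleotide sequences (FASTA, one record per ORF)
plus tab-delimited tables: expression (RPKM or read counts with library
sizes), per-yeast metadata (optimal temperature of growth, OTG), optional
per-ORF annotations (cellular pathway, regulation log2 fold-change) and
optional per-residue structure / localization label strings.

Filtering and grouping follow the study design: ORFs of at least 210 nt
with RPKM ≥ 10 are analysed; expression groups are L1 [10, 100],
L2 (100, 300], L3 (300, 500], L4 (500, 1000], L5 (> 1000); %GC groups are
gc1 (0, 20], gc2 (20, 40], gc3 (40, 60], gc4 (60, 80].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .codons import CodonCountVector, count_codons, gc_percent
from .genetic_code import GeneticCodeTable

logger = logging.getLogger(__name__)

MIN_ORF_LENGTH_NT = 210
MIN_RPKM = 10.0

#: Expression-group upper bounds; L1 lower bound is the RPKM ≥ 10 filter.
EXPRESSION_BOUNDS = {"L1": 100.0, "L2": 300.0, "L3": 500.0, "L4": 1000.0}
EXPRESSION_GROUPS = ("L1", "L2", "L3", "L4", "L5")
GC_BOUNDS = {"gc1": 20.0, "gc2": 40.0, "gc3": 60.0, "gc4": 80.0}
GC_GROUPS = ("gc1", "gc2", "gc3", "gc4")
UNGROUPED = "UNGROUPED"

STRUCTURE_CATEGORIES = {"H": "helix", "E": "strand", "T": "turn", "C": "coil"}
LOCALIZATION_CATEGORIES = {"c": "cyto", "e": "extra", "t": "trans"}


class OutOfDomainError(ValueError):
    pass


@dataclass
class OrfRecord:
    """One ORF with its sequence, expression, and optional annotations."""

    orf_id: str
    yeast_id: str
    seq: str
    rpkm: float
    pathway: str | None = None
    log2fc: float | None = None
    structure_labels: str | None = None
    localization_labels: str | None = None
    _counts: CodonCountVector | None = field(default=None, repr=False, compare=False)

    @property
    def length_nt(self) -> int:
        return len(self.seq)

    @property
    def n_residues(self) -> int:
        return self.length_nt // 3

    @property
    def gc(self) -> float:
        return gc_percent(self.seq)

    def codon_counts(self, code: GeneticCodeTable | None = None) -> CodonCountVector:
        """Codon counts, cached on first use."""
        if self._counts is None:
            self._counts = count_codons(self.seq, code=code, source=self.orf_id)
        return self._counts

    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq) - 2, 3)]

    def validate(self) -> None:
        if self.length_nt % 3 != 0:
            raise ValueError(f"{self.orf_id}: length {self.length_nt} not multiple of 3")
        for name, labels in (
            ("structure", self.structure_labels),
            ("localization", self.localization_labels),
        ):
            if labels is not None and len(labels) != self.n_residues:
                raise ValueError(
                    f"{self.orf_id}: {name} labels length {len(labels)} "
                    f"!= {self.n_residues} residues"
                )


@dataclass
class YeastDataset:
    """All retained ORFs of one yeast plus its optimal growth temperature."""

    yeast_id: str
    otg_c: float
    orfs: list[OrfRecord]

    def __post_init__(self) -> None:
        if not (0.0 <= self.otg_c <= 45.0):
            raise ValueError(f"{self.yeast_id}: OTG {self.otg_c} °C outside 0–45 °C")
        for o in self.orfs:
            if o.yeast_id != self.yeast_id:
                raise ValueError(f"ORF {o.orf_id} carries yeast {o.yeast_id!r}")

    def by_expression_group(self) -> dict[str, list[OrfRecord]]:
        out: dict[str, list[OrfRecord]] = {g: [] for g in EXPRESSION_GROUPS}
        for o in self.orfs:
            out[assign_expression_group(o.rpkm)].append(o)
        return out


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    removed_short: int = 0
    removed_low_rpkm: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept


def rpkm(read_count: int, orf_length_nt: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of ORF per million mapped reads."""
    if orf_length_nt <= 0 or total_mapped_reads <= 0:
        raise ZeroDivisionError("ORF length and library size must be positive")
    if read_count < 0:
        raise ValueError("read count cannot be negative")
    return read_count / ((orf_length_nt / 1000.0) * (total_mapped_reads / 1e6))


def max_rpkm_across_runs(per_run_rpkm: list[float]) -> float:
    """Collapse multiple transcriptome runs of one yeast to the maximum RPKM."""
    if not per_run_rpkm:
        raise ValueError("no per-run RPKM values")
    return max(per_run_rpkm)


def apply_inclusion_filters(
    orfs: list[OrfRecord],
    min_length_nt: int = MIN_ORF_LENGTH_NT,
    min_rpkm: float = MIN_RPKM,
) -> tuple[list[OrfRecord], FilterReport]:
    """Keep ORFs with length ≥ 210 nt and RPKM ≥ 10 (both inclusive)."""
    report = FilterReport(n_input=len(orfs))
    kept: list[OrfRecord] = []
    for o in orfs:
        short = o.length_nt < min_length_nt
        low = o.rpkm < min_rpkm
        if short:
            report.removed_short += 1
        if low:
            report.removed_low_rpkm += 1
        if not short and not low:
            kept.append(o)
    report.n_kept = len(kept)
    return kept, report


def assign_expression_group(rpkm_value: float) -> str:
    """L1 [10,100], L2 (100,300], L3 (300,500], L4 (500,1000], L5 (1000,∞)."""
    if rpkm_value < MIN_RPKM:
        raise OutOfDomainError(f"RPKM {rpkm_value} below the ≥ {MIN_RPKM} filter")
    for label, upper in EXPRESSION_BOUNDS.items():
        if rpkm_value <= upper:
            return label
    return "L5"


def assign_gc_group(gc: float) -> str:
    """gc1 (0,20], gc2 (20,40], gc3 (40,60], gc4 (60,80]; >80 is UNGROUPED."""
    if not (0.0 <= gc <= 100.0):
        raise OutOfDomainError(f"%GC {gc} outside [0, 100]")
    for label, upper in GC_BOUNDS.items():
        if gc <= upper:
            return label
    return UNGROUPED


# ---------------------------------------------------------------------------
# Table / FASTA readers


def read_fasta_orfs(path: str | Path) -> dict[str, str]:
    """FASTA → {orf_id: sequence}; record id is the ORF id."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate ORF id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Expression TSV with either an ``rpkm`` column or read counts.

    Accepted headers: (orf_id, yeast_id, rpkm) or
    (orf_id, yeast_id, read_count, total_mapped_reads); with counts, ORF
    lengths come from the FASTA at assembly time, so the count form is
    resolved in :func:`build_datasets`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"orf_id": str, "yeast_id": str})
    need = {"orf_id", "yeast_id"}
    if not need <= set(df.columns):
        raise ValueError(f"expression table must have columns {sorted(need)}")
    if "rpkm" not in df.columns and not {"read_count", "total_mapped_reads"} <= set(
        df.columns
    ):
        raise ValueError(
            "expression table needs an 'rpkm' column or "
            "'read_count' + 'total_mapped_reads'"
        )
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"yeast_id": str})
    if not {"yeast_id", "otg_c"} <= set(df.columns):
        raise ValueError("metadata table must have columns yeast_id, otg_c")
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Optional per-ORF pathway / regulation table (orf_id, pathway, log2fc)."""
    df = pd.read_csv(path, sep="\t", dtype={"orf_id": str})
    if "orf_id" not in df.columns:
        raise ValueError("annotation table must have an orf_id column")
    return df


def read_residue_labels(path: str | Path) -> pd.DataFrame:
    """Optional per-residue label strings (orf_id, structure_labels, localization_labels)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "orf_id" not in df.columns:
        raise ValueError("label table must have an orf_id column")
    return df


def build_datasets(
    seqs: dict[str, str],
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    labels: pd.DataFrame | None = None,
    apply_filters: bool = True,
) -> tuple[dict[str, YeastDataset], FilterReport]:
    """Assemble per-yeast datasets from the raw inputs.

    Multiple expression rows per ORF (several transcriptome runs) are
    collapsed with :func:`max_rpkm_across_runs`; the inclusion filters are
    applied afterwards.
    """
    expr = expression.copy()
    if "rpkm" not in expr.columns:
        lengths = expr["orf_id"].map(lambda o: len(seqs.get(o, "")))
        if (lengths == 0).any():
            missing = expr.loc[lengths == 0, "orf_id"].tolist()[:5]
            raise ValueError(f"expression rows without FASTA sequence, e.g. {missing}")
        expr["rpkm"] = [
            rpkm(int(r), int(l), int(t))
            for r, l, t in zip(
                expr["read_count"], lengths, expr["total_mapped_reads"]
            )
        ]
    collapsed = (
        expr.groupby(["yeast_id", "orf_id"], sort=True)["rpkm"].max().reset_index()
    )

    ann = annotations.set_index("orf_id") if annotations is not None else None
    lab = labels.set_index("orf_id") if labels is not None else None

    orfs_by_yeast: dict[str, list[OrfRecord]] = {}
    for row in collapsed.itertuples(index=False):
        seq = seqs.get(row.orf_id)
        if seq is None:
            logger.warning("ORF %s has expression but no sequence; dropped", row.orf_id)
            continue
        rec = OrfRecord(
            orf_id=row.orf_id, yeast_id=row.yeast_id, seq=seq, rpkm=float(row.rpkm)
        )
        if ann is not None and row.orf_id in ann.index:
            arow = ann.loc[row.orf_id]
            if "pathway" in ann.columns and pd.notna(arow.get("pathway")):
                rec.pathway = str(arow["pathway"])
            if "log2fc" in ann.columns and pd.notna(arow.get("log2fc")):
                rec.log2fc = float(arow["log2fc"])
        if lab is not None and row.orf_id in lab.index:
            lrow = lab.loc[row.orf_id]
            if "structure_labels" in lab.columns and pd.notna(
                lrow.get("structure_labels")
            ):
                rec.structure_labels = str(lrow["structure_labels"])
            if "localization_labels" in lab.columns and pd.notna(
                lrow.get("localization_labels")
            ):
                rec.localization_labels = str(lrow["localization_labels"])
        rec.validate()
        orfs_by_yeast.setdefault(row.yeast_id, []).append(rec)

    report = FilterReport()
    datasets: dict[str, YeastDataset] = {}
    otg = metadata.set_index("yeast_id")["otg_c"].astype(float)
    for yeast_id in sorted(orfs_by_yeast):
        if yeast_id not in otg.index:
            raise ValueError(f"yeast {yeast_id!r} missing from metadata")
        orfs = sorted(orfs_by_yeast[yeast_id], key=lambda o: o.orf_id)
        if apply_filters:
            orfs, rep = apply_inclusion_filters(orfs)
            report.n_input += rep.n_input
            report.n_kept += rep.n_kept
            report.removed_short += rep.removed_short
            report.removed_low_rpkm += rep.removed_low_rpkm
        else:
            report.n_input += len(orfs)
            report.n_kept += len(orfs)
        datasets[yeast_id] = YeastDataset(
            yeast_id=yeast_id, otg_c=float(otg.loc[yeast_id]), orfs=orfs
        )
    return datasets, report
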