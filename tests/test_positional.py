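"""30-nt segmentation, 5′-ramp summaries, and structure/localization content."""

import numpy as np
import pandas as pd
import pytest

from cubkit.codons import call_preferred
from cubkit.dataset import OrfRecord, YeastDataset
from cubkit.positional import fragment_orf, ramp_summary, structure_content
from cubkit.simulate import SimulationConfig, simulate_corpus
from cubkit.tables import pooled_group_rscu


def pref_of(codons):
    """A preferred set containing exactly the given codons."""
    from cubkit.codons import PreferredCodonSet

    return PreferredCodonSet(yeast_id="y", codons=frozenset(codons))


def orf_from_codons(codons, orf_id="o1", rpkm=2000.0, **kw):
    return OrfRecord(orf_id=orf_id, yeast_id="y", seq="".join(codons),
                     rpkm=rpkm, **kw)


class TestFragmentOrf:
    def test_exact_division(self):
        orf = orf_from_codons(["GGT"] * 30)  # 90 nt
        prof = fragment_orf(orf, pref_of(["GGT"]))
        assert prof.n_segments == 3
        assert prof.segment_percents == [100.0, 100.0, 100.0]

    def test_trailing_partial_dropped(self):
        orf = orf_from_codons(["GGT"] * 33)  # 99 nt → 3 segments, 9 nt dropped
        assert fragment_orf(orf, pref_of(["GGT"])).n_segments == 3

    def test_segment_percentage(self):
        codons = ["GGT"] * 7 + ["AAA"] * 3
        prof = fragment_orf(orf_from_codons(codons), pref_of(["GGT"]))
        assert prof.segment_percents == [70.0]

    def test_short_orf_skipped(self):
        assert fragment_orf(orf_from_codons(["GGT"] * 9), pref_of(["GGT"])) is None

    def test_concatenation_is_not_segment_concatenation(self):
        # frame/segment grid is per ORF: joining two 35-codon ORFs yields
        # different segments than the two ORFs segmented separately
        a = ["GGT"] * 35
        b = ["AAA"] * 35
        pref = pref_of(["GGT"])
        sep = (fragment_orf(orf_from_codons(a), pref).segment_percents
               + fragment_orf(orf_from_codons(b), pref).segment_percents)
        joined = fragment_orf(orf_from_codons(a + b), pref).segment_percents
        assert sep != joined


class TestRampSummary:
    def make_profiles(self, rng, n, n_seg=25, first_deficit=0.0):
        profs = []
        for i in range(n):
            base = rng.uniform(30, 70)
            percents = [
                max(0.0, base - (first_deficit if s == 0 else 0.0)
                    + 10 * rng.integers(-1, 2))
                for s in range(n_seg)
            ]
            from cubkit.positional import SegmentProfile

            profs.append(SegmentProfile(orf_id=f"o{i}", segment_percents=percents))
        return profs

    def test_no_positional_effect_deltas_near_zero(self):
        rng = np.random.default_rng(0)
        profs = self.make_profiles(rng, 2000)
        deltas = ramp_summary(profs, window=5, offsets=10)["ALL"]
        assert deltas.abs().max().max() <= 2.0

    def test_planted_first_segment_deficit(self):
        rng = np.random.default_rng(1)
        profs = self.make_profiles(rng, 1500, first_deficit=15.0)
        deltas = ramp_summary(profs, window=3, offsets=10)["ALL"]
        assert (deltas.iloc[0] < 0).all()
        # deficit localizes to segment 1: later rows are flat
        assert deltas.iloc[2].abs().max() <= 2.0

    def test_antisymmetry_on_identical_subsets(self):
        rng = np.random.default_rng(2)
        profs = self.make_profiles(rng, 300, n_seg=12)
        d = ramp_summary(profs, window=10, offsets=10, floor=1)["ALL"]
        # delta(s→s+j) = −delta reconstructed from the swapped comparison
        mat = np.array([p.segment_percents for p in profs])
        fwd = np.median(mat[:, 0] - mat[:, 4])
        rev = np.median(mat[:, 4] - mat[:, 0])
        assert d.loc[1, "+4"] == pytest.approx(fwd)
        assert fwd == pytest.approx(-rev)

    def test_below_floor_cells_missing(self):
        rng = np.random.default_rng(3)
        profs = self.make_profiles(rng, 3)
        deltas = ramp_summary(profs, window=3, offsets=5, floor=10)["ALL"]
        assert deltas.isna().all().all()

    def test_group_split(self):
        rng = np.random.default_rng(4)
        profs = self.make_profiles(rng, 60)
        groups = pd.Series({f"o{i}": ("L5" if i % 2 else "L1") for i in range(60)})
        out = ramp_summary(profs, groups, window=2, offsets=3)
        assert set(out) == {"ALL", "L1", "L5"}


class TestStructureContent:
    def test_constructed_two_block_orf(self):
        # helix half uses AAA, strand half uses GGT; only GGT preferred
        codons = ["ATG"] + ["AAA"] * 4 + ["GGT"] * 5
        orf = orf_from_codons(codons, structure_labels="HHHHHEEEEE")
        y = YeastDataset(yeast_id="y", otg_c=20.0, orfs=[orf, orf_from_codons(
            codons, orf_id="o2", structure_labels="HHHHHEEEEE")])
        out = structure_content(y, pref_of(["GGT"]), scheme="structure")
        tab = out["content"].set_index(["orf_id", "category"])
        assert tab.loc[("o1", "helix"), "content"] == 0.0
        assert tab.loc[("o1", "strand"), "content"] == 100.0

    def test_category_codon_counts_partition_orf(self):
        cfg = SimulationConfig(n_yeasts=1, n_orfs_per_yeast=30, seed=71,
                               group_proportions={"L5": 1.0},
                               with_pathways=False, with_regulation=False)
        ds, _ = simulate_corpus(cfg)
        y = ds["yeast001"]
        pref = call_preferred(pooled_group_rscu(y, "L5"), yeast_id="yeast001")
        out = structure_content(y, pref, scheme="structure")
        per_orf = out["content"].groupby("orf_id")["n_codons"].sum()
        for o in y.orfs:
            assert per_orf[o.orf_id] == o.n_residues

    def test_label_length_mismatch_rejected(self):
        orf = orf_from_codons(["GGT"] * 10, structure_labels="HHH")
        y = YeastDataset(yeast_id="y", otg_c=20.0, orfs=[orf])
        with pytest.raises(ValueError, match="labels"):
            structure_content(y, pref_of(["GGT"]), scheme="structure")

    def test_planted_strand_bias_top_category(self):
        cfg = SimulationConfig(n_yeasts=1, n_orfs_per_yeast=220, seed=72,
                               structure_bias={"strand": 2.0},
                               group_proportions={"L5": 1.0},
                               with_pathways=False, with_regulation=False)
        ds, _ = simulate_corpus(cfg)
        y = ds["yeast001"]
        pref = call_preferred(pooled_group_rscu(y, "L5"), yeast_id="yeast001")
        out = structure_content(y, pref, scheme="structure",
                                by_expression_group=False)
        med = out["content"].groupby("category")["content"].median()
        assert med.idxmax() == "strand"
        comps = out["comparisons"]
        strand = comps[(comps["group_a"] == "strand") | (comps["group_b"] == "strand")]
        assert strand["significant"].all()

    def test_localization_scheme(self):
        cfg = SimulationConfig(n_yeasts=1, n_orfs_per_yeast=40, seed=73,
                               group_proportions={"L5": 1.0},
                               with_pathways=False, with_regulation=False)
        ds, _ = simulate_corpus(cfg)
        y = ds["yeast001"]
        pref = call_preferred(pooled_group_rscu(y, "L5"), yeast_id="yeast001")
        out = structure_content(y, pref, scheme="localization",
                                by_expression_group=False)
        assert set(out["content"]["category"]) <= {"cyto", "extra", "trans"}
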