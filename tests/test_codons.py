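"""Codon counting, %GC, RSCU, and preferred-codon calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubkit.codons import (
    CodonCountVector,
    EmptyInputError,
    FrameError,
    UndefinedGCError,
    UndefinedPreferredSetError,
    call_preferred,
    count_codons,
    gc_percent,
    pooled_rscu,
    preferred_content,
    rscu,
)
from .conftest import brute_force_rscu, random_orf


class TestCountCodons:
    def test_basic_counts_with_stop_tally(self):
        cv = count_codons("ATGGGTGGTTAA")
        assert cv.counts == {"ATG": 1, "GGT": 2}
        assert cv.n_codons == 3
        assert cv.stop_tally == {"TAA": 1}

    def test_one_of_each_glycine(self):
        cv = count_codons("GGTGGCGGAGGG")
        assert cv.counts == {"GGT": 1, "GGC": 1, "GGA": 1, "GGG": 1}

    def test_n_codons_skipped_not_failed(self):
        cv = count_codons("ATGNNNGGT")
        assert cv.counts == {"ATG": 1, "GGT": 1}
        assert cv.skipped == 1

    def test_frame_error(self):
        with pytest.raises(FrameError):
            count_codons("ATGG")
        # frame check off: trailing bases ignored
        assert count_codons("ATGG", frame_check=False).counts == {"ATG": 1}

    def test_empty_and_bad_alphabet(self):
        with pytest.raises(EmptyInputError):
            count_codons("")
        with pytest.raises(ValueError):
            count_codons("ATGXYZ")


class TestGcPercent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 100.0), ("ATAT", 0.0), ("ATGC", 50.0), ("ATGCNN", 50.0)],
    )
    def test_values(self, seq, expected):
        assert gc_percent(seq) == pytest.approx(expected)

    def test_all_n_undefined(self):
        with pytest.raises(UndefinedGCError):
            gc_percent("NNN")


class TestRscu:
    def test_uniform_usage_gives_one(self):
        # equal use of all four Gly codons → no preference
        cv = CodonCountVector({"GGT": 5, "GGC": 5, "GGA": 5, "GGG": 5})
        v = rscu(cv)
        for c in ("GGT", "GGC", "GGA", "GGG"):
            assert v.values[c] == pytest.approx(1.0)

    def test_twofold_three_to_one(self):
        v = rscu(CodonCountVector({"AAA": 3, "AAG": 1}))
        assert v.values["AAA"] == pytest.approx(1.5)
        assert v.values["AAG"] == pytest.approx(0.5)

    def test_twofold_four_to_zero_real_zero(self):
        # the family occurs, so the unused codon has a true RSCU of 0
        v = rscu(CodonCountVector({"AAA": 4}))
        assert v.values["AAA"] == pytest.approx(2.0)
        assert v.values["AAG"] == 0.0
        assert not v.is_missing("AAG")

    def test_absent_family_is_missing(self):
        v = rscu(CodonCountVector({"GGT": 1}))
        assert v.is_missing("AAA") and v.is_missing("AAG")

    def test_family_sums_equal_k(self, code):
        rng = np.random.default_rng(0)
        seq = random_orf(rng, code, 200)
        v = rscu(count_codons(seq))
        for aa, fam in code.families.items():
            if len(fam) < 2:
                continue
            vals = [v.values[c] for c in fam]
            if not math.isnan(vals[0]):
                assert sum(vals) == pytest.approx(len(fam), abs=1e-9)

    @given(scale=st.integers(min_value=2, max_value=50))
    @settings(deadline=None, max_examples=20)
    def test_scale_invariance(self, scale):
        base = {"GGT": 3, "GGC": 1, "GGA": 2, "AAA": 5, "AAG": 2}
        v1 = rscu(CodonCountVector(dict(base)))
        v2 = rscu(CodonCountVector({c: n * scale for c, n in base.items()}))
        for c in v1.values:
            a, b = v1.values[c], v2.values[c]
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)

    def test_matches_brute_force_oracle(self, code):
        rng = np.random.default_rng(123)
        for _ in range(100):
            seq = random_orf(rng, code, int(rng.integers(20, 120)))
            ours = rscu(count_codons(seq)).values
            oracle = brute_force_rscu(seq, code)
            for c in oracle:
                if math.isnan(oracle[c]):
                    assert math.isnan(ours[c])
                else:
                    assert ours[c] == pytest.approx(oracle[c], abs=1e-12)


class TestPooledRscu:
    def test_pooling_two_singletons(self):
        a = CodonCountVector({"GGT": 1})
        b = CodonCountVector({"GGC": 1})
        v = pooled_rscu([a, b])
        assert v.values["GGT"] == pytest.approx(2.0)
        assert v.values["GGC"] == pytest.approx(2.0)
        assert v.values["GGA"] == 0.0 and v.values["GGG"] == 0.0

    def test_self_pooling_idempotent(self, code):
        rng = np.random.default_rng(5)
        cv = count_codons(random_orf(rng, code, 100))
        single = rscu(cv)
        doubled = pooled_rscu([cv, cv])
        for c in single.values:
            a, b = single.values[c], doubled.values[c]
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)

    def test_empty_list_rejected(self):
        with pytest.raises(EmptyInputError):
            pooled_rscu([])


class TestCallPreferred:
    def test_threshold_application(self):
        v = rscu(CodonCountVector({"AAG": 4, "AAA": 1}))  # 1.6 / 0.4
        assert call_preferred(v).codons == {"AAG"}

    def test_boundary_inclusive(self):
        v = rscu(CodonCountVector({"AAA": 3, "AAG": 1}))  # exactly 1.5
        assert "AAA" in call_preferred(v).codons

    def test_uniform_usage_empty_set(self):
        v = rscu(CodonCountVector({"GGT": 2, "GGC": 2, "GGA": 2, "GGG": 2}))
        assert call_preferred(v).codons == frozenset()

    def test_no_l5_orfs_flagged_undefined(self):
        p = call_preferred(None, yeast_id="y")
        assert p.undefined and p.codons == frozenset()

    def test_never_contains_stop_atg_tgg(self, code):
        rng = np.random.default_rng(9)
        v = rscu(count_codons(random_orf(rng, code, 500)))
        called = call_preferred(v, threshold=0.0).codons
        assert not called & ({"ATG", "TGG"} | set(code.stop_codons))


class TestPreferredContent:
    def test_direct_ratio(self):
        cv = CodonCountVector({"AAG": 4, "AAA": 6})
        pref = call_preferred(rscu(CodonCountVector({"AAG": 4, "AAA": 1})))
        assert preferred_content(cv, pref) == pytest.approx(40.0)

    def test_empty_set_zero_and_all_preferred_hundred(self):
        cv = CodonCountVector({"AAG": 5})
        none = call_preferred(rscu(CodonCountVector({"GGT": 1, "GGC": 1})))
        assert preferred_content(cv, none) == 0.0
        allpref = call_preferred(rscu(CodonCountVector({"AAG": 4, "AAA": 1})))
        assert preferred_content(cv, allpref) == 100.0

    def test_undefined_set_raises(self):
        cv = CodonCountVector({"AAG": 5})
        with pytest.raises(UndefinedPreferredSetError):
            preferred_content(cv, call_preferred(None))

    def test_codon_order_invariance(self, code):
        # content depends on counts only, never on codon order in the ORF
        rng = np.random.default_rng(3)
        seq = random_orf(rng, code, 80)
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        rng.shuffle(codons)
        pref = call_preferred(rscu(count_codons(seq)), threshold=1.2)
        a = preferred_content(count_codons(seq), pref)
        b = preferred_content(count_codons("".join(codons)), pref)
        assert a == pytest.approx(b)
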