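import numpy as np
import pysam
import pytest

from ervscan.errors import InputError
from ervscan.expression import (ExpressionRecord, bonferroni,
                                contrast_by_group, count_fragments, fpkm,
                                gag_coexpression, motif_class,
                                normality_diagnostic, rank_test)
from ervscan.synthetic import ANCESTOR_GAG, encode_protein

from oracles import mannwhitney_enum_p, wilcoxon_enum_p


def _write_sam(path, reads, sorted_header=True, ref_len=100000):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": ref_len}]}
    if sorted_header:
        header["HD"]["SO"] = "coordinate"
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for name, start, length in reads:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = "A" * length
            a.flag = 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{length}M"
            sam.write(a)


class TestCountFragments:
    def test_reads_inside_locus(self, tmp_path):
        path = tmp_path / "x.sam"
        _write_sam(path, [(f"r{i}", 1000 + 10 * i, 50) for i in range(10)])
        counts, lib = count_fragments(path, [("L", "chr1", 900, 2000)])
        assert counts["L"] == 10
        assert lib == 10

    def test_boundary_straddling_read_counted(self, tmp_path):
        path = tmp_path / "x.sam"
        _write_sam(path, [("r0", 1990, 50)])   # 10 bp inside [900, 2000)
        counts, _ = count_fragments(path, [("L", "chr1", 900, 2000)])
        assert counts["L"] == 1

    def test_read_outside_not_counted(self, tmp_path):
        path = tmp_path / "x.sam"
        _write_sam(path, [("r0", 2000, 50)])   # starts exactly at locus end
        counts, _ = count_fragments(path, [("L", "chr1", 900, 2000)])
        assert counts["L"] == 0

    def test_unsorted_header_rejected(self, tmp_path):
        path = tmp_path / "x.sam"
        _write_sam(path, [("r0", 100, 50)], sorted_header=False)
        with pytest.raises(InputError):
            count_fragments(path, [("L", "chr1", 0, 1000)])


class TestFpkm:
    def test_arithmetic(self):
        assert fpkm(100, 2000, 1_000_000) == pytest.approx(50.0)

    def test_zero_count(self):
        assert fpkm(0, 2000, 1_000_000) == 0.0

    def test_zero_library_rejected(self):
        with pytest.raises(InputError):
            fpkm(1, 1000, 0)

    def test_conservation_identity(self, rng):
        # sum_loci FPKM * (len/1000) * (lib/1e6) == sum counts
        for _ in range(20):
            n = int(rng.integers(1, 30))
            lengths = rng.integers(200, 20000, size=n)
            counts = rng.integers(0, 5000, size=n)
            lib = int(counts.sum()) + int(rng.integers(1, 1000))
            total = sum(
                fpkm(int(c), int(l), lib) * (int(l) / 1000) * (lib / 1e6)
                for c, l in zip(counts, lengths))
            assert total == pytest.approx(int(counts.sum()), abs=1e-9)


class TestRankTest:
    def test_identical_groups_p_one(self):
        p, name = rank_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert name == "mann_whitney_u"
        assert p == pytest.approx(1.0)

    def test_extreme_separation_exact_p(self):
        # most extreme U; 2 of the C(6,3)=20 arrangements are as extreme
        p, _ = rank_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n_a = int(rng.integers(2, 7))
            n_b = int(rng.integers(2, 7))
            a = rng.integers(0, 8, size=n_a).astype(float)   # with ties
            b = rng.integers(0, 8, size=n_b).astype(float)
            p, _ = rank_test(a, b)
            assert p == pytest.approx(mannwhitney_enum_p(a, b))

    def test_wilcoxon_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            p, name = rank_test(a, b, paired=True)
            assert name == "wilcoxon_signed_rank"
            assert p == pytest.approx(wilcoxon_enum_p(a - b))

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning):
            p, _ = rank_test([1.0, 2.0], [1.0, 2.0], paired=True)
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            rank_test([], [1.0])

    def test_null_calibration_small(self, rng):
        # smaller version of the acceptance check: exact test at n=8 vs 8
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            p, _ = rank_test(a, b)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_reps <= 0.09

    def test_normal_approximation_branch(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        p, _ = rank_test(a, b)
        assert 0.0 <= p <= 1.0


class TestBonferroni:
    def test_family_of_two(self):
        assert bonferroni([0.01, 0.02]) == [0.02, 0.04]

    def test_capped_at_one(self):
        assert bonferroni([0.9, 0.5, 0.2]) == [1.0, 1.0, 0.6000000000000001]

    def test_singleton_identity(self):
        assert bonferroni([0.3]) == [0.3]

    def test_order_invariant(self):
        ps = [0.04, 0.01, 0.2]
        fwd = bonferroni(ps)
        rev = bonferroni(ps[::-1])[::-1]
        assert fwd == rev


def _records(rng, effect=1.0, n=8, paired=False):
    records = []
    for cond, mult in (("case", effect), ("control", 1.0)):
        for k in range(n):
            base = rng.lognormal(0, 0.3)
            records.append(ExpressionRecord(
                locus_id="L1", sample_id=f"{cond}{k}", condition=cond,
                count=1, fpkm=base * mult,
                pairing_key=f"p{k}" if paired else None,
                clade="HML2", motif_class="DTGAD"))
    return records


class TestContrasts:
    def test_planted_effect_detected(self, rng):
        detected = 0
        for _ in range(20):
            results = contrast_by_group(_records(rng, effect=6.0, n=8),
                                        ("case", "control"))
            assert len(results) == 1
            detected += results[0].p_adjusted < 0.05
        assert detected >= 16

    def test_adjustment_invariants(self, rng):
        results = contrast_by_group(_records(rng), ("case", "control"))
        for r in results:
            assert r.p_adjusted >= r.p_value
            assert r.p_adjusted == pytest.approx(
                min(1.0, r.p_value * len(results)))

    def test_paired_branch(self, rng):
        results = contrast_by_group(_records(rng, effect=4.0, paired=True),
                                    ("case", "control"), paired=True)
        assert results[0].test_name == "wilcoxon_signed_rank"

    def test_missing_pairing_key_rejected(self, rng):
        records = _records(rng, paired=False)
        with pytest.raises(InputError):
            contrast_by_group(records, ("case", "control"), paired=True)

    def test_motif_class_mapping(self):
        assert motif_class("DTGAD") == "DTGAD"
        assert motif_class("DTGVD") == "DTGVD"
        assert motif_class("DTGSD") == "other"

    def test_normality_diagnostic_reports_only(self, rng):
        d = normality_diagnostic(rng.lognormal(size=50))
        assert set(d) == {"n", "skewness", "excess_kurtosis"}


@pytest.fixture(scope="module")
def gag_reads():
    rng = np.random.default_rng(4)
    gag_nt = encode_protein(ANCESTOR_GAG, rng)
    return {f"r{i}": gag_nt[i * 30:i * 30 + 90] for i in range(4)}


class TestGagCoexpression:
    def test_gag_reads_flag_true(self, gag_reads):
        from ervscan.search import SearchParams

        assert gag_coexpression(gag_reads, ANCESTOR_GAG,
                                SearchParams(min_score=60.0), min_reads=2)

    def test_unrelated_reads_flag_false(self):
        rng = np.random.default_rng(6)
        reads = {f"r{i}": "".join(rng.choice(list("ACGT"), 90))
                 for i in range(4)}
        from ervscan.search import SearchParams

        assert not gag_coexpression(reads, ANCESTOR_GAG,
                                    SearchParams(min_score=60.0))

    def test_monotone_in_threshold(self, gag_reads):
        from ervscan.search import SearchParams

        flags = [gag_coexpression(gag_reads, ANCESTOR_GAG,
                                  SearchParams(min_score=s), min_reads=2)
                 for s in (40.0, 80.0, 120.0, 400.0)]
        assert flags == sorted(flags, reverse=True)
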