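import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ervscan.errors import ConfigurationError, InputError
from ervscan.search import (MIXED_FRAME, Profile, SearchParams, TranslatedHit,
                            build_profile, flush_extend, hits_mergeable,
                            load_matrix, merge_frame_hits, profile_scan,
                            score_window, six_frames, translated_search)
from ervscan.seqio import revcomp
from ervscan.synthetic import encode_protein

from oracles import closure_partition, sw_score

PARAMS = SearchParams(min_score=50.0)
QUERY = "WVPLTQLKQPISFIKPNQAGLDTGADITVLNRKDFQVIGANGQTHTFGGI"


def encode(protein, seed=0):
    return encode_protein(protein, np.random.default_rng(seed))


class TestTranslatedSearch:
    def test_verbatim_frame0_self_match(self):
        target = encode(QUERY)
        hits = translated_search("t", target, "q", QUERY, PARAMS)
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.start, hit.end) == (0, 3 * len(QUERY))
        assert (hit.strand, hit.frame) == ("+", 0)
        assert (hit.query_start, hit.query_end) == (0, len(QUERY))
        matrix = load_matrix(PARAMS.matrix_name, PARAMS.stop_score)
        assert hit.score == sum(matrix[a, a] for a in QUERY)

    def test_reverse_complement_strand_symmetry(self):
        target = "ACGTT" * 30 + encode(QUERY) + "GGATC" * 25
        fwd = translated_search("t", target, "q", QUERY, PARAMS)
        rev = translated_search("t", revcomp(target), "q", QUERY, PARAMS)
        assert len(fwd) == len(rev) == 1
        f, r = fwd[0], rev[0]
        assert f.score == r.score
        assert r.strand == "-"
        L = len(target)
        assert (r.start, r.end) == (L - f.end, L - f.start)

    def test_non_iupac_characters_rejected(self):
        with pytest.raises(InputError):
            translated_search("t", "ACGTJ" * 10, "q", QUERY, PARAMS)

    def test_ambiguity_codes_accepted(self):
        hits = translated_search("t", "ANNGT" * 20, "q", QUERY, PARAMS)
        assert hits == []

    def test_matches_smith_waterman_oracle_per_frame(self):
        # independent full-DP oracle over all six frame translations
        matrix = load_matrix(PARAMS.matrix_name, PARAMS.stop_score)
        rng = np.random.default_rng(99)
        query = QUERY[:30]
        params = SearchParams(min_score=1.0)
        for _ in range(8):
            target = "".join(rng.choice(list("ACGT"), 240))
            expected = max(
                sw_score(protein, query, matrix, params.gap_open,
                         params.gap_extend)
                for _, _, protein in six_frames(target))
            hits = translated_search("t", target, "q", query, params)
            observed = max((h.score for h in hits), default=0.0)
            assert observed == pytest.approx(expected)

    def test_multiple_hits_recovered(self):
        spacer = "GTGTC" * 50
        target = spacer + encode(QUERY, 1) + spacer + encode(QUERY, 2) + spacer
        hits = translated_search("t", target, "q", QUERY, PARAMS)
        full = [h for h in hits if h.query_end - h.query_start == len(QUERY)]
        assert len(full) == 2


class TestMergeFrameHits:
    def _hit(self, start, end, frame, qs, qe, strand="+", score=10.0):
        return TranslatedHit("t", start, end, strand, frame, qs, qe, score, "q")

    def test_frame_split_hits_merge(self):
        a = self._hit(100, 250, 0, 0, 50)
        b = self._hit(251, 400, 2, 48, 98)
        merged = merge_frame_hits([a, b], PARAMS)
        assert len(merged) == 1
        m = merged[0]
        assert (m.start, m.end) == (100, 400)
        assert (m.query_start, m.query_end) == (0, 98)
        assert m.score == 20.0
        assert m.frame == MIXED_FRAME

    def test_single_hit_unchanged(self):
        a = self._hit(10, 40, 1, 0, 10)
        assert merge_frame_hits([a], PARAMS) == [a]

    def test_empty_input(self):
        assert merge_frame_hits([], PARAMS) == []

    def test_opposite_strands_never_merge(self):
        a = self._hit(100, 250, 0, 0, 50, "+")
        b = self._hit(251, 400, 2, 48, 98, "-")
        assert len(merge_frame_hits([a, b], PARAMS)) == 2

    def test_non_collinear_hits_do_not_merge(self):
        a = self._hit(100, 250, 0, 50, 98)
        b = self._hit(251, 400, 2, 0, 40)   # query order reversed
        assert len(merge_frame_hits([a, b], PARAMS)) == 2

    def test_matches_brute_force_closure(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(2, 12))
            hits = []
            for _ in range(n):
                s = int(rng.integers(0, 5000))
                e = s + int(rng.integers(30, 400))
                qs = int(rng.integers(0, 80))
                qe = qs + int(rng.integers(5, 30))
                strand = "+" if rng.random() < 0.7 else "-"
                hits.append(TranslatedHit("t", s, e, strand,
                                          int(rng.integers(0, 3)),
                                          qs, qe, 5.0, "q"))
            merged = merge_frame_hits(hits, PARAMS)
            expected = closure_partition(
                hits, lambda a, b: hits_mergeable(a, b, PARAMS))
            assert len(merged) == len(expected)
            merged_spans = sorted((m.start, m.end) for m in merged)
            oracle_spans = sorted(
                (min(hits[i].start for i in g), max(hits[i].end for i in g))
                for g in expected)
            assert merged_spans == oracle_spans

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(8)
        hits = []
        for _ in range(8):
            s = int(rng.integers(0, 2000))
            hits.append(TranslatedHit("t", s, s + 90, "+", 0,
                                      int(rng.integers(0, 40)),
                                      int(rng.integers(40, 90)), 3.0, "q"))
        once = merge_frame_hits(hits, PARAMS)
        assert merge_frame_hits(once, PARAMS) == once
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert merge_frame_hits(shuffled, PARAMS) == once


class TestFlushExtend:
    def _hit(self, start, end, qs, qe, strand="+"):
        return TranslatedHit("t", start, end, strand, 0, qs, qe, 10.0, "q")

    def test_arithmetic_example(self):
        ext = flush_extend(self._hit(1000, 1258, 10, 96), 106, 5000)
        assert (ext.start, ext.end) == (970, 1288)
        assert not ext.clipped_start and not ext.clipped_end

    def test_already_flush_unchanged(self):
        ext = flush_extend(self._hit(300, 618, 0, 106), 106, 5000)
        assert (ext.start, ext.end) == (300, 618)

    def test_clipped_at_contig_start(self):
        ext = flush_extend(self._hit(20, 278, 10, 96), 106, 5000)
        assert ext.start == 0
        assert ext.clipped_start

    def test_minus_strand_mirrored(self):
        ext = flush_extend(self._hit(1000, 1258, 10, 96, strand="-"), 106, 5000)
        assert (ext.start, ext.end) == (970, 1288)

    @given(start=st.integers(0, 10000), qlen=st.integers(1, 200),
           qs=st.integers(0, 200), span=st.integers(1, 100))
    @settings(max_examples=100, deadline=None)
    def test_never_shrinks(self, start, qlen, qs, span):
        qs = min(qs, qlen)
        qe = min(qs + span, qlen)
        hit = TranslatedHit("t", start, start + 3 * (qe - qs), "+", 0,
                            qs, qe, 1.0, "q")
        ext = flush_extend(hit, qlen, 100000)
        assert ext.start <= hit.start
        assert ext.end >= hit.end


@pytest.fixture(scope="module")
def profile():
    rng = np.random.default_rng(3)
    base = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 40))
    exemplars = []
    for _ in range(6):
        chars = list(base)
        for i in rng.integers(0, 40, size=4):
            chars[i] = str(rng.choice(list("ARNDCQEGHILKMFPSTWYV")))
        exemplars.append("".join(chars))
    return build_profile(exemplars, kind="RVP")


class TestProfileScan:
    def test_consensus_scores_maximum(self, profile):
        assert score_window(profile, profile.consensus) == pytest.approx(
            profile.max_score)

    def test_consensus_window_reported(self, profile):
        target = encode_protein(profile.consensus, np.random.default_rng(0))
        hits = profile_scan("t", target, profile,
                            SearchParams(profile_threshold=10.0))
        assert any(h.kind == "RVP" and h.start == 0 for h in hits)

    def test_random_null_hit_rate_below_one_percent(self, profile):
        rng = np.random.default_rng(44)
        aa = list("ARNDCQEGHILKMFPSTWYV")
        threshold = 0.5 * profile.max_score
        null_hits = sum(
            score_window(profile, "".join(rng.choice(aa, profile.ncols)))
            >= threshold
            for _ in range(1000))
        assert null_hits / 1000 < 0.01

    def test_partial_randomisation_scores_between_null_and_max(self, profile):
        rng = np.random.default_rng(17)
        aa = list("ARNDCQEGHILKMFPSTWYV")
        chars = list(profile.consensus)
        for i in rng.choice(profile.ncols, size=int(0.4 * profile.ncols),
                            replace=False):
            chars[i] = str(rng.choice(aa))
        score = score_window(profile, "".join(chars))
        null_mean = np.mean([
            score_window(profile, "".join(rng.choice(aa, profile.ncols)))
            for _ in range(200)])
        assert null_mean < score < profile.max_score

    def test_too_few_columns_rejected(self):
        with pytest.raises(ConfigurationError):
            build_profile(["ACDEF"] * 3)

    def test_alphabet_mismatch_rejected(self, profile):
        bad = Profile(kind="x", matrix=profile.matrix, alphabet="ACGT")
        with pytest.raises(ConfigurationError):
            profile_scan("t", "ACGT" * 30, bad, PARAMS)
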