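"""Suffix structures against brute-force oracles and the worked fixture."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hyp

import colormove as cm
from colormove.oracles import brute_bwt
from conftest import random_text


class TestBuildConcat:
    def test_worked_concatenation(self, worked):
        assert worked["text"].S == "ACAACG$"
        assert worked["text"].boundaries == [(0, 3), (3, 6)]

    def test_single_document(self):
        coll = cm.DocumentCollection([cm.Document(0, "D1", ["A"])])
        text = cm.build_concat(coll)
        assert text.S == "A$" and text.n == 2

    def test_sanitization_splits_non_acgt(self):
        assert cm.sanitize_sequence("ACNNGT") == ["AC", "GT"]
        assert cm.sanitize_sequence("acgt") == ["ACGT"]
        coll = cm.DocumentCollection([cm.Document(0, "D1", ["ACNNGT"])])
        assert cm.build_concat(coll).S == "ACGT$"

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            cm.build_concat(cm.DocumentCollection([]))

    def test_all_ambiguous_document_rejected(self):
        coll = cm.DocumentCollection([cm.Document(0, "D1", ["NNNN"])])
        with pytest.raises(ValueError):
            cm.build_concat(coll)


class TestSuffixStructures:
    def test_worked_example(self, worked):
        st = worked["structures"]
        assert st.SA.tolist() == [6, 2, 0, 3, 1, 4, 5]
        assert st.BWT == "GC$AAAC"
        assert st.LCP.tolist() == [0, 0, 1, 2, 0, 1, 0]
        # '$' suffix attributed to the last document (D2)
        assert st.DA.tolist() == [1, 0, 0, 1, 0, 1, 1]

    def test_two_character_text(self):
        st = cm.build_suffix_structures(cm.ConcatText("A$", [(0, 1)]))
        assert st.BWT == "A$"

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hyp.integers(0, 10_000))
    def test_matches_brute_force_oracles(self, seed):
        rng = np.random.default_rng(seed)
        coll = random_text(rng)
        text = cm.build_concat(coll)
        st = cm.build_suffix_structures(text)
        sa, bwt = brute_bwt(text.S)
        assert st.SA.tolist() == sa
        assert st.BWT == bwt
        # LCP against pairwise prefix comparison
        suffixes = [text.S[i:] for i in sa]
        for i in range(1, len(sa)):
            a, b = suffixes[i - 1], suffixes[i]
            expected = next(
                (k for k in range(min(len(a), len(b))) if a[k] != b[k]),
                min(len(a), len(b)),
            )
            assert st.LCP[i] == expected
        # document array by direct lookup
        for row, pos in enumerate(sa):
            doc = next(
                (d for d, (s, e) in enumerate(text.boundaries) if s <= pos < e),
                len(text.boundaries) - 1,
            )
            assert st.DA[row] == doc

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(hyp.integers(0, 10_000))
    def test_inverse_bwt_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 2000))
        s = "".join(rng.choice(list("ACGT"), n)) + "$"
        st = cm.build_suffix_structures(cm.ConcatText(s, [(0, n)]))
        assert cm.inverse_bwt(st.BWT) == s


class TestRuns:
    def test_worked_runs(self, worked):
        runs = worked["runs"]
        assert runs.r == 5
        assert [runs.char_str(i) for i in range(5)] == ["G", "C", "$", "A", "C"]
        assert runs.lengths.tolist() == [1, 1, 1, 3, 1]

    @pytest.mark.parametrize(
        "bwt,r,lengths",
        [("AAAA", 1, [4]), ("ACGT", 4, [1, 1, 1, 1]), ("GC$AAAC", 5, [1, 1, 1, 3, 1])],
    )
    def test_maximal_runs(self, bwt, r, lengths):
        runs = cm.find_runs(bwt)
        assert runs.r == r
        assert runs.lengths.tolist() == lengths
        assert runs.lengths.sum() == len(bwt)
        assert all(runs.chars[i] != runs.chars[i + 1] for i in range(r - 1))


def _nearest_occurrence_lcps(st, flat, c_code):
    """(up-LCP, down-LCP) of the suffix at BWT offset ``flat`` to the nearest
    offsets carrying ``c_code``, by scanning the LCP array directly."""
    bwt = st.bwt_codes
    up = down = None
    cur = None
    for q in range(flat - 1, -1, -1):
        step = st.LCP[q + 1]
        cur = step if cur is None else min(cur, step)
        if bwt[q] == c_code:
            up = cur
            break
    cur = None
    for q in range(flat + 1, len(bwt)):
        step = st.LCP[q]
        cur = step if cur is None else min(cur, step)
        if bwt[q] == c_code:
            down = cur
            break
    return up, down


class TestThresholds:
    def test_worked_thresholds(self, worked):
        th = worked["thresholds"].thresholds
        # run of A at flat 3..5, c='C': first min of LCP over (1, 6] at 4 -> 1
        assert th[3, 1] == 1
        # run of C at flat 6, c='G': G only above -> run length (always up)
        assert th[4, 2] == 1
        # run of G at flat 0, c='C': C only below -> 0 (always down)
        assert th[0, 1] == 0

    def test_threshold_monotonicity_brute(self):
        # for offsets below the threshold, repositioning up keeps at least as
        # long a common prefix as repositioning down (and conversely)
        rng = np.random.default_rng(7)
        for _ in range(20):
            coll = random_text(rng, n_docs=2, max_len=60)
            text = cm.build_concat(coll)
            st = cm.build_suffix_structures(text)
            runs = cm.find_runs(st.bwt_codes)
            th = cm.compute_thresholds(runs, st).thresholds
            for i in range(runs.r):
                for c_code in range(1, 5):
                    if c_code == runs.chars[i]:
                        continue
                    for j in range(int(runs.lengths[i])):
                        flat = int(runs.starts[i]) + j
                        up, down = _nearest_occurrence_lcps(st, flat, c_code)
                        if up is None or down is None:
                            continue
                        if j < th[i, c_code - 1]:
                            assert up >= down
                        else:
                            assert down >= up


class TestSharedLcp:
    def test_worked_run(self, worked):
        assert cm.shared_lcp(3, worked["runs"], worked["structures"]) == 0

    def test_length_one_run_is_suffix_length(self, worked):
        # run 0 is the single 'G' row whose suffix is "$"
        assert cm.shared_lcp(0, worked["runs"], worked["structures"]) == 1

    def test_pairwise_lcp_for_length_two_run(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            coll = random_text(rng, n_docs=2, max_len=50)
            text = cm.build_concat(coll)
            st = cm.build_suffix_structures(text)
            runs = cm.find_runs(st.bwt_codes)
            for i in range(runs.r):
                if runs.lengths[i] < 2:
                    continue
                s, L = int(runs.starts[i]), int(runs.lengths[i])
                sufs = [text.S[st.SA[p]:] for p in range(s, s + L)]
                pair_lcp = min(
                    next((k for k in range(min(len(a), len(b))) if a[k] != b[k]),
                         min(len(a), len(b)))
                    for a, b in zip(sufs, sufs[1:])
                )
                assert cm.shared_lcp(i, runs, st) == pair_lcp
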