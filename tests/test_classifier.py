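"""PML computation, color-tally scoring, gating and multi-class decisions."""

import numpy as np
import pytest

import colormove as cm
from colormove.oracles import brute_matching_statistics
from colormove.taxonomy import build_taxonomy
from conftest import build_table_for, random_text

STRATEGIES = ["true", "mid-run", "always-up"]


@pytest.fixture
def two_doc_tree():
    return build_taxonomy([
        (1, 1, "domain", "root"),
        (10, 1, "genus", "g"),
        (100, 10, "species", "s1"),
        (101, 10, "species", "s2"),
        (102, 1, "species", "far"),
    ])


class TestComputePmls:
    def test_worked_read(self, worked):
        res = cm.compute_pmls(worked["table"], "ACG", "true")
        assert res.pml.tolist() == [2, 1, 0]
        assert res.visited.tolist()[0:2] == [3, 3]  # post-LF run for k=0,1

    def test_absent_character_gives_zero(self, worked):
        res = cm.compute_pmls(worked["table"], "TTTT", "true")
        assert res.pml.tolist() == [0, 0, 0, 0]
        assert all(v == -1 for v in res.visited)

    def test_non_acgt_never_matches(self, worked):
        res = cm.compute_pmls(worked["table"], "ANCG", "true")
        assert res.pml[1] == 0 and res.visited[1] == -1

    def test_empty_read_rejected(self, worked):
        with pytest.raises(ValueError):
            cm.compute_pmls(worked["table"], "")

    def test_true_strategy_requires_thresholds(self, worked):
        t = worked["table"]
        bare = cm.MoveTable(
            n=t.n, run_chars=t.run_chars, run_lens=t.run_lens, starts=t.starts,
            dest_run=t.dest_run, dest_off=t.dest_off, thresholds=None,
            color_ids=t.color_ids, char_present=t.char_present,
        )
        with pytest.raises(ValueError, match="thresholds"):
            cm.compute_pmls(bare, "ACG", "true")
        assert cm.compute_pmls(bare, "ACG", "mid-run").pml.tolist() == [2, 1, 0]

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_pml_bounded_by_matching_statistics(self, strategy):
        rng = np.random.default_rng(31)
        for _ in range(40):
            coll = random_text(rng, n_docs=2, max_len=150)
            text = cm.build_concat(coll)
            _, _, table, _ = build_table_for(text.S, text.boundaries)
            m = int(rng.integers(5, 60))
            read = "".join(rng.choice(list("ACGT"), m))
            res = cm.compute_pmls(table, read, strategy)
            ms = brute_matching_statistics(text.S[:-1], read)
            assert all(p <= s for p, s in zip(res.pml.tolist(), ms))
            # a length can grow by at most one per leftward step
            assert all(res.pml[k] <= res.pml[k + 1] + 1 for k in range(m - 1))

    def test_determinism(self, worked):
        a = cm.compute_pmls(worked["table"], "ACGACG", "true")
        b = cm.compute_pmls(worked["table"], "ACGACG", "true")
        assert np.array_equal(a.pml, b.pml) and np.array_equal(a.visited, b.visited)


class TestScoreRead:
    def test_worked_scores(self, worked):
        res = cm.compute_pmls(worked["table"], "ACG", "true")
        assert cm.score_read(res, worked["colors"]) == {0: 2, 1: 2}

    def test_zero_pml_gives_no_scores(self, worked):
        res = cm.compute_pmls(worked["table"], "TTTT", "true")
        assert cm.score_read(res, worked["colors"]) == {}

    def test_score_mass_equals_color_sizes(self, worked):
        rng = np.random.default_rng(33)
        for _ in range(20):
            coll = random_text(rng, n_docs=3, max_len=120)
            text = cm.build_concat(coll)
            _, _, table, colors = build_table_for(text.S, text.boundaries)
            read = "".join(rng.choice(list("ACGT"), 40))
            res = cm.compute_pmls(table, read, "true")
            scores = cm.score_read(res, colors)
            mask = (res.pml > 0) & (res.visited >= 0)
            mass = sum(len(colors.docs_of_run(int(v))) for v in res.visited[mask])
            assert sum(scores.values()) == mass
            n_pos = int(mask.sum())
            assert all(s <= n_pos for s in scores.values())


class TestAveragePml:
    def test_arithmetic(self):
        res = cm.PMLResult(np.array([2, 1, 0]), np.array([3, 3, 4]))
        assert cm.average_pml(res) == 1.0
        zeros = cm.PMLResult(np.zeros(4, int), np.full(4, -1))
        assert cm.average_pml(zeros) == 0.0

    def test_indexed_read_beats_random_read(self, worked):
        S = worked["text"].S
        rng = np.random.default_rng(4)
        genome = "".join(rng.choice(list("ACGT"), 400)) + "$"
        _, _, table, _ = build_table_for(genome)
        exact = cm.compute_pmls(table, genome[50:150], "true")
        rand = cm.compute_pmls(
            table, "".join(rng.choice(list("ACGT"), 100)), "true")
        assert cm.average_pml(exact) > cm.average_pml(rand)


class TestCalibrateCutoff:
    def test_nearest_rank_on_grid(self):
        vals = [(i + 1) / 100 for i in range(100)]
        assert cm.calibrate_cutoff(vals, 95).cutoff == pytest.approx(0.95)

    def test_identical_values(self):
        calib = cm.calibrate_cutoff([0.7] * 20, 95)
        assert calib.cutoff == 0.7 and calib.n_null == 20

    def test_too_few_nulls_rejected(self):
        with pytest.raises(ValueError):
            cm.calibrate_cutoff([0.1] * 19)


class TestClassifyRead:
    DOC_TAXON = {0: 100, 1: 101, 2: 102}

    def test_close_second_reported_as_lca(self, two_doc_tree):
        cls = cm.classify_read({0: 100, 1: 96, 2: 50}, 5.0, None, two_doc_tree,
                               self.DOC_TAXON)
        assert cls.reported_docs == [0, 1]
        assert cls.assigned_taxon == 10  # LCA of the two species = genus

    def test_below_ratio_second_dropped(self, two_doc_tree):
        cls = cm.classify_read({0: 100, 1: 94}, 5.0, None, two_doc_tree,
                               self.DOC_TAXON)
        assert cls.reported_docs == [0] and cls.assigned_taxon == 100

    def test_gate_overrides_scores(self, two_doc_tree):
        calib = cm.BinaryCalibration(cutoff=0.9, percentile=95, n_null=100)
        cls = cm.classify_read({0: 100}, 0.4, calib, two_doc_tree, self.DOC_TAXON)
        assert cls.status == "unclassified" and cls.reported_docs == []

    def test_all_zero_scores_unclassified(self, two_doc_tree):
        cls = cm.classify_read({}, 5.0, None, two_doc_tree, self.DOC_TAXON)
        assert cls.status == "unclassified"

    def test_tie_breaks_to_smallest_doc(self, two_doc_tree):
        cls = cm.classify_read({1: 50, 0: 50}, 5.0, None, two_doc_tree,
                               self.DOC_TAXON, max_secondary=0)
        assert cls.reported_docs == [0]

    def test_max_secondary_limits_reports(self, two_doc_tree):
        cls = cm.classify_read({0: 100, 1: 100, 2: 99}, 5.0, None, two_doc_tree,
                               self.DOC_TAXON, max_secondary=1)
        assert cls.reported_docs == [0, 1]


class TestStrandHandling:
    def test_reverse_complement_read_recovers_orientation(self):
        rng = np.random.default_rng(8)
        genome = "".join(rng.choice(list("ACGT"), 500)) + "$"
        _, _, table, _ = build_table_for(genome)
        fragment = genome[100:220]
        rc = cm.reverse_complement(fragment)
        res = cm.compute_pmls_best_orientation(table, rc, "true")
        assert res.orientation == "-"
        fwd = cm.compute_pmls_best_orientation(table, fragment, "true")
        assert fwd.orientation == "+"
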