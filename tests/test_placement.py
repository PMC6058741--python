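import numpy as np
import pytest

from ervscan.codonalign import align_codon_aware
from ervscan.errors import ConfigurationError, InputError
from ervscan.placement import (INTERNAL, UNPLACED, Placement, PlacementEngine,
                               align_query_to_reference, build_reference_tree,
                               classify_placement, edge_clade,
                               reconcile_locus)
from ervscan.synthetic import make_reference_set

from conftest import TEN_CLADE_TREE

AA = list("ARNDCQEGHILKMFPSTWYV")


@pytest.fixture(scope="module")
def ref_alignment(reference_library):
    ca = align_codon_aware(reference_library)
    return ca.aa_rows


@pytest.fixture(scope="module")
def ref_tree(ref_alignment):
    return build_reference_tree(ref_alignment,
                                {name: name for name in ref_alignment})


@pytest.fixture(scope="module")
def engine(ref_tree, ref_alignment):
    return PlacementEngine(ref_tree, ref_alignment)


class TestBuildReferenceTree:
    def test_recovers_additive_four_taxon_split(self):
        # distances from tree ((A:1,B:2):1,(C:3,D:1)); exhaustive
        # least-squares over the 3 topologies puts AB|CD strictly first
        rows = {
            "A": "AAAAAAAAAA" * 4,
            "B": "AAAAAAAACC" * 4,   # etc: we feed distances directly below
        }
        import numpy as np
        from skbio import DistanceMatrix
        from skbio.tree import nj

        d = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0]], dtype=float)
        tree = nj(DistanceMatrix(d, ["A", "B", "C", "D"]))
        ab = tree.lowest_common_ancestor(["A", "B"])
        assert {t.name for t in ab.tips()} == {"A", "B"} \
            or {t.name for t in tree.lowest_common_ancestor(["C", "D"]).tips()} \
            == {"C", "D"}

    def test_too_few_references_rejected(self, ref_alignment):
        three = dict(list(ref_alignment.items())[:3])
        with pytest.raises(InputError):
            build_reference_tree(three, {k: k for k in three})

    def test_unlabeled_leaf_rejected(self, ref_alignment):
        labels = {k: k for k in ref_alignment}
        labels.pop("HML2")
        with pytest.raises(ConfigurationError):
            build_reference_tree(ref_alignment, labels)

    def test_topology_recovery_from_simulated_references(self):
        # low-divergence references: NJ should recover the simulation tree
        from skbio import TreeNode

        truth = TreeNode.read([TEN_CLADE_TREE])
        recovered = 0
        n_seeds = 10
        for seed in range(n_seeds):
            refs = make_reference_set(TEN_CLADE_TREE, rng_seed=seed + 500)
            ca = align_codon_aware(refs)
            tree = build_reference_tree(ca.aa_rows, {k: k for k in refs})
            rf = truth.compare_rfd(tree.tree)
            if rf == 0:
                recovered += 1
        assert recovered >= int(0.9 * n_seeds)


class TestPlaceQuery:
    def test_self_placement_on_pendant_edge(self, engine, ref_tree,
                                            ref_alignment):
        for leaf in ("HML2", "HML7"):
            placement = engine.place(leaf, ref_alignment[leaf])
            assert placement.verdict == leaf
            assert placement.best_weight >= 0.99
            edge = ref_tree.edges()[placement.best_edge]
            assert edge.is_tip() and edge.name == leaf

    def test_weights_sum_to_one(self, engine, ref_alignment):
        placement = engine.place("q", ref_alignment["HML5"])
        assert sum(placement.edge_weights.values()) == pytest.approx(1.0)

    def test_midpoint_query_splits_weight(self, engine, ref_tree,
                                          ref_alignment):
        a, b = ref_alignment["HML1"], ref_alignment["HML2"]
        # exactly intermediate: alternate residues from the two leaves
        mid = "".join(x if i % 2 == 0 else y
                      for i, (x, y) in enumerate(zip(a, b)))
        placement = engine.place("mid", mid, threshold=0.90)
        assert placement.verdict in (UNPLACED, "HML1", "HML2")
        if placement.verdict == UNPLACED:
            assert placement.best_weight < 0.90

    def test_random_sequence_unplaced(self, engine):
        rng = np.random.default_rng(0)
        rand = "".join(rng.choice(AA, engine.ncols))
        placement = engine.place("rand", rand)
        assert placement.verdict == UNPLACED

    def test_insufficient_overlap(self, engine):
        row = "-" * engine.ncols
        placement = engine.place("gap", row)
        assert placement.verdict == UNPLACED
        assert placement.reason == "insufficient overlap"

    def test_diverged_queries_recover_clade(self, engine, ref_alignment):
        rng = np.random.default_rng(9)
        correct = total = 0
        for clade in ref_alignment:
            for _ in range(5):
                row = "".join(
                    ch if ch == "-" or rng.random() > 0.08
                    else str(rng.choice(AA))
                    for ch in ref_alignment[clade])
                placement = engine.place("q", row)
                total += 1
                correct += placement.verdict == clade
        assert correct / total >= 0.9


class TestClassifyPlacement:
    def _placement(self, edge, weight):
        return Placement(query_id="q", edge_weights={edge: weight},
                         best_edge=edge, best_weight=weight, verdict="")

    def test_high_weight_within_clade(self, ref_tree):
        edges = ref_tree.edges()
        tip_idx = next(i for i, e in enumerate(edges)
                       if e.is_tip() and e.name == "HML3")
        verdict = classify_placement(self._placement(tip_idx, 0.95), ref_tree)
        assert verdict == "HML3"

    def test_below_threshold_unplaced(self, ref_tree):
        verdict = classify_placement(self._placement(0, 0.85), ref_tree)
        assert verdict == UNPLACED

    def test_internal_edge(self, ref_tree):
        edges = ref_tree.edges()
        internal_idx = next(
            i for i, e in enumerate(edges)
            if edge_clade(ref_tree, e) == INTERNAL)
        verdict = classify_placement(self._placement(internal_idx, 0.95),
                                     ref_tree)
        assert verdict == INTERNAL

    def test_threshold_monotonicity(self, engine, ref_alignment):
        placement = engine.place("q", ref_alignment["HML4"])
        placed_at = [t for t in (0.5, 0.7, 0.9, 0.95, 0.999)
                     if classify_placement(placement, engine.ref_tree,
                                           threshold=t) != UNPLACED]
        # once unplaced at some threshold, never placed at a higher one
        thresholds = (0.5, 0.7, 0.9, 0.95, 0.999)
        verdicts = [classify_placement(placement, engine.ref_tree, threshold=t)
                    != UNPLACED for t in thresholds]
        assert verdicts == sorted(verdicts, reverse=True)
        assert placed_at  # self-placement survives reasonable thresholds


class TestReconcileLocus:
    def test_unanimous(self):
        assert reconcile_locus({"a": "HML2", "b": "HML2"}) == \
            ("HML2", False, [])

    def test_unplaced_ignored(self):
        assert reconcile_locus({"a": "HML2", "b": UNPLACED}) == \
            ("HML2", False, [])

    def test_tie_is_conflict(self):
        verdict, conflict, dissenters = reconcile_locus(
            {"a": "HML2", "b": "HML3"})
        assert verdict == "conflict"
        assert conflict

    def test_majority_reported_with_dissenters(self):
        verdict, conflict, dissenters = reconcile_locus(
            {"a": "HML2", "b": "HML2", "c": "HML3"})
        assert verdict == "HML2"
        assert conflict
        assert dissenters == ["c"]

    def test_all_unplaced(self):
        assert reconcile_locus({"a": UNPLACED})[0] == UNPLACED

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            reconcile_locus({})


class TestQueryProfileAlignment:
    def test_reference_row_round_trips(self, ref_alignment):
        row = ref_alignment["HML6"]
        query = row.replace("-", "")
        aligned = align_query_to_reference(ref_alignment, query)
        assert len(aligned) == len(row)
        assert aligned.replace("-", "") == query
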