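import random

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from its_structphylo.trees import (bipartitions, bootstrap_support, nj_tree,
                                   rf_distance, upgma_tree)


def _additive_matrix(newick, taxa):
    """Patristic distance matrix of a tree (the additive-matrix oracle)."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = pdm.patristic_distance(tx[taxa[i]], tx[taxa[j]])
    return d


class TestNeighborJoining:
    def test_recovers_four_taxon_topology(self):
        taxa = ["A", "B", "C", "D"]
        d = _additive_matrix("((A:0.1,B:0.2):0.15,(C:0.12,D:0.18):0.1);", taxa)
        t = nj_tree(d, taxa)
        assert bipartitions(t) == {frozenset({"C", "D"})}

    def test_three_taxa_three_point_formulas(self):
        d = np.array([[0.0, 0.3, 0.4], [0.3, 0.0, 0.5], [0.4, 0.5, 0.0]])
        t = nj_tree(d, ["A", "B", "C"])
        lens = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lens["A"] == pytest.approx(0.5 * (0.3 + 0.4 - 0.5))
        assert lens["B"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.4))
        assert lens["C"] == pytest.approx(0.5 * (0.4 + 0.5 - 0.3))

    def test_recovers_topologies_up_to_12_taxa(self):
        rng = random.Random(77)
        for n in (6, 9, 12):
            taxa = [f"T{k}" for k in range(n)]
            tns = dendropy.TaxonNamespace(taxa)
            true = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
                num_extant_tips=len(tns), rng=rng)
            true.is_rooted = False
            d = _additive_matrix(true.as_string(schema="newick"), taxa)
            t = nj_tree(d, taxa)
            assert rf_distance(true, t) == 0

    def test_ultrametric_matrix_matches_upgma_topology(self):
        # ultrametric: heights 0.1 (A,B), 0.2 ((A,B),C), 0.3 (...,D)
        taxa = ["A", "B", "C", "D"]
        d = np.array([
            [0.0, 0.2, 0.4, 0.6],
            [0.2, 0.0, 0.4, 0.6],
            [0.4, 0.4, 0.0, 0.6],
            [0.6, 0.6, 0.6, 0.0],
        ])
        assert bipartitions(nj_tree(d, taxa)) == bipartitions(upgma_tree(d, taxa))

    def test_non_symmetric_rejected(self):
        d = np.array([[0.0, 0.1, 0.2], [0.3, 0.0, 0.1], [0.2, 0.1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d, ["A", "B", "C"])

    def test_branch_lengths_non_negative(self):
        rng = random.Random(5)
        for _ in range(20):
            n = 6
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = rng.random()
            t = nj_tree(d, [f"T{k}" for k in range(n)])
            for e in t.preorder_edge_iter():
                if e.length is not None:
                    assert e.length >= 0


class TestUpgma:
    def test_two_taxa_split_evenly(self):
        t = upgma_tree(np.array([[0.0, 0.2], [0.2, 0.0]]), ["A", "B"])
        lens = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lens["A"] == pytest.approx(0.1) and lens["B"] == pytest.approx(0.1)

    def test_zero_matrix_star_with_zero_lengths(self):
        t = upgma_tree(np.zeros((4, 4)), ["A", "B", "C", "D"])
        for lf in t.leaf_node_iter():
            assert lf.edge.length == pytest.approx(0.0)

    def test_groups_planted_cbc_history(self, small_family):
        from its_structphylo.cbc import cbc_matrix, tabulate_events
        _, truth = small_family
        aln = truth.alignment
        events, _ = tabulate_events(aln, paired_cols=truth.paired_cols)
        m = cbc_matrix(events, aln.taxa)
        if m.values.sum() > 0:
            t = upgma_tree(m.values.astype(float), list(m.index))
            assert {lf.taxon.label for lf in t.leaf_node_iter()} == set(aln.taxa)


class TestRfDistance:
    def test_identical_trees_zero(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t2 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        assert rf_distance(t1, t2) == 0

    def test_alternative_quartets_distance_two(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t2 = dendropy.Tree.get(data="((A,C),(B,D));", schema="newick")
        assert rf_distance(t1, t2) == 2

    def test_matches_dendropy_oracle_on_random_trees(self):
        rng = random.Random(11)
        tns = dendropy.TaxonNamespace([f"T{k}" for k in range(8)])
        for _ in range(20):
            t1 = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
                num_extant_tips=len(tns), rng=rng)
            t2 = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
                num_extant_tips=len(tns), rng=rng)
            t1.is_rooted = False
            t2.is_rooted = False
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            expected = treecompare.symmetric_difference(t1, t2)
            assert rf_distance(t1, t2) == expected

    def test_leaf_set_mismatch_rejected(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t2 = dendropy.Tree.get(data="((A,B),(C,E));", schema="newick")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)


def _block_matrix_builder(rows):
    from its_structphylo.diversity import pairwise_distance_matrix

    def build(cols):
        return pairwise_distance_matrix(rows, cols=cols)

    return build


class TestBootstrap:
    def _rows(self):
        # two 4-taxon blocks with many diagnostic columns
        a = "A" * 30
        b = "A" * 15 + "C" * 15
        rows = {}
        for k in range(4):
            rows[f"x{k}"] = a
            rows[f"y{k}"] = b
        # add tiny unique noise so taxa are distinct
        rows = {t: s[:-1] + "ACGU"[i % 4] for i, (t, s) in enumerate(rows.items())}
        return rows

    def test_seed_reproducible(self):
        rows = self._rows()
        t1 = bootstrap_support(_block_matrix_builder(rows), 30, reps=25, seed=4)
        t2 = bootstrap_support(_block_matrix_builder(rows), 30, reps=25, seed=4)
        lab1 = sorted(nd.label for nd in t1.preorder_node_iter() if nd.label)
        lab2 = sorted(nd.label for nd in t2.preorder_node_iter() if nd.label)
        assert lab1 == lab2

    def test_block_bipartition_fully_supported(self):
        rows = self._rows()
        t = bootstrap_support(_block_matrix_builder(rows), 30, reps=50, seed=1)
        block = frozenset({"y0", "y1", "y2", "y3"})
        for nd in t.preorder_node_iter():
            if nd.is_leaf() or nd is t.seed_node:
                continue
            side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if side == block:
                assert nd.label == "100"

    def test_single_rep_support_all_or_nothing(self):
        rows = self._rows()
        t = bootstrap_support(_block_matrix_builder(rows), 30, reps=1, seed=2)
        for nd in t.preorder_node_iter():
            if nd.label:
                assert nd.label in ("0", "100")

    def test_invalid_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(_block_matrix_builder(self._rows()), 30, reps=0, seed=0)
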