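"""Neighbor joining exactness and the ortholog-pairing statistic."""

import numpy as np
import pytest

from cypminer.phylo import (
    DistanceMatrix,
    distance_matrix,
    neighbor_joining,
    pairing_statistic,
    tree_path_lengths,
)
from cypminer.seqio import ProteinRecord


def _additive_matrix_from_random_tree(n_taxa, rng):
    """Random binary tree by successive cluster joins; returns labels and
    the additive leaf-to-leaf path-length matrix (independent oracle)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    dist = {}
    clusters = [{lbl: 0.0} for lbl in labels]  # leaf -> distance to root
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        li, lj = rng.uniform(0.5, 3.0), rng.uniform(0.5, 3.0)
        b = clusters.pop(int(j))
        a = clusters.pop(int(i))
        for x, dx in a.items():
            for y, dy in b.items():
                dist[(x, y)] = dist[(y, x)] = dx + li + dy + lj
        clusters.append(
            {x: dx + li for x, dx in a.items()}
            | {y: dy + lj for y, dy in b.items()}
        )
    d = np.zeros((n_taxa, n_taxa))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i != j:
                d[i, j] = dist[(x, y)]
    return labels, d


class TestDistanceMatrix:
    def test_identical_sequences_zero(self):
        prots = [ProteinRecord(f"p{i}", "MKVLAWT" * 10) for i in range(3)]
        dm = distance_matrix(prots)
        assert np.allclose(dm.d, 0.0)

    def test_symmetry_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_fewer_than_three_errors(self):
        with pytest.raises(ValueError):
            distance_matrix([ProteinRecord("a", "MK"),
                             ProteinRecord("b", "MK")])


class TestNeighborJoining:
    def test_known_four_taxon_tree(self):
        # classic worked example: additive matrix with known NJ solution
        labels = ("a", "b", "c", "d")
        d = np.array([
            [0, 5, 9, 9],
            [5, 0, 10, 10],
            [9, 10, 0, 8],
            [9, 10, 8, 0],
        ], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        paths = tree_path_lengths(tree)
        for (x, y), dist in paths.items():
            i, j = labels.index(x), labels.index(y)
            assert dist == pytest.approx(d[i, j], abs=1e-9)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_additive_matrices_reproduced_exactly(self, n, rng):
        labels, d = _additive_matrix_from_random_tree(n, rng)
        tree = neighbor_joining(DistanceMatrix(tuple(labels), d))
        paths = tree_path_lengths(tree)
        for (x, y), dist in paths.items():
            i, j = labels.index(x), labels.index(y)
            assert dist == pytest.approx(d[i, j], abs=1e-9)

    def test_equidistant_taxa_star(self):
        labels = ("a", "b", "c", "d")
        d = np.ones((4, 4)) - np.eye(4)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        internal = [
            e.length for e in tree.preorder_edge_iter()
            if e.head_node.taxon is None and e.length is not None
        ]
        assert all(abs(x) < 1e-12 for x in internal)

    def test_label_order_invariance(self, rng):
        labels, d = _additive_matrix_from_random_tree(6, rng)
        t1 = neighbor_joining(DistanceMatrix(tuple(labels), d))
        perm = list(rng.permutation(len(labels)))
        labels2 = tuple(labels[i] for i in perm)
        d2 = d[np.ix_(perm, perm)]
        t2 = neighbor_joining(DistanceMatrix(labels2, d2))
        assert tree_path_lengths(t1) == pytest.approx(tree_path_lengths(t2))

    def test_agrees_with_skbio_on_additive_input(self, rng):
        """Independent cross-check: path lengths match scikit-bio's NJ."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        labels, d = _additive_matrix_from_random_tree(6, rng)
        ours = tree_path_lengths(
            neighbor_joining(DistanceMatrix(tuple(labels), d))
        )
        sk_tree = skbio_nj(skbio.DistanceMatrix(d, labels))
        for (a, b), dist in ours.items():
            assert sk_tree.find(a).distance(sk_tree.find(b)) == pytest.approx(
                dist, abs=1e-6
            )


class TestPairingStatistic:
    def _perfect_matrix(self):
        labels = ("spA|x1", "spA|x2", "spB|x1", "spB|x2")
        d = np.array([
            [0.0, 0.5, 0.1, 0.6],
            [0.5, 0.0, 0.6, 0.1],
            [0.1, 0.6, 0.0, 0.5],
            [0.6, 0.1, 0.5, 0.0],
        ])
        return DistanceMatrix(labels, d)

    def test_perfect_pairs_give_one(self):
        dm = self._perfect_matrix()
        res = pairing_statistic(dm, lambda l: l.split("|")[0], "spA", "spB")
        assert res == {"fraction": 1.0, "n_paired": 2, "n_total": 2}

    def test_absent_species_errors(self):
        dm = self._perfect_matrix()
        with pytest.raises(ValueError):
            pairing_statistic(dm, lambda l: "spA", "spA", "spB")

    def test_partial_ortholog_deletion(self):
        """Synthetic run with orthologs missing at rate 0.2 and no partial
        transcripts: the statistic is about 0.8."""
        from cypminer.redundancy import ClusterConfig, greedy_cluster
        from cypminer.synthgen import SimConfig, emit_transcriptome

        cfg = SimConfig(seed=5, n_families=2, subfamilies_per_family=2,
                        members_per_subfamily=6, allelic_rate=0.0,
                        partial_fraction=0.0, decoy_count=0,
                        ortholog_missing_rate=0.2)
        res = emit_transcriptome(cfg)
        fractions = []
        truth = res.truth.set_index("id")
        for fam in sorted(truth.family.unique()):
            prots = [p for p in res.proteins
                     if truth.loc[p.id].family == fam]
            dm = distance_matrix(sorted(prots, key=lambda p: p.id))
            species = {l: l.split("|")[0] for l in dm.labels}
            res_stat = pairing_statistic(dm, species, "spA", "spB")
            fractions.append(res_stat)
        total = sum(r["n_total"] for r in fractions)
        paired = sum(r["n_paired"] for r in fractions)
        expected = 1.0 - cfg.ortholog_missing_rate
        assert abs(paired / total - expected) < 0.15
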