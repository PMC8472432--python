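"""Alignment, distance models, NJ (vs exhaustive least-squares oracle),
Robinson-Foulds (vs split enumeration), bootstrap, identity matrices."""
import itertools
import math

import numpy as np
import pytest

from tesurvey.phylo import (DistanceMatrix, align_proteins, bootstrap_support,
                            distance_matrix, identity_matrix,
                            neighbor_joining, robinson_foulds, tree_splits)

# ---------------------------------------------------------------------------
# Oracle: exhaustive unrooted topologies + ordinary least-squares fit
# ---------------------------------------------------------------------------


def _all_topologies(labels):
    """All unrooted binary topologies as adjacency dicts (leaves = labels)."""
    base = {0: {labels[0], labels[1], labels[2]},
            labels[0]: {0}, labels[1]: {0}, labels[2]: {0}}
    trees = [base]
    next_internal = 1
    for leaf in labels[3:]:
        grown = []
        for tree in trees:
            edges = {frozenset((u, v)) for u in tree for v in tree[u]}
            for edge in edges:
                u, v = tuple(edge)
                new = {k: set(vs) for k, vs in tree.items()}
                w = next_internal
                new[u].discard(v)
                new[v].discard(u)
                new[w] = {u, v, leaf}
                new[u].add(w)
                new[v].add(w)
                new[leaf] = {w}
                grown.append(new)
        next_internal += 1
        trees = grown
    return trees


def _paths(tree, labels):
    """Leaf-pair -> list of edges (frozensets) on the connecting path."""
    out = {}
    for a, b in itertools.combinations(labels, 2):
        # BFS
        prev = {a: None}
        queue = [a]
        while queue:
            x = queue.pop(0)
            if x == b:
                break
            for y in tree[x]:
                if y not in prev:
                    prev[y] = x
                    queue.append(y)
        path = []
        x = b
        while prev[x] is not None:
            path.append(frozenset((x, prev[x])))
            x = prev[x]
        out[(a, b)] = path
    return out


def _ls_fit_sse(tree, labels, D):
    """Ordinary least-squares branch fit; returns the SSE."""
    edges = sorted({frozenset((u, v)) for u in tree for v in tree[u]},
                   key=lambda e: sorted(map(str, e)))
    eidx = {e: i for i, e in enumerate(edges)}
    paths = _paths(tree, labels)
    pairs = list(itertools.combinations(labels, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        for e in paths[(a, b)]:
            A[r, eidx[e]] = 1.0
        y[r] = D[labels.index(a), labels.index(b)]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ x - y) ** 2).sum())


def _topology_splits(tree, labels):
    """Non-trivial splits of an adjacency-dict topology (anchored)."""
    anchor = sorted(labels)[0]
    full = frozenset(labels)
    splits = set()
    for u in tree:
        for v in tree[u]:
            # component of v when edge (u, v) removed
            seen = {u, v}
            stack = [v]
            comp = set()
            while stack:
                x = stack.pop()
                if isinstance(x, str):
                    comp.add(x)
                for y in tree[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            side = frozenset(comp)
            if 2 <= len(side) <= len(labels) - 2:
                if anchor in side:
                    side = full - side
                splits.add(side)
    return splits


def _random_additive(labels, seed):
    """A random topology with random branch lengths and its distance
    matrix (additive by construction)."""
    rng = np.random.default_rng(seed)
    trees = _all_topologies(labels)
    tree = trees[rng.integers(len(trees))]
    edges = {frozenset((u, v)) for u in tree for v in tree[u]}
    lengths = {e: rng.uniform(0.05, 1.0) for e in edges}
    paths = _paths(tree, labels)
    n = len(labels)
    D = np.zeros((n, n))
    for (a, b), path in paths.items():
        d = sum(lengths[e] for e in path)
        i, j = labels.index(a), labels.index(b)
        D[i, j] = D[j, i] = d
    return tree, D


class TestNeighborJoining:
    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_recovers_additive_topologies_vs_ls_oracle(self, n):
        labels = [chr(65 + i) for i in range(n)]
        for seed in range(10):
            topo, D = _random_additive(labels, 1000 * n + seed)
            nj = neighbor_joining(DistanceMatrix(labels, D, "p"))
            nj_splits = tree_splits(nj.newick)
            # oracle: best least-squares topology over ALL topologies
            best = min(_all_topologies(labels),
                       key=lambda t: _ls_fit_sse(t, labels, D))
            assert _ls_fit_sse(best, labels, D) < 1e-18
            assert nj_splits == _topology_splits(best, labels)
            assert nj_splits == _topology_splits(topo, labels)

    def test_label_permutation_invariance(self):
        labels = list("ABCDE")
        _topo, D = _random_additive(labels, 99)
        t1 = neighbor_joining(DistanceMatrix(labels, D, "p"))
        perm = [3, 1, 4, 0, 2]
        t2 = neighbor_joining(DistanceMatrix(
            [labels[i] for i in perm], D[np.ix_(perm, perm)], "p"))
        assert robinson_foulds(t1, t2) == 0

    def test_requires_three_labels(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"],
                                            np.zeros((2, 2)), "p"))

    def test_negative_branches_clamped(self):
        # a strongly non-additive matrix can produce negative estimates
        D = np.array([[0, 1, 4, 4], [1, 0, 4, 4],
                      [4, 4, 0, 0.1], [4, 4, 0.1, 0]], float)
        t = neighbor_joining(DistanceMatrix(list("ABCD"), D, "p"))
        assert ":-" not in t.newick


class TestRobinsonFoulds:
    def test_identical_trees(self):
        assert robinson_foulds("((A,B),(C,D));", "((A,B),(C,D));") == 0

    def test_swapped_quartet_is_two(self):
        # oracle by split enumeration: {AB} vs {AC} differ -> 2
        a, b = "((A,B),(C,D));", "((A,C),(B,D));"
        sa, sb = tree_splits(a), tree_splits(b)
        assert len(sa ^ sb) == 2
        assert robinson_foulds(a, b) == 2

    def test_agrees_with_split_enumeration_on_random_trees(self):
        labels = list("ABCDEF")
        for seed in range(5):
            t1, _ = _random_additive(labels, 7000 + seed)
            t2, _ = _random_additive(labels, 8000 + seed)
            nw1 = _adjacency_to_newick(t1, labels)
            nw2 = _adjacency_to_newick(t2, labels)
            expected = len(_topology_splits(t1, labels)
                           ^ _topology_splits(t2, labels))
            assert robinson_foulds(nw1, nw2) == expected

    def test_bounded_by_2n_minus_6(self):
        labels = list("ABCDEF")
        for seed in range(5):
            t1, _ = _random_additive(labels, 1 + seed)
            t2, _ = _random_additive(labels, 100 + seed)
            rf = robinson_foulds(_adjacency_to_newick(t1, labels),
                                 _adjacency_to_newick(t2, labels))
            assert 0 <= rf <= 2 * (len(labels) - 3)

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            robinson_foulds("((A,B),(C,D));", "((A,B),(C,E));")


def _adjacency_to_newick(tree, labels):
    start = next(k for k in tree if not isinstance(k, str))

    def walk(node, parent):
        if isinstance(node, str):
            return node
        parts = [walk(c, node) for c in tree[node] if c != parent]
        return "(" + ",".join(parts) + ")"

    return walk(start, None) + ";"


class TestDistanceModels:
    def test_p_distance_direct_count(self):
        dm = distance_matrix([("a", "AAAA"), ("b", "AATT")], model="p")
        assert dm.get("a", "b") == pytest.approx(0.5)

    def test_identical_pair_zero_under_every_model(self):
        for model in ("p", "k2p", "poisson"):
            dm = distance_matrix([("a", "ACGT" * 5), ("b", "ACGT" * 5)],
                                 model=model)
            assert dm.get("a", "b") == 0.0

    def test_k2p_matches_census_kimura2p(self):
        from tesurvey.census import kimura2p
        a, b = "ACGTACGTACGTAAAA", "ACGTACGTACGTGGGA"
        dm = distance_matrix([("x", a), ("y", b)], model="k2p")
        assert dm.get("x", "y") == pytest.approx(kimura2p(a, b).k)

    def test_poisson_correction(self):
        dm = distance_matrix([("a", "AAAA"), ("b", "AATT")],
                             model="poisson")
        assert dm.get("a", "b") == pytest.approx(-math.log(0.5))

    def test_saturated_pair_flagged(self):
        dm = distance_matrix([("a", "AAAA"), ("b", "TTTT")], model="poisson")
        assert (0, 1) in dm.saturated


class TestAlignProteins:
    def test_identical_sequences_align_gap_free(self):
        aln = align_proteins([("a", "MKVLITGAW"), ("b", "MKVLITGAW")])
        assert all("-" not in s for _n, s in aln)

    def test_single_insertion_gives_single_gap(self):
        aln = dict(align_proteins([("a", "MKVLQITGAW"), ("b", "MKVLITGAW")]))
        assert aln["b"].count("-") == 1
        assert len(aln["a"]) == len(aln["b"]) == 10

    def test_column_count_at_least_longest_input(self):
        seqs_in = [("a", "MKVLITGAWQQ"), ("b", "MKVLGAW"), ("c", "MKVITGAW")]
        aln = align_proteins(seqs_in)
        assert len(aln[0][1]) >= max(len(s) for _n, s in seqs_in)

    def test_single_sequence_passthrough(self):
        assert align_proteins([("a", "MKV")]) == [("a", "MKV")]


class TestBootstrap:
    def _alignment(self):
        return [("a", "ACGTACGTACGTACGTCCCCC"),
                ("b", "ACGTACGTACGTACGTCCCCA"),
                ("c", "TTTTACGAACGAACGTAGGGA"),
                ("d", "TTTAACGAACGAACGTAGGGA")]

    def test_saturated_groups_get_full_support(self):
        tree = bootstrap_support(self._alignment(), n_reps=50, seed=1,
                                 model="p")
        assert tree.supports
        assert all(v == 100.0 for v in tree.supports.values())

    def test_supports_within_0_100(self):
        rng = np.random.default_rng(3)
        from tesurvey import seqs as sq
        rows = [(l, sq.random_seq(60, 0.5, rng)) for l in "abcde"]
        tree = bootstrap_support(rows, n_reps=30, seed=2, model="p")
        assert all(0.0 <= v <= 100.0 for v in tree.supports.values())

    def test_deterministic_for_fixed_seed(self):
        t1 = bootstrap_support(self._alignment(), n_reps=40, seed=9)
        t2 = bootstrap_support(self._alignment(), n_reps=40, seed=9)
        assert t1.supports == t2.supports


class TestIdentityMatrix:
    def test_identical_sequences_100(self):
        labels, mat, mean, sd = identity_matrix(
            [("a", "ACGT" * 10), ("b", "ACGT" * 10)])
        assert mean == pytest.approx(100.0) and sd == 0.0

    def test_symmetric_with_diagonal_100(self):
        labels, mat, _m, _s = identity_matrix(
            [("a", "ACGTACGTAC"), ("b", "ACGTACGTTT"), ("c", "AAAAACGTAC")])
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 100.0)

    def test_simulated_cluster_identity_tracks_divergence(self):
        from tesurvey import seqs as sq
        rng = np.random.default_rng(11)
        root = sq.seq_to_codes(sq.random_seq(2000, 0.4, rng))
        members = [("m%d" % i, sq.codes_to_seq(
            sq.mutate_k2p_exact(root, 0.02, rng))) for i in range(4)]
        _l, _m, mean, _s = identity_matrix(members)
        assert mean > 95.0
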