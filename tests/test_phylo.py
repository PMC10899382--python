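import itertools
import math

import numpy as np
import pytest

from arseq.phylo import (
    DistanceMatrix,
    MsaView,
    NoOverlapError,
    distance_matrix,
    nj_tree,
    pairwise_p_distance,
    poisson_correct,
)


def splits(tree):
    """Non-trivial bipartitions (as frozensets of the smaller... both sides)."""
    all_leaves = frozenset(tree.ids)
    out = set()

    def collect(node):
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            sub = collect(child)
            if 1 < len(sub) < len(all_leaves) - 1:
                out.add(frozenset([sub, all_leaves - sub]))
            below |= sub
        return below

    collect(tree.root)
    return out


class TestPDistance:
    def test_identical_sequences(self):
        msa = MsaView(ids=["a", "b"], rows=["ACDEF", "ACDEF"])
        p, n = pairwise_p_distance(msa)
        assert p[0, 1] == 0.0 and n[0, 1] == 5

    def test_one_in_five(self):
        msa = MsaView(ids=["a", "b"], rows=["ACDEF", "ACDEY"])
        p, n = pairwise_p_distance(msa)
        assert p[0, 1] == pytest.approx(0.2) and n[0, 1] == 5

    def test_pairwise_deletion_gap(self):
        msa = MsaView(ids=["a", "b"], rows=["AC-EF", "ACDEF"])
        p, n = pairwise_p_distance(msa)
        assert n[0, 1] == 4 and p[0, 1] == 0.0

    def test_pairwise_deletion_is_per_pair(self):
        # the gap in c removes a column for pairs with c only
        msa = MsaView(ids=["a", "b", "c"], rows=["ACDEF", "ACDEY", "AC-EF"])
        p, n = pairwise_p_distance(msa)
        assert n[0, 1] == 5 and n[0, 2] == 4 and n[1, 2] == 4
        assert p[1, 2] == pytest.approx(0.25)  # Y vs F over 4 sites

    def test_ambiguous_x_removed(self):
        msa = MsaView(ids=["a", "b"], rows=["AXDEF", "ACDEF"])
        _, n = pairwise_p_distance(msa)
        assert n[0, 1] == 4

    def test_no_overlap_raises(self):
        msa = MsaView(ids=["a", "b"], rows=["AC---", "--DEF"])
        with pytest.raises(NoOverlapError):
            pairwise_p_distance(msa)


class TestPoisson:
    @pytest.mark.parametrize("p,d", [(0.0, 0.0), (0.5, math.log(2)),
                                     (0.1, 0.10536051565782628)])
    def test_closed_form(self, p, d):
        assert poisson_correct(p) == pytest.approx(d, abs=1e-12)

    def test_rejects_p_ge_one(self):
        with pytest.raises(ValueError):
            poisson_correct(1.0)

    def test_monotone_and_dominates_identity(self):
        ps = np.linspace(0, 0.95, 50)
        ds = poisson_correct(ps)
        assert np.all(np.diff(ds) > 0)
        assert np.all(ds >= ps)


def _random_additive(rng, n_leaves):
    """Random binary unrooted tree as (edges, leaf ids) plus its path matrix."""
    # grow by attaching each new leaf to a random existing edge
    ids = [f"t{i}" for i in range(n_leaves)]
    # adjacency with branch lengths; nodes 0..2 start as a star around node -1
    next_node = n_leaves
    adj = {i: {} for i in range(3)}
    center = next_node
    next_node += 1
    adj[center] = {}
    for i in range(3):
        w = rng.uniform(0.1, 1.0)
        adj[i][center] = w
        adj[center][i] = w
    for leaf in range(3, n_leaves):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(0, len(edges))]
        w = adj[u][v]
        mid = next_node; next_node += 1
        cut = rng.uniform(0.2, 0.8) * w
        del adj[u][v]; del adj[v][u]
        adj.setdefault(mid, {})
        adj[u][mid] = adj[mid][u] = cut
        adj[v][mid] = adj[mid][v] = w - cut
        wl = rng.uniform(0.1, 1.0)
        adj.setdefault(leaf, {})
        adj[leaf][mid] = adj[mid][leaf] = wl
    # all-pairs leaf path lengths by BFS
    import heapq

    def dists(src):
        d = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            dist, u = heapq.heappop(heap)
            if dist > d.get(u, np.inf):
                continue
            for v, w in adj[u].items():
                nd = dist + w
                if nd < d.get(v, np.inf):
                    d[v] = nd
                    heapq.heappush(heap, (nd, v))
        return d

    m = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        di = dists(i)
        for j in range(n_leaves):
            m[i, j] = di[j]
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(ids=ids, matrix=(m + m.T) / 2)


class TestNj:
    def test_four_taxon_additive_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): path lengths below
        ids = ["A", "B", "C", "D"]
        m = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        dm = DistanceMatrix(ids=ids, matrix=m)
        tree = nj_tree(dm)
        assert frozenset([frozenset("AB"), frozenset("CD")]) in splits(tree)
        paths = tree.leaf_path_lengths()
        for (i, j) in itertools.combinations(range(4), 2):
            key = tuple(sorted((ids[i], ids[j])))
            assert paths[key] == pytest.approx(m[i, j], abs=1e-9)

    def test_three_taxon_closed_form(self):
        m = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids=["i", "j", "k"], matrix=m))
        bl = {c.name: l for c, l in tree.root.children}
        assert bl["i"] == pytest.approx((2 + 3 - 5) / 2)
        assert bl["j"] == pytest.approx((2 + 5 - 3) / 2)
        assert bl["k"] == pytest.approx((3 + 5 - 2) / 2)

    def test_equidistant_matrix_zero_internal_branches(self):
        n = 5
        m = np.full((n, n), 2.0)
        np.fill_diagonal(m, 0.0)
        tree = nj_tree(DistanceMatrix(ids=list("abcde"), matrix=m))

        def internal_lengths(node):
            out = []
            for child, bl in node.children:
                if not child.is_leaf():
                    out.append(bl)
                    out.extend(internal_lengths(child))
            return out

        assert all(bl == pytest.approx(0.0, abs=1e-12)
                   for bl in internal_lengths(tree.root))

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_additive_recovery_random_trees(self, n_leaves):
        """NJ is exact on additive matrices: all path lengths reproduced."""
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(4):
            dm = _random_additive(rng, n_leaves)
            tree = nj_tree(dm)
            paths = tree.leaf_path_lengths()
            for i, j in itertools.combinations(range(n_leaves), 2):
                key = tuple(sorted((dm.ids[i], dm.ids[j])))
                assert paths[key] == pytest.approx(dm.matrix[i, j], abs=1e-9)

    def test_exhaustive_least_squares_oracle_n5(self):
        """NJ topology = least-squares-best of all 15 unrooted 5-leaf topologies."""
        rng = np.random.default_rng(200)
        dm = _random_additive(rng, 5)
        tree = nj_tree(dm)
        nj_splits = splits(tree)

        ids = dm.ids
        pair_idx = list(itertools.combinations(range(5), 2))

        best = (np.inf, None)
        # enumerate topologies: insert taxa 3,4 on every edge of the grown tree
        for e1 in range(3):
            for e2 in range(5):
                topo = _build_topology(e1, e2)
                sse, topo_splits = _ls_fit(topo, dm.matrix, pair_idx, ids)
                if sse < best[0] - 1e-12:
                    best = (sse, topo_splits)
        assert best[1] == nj_splits

    def test_skbio_cross_check(self):
        """Independent implementation agrees on the induced topology."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(300)
        dm = _random_additive(rng, 6)
        ours = splits(nj_tree(dm))
        sk_dm = skbio.DistanceMatrix(dm.matrix, ids=dm.ids)
        sk_tree = skbio.tree.nj(sk_dm)
        theirs = set()
        for node in sk_tree.non_tips():
            sub = frozenset(t.name for t in node.tips())
            if 1 < len(sub) < 5:
                theirs.add(frozenset([sub, frozenset(dm.ids) - sub]))
        assert ours == theirs


def _build_topology(e1, e2):
    """5-leaf unrooted binary topology: leaf 3 on edge e1 of the 3-star,
    leaf 4 on edge e2 of the resulting tree.  Returns adjacency dict."""
    adj = {0: {4}, 1: {4}, 2: {4}, 4: {0, 1, 2}}  # node 4 = center; leaves 0-2
    next_node = 5

    def edge_list():
        return sorted({tuple(sorted((u, v))) for u in adj for v in adj[u]})

    def insert(leaf, edge_i):
        nonlocal next_node
        u, v = edge_list()[edge_i]
        mid = next_node; next_node += 1
        adj[u].remove(v); adj[v].remove(u)
        adj[u].add(mid); adj[v].add(mid)
        adj[mid] = {u, v, leaf}
        adj[leaf] = {mid}

    insert(3, e1)
    insert(10, e2)  # taxon index 4 stored as node 10 (4 is the center)
    return adj


def _ls_fit(adj, matrix, pair_idx, ids):
    """Least-squares branch lengths for a fixed topology; returns (SSE, splits)."""
    leaf_node = {0: 0, 1: 1, 2: 2, 3: 3, 4: 10}
    edges = sorted({tuple(sorted((u, v))) for u in adj for v in adj[u]})

    def path(a, b):
        # DFS path between nodes
        stack = [(a, [a])]
        seen = {a}
        while stack:
            u, p = stack.pop()
            if u == b:
                return p
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append((v, p + [v]))
        raise AssertionError

    rows, y = [], []
    for i, j in pair_idx:
        p = path(leaf_node[i], leaf_node[j])
        on_path = {tuple(sorted((p[k], p[k + 1]))) for k in range(len(p) - 1)}
        rows.append([1.0 if e in on_path else 0.0 for e in edges])
        y.append(matrix[i, j])
    A = np.array(rows)
    b, res, *_ = np.linalg.lstsq(A, np.array(y), rcond=None)
    sse = float(np.sum((A @ b - np.array(y)) ** 2))

    # splits induced by internal edges
    all_leaves = frozenset(ids)
    out = set()
    for u, v in edges:
        if u in leaf_node.values() or v in leaf_node.values():
            continue
        # leaves on u's side when edge (u,v) removed
        stack, seen = [u], {u, v}
        side = set()
        while stack:
            x = stack.pop()
            for w in adj[x]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
            for li, ln in leaf_node.items():
                if ln == x:
                    side.add(ids[li])
        sub = frozenset(side)
        if 1 < len(sub) < len(all_leaves) - 1:
            out.add(frozenset([sub, all_leaves - sub]))
    return sse, out


def test_distance_matrix_pipeline():
    """MSA -> pairwise deletion -> Poisson correction, end to end."""
    msa = MsaView(ids=["a", "b", "c"],
                  rows=["ACDEFGHIKL", "ACDEFGHIKV", "ACDEY-HIKV"])
    dm = distance_matrix(msa)
    assert dm.matrix[0, 1] == pytest.approx(-math.log(1 - 0.1))
    # a vs c: gap column removed -> 9 sites, 2 differences
    assert dm.matrix[0, 2] == pytest.approx(-math.log(1 - 2 / 9))
    tree = nj_tree(dm)
    assert sorted(l for l in tree.ids) == ["a", "b", "c"]
    assert tree.newick().endswith(";")
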