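"""Window construction, distances, neighbor joining, newick ingest."""

import itertools

import numpy as np
import pytest

from ancestry_scan import (UnrootedTree, make_windows, neighbor_joining,
                           pairwise_distances, pseudo_haploidize,
                           read_newick_stream, window_passes)
from ancestry_scan.genotype_matrix import MISSING, HaplotypeMatrix
from ancestry_scan.window_forest import DegenerateWindowError, WindowSpec


def make_hm(alleles, positions=None):
    alleles = np.asarray(alleles, dtype=np.int16)
    n_sites, n_tips = alleles.shape
    if positions is None:
        positions = 10 * (1 + np.arange(n_sites))
    tips = [f"t{i}" for i in range(n_tips)]
    return HaplotypeMatrix("scaf1", np.asarray(positions, dtype=np.int64),
                           tips, alleles, {t: t for t in tips}, seed=0)


def normalized_splits(tree, leaves):
    """Orient each non-trivial split away from the first leaf for comparison."""
    out = set()
    for side in tree.splits:
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(frozenset(leaves) - side if leaves[0] in side
                    else frozenset(side))
    return out


def path_distance_matrix(adjacency: dict, leaves: list[str]) -> np.ndarray:
    """Independent oracle: all-pairs path lengths on a weighted tree."""
    import heapq

    def dist(a, b):
        best = {a: 0.0}
        heap = [(0.0, a)]
        while heap:
            d, u = heapq.heappop(heap)
            if u == b:
                return d
            for v, w in adjacency[u]:
                nd = d + w
                if nd < best.get(v, np.inf):
                    best[v] = nd
                    heapq.heappush(heap, (nd, v))
        raise KeyError(b)

    dm = np.array([[dist(a, b) for b in leaves] for a in leaves])
    return (dm + dm.T) / 2  # exact symmetry despite float summation order


SIX_TIP_TREE = {
    # ((A,B),(C,D),(E,F)) with distinct branch lengths
    "A": [("x", 1.0)], "B": [("x", 2.0)],
    "C": [("y", 1.5)], "D": [("y", 0.5)],
    "E": [("z", 3.0)], "F": [("z", 1.0)],
    "x": [("A", 1.0), ("B", 2.0), ("c", 1.0)],
    "y": [("C", 1.5), ("D", 0.5), ("c", 2.0)],
    "z": [("E", 3.0), ("F", 1.0), ("c", 0.7)],
    "c": [("x", 1.0), ("y", 2.0), ("z", 0.7)],
}


class TestMakeWindows:
    @pytest.mark.parametrize("n_sites,expected_starts", [
        (100, [0]),
        (175, [0, 25, 50, 75]),
        (99, []),
    ])
    def test_window_starts(self, n_sites, expected_starts):
        pos = 10 * (1 + np.arange(n_sites))
        ws = make_windows(pos, "s", size=100, step=25)
        assert [w.snp_index_start for w in ws] == expected_starts

    def test_windows_are_full_size_with_fixed_overlap(self):
        pos = np.arange(1, 1001)
        ws = make_windows(pos, "s", size=100, step=25)
        assert all(w.snp_index_end - w.snp_index_start == 100 for w in ws)
        for a, b in zip(ws, ws[1:]):
            assert a.snp_index_end - b.snp_index_start == 75

    def test_genomic_bounds_are_first_and_last_snp(self):
        pos = 7 * (1 + np.arange(130))
        w = make_windows(pos, "s")[0]
        assert (w.genomic_start, w.genomic_end) == (7, 7 * 100)

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            make_windows(np.arange(1, 200), "s", size=100, step=0)


class TestWindowPasses:
    def test_complete_window_passes(self):
        hm = make_hm(np.zeros((100, 5)))
        w = make_windows(hm.positions, "scaf1")[0]
        assert window_passes(hm, w)

    def test_sample_with_29_calls_fails(self):
        a = np.zeros((100, 5))
        a[:71, 2] = MISSING  # 29 non-missing calls for tip 2
        hm = make_hm(a)
        w = make_windows(hm.positions, "scaf1")[0]
        assert not window_passes(hm, w)
        a[70, 2] = 0  # 30th call
        assert window_passes(make_hm(a), w)

    def test_zero_threshold_always_passes(self):
        hm = make_hm(np.full((100, 4), MISSING))
        w = make_windows(hm.positions, "scaf1")[0]
        assert window_passes(hm, w, min_snps_per_sample=0)


class TestPairwiseDistances:
    def test_identical_tips_have_zero_distance(self):
        hm = make_hm(np.ones((50, 3)))
        dm, _ = pairwise_distances(hm, WindowSpec("scaf1", 0, 50, 1, 50))
        assert (dm == 0).all()

    def test_hand_counted_proportion(self):
        a = np.zeros((100, 2))
        a[:10, 1] = 1  # 10 differences over 100 comparable sites
        dm, _ = pairwise_distances(make_hm(a), WindowSpec("scaf1", 0, 100, 1, 100))
        assert dm[0, 1] == pytest.approx(0.10)

    def test_missing_excluded_pairwise(self):
        a = np.zeros((100, 2))
        a[:50, 0] = MISSING      # 50 comparable sites remain
        a[50:52, 1] = 1          # 2 differences among them
        dm, _ = pairwise_distances(make_hm(a), WindowSpec("scaf1", 0, 100, 1, 100))
        assert dm[0, 1] == pytest.approx(2 / 50)

    def test_zero_comparable_sites_is_degenerate(self):
        a = np.zeros((10, 2))
        a[:5, 0] = MISSING
        a[5:, 1] = MISSING
        with pytest.raises(DegenerateWindowError):
            pairwise_distances(make_hm(a), WindowSpec("scaf1", 0, 10, 1, 10))


class TestNeighborJoining:
    def test_recovers_additive_six_tip_topology(self):
        tips = list("ABCDEF")
        dm = path_distance_matrix(SIX_TIP_TREE, tips)
        tree = neighbor_joining(dm, tips)
        assert normalized_splits(tree, tips) == {
            frozenset("CD"), frozenset("EF"), frozenset("CDEF")}

    def test_four_tip_topology_matches_four_point_oracle(self):
        tips = list("ABCD")
        dm = np.array([[0, 0.02, 0.2, 0.2],
                       [0.02, 0, 0.2, 0.2],
                       [0.2, 0.2, 0, 0.02],
                       [0.2, 0.2, 0.02, 0]])
        # four-point condition: true split pairs the two tips whose
        # within-pair sums are smallest
        sums = {("AB", "CD"): dm[0, 1] + dm[2, 3],
                ("AC", "BD"): dm[0, 2] + dm[1, 3],
                ("AD", "BC"): dm[0, 3] + dm[1, 2]}
        best = min(sums, key=sums.get)
        assert best == ("AB", "CD")
        tree = neighbor_joining(dm, tips)
        assert frozenset("AB") in {frozenset(s) for s in tree.splits} or \
               frozenset("CD") in {frozenset(s) for s in tree.splits}

    def test_uniform_distances_join_lowest_index_pair_first(self):
        tips = list("ABCDE")
        dm = np.full((5, 5), 0.3)
        np.fill_diagonal(dm, 0)
        tree = neighbor_joining(dm, tips)
        assert frozenset("AB") in {frozenset(s) for s in tree.splits}

    def test_topology_invariant_to_tip_input_order(self):
        tips = list("ABCDEF")
        dm = path_distance_matrix(SIX_TIP_TREE, tips)
        ref = {frozenset(s) for s in neighbor_joining(dm, tips).splits}
        rng = np.random.default_rng(4)
        for _ in range(5):
            perm = rng.permutation(6)
            tree = neighbor_joining(dm[np.ix_(perm, perm)],
                                    [tips[i] for i in perm])
            assert {frozenset(s) for s in tree.splits} == ref

    def test_matches_scikit_bio_on_random_additive_matrices(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        for _ in range(5):
            adj, leaves = random_additive_tree(rng, n_leaves=7)
            dm = path_distance_matrix(adj, leaves)
            ours = {frozenset(s) for s in neighbor_joining(dm, leaves).splits}
            sk = skbio_nj(DistanceMatrix(dm, leaves))
            theirs = set()
            for node in sk.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= len(leaves) - 2:
                    theirs.add(side if leaves[0] not in side
                               else frozenset(leaves) - side)
            ours = {s if leaves[0] not in s else frozenset(leaves) - s
                    for s in ours if 2 <= len(s) <= len(leaves) - 2}
            assert ours == theirs

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["a", "b"])

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(6)
        d = rng.random((8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = neighbor_joining(d, [f"t{i}" for i in range(8)])
        newick = tree.to_newick()
        assert ":-" not in newick


def random_additive_tree(rng, n_leaves):
    """Random binary unrooted tree with positive branch lengths."""
    leaves = [f"L{i}" for i in range(n_leaves)]
    adj = {leaves[0]: [], leaves[1]: [], leaves[2]: [], "i0": []}
    for leaf in leaves[:3]:
        w = float(rng.uniform(0.5, 2.0))
        adj[leaf].append(("i0", w))
        adj["i0"].append((leaf, w))
    next_internal = 1
    for leaf in leaves[3:]:
        edges = [(u, v) for u in adj for v, _ in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w_uv = next(w for x, w in adj[u] if x == v)
        mid = f"i{next_internal}"
        next_internal += 1
        adj[u] = [(x, w) for x, w in adj[u] if x != v] + [(mid, w_uv / 2)]
        adj[v] = [(x, w) for x, w in adj[v] if x != u] + [(mid, w_uv / 2)]
        w_leaf = float(rng.uniform(0.5, 2.0))
        adj[mid] = [(u, w_uv / 2), (v, w_uv / 2), (leaf, w_leaf)]
        adj[leaf] = [(mid, w_leaf)]
    return adj, leaves


class TestNewickIngest:
    def test_reads_one_tree_per_window(self, tmp_path):
        trees = ["((t0,t1),(t2,t3));"] * 4
        path = tmp_path / "trees.nwk"
        path.write_text("\n".join(trees) + "\n")
        windows = [WindowSpec("s", i * 25, i * 25 + 100, 1, 100) for i in range(4)]
        out = read_newick_stream(path, windows)
        assert len(out) == 4 and all(len(t) == 4 for t in out)

    def test_unknown_tip_label_named_in_error(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("((t0,t1),(t2,BAD));\n")
        with pytest.raises(ValueError, match="BAD"):
            read_newick_stream(path, [WindowSpec("s", 0, 100, 1, 100)],
                               expected_tips={"t0", "t1", "t2", "t3"})

    def test_polytomy_rejected_with_window_index(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("((t0,t1),(t2,t3));\n(t0,t1,t2,t3);\n")
        windows = [WindowSpec("s", 0, 100, 1, 100),
                   WindowSpec("s", 25, 125, 1, 100)]
        with pytest.raises(ValueError, match="window 1"):
            read_newick_stream(path, windows)

    def test_count_mismatch_rejected(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("((t0,t1),(t2,t3));\n")
        with pytest.raises(ValueError, match="expected 2"):
            read_newick_stream(path, [WindowSpec("s", 0, 100, 1, 100)] * 2)
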