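"""Topology enumeration, canonicalization, and topology weighting.

Topology weighting decomposes a tree with multiple tips per taxon group into
the proportions of single-tip-per-group unrooted topologies induced by
sampling one tip from each group.  With six groups there are
(2*6-5)!! = 105 possible unrooted binary shapes; the shared-ancestry scan
sums the weight of the five shapes in which a focal pair of non-sister
groups is monophyletic while the remaining four groups follow the species
tree.

Weights can be computed exactly, by enumerating every tip combination, or by
Monte-Carlo sampling with a Wilson-interval stopping rule for large trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from statsmodels.stats.proportion import proportion_confint


class Topology:
    """An unrooted, binary, leaf-labeled tree shape with order-invariant identity.

    Two topologies are equal iff they have the same leaf labels and the same
    set of non-trivial bipartitions (splits).  ``canonical_id`` is a newick
    string rooted on the pendant edge of the smallest label, with children
    recursively sorted, so it is invariant to tip input order and branch
    rotations.
    """

    __slots__ = ("_adj", "_leaf_label", "labels", "_splits", "_id", "_hash")

    def __init__(self, adj: dict[int, tuple[int, ...]], leaf_label: dict[int, str]):
        self._adj = adj
        self._leaf_label = leaf_label
        self.labels: tuple[str, ...] = tuple(sorted(leaf_label.values()))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate leaf labels")
        self._splits: frozenset[frozenset[str]] | None = None
        self._id: str | None = None
        self._hash: int | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Topology":
        """Parse a newick string (branch lengths ignored) into a Topology."""
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        tree.deroot()
        adj: dict[int, list[int]] = {}
        leaf_label: dict[int, str] = {}
        ids: dict[object, int] = {}

        def nid(node) -> int:
            if node not in ids:
                ids[node] = len(ids)
                adj[ids[node]] = []
            return ids[node]

        for edge in tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            u, v = nid(edge.tail_node), nid(edge.head_node)
            adj[u].append(v)
            adj[v].append(u)
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else None
            if not label:
                raise ValueError("unlabeled leaf in newick")
            leaf_label[nid(leaf)] = label
        topo = cls({k: tuple(v) for k, v in adj.items()}, leaf_label)
        for node, nbrs in topo._adj.items():
            deg = len(nbrs)
            if node in leaf_label:
                if deg != 1:
                    raise ValueError("leaf with degree != 1")
            elif deg != 3:
                raise ValueError("topology is not strictly binary (polytomy or unifurcation)")
        return topo

    # -- identity ---------------------------------------------------------

    @property
    def ref_label(self) -> str:
        return self.labels[0]

    def _leaves_beyond(self, u: int, v: int) -> frozenset[str]:
        """Labels reachable from v when the edge (u, v) is cut."""
        seen = {u, v}
        stack = [v]
        out = []
        while stack:
            n = stack.pop()
            if n in self._leaf_label:
                out.append(self._leaf_label[n])
            for nb in self._adj[n]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return frozenset(out)

    def _canonical_side(self, side: frozenset[str]) -> frozenset[str]:
        return frozenset(self.labels) - side if self.ref_label in side else side

    @property
    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, each as the side excluding the smallest label."""
        if self._splits is None:
            k = len(self.labels)
            sides = set()
            for u in self._adj:
                if u in self._leaf_label:
                    continue
                for v in self._adj[u]:
                    if v in self._leaf_label:
                        continue
                    side = self._leaves_beyond(u, v)
                    if 2 <= len(side) <= k - 2:
                        sides.add(self._canonical_side(side))
            self._splits = frozenset(sides)
        return self._splits

    def branch_sides(self) -> list[frozenset[str]]:
        """One label-set per edge (pendant edges included): the side away from
        the smallest label.  Used by the simulator to place mutations."""
        out = []
        seen_edges = set()
        for u in self._adj:
            for v in self._adj[u]:
                e = (min(u, v), max(u, v))
                if e in seen_edges:
                    continue
                seen_edges.add(e)
                side = self._leaves_beyond(u, v)
                out.append(self._canonical_side(side) if self.ref_label in side
                           else side)
        return out

    @property
    def canonical_id(self) -> str:
        if self._id is None:
            root_leaf = next(n for n, lab in self._leaf_label.items()
                             if lab == self.ref_label)
            start = self._adj[root_leaf][0]

            def canon(node: int, parent: int) -> str:
                if node in self._leaf_label:
                    return self._leaf_label[node]
                parts = sorted(canon(nb, node) for nb in self._adj[node]
                               if nb != parent)
                return "(" + ",".join(parts) + ")"

            self._id = f"({self.ref_label},{canon(start, root_leaf)});"
        return self._id

    def to_newick(self) -> str:
        return self.canonical_id

    def __eq__(self, other) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return self.labels == other.labels and self.splits == other.splits

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash((self.labels, self.splits))
        return self._hash

    def __repr__(self) -> str:
        return f"Topology({self.canonical_id!r})"

    # -- queries ----------------------------------------------------------

    def has_cherry(self, a: str, b: str) -> bool:
        """True iff tips a and b attach to the same internal vertex."""
        return self._canonical_side(frozenset((a, b))) in self.splits

    def restrict(self, sub_labels) -> "Topology":
        """The topology induced on a subset of >= 4 leaves."""
        sub = frozenset(sub_labels)
        if not sub <= set(self.labels) or len(sub) < 4:
            raise ValueError("restriction requires >= 4 labels present in the topology")
        k = len(sub)
        ref = min(sub)
        restricted = set()
        for side in self.splits:
            a = side & sub
            if ref in a:
                a = sub - a
            if 2 <= len(a) <= k - 2:
                restricted.add(a)
        # pendant-derived splits never become non-trivial, so the restricted
        # split set fully determines the induced binary topology
        return topology_from_splits(tuple(sorted(sub)), frozenset(restricted))


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


@lru_cache(maxsize=None)
def enumerate_topologies(group_labels: tuple[str, ...]) -> tuple[Topology, ...]:
    """All (2k-5)!! unrooted binary topologies over k >= 4 labels.

    Generated by sequential leaf insertion onto every edge; the returned
    order is deterministic (sorted by canonical id).
    """
    labels = tuple(sorted(group_labels))
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")
    k = len(labels)
    if k < 4:
        raise ValueError("need at least 4 groups for informative unrooted shapes")

    # seed: the unique shape on the first three labels (one internal vertex)
    trees: list[tuple[dict[int, tuple[int, ...]], dict[int, str]]] = [(
        {0: (3,), 1: (3,), 2: (3,), 3: (0, 1, 2)},
        {0: labels[0], 1: labels[1], 2: labels[2]},
    )]
    for label in labels[3:]:
        nxt = []
        for adj, leaf_label in trees:
            edges = sorted({(min(u, v), max(u, v)) for u in adj for v in adj[u]})
            for u, v in edges:
                new_adj = {n: list(nb) for n, nb in adj.items()}
                mid = max(new_adj) + 1
                leaf = mid + 1
                new_adj[u] = [mid if x == v else x for x in new_adj[u]]
                new_adj[v] = [mid if x == u else x for x in new_adj[v]]
                new_adj[mid] = [u, v, leaf]
                new_adj[leaf] = [mid]
                nxt.append(({n: tuple(nb) for n, nb in new_adj.items()},
                            {**leaf_label, leaf: label}))
        trees = nxt

    topos = [Topology(adj, leaf_label) for adj, leaf_label in trees]
    assert len(topos) == _double_factorial(2 * k - 5)
    return tuple(sorted(topos, key=lambda t: t.canonical_id))


@lru_cache(maxsize=None)
def _splits_index(labels: tuple[str, ...]) -> dict[frozenset, Topology]:
    return {t.splits: t for t in enumerate_topologies(labels)}


def topology_from_splits(labels: tuple[str, ...], splits: frozenset) -> Topology:
    """Look up the unique topology over `labels` with the given split set."""
    try:
        return _splits_index(tuple(sorted(labels)))[splits]
    except KeyError:
        raise ValueError("split set does not define a binary topology on these labels")


def move_leaf(topology: Topology, leaf: str, sister: str) -> Topology:
    """Detach `leaf` and re-attach it as the sister of `sister`.

    Used by the simulator to force a donor/recipient cherry inside
    introgression tracts.
    """
    if leaf == sister or leaf not in topology.labels or sister not in topology.labels:
        raise ValueError("leaf and sister must be distinct labels of the topology")
    adj = {n: list(nb) for n, nb in topology._adj.items()}
    leaf_label = dict(topology._leaf_label)
    lnode = next(n for n, lab in leaf_label.items() if lab == leaf)
    v = adj[lnode][0]
    # remove the leaf and splice out its (now degree-2) attachment vertex
    a, b = (x for x in adj[v] if x != lnode)
    adj[a] = [b if x == v else x for x in adj[a]]
    adj[b] = [a if x == v else x for x in adj[b]]
    del adj[v], adj[lnode]
    # split the sister's pendant edge with a fresh vertex and hang the leaf
    snode = next(n for n, lab in leaf_label.items() if lab == sister)
    u = adj[snode][0]
    mid = max(max(adj), lnode, v) + 1
    new_leaf = mid + 1
    adj[snode] = [mid]
    adj[u] = [mid if x == snode else x for x in adj[u]]
    adj[mid] = [u, snode, new_leaf]
    adj[new_leaf] = [mid]
    del leaf_label[lnode]
    leaf_label[new_leaf] = leaf
    return Topology({n: tuple(nb) for n, nb in adj.items()}, leaf_label)


def shared_ancestry_set(species_tree: Topology, focal_pair: tuple[str, str]) -> list[Topology]:
    """The topologies diagnostic of shared ancestry between a focal pair.

    Given the species topology on the four non-focal groups, these are the
    six-group topologies in which the focal pair forms a cherry and the
    induced topology on the other four groups equals the species tree: one
    per edge of the four-taxon tree (4 pendant + 1 internal = 5 shapes).
    """
    a, b = focal_pair
    if len(species_tree.labels) != 4:
        raise ValueError("species_tree must be on exactly 4 groups")
    if a in species_tree.labels or b in species_tree.labels or a == b:
        raise ValueError("focal pair must be two labels disjoint from the species tree")
    out = []
    adj0 = species_tree._adj
    edges = sorted({(min(u, v), max(u, v)) for u in adj0 for v in adj0[u]})
    for u, v in edges:
        adj = {n: list(nb) for n, nb in adj0.items()}
        mid = max(adj) + 1
        cherry = mid + 1
        la, lb = cherry + 1, cherry + 2
        adj[u] = [mid if x == v else x for x in adj[u]]
        adj[v] = [mid if x == u else x for x in adj[v]]
        adj[mid] = [u, v, cherry]
        adj[cherry] = [mid, la, lb]
        adj[la] = [cherry]
        adj[lb] = [cherry]
        leaf_label = dict(species_tree._leaf_label)
        leaf_label[la] = a
        leaf_label[lb] = b
        out.append(Topology({n: tuple(nb) for n, nb in adj.items()}, leaf_label))
    return sorted(out, key=lambda t: t.canonical_id)


# ---------------------------------------------------------------------------
# weighting


@dataclass
class Weighting:
    """Per-topology weights for one window tree.

    weights maps canonical_id -> proportion over the full topology set for
    the group labels; n_sampled is 0 in exact mode; ci_width holds Wilson
    full interval widths in sampled mode.
    """

    weights: dict[str, float]
    mode: str  # "exact" | "sampled"
    n_sampled: int = 0
    ci_width: dict[str, float] = field(default_factory=dict)
    seed: int | None = None
    converged: bool = True


class _GroupedTree:
    """Precomputed split/group membership structure for fast weighting."""

    def __init__(self, tree, groups: dict[str, list[str]]):
        self.group_labels = tuple(sorted(groups))
        self.k = len(self.group_labels)
        tip_set = set(tree.tip_ids)
        self.group_tips = []
        for g in self.group_labels:
            tips = [t for t in groups[g] if t in tip_set]
            if not tips:
                raise ValueError(f"group {g!r} has no tips present in the tree")
            self.group_tips.append(tips)
        self.sizes = np.array([len(t) for t in self.group_tips])
        splits = tree.splits  # internal-edge tip sets
        # membership[e, g, t]: is the t-th tip of group g on side e?
        maxsz = int(self.sizes.max())
        self.membership = np.zeros((len(splits), self.k, maxsz), dtype=bool)
        for e, side in enumerate(splits):
            for g, tips in enumerate(self.group_tips):
                for t, tip in enumerate(tips):
                    self.membership[e, g, t] = tip in side
        self.full_mask = (1 << self.k) - 1
        self._popcount = np.array([bin(m).count("1")
                                   for m in range(self.full_mask + 1)])
        # canonical split-mask set -> canonical_id
        self._key_to_id = {}
        for topo in enumerate_topologies(self.group_labels):
            key = frozenset(self._side_mask(side) for side in topo.splits)
            self._key_to_id[key] = topo.canonical_id

    def _side_mask(self, side: frozenset[str]) -> int:
        m = 0
        for i, g in enumerate(self.group_labels):
            if g in side:
                m |= 1 << i
        return m

    def topology_ids(self) -> list[str]:
        return [t.canonical_id for t in enumerate_topologies(self.group_labels)]

    def classify(self, combos: np.ndarray) -> list[str]:
        """Canonical id of the induced topology for each row of tip indices."""
        if self.membership.shape[0] == 0:
            raise ValueError("tree has no internal edges; need >= 4 tips")
        E = self.membership.shape[0]
        C = combos.shape[0]
        vals = np.empty((E, C, self.k), dtype=bool)
        for g in range(self.k):
            vals[:, :, g] = self.membership[:, g, combos[:, g]]
        bits = 1 << np.arange(self.k)
        masks = (vals * bits).sum(axis=2)  # (E, C)
        masks = np.where(masks & 1, masks ^ self.full_mask, masks)
        pc = self._popcount[masks]
        ok = (pc >= 2) & (pc <= self.k - 2)
        ids = []
        for c in range(C):
            key = frozenset(masks[ok[:, c], c].tolist())
            ids.append(self._key_to_id[key])
        return ids


def induced_topology(tree, tip_choice: dict[str, str]) -> Topology:
    """Prune the tree to one chosen tip per group and canonicalize the shape.

    tip_choice maps group label -> tip id; the result is a Topology whose
    leaves carry the group labels.
    """
    groups = sorted(tip_choice)
    tips = [tip_choice[g] for g in groups]
    missing = [t for t in tips if t not in set(tree.tip_ids)]
    if missing:
        raise ValueError(f"chosen tips absent from tree: {missing}")
    k = len(groups)
    ref = groups[0]
    chosen = dict(zip(tips, groups))
    sides = set()
    for side in tree.splits:
        a = frozenset(chosen[t] for t in side if t in chosen)
        if ref in a:
            a = frozenset(groups) - a
        if 2 <= len(a) <= k - 2:
            sides.add(a)
    return topology_from_splits(tuple(groups), frozenset(sides))


def weight_exact(tree, groups: dict[str, list[str]]) -> Weighting:
    """Exact topology weighting: enumerate every one-tip-per-group combination."""
    gt = _GroupedTree(tree, groups)
    combos = np.array(list(itertools.product(*(range(n) for n in gt.sizes))),
                      dtype=np.intp)
    ids = gt.classify(combos)
    counts: dict[str, int] = {tid: 0 for tid in gt.topology_ids()}
    for tid in ids:
        counts[tid] += 1
    total = combos.shape[0]
    return Weighting(weights={tid: c / total for tid, c in counts.items()},
                     mode="exact")


def weight_sampled(tree, groups: dict[str, list[str]], *,
                   ci_level: float = 0.95, max_ci_width: float = 0.05,
                   batch: int = 100, max_iter: int = 10_000,
                   seed: int = 0) -> Weighting:
    """Monte-Carlo weighting with a Wilson-interval stopping rule.

    Tip combinations are drawn uniformly with replacement; sampling stops
    when the Wilson ci_level interval for every topology's weight has full
    width < max_ci_width, or after max_iter batches (converged=False).
    """
    if batch < 1:
        raise ValueError("batch must be >= 1")
    gt = _GroupedTree(tree, groups)
    ids = gt.topology_ids()
    index = {tid: i for i, tid in enumerate(ids)}
    counts = np.zeros(len(ids), dtype=np.int64)
    rng = np.random.default_rng(seed)
    n = 0
    converged = False
    for _ in range(max_iter):
        combos = np.column_stack([rng.integers(0, sz, size=batch)
                                  for sz in gt.sizes])
        for tid in gt.classify(combos):
            counts[index[tid]] += 1
        n += batch
        lo, hi = proportion_confint(counts, n, alpha=1 - ci_level, method="wilson")
        widths = np.asarray(hi) - np.asarray(lo)
        if widths.max() < max_ci_width:
            converged = True
            break
    return Weighting(
        weights={tid: counts[i] / n for tid, i in index.items()},
        mode="sampled", n_sampled=n,
        ci_width={tid: float(widths[i]) for tid, i in index.items()},
        seed=seed, converged=converged,
    )


def weight_tree(tree, groups: dict[str, list[str]], *,
                exact_limit: int = 100_000, **sampled_kwargs) -> Weighting:
    """Exact weighting when the combination space is small, sampling otherwise."""
    n_comb = int(np.prod([len(v) for v in groups.values()], dtype=np.float64))
    if n_comb <= exact_limit:
        return weight_exact(tree, groups)
    return weight_sampled(tree, groups, **sampled_kwargs)
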