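"""Sliding SNP-index windows and per-window unrooted trees.

Windows are 100 SNPs sliding by 25 by default; a tree is built only where
every sample has at least 30 non-missing calls in the window.  Trees come
from neighbor joining on pairwise Hamming-proportion distances, or from a
newick stream produced by an external tree builder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .genotype_matrix import MISSING, HaplotypeMatrix

log = logging.getLogger(__name__)


class DegenerateWindowError(ValueError):
    """A tip pair has zero pairwise-complete sites in the window."""


@dataclass(frozen=True)
class WindowSpec:
    """A window of consecutive filtered SNPs.

    snp_index_start/end are 0-based half-open indices into the filtered site
    list; genomic_start/end are the 1-based positions of the first and last
    SNP in the window.
    """

    scaffold_id: str
    snp_index_start: int
    snp_index_end: int
    genomic_start: int
    genomic_end: int


def make_windows(positions: np.ndarray, scaffold_id: str = "",
                 size: int = 100, step: int = 25) -> list[WindowSpec]:
    """Full-size windows starting at SNP indices 0, step, 2*step, ...

    Trailing partial windows are dropped; consecutive windows overlap by
    size - step sites.
    """
    if size <= 0 or not 0 < step <= size:
        raise ValueError("need size > 0 and 0 < step <= size")
    positions = np.asarray(positions)
    n = len(positions)
    out = []
    for start in range(0, n - size + 1, step):
        end = start + size
        out.append(WindowSpec(scaffold_id, start, end,
                              int(positions[start]), int(positions[end - 1])))
    return out


def window_passes(hm: HaplotypeMatrix, w: WindowSpec,
                  min_snps_per_sample: int = 30) -> bool:
    """True iff every tip has >= min_snps_per_sample non-missing calls in w."""
    block = hm.alleles[w.snp_index_start:w.snp_index_end]
    return bool(((block != MISSING).sum(axis=0) >= min_snps_per_sample).all())


def pairwise_distances(hm: HaplotypeMatrix, w: WindowSpec) -> tuple[np.ndarray, list[str]]:
    """Hamming-proportion distances over pairwise-complete sites in a window.

    d(i, j) is the fraction of sites, among those non-missing in both tips,
    where the alleles differ.  No substitution-model correction is applied:
    distances feed a topology-only tree builder.
    """
    block = hm.alleles[w.snp_index_start:w.snp_index_end]
    present = block != MISSING  # (L, N)
    both = present.T.astype(np.int64) @ present  # comparable sites per pair
    if np.any(both == 0):
        i, j = np.argwhere(both == 0)[0]
        raise DegenerateWindowError(
            f"tips {hm.tip_ids[i]!r} and {hm.tip_ids[j]!r} share no called "
            f"sites in window [{w.snp_index_start}, {w.snp_index_end})")
    n = block.shape[1]
    diff = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        neq = (block[:, i, None] != block) & present[:, i, None] & present
        diff[i] = neq.sum(axis=0)
    return diff / both, list(hm.tip_ids)


class UnrootedTree:
    """An unrooted strictly binary tree over named tips.

    Wraps a dendropy tree; `splits` exposes the tip set on one side of each
    internal edge (what topology weighting consumes).
    """

    def __init__(self, tree: dendropy.Tree):
        tree.deroot()
        self._tree = tree
        self.tip_ids = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(self.tip_ids)) != len(self.tip_ids):
            raise ValueError("duplicate tip labels")
        seed = tree.seed_node
        for node in tree.preorder_node_iter():
            n_children = len(node.child_nodes())
            if node is seed:
                if n_children != (3 if len(self.tip_ids) > 2 else n_children):
                    raise ValueError("tree is not strictly binary (unrooted)")
            elif n_children not in (0, 2):
                raise ValueError("tree contains a polytomy or unifurcation")
        self._splits: list[frozenset[str]] | None = None

    @classmethod
    def from_newick(cls, newick: str) -> "UnrootedTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls(tree)

    @property
    def splits(self) -> list[frozenset[str]]:
        """Tip sets below each internal (non-pendant) edge."""
        if self._splits is None:
            out = []
            seed = self._tree.seed_node
            for node in self._tree.preorder_internal_node_iter():
                if node is seed:
                    continue
                out.append(frozenset(l.taxon.label for l in node.leaf_iter()))
            self._splits = out
        return self._splits

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __len__(self) -> int:
        return len(self.tip_ids)


def neighbor_joining(dm: np.ndarray, tip_ids: list[str]) -> UnrootedTree:
    """Standard neighbor joining with deterministic tie-breaking.

    When several pairs minimize the Q criterion the lowest-index pair is
    joined first (original tips first, merged nodes in creation order).
    Negative branch-length estimates are clamped to 0.
    """
    dm = np.asarray(dm, dtype=np.float64)
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 tips")
    if dm.shape != (n, n) or not np.allclose(dm, dm.T) or np.any(np.diag(dm) != 0):
        raise ValueError("distance matrix must be square, symmetric, zero-diagonal")
    if len(tip_ids) != n:
        raise ValueError("tip_ids length must match the matrix")

    taxa = dendropy.TaxonNamespace(tip_ids)
    nodes = []
    for label in tip_ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    D = dm.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        iu = np.triu_indices(m, k=1)
        flat = Q[iu]
        k = int(np.argmin(flat))  # row-major => lexicographic lowest (i, j)
        i, j = int(iu[0][k]), int(iu[1][k])
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = max(li, 0.0)
        nj.edge.length = max(lj, 0.0)
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[x] for x in keep] + [parent]

    center = dendropy.Node()
    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        lens = [0.5 * (d01 + d02 - d12), 0.5 * (d01 + d12 - d02),
                0.5 * (d02 + d12 - d01)]
    else:  # exactly 2 remaining (n == 2 never reaches here; n == 3 start)
        lens = [D[0, 1] / 2, D[0, 1] / 2]
    for node, ln in zip(nodes, lens):
        center.add_child(node)
        node.edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=center)
    tree.is_rooted = False
    return UnrootedTree(tree)


def build_forest(hm: HaplotypeMatrix, windows: list[WindowSpec],
                 min_snps_per_sample: int = 30
                 ) -> tuple[list[UnrootedTree | None], list[bool]]:
    """One NJ tree per passing window; None where the window fails the
    data-sufficiency rule or is degenerate."""
    trees: list[UnrootedTree | None] = []
    passed: list[bool] = []
    for w in windows:
        ok = window_passes(hm, w, min_snps_per_sample)
        if not ok:
            trees.append(None)
            passed.append(False)
            continue
        try:
            dm, tips = pairwise_distances(hm, w)
        except DegenerateWindowError as err:
            log.warning("skipping degenerate window %s: %s", w, err)
            trees.append(None)
            passed.append(False)
            continue
        trees.append(neighbor_joining(dm, tips))
        passed.append(True)
    return trees, passed


def read_newick_stream(path, windows: list[WindowSpec],
                       expected_tips: set[str] | None = None
                       ) -> list[UnrootedTree]:
    """Ingest externally built per-window trees (one newick line per passing
    window, in window order).  Polytomies and unknown tip labels are
    rejected with the offending window index."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) != len(windows):
        raise ValueError(f"expected {len(windows)} newick lines, got {len(lines)}")
    trees = []
    for idx, line in enumerate(lines):
        try:
            tree = UnrootedTree.from_newick(line)
        except ValueError as err:
            raise ValueError(f"window {idx}: {err}") from err
        if expected_tips is not None:
            unknown = set(tree.tip_ids) - expected_tips
            if unknown:
                raise ValueError(
                    f"window {idx}: unknown tip labels {sorted(unknown)}")
        trees.append(tree)
    return trees
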