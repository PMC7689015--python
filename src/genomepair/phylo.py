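"""Neighbor-joining phylogenies of repeat sequences under the Jukes-Cantor
model, with end/gap-column trimming, bootstrap supports and long-branch
removal.

Alignment itself is upstream (e.g. MAFFT); this module consumes a gapped
multiple alignment.  Distances use pairwise deletion: each pair is compared
over the columns where both rows carry a residue, because repeat alignments
are gappy enough that complete deletion can empty the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .formats import SequenceRecord

_GAP = ord("-")


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over {A, C, G, T, N, -}."""
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        return np.array(
            [np.frombuffer(r.encode("ascii"), dtype=np.uint8)
             for r in self.rows])

    @classmethod
    def from_matrix(cls, taxa: Sequence[str], mat: np.ndarray
                    ) -> "MultipleAlignment":
        return cls(list(taxa), [m.tobytes().decode("ascii") for m in mat])

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord]
                     ) -> "MultipleAlignment":
        return cls([r.id for r in records], [r.residues for r in records])

    def subset(self, keep: Sequence[str]) -> "MultipleAlignment":
        keep_set = set(keep)
        idx = [i for i, t in enumerate(self.taxa) if t in keep_set]
        return MultipleAlignment([self.taxa[i] for i in idx],
                                 [self.rows[i] for i in idx])


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        self.values = v


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------

def trim_alignment(msa: MultipleAlignment,
                   end_presence_frac: float = 0.25,
                   gap_col_frac: float = 0.25) -> MultipleAlignment:
    """Trim an alignment's ragged ends and gappy columns.

    Leading (and trailing) columns are stripped while the fraction of rows
    carrying a residue is strictly below ``end_presence_frac`` (a column at
    exactly the threshold is kept); remaining columns whose gap fraction is
    strictly above ``gap_col_frac`` are removed.
    """
    mat = msa.matrix()
    n, m = mat.shape
    presence = (mat != _GAP).sum(axis=0) / n
    first = 0
    while first < m and presence[first] < end_presence_frac:
        first += 1
    last = m
    while last > first and presence[last - 1] < end_presence_frac:
        last -= 1
    if last <= first:
        raise ValueError("trimming removed every column")
    mat = mat[:, first:last]
    gap_frac = (mat == _GAP).sum(axis=0) / n
    keep = gap_frac <= gap_col_frac
    if not keep.any():
        raise ValueError("trimming removed every column")
    return MultipleAlignment.from_matrix(msa.taxa, mat[:, keep])


# ---------------------------------------------------------------------------
# Jukes-Cantor distances
# ---------------------------------------------------------------------------

def jc_distance(msa: MultipleAlignment, cap: float = 5.0) -> DistanceMatrix:
    """Jukes-Cantor distances d = -(3/4) ln(1 - (4/3) p) with pairwise
    deletion; saturated pairs (p >= 0.75) are set to ``cap`` with a
    warning."""
    mat = msa.matrix()
    n = msa.n_taxa
    d = np.zeros((n, n))
    residue = mat != _GAP
    for i in range(n):
        for j in range(i + 1, n):
            both = residue[i] & residue[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {msa.taxa[i]!r} "
                    f"and {msa.taxa[j]!r}")
            p = float((mat[i, both] != mat[j, both]).sum()) / comparable
            if p >= 0.75:
                warnings.warn(
                    f"saturated pair {msa.taxa[i]!r}/{msa.taxa[j]!r} "
                    f"(p = {p:.3f}); distance capped at {cap}")
                dist = cap
            else:
                dist = -0.75 * np.log(1.0 - (4.0 / 3.0) * p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(msa.taxa), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor joining with the Q-criterion.

    Ties are broken toward the lowest-index pair; a negative branch length
    is clamped to zero with the deficit transferred to its sister branch
    (path lengths are preserved).  The returned tree is unrooted.
    """
    d = np.array(dm.values, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    tns = dendropy.TaxonNamespace(dm.taxa)
    nodes = [dendropy.Node(taxon=tns.get_taxon(t)) for t in dm.taxa]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # first minimal entry in row-major order -> lowest-index pair
        fi, fj = divmod(int(np.argmin(q)), m)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = d[i, j]
        li = 0.5 * dij + (r[fi] - r[fj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        new = dendropy.Node()
        _attach(new, nodes[i], li)
        _attach(new, nodes[j], lj)
        # distances from the new node to the remaining taxa
        dnew = np.zeros(d.shape[0] + 1)
        for fk in range(m):
            kidx = active[fk]
            if kidx in (i, j):
                continue
            dnew[kidx] = 0.5 * (d[i, kidx] + d[j, kidx] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = dnew[:-1]
        d[:-1, -1] = dnew[:-1]
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        for idx, ln in ((i, li), (j, lj), (k, lk)):
            _attach(root, nodes[idx], max(ln, 0.0))
    else:  # exactly 2 active nodes (n == 3 handled above; safety path)
        i, j = active
        _attach(root, nodes[i], d[i, j] / 2.0)
        _attach(root, nodes[j], d[i, j] / 2.0)
    tree.is_rooted = False
    return tree


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _attach(parent: dendropy.Node, child: dendropy.Node,
            length: float) -> None:
    parent.add_child(child)
    child.edge.length = float(length)


def tree_path_distances(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths keyed by the unordered label pair."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the smaller leaf-label side
    (label-based, so trees over different namespaces compare equal)."""
    labels = frozenset(t.label for t in tree.taxon_namespace)
    out: set[frozenset] = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.head_node.is_leaf():
            continue
        side = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter())
        if 1 < len(side) < len(labels) - 1:
            other = labels - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(msa: MultipleAlignment, n_reps: int = 1000,
                      seed: int = 0, cap: float = 5.0) -> dendropy.Tree:
    """NJ tree of ``msa`` with bootstrap supports on internal nodes.

    Columns are resampled with replacement ``n_reps`` times, the tree is
    rebuilt per replicate (JC distances, then NJ), and the support of each
    internal edge of the original tree is the percentage of replicates
    whose tree contains the same bipartition.  With ``n_reps`` = 0 the
    original tree is returned without supports.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tree = neighbor_joining(jc_distance(msa, cap=cap))
    if n_reps == 0:
        return tree
    rng = np.random.default_rng(seed)
    mat = msa.matrix()
    counts: dict[frozenset, int] = {}
    orig = tree_bipartitions(tree)
    for _ in range(n_reps):
        cols = rng.integers(0, mat.shape[1], size=mat.shape[1])
        rep = MultipleAlignment.from_matrix(msa.taxa, mat[:, cols])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep_tree = neighbor_joining(jc_distance(rep, cap=cap))
        for bp in tree_bipartitions(rep_tree):
            if bp in orig:
                counts[bp] = counts.get(bp, 0) + 1
    labels = frozenset(t.label for t in tree.taxon_namespace)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if not (1 < len(side) < len(labels) - 1):
            continue
        key = min(side, labels - side, key=lambda s: (len(s), sorted(s)))
        support = 100.0 * counts.get(key, 0) / n_reps
        node.label = str(int(round(support)))
    return tree


# ---------------------------------------------------------------------------
# Long-branch removal
# ---------------------------------------------------------------------------

def prune_long_branches(tree: dendropy.Tree, msa: MultipleAlignment,
                        factor: float = 10.0, max_iter: int = 2,
                        cap: float = 5.0
                        ) -> tuple[MultipleAlignment, dendropy.Tree, list[str]]:
    """Remove leaves whose terminal branch exceeds ``factor`` times the
    median terminal branch length, rebuild from the reduced alignment, and
    iterate at most ``max_iter`` times.

    Returns ``(kept alignment, rebuilt tree, removed taxon labels)``.
    """
    removed: list[str] = []
    current_tree, current_msa = tree, msa
    for _ in range(max_iter):
        term = {lf.taxon.label: (lf.edge.length or 0.0)
                for lf in current_tree.leaf_node_iter()}
        med = float(np.median(list(term.values())))
        if not np.isfinite(factor):
            break
        drop = [t for t, ln in term.items() if ln > factor * med]
        if not drop:
            break
        keep = [t for t in current_msa.taxa if t not in drop]
        if len(keep) < 3:
            raise ValueError(
                "long-branch pruning would leave fewer than 3 taxa")
        removed.extend(drop)
        current_msa = current_msa.subset(keep)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            current_tree = neighbor_joining(jc_distance(current_msa, cap=cap))
    return current_msa, current_tree, removed
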