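"""Kingman coalescent genealogies and branch-proportional mutation placement.

The genealogy of a constant-size Wright-Fisher population of ``n`` haploid
individuals is simulated backwards in time: while ``k`` lineages remain, the
waiting time to the next coalescence is Exponential with rate k(k-1)/2 (time
measured in units of N generations) and the merging pair is uniform among
unordered pairs.  Causative mutations are then dropped onto branches as a
Poisson process along total branch length, i.e. each mutation lands on a
branch with probability proportional to that branch's length
(infinite-sites: every mutation is a distinct record).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from coalor._kernels import kingman_merge, leaf_interval_labels

__all__ = [
    "GenealogyTree",
    "Mutation",
    "simulate_tree",
    "total_branch_length",
    "place_mutations",
    "carriers",
]


@dataclass
class GenealogyTree:
    """A coalescent genealogy of ``n`` haploid individuals.

    Nodes are indexed ``0..2n-2``: leaves ``0..n-1`` (all at time 0),
    internal nodes ``n..2n-2`` in order of creation, so every parent has a
    larger index (and a strictly larger time) than its children.  The root
    is node ``2n-2`` and has parent ``-1``.  Times are in coalescent units
    of N generations.
    """

    node_time: np.ndarray
    parent: np.ndarray
    children: np.ndarray
    _labels: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        """Number of leaves (haploid individuals)."""
        return (self.node_time.shape[0] + 1) // 2

    @property
    def n_nodes(self) -> int:
        return self.node_time.shape[0]

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        """Time to the most recent common ancestor of the sample."""
        return float(self.node_time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Per-node length of the branch to its parent (0 for the root)."""
        out = self.node_time[self.parent] - self.node_time
        out[self.root] = 0.0
        return out

    def _leaf_labels(self):
        if self._labels is None:
            self._labels = leaf_interval_labels(self.n, self.children)
        return self._labels

    def subtree_leaf_count(self, node: int) -> int:
        return int(self._leaf_labels()[0][node])

    def leaf_intervals(self):
        """``(lo, hi, tour)``: leaves below node v are ``tour[lo[v]:hi[v]]``."""
        _, lo, hi, tour = self._leaf_labels()
        return lo, hi, tour

    def validate(self) -> None:
        """Raise ``ValueError`` if the structural invariants do not hold."""
        n = self.n
        if self.n_nodes != 2 * n - 1 or self.children.shape != (n - 1, 2):
            raise ValueError("node arrays inconsistent with leaf count")
        if np.any(self.node_time[:n] != 0.0):
            raise ValueError("leaves must be at time 0 (ultrametric)")
        if self.parent[self.root] != -1:
            raise ValueError("root must have no parent")
        if n > 1:
            nonroot = np.arange(2 * n - 2)
            if np.any(self.parent[nonroot] < 0):
                raise ValueError("every non-root node needs a parent")
            if np.any(
                self.node_time[self.parent[nonroot]] <= self.node_time[nonroot]
            ):
                raise ValueError("node times must increase towards the root")
            # every leaf reaches the root: parent indices strictly increase,
            # so a finite walk suffices
            for leaf in range(n):
                v = leaf
                while self.parent[v] != -1:
                    v = int(self.parent[v])
                if v != self.root:
                    raise ValueError("leaf %d does not reach the root" % leaf)

    def to_newick(self, precision: int = 6) -> str:
        """Newick string with branch lengths (debugging aid)."""
        n = self.n
        if n == 1:
            return "0;"
        lens = self.branch_lengths()
        label = [str(i) for i in range(n)] + [""] * (n - 1)
        for s in range(n - 1):
            c0, c1 = self.children[s]
            sub = "(%s:%.*f,%s:%.*f)" % (
                label[c0], precision, lens[c0],
                label[c1], precision, lens[c1],
            )
            label[n + s] = sub
        return label[2 * n - 2] + ";"


@dataclass
class Mutation:
    """A causative mutation on one branch of one locus's genealogy.

    ``branch_child_node`` identifies the branch immediately above that node;
    carriers are the leaves of the subtree rooted there.  ``carrier_leaves``
    is materialised by :func:`place_mutations` (and by :func:`carriers`); the
    scenario engine leaves it ``None`` on large populations and works from
    the tree's leaf intervals instead.
    """

    locus_index: int
    branch_child_node: int
    carrier_count: int
    frequency: float
    carrier_leaves: frozenset | None = None


def simulate_tree(n: int, rng: np.random.Generator) -> GenealogyTree:
    """Simulate a Kingman coalescent genealogy for ``n`` haploid individuals.

    While ``k`` lineages are active the inter-coalescence wait is
    Exponential(k(k-1)/2) in units of N generations; the merging pair is
    uniform.  Identical seeds give identical trees.
    """
    if int(n) != n or n < 1:
        raise ValueError("sample size n must be a positive integer, got %r" % (n,))
    n = int(n)
    if n == 1:
        return GenealogyTree(
            node_time=np.zeros(1),
            parent=np.full(1, -1, dtype=np.int32),
            children=np.empty((0, 2), dtype=np.int32),
        )
    k = np.arange(n, 1, -1, dtype=np.float64)
    waits = rng.exponential(scale=2.0 / (k * (k - 1.0)))
    u_first = rng.random(n - 1)
    u_second = rng.random(n - 1)
    node_time, parent, children = kingman_merge(n, waits, u_first, u_second)
    return GenealogyTree(node_time=node_time, parent=parent, children=children)


def total_branch_length(tree: GenealogyTree) -> float:
    """Sum of all branch lengths; 0 for a single-leaf tree."""
    return float(tree.branch_lengths().sum())


def sample_mutation_nodes(
    tree: GenealogyTree, mutation_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Branch-proportional Poisson mutation placement; returns child nodes.

    The number of mutations is Poisson(rate * total length); each lands on a
    branch with probability proportional to its length.  Returned array holds
    the ``branch_child_node`` of every mutation (may repeat: distinct
    mutations on one branch share a carrier set under infinite sites).
    """
    if mutation_rate < 0:
        raise ValueError("mutation rate must be non-negative")
    lens = tree.branch_lengths()
    total = lens.sum()
    if total <= 0 or mutation_rate == 0:
        # draw anyway so the stream layout is stable across rates
        rng.poisson(0.0)
        return np.empty(0, dtype=np.int64)
    count = rng.poisson(mutation_rate * total)
    if count == 0:
        return np.empty(0, dtype=np.int64)
    cum = np.cumsum(lens)
    return np.searchsorted(cum, rng.random(count) * total, side="right")


def place_mutations(
    tree: GenealogyTree,
    mutation_rate: float,
    rng: np.random.Generator,
    locus_index: int = 0,
) -> list[Mutation]:
    """Place causative mutations on the tree; see :func:`sample_mutation_nodes`."""
    nodes = sample_mutation_nodes(tree, mutation_rate, rng)
    lo, hi, tour = tree.leaf_intervals() if nodes.size else (None, None, None)
    out = []
    for v in nodes:
        v = int(v)
        leaves = frozenset(int(x) for x in tour[lo[v]:hi[v]])
        out.append(
            Mutation(
                locus_index=locus_index,
                branch_child_node=v,
                carrier_count=len(leaves),
                frequency=len(leaves) / tree.n,
                carrier_leaves=leaves,
            )
        )
    return out


def carriers(tree: GenealogyTree, branch_child_node: int) -> frozenset:
    """Leaves descending from (and including, if a leaf) ``branch_child_node``.

    The root has no branch above it, so asking for its carriers is an error.
    """
    v = int(branch_child_node)
    if v == tree.root and tree.n > 1 or v < 0 or v >= tree.n_nodes:
        raise ValueError("node %d has no branch above it" % v)
    if tree.n == 1:
        raise ValueError("single-leaf tree has no branches")
    lo, hi, tour = tree.leaf_intervals()
    return frozenset(int(x) for x in tour[lo[v]:hi[v]])
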