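"""Distance-based phylogenetics for NRPS domain comparison.

A-domain substrate calling by placement, C/TE subtype calling and the
module-grouping view of an assembly line all reduce to the same machinery:
pairwise distances on an alignment, a tree, and patristic distances (summed
branch lengths between leaves).  Two domains whose A-domain patristic
distance falls below a threshold (0.45 by default) are treated as members of
the same specificity group.

The internal tree method is Saitou-Nei neighbor joining on p-distances or
Poisson-corrected distances.  Maximum-likelihood estimation is deliberately
out of scope: externally built trees can be imported from newick and used
everywhere a tree is accepted (placement, grouping), which is the fidelity
path for reproducing published figures whose thresholds were calibrated on
ML branch lengths.

Trees are carried as :class:`PhyloTree`, a thin wrapper over ``dendropy.Tree``
(newick round-trip, patristic matrix, outgroup rooting).
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import dendropy
import networkx as nx
import numpy as np

__all__ = [
    "MultipleAlignment",
    "DistanceMatrix",
    "PhyloTree",
    "PhyloConfig",
    "pairwise_distances",
    "nj_tree",
    "patristic_distances",
    "group_by_patristic",
    "root_with_outgroup",
]

GAP = "-"

DistanceModel = Literal["p-distance", "poisson"]


class SaturatedPairError(ValueError):
    """Poisson correction undefined for a pair with p >= 1."""


@dataclass(frozen=True)
class MultipleAlignment:
    """Ordered (label, row) pairs of equal length; gap character '-'."""

    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValueError("alignment needs >= 2 rows")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("alignment labels must be unique")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValueError("alignment rows must have equal length")

    @property
    def n_rows(self) -> int:
        return len(self.labels)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "MultipleAlignment":
        labels, rows = zip(*pairs)
        return cls(tuple(labels), tuple(r.upper() for r in rows))

    @classmethod
    def from_fasta(cls, path) -> "MultipleAlignment":
        from Bio import SeqIO

        pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        return cls.from_pairs(pairs)


class DistanceMatrix:
    """Symmetric non-negative distance matrix with labelled rows/columns."""

    def __init__(self, labels: Sequence[str], matrix: np.ndarray):
        labels = tuple(labels)
        matrix = np.asarray(matrix, dtype=float)
        n = len(labels)
        if matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(labels)) != n:
            raise ValueError("duplicate labels")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("distances must be finite")
        if not np.allclose(matrix, matrix.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(matrix), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if np.any(matrix < -1e-12):
            raise ValueError("distances must be non-negative")
        self.labels = labels
        self.matrix = np.clip((matrix + matrix.T) / 2.0, 0.0, None)
        self._index = {lb: i for i, lb in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.matrix[self._index[a], self._index[b]])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", index_label="label"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy())


@dataclass
class PhyloConfig:
    """Tunable constants for distance/grouping analyses."""

    distance_model: DistanceModel = "p-distance"
    grouping_threshold: float = 0.45  # patristic distance below which two
    # domains are put in the same group
    outgroup: str | None = None

    def __post_init__(self):
        if self.grouping_threshold <= 0:
            raise ValueError("grouping threshold must be positive")


def pairwise_distances(
    aln: MultipleAlignment, model: DistanceModel = "p-distance"
) -> DistanceMatrix:
    """p-distances (optionally Poisson-corrected) between all row pairs.

    A column contributes to a pair only when neither row is gapped there; a
    pair with zero comparable columns is an error.  The Poisson correction
    -ln(1 - p) diverges at p >= 1 (saturation), which raises
    :class:`SaturatedPairError` naming the pair.
    """
    n = aln.n_rows
    arr = np.frombuffer(
        "".join(aln.rows).encode("ascii"), dtype=np.uint8
    ).reshape(n, aln.n_cols)
    gap = arr == ord(GAP)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"rows {aln.labels[i]!r} and {aln.labels[j]!r} share no "
                    "comparable (gap-free) columns"
                )
            p = float(np.sum(arr[i, ok] != arr[j, ok])) / m
            if model == "poisson":
                if p >= 1.0:
                    raise SaturatedPairError(
                        f"pair ({aln.labels[i]!r}, {aln.labels[j]!r}) is "
                        f"saturated (p = {p}); Poisson correction undefined"
                    )
                p = -math.log(1.0 - p)
            elif model != "p-distance":
                raise ValueError(f"unknown distance model {model!r}")
            d[i, j] = d[j, i] = p
    return DistanceMatrix(aln.labels, d)


# ---------------------------------------------------------------------------
# Trees


class PhyloTree:
    """A tree with branch lengths and unique leaf labels (dendropy-backed)."""

    def __init__(self, tree: dendropy.Tree, rooted: bool):
        self._tree = tree
        self.rooted = rooted
        labels = self.leaf_labels
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is not None and (
                not math.isfinite(edge.length) or edge.length < 0
            ):
                raise ValueError("branch lengths must be finite and >= 0")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(
            lf.taxon.label for lf in self._tree.leaf_node_iter()
        )

    def to_newick(self) -> str:
        return (
            self._tree.as_string(schema="newick", suppress_rooting=True).strip()
        )

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, source: str, rooted: bool = False) -> "PhyloTree":
        """Parse newick from a string or a path-like pointing at a file."""
        import os

        if os.path.exists(str(source)):
            with open(source) as fh:
                source = fh.read()
        tree = dendropy.Tree.get(
            data=source, schema="newick", preserve_underscores=True
        )
        return cls(tree, rooted=rooted)

    def copy(self) -> "PhyloTree":
        return PhyloTree.from_newick(self.to_newick(), rooted=self.rooted)


def _edge_graph(tree: dendropy.Tree) -> nx.Graph:
    g = nx.Graph()
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            raise ValueError("tree has missing branch lengths")
        g.add_edge(id(edge.tail_node), id(edge.head_node), weight=edge.length)
    return g


def patristic_distances(t: PhyloTree) -> DistanceMatrix:
    """Leaf-pair patristic distances: summed branch lengths on the i->j path."""
    tree = t.dendropy_tree
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    labels = [lf.taxon.label for lf in leaves]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                leaves[i].taxon, leaves[j].taxon
            )
    return DistanceMatrix(labels, d)


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; deterministic; unrooted.

    Tie-breaking at the Q-matrix minimum is by the lexicographically smallest
    (representative-label) pair, where a cluster's representative is its
    smallest leaf label.  A negative branch length produced by the NJ
    formulas is clamped to zero and the deficit shifted onto the sister
    branch, so output branch lengths are always >= 0.
    """
    n = len(d)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    taxa = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    reps: list[str] = []
    for lb in d.labels:
        taxon = taxa.new_taxon(lb)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
        reps.append(lb)
    dm = d.matrix.copy()
    active = list(range(n))

    def _clamped(bi: float, bj: float) -> tuple[float, float]:
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        return max(bi, 0.0), max(bj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                pair = tuple(sorted((reps[active[a]], reps[active[b]])))
                key = (round(q, 12), pair)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = dm[i, j]
        bi = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        bj = dij - bi
        bi, bj = _clamped(bi, bj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = bi
        parent.add_child(nodes[j])
        nodes[j].edge.length = bj
        # distances from the new cluster to the remaining active clusters
        new_row = np.zeros(dm.shape[0] + 1)
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = max(0.5 * (dm[i, k] + dm[j, k] - dij), 0.0)
        dm = np.pad(dm, ((0, 1), (0, 1)))
        dm[-1, :-1] = new_row[:-1]
        dm[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        u = dm.shape[0] - 1
        active = [k for k in active if k not in (i, j)] + [u]

    # join the final three clusters at an unrooted trifurcation
    i, j, k = active
    bi = 0.5 * (dm[i, j] + dm[i, k] - dm[j, k])
    bj = 0.5 * (dm[i, j] + dm[j, k] - dm[i, k])
    bk = 0.5 * (dm[i, k] + dm[j, k] - dm[i, j])
    shortfall = 0.0
    lens = []
    for b in (bi, bj, bk):
        if b < 0:
            shortfall += b
            b = 0.0
        lens.append(b)
    if shortfall:
        # spread the deficit over the other branches, keeping them >= 0
        pos = [x for x in lens if x > 0]
        if pos:
            share = shortfall / len(pos)
            lens = [max(x + share, 0.0) if x > 0 else x for x in lens]
    root = dendropy.Node()
    for idx, b in zip((i, j, k), lens):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = b
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return PhyloTree(tree, rooted=False)


def group_by_patristic(
    d: DistanceMatrix,
    threshold: float = 0.45,
    mode: Literal["components", "pairwise"] = "components",
) -> list[tuple[str, ...]] | set[frozenset]:
    """Group leaves whose patristic distance is below `threshold`.

    ``components`` (default): single-linkage transitive closure — connected
    components of the graph with an edge for every pair with d < threshold;
    returns a partition as tuples sorted internally, ordered by smallest
    member.  ``pairwise`` returns the raw edge set (frozenset pairs) instead,
    for users who read the rule as a statement about pairs only.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    g = nx.Graph()
    g.add_nodes_from(d.labels)
    n = len(d)
    for i in range(n):
        for j in range(i + 1, n):
            if d.matrix[i, j] < threshold:
                g.add_edge(d.labels[i], d.labels[j])
    if mode == "pairwise":
        return {frozenset(e) for e in g.edges}
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return comps


def root_with_outgroup(t: PhyloTree, leaf_label: str) -> PhyloTree:
    """Root the tree at the midpoint of the outgroup leaf's pendant edge.

    Patristic distances are unchanged by rooting (only the traversal origin
    moves); the outgroup leaf becomes one of the two children of the root.
    """
    t2 = t.copy()
    tree = t2.dendropy_tree
    target = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == leaf_label:
            target = lf
            break
    if target is None:
        raise KeyError(f"leaf label {leaf_label!r} not in tree")
    edge = target.edge
    length = edge.length if edge.length is not None else 0.0
    tree.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0)
    tree.is_rooted = True
    return PhyloTree(tree, rooted=True)
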