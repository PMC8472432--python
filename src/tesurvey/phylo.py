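"""Alignments, distance matrices, neighbor-joining trees, bootstrap, RF.

Distance models: p-distance, Kimura two-parameter (nucleotide) and
Poisson-corrected (protein), all with pairwise deletion of gapped columns.
Tree inference is neighbor joining with negative branch lengths clamped to
zero and deterministic tie-breaking by lowest label index -- a desk-scale
stand-in for likelihood inference that is entirely adequate for the
topology-incongruence tests the horizontal-transfer verdict needs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from ._align import mafft, nucleotide_aligner, protein_aligner
from .census import kimura2p

__all__ = ["DistanceMatrix", "PhyloTree", "align_proteins", "distance_matrix",
           "neighbor_joining", "bootstrap_support", "robinson_foulds",
           "identity_matrix", "tree_splits"]


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray            # symmetric, zero diagonal
    model: str                    # "p" | "k2p" | "poisson"
    saturated: set[tuple[int, int]] = field(default_factory=set)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                row = "\t".join(f"{v:.6f}" for v in self.matrix[i])
                fh.write(f"{lab}\t{row}\n")


@dataclass
class PhyloTree:
    newick: str
    labels: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    def dendropy_tree(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick",
                                 taxon_namespace=taxon_namespace)


def align_proteins(sequences: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Multiple protein alignment (MAFFT); single sequences pass through."""
    if not sequences:
        raise ValueError("no sequences")
    return mafft(sequences, protein=True)


def align_nucleotides(sequences: list[tuple[str, str]],
                      ) -> list[tuple[str, str]]:
    """Multiple nucleotide alignment; equal-length inputs pass through."""
    if not sequences:
        raise ValueError("no sequences")
    if len({len(s) for _n, s in sequences}) == 1:
        return list(sequences)
    return mafft(sequences, protein=False)


def _pair_distance(a: str, b: str, model: str) -> tuple[float, bool]:
    """(distance, saturated) for one aligned pair under ``model``."""
    if model == "k2p":
        res = kimura2p(a, b)
        return (res.k if res.k is not None else float("nan")), res.saturated
    n = diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-.X?" or y in "-.X?":
            continue
        n += 1
        diff += x != y
    if n == 0:
        return float("nan"), True
    p = diff / n
    if model == "p":
        return p, False
    if model == "poisson":
        if p >= 1.0:
            return float("nan"), True
        return -math.log(1.0 - p), False
    raise ValueError(f"unknown model: {model}")


def distance_matrix(alignment: list[tuple[str, str]],
                    model: str = "k2p") -> DistanceMatrix:
    """Pairwise distances with per-pair deletion of gapped columns."""
    if len(alignment) < 2:
        raise ValueError("need >= 2 sequences")
    labels = [name for name, _ in alignment]
    n = len(labels)
    mat = np.zeros((n, n))
    saturated: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            d, sat = _pair_distance(alignment[i][1], alignment[j][1], model)
            if sat or math.isnan(d):
                saturated.add((i, j))
                d = float("nan")
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels, mat, model, saturated)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Standard NJ agglomeration (Saitou-Nei with Studier-Keppler Q).

    Negative branch lengths are clamped to zero; ties in the Q matrix
    break to the lowest label-index pair, so the result is deterministic
    and invariant to input label order up to the unrooted topology.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need >= 3 labels")
    if np.isnan(dm.matrix).any():
        raise ValueError("distance matrix contains undefined entries")
    D = dm.matrix.astype(float).copy()
    nodes = [f"{_quote(l)}" for l in dm.labels]
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin over row-major order = lowest (i, j) pair on ties
        flat = int(np.argmin(np.round(Q, 12)))
        ii, jj = divmod(flat, m)
        if ii > jj:
            ii, jj = jj, ii
        i, j = active[ii], active[jj]
        dij = sub[ii, jj]
        vi = 0.5 * dij + (r[ii] - r[jj]) / (2 * (m - 2))
        vj = dij - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        new_row = 0.5 * (D[i, active] + D[j, active] - dij)
        label = f"({nodes[i]}:{vi:.8f},{nodes[j]}:{vj:.8f})"
        D = np.vstack([D, np.zeros((1, D.shape[1]))])
        D = np.hstack([D, np.zeros((D.shape[0], 1))])
        k = D.shape[0] - 1
        for idx, a in enumerate(active):
            D[k, a] = D[a, k] = new_row[idx]
        D[k, k] = 0.0
        nodes.append(label)
        active = [a for a in active if a not in (i, j)] + [k]
    i, j = active
    v = max(D[i, j], 0.0)
    newick = f"({nodes[i]}:{v / 2:.8f},{nodes[j]}:{v / 2:.8f});"
    return PhyloTree(newick=newick, labels=list(dm.labels))


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_splits(newick: str, labels: list[str] | None = None) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, one side per split.

    Each split is represented by the side not containing the first label
    (alphabetically), so representations compare across trees.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
    anchor = taxa[0]
    full = frozenset(taxa)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(side)
    return splits


def robinson_foulds(tree_a: PhyloTree | str, tree_b: PhyloTree | str) -> int:
    """Unrooted RF distance (symmetric difference of non-trivial splits)."""
    nw_a = tree_a.newick if isinstance(tree_a, PhyloTree) else tree_a
    nw_b = tree_b.newick if isinstance(tree_b, PhyloTree) else tree_b
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=nw_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=nw_b, schema="newick", taxon_namespace=tns)
    la = {l.taxon.label for l in ta.leaf_node_iter()}
    lb = {l.taxon.label for l in tb.leaf_node_iter()}
    if la != lb:
        raise ValueError("trees must share one leaf set")
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))


def bootstrap_support(alignment: list[tuple[str, str]], n_reps: int = 100,
                      seed: int = 0, model: str = "poisson") -> PhyloTree:
    """Ordinary bootstrap on alignment columns; NJ per replicate.

    Support for each internal split of the full-data NJ tree is the
    percentage of replicate trees containing that split.
    """
    if len(alignment) < 4:
        raise ValueError("need >= 4 sequences for meaningful supports")
    base = neighbor_joining(distance_matrix(alignment, model))
    base_splits = tree_splits(base.newick)
    counts = {s: 0 for s in base_splits}
    rng = np.random.default_rng(seed)
    names = [n for n, _ in alignment]
    rows = [s for _, s in alignment]
    L = len(rows[0])
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = [(names[i], "".join(rows[i][c] for c in cols))
               for i in range(len(rows))]
        try:
            rep_tree = neighbor_joining(distance_matrix(rep, model))
        except ValueError:
            continue
        rep_splits = tree_splits(rep_tree.newick)
        for s in base_splits:
            if s in rep_splits:
                counts[s] += 1
    base.supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return base


def identity_matrix(sequences: list[tuple[str, str]],
                    protein: bool = False) -> tuple[list[str], np.ndarray,
                                                    float, float]:
    """Global pairwise identities: (labels, matrix, mean, sd).

    Equal-length sequences compare column-wise; otherwise each pair is
    globally aligned first.  Mean and sd summarise the off-diagonal pairs.
    """
    if len(sequences) < 2:
        raise ValueError("need >= 2 sequences")
    labels = [n for n, _ in sequences]
    n = len(labels)
    mat = np.full((n, n), 100.0)
    aligner = None
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sequences[i][1], sequences[j][1]
            if len(a) == len(b):
                ident = 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
            else:
                if aligner is None:
                    aligner = (protein_aligner if protein
                               else nucleotide_aligner)("global")
                aln = next(iter(aligner.align(a, b)))
                counts = aln.counts()
                cols = counts.identities + counts.mismatches + counts.gaps
                ident = 100.0 * counts.identities / cols
            mat[i, j] = mat[j, i] = ident
            vals.append(ident)
    arr = np.array(vals)
    return labels, mat, float(arr.mean()), float(arr.std(ddof=1) if
                                                 len(vals) > 1 else 0.0)
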