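"""Packaged simulation scenarios with known ground truth.

``ht_scenario`` builds one sequence-level horizontal-transfer test case --
a dated host tree, clock-like control genes, and one element family either
inherited vertically or transferred between hosts diverged beyond the age
threshold -- and runs the full cluster-detection + verdict machinery on
it.  Power and specificity of the HT caller are measured by running it
over seed batches.

``demo_tree``/``demo_config`` define the end-to-end demonstration used by
the pipeline: five species, a young active mariner family in every genome
plus a Tigger family restricted to two sister species with one recent
transfer into a host diverged 110 Myr from the donor.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import seqs
from .census import CensusTable
from .ht import (ClusterElement, HTReport, HTThresholds,
                 find_candidate_clusters, ht_verdict)
from .synthetic import (HostTree, _Node, evolve_control_genes,
                        evolve_sequence_on_tree, simulate_host_tree)

__all__ = ["ht_scenario", "HTScenarioResult", "ht_power", "demo_tree",
           "demo_config"]

def _subtree_leaves(node) -> list[str]:
    if node.label is not None:
        return [node.label]
    return [l for c in node.children for l in _subtree_leaves(c)]


def _sister_pairs(tree: HostTree) -> set[frozenset]:
    """Leaf pairs forming a cherry in the host topology."""
    out: set[frozenset] = set()

    def walk(node):
        if node.label is not None:
            return
        kids = node.children
        if len(kids) == 2 and all(k.label is not None for k in kids):
            out.add(frozenset((kids[0].label, kids[1].label)))
        for k in kids:
            walk(k)

    walk(tree.root)
    return out


def _are_cherry_after_prune(tree: HostTree, keep: list[str],
                            a: str, b: str) -> bool:
    """Are ``a`` and ``b`` adjacent in the unrooted topology induced on
    ``keep``?  (Adjacent = the pair {a, b} is itself a bipartition side,
    so moving one next to the other changes nothing.)"""
    from .phylo import tree_splits
    induced = tree.induced_newick({sp: [sp] for sp in keep})
    full = frozenset(keep)
    pair = frozenset((a, b))
    for side in tree_splits(induced):
        if side == pair or full - side == pair:
            return True
    return False


def _containing_clade_labels(tree: HostTree, a: str, b: str) -> list[str]:
    """Leaves of the smallest clade containing both species."""
    def walk(node):
        if node.label is not None:
            return ([node.label], None)
        leaves = []
        for child in node.children:
            got, found = walk(child)
            if found is not None:
                return ([], found)
            leaves.extend(got)
        if a in leaves and b in leaves:
            return ([], leaves)
        return (leaves, None)

    _, clade = walk(tree.root)
    return clade if clade is not None else list(tree.labels)


TE_RATE = 0.002        # subs/site/Myr, neutral decay of a dead element copy
GENE_RATE = 0.002      # subs/site/Myr for the conserved control genes
GENE_LENGTH = 1500
N_GENES = 20


@dataclass
class HTScenarioResult:
    detected: bool                  # any cluster judged HT-supported
    n_clusters: int
    reports: list[HTReport]
    donor: str | None
    recipient: str | None


def ht_scenario(seed: int, ht: bool = True, residual: float = 0.05,
                n_species: int = 6, root_age: float = 110.0,
                te_length: int = 1000, n_genes: int = N_GENES,
                gene_length: int = GENE_LENGTH,
                thresholds: HTThresholds = HTThresholds(),
                ) -> HTScenarioResult:
    """One simulated HT (or vertical-only) test case, fully analysed.

    The family is present in all but one randomly chosen species (so a
    patchy distribution exists in both arms of the experiment and cannot
    by itself separate them).  In the HT arm, one element from a host pair
    diverged at least ``thresholds.age`` Myr is replaced by a copy of the
    donor's element carrying only ``residual`` substitutions/site.
    """
    master = np.random.default_rng(seed)
    tree = simulate_host_tree(n_species, root_age,
                              int(master.integers(2**31)))
    genes = evolve_control_genes(tree, n_genes, gene_length, GENE_RATE,
                                 int(master.integers(2**31)))
    donor = recipient = None
    if ht:
        # HT between topological sister species cannot produce tree
        # incongruence (the transferred element lands exactly where
        # vertical descent would put it), so the event class is deep
        # non-sister host pairs.
        sisters = _sister_pairs(tree)
        deep_pairs = [(a, b) for i, a in enumerate(tree.labels)
                      for b in tree.labels[i + 1:]
                      if tree.divergence_time(a, b) >= thresholds.age
                      and frozenset((a, b)) not in sisters]
        if not deep_pairs:
            raise RuntimeError("tree has no deep non-sister host pair")
        # patchiness is judged inside the members' containing clade, so
        # the family gap goes inside the donor/recipient clade -- but not
        # at a species whose removal would leave donor and recipient
        # adjacent in the induced topology (that would erase the
        # incongruence signal along with the gap)
        options: list[tuple[str, str, str]] = []
        for a, b in deep_pairs:
            clade = _containing_clade_labels(tree, a, b)
            for gap in sorted(set(clade) - {a, b}):
                keep = [sp for sp in tree.labels if sp != gap]
                if not _are_cherry_after_prune(tree, keep, a, b):
                    options.append((a, b, gap))
        if not options:
            raise RuntimeError("no viable donor/recipient/gap combination")
        donor, recipient, absent_choice = \
            options[int(master.integers(len(options)))]
        candidates = [absent_choice]
    else:
        candidates = []
        for child in tree.root.children:
            leaves = _subtree_leaves(child)
            if len(leaves) >= 2:
                candidates.extend(leaves)
        candidates = sorted(candidates)
    absent = candidates[int(master.integers(len(candidates)))]
    present = [sp for sp in tree.labels if sp != absent]
    root_seq = seqs.random_seq(te_length, 0.4,
                               np.random.default_rng(
                                   int(master.integers(2**31))))
    leaf_seqs = evolve_sequence_on_tree(tree, root_seq, TE_RATE,
                                        int(master.integers(2**31)))
    if ht:
        rng = np.random.default_rng(int(master.integers(2**31)))
        ht_codes = seqs.mutate_k2p_exact(
            seqs.seq_to_codes(leaf_seqs[donor]), residual, rng)
        leaf_seqs[recipient] = seqs.codes_to_seq(ht_codes)
    elements = [ClusterElement(f"Tigger_{sp}", sp, leaf_seqs[sp])
                for sp in present]
    census = CensusTable.from_counts(
        {(sp, "Tigger"): (1, 1) for sp in present}, species=tree.labels)
    clusters = find_candidate_clusters(elements, tree, thresholds,
                                       family="Tigger")
    reports = [ht_verdict(c, tree, census, genes, thresholds)
               for c in clusters]
    detected = any(r.verdict == "HT-supported" for r in reports)
    return HTScenarioResult(detected, len(clusters), reports,
                            donor, recipient)


def ht_power(n_seeds: int = 100, base_seed: int = 0, ht: bool = True,
             residual: float = 0.05, **kwargs) -> float:
    """Fraction of seeded scenarios called HT-supported."""
    hits = 0
    for i in range(n_seeds):
        res = ht_scenario(base_seed * 100_003 + i, ht=ht,
                          residual=residual, **kwargs)
        hits += res.detected
    return hits / n_seeds


# ---------------------------------------------------------------------------
# End-to-end demonstration scenario
# ---------------------------------------------------------------------------

def demo_tree() -> HostTree:
    """Fixed five-species dated tree for the packaged demonstration.

    ((sp01,sp02) at 30 Myr, ((sp03,sp04) at 20, sp05) at 55) rooted at
    110 Myr -- sp01 and sp03 are separated by the root age, the "distantly
    related hosts sharing a near-identical element" configuration.
    """
    sp = {i: _Node(0.0, label=f"sp{i:02d}") for i in range(1, 6)}
    left = _Node(30.0, children=[sp[1], sp[2]])
    inner = _Node(20.0, children=[sp[3], sp[4]])
    right = _Node(55.0, children=[inner, sp[5]])
    root = _Node(110.0, children=[left, right])
    return HostTree(root, [f"sp{i:02d}" for i in range(1, 6)], 110.0)


def demo_config(seed: int = 1, output_dir: str = "demo_out") -> dict:
    """Configuration dict for the packaged run-all demonstration.

    mariner: young, active, in every genome (2 intact copies + 1
    frameshifted per species).  Tigger: vertical in sp01, sp02 and sp05
    (both sides of the root, so the host topology constrains the family
    tree), with one recent transfer (residual divergence 0.005) from
    sp01 into sp03 -- hosts diverged 110 Myr -- and absent from sp04, so
    all three HT conditions are on the table: the transferred copy nests
    inside the sp01/sp02 side of the family tree while its host sits on
    the other side of the root.
    """
    return {
        "seed": seed,
        "output_dir": output_dir,
        "synthetic": {
            "tree": "demo",
            "genome_length": 300_000,
            "gc": 0.35,
            "families": [
                {"family": "mariner", "mode": "tree",
                 "copies_per_species": 3, "rate": TE_RATE,
                 "within_divergence": 0.015,
                 "defective_fraction": 0.34,
                 "defective_mode": "frameshift",
                 "species": "all"},
                {"family": "Tigger", "mode": "tree",
                 "copies_per_species": 2, "rate": TE_RATE,
                 "within_divergence": 0.015,
                 "defective_fraction": 0.0,
                 "species": ["sp01", "sp02", "sp05"],
                 "ht_events": [
                     {"donor": "sp01", "recipient": "sp03",
                      "residual_divergence": 0.005}]},
            ],
            "control_genes": {"n_genes": N_GENES,
                              "length_bp": GENE_LENGTH,
                              "rate": GENE_RATE},
        },
    }
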