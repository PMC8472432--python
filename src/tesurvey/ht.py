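"""Horizontal-transfer inference via host-gene distance controls.

A horizontal transfer (HT) is called on the paper-style three conditions:
(1) high sequence similarity between elements from taxa whose divergence
exceeds an age threshold (default 100 Myr, identity >= 80%); (2)
incongruence between the element tree and the host tree (Robinson-Foulds
distance > 0); (3) a patchy taxonomic distribution (the family is absent
from at least one surveyed species inside the members' smallest containing
host clade).  A verdict of "HT-supported" additionally requires the
element distances to sit significantly below conserved host-gene distances
for the same species pairs (one-factor ANOVA, p < 0.05, with per-gene
Welch t-tests under Holm correction).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .census import CensusTable, kimura2p
from .phylo import (align_nucleotides, distance_matrix, identity_matrix,
                    neighbor_joining, robinson_foulds)
from .synthetic import HostTree

__all__ = ["ClusterElement", "HTCluster", "HTThresholds", "HTDistanceTest",
           "HTReport", "ht_distance_test", "find_candidate_clusters",
           "species_pair_distances", "ht_verdict"]


@dataclass(frozen=True)
class ClusterElement:
    label: str
    species: str
    seq: str          # element or transposase nucleotide sequence


@dataclass
class HTCluster:
    family: str
    members: list[ClusterElement]     # the high-identity candidate subgroup
    elements: list[ClusterElement]    # all surveyed elements of the family


@dataclass(frozen=True)
class HTThresholds:
    identity: float = 80.0    # percent, condition 1
    age: float = 100.0        # Myr, minimum host divergence for condition 1
    alpha: float = 0.05       # distance-test significance level


@dataclass
class PerGeneResult:
    gene: str
    mean_gene: float
    mean_te: float
    p_holm: float | None
    te_lower: bool            # significantly lower TE distance


@dataclass
class HTDistanceTest:
    f_stat: float | None
    p_value: float | None
    grouping: str             # "per_gene" | "pooled"
    per_gene: list[PerGeneResult] = field(default_factory=list)
    undefined: bool = False
    reason: str = ""

    @property
    def significant(self) -> bool:
        return (not self.undefined and self.p_value is not None
                and self.p_value < 0.05)


def ht_distance_test(te_distances: list[float],
                     gene_distances: dict[str, list[float]],
                     grouping: str = "auto",
                     alpha: float = 0.05) -> HTDistanceTest:
    """One-factor ANOVA of element vs host-gene pairwise distances.

    ``per_gene`` grouping treats each control gene as its own factor
    level; ``pooled`` collapses all genes into one level (needed when only
    one species pair exists).  ``auto`` picks per_gene when the element
    group has >= 2 values.  Per-gene Welch t-tests (TE vs gene) with Holm
    correction flag which genes the element distances undercut.
    """
    te = [d for d in te_distances if d is not None and not math.isnan(d)]
    genes = {g: [d for d in v if d is not None and not math.isnan(d)]
             for g, v in gene_distances.items()}
    genes = {g: v for g, v in genes.items() if v}
    if not te or not genes:
        return HTDistanceTest(None, None, "none", undefined=True,
                              reason="empty element or gene distance set")
    if grouping == "auto":
        grouping = "per_gene" if len(te) >= 2 else "pooled"
    if grouping == "per_gene":
        groups = [te] + list(genes.values())
    elif grouping == "pooled":
        groups = [te, [d for v in genes.values() for d in v]]
    else:
        raise ValueError(f"unknown grouping: {grouping}")
    n_total = sum(len(g) for g in groups)
    if n_total - len(groups) < 1 or len(groups) < 2:
        return HTDistanceTest(None, None, grouping, undefined=True,
                              reason="no residual degrees of freedom")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if np.allclose(pooled.var(), 0.0):
        return HTDistanceTest(None, None, grouping, undefined=True,
                              reason="zero variance in every group")
    f_stat, p_value = stats.f_oneway(*groups)
    if math.isnan(f_stat):
        return HTDistanceTest(None, None, grouping, undefined=True,
                              reason="ANOVA undefined on these groups")
    per_gene: list[PerGeneResult] = []
    raw_p = []
    usable = []
    mean_te = float(np.mean(te))
    for g, vals in genes.items():
        if len(te) >= 2 and len(vals) >= 2:
            _t, p = stats.ttest_ind(te, vals, equal_var=False)
            raw_p.append(p)
            usable.append(g)
        per_gene.append(PerGeneResult(g, float(np.mean(vals)), mean_te,
                                      None, False))
    if raw_p:
        from statsmodels.stats.multitest import multipletests
        reject, p_adj, _a, _b = multipletests(raw_p, alpha=alpha,
                                              method="holm")
        adj = dict(zip(usable, zip(p_adj, reject)))
        for res in per_gene:
            if res.gene in adj:
                p_holm, rej = adj[res.gene]
                res.p_holm = float(p_holm)
                res.te_lower = bool(rej) and res.mean_te < res.mean_gene
    return HTDistanceTest(float(f_stat), float(p_value), grouping,
                          per_gene=per_gene)


def find_candidate_clusters(elements: list[ClusterElement],
                            host_tree: HostTree,
                            thresholds: HTThresholds = HTThresholds(),
                            family: str = "") -> list[HTCluster]:
    """High-identity cross-taxon groups worth testing for HT.

    A cluster is seeded by any element pair from species diverged at least
    ``thresholds.age`` Myr with pairwise identity >= ``thresholds.identity``
    (the anomaly vertical inheritance cannot produce), then expanded with
    any element at that identity to a member (recent same-lineage
    companions), by connected components.
    """
    if len(elements) < 2:
        return []
    labels, mat, _m, _s = identity_matrix([(e.label, e.seq)
                                           for e in elements])
    by_label = {e.label: e for e in elements}
    n = len(labels)
    seeds: set[int] = set()
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            ei, ej = by_label[labels[i]], by_label[labels[j]]
            if mat[i, j] < thresholds.identity:
                continue
            adj[i].add(j)
            adj[j].add(i)
            if ei.species != ej.species and host_tree.divergence_time(
                    ei.species, ej.species) >= thresholds.age:
                seeds.update((i, j))
    clusters: list[HTCluster] = []
    seen: set[int] = set()
    for s in sorted(seeds):
        if s in seen:
            continue
        comp = {s}
        stack = [s]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in comp:
                    comp.add(y)
                    stack.append(y)
        seen |= comp
        members = [by_label[labels[i]] for i in sorted(comp)]
        clusters.append(HTCluster(family=family, members=members,
                                  elements=list(elements)))
    return clusters


def species_pair_distances(genes: dict[str, dict[str, str]],
                           pairs: list[tuple[str, str]],
                           ) -> dict[str, list[float]]:
    """Per-gene K2P distances for the given species pairs.

    Orthologs of unequal length are aligned (MAFFT) before the distance;
    the synthetic generator's genes are already length-matched.
    """
    out: dict[str, list[float]] = {}
    for gene, per_species in genes.items():
        needed = sorted({s for p in pairs for s in p})
        seqs = [(sp, per_species[sp]) for sp in needed if sp in per_species]
        aligned = dict(align_nucleotides(seqs)) if seqs else {}
        vals = []
        for a, b in pairs:
            if a not in aligned or b not in aligned:
                vals.append(float("nan"))
                continue
            res = kimura2p(aligned[a], aligned[b])
            vals.append(res.k if res.k is not None else float("nan"))
        out[gene] = vals
    return out


@dataclass
class HTReport:
    cluster_family: str
    members: list[str]
    member_species: list[str]
    te_pair_distances: dict[str, float]
    identity_mean: float
    identity_sd: float
    deep_pair_identity_mean: float | None
    condition_high_identity: bool
    rf_distance: int | None
    condition_incongruent: bool
    absent_species: list[str]
    condition_patchy: bool
    distance_test: HTDistanceTest
    verdict: str          # "HT-supported" | "vertical/unresolved" | ...

    def to_json(self, path=None) -> str:
        payload = {
            "family": self.cluster_family,
            "members": self.members,
            "member_species": self.member_species,
            "te_pair_distances": self.te_pair_distances,
            "identity_mean": self.identity_mean,
            "identity_sd": self.identity_sd,
            "deep_pair_identity_mean": self.deep_pair_identity_mean,
            "conditions": {
                "high_identity_across_divergent_taxa":
                    self.condition_high_identity,
                "tree_incongruence": self.condition_incongruent,
                "patchy_distribution": self.condition_patchy,
            },
            "rf_distance": self.rf_distance,
            "absent_species": self.absent_species,
            "distance_test": {
                "f": self.distance_test.f_stat,
                "p": self.distance_test.p_value,
                "grouping": self.distance_test.grouping,
                "undefined": self.distance_test.undefined,
                "per_gene": [
                    {"gene": r.gene, "mean_gene": r.mean_gene,
                     "mean_te": r.mean_te, "p_holm": r.p_holm,
                     "te_significantly_lower": r.te_lower}
                    for r in self.distance_test.per_gene],
            },
            "verdict": self.verdict,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def ht_verdict(cluster: HTCluster, host_tree: HostTree, census: CensusTable,
               control_genes: dict[str, dict[str, str]],
               thresholds: HTThresholds = HTThresholds()) -> HTReport:
    """Assemble the full evidence table and three-condition verdict.

    Condition 1 uses the cluster members; condition 2 compares the
    neighbor-joining tree of ALL surveyed family elements against the host
    topology induced on their species; condition 3 asks the census whether
    the family is missing from a surveyed species inside the members'
    smallest containing host clade.  "HT-supported" requires all three
    plus a significant distance test with the element mean below the
    pooled gene mean.
    """
    member_species = sorted({m.species for m in cluster.members})
    labels, mat, ident_mean, ident_sd = identity_matrix(
        [(m.label, m.seq) for m in cluster.members]) \
        if len(cluster.members) >= 2 else ([m.label for m in
                                            cluster.members],
                                           np.full((1, 1), 100.0), 100.0, 0.0)
    if len(member_species) < 2:
        test = HTDistanceTest(None, None, "none", undefined=True,
                              reason="cluster spans a single species")
        return HTReport(cluster.family, [m.label for m in cluster.members],
                        member_species, {}, ident_mean, ident_sd, None,
                        False, None, False, [], False, test,
                        "not-applicable")

    by_label = {m.label: m for m in cluster.members}
    deep_idents = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = by_label[labels[i]], by_label[labels[j]]
            if a.species == b.species:
                continue
            if host_tree.divergence_time(a.species, b.species) \
                    >= thresholds.age:
                deep_idents.append(mat[i, j])
    deep_mean = float(np.mean(deep_idents)) if deep_idents else None
    cond1 = deep_mean is not None and deep_mean >= thresholds.identity

    # condition 2: family tree vs induced host topology
    rf = None
    cond2 = False
    if len(cluster.elements) >= 4:
        aligned = align_nucleotides([(e.label, e.seq)
                                     for e in cluster.elements])
        dm = distance_matrix(aligned, model="k2p")
        if not dm.saturated:
            te_tree = neighbor_joining(dm)
            groups: dict[str, list[str]] = {}
            for e in cluster.elements:
                groups.setdefault(e.species, []).append(e.label)
            host_nw = host_tree.induced_newick(groups)
            rf = robinson_foulds(te_tree.newick, host_nw)
            cond2 = rf > 0

    # condition 3: patchiness inside the members' containing clade
    clade = _containing_clade(host_tree, member_species)
    surveyed = set(census.species)
    absent = sorted(sp for sp in clade
                    if sp in surveyed
                    and not census.present(sp, cluster.family))
    cond3 = len(absent) >= 1

    # Distance test on cross-species member pairs.  Only pairs old enough
    # for vertical decay to matter (host divergence >= the age threshold)
    # carry signal: shallow companion pairs have element distances that
    # legitimately match gene distances and only dilute the comparison.
    member_aligned = dict(align_nucleotides(
        [(m.label, m.seq) for m in cluster.members]))

    def collect(min_age: float):
        pairs: list[tuple[str, str]] = []
        te_dists: dict[str, float] = {}
        te_vals: list[float] = []
        done = set()
        for i, mi in enumerate(cluster.members):
            for mj in cluster.members[i + 1:]:
                if mi.species == mj.species:
                    continue
                if host_tree.divergence_time(mi.species,
                                             mj.species) < min_age:
                    continue
                key = tuple(sorted((mi.species, mj.species)))
                res = kimura2p(member_aligned[mi.label],
                               member_aligned[mj.label])
                d = res.k if res.k is not None else float("nan")
                te_dists[f"{mi.label}|{mj.label}"] = d
                te_vals.append(d)
                if key not in done:
                    done.add(key)
                    pairs.append(key)
        return pairs, te_dists, te_vals

    pairs, te_dists, te_vals = collect(thresholds.age)
    if not pairs:
        pairs, te_dists, te_vals = collect(0.0)
    gene_dists = species_pair_distances(control_genes, pairs) \
        if control_genes else {}
    test = ht_distance_test(te_vals, gene_dists, alpha=thresholds.alpha) \
        if gene_dists else HTDistanceTest(None, None, "none", undefined=True,
                                          reason="no control genes")
    te_lower_overall = False
    if not test.undefined:
        gene_all = [d for v in gene_dists.values() for d in v
                    if not math.isnan(d)]
        te_clean = [d for d in te_vals if not math.isnan(d)]
        te_lower_overall = (np.mean(te_clean) < np.mean(gene_all)
                            if te_clean and gene_all else False)
    supported = (cond1 and cond2 and cond3 and test.significant
                 and te_lower_overall)
    return HTReport(
        cluster_family=cluster.family,
        members=[m.label for m in cluster.members],
        member_species=member_species,
        te_pair_distances=te_dists,
        identity_mean=ident_mean, identity_sd=ident_sd,
        deep_pair_identity_mean=deep_mean,
        condition_high_identity=cond1,
        rf_distance=rf, condition_incongruent=cond2,
        absent_species=absent, condition_patchy=cond3,
        distance_test=test,
        verdict="HT-supported" if supported else "vertical/unresolved")


def _containing_clade(tree: HostTree, species: list[str]) -> list[str]:
    """Leaves of the smallest host clade containing all given species."""
    want = set(species)

    def walk(node):
        if node.label is not None:
            return ({node.label}, None)
        leaves = set()
        for child in node.children:
            got, found = walk(child)
            if found is not None:
                return (set(), found)
            leaves |= got
        if want <= leaves:
            return (set(), sorted(leaves))
        return (leaves, None)

    _, clade = walk(tree.root)
    return clade if clade is not None else list(tree.labels)
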