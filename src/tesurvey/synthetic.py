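"""Synthetic genomes with planted DNA transposons and complete ground truth.

The generator emulates the study conditions a pogo / Tc1/mariner survey
faces: several host genomes related by a dated ultrametric tree, element
copies planted per family with TA target-site duplications, terminal
inverted repeats, a transposase ORF with a conserved DDE/D triad, family
signature pentanucleotides, configurable nucleotide divergence, a
configurable fraction of defective copies, clock-like conserved host genes,
and optional horizontal-transfer events placing near-identical elements in
distantly related hosts.

Two planting modes are provided.  ``plant_elements`` mutates every copy
independently from the family progenitor (a star phylogeny: right for
recall/census/classification experiments with a controlled per-copy
divergence).  ``plant_family_on_tree`` evolves a functional master lineage
along the host tree -- triad and signature conserved, TIR arms kept
reverse-complementary -- and drops recently amplified copies in each host,
so cross-species element distances track the host tree as they do for a
vertically inherited family.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seqs
from .references import FAMILIES, ReferenceTransposase, build_reference_set

__all__ = [
    "HostTree", "GenomeRecord", "ElementSpec", "TruthRecord", "HTEvent",
    "SyntheticTruth", "simulate_host_tree", "synthesize_genomes",
    "default_spec", "build_progenitor", "plant_elements",
    "plant_family_on_tree", "simulate_ht_event", "evolve_control_genes",
    "write_genomes", "write_control_genes",
]

_EDGE_MARGIN = 2500   # bp kept free of insertions at contig ends
_MIN_GAP = 3000       # bp between planted copies (keeps loci and HSPs apart)


# ---------------------------------------------------------------------------
# Host tree
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("age", "children", "label")

    def __init__(self, age, children=None, label=None):
        self.age = age
        self.children = children or []
        self.label = label


@dataclass
class HostTree:
    """Dated ultrametric species tree (branch lengths in Myr)."""
    root: _Node
    labels: list[str]
    root_age: float

    def __post_init__(self):
        self._mrca: dict[tuple[str, str], float] = {}
        self._collect_mrca(self.root)

    def _collect_mrca(self, node) -> list[str]:
        if node.label is not None:
            return [node.label]
        groups = [self._collect_mrca(c) for c in node.children]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for a in groups[i]:
                    for b in groups[j]:
                        key = (a, b) if a < b else (b, a)
                        self._mrca[key] = node.age
        return [x for g in groups for x in g]

    def divergence_time(self, a: str, b: str) -> float:
        """Age (Myr) of the most recent common ancestor of two species."""
        if a == b:
            return 0.0
        return self._mrca[(a, b) if a < b else (b, a)]

    def newick(self) -> str:
        def fmt(node, parent_age):
            if node.label is not None:
                return f"{node.label}:{parent_age - node.age:.6f}"
            inner = ",".join(fmt(c, node.age) for c in node.children)
            return f"({inner}):{parent_age - node.age:.6f}"
        inner = ",".join(fmt(c, self.root.age) for c in self.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, newick: str) -> "HostTree":
        """Build from a dated (ultrametric) newick string.

        Node ages are recovered from root-to-node depths; the deepest
        leaf defines the root age and all leaves are assumed coeval.
        """
        import dendropy
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        depths: dict[int, float] = {}

        def depth_of(node):
            if node.parent_node is None:
                return 0.0
            return depths[id(node.parent_node)] + (node.edge.length or 0.0)

        for node in dtree.preorder_node_iter():
            depths[id(node)] = depth_of(node)
        root_age = max(depths[id(l)] for l in dtree.leaf_node_iter())

        def convert(node):
            if node.is_leaf():
                return _Node(0.0, label=node.taxon.label)
            return _Node(root_age - depths[id(node)],
                         children=[convert(c) for c in node.child_nodes()])

        root = convert(dtree.seed_node)
        labels = sorted(l.taxon.label for l in dtree.leaf_node_iter())
        return cls(root, labels, float(root_age))

    def induced_newick(self, members: dict[str, list[str]]) -> str:
        """Topology restricted to ``members`` species, leaves relabelled.

        ``members`` maps species to the element labels it contributes;
        several elements in one species become a multifurcating tip group.
        Branch lengths are dropped (topology-only, for RF comparisons).
        """
        def prune(node):
            if node.label is not None:
                if node.label not in members:
                    return None
                tips = members[node.label]
                if len(tips) == 1:
                    return tips[0]
                return "(" + ",".join(tips) + ")"
            kept = [p for p in (prune(c) for c in node.children) if p]
            if not kept:
                return None
            if len(kept) == 1:
                return kept[0]
            return "(" + ",".join(kept) + ")"
        out = prune(self.root)
        if out is None:
            raise ValueError("no member species found in tree")
        return out + ";"


def simulate_host_tree(n_species: int, root_age: float, seed: int) -> HostTree:
    """Random dated binary ultrametric tree with ``n_species`` leaves.

    Coalescent-style construction: lineage pairs are merged at node ages
    drawn uniformly on (0, root_age), the final merge at exactly
    ``root_age``, so every root-to-leaf path sums to the root age.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if root_age <= 0:
        raise ValueError("root_age must be > 0")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_species)))
    labels = [f"sp{i + 1:0{width}d}" for i in range(n_species)]
    nodes = [_Node(0.0, label=l) for l in labels]
    inner = sorted(rng.uniform(0, root_age, size=n_species - 2).tolist())
    for age in inner + [float(root_age)]:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        merged = _Node(age, children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return HostTree(nodes[0], labels, float(root_age))


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

@dataclass
class GenomeRecord:
    """One species' assembly: contig name -> ACGT sequence."""
    species: str
    contigs: dict[str, str]

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


def synthesize_genomes(tree: HostTree, length_bp: int, gc: float = 0.35,
                       seed: int = 0) -> list[GenomeRecord]:
    """One random genome per tree leaf (single contig, i.i.d. bases).

    The default GC of 0.35 mirrors AT-rich bee genomes; purely a default.
    """
    if length_bp < 10_000:
        raise ValueError("length_bp must be >= 10000")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    master = np.random.default_rng(seed)
    out = []
    for label in tree.labels:
        child = np.random.default_rng(master.integers(2**31))
        out.append(GenomeRecord(label, {"c1": seqs.random_seq(length_bp, gc, child)}))
    return out


# ---------------------------------------------------------------------------
# Element specification and progenitor construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementSpec:
    """Structural blueprint of a transposon family's exemplar element."""
    family: str
    spacing: int             # residues between 2nd and 3rd catalytic residue
    third: str               # D or E
    transposase_aa: int
    tir_bp: int
    tsd: str = "TA"
    signature: str | None = None   # 5' pentanucleotide, if the family has one
    element_bp: int = 1500

    def __post_init__(self):
        if self.third not in "DE":
            raise ValueError("third residue must be D or E")
        if self.tir_bp < 10:
            raise ValueError("TIR length must be >= 10 bp")
        if self.transposase_aa < 300:
            raise ValueError("transposase must be >= 300 aa for intact copies")


def default_spec(family: str) -> ElementSpec:
    fam = FAMILIES[family]
    return ElementSpec(
        family=family, spacing=fam.canonical, third=fam.third,
        transposase_aa=fam.transposase_aa, tir_bp=fam.tir_bp,
        signature=fam.signatures[0] if fam.signatures else None,
        element_bp=fam.element_bp)


@dataclass(frozen=True)
class Progenitor:
    """A full-length progenitor element with structural annotation."""
    spec: ElementSpec
    seq: str
    orf: tuple[int, int]          # coding span (stop excluded), 0-based
    protein: str
    triad_nt: tuple[int, ...]     # nt indices of the three triad codons
    protected: np.ndarray         # sites never mutated in derived copies

    @property
    def codes(self) -> np.ndarray:
        return seqs.seq_to_codes(self.seq)

    @property
    def tir(self) -> str:
        return self.seq[:self.spec.tir_bp]


_PROGENITORS: dict[str, Progenitor] = {}


def build_progenitor(spec: ElementSpec,
                     reference: ReferenceTransposase | None = None) -> Progenitor:
    """Deterministically construct the family progenitor element.

    Layout: TIR + spacer + TAA + coding sequence + TAA + spacer + rc(TIR),
    with in-frame stops bounding the ORF so the longest stop-free span
    equals the transposase exactly.  The left TIR begins with the family
    signature pentanucleotide when one is defined.
    """
    if spec.family in _PROGENITORS and reference is None:
        return _PROGENITORS[spec.family]
    if reference is None:
        reference = next(r for r in build_reference_set()
                         if r.family == spec.family)
    digest = hashlib.sha256(f"tesurvey-prog-{spec.family}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:4], "big"))
    protein = reference.protein[:spec.transposase_aa]
    tir = spec.signature or ""
    tir += seqs.random_seq(spec.tir_bp - len(tir), 0.5, rng)
    cds = seqs.back_translate(protein, rng)
    fixed = 2 * spec.tir_bp + 6 + len(cds)
    rem = spec.element_bp - fixed
    if rem < 20:
        raise ValueError("element_bp too small for TIRs + ORF")
    sp1 = seqs.random_seq(rem // 2, 0.4, rng)
    sp2 = seqs.random_seq(rem - rem // 2, 0.4, rng)
    seq = tir + sp1 + "TAA" + cds + "TAA" + sp2 + seqs.revcomp(tir)
    orf_start = spec.tir_bp + len(sp1) + 3
    orf = (orf_start, orf_start + len(cds))
    triad_nt = tuple(orf_start + 3 * p + k
                     for p in reference.triad for k in range(3))
    protected = sorted(set(triad_nt)
                       | set(range(orf_start - 3, orf_start))      # 5' stop
                       | set(range(orf[1], orf[1] + 3))            # 3' stop
                       | (set(range(len(spec.signature)))
                          if spec.signature else set()))
    prog = Progenitor(spec, seq, orf, protein, triad_nt,
                      np.array(protected, dtype=int))
    if reference.family == spec.family:
        _PROGENITORS[spec.family] = prog
    return prog


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    species: str
    contig: str
    start: int       # 0-based half-open interval of the element itself
    end: int
    strand: str
    family: str
    divergence: float    # realized K2P distance to the progenitor
    intact: bool
    origin: str = "vertical"   # or "ht"


@dataclass
class HTEvent:
    donor: str
    recipient: str
    family: str
    residual_divergence: float


@dataclass
class SyntheticTruth:
    """Everything the generator knows about what it planted."""
    records: list[TruthRecord] = field(default_factory=list)
    ht_events: list[HTEvent] = field(default_factory=list)
    species: list[str] = field(default_factory=list)

    def for_species(self, species: str) -> list[TruthRecord]:
        return [r for r in self.records if r.species == species]

    def census(self) -> pd.DataFrame:
        """Copy / intact-copy counts per (species, family)."""
        rows = []
        fams = sorted({r.family for r in self.records})
        for sp in self.species or sorted({r.species for r in self.records}):
            for fam in fams:
                recs = [r for r in self.records
                        if r.species == sp and r.family == fam]
                rows.append({"species": sp, "family": fam,
                             "copies": len(recs),
                             "intact": sum(r.intact for r in recs)})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        # written 1-based inclusive, per the report coordinate convention
        with open(path, "w") as fh:
            fh.write("species\tcontig\tstart\tend\tstrand\tfamily"
                     "\tdivergence\tintact\torigin\n")
            for r in self.records:
                fh.write(f"{r.species}\t{r.contig}\t{r.start + 1}\t{r.end}"
                         f"\t{r.strand}\t{r.family}\t{r.divergence:.4f}"
                         f"\t{int(r.intact)}\t{r.origin}\n")

    def to_json(self, path) -> None:
        payload = {
            "records": [vars(r) for r in self.records],
            "ht_events": [vars(e) for e in self.ht_events],
            "species": self.species,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


class CapacityError(RuntimeError):
    """Genome too small to host the requested copies."""


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def _estimate_k2p(a: np.ndarray, b: np.ndarray) -> float:
    """Closed-form K2P estimate between equal-length code arrays."""
    n = a.size
    x = a ^ b
    p = float(np.count_nonzero(x == 2)) / n
    q = float(np.count_nonzero((x == 1) | (x == 3))) / n
    arg = (1 - 2 * p - q) * math.sqrt(max(1 - 2 * q, 0.0))
    if arg <= 0:
        return float("inf")
    return -0.5 * math.log(arg)


def _pick_positions(occupied: list[tuple[int, int]], contig_len: int,
                    n: int, insert_len: int,
                    rng: np.random.Generator) -> list[int]:
    """Non-overlapping insertion points with margins; CapacityError if stuck."""
    chosen: list[int] = []
    lo = _EDGE_MARGIN
    hi = contig_len - _EDGE_MARGIN - insert_len
    if hi - lo < n * (insert_len + _MIN_GAP):
        raise CapacityError("genome too small for requested copies")
    for _ in range(n):
        for _try in range(200):
            pos = int(rng.integers(lo, hi))
            ok = all(abs(pos - c) >= insert_len + _MIN_GAP for c in chosen)
            ok = ok and all(pos + insert_len + _MIN_GAP <= s
                            or pos >= e + _MIN_GAP
                            for s, e in occupied)
            if ok:
                chosen.append(pos)
                break
        else:
            raise CapacityError("could not place copy without overlap")
    return sorted(chosen)


def _insert_copies(genome: GenomeRecord, contig: str,
                   inserts: list[tuple[int, str, dict]],
                   truth: SyntheticTruth, tsd: str) -> None:
    """Splice TSD-flanked copies into a contig, shifting prior truth."""
    inserts = sorted(inserts, key=lambda t: t[0])
    seq = genome.contigs[contig]
    pieces, cursor, offset = [], 0, 0
    for pos, elem, meta in inserts:
        pieces.append(seq[cursor:pos])
        insert_str = tsd + elem + tsd
        start = pos + offset + len(tsd)
        truth.records.append(TruthRecord(
            species=genome.species, contig=contig,
            start=start, end=start + len(elem), **meta))
        pieces.append(insert_str)
        offset += len(insert_str)
        cursor = pos
    pieces.append(seq[cursor:])
    genome.contigs[contig] = "".join(pieces)


def _shift_existing(truth: SyntheticTruth, species: str, contig: str,
                    inserts: list[tuple[int, int]]) -> None:
    """Shift prior truth intervals for insertions at (pos, total_len)."""
    for rec in truth.records:
        if rec.species != species or rec.contig != contig:
            continue
        delta = sum(L for pos, L in inserts if pos <= rec.start)
        rec.start += delta
        rec.end += delta


def _make_defective(elem: str, orf: tuple[int, int], mode: str,
                    rng: np.random.Generator) -> str:
    """Frameshift (middle third of the ORF) or 3' 60% truncation.

    The frameshift position is restricted to the middle third so that no
    stop-free span of >=300 aa can survive: a shift near the ORF terminus
    would leave a copy that still satisfies the intact-transposase rule.
    """
    if mode == "mixed":
        mode = "frameshift" if rng.random() < 0.5 else "truncation"
    if mode == "frameshift":
        s, e = orf
        span = e - s
        pos = s + int(rng.integers(span // 3, 2 * span // 3))
        base = "ACGT"[rng.integers(4)]
        return elem[:pos] + base + elem[pos:]
    if mode == "truncation":
        return elem[:int(len(elem) * 0.4)]
    raise ValueError(f"unknown defective mode: {mode}")


def plant_elements(genomes: list[GenomeRecord], spec: ElementSpec,
                   copies_per_species: int,
                   divergence: float | list[float],
                   defective_fraction: float = 0.0, seed: int = 0,
                   truth: SyntheticTruth | None = None,
                   defective_mode: str = "mixed",
                   ) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """Plant TSD-flanked copies of a family, star-wise from the progenitor.

    Each copy is mutated independently to its target K2P divergence (exact
    substitution counts, so the realized divergence is within +/-0.02 of
    target for kilobase-scale elements).  Signature pentanucleotide, triad
    codons and the ORF-bounding stops are held invariant; in-frame stop
    creation inside the ORF is rejected so intact copies stay intact.
    ``defective_fraction`` of the copies (rounded to the nearest count per
    species) get a frameshift or a 3' 60% truncation instead.
    """
    if truth is None:
        truth = SyntheticTruth(species=[g.species for g in genomes])
    prog = build_progenitor(spec)
    prog_codes = prog.codes
    divs = (list(divergence) if isinstance(divergence, (list, tuple))
            else [float(divergence)] * copies_per_species)
    if len(divs) != copies_per_species:
        raise ValueError("divergence list length != copies_per_species")
    if any(d < 0 for d in divs):
        raise ValueError("divergence must be >= 0")
    master = np.random.default_rng(seed)
    n_def = round(defective_fraction * copies_per_species)
    for genome in genomes:
        rng = np.random.default_rng(master.integers(2**31))
        contig = next(iter(genome.contigs))
        occupied = [(r.start, r.end) for r in truth.records
                    if r.species == genome.species and r.contig == contig]
        positions = _pick_positions(occupied, len(genome.contigs[contig]),
                                    copies_per_species, len(prog.seq), rng)
        defect_idx = set(rng.choice(copies_per_species, size=n_def,
                                    replace=False).tolist()) if n_def else set()
        inserts, shifts = [], []
        for i, pos in enumerate(positions):
            codes = seqs.mutate_k2p_exact(prog_codes, divs[i], rng,
                                          protected=prog.protected,
                                          orf=prog.orf)
            realized = _estimate_k2p(prog_codes, codes)
            elem = seqs.codes_to_seq(codes)
            intact = True
            if i in defect_idx:
                elem = _make_defective(elem, prog.orf, defective_mode, rng)
                intact = False
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                elem = seqs.revcomp(elem)
            meta = {"strand": strand, "family": spec.family,
                    "divergence": realized, "intact": intact}
            inserts.append((pos, elem, meta))
            shifts.append((pos, len(elem) + 2 * len(spec.tsd)))
        _shift_existing(truth, genome.species, contig, shifts)
        _insert_copies(genome, contig, inserts, truth, spec.tsd)
    return genomes, truth


def plant_family_on_tree(genomes: list[GenomeRecord], tree: HostTree,
                         spec: ElementSpec, copies_per_species: int = 1,
                         rate: float = 0.002, within_divergence: float = 0.01,
                         defective_fraction: float = 0.0, seed: int = 0,
                         species: list[str] | None = None,
                         truth: SyntheticTruth | None = None,
                         defective_mode: str = "frameshift",
                         ht_events: list[tuple[str, str, float]] = (),
                         ) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """Plant a vertically inherited family along the host tree.

    A functional master lineage evolves from the progenitor at ``rate``
    substitutions/site/Myr: its triad, signature and ORF stay intact and
    its TIR arms mutate mirrored (reverse complementarity is a functional
    constraint on a transposition-competent element).  Each listed species
    receives ``copies_per_species`` recently amplified copies at
    ``within_divergence`` from its master.  ``ht_events`` is a list of
    ``(donor, recipient, residual_divergence)`` horizontal transfers: the
    recipient gains one copy derived from the donor's master state.
    """
    if truth is None:
        truth = SyntheticTruth(species=[g.species for g in genomes])
    chosen = set(species if species is not None else tree.labels)
    unknown = chosen - set(tree.labels)
    if unknown:
        raise KeyError(f"unknown species: {sorted(unknown)}")
    prog = build_progenitor(spec)
    L = len(prog.seq)
    mirror = (0, spec.tir_bp, L - spec.tir_bp, L)
    master = np.random.default_rng(seed)
    by_species = {g.species: g for g in genomes}

    leaf_states: dict[str, np.ndarray] = {}

    def descend(node, state):
        if node.label is not None:
            leaf_states[node.label] = state
            return
        for child in node.children:
            d = rate * (node.age - (child.age if child.label is None else 0.0))
            rng = np.random.default_rng(master.integers(2**31))
            descend(child, seqs.evolve_k2p(
                state, d, rng, protected=prog.protected, orf=prog.orf,
                mirror=mirror))

    descend(tree.root, prog.codes)

    def drop_copies(sp, source_codes, n, origin, within=None):
        genome = by_species[sp]
        rng = np.random.default_rng(master.integers(2**31))
        contig = next(iter(genome.contigs))
        occupied = [(r.start, r.end) for r in truth.records
                    if r.species == sp and r.contig == contig]
        positions = _pick_positions(occupied, len(genome.contigs[contig]),
                                    n, L, rng)
        n_def = round(defective_fraction * n) if origin == "vertical" else 0
        defect_idx = set(rng.choice(n, size=n_def, replace=False).tolist()) \
            if n_def else set()
        if within is None:
            within = within_divergence
        inserts, shifts = [], []
        for i, pos in enumerate(positions):
            codes = seqs.mutate_k2p_exact(source_codes, within,
                                          rng, protected=prog.protected,
                                          orf=prog.orf)
            realized = _estimate_k2p(prog.codes, codes)
            elem = seqs.codes_to_seq(codes)
            intact = True
            if i in defect_idx:
                elem = _make_defective(elem, prog.orf, defective_mode, rng)
                intact = False
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                elem = seqs.revcomp(elem)
            meta = {"strand": strand, "family": spec.family,
                    "divergence": realized, "intact": intact,
                    "origin": origin}
            inserts.append((pos, elem, meta))
            shifts.append((pos, len(elem) + 2 * len(spec.tsd)))
        _shift_existing(truth, sp, contig, shifts)
        _insert_copies(genome, contig, inserts, truth, spec.tsd)

    for sp in tree.labels:
        if sp in chosen:
            drop_copies(sp, leaf_states[sp], copies_per_species, "vertical")
    for donor, recipient, residual in ht_events:
        if donor not in leaf_states or recipient not in by_species:
            raise KeyError(f"unknown species in HT event: {donor}->{recipient}")
        rng = np.random.default_rng(master.integers(2**31))
        ht_codes = seqs.mutate_k2p_exact(leaf_states[donor], residual, rng,
                                         protected=prog.protected,
                                         orf=prog.orf)
        drop_copies(recipient, ht_codes, 1, "ht", within=0.0)
        truth.ht_events.append(HTEvent(donor, recipient, spec.family,
                                       float(residual)))
    return genomes, truth


def simulate_ht_event(genomes: list[GenomeRecord], donor: str, recipient: str,
                      spec: ElementSpec, residual_divergence: float,
                      seed: int = 0, truth: SyntheticTruth | None = None,
                      donor_state: np.ndarray | None = None,
                      ) -> tuple[list[GenomeRecord], HTEvent]:
    """Insert one horizontally transferred copy into the recipient genome.

    The copy derives from ``donor_state`` (default: the family progenitor,
    i.e. a star-mode donor) with ``residual_divergence`` of post-transfer
    mutation, so its K2P distance to the donor element is close to the
    residual regardless of how long ago the hosts split.
    """
    if donor == recipient:
        raise ValueError("donor and recipient must differ")
    species = {g.species for g in genomes}
    if donor not in species or recipient not in species:
        raise KeyError("donor and recipient must both be in the genome set")
    if truth is None:
        truth = SyntheticTruth(species=sorted(species))
    prog = build_progenitor(spec)
    source = prog.codes if donor_state is None else donor_state
    rng = np.random.default_rng(seed)
    codes = seqs.mutate_k2p_exact(source, residual_divergence, rng,
                                  protected=prog.protected, orf=prog.orf)
    elem = seqs.codes_to_seq(codes)
    genome = next(g for g in genomes if g.species == recipient)
    contig = next(iter(genome.contigs))
    occupied = [(r.start, r.end) for r in truth.records
                if r.species == recipient and r.contig == contig]
    pos = _pick_positions(occupied, len(genome.contigs[contig]), 1,
                          len(elem), rng)[0]
    _shift_existing(truth, recipient, contig,
                    [(pos, len(elem) + 2 * len(spec.tsd))])
    meta = {"strand": "+", "family": spec.family,
            "divergence": _estimate_k2p(prog.codes, codes),
            "intact": True, "origin": "ht"}
    _insert_copies(genome, contig, [(pos, elem, meta)], truth, spec.tsd)
    event = HTEvent(donor, recipient, spec.family, float(residual_divergence))
    truth.ht_events.append(event)
    return genomes, event


# ---------------------------------------------------------------------------
# Control genes
# ---------------------------------------------------------------------------

def evolve_sequence_on_tree(tree: HostTree, root_seq: str, rate: float,
                            seed: int = 0) -> dict[str, str]:
    """Neutral K2P evolution of one sequence along the host tree.

    Returns the leaf states (species -> sequence); expected pairwise
    distance between two leaves is 2 * rate * divergence time.
    """
    rng = np.random.default_rng(seed)
    leaves: dict[str, str] = {}

    def descend(node, state):
        if node.label is not None:
            leaves[node.label] = seqs.codes_to_seq(state)
            return
        for child in node.children:
            child_age = 0.0 if child.label is not None else child.age
            d = rate * (node.age - child_age)
            descend(child, seqs.evolve_k2p(state, d, rng))

    descend(tree.root, seqs.seq_to_codes(root_seq))
    return leaves


def evolve_control_genes(tree: HostTree, n_genes: int, length_bp: int,
                         rate: float, seed: int = 0,
                         ) -> dict[str, dict[str, str]]:
    """Clock-like orthologs: gene name -> species -> sequence.

    Each gene starts from a random root sequence and evolves along every
    branch under K2P at ``rate`` substitutions/site/Myr, so the expected
    pairwise distance between two species is 2 * rate * divergence time.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    master = np.random.default_rng(seed)
    genes: dict[str, dict[str, str]] = {}
    width = len(str(n_genes))
    for g in range(n_genes):
        rng = np.random.default_rng(master.integers(2**31))
        root = seqs.seq_to_codes(seqs.random_seq(length_bp, 0.42, rng))
        leaves: dict[str, str] = {}

        def descend(node, state):
            if node.label is not None:
                leaves[node.label] = seqs.codes_to_seq(state)
                return
            for child in node.children:
                child_age = 0.0 if child.label is not None else child.age
                d = rate * (node.age - child_age)
                descend(child, seqs.evolve_k2p(state, d, rng))

        descend(tree.root, root)
        genes[f"gene{g + 1:0{width}d}"] = leaves
    return genes


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_genomes(genomes: list[GenomeRecord], directory) -> list[str]:
    """One FASTA per species; returns the written paths."""
    import os
    paths = []
    for g in genomes:
        path = os.path.join(str(directory), f"{g.species}.fa")
        with open(path, "w") as fh:
            for contig, seq in g.contigs.items():
                fh.write(f">{g.species}|{contig}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        paths.append(path)
    return paths


def write_control_genes(genes: dict[str, dict[str, str]], directory) -> list[str]:
    """One multi-FASTA per gene; returns the written paths."""
    import os
    paths = []
    for gene, per_species in genes.items():
        path = os.path.join(str(directory), f"{gene}.fa")
        with open(path, "w") as fh:
            for sp, seq in per_species.items():
                fh.write(f">{sp}\n{seq}\n")
        paths.append(path)
    return paths
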