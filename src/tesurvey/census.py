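"""Copy census, Kimura two-parameter distances and divergence landscapes.

A "copy" follows the survey convention: a nucleotide BLAST match of the
family consensus against the genome with >=80% identity and >=40% query
coverage (both configurable).  An "intact copy" additionally carries a
frameshift-free transposase of >=300 aa flanked by both TIR arms; that flag
is determined by the element builder/classifier and attached here.

The divergence landscape bins each copy's K2P distance to the consensus
(percent scale, 1%-wide bins by default) and weighs bins by the genome
fraction the copies occupy -- low-divergence mass means recent
transpositional activity.
"""
from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .synthetic import GenomeRecord

__all__ = ["K2PResult", "CopyRecord", "CensusTable", "DivergenceProfile",
           "kimura2p", "count_copies", "divergence_landscape",
           "UndefinedDistanceError"]

_GAPLIKE = set("-.Nn")


class UndefinedDistanceError(ValueError):
    """No comparable columns after pairwise deletion."""


@dataclass(frozen=True)
class K2PResult:
    p: float              # transition proportion
    q: float              # transversion proportion
    k: float | None       # Kimura distance; None when saturated
    n_sites: int          # comparable columns after pairwise deletion
    saturated: bool

    def __iter__(self):   # allows  P, Q, K = kimura2p(a, b)
        return iter((self.p, self.q, self.k))


_PURINE = {"A", "G"}
_PYRIMIDINE = {"C", "T"}


def kimura2p(seq_a: str, seq_b: str) -> K2PResult:
    """K2P distance between two aligned sequences (pairwise deletion).

    Columns with a gap or ambiguity symbol in either sequence are excluded.
    K = -1/2 ln((1-2P-Q) sqrt(1-2Q)); if the log argument is non-positive
    the pair is flagged saturated and K is left unset.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    n = ts = tv = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in _GAPLIKE or b in _GAPLIKE:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINE) == (b in _PURINE):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise UndefinedDistanceError("no comparable columns")
    p, q = ts / n, tv / n
    arg = (1 - 2 * p - q) * math.sqrt(max(1 - 2 * q, 0.0))
    if arg <= 0:
        return K2PResult(p, q, None, n, True)
    return K2PResult(p, q, -0.5 * math.log(arg), n, False)


@dataclass
class CopyRecord:
    species: str
    contig: str
    start: int            # 0-based half-open on the genome
    end: int
    strand: str
    identity: float       # percent, gap columns count as mismatches
    coverage: float       # percent of the consensus covered
    score: float
    k2p: K2PResult
    aligned_bp: int
    intact: bool | None = None


def _require_blastn() -> str:
    path = shutil.which("blastn")
    if path is None:
        raise RuntimeError("blastn not found on PATH; the copy census "
                           "requires the NCBI BLAST+ suite")
    return path


def _chain_hsps(rows, qlen, max_gap):
    """Chain same-strand HSPs within ``max_gap`` bp into per-copy clusters."""
    clusters = []
    for (contig, strand), group in rows.items():
        group.sort(key=lambda r: r["sstart"])
        current = [group[0]]
        for r in group[1:]:
            if r["sstart"] - max(x["send"] for x in current) <= max_gap:
                current.append(r)
            else:
                clusters.append((contig, strand, current))
                current = [r]
        clusters.append((contig, strand, current))
    out = []
    for contig, strand, hsps in clusters:
        qiv = []
        for r in hsps:
            qiv.append((min(r["qstart"], r["qend"]) - 1,
                        max(r["qstart"], r["qend"])))
        qiv.sort()
        covered, hi = 0, -1
        for s, e in qiv:
            s = max(s, hi)
            if e > s:
                covered += e - s
                hi = e
            hi = max(hi, e)
        length = sum(r["length"] for r in hsps)
        ident = sum(r["pident"] * r["length"] for r in hsps) / length
        qseq = "".join(r["qseq"] for r in hsps)
        sseq = "".join(r["sseq"] for r in hsps)
        out.append({
            "contig": contig, "strand": strand,
            "sstart": min(r["sstart"] for r in hsps) - 1,
            "send": max(r["send"] for r in hsps),
            "identity": ident, "coverage": 100.0 * covered / qlen,
            "score": sum(r["bitscore"] for r in hsps),
            "aligned_bp": length, "qseq": qseq, "sseq": sseq,
        })
    return out


def count_copies(genome: GenomeRecord, consensus: str,
                 min_identity: float = 80.0, min_coverage: float = 40.0,
                 max_gap: int = 1500) -> list[CopyRecord]:
    """Census one family consensus against one genome with blastn.

    HSPs on the same contig/strand within ``max_gap`` bp are chained first
    (a single diverged copy is often reported as several HSPs), then the
    identity/coverage thresholds are applied to the chained records, and
    overlapping surviving records collapse to the best-scoring one.
    """
    if len(consensus) < 100:
        raise ValueError("consensus must be >= 100 bp")
    _require_blastn()
    with tempfile.TemporaryDirectory() as tmp:
        qpath, spath = Path(tmp) / "q.fa", Path(tmp) / "s.fa"
        qpath.write_text(f">consensus\n{consensus}\n")
        with open(spath, "w") as fh:
            for contig, seq in genome.contigs.items():
                fh.write(f">{contig}\n{seq}\n")
        proc = subprocess.run(
            ["blastn", "-task", "blastn", "-query", str(qpath),
             "-subject", str(spath), "-evalue", "1e-5",
             "-dust", "no", "-soft_masking", "false",
             "-outfmt",
             "6 sseqid pident length qstart qend sstart send bitscore qseq sseq"],
            capture_output=True, text=True, check=True)
    rows: dict[tuple[str, str], list[dict]] = {}
    for line in proc.stdout.splitlines():
        f = line.rstrip("\n").split("\t")
        sstart, send = int(f[5]), int(f[6])
        strand = "+" if send >= sstart else "-"
        if strand == "-":
            sstart, send = send, sstart
        rows.setdefault((f[0], strand), []).append({
            "pident": float(f[1]), "length": int(f[2]),
            "qstart": int(f[3]), "qend": int(f[4]),
            "sstart": sstart, "send": send,
            "bitscore": float(f[7]), "qseq": f[8], "sseq": f[9]})
    if not rows:
        return []
    chained = _chain_hsps(rows, len(consensus), max_gap)
    kept = [c for c in chained
            if c["identity"] >= min_identity and c["coverage"] >= min_coverage]
    # collapse overlaps (same contig, either strand): best score wins
    kept.sort(key=lambda c: -c["score"])
    final = []
    for c in kept:
        if any(f["contig"] == c["contig"]
               and c["sstart"] < f["send"] and f["sstart"] < c["send"]
               for f in final):
            continue
        final.append(c)
    final.sort(key=lambda c: (c["contig"], c["sstart"]))
    return [CopyRecord(
        species=genome.species, contig=c["contig"], start=c["sstart"],
        end=c["send"], strand=c["strand"], identity=c["identity"],
        coverage=c["coverage"], score=c["score"],
        k2p=kimura2p(c["qseq"], c["sseq"]), aligned_bp=c["aligned_bp"],
    ) for c in final]


@dataclass
class CensusTable:
    """Per (species, family) copy and intact-copy counts."""
    frame: pd.DataFrame   # columns: species, family, copies, intact

    @classmethod
    def from_counts(cls, counts: dict[tuple[str, str], tuple[int, int]],
                    species: list[str] | None = None) -> "CensusTable":
        rows = [{"species": sp, "family": fam, "copies": c, "intact": i}
                for (sp, fam), (c, i) in sorted(counts.items())]
        df = pd.DataFrame(rows, columns=["species", "family", "copies",
                                         "intact"])
        if species:
            seen = set(df["species"])
            extra = [{"species": sp, "family": "", "copies": 0, "intact": 0}
                     for sp in species if sp not in seen]
            if extra:
                df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
        return cls(df)

    @property
    def species(self) -> list[str]:
        return sorted(self.frame["species"].unique())

    def copies(self, species: str, family: str) -> int:
        sel = self.frame[(self.frame.species == species)
                         & (self.frame.family == family)]
        return int(sel["copies"].sum())

    def present(self, species: str, family: str) -> bool:
        return self.copies(species, family) > 0

    def to_tsv(self, path) -> None:
        """Write in the per-family-column layout of a survey copy table."""
        fams = sorted(f for f in self.frame["family"].unique() if f)
        with open(path, "w") as fh:
            fh.write("species\tmetric\t" + "\t".join(fams) + "\n")
            for sp in self.species:
                for metric in ("copies", "intact"):
                    vals = []
                    for fam in fams:
                        sel = self.frame[(self.frame.species == sp)
                                         & (self.frame.family == fam)]
                        vals.append(str(int(sel[metric].sum())))
                    label = ("copy number" if metric == "copies"
                             else "intact copy number")
                    fh.write(f"{sp}\t{label}\t" + "\t".join(vals) + "\n")


@dataclass
class DivergenceProfile:
    """Histogram of genome percentage per K2P-divergence bin."""
    family: str
    species: str
    k_values: list[float] = field(default_factory=list)
    bin_width: float = 1.0                 # on the percent scale
    bins: dict[int, float] = field(default_factory=dict)
    saturated: int = 0

    @property
    def total_mass(self) -> float:
        return sum(self.bins.values())

    def mode_bin(self) -> int | None:
        if not self.bins:
            return None
        return max(self.bins, key=lambda b: (self.bins[b], -b))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kimura_bin_pct\tgenome_pct\n")
            for b in sorted(self.bins):
                fh.write(f"{b * self.bin_width:g}\t{self.bins[b]:.6f}\n")


def divergence_landscape(records: list[CopyRecord], genome_length: int,
                         bin_width: float = 1.0, family: str = "",
                         species: str = "") -> DivergenceProfile:
    """Bin copy K2P divergences (percent scale) by genome-percentage mass."""
    prof = DivergenceProfile(family=family, species=species,
                             bin_width=bin_width)
    for rec in records:
        if rec.k2p.saturated or rec.k2p.k is None:
            prof.saturated += 1
            continue
        k_pct = 100.0 * rec.k2p.k
        b = int(k_pct // bin_width)
        prof.k_values.append(rec.k2p.k)
        prof.bins[b] = prof.bins.get(b, 0.0) \
            + 100.0 * rec.aligned_bp / genome_length
    return prof
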