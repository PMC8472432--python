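"""Reference transposases and the DD-spacing family table.

The classification scheme for pogo and Tc1/mariner DNA transposons encodes
the catalytic triad geometry in the family name: ``DD{n}{D|E}`` means two
aspartates followed, ``n`` residues later, by a third aspartate (D) or
glutamate (E).  The table below carries the spacing ranges observed for the
in-scope families (Tigger and Fot of pogo; mariner, maT, GT, VS, Tc1, IC,
IT of Tc1/mariner, plus TR and TRT for completeness) together with the 5'
signature pentanucleotides that some families conserve: maT elements start
with CAGGG, IT with CACTA or CACTG, GT with CTCCC.

The shipped reference set (``data/synthetic_references.*``) is synthetic:
randomly generated transposase proteins with the catalytic triad planted at
the family's canonical spacing.  It stands in for curated exemplar
transposases, which keeps the package self-contained; the classification
logic only relies on the annotated triad positions and spacing ranges.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .seqs import random_protein

POGO = "pogo"
TC1M = "Tc1/mariner"


@dataclass(frozen=True)
class FamilyDef:
    """Static description of one transposon family."""
    family: str
    superfamily: str
    n_min: int
    n_max: int
    third: str           # expected third catalytic residue, D or E
    canonical: int       # spacing used for the synthetic exemplar
    signatures: tuple[str, ...]  # allowed 5' pentanucleotides ( () = none )
    transposase_aa: int  # exemplar transposase length
    tir_bp: int          # exemplar TIR arm length
    element_bp: int      # exemplar full element length


#: In-scope families first (plantable), then reference-only families.
FAMILY_TABLE: tuple[FamilyDef, ...] = (
    FamilyDef("Tigger", POGO, 29, 36, "D", 30, (), 480, 28, 2400),
    FamilyDef("Fot", POGO, 35, 36, "D", 35, (), 440, 24, 2200),
    FamilyDef("mariner", TC1M, 34, 34, "D", 34, (), 345, 28, 1400),
    FamilyDef("maT", TC1M, 37, 37, "D", 37, ("CAGGG",), 340, 26, 1400),
    FamilyDef("GT", TC1M, 39, 39, "D", 39, ("CTCCC",), 350, 30, 2000),
    FamilyDef("VS", TC1M, 40, 41, "D", 41, (), 345, 30, 1600),
    FamilyDef("Tc1", TC1M, 34, 34, "E", 34, (), 340, 30, 1700),
    FamilyDef("IC", TC1M, 36, 36, "E", 36, (), 340, 26, 1500),
    FamilyDef("IT", TC1M, 38, 38, "E", 38, ("CACTA", "CACTG"), 340, 26, 1500),
    FamilyDef("TR", TC1M, 35, 35, "E", 35, (), 340, 28, 1500),
    FamilyDef("TRT", TC1M, 37, 37, "E", 37, (), 340, 28, 1500),
)

FAMILIES: dict[str, FamilyDef] = {f.family: f for f in FAMILY_TABLE}
#: families the synthetic generator can plant (surveyed in-scope set)
PLANTABLE = tuple(f.family for f in FAMILY_TABLE[:9])


@dataclass(frozen=True)
class ReferenceTransposase:
    """An exemplar transposase with an annotated catalytic triad."""
    family: str
    superfamily: str
    protein: str
    triad: tuple[int, int, int]  # 0-based indices into ``protein``
    n_min: int
    n_max: int
    third: str

    def __post_init__(self):
        p1, p2, p3 = self.triad
        if not (self.protein[p1] == "D" and self.protein[p2] == "D"):
            raise ValueError(f"{self.family}: first two triad residues must be D")
        if self.protein[p3] not in "DE":
            raise ValueError(f"{self.family}: third triad residue must be D or E")

    @property
    def spacing(self) -> int:
        return self.triad[2] - self.triad[1]


def _family_rng(family: str) -> np.random.Generator:
    # stable per-family stream, independent of any user seed
    digest = hashlib.sha256(f"tesurvey-ref-{family}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def build_reference_set() -> list[ReferenceTransposase]:
    """Deterministically regenerate the synthetic reference transposases."""
    refs = []
    for fam in FAMILY_TABLE:
        rng = _family_rng(fam.family)
        length = fam.transposase_aa
        prot = list("M" + random_protein(length - 1, rng))
        p1 = int(rng.integers(100, 140))
        p2 = p1 + int(rng.integers(85, 105))
        p3 = p2 + fam.canonical
        if p3 >= length - 20:
            raise AssertionError("triad does not fit exemplar length")
        prot[p1] = "D"
        prot[p2] = "D"
        prot[p3] = fam.third
        refs.append(ReferenceTransposase(
            fam.family, fam.superfamily, "".join(prot), (p1, p2, p3),
            fam.n_min, fam.n_max, fam.third))
    return refs


def write_reference_files(fasta_path, tsv_path) -> None:
    """Export the reference set as FASTA plus a TSV annotation table.

    Triad positions are written 1-based, matching the written-report
    coordinate convention used across the package.
    """
    refs = build_reference_set()
    with open(fasta_path, "w") as fh:
        for r in refs:
            fh.write(f">{r.family}\n{r.protein}\n")
    with open(tsv_path, "w") as fh:
        fh.write("family\tsuperfamily\td1\td2\tde3\tn_min\tn_max\tthird\n")
        for r in refs:
            p1, p2, p3 = (i + 1 for i in r.triad)
            fh.write(f"{r.family}\t{r.superfamily}\t{p1}\t{p2}\t{p3}"
                     f"\t{r.n_min}\t{r.n_max}\t{r.third}\n")


def load_references(fasta_path=None, tsv_path=None) -> list[ReferenceTransposase]:
    """Load a reference set (defaults to the packaged synthetic exemplars)."""
    if fasta_path is None:
        pkg = resources.files("tesurvey") / "data"
        fasta_path = pkg / "synthetic_references.faa"
        tsv_path = pkg / "synthetic_references.tsv"
    seqs: dict[str, str] = {}
    name = None
    for line in str(fasta_path.read_text() if hasattr(fasta_path, "read_text")
                    else open(fasta_path).read()).splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name is not None:
            seqs[name] += line.strip()
    refs = []
    text = (tsv_path.read_text() if hasattr(tsv_path, "read_text")
            else open(tsv_path).read())
    for line in text.splitlines()[1:]:
        fam, sup, d1, d2, de3, n_min, n_max, third = line.split("\t")
        refs.append(ReferenceTransposase(
            fam, sup, seqs[fam], (int(d1) - 1, int(d2) - 1, int(de3) - 1),
            int(n_min), int(n_max), third))
    return refs
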