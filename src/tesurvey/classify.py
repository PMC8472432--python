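"""Family classification by DDE/D catalytic-triad spacing.

A transposase protein is aligned to each annotated reference; the best
reference's triad positions are mapped through the alignment onto the
query, the spacing ``n`` between the 2nd and 3rd catalytic residues is
read off, and the ``DD{n}{D|E}`` label is resolved against the family
spacing table.  Spacing is counted as the index difference between the
2nd and 3rd residues (an intervening-residue convention would differ by
one; ``spacing_offset`` exposes the toggle).  Structural signatures (the
5' pentanucleotide some families conserve) and the intact-copy rule
(frameshift-free transposase >=300 aa plus both TIR arms) live here too.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from ._align import protein_aligner
from .elements import ElementModel
from .references import FAMILIES, FAMILY_TABLE, ReferenceTransposase

__all__ = ["FamilyLabel", "TriadResult", "locate_catalytic_triad",
           "spacing_label", "assign_family", "check_signature", "is_intact",
           "classify_protein"]

SIGNATURES: dict[str, tuple[str, ...]] = {
    f.family: f.signatures for f in FAMILY_TABLE if f.signatures}

MIN_INTACT_AA = 300


@dataclass
class TriadResult:
    positions: tuple[int, int, int] | None   # 0-based indices in the query
    reference: ReferenceTransposase | None
    score: float
    reason: str = ""                         # set when positions is None

    @property
    def ok(self) -> bool:
        return self.positions is not None


@dataclass
class FamilyLabel:
    n: int
    third: str
    label: str                # "DD{n}{D|E}"
    family: str = ""          # filled by assign_family
    notes: list[str] = field(default_factory=list)


def locate_catalytic_triad(protein: str,
                           references: list[ReferenceTransposase],
                           score_floor: float = 50.0,
                           spacing_offset: int = 0) -> TriadResult:
    """Map a reference catalytic triad onto the query protein.

    Aligns the query against every reference (local, BLOSUM62), takes the
    best-scoring reference (ties break by family name so reference order
    never matters), and carries its annotated triad through the alignment
    columns.  Fails cleanly -- reason set, positions None -- if the best
    score is below ``score_floor``, a triad residue falls in a gap, or a
    mapped residue is not D/E.
    """
    if len(protein) < 100:
        raise ValueError("protein must be >= 100 aa")
    aligner = protein_aligner("local")
    best = None
    for ref in sorted(references, key=lambda r: r.family):
        alns = aligner.align(protein, ref.protein)
        try:
            aln = next(iter(alns))
        except StopIteration:
            continue
        if best is None or aln.score > best[0]:
            best = (float(aln.score), ref, aln)
    if best is None or best[0] < score_floor:
        return TriadResult(None, None, best[0] if best else 0.0,
                           "no reference alignment above score floor")
    score, ref, aln = best
    qblocks, tblocks = aln.aligned[0], aln.aligned[1]
    mapped = []
    for rpos in ref.triad:
        qpos = None
        for (qs, qe), (ts, te) in zip(qblocks, tblocks):
            if ts <= rpos < te:
                qpos = int(qs) + (rpos - int(ts))
                break
        if qpos is None:
            return TriadResult(None, ref, score,
                               "triad residue falls in an alignment gap")
        mapped.append(qpos)
    p1, p2, p3 = mapped
    p3 += spacing_offset
    if not (0 <= p3 < len(protein) and p1 < p2 < p3):
        return TriadResult(None, ref, score, "mapped triad out of order")
    if protein[p1] != "D" or protein[p2] != "D" or protein[p3] not in "DE":
        return TriadResult(None, ref, score,
                           "mapped residue is not D/E (triad degenerate)")
    return TriadResult((p1, p2, p3), ref, score)


def spacing_label(positions: tuple[int, int, int], protein: str) -> FamilyLabel:
    """``DD{n}{letter}`` with n = index difference of residues 2 and 3."""
    p1, p2, p3 = positions
    if not p1 < p2 < p3:
        raise ValueError("triad positions must be strictly increasing")
    if protein[p1] != "D" or protein[p2] != "D":
        raise ValueError("invalid triad: first two residues must be D")
    letter = protein[p3]
    if letter not in "DE":
        raise ValueError("invalid triad: third residue must be D or E")
    n = p3 - p2
    return FamilyLabel(n=n, third=letter, label=f"DD{n}{letter}")


def assign_family(label: FamilyLabel,
                  best_ref: ReferenceTransposase | None = None,
                  drift_tolerance: int = 2) -> FamilyLabel:
    """Resolve a spacing label against the family table.

    Overlapping ranges (e.g. DD35D fits both Fot and Tigger) resolve via
    the best-matching reference's family, then superfamily.  A label
    outside every range but within ``drift_tolerance`` of the best
    reference's range is assigned there and flagged drifted -- the
    bumblebee DD41D->DD40D and stingless-bee DD33D->DD33E cases.  Anything
    else comes back as ``novel:DD{n}{letter}``.
    """
    n, letter = label.n, label.third
    candidates = [f for f in FAMILY_TABLE
                  if f.n_min <= n <= f.n_max and f.third == letter]
    family = None
    if len(candidates) == 1:
        family = candidates[0].family
    elif candidates:
        names = {f.family for f in candidates}
        if best_ref and best_ref.family in names:
            family = best_ref.family
        elif best_ref:
            same_sf = [f for f in candidates
                       if f.superfamily == best_ref.superfamily]
            family = (min(f.family for f in same_sf) if same_sf
                      else min(names))
        else:
            family = min(names)
    elif best_ref is not None:
        ref_fam = FAMILIES[best_ref.family]
        if (ref_fam.n_min - drift_tolerance <= n
                <= ref_fam.n_max + drift_tolerance):
            family = best_ref.family
            label.notes.append("drifted")
    if family is None:
        label.family = f"novel:{label.label}"
        return label
    label.family = family
    if best_ref and best_ref.family == family and (
            n != best_ref.spacing or letter != best_ref.third):
        if "drifted" not in label.notes:
            label.notes.append("drifted")
    return label


def check_signature(element: ElementModel | str, family: str) -> str:
    """First-five-bases family signature: pass / fail / not-applicable.

    maT starts with CAGGG; IT with CACTA or CACTG; GT with CTCCC.
    Families without a defined signature, and boundary-less elements,
    are not-applicable.
    """
    sigs = SIGNATURES.get(family)
    if not sigs:
        return "not-applicable"
    if isinstance(element, ElementModel):
        if not element.boundary_called or not element.sequence:
            return "not-applicable"
        head = element.sequence[:5]
    else:
        head = element[:5]
    return "pass" if head.upper() in sigs else "fail"


def is_intact(element: ElementModel) -> bool:
    """Intact copy: frameshift-free transposase >=300 aa plus both TIRs."""
    return (element.orf is not None
            and element.orf.length_aa >= MIN_INTACT_AA
            and element.orf.frameshift_free
            and element.tir is not None)


def classify_protein(protein: str, references: list[ReferenceTransposase],
                     score_floor: float = 50.0) -> tuple[FamilyLabel | None,
                                                         TriadResult]:
    """Triad location + labelling + family assignment in one call."""
    triad = locate_catalytic_triad(protein, references, score_floor)
    if not triad.ok:
        return None, triad
    label = spacing_label(triad.positions, protein)
    return assign_family(label, triad.reference), triad
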