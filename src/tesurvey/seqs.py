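"""Low-level nucleotide and protein sequence machinery.

Sequences are plain Python strings at module boundaries; hot paths work on
uint8 code arrays (A=0, C=1, G=2, T=3).  With this encoding a transition is
``code ^ 2`` and the two transversions are ``code ^ 1`` and ``code ^ 3``,
which keeps the Kimura two-parameter mutation samplers branch-free.
"""
from __future__ import annotations

import math

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_table = CodonTable.unambiguous_dna_by_id[1]
#: amino acid -> list of codons (standard code, stops excluded)
CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_table.forward_table.items()):
    CODONS.setdefault(_aa, []).append(_codon)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def revcomp(seq: str) -> str:
    """Reverse complement (N and case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode ACGT string as uint8 codes; non-ACGT raises ValueError."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        raise ValueError("sequence contains non-ACGT symbols")
    return codes.copy()


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random nucleotide sequence with expected GC content ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return codes_to_seq(rng.choice(4, size=length, p=p).astype(np.uint8))


def gc_content(seq: str) -> float:
    n = len(seq)
    return (seq.count("G") + seq.count("C")) / n if n else 0.0


def translate(seq: str) -> str:
    """Translate a nucleotide string; non-ACGT symbols become X, stops '*'."""
    n = len(seq) - len(seq) % 3
    if n <= 0:
        return ""
    clean = "".join(c if c in "ACGT" else "N" for c in seq[:n]) \
        if any(c not in "ACGT" for c in seq[:n]) else seq[:n]
    return str(Seq(clean).translate())


def six_frame_translations(seq: str) -> list[tuple[str, int, str]]:
    """All six reading frames as ``(strand, frame, protein)`` tuples.

    ``frame`` is the 0-based offset on the given strand ('+' uses ``seq``
    itself, '-' uses its reverse complement).
    """
    out = []
    rc = revcomp(seq)
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            out.append((strand, frame, translate(s[frame:])))
    return out


def frame_to_genomic(aa_start: int, aa_end: int, frame: int, strand: str,
                     contig_length: int) -> tuple[int, int]:
    """Map an amino-acid span in a reading frame to 0-based genomic coords."""
    s = frame + 3 * aa_start
    e = frame + 3 * aa_end
    if strand == "+":
        return s, e
    return contig_length - e, contig_length - s


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Nucleotide coding sequence for a protein, codons drawn uniformly."""
    parts = []
    for aa in protein:
        codons = CODONS[aa]
        parts.append(codons[rng.integers(len(codons))])
    return "".join(parts)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


# ---------------------------------------------------------------------------
# Kimura two-parameter mutation model (generator side)
# ---------------------------------------------------------------------------

def k2p_expected_pq(distance: float, kappa: float = 2.0) -> tuple[float, float]:
    """Expected transition (P) and transversion (Q) proportions.

    For a K2P process run for total expected distance ``distance``
    substitutions/site with transition/transversion rate ratio ``kappa``.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    beta = distance / (kappa + 2.0)
    alpha = kappa * beta
    q = 0.5 - 0.5 * math.exp(-4.0 * beta)
    p = 0.25 + 0.25 * math.exp(-4.0 * beta) - 0.5 * math.exp(-2.0 * (alpha + beta))
    return p, q


def _fix_orf_stops(codes: np.ndarray, original: np.ndarray,
                   orf: tuple[int, int]) -> None:
    """Revert any mutation that created an in-frame stop codon inside ``orf``."""
    s, e = orf
    seq = codes_to_seq(codes[s:e])
    for i in range(0, e - s - 2, 3):
        if seq[i:i + 3] in STOP_CODONS:
            codes[s + i:s + i + 3] = original[s + i:s + i + 3]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    # complement: A<->T (0<->3), C<->G (1<->2)  ==  3 - code
    return (3 - codes[::-1]).astype(np.uint8)


def mutate_k2p_exact(codes: np.ndarray, distance: float,
                     rng: np.random.Generator, kappa: float = 2.0,
                     protected: np.ndarray | None = None,
                     orf: tuple[int, int] | None = None) -> np.ndarray:
    """Mutate so the realized K2P divergence matches ``distance`` closely.

    Applies exactly ``round(P*L)`` transitions and ``round(Q*L)``
    transversions at distinct unprotected sites, where P and Q are the
    expected proportions under the model.  Mutations that would create an
    in-frame stop codon inside ``orf`` are reverted (a handful at most, so
    the realized divergence stays within the contract's +/-0.02 band).
    """
    p, q = k2p_expected_pq(distance, kappa)
    n = codes.size
    n_ts = round(p * n)
    n_tv = round(q * n)
    out = codes.copy()
    allowed = np.ones(n, dtype=bool)
    if protected is not None:
        allowed[protected] = False
    pool = np.flatnonzero(allowed)
    if n_ts + n_tv > pool.size:
        raise ValueError("requested divergence exceeds mutable sites")
    sites = rng.choice(pool, size=n_ts + n_tv, replace=False)
    ts, tv = sites[:n_ts], sites[n_ts:]
    out[ts] ^= np.uint8(2)
    flips = np.where(rng.random(tv.size) < 0.5, 1, 3).astype(np.uint8)
    out[tv] ^= flips
    if orf is not None:
        _fix_orf_stops(out, codes, orf)
    return out


def evolve_k2p(codes: np.ndarray, distance: float, rng: np.random.Generator,
               kappa: float = 2.0, protected: np.ndarray | None = None,
               orf: tuple[int, int] | None = None,
               mirror: tuple[int, int, int, int] | None = None) -> np.ndarray:
    """One stochastic K2P step of expected length ``distance`` subs/site.

    Per-site multinomial draw from the exact K2P transition probabilities.
    ``mirror=(ls, le, rs, re)`` re-imposes reverse complementarity of the
    right block on the left one after mutation (terminal-inverted-repeat
    conservation in a functional master lineage).
    """
    p, q = k2p_expected_pq(distance, kappa)
    out = codes.copy()
    r = rng.random(codes.size)
    ts = r < p
    tv = (~ts) & (r < p + q)
    if protected is not None:
        ts[protected] = False
        tv[protected] = False
    out[ts] ^= np.uint8(2)
    idx = np.flatnonzero(tv)
    flips = np.where(rng.random(idx.size) < 0.5, 1, 3).astype(np.uint8)
    out[idx] ^= flips
    if orf is not None:
        _fix_orf_stops(out, codes, orf)
    if mirror is not None:
        ls, le, rs, re = mirror
        out[rs:re] = _revcomp_codes(out[ls:le])
    return out
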