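"""Shared alignment helpers: MAFFT wrapper and PairwiseAligner factories."""
from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices


def mafft(sequences: list[tuple[str, str]], protein: bool = False,
          ) -> list[tuple[str, str]]:
    """Multiple alignment via the MAFFT CLI (FFT-NS-2, deterministic).

    A single sequence is returned unchanged; equal-length inputs are NOT
    shortcut here (callers decide whether they are already aligned).
    """
    if len(sequences) == 1:
        return list(sequences)
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fa"
        with open(inp, "w") as fh:
            for name, seq in sequences:
                fh.write(f">{name}\n{seq}\n")
        mode = "--amino" if protein else "--nuc"
        proc = subprocess.run(
            ["mafft", "--quiet", "--retree", "2", "--maxiterate", "0",
             mode, str(inp)],
            capture_output=True, text=True, check=True)
    out: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            if name is not None:
                out.append((name, "".join(chunks).upper()))
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if name is not None:
        out.append((name, "".join(chunks).upper()))
    # mafft may reorder; restore input order
    order = {name: i for i, (name, _) in enumerate(sequences)}
    return sorted(out, key=lambda t: order[t[0]])


def protein_aligner(mode: str = "local") -> Align.PairwiseAligner:
    """BLOSUM62, affine gaps (open 11, extend 1)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def nucleotide_aligner(mode: str = "local") -> Align.PairwiseAligner:
    """BLAST-like nucleotide scoring: +2/-3, gap open 5 extend 2."""
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def alignment_identity(alignment) -> tuple[float, int]:
    """Percent identity over aligned columns and the column count."""
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return 0.0, 0
    return 100.0 * counts.identities / columns, columns
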