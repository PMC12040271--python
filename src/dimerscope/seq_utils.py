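"""Pairwise global sequence identity for model–template validation.

When a homology model is built, the percent identity between the target
sequence and the template chain is the first sanity number reported.  This
module computes it from a Needleman–Wunsch global alignment (BLOSUM62,
affine gaps: open −10, extend −0.5) via :class:`Bio.Align.PairwiseAligner`.

Identity is counted as identical aligned positions divided by alignment
columns *excluding terminal gap overhangs* — dangling unaligned termini
(e.g. a signal peptide absent from the crystal construct) do not dilute
the percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = ["SequencePair", "global_align_identity", "read_fasta_sequence"]

_VALID = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequencePair:
    """Two amino-acid sequences (one-letter codes, 20 standard + X)."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        for label, seq in ((self.id_a, self.seq_a), (self.id_b, self.seq_b)):
            if not seq:
                raise ValueError(f"sequence {label!r} is empty")
            bad = set(seq.upper()) - _VALID
            if bad:
                raise ValueError(f"sequence {label!r} has invalid letters {sorted(bad)}")


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align_identity(
    pair: SequencePair, gap_open: float = -10.0, gap_extend: float = -0.5
) -> float:
    """Percent identity from a global alignment of the pair.

    Returns identical columns / aligned columns (terminal overhangs
    excluded) × 100.
    """
    aligner = _make_aligner(gap_open, gap_extend)
    alignment = aligner.align(pair.seq_a.upper(), pair.seq_b.upper())[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])

    # trim terminal overhangs: columns where either row is still gap-only tail
    start = 0
    while row_a[start] == "-" or row_b[start] == "-":
        start += 1
    end = len(row_a)
    while row_a[end - 1] == "-" or row_b[end - 1] == "-":
        end -= 1
    row_a, row_b = row_a[start:end], row_b[start:end]
    if not row_a:
        return 0.0
    identical = sum(a == b and a != "-" for a, b in zip(row_a, row_b))
    return 100.0 * identical / len(row_a)


def read_fasta_sequence(path: str | Path) -> tuple[str, str]:
    """First record of a FASTA file as ``(id, sequence)``."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq)
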