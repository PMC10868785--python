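"""Small sequence utilities."""

from __future__ import annotations

from collections import Counter
from pathlib import Path

from Bio import SeqIO


def residue_composition(sequence: str, start: int = 1, end: int | None = None) -> dict[str, float]:
    """Percentage composition of a protein subsequence.

    ``start``/``end`` are 1-based inclusive residue coordinates. Returns a
    mapping of one-letter residue codes to percentages of the subsequence.
    """
    if start < 1:
        raise ValueError("start is 1-based and must be >= 1")
    sub = sequence[start - 1 : end] if end is not None else sequence[start - 1 :]
    if not sub:
        raise ValueError("empty subsequence")
    counts = Counter(sub.upper())
    total = len(sub)
    return {aa: 100.0 * n / total for aa, n in sorted(counts.items())}


def read_single_fasta(path: str | Path) -> str:
    """Read the single sequence of a FASTA file as a string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one sequence in {path}, found {len(records)}")
    return str(records[0].seq)
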