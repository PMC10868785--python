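"""sgRNA amplicon sequencing: read synthesis, spacer extraction, counting.

Sorted cell pools are sequenced as PCR amplicons of the integrated sgRNA
cassette. Each read is `left_flank + 20-nt spacer + right_flank` (the flanks
are the constant vector sequence around the spacer; defaults are the
lentiCRISPR U6 promoter tail and the sgRNA scaffold head). Counting trims
the flanks and matches the spacer against the library — exact hash match, or
optionally unique Hamming-distance-1 rescue. Ambiguous assignments are
dropped, never split. QC categories partition the reads:

    n_reads = n_assigned + n_flank_fail + n_no_match + n_ambiguous
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from pulsa_screen.screen_model import GuideLibrary

# constant vector sequence flanking the spacer in the amplicon (U6 tail /
# scaffold head of the lentiCRISPRv2 backbone)
DEFAULT_LEFT_FLANK = "TTGTGGAAAGGACGAAACACCG"
DEFAULT_RIGHT_FLANK = "GTTTTAGAGCTAGAAATAGCAAG"

FLANK_NOT_FOUND = "flank_not_found"
TRUNCATED = "truncated"
RIGHT_FLANK_MISMATCH = "right_flank_mismatch"

_BASE_TO_CODE = {b: i for i, b in enumerate("ACGT")}
_CODE_TO_BASE = np.array(list("ACGT"))


@dataclass(frozen=True)
class AmpliconDesign:
    """Constant amplicon structure around the programmable spacer."""

    left_flank: str = DEFAULT_LEFT_FLANK
    right_flank: str = DEFAULT_RIGHT_FLANK
    spacer_length: int = 20
    require_right_flank: bool = True

    def __post_init__(self) -> None:
        for name, flank in (("left_flank", self.left_flank), ("right_flank", self.right_flank)):
            if not flank or set(flank) - set("ACGT"):
                raise ValueError(f"{name} must be a non-empty ACGT string")
        if self.spacer_length < 1:
            raise ValueError("spacer_length must be >= 1")


@dataclass
class CountMatrix:
    """sgRNA x sample integer counts plus per-sample QC tallies.

    ``counts`` is indexed by guide_id with exactly the library's guides as
    rows (zeros allowed); ``qc`` maps sample -> the QC partition dict.
    """

    counts: pd.DataFrame
    qc: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate guide_ids in count matrix")
        vals = c.to_numpy()
        if vals.size and (not np.issubdtype(vals.dtype, np.integer)):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integral")
            self.counts = c.astype(np.int64)
        if vals.size and vals.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def guide_ids(self) -> np.ndarray:
        return self.counts.index.to_numpy()


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    """Write (read_id, sequence, quality) triples as 4-line FASTQ records."""
    n = 0
    with _open_text(path, "wt") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a (possibly gzipped) 4-line FASTQ file."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record near {header!r} in {path}")
            yield seq


def _proportional_allocation(tallies: np.ndarray, depth: int) -> np.ndarray:
    """Largest-remainder allocation of ``depth`` reads proportional to tallies."""
    total = tallies.sum()
    quota = tallies * (depth / total)
    base = np.floor(quota).astype(np.int64)
    short = depth - int(base.sum())
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def synthesize_reads(
    guide_tallies: Mapping[str, int] | pd.Series,
    library: GuideLibrary,
    design: AmpliconDesign,
    depth: int,
    error_rate: float = 0.0,
    seed: int = 0,
    read_length: int | None = None,
    exact_proportions: bool = False,
) -> list[tuple[str, str, str]]:
    """Sample ``depth`` amplicon reads from per-guide tallies.

    Reads are drawn multinomially from the tallies (or, with
    ``exact_proportions``, allocated deterministically by largest remainder)
    and built as flank + spacer + flank, padded with random bases up to
    ``read_length`` when given. Per-base substitution errors are applied at
    ``error_rate``; qualities are a constant 'I'.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    if depth == 0:
        return []
    tallies = pd.Series(guide_tallies, dtype=float).reindex(library.guide_ids, fill_value=0.0)
    if tallies.sum() <= 0:
        raise ValueError("all guide tallies are zero; nothing to sequence")
    rng = np.random.default_rng(seed)
    t = tallies.to_numpy()
    if exact_proportions:
        per_guide = _proportional_allocation(t, depth)
    else:
        per_guide = rng.multinomial(depth, t / t.sum())

    core_len = len(design.left_flank) + design.spacer_length + len(design.right_flank)
    length = core_len if read_length is None else int(read_length)
    if length < 1:
        raise ValueError("read_length must be >= 1")

    spacer_codes = np.array(
        [[_BASE_TO_CODE[b] for b in s] for s in library.spacers], dtype=np.int8
    )
    guide_per_read = np.repeat(np.arange(len(library)), per_guide)
    rng.shuffle(guide_per_read)

    mat = np.empty((depth, length), dtype=np.int8)
    template = np.array([_BASE_TO_CODE[b] for b in design.left_flank], dtype=np.int8)
    lf = len(template)
    mat[:, : min(lf, length)] = template[: min(lf, length)]
    sl = design.spacer_length
    if length > lf:
        take = min(sl, length - lf)
        mat[:, lf : lf + take] = spacer_codes[guide_per_read][:, :take]
    rf_codes = np.array([_BASE_TO_CODE[b] for b in design.right_flank], dtype=np.int8)
    end = min(length, lf + sl + len(rf_codes))
    if end > lf + sl:
        mat[:, lf + sl : end] = rf_codes[: end - lf - sl]
    if length > core_len:
        mat[:, core_len:] = rng.integers(0, 4, size=(depth, length - core_len), dtype=np.int8)
    mat = mat[:, :length]

    if error_rate > 0:
        err = rng.random((depth, length)) < error_rate
        n_err = int(err.sum())
        if n_err:
            mat[err] = (mat[err] + rng.integers(1, 4, n_err, dtype=np.int8)) % 4

    qual = "I" * length
    seqs = ["".join(row) for row in _CODE_TO_BASE[mat]]
    return [(f"read_{i}", seq, qual) for i, seq in enumerate(seqs)]


def extract_spacer(read: str, design: AmpliconDesign) -> tuple[str | None, str | None]:
    """Trim the constant flanks off a read and return the spacer.

    Returns ``(spacer, None)`` on success or ``(None, reason)`` with reason
    in {flank_not_found, truncated, right_flank_mismatch}. The anchor is the
    first exact occurrence of the left flank; the right flank is verified
    only when the design requires it.
    """
    pos = read.find(design.left_flank)
    if pos < 0:
        return None, FLANK_NOT_FOUND
    start = pos + len(design.left_flank)
    end = start + design.spacer_length
    if end > len(read):
        return None, TRUNCATED
    if design.require_right_flank:
        rf = design.right_flank
        tail = read[end : end + len(rf)]
        if len(tail) < len(rf):
            return None, TRUNCATED
        if tail != rf:
            return None, RIGHT_FLANK_MISMATCH
    return read[start:end], None


def _hamming1_index(spacers: np.ndarray) -> dict[str, int]:
    """Map every Hamming-1 neighbor of each spacer to its guide index.

    Neighbors claimed by more than one guide map to -1 (ambiguous).
    """
    index: dict[str, int] = {}
    for gi, spacer in enumerate(spacers):
        for pos in range(len(spacer)):
            orig = spacer[pos]
            for base in "ACGT":
                if base == orig:
                    continue
                variant = spacer[:pos] + base + spacer[pos + 1 :]
                if variant in index and index[variant] != gi:
                    index[variant] = -1
                else:
                    index[variant] = gi
    return index


def count_spacers(
    reads: Iterable[str] | str | Path,
    library: GuideLibrary,
    design: AmpliconDesign,
    max_mismatch: int = 0,
) -> tuple[pd.Series, dict[str, int]]:
    """Count library spacers in reads; returns (counts per guide, QC dict).

    Matching is exact at ``max_mismatch=0``; at 1, a read whose spacer is
    within Hamming distance 1 of exactly one library spacer is rescued,
    while equidistant multi-hits are dropped as ambiguous. Exact matches
    always take precedence (minimum-distance rule).
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads)

    spacers = library.spacers
    exact = {s: i for i, s in enumerate(spacers)}
    if len(exact) != len(spacers):
        raise ValueError("duplicate spacers in library")
    near = _hamming1_index(spacers) if max_mismatch == 1 else {}

    counts = np.zeros(len(library), dtype=np.int64)
    qc = {"n_reads": 0, "n_assigned": 0, "n_flank_fail": 0, "n_no_match": 0, "n_ambiguous": 0}
    for read in reads:
        qc["n_reads"] += 1
        spacer, reason = extract_spacer(read, design)
        if spacer is None:
            qc["n_flank_fail"] += 1
            continue
        gi = exact.get(spacer, -2)
        if gi == -2 and max_mismatch == 1:
            gi = near.get(spacer, -2)
        if gi == -2:
            qc["n_no_match"] += 1
        elif gi == -1:
            qc["n_ambiguous"] += 1
        else:
            counts[gi] += 1
            qc["n_assigned"] += 1
    return pd.Series(counts, index=pd.Index(library.guide_ids, name="guide_id")), qc


def write_counts_tsv(matrix: CountMatrix, path: str | Path) -> None:
    """Write the count matrix as TSV: guide_id column then one column per sample."""
    out = matrix.counts.copy()
    out.index.name = "guide_id"
    out.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> CountMatrix:
    """Load a counts TSV, validating integrality and non-negativity cell by cell."""
    df = pd.read_csv(path, sep="\t", index_col="guide_id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0)
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"invalid count at guide {row!r}, sample {col!r}: {df.loc[row, col]!r}"
            )
        df[col] = vals.astype(np.int64)
    return CountMatrix(df)
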