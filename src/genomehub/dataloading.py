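"""Turn genomic file formats into numeric model inputs.

Intervals follow the BED convention throughout: 0-based, half-open
``[start, end)``. One-hot encoding uses column order A, C, G, T; the
ambiguity code N encodes to an all-zero row so that padding and masked
bases are visible to downstream models rather than being smeared into a
uniform background.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from pyfaidx import Fasta

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic window in 0-based half-open coordinates.

    ``start`` may be negative and ``end`` may run past the chromosome:
    out-of-bounds positions are fetched as 'N' so that variant-centered
    windows near chromosome edges never crash.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def resized(self, target_len: int) -> "GenomicInterval":
        """Resize about the midpoint to ``target_len`` (deterministic for
        even lengths: start = (start+end)//2 - target_len//2)."""
        if target_len < 1:
            raise ValueError("target_len must be >= 1")
        if len(self) == target_len:
            return self
        mid = (self.start + self.end) // 2
        start = mid - target_len // 2
        return replace(self, start=start, end=start + target_len)


@dataclass
class OneHotBatch:
    """A (batch, L, 4) one-hot array plus the source interval per row."""

    array: np.ndarray
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return self.array.shape[0]


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, preserving file order.

    Lines starting with ``track``, ``browser`` or ``#`` are skipped.
    Column 6 is read as strand when present, else '+'.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinate") from None
            if start >= end:
                raise ValueError(f"line {lineno}: start >= end")
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "+"
            intervals.append(GenomicInterval(chrom, start, end, strand, name))
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def open_fasta(fasta: str | os.PathLike | Fasta) -> Fasta:
    if isinstance(fasta, Fasta):
        return fasta
    return Fasta(str(fasta), sequence_always_upper=True)


def reverse_complement(seq: str) -> str:
    """Reverse-complement over the alphabet {A,C,G,T,N} (case-insensitive
    input, uppercase output)."""
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in "ACGTN":
            raise ValueError(f"invalid character {ch!r} at position {pos}")
    return seq.translate(_COMPLEMENT)[::-1]


def fetch_sequence(fasta: str | os.PathLike | Fasta, iv: GenomicInterval) -> str:
    """Fetch the uppercase sequence of ``iv``; positions outside
    [0, chrom_length) are returned as 'N'. Minus-strand intervals return
    the reverse complement of the forward slice."""
    fa = open_fasta(fasta)
    if iv.chrom not in fa:
        raise KeyError(
            f"unknown chromosome {iv.chrom!r}; available: {sorted(fa.keys())}"
        )
    chrom_len = len(fa[iv.chrom])
    lo = max(iv.start, 0)
    hi = min(iv.end, chrom_len)
    core = str(fa[iv.chrom][lo:hi]).upper() if hi > lo else ""
    seq = "N" * (lo - iv.start) + core + "N" * (iv.end - max(hi, iv.start))
    seq = seq[: len(iv)]  # guard fully-out-of-range intervals
    if len(seq) < len(iv):
        seq = seq + "N" * (len(iv) - len(seq))
    if iv.strand == "-":
        seq = reverse_complement(seq)
    return seq


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a DNA string as an (L, 4) binary matrix, columns A,C,G,T.
    'N' becomes an all-zero row."""
    seq = seq.upper()
    out = np.zeros((len(seq), 4), dtype=np.float64)
    for i, ch in enumerate(seq):
        if ch == "N":
            continue
        j = BASE_INDEX.get(ch)
        if j is None:
            raise ValueError(f"invalid character {ch!r} at position {i}")
        out[i, j] = 1.0
    return out


def one_hot_decode(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to 'N'."""
    mat = np.asarray(mat)
    chars = []
    for row in mat:
        s = row.sum()
        if s == 0:
            chars.append("N")
        else:
            chars.append(BASES[int(np.argmax(row))])
    return "".join(chars)


def one_hot_reverse_complement(mat: np.ndarray) -> np.ndarray:
    # reversing both axes complements (A<->T, C<->G) and flips position
    return np.ascontiguousarray(mat[::-1, ::-1])


def interval_batches(
    fasta: str | os.PathLike | Fasta,
    intervals: Sequence[GenomicInterval],
    target_len: int | None = None,
    batch_size: int = 32,
) -> Iterator[OneHotBatch]:
    """Yield one-hot batches for ``intervals`` in order.

    Intervals whose length differs from ``target_len`` (when given) are
    midpoint-resized before fetching. All batches are full except
    possibly the last.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    fa = open_fasta(fasta)
    buf_arrays: list[np.ndarray] = []
    buf_ivs: list[GenomicInterval] = []
    for iv in intervals:
        if target_len is not None and len(iv) != target_len:
            iv = iv.resized(target_len)
        try:
            seq = fetch_sequence(fa, iv)
        except Exception as exc:
            raise type(exc)(
                f"while fetching {iv.chrom}:{iv.start}-{iv.end}({iv.strand}): {exc}"
            ) from exc
        buf_arrays.append(one_hot_encode(seq))
        buf_ivs.append(iv)
        if len(buf_arrays) == batch_size:
            yield OneHotBatch(np.stack(buf_arrays), buf_ivs)
            buf_arrays, buf_ivs = [], []
    if buf_arrays:
        yield OneHotBatch(np.stack(buf_arrays), buf_ivs)
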