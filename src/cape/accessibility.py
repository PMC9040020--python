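"""Chromatin accessibility scores from DNase-seq read starts.

For each position the score is S = N / Ñ where N is the number of read 5′
ends at the position and Ñ = M / W is the mean read-start rate in a
background window of size W centered there (M read starts in the window).
A uniform track therefore scores 1 everywhere; S > 1 marks positions cut
more often than their local background.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from cape.core_io import GenomicInterval

DEFAULT_WINDOW = 201


@dataclass
class ReadStartTrack:
    """Per-position read 5′-end counts for one chromosome of one replicate."""

    chrom: str
    counts: np.ndarray
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("negative read-start count")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class AccessibilityTrack:
    """Per-position accessibility scores S for one chromosome of one replicate."""

    chrom: str
    scores: np.ndarray
    replicate_id: str = "rep1"
    window_size: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite accessibility score")
        if (self.scores < 0).any():
            raise ValueError("negative accessibility score")

    def __len__(self) -> int:
        return len(self.scores)


def count_read_starts(
    reads: Iterable[GenomicInterval], chrom_length: int, chrom: str | None = None,
    replicate_id: str = "rep1",
) -> ReadStartTrack:
    """Count read 5′ ends per position.

    Plus-strand (or unstranded) reads contribute at ``start``; minus-strand
    reads at ``end - 1``.  Reads outside ``[0, chrom_length)`` raise.
    """
    counts = np.zeros(chrom_length, dtype=np.int64)
    inferred_chrom = chrom
    for read in reads:
        if inferred_chrom is None:
            inferred_chrom = read.chrom
        elif chrom is None and read.chrom != inferred_chrom:
            raise ValueError(
                f"mixed chromosomes in read set: {inferred_chrom!r} vs {read.chrom!r}"
            )
        if chrom is not None and read.chrom != chrom:
            continue
        pos = read.end - 1 if read.strand == "-" else read.start
        if not 0 <= pos < chrom_length:
            raise ValueError(
                f"read 5' end {pos} outside chromosome of length {chrom_length}"
            )
        counts[pos] += 1
    return ReadStartTrack(inferred_chrom or chrom or "chr", counts, replicate_id)


def accessibility_score(track: ReadStartTrack, window_size: int = DEFAULT_WINDOW) -> AccessibilityTrack:
    """Compute S = N / (M / W) for every position with a centered window.

    ``window_size`` is forced odd (incremented if even) so the window is
    symmetric.  At chromosome ends the window is truncated and W in Ñ is
    replaced by the truncated length, keeping S a ratio of rates.  Where
    M = 0 the score is defined as 0.
    """
    if window_size < 1:
        raise ValueError(f"window size must be >= 1, got {window_size}")
    if window_size % 2 == 0:
        window_size += 1
    counts = track.counts.astype(np.float64)
    length = len(counts)
    half = window_size // 2
    # M via prefix sums; effective window length accounts for truncation.
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    pos = np.arange(length)
    lo = np.maximum(pos - half, 0)
    hi = np.minimum(pos + half + 1, length)
    m = csum[hi] - csum[lo]
    eff_w = (hi - lo).astype(np.float64)
    scores = np.zeros(length, dtype=np.float64)
    nz = m > 0
    scores[nz] = counts[nz] * eff_w[nz] / m[nz]
    return AccessibilityTrack(track.chrom, scores, track.replicate_id, window_size)


def window_accessibility(
    tracks: Sequence[AccessibilityTrack], iv: GenomicInterval
) -> np.ndarray:
    """Slice k replicate tracks over an interval into a k×L matrix."""
    if len(tracks) == 0:
        raise ValueError("no accessibility tracks given")
    rows = []
    for track in tracks:
        if track.chrom != iv.chrom:
            raise ValueError(
                f"track {track.replicate_id} covers {track.chrom}, not {iv.chrom}"
            )
        if iv.end > len(track.scores):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds track length "
                f"{len(track.scores)} (replicate {track.replicate_id})"
            )
        rows.append(track.scores[iv.start:iv.end])
    return np.stack(rows, axis=0)


def read_count_track(path: str | os.PathLike, chrom_sizes: dict[str, int],
                     replicate_id: str = "rep1") -> dict[str, ReadStartTrack]:
    """Read a per-position count track TSV (chrom, pos, count); 0-based positions.

    Positions absent from the file count 0.
    """
    tracks = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected chrom<TAB>pos<TAB>count")
            chrom, pos, count = fields[0], int(fields[1]), int(fields[2])
            if chrom not in tracks:
                raise ValueError(f"line {lineno}: unknown chromosome {chrom!r}")
            if not 0 <= pos < len(tracks[chrom]):
                raise ValueError(f"line {lineno}: position {pos} out of bounds")
            tracks[chrom][pos] = count
    return {c: ReadStartTrack(c, v, replicate_id) for c, v in tracks.items()}


def write_count_track(tracks: Iterable[ReadStartTrack], path: str | os.PathLike) -> None:
    """Write non-zero counts as a chrom/pos/count TSV."""
    with open(path, "w") as out:
        for track in tracks:
            for pos in np.flatnonzero(track.counts):
                out.write(f"{track.chrom}\t{pos}\t{track.counts[pos]}\n")


def write_bedgraph(track: AccessibilityTrack, path: str | os.PathLike) -> None:
    """Write scores as bedGraph, merging runs of equal value."""
    scores = track.scores
    with open(path, "w") as out:
        if len(scores) == 0:
            return
        boundaries = np.flatnonzero(np.diff(scores) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(scores)]])
        for s, e in zip(starts, ends):
            out.write(f"{track.chrom}\t{s}\t{e}\t{scores[s]:g}\n")
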