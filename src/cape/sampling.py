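"""Training-set construction: background model, matched negatives, windowing, folds.

Negatives are drawn from the genomic background (genome minus exclusion
regions) with lengths matched exactly to the positives and, optionally, GC
content matched within a tolerance — so a classifier cannot separate the
classes on length or base composition alone.  Variable-length regions are
converted to fixed-length windows by fixed-stride augmentation, and
cross-validation folds are assigned per origin region *before*
augmentation so that no two windows of one region ever land in different
folds.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from cape.accessibility import AccessibilityTrack, window_accessibility
from cape.core_io import Genome, GenomicInterval, extract_sequence, gc_content

DEFAULT_TARGET_LEN = 300
DEFAULT_GC_TOL = 0.02
DEFAULT_MAX_ATTEMPTS = 10_000


@dataclass
class BackgroundModel:
    """Sampleable background: per-chromosome allowed intervals and the genome."""

    allowed: list[GenomicInterval]
    genome: Genome | None = None

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.allowed:
            out.setdefault(iv.chrom, []).append(iv)
        return out


@dataclass(frozen=True)
class AugmentationConfig:
    target_len: int = DEFAULT_TARGET_LEN
    stride: int = 1

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.target_len < self.stride:
            raise ValueError("target_len must be >= stride")


@dataclass
class Sample:
    """One fixed-length training/test unit."""

    origin_id: str
    window: GenomicInterval
    label: int
    fold: int
    sequence: str | None = None
    accessibility: np.ndarray | None = None  # k × target_len

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass
class FoldSplit:
    n_folds: int
    assignment: dict[str, int]

    def fold_of(self, origin_id: str) -> int:
        return self.assignment[origin_id]


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping/adjacent intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def build_background(
    chrom_sizes: Mapping[str, int],
    exclusions: Sequence[GenomicInterval],
    genome: Genome | None = None,
) -> BackgroundModel:
    """Complement of the union of exclusions within each chromosome."""
    for iv in exclusions:
        if iv.chrom not in chrom_sizes:
            raise ValueError(f"exclusion on unknown chromosome {iv.chrom!r}")
        if iv.end > chrom_sizes[iv.chrom]:
            raise ValueError(
                f"exclusion {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {chrom_sizes[iv.chrom]}"
            )
    merged = merge_intervals(exclusions) if exclusions else []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    allowed: list[GenomicInterval] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        cursor = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > cursor:
                allowed.append(GenomicInterval(chrom, cursor, iv.start))
            cursor = max(cursor, iv.end)
        if cursor < size:
            allowed.append(GenomicInterval(chrom, cursor, size))
    return BackgroundModel(allowed=allowed, genome=genome)


def _candidate_starts(allowed: Sequence[GenomicInterval], length: int,
                      clearance: int = 0):
    """Allowed (chrom, start) slots for a window of the given length.

    ``clearance`` demands that many extra background bases on each side, so
    that fixed-length windows later augmented around a short region also
    stay clear of the exclusions.  Returns the host intervals and their
    per-interval slot counts, for uniform sampling over every valid start.
    """
    span = length + 2 * clearance
    hosts = [iv for iv in allowed if iv.length >= span]
    slots = np.array([iv.length - span + 1 for iv in hosts], dtype=np.int64)
    return hosts, slots


def sample_negatives(
    positives: Sequence[GenomicInterval],
    bg: BackgroundModel,
    ratio: int = 10,
    match_gc: bool = True,
    gc_tol: float = DEFAULT_GC_TOL,
    seed: int = 0,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
    clearance_len: int | None = None,
) -> list[GenomicInterval]:
    """Draw ``ratio`` background negatives per positive by rejection sampling.

    Negative ``i*ratio + j`` has exactly the length of positive ``i``.  When
    ``match_gc`` the negative's GC content must lie within ``gc_tol`` of its
    positive's.  Negatives never overlap the exclusions (they are drawn from
    the background) nor one another.  With ``clearance_len`` set to the
    augmentation window length, every window of that length containing a
    short negative is also guaranteed to avoid the exclusions.
    Deterministic for a given seed.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if not bg.allowed:
        raise ValueError("background model has no allowed intervals")
    if match_gc and bg.genome is None:
        raise ValueError("GC matching requires a genome in the background model")
    rng = np.random.default_rng(seed)
    placed: dict[str, list[tuple[int, int]]] = {}
    negatives: list[GenomicInterval] = []
    for i, pos_iv in enumerate(positives):
        length = pos_iv.length
        clearance = max(0, (clearance_len or 0) - length)
        hosts, slots = _candidate_starts(bg.allowed, length, clearance)
        if len(hosts) == 0:
            raise ValueError(
                f"no background interval can host a negative of length {length}"
            )
        total = int(slots.sum())
        cum = np.cumsum(slots)
        target_gc = (
            gc_content(extract_sequence(bg.genome, pos_iv)) if match_gc else None
        )
        for j in range(ratio):
            for attempt in range(max_attempts):
                flat = int(rng.integers(total))
                host_idx = int(np.searchsorted(cum, flat, side="right"))
                offset = flat - (cum[host_idx - 1] if host_idx > 0 else 0)
                host = hosts[host_idx]
                start = host.start + clearance + int(offset)
                cand = GenomicInterval(host.chrom, start, start + length,
                                       name=f"neg_{i}_{j}")
                if any(
                    cand.start < e and s < cand.end
                    for s, e in placed.get(cand.chrom, [])
                ):
                    continue
                if target_gc is not None:
                    cand_gc = gc_content(extract_sequence(bg.genome, cand))
                    if abs(cand_gc - target_gc) > gc_tol:
                        continue
                placed.setdefault(cand.chrom, []).append((cand.start, cand.end))
                negatives.append(cand)
                break
            else:
                gc_msg = f" (GC {target_gc:.3f})" if target_gc is not None else ""
                raise RuntimeError(
                    f"could not place negative {j} for positive "
                    f"{pos_iv.chrom}:{pos_iv.start}-{pos_iv.end}{gc_msg} "
                    f"after {max_attempts} attempts"
                )
    return negatives


def augment(
    region: GenomicInterval, cfg: AugmentationConfig, chrom_length: int
) -> list[GenomicInterval]:
    """Fixed-stride windows of length ``target_len`` for one region.

    Regions at least as long as the target emit every in-region window at
    the stride; shorter regions emit every window fully containing them
    (clipped to chromosome bounds).  Without clipping the window count is
    ``floor(|len - target| / stride) + 1``.
    """
    target, stride = cfg.target_len, cfg.stride
    if chrom_length < target:
        raise ValueError(
            f"chromosome length {chrom_length} shorter than window {target}"
        )
    if region.end > chrom_length:
        raise ValueError("region exceeds chromosome bounds")
    windows = []
    if region.length >= target:
        start = region.start
        while start + target <= region.end:
            windows.append(GenomicInterval(region.chrom, start, start + target))
            start += stride
    else:
        start = region.end - target
        while start <= region.start:
            s = min(max(start, 0), chrom_length - target)
            iv = GenomicInterval(region.chrom, s, s + target)
            if not windows or windows[-1].start != iv.start:
                windows.append(iv)
            start += stride
    return windows


def split_folds(
    positive_ids: Sequence[str],
    negative_ids: Sequence[str],
    n_folds: int = 5,
    seed: int = 0,
) -> FoldSplit:
    """Stratified random partition of origin ids into folds balanced within 1."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    for name, ids in (("positive", positive_ids), ("negative", negative_ids)):
        if len(ids) < n_folds:
            raise ValueError(
                f"{name} class has {len(ids)} origins, fewer than {n_folds} folds"
            )
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for ids in (positive_ids, negative_ids):
        order = rng.permutation(len(ids))
        for rank, idx in enumerate(order):
            assignment[ids[idx]] = rank % n_folds
    return FoldSplit(n_folds=n_folds, assignment=assignment)


def assemble_dataset(
    positives: Sequence[GenomicInterval],
    negatives: Sequence[GenomicInterval],
    genome: Genome,
    tracks: Mapping[str, Sequence[AccessibilityTrack]],
    cfg: AugmentationConfig,
    folds: FoldSplit,
) -> list[Sample]:
    """Window every origin region and attach sequence + accessibility slices.

    ``tracks`` maps chromosome -> the k replicate accessibility tracks.
    Sequence and accessibility for each Sample cover identical coordinates.
    """
    samples: list[Sample] = []
    for label, regions, prefix in ((1, positives, "pos"), (0, negatives, "neg")):
        for i, region in enumerate(regions):
            origin_id = region.name or f"{prefix}_{i}"
            fold = folds.fold_of(origin_id)
            chrom_len = genome.chrom_length(region.chrom)
            for window in augment(region, cfg, chrom_len):
                seq = extract_sequence(genome, window).seq
                acc = window_accessibility(tracks[window.chrom], window)
                samples.append(
                    Sample(
                        origin_id=origin_id,
                        window=window,
                        label=label,
                        fold=fold,
                        sequence=seq,
                        accessibility=acc,
                    )
                )
    return samples


def write_manifest(samples: Sequence[Sample], path: str | os.PathLike) -> None:
    """Write the dataset manifest TSV (origin_id, chrom, start, end, label, fold)."""
    with open(path, "w") as out:
        out.write("origin_id\tchrom\tstart\tend\tlabel\tfold\n")
        for s in samples:
            out.write(
                f"{s.origin_id}\t{s.window.chrom}\t{s.window.start}\t"
                f"{s.window.end}\t{s.label}\t{s.fold}\n"
            )


def read_manifest(path: str | os.PathLike) -> list[Sample]:
    samples = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = ["origin_id", "chrom", "start", "end", "label", "fold"]
        if header != expected:
            raise ValueError(f"unexpected manifest header {header}")
        for line in handle:
            origin_id, chrom, start, end, label, fold = line.rstrip("\n").split("\t")
            samples.append(
                Sample(
                    origin_id=origin_id,
                    window=GenomicInterval(chrom, int(start), int(end)),
                    label=int(label),
                    fold=int(fold),
                )
            )
    return samples
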