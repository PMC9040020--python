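"""Self-contained synthetic datasets with the structure the method assumes.

The generator emulates the real inputs end to end: a random background
genome, enhancer intervals (lengths bracketing the 275/288 bp
median/mean of catalogued enhancers) carrying one implanted
transcription-factor motif site each, and k replicate DNase-seq read-start
tracks whose Poisson rate is elevated inside enhancers.  Both signal
channels (sequence motif, accessibility rate) can be silenced
independently, so channel-ablation behaviour is testable.

Everything is deterministic given the config seed, and all outputs flow
through the same data-construction code as real data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from cape.accessibility import (
    AccessibilityTrack,
    ReadStartTrack,
    accessibility_score,
)
from cape.core_io import ALPHABET, Genome, GenomicInterval, SequenceRecord
from cape.sampling import (
    AugmentationConfig,
    FoldSplit,
    Sample,
    assemble_dataset,
    build_background,
    sample_negatives,
    split_folds,
)

# AP-1/CREB-like consensus with 85% per-position information: strong enough
# to be learnable from ~50 sites yet not a deterministic string.
DEFAULT_MOTIF_CONSENSUS = "TGACGTCA"


def consensus_pwm(consensus: str, strength: float = 0.85) -> np.ndarray:
    """PWM with ``strength`` probability on the consensus base per position."""
    pwm = np.full((len(consensus), 4), (1.0 - strength) / 3.0)
    for i, base in enumerate(consensus):
        pwm[i, ALPHABET.index(base)] = strength
    return pwm


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults: 50 enhancers of 200–400 bp on a 600 kb chromosome, one
    implanted motif site per enhancer, 1:10 negatives (GC-matched), two
    DNase replicates with a 5-fold read-start rate elevation inside
    enhancers, stride-10 augmentation to 300 bp windows, 5 folds.
    """

    genome_length: int = 600_000
    gc: float = 0.41
    n_enhancers: int = 50
    enhancer_length_range: tuple[int, int] = (200, 400)
    motif: np.ndarray = field(
        default_factory=lambda: consensus_pwm(DEFAULT_MOTIF_CONSENSUS)
    )
    motif_prob: float = 1.0
    k_replicates: int = 2
    lambda_bg: float = 0.1
    lambda_enh: float = 0.5
    ratio: int = 10
    match_gc: bool = True
    gc_tol: float = 0.02
    target_len: int = 300
    stride: int = 10
    n_folds: int = 5
    accessibility_window: int = 201
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.gc <= 1.0:
            raise ValueError(f"gc must be in (0, 1], got {self.gc}")
        if not 0.0 <= self.motif_prob <= 1.0:
            raise ValueError("motif_prob must be in [0, 1]")
        if self.lambda_bg < 0 or self.lambda_enh < 0:
            raise ValueError("Poisson rates must be non-negative")
        lo, hi = self.enhancer_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid enhancer length range")
        if self.genome_length < 10 * hi:
            raise ValueError("genome too short for the requested enhancers")

    def null(self) -> "SyntheticConfig":
        """Matched no-signal condition: no motif, equal Poisson rates."""
        return replace(self, motif_prob=0.0, lambda_enh=self.lambda_bg)

    def motif_discovery(self) -> "SyntheticConfig":
        """Conditions for the motif-recovery experiment: many distinct
        enhancers (hence motif sites) with sparse windowing and balanced
        classes.  Kernel sharpening needs hundreds of distinct sites —
        mirroring that real training sets contain hundreds to thousands of
        enhancers — while extra shifted window copies add nothing."""
        return replace(self, n_enhancers=800, ratio=1,
                       genome_length=2_000_000, stride=60)


@dataclass
class SyntheticDataset:
    genome: Genome
    enhancers: list[GenomicInterval]
    negatives: list[GenomicInterval]
    exclusions: list[GenomicInterval]
    read_tracks: list[ReadStartTrack]
    accessibility: list[AccessibilityTrack]
    truth: list[GenomicInterval]
    motif: np.ndarray
    folds: FoldSplit
    samples: list[Sample]


def generate_genome(cfg: SyntheticConfig,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """I.i.d. base indices (0..3 for A,C,G,T) with P(G)+P(C) = gc."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    at = (1.0 - cfg.gc) / 2.0
    gc = cfg.gc / 2.0
    return rng.choice(4, size=cfg.genome_length, p=[at, gc, gc, at]).astype(np.uint8)


def _indices_to_seq(indices: np.ndarray) -> str:
    lut = np.frombuffer("ACGT".encode("ascii"), dtype=np.uint8)
    return lut[indices].tobytes().decode("ascii")


def plant_enhancers(
    genome_idx: np.ndarray, cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    max_attempts_factor: int = 1000,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Place non-overlapping enhancers and implant motif sites in-place.

    Enhancers keep a margin of one window length from the chromosome ends
    and from each other.  A ``motif_prob`` fraction receives one
    PWM-sampled 8-mer at a uniform internal offset, written into
    ``genome_idx``.  Returns (enhancers, truth motif-site intervals).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.enhancer_length_range
    margin = cfg.target_len
    placed: list[tuple[int, int]] = []
    enhancers: list[GenomicInterval] = []
    truth: list[GenomicInterval] = []
    attempts_left = max_attempts_factor * cfg.n_enhancers
    motif_len = cfg.motif.shape[0]
    for i in range(cfg.n_enhancers):
        length = int(rng.integers(lo, hi + 1))
        while True:
            if attempts_left <= 0:
                raise RuntimeError(
                    f"could not place {cfg.n_enhancers} non-overlapping enhancers"
                )
            attempts_left -= 1
            start = int(rng.integers(margin, cfg.genome_length - margin - length))
            if all(start - margin >= e or start + length + margin <= s
                   for s, e in placed):
                break
        placed.append((start, start + length))
        iv = GenomicInterval(cfg.chrom, start, start + length, name=f"pos_{i}")
        enhancers.append(iv)
        if rng.random() < cfg.motif_prob:
            offset = int(rng.integers(0, length - motif_len + 1))
            site = np.array(
                [rng.choice(4, p=row) for row in cfg.motif], dtype=np.uint8
            )
            genome_idx[start + offset:start + offset + motif_len] = site
            truth.append(
                GenomicInterval(cfg.chrom, start + offset,
                                start + offset + motif_len, name=iv.name)
            )
    return enhancers, truth


def simulate_read_starts(
    enhancers: Sequence[GenomicInterval], cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> list[ReadStartTrack]:
    """k independent replicate tracks: Poisson(lambda_enh) inside enhancers,
    Poisson(lambda_bg) elsewhere."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    in_enh = np.zeros(cfg.genome_length, dtype=bool)
    for iv in enhancers:
        in_enh[iv.start:iv.end] = True
    rates = np.where(in_enh, cfg.lambda_enh, cfg.lambda_bg)
    return [
        ReadStartTrack(cfg.chrom, rng.poisson(rates), replicate_id=f"rep{r + 1}")
        for r in range(cfg.k_replicates)
    ]


def make_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate a dataset and run the full data-construction pipeline on it."""
    rng = np.random.default_rng(cfg.seed)
    genome_idx = generate_genome(cfg, rng)
    enhancers, truth = plant_enhancers(genome_idx, cfg, rng)
    genome = Genome({cfg.chrom: _indices_to_seq(genome_idx)})
    exclusions = list(enhancers)
    bg = build_background(genome.chrom_sizes(), exclusions, genome=genome)
    negatives = sample_negatives(
        enhancers, bg, ratio=cfg.ratio, match_gc=cfg.match_gc, gc_tol=cfg.gc_tol,
        seed=int(rng.integers(2 ** 31)), clearance_len=cfg.target_len,
    )
    read_tracks = simulate_read_starts(enhancers, cfg, rng)
    accessibility = [
        accessibility_score(t, cfg.accessibility_window) for t in read_tracks
    ]
    folds = split_folds(
        [iv.name for iv in enhancers],
        [iv.name for iv in negatives],
        n_folds=cfg.n_folds,
        seed=int(rng.integers(2 ** 31)),
    )
    samples = assemble_dataset(
        enhancers, negatives, genome, {cfg.chrom: accessibility},
        AugmentationConfig(target_len=cfg.target_len, stride=cfg.stride), folds,
    )
    return SyntheticDataset(
        genome=genome,
        enhancers=enhancers,
        negatives=negatives,
        exclusions=exclusions,
        read_tracks=read_tracks,
        accessibility=accessibility,
        truth=truth,
        motif=np.asarray(cfg.motif),
        folds=folds,
        samples=samples,
    )


def export_dataset(dataset: SyntheticDataset, outdir: str | os.PathLike) -> None:
    """Write the dataset in the standard formats the CLI consumes."""
    from cape.accessibility import write_count_track
    from cape.core_io import write_bed, write_fasta
    from cape.sampling import write_manifest

    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    chrom = dataset.enhancers[0].chrom
    write_fasta(
        [SequenceRecord(chrom, dataset.genome[chrom])],
        os.path.join(outdir, "genome.fa"),
    )
    with open(os.path.join(outdir, "chrom.sizes"), "w") as out:
        for c, n in dataset.genome.chrom_sizes().items():
            out.write(f"{c}\t{n}\n")
    write_bed(dataset.enhancers, os.path.join(outdir, "enhancers.bed"))
    write_bed(dataset.negatives, os.path.join(outdir, "negatives.bed"))
    write_bed(dataset.exclusions, os.path.join(outdir, "exclusions.bed"))
    write_bed(dataset.truth, os.path.join(outdir, "motif_sites.bed"))
    for track in dataset.read_tracks:
        write_count_track(
            [track], os.path.join(outdir, f"reads_{track.replicate_id}.tsv")
        )
    write_manifest(dataset.samples, os.path.join(outdir, "manifest.tsv"))
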