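"""Background model, matched negatives, augmentation windows, fold splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from intervaltree import IntervalTree

from cape.core_io import Genome, GenomicInterval, extract_sequence, gc_content
from cape.sampling import (
    AugmentationConfig,
    Sample,
    assemble_dataset,
    augment,
    build_background,
    merge_intervals,
    read_manifest,
    sample_negatives,
    split_folds,
    write_manifest,
)


def random_genome(length, seed=0, gc=0.5):
    rng = np.random.default_rng(seed)
    at, g = (1 - gc) / 2, gc / 2
    bases = rng.choice(list("ACGT"), size=length, p=[at, g, g, at])
    return Genome({"chr1": "".join(bases)})


class TestBuildBackground:
    def test_single_exclusion_complement(self):
        bg = build_background({"c": 100}, [GenomicInterval("c", 20, 40)])
        assert [(iv.start, iv.end) for iv in bg.allowed] == [(0, 20), (40, 100)]

    def test_no_exclusions_whole_chromosome(self):
        bg = build_background({"c": 100}, [])
        assert [(iv.start, iv.end) for iv in bg.allowed] == [(0, 100)]

    def test_fully_excluded_chromosome(self):
        bg = build_background({"c": 50}, [GenomicInterval("c", 0, 50)])
        assert bg.allowed == []

    def test_overlapping_exclusions_merged(self):
        bg = build_background(
            {"c": 100},
            [GenomicInterval("c", 10, 30), GenomicInterval("c", 20, 50)],
        )
        assert [(iv.start, iv.end) for iv in bg.allowed] == [(0, 10), (50, 100)]

    def test_out_of_bounds_exclusion_rejected(self):
        with pytest.raises(ValueError):
            build_background({"c": 100}, [GenomicInterval("c", 90, 120)])


class TestSampleNegatives:
    def setup_method(self):
        self.genome = random_genome(60_000, seed=3)
        self.positives = [
            GenomicInterval("chr1", 1000 + 500 * i, 1000 + 500 * i + 200 + 10 * i,
                            name=f"p{i}")
            for i in range(5)
        ]
        self.bg = build_background(
            self.genome.chrom_sizes(), self.positives, genome=self.genome
        )

    def test_count_is_ratio_times_positives(self):
        negs = sample_negatives(self.positives, self.bg, ratio=10, match_gc=False,
                                seed=0)
        assert len(negs) == 50

    def test_lengths_match_each_positive_exactly(self):
        negs = sample_negatives(self.positives, self.bg, ratio=3, match_gc=False,
                                seed=0)
        for i, pos in enumerate(self.positives):
            for j in range(3):
                assert negs[i * 3 + j].length == pos.length

    def test_gc_matched_within_tolerance(self):
        negs = sample_negatives(self.positives, self.bg, ratio=5, match_gc=True,
                                gc_tol=0.02, seed=0)
        for i, pos in enumerate(self.positives):
            pos_gc = gc_content(extract_sequence(self.genome, pos))
            for j in range(5):
                neg_gc = gc_content(extract_sequence(self.genome, negs[i * 5 + j]))
                assert abs(neg_gc - pos_gc) <= 0.02 + 1e-12

    def test_no_overlap_with_exclusions_interval_tree_oracle(self):
        negs = sample_negatives(self.positives, self.bg, ratio=10, match_gc=False,
                                seed=1)
        tree = IntervalTree()
        for iv in self.positives:
            tree[iv.start:iv.end] = iv.name
        assert all(not tree.overlap(n.start, n.end) for n in negs)

    def test_negatives_mutually_disjoint(self):
        negs = sample_negatives(self.positives, self.bg, ratio=10, match_gc=False,
                                seed=2)
        tree = IntervalTree()
        for n in negs:
            assert not tree.overlap(n.start, n.end)
            tree[n.start:n.end] = True

    def test_deterministic_given_seed(self):
        a = sample_negatives(self.positives, self.bg, ratio=4, seed=9)
        b = sample_negatives(self.positives, self.bg, ratio=4, seed=9)
        assert a == b

    def test_impossible_gc_raises_with_context(self):
        # a GC-only positive in an otherwise AT-only genome cannot be matched
        genome = Genome({"chr1": "AT" * 50 + "GC" * 100 + "AT" * 4950})
        positives = [GenomicInterval("chr1", 100, 300, name="p0")]
        bg = build_background(genome.chrom_sizes(), positives, genome=genome)
        with pytest.raises(RuntimeError, match="GC"):
            sample_negatives(
                positives, bg, ratio=1, match_gc=True, gc_tol=0.02, seed=0,
                max_attempts=50,
            )

    def test_clearance_keeps_containing_windows_in_background(self):
        negs = sample_negatives(self.positives, self.bg, ratio=10, match_gc=False,
                                seed=3, clearance_len=300)
        tree = IntervalTree()
        for iv in self.positives:
            tree[iv.start:iv.end] = True
        for n in negs:
            lo = n.end - 300 if n.length < 300 else n.start
            hi = n.start + 300 if n.length < 300 else n.end
            assert not tree.overlap(max(lo, 0), hi)


class TestAugment:
    def test_long_region_windows(self):
        cfg = AugmentationConfig(target_len=300, stride=5)
        region = GenomicInterval("c", 1000, 1310)
        windows = augment(region, cfg, 5000)
        assert [w.start for w in windows] == [1000, 1005, 1010]
        assert all(w.length == 300 for w in windows)

    def test_exact_length_region_is_fixed_point(self):
        cfg = AugmentationConfig(target_len=300, stride=7)
        region = GenomicInterval("c", 50, 350)
        (w,) = augment(region, cfg, 1000)
        assert (w.start, w.end) == (50, 350)

    def test_short_region_containing_windows(self):
        cfg = AugmentationConfig(target_len=300, stride=1)
        region = GenomicInterval("c", 1000, 1290)
        windows = augment(region, cfg, 5000)
        assert len(windows) == 11
        assert all(w.start <= region.start and w.end >= region.end for w in windows)

    def test_chromosome_too_short(self):
        with pytest.raises(ValueError):
            augment(GenomicInterval("c", 0, 100), AugmentationConfig(300, 1), 200)

    @settings(max_examples=100, deadline=None)
    @given(
        length=st.integers(1, 500),
        target=st.integers(1, 500),
        stride=st.integers(1, 50),
    )
    def test_window_count_matches_enumeration(self, length, target, stride):
        """Count formula floor(|len-target|/stride)+1, via exhaustive check."""
        if stride > target:
            return
        chrom_len = 3000
        region = GenomicInterval("c", 1000, 1000 + length)
        windows = augment(region, AugmentationConfig(target, stride), chrom_len)
        assert len(windows) == abs(length - target) // stride + 1
        assert all(w.length == target for w in windows)


class TestSplitFolds:
    def test_stratified_balance_within_one(self):
        split = split_folds([f"p{i}" for i in range(10)],
                            [f"n{i}" for i in range(103)], n_folds=5, seed=0)
        pos_counts = np.bincount(
            [split.assignment[f"p{i}"] for i in range(10)], minlength=5
        )
        neg_counts = np.bincount(
            [split.assignment[f"n{i}"] for i in range(103)], minlength=5
        )
        assert pos_counts.max() - pos_counts.min() <= 1
        assert neg_counts.max() - neg_counts.min() <= 1
        assert pos_counts.sum() == 10 and neg_counts.sum() == 103

    def test_deterministic(self):
        ids = ([f"p{i}" for i in range(7)], [f"n{i}" for i in range(20)])
        assert split_folds(*ids, 5, seed=3).assignment == \
            split_folds(*ids, 5, seed=3).assignment

    def test_class_smaller_than_folds_rejected(self):
        with pytest.raises(ValueError):
            split_folds(["a"], [f"n{i}" for i in range(10)], n_folds=5, seed=0)


class TestAssembleDataset:
    def _make(self, stride=1):
        from cape.accessibility import AccessibilityTrack

        genome = random_genome(20_000, seed=5)
        positives = [GenomicInterval("chr1", 2000, 2300, name="pos_0")]
        negatives = [
            GenomicInterval("chr1", 4000 + 400 * i, 4300 + 400 * i, name=f"neg_{i}")
            for i in range(10)
        ]
        tracks = {
            "chr1": [AccessibilityTrack("chr1", np.ones(20_000), f"rep{r}")
                     for r in range(2)]
        }
        # 1 positive cannot fill 5 folds via split_folds; assign manually
        from cape.sampling import FoldSplit

        assignment = {"pos_0": 0}
        assignment.update({f"neg_{i}": i % 5 for i in range(10)})
        folds = FoldSplit(n_folds=5, assignment=assignment)
        cfg = AugmentationConfig(target_len=300, stride=stride)
        return assemble_dataset(positives, negatives, genome, tracks, cfg, folds)

    def test_window_counts_and_labels(self):
        samples = self._make()
        assert len(samples) == 11  # every region is exactly 300 bp
        assert sum(s.label for s in samples) == 1

    def test_sample_invariants(self):
        for s in self._make():
            assert s.window.length == 300
            assert len(s.sequence) == 300
            assert s.accessibility.shape == (2, 300)

    def test_windows_of_one_origin_share_fold(self):
        samples = self._make()
        by_origin = {}
        for s in samples:
            by_origin.setdefault(s.origin_id, set()).add(s.fold)
        assert all(len(folds) == 1 for folds in by_origin.values())


def test_manifest_round_trip(tmp_path):
    samples = [
        Sample("pos_0", GenomicInterval("chr1", 0, 300), 1, 2),
        Sample("neg_1", GenomicInterval("chr1", 500, 800), 0, 4),
    ]
    p = tmp_path / "manifest.tsv"
    write_manifest(samples, p)
    back = read_manifest(p)
    assert [(s.origin_id, s.window.start, s.label, s.fold) for s in back] == [
        ("pos_0", 0, 1, 2),
        ("neg_1", 500, 0, 4),
    ]


def test_merge_intervals_sorts_and_merges():
    merged = merge_intervals(
        [
            GenomicInterval("c", 50, 60),
            GenomicInterval("c", 10, 30),
            GenomicInterval("c", 25, 55),
        ]
    )
    assert [(iv.start, iv.end) for iv in merged] == [(10, 60)]
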