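"""Classification metrics and interval overlap rates.

AUROC equals the Mann–Whitney U statistic (ties counted one half); AUPRC
is computed as average precision (step-wise, no interpolation between
precision–recall points) — the preferred metric under the strong class
imbalance of enhancer prediction.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from cape.core_io import GenomicInterval


def _check_scores(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if not np.isfinite(scores).all():
        raise ValueError("non-finite score")
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    return scores, labels.astype(np.int64)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve."""
    scores, labels = _check_scores(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve (average precision)."""
    scores, labels = _check_scores(scores, labels)
    if labels.sum() == 0:
        raise ValueError("AUPRC needs at least one positive")
    return float(average_precision_score(labels, scores))


def overlap_rate(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> float:
    """Fraction of intervals in ``a`` overlapping (>= 1 bp) any interval in ``b``."""
    if len(a) == 0:
        raise ValueError("overlap_rate needs a non-empty query set")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    starts = {c: np.array([s for s, _ in ivs]) for c, ivs in by_chrom.items()}
    ends = {c: np.array([e for _, e in ivs]) for c, ivs in by_chrom.items()}
    hits = 0
    for iv in a:
        if iv.chrom not in by_chrom:
            continue
        s, e = starts[iv.chrom], ends[iv.chrom]
        # any b-interval with start < iv.end and end > iv.start
        idx = np.searchsorted(s, iv.end, side="left")
        if idx > 0 and (e[:idx] > iv.start).any():
            hits += 1
    return hits / len(a)
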