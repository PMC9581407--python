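"""Evaluation machinery: classification metrics, APA, loop-set matching,
distance profiling.

APA (aggregate peak analysis) averages the raw contact submatrices centered
on a loop set and reports the center value divided by the mean of the
corner block nearest the matrix diagonal (the short-distance corner), so a
score above 1 indicates focal enrichment over the local background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score

from .io import ContactMap, Interaction

__all__ = [
    "EvalReport",
    "APAResult",
    "classification_metrics",
    "apa",
    "match_loops",
    "distance_profile",
]


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    prauc: float
    threshold: float
    tp: int
    fp: int
    fn: int


@dataclass
class APAResult:
    aggregate: np.ndarray
    apa_score: float
    n_used: int
    n_excluded: int


def classification_metrics(labels, probabilities, threshold: float = 0.5) -> EvalReport:
    """Precision/recall/F1 at a probability threshold (predicted positive iff
    probability >= threshold) plus PRAUC by all-thresholds step integration
    (no interpolation)."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=np.float64)
    if len(y) == 0:
        raise ValueError("empty input")
    if y.shape != p.shape:
        raise ValueError("labels and probabilities differ in length")
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    prauc = float(average_precision_score(y, p)) if y.max() == 1 else 0.0
    return EvalReport(precision, recall, f1, prauc, threshold, tp, fp, fn)


def apa(cmap: ContactMap, loops: list[Interaction], flank: int = 10, corner: int = 6) -> APAResult:
    """Aggregate peak analysis over a loop set.

    Loops with out-of-bounds (2*flank+1)-windows or with anchor distance
    < 2*flank + 1 bins are excluded (counted). The aggregate is the
    elementwise mean of raw-value windows; the score divides its center by
    the mean of the corner x corner block at the lower-left (rows nearest the
    diagonal, columns at the shortest distance)."""
    if not flank >= corner >= 1:
        raise ValueError("require flank >= corner >= 1")
    size = 2 * flank + 1
    dense = cmap.dense_symmetric()
    agg = np.zeros((size, size))
    used = excluded = 0
    for lp in loops:
        i, j = lp.bin1, lp.bin2
        if (j - i) < size or i - flank < 0 or j + flank >= cmap.n_bins:
            excluded += 1
            continue
        agg += dense[i - flank : i + flank + 1, j - flank : j + flank + 1]
        used += 1
    if used == 0:
        raise ValueError("no usable loops for APA")
    agg /= used
    corner_block = agg[size - corner :, :corner]
    corner_mean = float(corner_block.mean())
    score = float(agg[flank, flank] / corner_mean) if corner_mean > 0 else float("inf")
    return APAResult(agg, score, used, excluded)


def _anchors_match(a: Interaction, b: Interaction, mode: str, tol: int, resolution: int) -> bool:
    if a.chrom != b.chrom:
        return False
    if mode == "exact":
        return a.bin1 == b.bin1 and a.bin2 == b.bin2
    # tolerant: each anchor's +-tol window around its center overlaps the other's
    c1a = (a.bin1 + 0.5) * resolution
    c2a = (a.bin2 + 0.5) * resolution
    c1b = (b.bin1 + 0.5) * resolution
    c2b = (b.bin2 + 0.5) * resolution
    return abs(c1a - c1b) <= 2 * tol and abs(c2a - c2b) <= 2 * tol


def match_loops(
    a: list[Interaction],
    b: list[Interaction],
    mode: str = "tolerant",
    tol: int = 10000,
    resolution: int = 10000,
) -> tuple[int, int, list[tuple[int, int]]]:
    """Match two loop sets; returns (n_matched_a, n_matched_b, pairs).

    ``exact``: both anchor bins equal. ``tolerant``: the +-tol region around
    each anchor center overlaps the partner's, i.e. center distance <= 2*tol
    per anchor. Counts are of matched elements per side (one element may pair
    with several on the other side); ``pairs`` holds (index_in_a, index_in_b).
    """
    if mode not in ("exact", "tolerant"):
        raise ValueError(f"unknown mode {mode!r}")
    pairs: list[tuple[int, int]] = []
    hit_a = np.zeros(len(a), dtype=bool)
    hit_b = np.zeros(len(b), dtype=bool)
    if a and b:
        a1 = np.array([x.bin1 for x in a])
        a2 = np.array([x.bin2 for x in a])
        b1 = np.array([x.bin1 for x in b])
        b2 = np.array([x.bin2 for x in b])
        ca = np.array([x.chrom for x in a])
        cb = np.array([x.chrom for x in b])
        if mode == "exact":
            ok = (a1[:, None] == b1[None, :]) & (a2[:, None] == b2[None, :])
        else:
            max_off = 2 * tol / resolution  # center distance in bins
            ok = (np.abs(a1[:, None] - b1[None, :]) <= max_off) & (
                np.abs(a2[:, None] - b2[None, :]) <= max_off
            )
        ok &= ca[:, None] == cb[None, :]
        ia, ib = np.nonzero(ok)
        pairs = list(zip(ia.tolist(), ib.tolist()))
        hit_a[ia] = True
        hit_b[ib] = True
    return int(hit_a.sum()), int(hit_b.sum()), pairs


def distance_profile(
    loops: list[Interaction], resolution: int, breakpoints: list[float]
) -> np.ndarray:
    """Proportion of loops per half-open genomic-distance band
    [breakpoints[k], breakpoints[k+1]); proportions sum to 1."""
    if not loops:
        raise ValueError("empty loop list")
    bp = np.asarray(breakpoints, dtype=np.float64)
    if len(bp) < 2 or np.any(np.diff(bp) <= 0):
        raise ValueError("breakpoints must be strictly increasing with >= 2 values")
    d = np.array([lp.distance for lp in loops], dtype=np.float64) * resolution
    if np.any(d < bp[0]) or np.any(d >= bp[-1]):
        raise ValueError("some loop distances fall outside the band range")
    counts, _ = np.histogram(d, bins=bp)
    return counts / counts.sum()
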