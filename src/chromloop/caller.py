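"""Genome-wide loop calling with a trained classifier.

Two stages, mirroring the training-free part of the method: (1) score every
stored (non-zero) pixel within the configured distance range whose window
fits inside the chromosome, using exactly the two-channel normalized window
construction the classifier was trained on; (2) keep candidates whose contact
frequency exceeds the per-chromosome candidate mean, keep those at or above
the probability threshold, and pool the survivors into single-linkage
Chebyshev clusters, reporting the highest-probability pixel of each cluster.

Binomial read downsampling (per-entry Binomial(count, fraction) thinning) is
provided for sequencing-depth robustness studies and operates on raw counts
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .io import ContactMap, AccessibilityTrack
from .model import LoopClassifier
from .samples import normalize_window

log = logging.getLogger(__name__)

__all__ = [
    "CandidateLoop",
    "CallParams",
    "score_chromosome",
    "filter_by_frequency",
    "filter_by_probability",
    "pool_candidates",
    "calibrate_threshold",
    "downsample",
    "call_loops",
]


@dataclass
class CandidateLoop:
    chrom: str
    i: int
    j: int
    probability: float
    raw_value: float

    @property
    def bin1(self) -> int:
        return self.i

    @property
    def bin2(self) -> int:
        return self.j


@dataclass
class CallParams:
    min_dist: int = 3       # bins; excludes near-diagonal self-ligation signal
    max_dist: int = 300     # bins; 3 Mb at 10 kb
    w: int = 23
    threshold: float = 0.5
    radius: int = 2         # pooling radius in bins


def _batch_windows(
    dense: np.ndarray, acc: np.ndarray, i: np.ndarray, j: np.ndarray, w: int
) -> np.ndarray:
    """Vectorized normalized two-channel windows for candidate pixels.

    ``dense`` is the symmetrized contact matrix; per-window normalization is
    applied exactly as in sample generation (log10(1+m) then /(1+max))."""
    half = (w - 1) // 2
    off = np.arange(-half, half + 1)
    rows = i[:, None] + off
    cols = j[:, None] + off
    hic = dense[rows[:, :, None], cols[:, None, :]]
    av = acc[rows][:, :, None] * acc[cols][:, None, :]

    def _norm(m):
        l = np.log10(1.0 + m)
        return l / (1.0 + l.max(axis=(1, 2)))[:, None, None]

    return np.stack([_norm(hic), _norm(av)], axis=1).astype(np.float32)


def score_chromosome(
    model: LoopClassifier,
    cmap: ContactMap,
    track: AccessibilityTrack,
    min_dist: int = 3,
    max_dist: int = 300,
    w: int = 23,
    batch_size: int = 2048,
) -> list[CandidateLoop]:
    """One CandidateLoop per stored pixel with ``min_dist <= j - i <= max_dist``
    and an in-bounds window, scored by the classifier."""
    if track.n_bins != cmap.n_bins:
        raise ValueError("track and map disagree on n_bins")
    half = (w - 1) // 2
    d = cmap.distance
    ok = (
        (d >= min_dist) & (d <= max_dist)
        & (cmap.bin1 >= half) & (cmap.bin2 >= half)
        & (cmap.bin1 + half < cmap.n_bins) & (cmap.bin2 + half < cmap.n_bins)
    )
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        return []
    dense = cmap.dense_symmetric()
    acc = track.values
    probs = np.empty(len(idx))
    for s in range(0, len(idx), batch_size):
        sel = idx[s : s + batch_size]
        x = _batch_windows(dense, acc, cmap.bin1[sel], cmap.bin2[sel], w)
        probs[s : s + len(sel)] = model.predict_array(x)
    return [
        CandidateLoop(cmap.chrom, int(cmap.bin1[k]), int(cmap.bin2[k]),
                      float(probs[t]), float(cmap.value[k]))
        for t, k in enumerate(idx)
    ]


def filter_by_frequency(cands: list[CandidateLoop]) -> list[CandidateLoop]:
    """Keep candidates whose contact value is strictly greater than the mean
    contact value over all candidates of the same chromosome."""
    if not cands:
        return []
    out: list[CandidateLoop] = []
    chroms = {}
    for c in cands:
        chroms.setdefault(c.chrom, []).append(c)
    for group in chroms.values():
        mean = float(np.mean([c.raw_value for c in group]))
        out.extend(c for c in group if c.raw_value > mean)
    return out


def filter_by_probability(cands: list[CandidateLoop], threshold: float) -> list[CandidateLoop]:
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    return [c for c in cands if c.probability >= threshold]


def pool_candidates(cands: list[CandidateLoop], radius: int = 2) -> list[CandidateLoop]:
    """Single-linkage clustering under Chebyshev distance <= radius on (i, j);
    each cluster is represented by its highest-probability candidate (ties:
    higher raw_value, then smaller (i, j) lexicographically)."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if not cands:
        return []
    out: list[CandidateLoop] = []
    by_chrom: dict[str, list[CandidateLoop]] = {}
    for c in cands:
        by_chrom.setdefault(c.chrom, []).append(c)
    for group in by_chrom.values():
        pts = np.array([(c.i, c.j) for c in group], dtype=np.float64)
        n = len(group)
        if n == 1:
            out.append(group[0])
            continue
        pairs = cKDTree(pts).query_pairs(r=radius, p=np.inf, output_type="ndarray")
        adj = sp.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        n_comp, labels = connected_components(adj, directed=False)
        for comp in range(n_comp):
            members = [group[k] for k in np.flatnonzero(labels == comp)]
            best = min(members, key=lambda c: (-c.probability, -c.raw_value, c.i, c.j))
            out.append(best)
    out.sort(key=lambda c: (c.chrom, c.i, c.j))
    return out


def calibrate_threshold(
    cands: list[CandidateLoop],
    target_count: int,
    radius: int = 2,
    lo: float = 0.5,
) -> float:
    """Probability threshold whose pooled call count is closest to (at most)
    ``target_count`` on a calibration chromosome.

    Depth and training variability shift the classifier's probability scale;
    the practical operating point is therefore chosen to yield an expected
    number of loops — here per calibration chromosome — rather than fixed at
    0.5. ``cands`` should already be frequency-filtered. Binary search over
    the threshold; never returns less than ``lo``.
    """
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    hi = 1.0 - 1e-9
    if len(pool_candidates(filter_by_probability(cands, lo), radius)) <= target_count:
        return lo
    best = hi
    a, b = lo, hi
    for _ in range(40):
        mid = (a + b) / 2
        n = len(pool_candidates(filter_by_probability(cands, mid), radius))
        if n > target_count:
            a = mid
        else:
            best, b = mid, mid
    return best


def downsample(cmap: ContactMap, fraction: float, seed: int = 0) -> ContactMap:
    """Binomial thinning of raw counts: each entry becomes
    Binomial(count, fraction); zero draws are dropped."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    counts = cmap.value
    rounded = np.rint(counts)
    if cmap.balanced or np.any(np.abs(counts - rounded) > 1e-9):
        raise ValueError("downsampling is defined on raw integer counts only")
    rng = np.random.default_rng(seed)
    drawn = rng.binomial(rounded.astype(np.int64), fraction)
    keep = drawn > 0
    return ContactMap(
        cmap.chrom, cmap.resolution, cmap.n_bins,
        cmap.bin1[keep], cmap.bin2[keep], drawn[keep].astype(np.float64),
    )


def call_loops(
    model: LoopClassifier,
    cmap: ContactMap,
    track: AccessibilityTrack,
    params: CallParams | None = None,
    return_counts: bool = False,
):
    """Full pipeline: score -> frequency filter -> probability filter -> pool.

    Stage counts are logged; pass ``return_counts=True`` to also receive the
    stage-count dict (candidates, after_frequency, after_probability, pooled).
    """
    p = params or CallParams()
    cands = score_chromosome(model, cmap, track, p.min_dist, p.max_dist, p.w)
    after_freq = filter_by_frequency(cands)
    after_prob = filter_by_probability(after_freq, p.threshold)
    pooled = pool_candidates(after_prob, p.radius)
    counts = {
        "candidates": len(cands),
        "after_frequency": len(after_freq),
        "after_probability": len(after_prob),
        "pooled": len(pooled),
    }
    log.info("call_loops %s: %s", cmap.chrom, counts)
    if return_counts:
        return pooled, counts
    return pooled
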