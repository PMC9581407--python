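"""Labeled two-channel training windows from a contact map and an accessibility track.

A sample is a ``w x w`` (default 23x23, ``w`` odd) pair of matrices centered on a
bin pair (i, j): channel 1 is the local Hi-C contact submatrix, channel 2 the
outer product of the accessibility values over the row and column bins. Both
channels are normalized per window: elementwise ``log10(1 + M)`` followed by
division by ``1 + max`` of the logged window, which maps any non-negative
window into [0, 1) and the all-zero window to itself.

Negatives are drawn from non-zero pixels, in equal number to positives, using
two strategies: most match the empirical distance distribution of the
positives, and a minority (``far_fraction``) lie strictly beyond the maximum
positive distance, probing long-range background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import h5py
import numpy as np

from .io import AccessibilityTrack, ContactMap, Interaction

log = logging.getLogger(__name__)

__all__ = [
    "SampleWindow",
    "DatasetManifest",
    "WindowBoundsError",
    "extract_window",
    "accessibility_matrix",
    "normalize_window",
    "distance_pdf",
    "DistancePDF",
    "sample_negatives",
    "build_dataset",
    "save_dataset",
    "load_dataset",
]


class WindowBoundsError(ValueError):
    """Requested window overruns the chromosome bounds."""


@dataclass
class SampleWindow:
    chrom: str
    center: tuple[int, int]
    w: int
    hic: np.ndarray
    acc: np.ndarray
    label: int

    def stacked(self) -> np.ndarray:
        """(2, w, w) array: channel 0 Hi-C, channel 1 accessibility."""
        return np.stack([self.hic, self.acc])


@dataclass
class DatasetManifest:
    chrom: str
    n_positive: int
    n_negative: int
    n_dropped: int
    seed: int
    w: int
    far_fraction: float
    max_positive_distance: int

    def to_dict(self) -> dict:
        return asdict(self)


def _check_bounds(i: int, j: int, w: int, n_bins: int) -> None:
    if w % 2 != 1:
        raise ValueError(f"window size must be odd, got {w}")
    half = (w - 1) // 2
    if i - half < 0 or j - half < 0 or i + half >= n_bins or j + half >= n_bins:
        raise WindowBoundsError(
            f"window {w}x{w} at ({i}, {j}) overruns chromosome of {n_bins} bins"
        )


def extract_window(cmap: ContactMap, i: int, j: int, w: int = 23) -> np.ndarray:
    """Dense w x w submatrix of the symmetrized contact matrix centered on (i, j).

    Absent entries are 0; cells below the matrix diagonal take the mirrored
    upper-triangle value.
    """
    if not i < j:
        raise ValueError(f"require i < j, got ({i}, {j})")
    _check_bounds(i, j, w, cmap.n_bins)
    half = (w - 1) // 2
    return cmap.symmetric()[i - half : i + half + 1, j - half : j + half + 1].toarray()


def accessibility_matrix(track: AccessibilityTrack, i: int, j: int, w: int = 23) -> np.ndarray:
    """Outer product of the accessibility values over the window's row bins
    (around anchor i) and column bins (around anchor j)."""
    _check_bounds(i, j, w, track.n_bins)
    half = (w - 1) // 2
    x = track.values[i - half : i + half + 1]
    y = track.values[j - half : j + half + 1]
    return np.outer(x, y)


def normalize_window(m: np.ndarray) -> np.ndarray:
    """Per-window normalization: log10(1 + m), then divide by 1 + max of the
    logged window. Output lies in [0, 1); the all-zero window is a fixed point."""
    m = np.asarray(m, dtype=np.float64)
    if np.any(m < 0):
        raise ValueError("normalize_window requires non-negative entries")
    logged = np.log10(1.0 + m)
    return logged / (1.0 + logged.max())


class DistancePDF:
    """Empirical distribution over anchor distances (in bins)."""

    def __init__(self, distances: np.ndarray):
        d = np.asarray(distances, dtype=np.int64)
        if len(d) == 0:
            raise ValueError("empty distance multiset")
        self.support, counts = np.unique(d, return_counts=True)
        self.probabilities = counts / counts.sum()

    def prob(self, d: int) -> float:
        k = np.searchsorted(self.support, d)
        if k < len(self.support) and self.support[k] == d:
            return float(self.probabilities[k])
        return 0.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.support, size=n, p=self.probabilities)


def distance_pdf(positives: list[Interaction]) -> DistancePDF:
    if not positives:
        raise ValueError("need at least one positive interaction")
    return DistancePDF(np.array([p.distance for p in positives]))


def sample_negatives(
    cmap: ContactMap,
    positives: list[Interaction],
    far_fraction: float = 0.2,
    w: int = 23,
    seed: int = 0,
    max_dist: int = 300,
) -> list[Interaction]:
    """Draw one negative per positive from non-zero pixels of the map.

    Exactly ``round(far_fraction * n)`` negatives have distance strictly
    greater than the maximum positive distance (capped at ``max_dist``); the
    rest have distances drawn from the positives' empirical distance
    distribution. Negatives never coincide with, or neighbor within Chebyshev
    distance 1, any positive center; all have in-bounds windows; sampling is
    without replacement and deterministic given ``seed``.
    """
    if not 0 <= far_fraction <= 1:
        raise ValueError("far_fraction must be in [0, 1]")
    if not positives:
        return []
    rng = np.random.default_rng(seed)
    half = (w - 1) // 2

    halo = set()
    for p in positives:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                halo.add((p.bin1 + di, p.bin2 + dj))

    d = cmap.distance
    in_bounds = (
        (cmap.bin1 >= half)
        & (cmap.bin2 >= half)
        & (cmap.bin1 + half < cmap.n_bins)
        & (cmap.bin2 + half < cmap.n_bins)
    )
    eligible = (d >= 1) & (d <= max_dist) & in_bounds
    idx = np.flatnonzero(eligible)
    not_halo = np.array(
        [(cmap.bin1[k], cmap.bin2[k]) not in halo for k in idx], dtype=bool
    )
    idx = idx[not_halo]
    if len(idx) == 0:
        raise ValueError("no eligible non-zero pixels for negative sampling")

    n = len(positives)
    n_far = int(round(far_fraction * n))
    n_near = n - n_far
    dmax_pos = max(p.distance for p in positives)

    dist_of = cmap.distance[idx]
    pools: dict[int, list[int]] = {}
    for dd in np.unique(dist_of):
        members = idx[dist_of == dd]
        pools[int(dd)] = list(rng.permutation(members))
    avail = sorted(pools)

    chosen: list[int] = []

    # far negatives: strictly beyond the maximum positive distance
    far_pool: list[int] = []
    for dd in avail:
        if dd > dmax_pos:
            far_pool.extend(pools[dd])
    if len(far_pool) < n_far:
        raise ValueError(
            f"only {len(far_pool)} pixels beyond distance {dmax_pos}, need {n_far}"
        )
    far_pool = list(rng.permutation(np.array(far_pool, dtype=np.int64)))
    far_chosen = far_pool[:n_far]
    for k in far_chosen:
        pools[int(cmap.distance[k])].remove(k)
    chosen.extend(far_chosen)

    # distance-matched negatives
    pdf = distance_pdf(positives)
    wanted = pdf.sample(n_near, rng)
    n_fallback = 0
    for dd in wanted:
        dd = int(dd)
        pick = None
        if pools.get(dd):
            pick = pools[dd].pop()
        else:
            # nearest available distance with remaining pixels (ties: smaller)
            cands = [a for a in avail if pools[a]]
            if not cands:
                raise ValueError("exhausted eligible pixels while sampling negatives")
            best = min(cands, key=lambda a: (abs(a - dd), a))
            pick = pools[best].pop()
            n_fallback += 1
        chosen.append(pick)
    if n_fallback:
        log.info("sample_negatives: %d draw(s) fell back to nearest distance", n_fallback)

    return [
        Interaction(cmap.chrom, int(cmap.bin1[k]), int(cmap.bin2[k]), label="negative")
        for k in chosen
    ]


def build_dataset(
    cmap: ContactMap,
    track: AccessibilityTrack,
    positives: list[Interaction],
    w: int = 23,
    far_fraction: float = 0.2,
    seed: int = 0,
    max_dist: int = 300,
) -> tuple[list[SampleWindow], DatasetManifest]:
    """One labeled SampleWindow per usable positive and per sampled negative.

    Positives whose window exceeds chromosome bounds are dropped (counted in
    the manifest); both channels are normalized per window, independently.
    """
    if track.n_bins != cmap.n_bins:
        raise ValueError("track and map disagree on n_bins")
    half = (w - 1) // 2
    usable, dropped = [], 0
    for p in positives:
        if p.bin1 - half < 0 or p.bin2 + half >= cmap.n_bins or p.bin1 + half >= cmap.n_bins:
            dropped += 1
        else:
            usable.append(p)
    if dropped:
        log.info("build_dataset %s: dropped %d out-of-bounds positive(s)", cmap.chrom, dropped)

    negatives = sample_negatives(cmap, usable, far_fraction, w, seed, max_dist)

    windows: list[SampleWindow] = []
    for inter, label in [(p, 1) for p in usable] + [(q, 0) for q in negatives]:
        hic = normalize_window(extract_window(cmap, inter.bin1, inter.bin2, w))
        acc = normalize_window(accessibility_matrix(track, inter.bin1, inter.bin2, w))
        windows.append(SampleWindow(cmap.chrom, (inter.bin1, inter.bin2), w, hic, acc, label))

    manifest = DatasetManifest(
        chrom=cmap.chrom,
        n_positive=len(usable),
        n_negative=len(negatives),
        n_dropped=dropped,
        seed=seed,
        w=w,
        far_fraction=far_fraction,
        max_positive_distance=max((p.distance for p in usable), default=0),
    )
    return windows, manifest


def save_dataset(path: str, windows: list[SampleWindow], manifest: DatasetManifest) -> None:
    """Serialize a chromosome's windows + manifest to an HDF5 container."""
    x = np.stack([s.stacked() for s in windows]).astype(np.float32) if windows else \
        np.zeros((0, 2, manifest.w, manifest.w), dtype=np.float32)
    y = np.array([s.label for s in windows], dtype=np.int8)
    centers = np.array([s.center for s in windows], dtype=np.int64).reshape(-1, 2)
    opts = dict(track_times=False)
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=x, **opts)
        f.create_dataset("labels", data=y, **opts)
        f.create_dataset("centers", data=centers, **opts)
        for k, v in manifest.to_dict().items():
            f.attrs[k] = v


def load_dataset(path: str) -> tuple[list[SampleWindow], DatasetManifest]:
    with h5py.File(path, "r") as f:
        x = f["windows"][:]
        y = f["labels"][:]
        centers = f["centers"][:]
        attrs = dict(f.attrs)
    manifest = DatasetManifest(
        chrom=str(attrs["chrom"]),
        n_positive=int(attrs["n_positive"]),
        n_negative=int(attrs["n_negative"]),
        n_dropped=int(attrs["n_dropped"]),
        seed=int(attrs["seed"]),
        w=int(attrs["w"]),
        far_fraction=float(attrs["far_fraction"]),
        max_positive_distance=int(attrs["max_positive_distance"]),
    )
    windows = [
        SampleWindow(manifest.chrom, (int(c[0]), int(c[1])), manifest.w,
                     x[k, 0].astype(np.float64), x[k, 1].astype(np.float64), int(y[k]))
        for k, c in enumerate(centers)
    ]
    return windows, manifest
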