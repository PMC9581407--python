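"""Readers and writers for contact matrices, accessibility tracks and BEDPE interactions.

All coordinates are 0-based half-open. Bins are indexed from 0 at a fixed
resolution (10 kb by default); an anchor interval is assigned to the bin
containing its midpoint, with midpoints landing exactly on a bin boundary
going to the left bin.

Two contact-matrix dialects are supported:

* a cool-style HDF5 container with ``chroms``/``bins``/``pixels`` tables and
  an optional per-bin balancing ``weight`` column,
* plain whitespace-separated sparse triplet text (``i j value``), one entry
  per line, as a dependency-free fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp

log = logging.getLogger(__name__)

__all__ = [
    "ContactMap",
    "AccessibilityTrack",
    "Interaction",
    "FormatError",
    "ParseError",
    "read_contact_map",
    "read_accessibility",
    "read_interactions",
    "write_loops",
    "write_cool",
]


class FormatError(ValueError):
    """A file does not match the expected dialect or resolution."""


class ParseError(ValueError):
    """A malformed record; the message names the offending line."""


@dataclass
class Interaction:
    """An intra-chromosomal bin pair, optionally labeled and/or scored."""

    chrom: str
    bin1: int
    bin2: int
    label: str | None = None
    probability: float | None = None

    def __post_init__(self) -> None:
        if not self.bin1 < self.bin2:
            raise ValueError(f"anchors must be ordered: bin1={self.bin1} >= bin2={self.bin2}")

    @property
    def distance(self) -> int:
        return self.bin2 - self.bin1


@dataclass
class ContactMap:
    """Sparse upper-triangular intra-chromosomal contact matrix at fixed resolution.

    Entries are stored as parallel arrays ``bin1 <= bin2`` with strictly
    positive values; zeros are absent, not stored. ``balanced`` states whether
    ``value`` holds matrix-balanced values or raw counts; when balanced,
    ``raw_value`` retains the raw counts so that read-level operations
    (binomial downsampling) remain possible.
    """

    chrom: str
    resolution: int
    n_bins: int
    bin1: np.ndarray
    bin2: np.ndarray
    value: np.ndarray
    balanced: bool = False
    raw_value: np.ndarray | None = None
    _sym: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.bin1 = np.asarray(self.bin1, dtype=np.int64)
        self.bin2 = np.asarray(self.bin2, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=np.float64)
        if not (len(self.bin1) == len(self.bin2) == len(self.value)):
            raise ValueError("bin1/bin2/value lengths differ")
        if len(self.bin1):
            if self.bin1.min() < 0 or self.bin2.max() >= self.n_bins:
                raise ValueError("bin index outside [0, n_bins)")
            if np.any(self.bin1 > self.bin2):
                raise ValueError("entries must be upper-triangular (bin1 <= bin2)")
            if np.any(self.value <= 0):
                raise ValueError("stored contact values must be strictly positive")
            key = self.bin1 * self.n_bins + self.bin2
            if len(np.unique(key)) != len(key):
                raise ValueError("duplicate (bin1, bin2) entries")
            order = np.argsort(key, kind="stable")
            self.bin1, self.bin2, self.value = self.bin1[order], self.bin2[order], self.value[order]
            if self.raw_value is not None:
                self.raw_value = np.asarray(self.raw_value, dtype=np.float64)[order]

    @classmethod
    def from_entries(
        cls,
        chrom: str,
        resolution: int,
        n_bins: int,
        i: np.ndarray,
        j: np.ndarray,
        v: np.ndarray,
        balanced: bool = False,
        raw: np.ndarray | None = None,
    ) -> "ContactMap":
        """Build a map from unordered entries, mirroring lower-triangle input
        to (min, max) order and summing duplicate mirrored entries."""
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        v = np.asarray(v, dtype=np.float64)
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        key = lo * n_bins + hi
        uk, inv = np.unique(key, return_inverse=True)
        vv = np.zeros(len(uk))
        np.add.at(vv, inv, v)
        rr = None
        if raw is not None:
            rr = np.zeros(len(uk))
            np.add.at(rr, inv, np.asarray(raw, dtype=np.float64))
        keep = vv > 0
        return cls(
            chrom, resolution, n_bins,
            (uk // n_bins)[keep], (uk % n_bins)[keep], vv[keep],
            balanced=balanced, raw_value=None if rr is None else rr[keep],
        )

    def __len__(self) -> int:
        return len(self.value)

    @property
    def distance(self) -> np.ndarray:
        return self.bin2 - self.bin1

    def total(self) -> float:
        return float(self.value.sum())

    def symmetric(self) -> sp.csr_matrix:
        """Symmetrized sparse matrix (upper triangle mirrored), cached."""
        if self._sym is None:
            upper = sp.coo_matrix(
                (self.value, (self.bin1, self.bin2)), shape=(self.n_bins, self.n_bins)
            )
            diag = sp.diags(upper.diagonal())
            self._sym = (upper + upper.T - diag).tocsr()
        return self._sym

    def dense_symmetric(self) -> np.ndarray:
        return self.symmetric().toarray()


@dataclass
class AccessibilityTrack:
    """Per-bin mean accessible-chromatin signal for one chromosome."""

    chrom: str
    resolution: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("accessibility values must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------

def read_contact_map(
    path: str,
    chrom: str,
    resolution: int = 10000,
    use_balanced: bool = False,
    n_bins: int | None = None,
) -> ContactMap:
    """Read one chromosome's contact matrix from a cool-dialect HDF5 container
    or from sparse triplet text.

    Parameters
    ----------
    path
        HDF5 container (``chroms``/``bins``/``pixels`` tables) or triplet text.
    chrom
        Chromosome name (HDF5) — for triplet text it only names the result.
    resolution
        Bin size in bp; must match the container's stored bin size.
    use_balanced
        Apply per-bin balancing weights when present; raw counts are retained
        alongside. Pixels touching a bin with an undefined (NaN) weight are
        dropped, matching the usual balancing convention.
    n_bins
        Bin count override for the triplet dialect (default: max index + 1).
    """
    if h5py.is_hdf5(path):
        return _read_cool(path, chrom, resolution, use_balanced)
    return _read_triplets(path, chrom, resolution, n_bins)


def _read_triplets(path: str, chrom: str, resolution: int, n_bins: int | None) -> ContactMap:
    try:
        data = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed triplet line ({exc})") from exc
    if data.size == 0:
        return ContactMap(chrom, resolution, n_bins or 0, [], [], [])
    if data.shape[1] != 3:
        raise FormatError(f"{path}: expected 3 columns (i j value), got {data.shape[1]}")
    i, j, v = data[:, 0].astype(np.int64), data[:, 1].astype(np.int64), data[:, 2]
    nb = n_bins if n_bins is not None else int(max(i.max(), j.max())) + 1
    return ContactMap.from_entries(chrom, resolution, nb, i, j, v)


def _read_cool(path: str, chrom: str, resolution: int, use_balanced: bool) -> ContactMap:
    with h5py.File(path, "r") as f:
        stored_res = int(f.attrs["bin-size"])
        if stored_res != resolution:
            raise FormatError(
                f"{path}: container resolution {stored_res} != requested {resolution}"
            )
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in f["chroms/name"][:]]
        if chrom not in names:
            raise KeyError(f"chromosome {chrom!r} not in {path} (has {names})")
        cid = names.index(chrom)
        bin_chrom = f["bins/chrom"][:]
        sel = np.flatnonzero(bin_chrom == cid)
        offset, nb = int(sel[0]), len(sel)
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        count = f["pixels/count"][:].astype(np.float64)
        mask = (b1 >= offset) & (b1 < offset + nb) & (b2 >= offset) & (b2 < offset + nb)
        i, j, raw = b1[mask] - offset, b2[mask] - offset, count[mask]
        if use_balanced and "weight" in f["bins"]:
            w = f["bins/weight"][sel]
            wi, wj = w[i], w[j]
            ok = np.isfinite(wi) & np.isfinite(wj)
            i, j, raw = i[ok], j[ok], raw[ok]
            val = raw * w[i] * w[j]
            return ContactMap.from_entries(chrom, resolution, nb, i, j, val,
                                           balanced=True, raw=raw)
        return ContactMap.from_entries(chrom, resolution, nb, i, j, raw)


def write_cool(path: str, maps: list[ContactMap], weights: dict[str, np.ndarray] | None = None) -> None:
    """Write a single-resolution cool-dialect HDF5 container.

    ``maps`` holds one ContactMap per chromosome (shared resolution). Datasets
    are created with ``track_times=False`` so identical inputs yield
    byte-identical files.
    """
    if not maps:
        raise ValueError("no maps to write")
    res = maps[0].resolution
    if any(m.resolution != res for m in maps):
        raise ValueError("maps must share one resolution")
    names = [m.chrom for m in maps]
    opts = dict(track_times=False)
    with h5py.File(path, "w") as f:
        f.attrs["bin-size"] = res
        f.attrs["format"] = "HDF5::chromloop-cool-dialect"
        g = f.create_group("chroms")
        g.create_dataset("name", data=np.array(names, dtype="S32"), **opts)
        g.create_dataset("length", data=np.array([m.n_bins * res for m in maps], dtype=np.int64), **opts)
        bc, bs, be, bw = [], [], [], []
        offsets, off = {}, 0
        for cid, m in enumerate(maps):
            offsets[m.chrom] = off
            bc.append(np.full(m.n_bins, cid, dtype=np.int32))
            starts = np.arange(m.n_bins, dtype=np.int64) * res
            bs.append(starts)
            be.append(starts + res)
            if weights and m.chrom in weights:
                bw.append(np.asarray(weights[m.chrom], dtype=np.float64))
            off += m.n_bins
        g = f.create_group("bins")
        g.create_dataset("chrom", data=np.concatenate(bc), **opts)
        g.create_dataset("start", data=np.concatenate(bs), **opts)
        g.create_dataset("end", data=np.concatenate(be), **opts)
        if bw:
            g.create_dataset("weight", data=np.concatenate(bw), **opts)
        p1 = np.concatenate([m.bin1 + offsets[m.chrom] for m in maps])
        p2 = np.concatenate([m.bin2 + offsets[m.chrom] for m in maps])
        pv = np.concatenate([m.value for m in maps])
        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=p1, **opts)
        g.create_dataset("bin2_id", data=p2, **opts)
        g.create_dataset("count", data=pv, **opts)


# ---------------------------------------------------------------------------
# accessibility
# ---------------------------------------------------------------------------

def read_accessibility(path: str, chrom: str, resolution: int, n_bins: int) -> AccessibilityTrack:
    """Bin a 1D signal track (bedGraph or bigWig) to per-bin means.

    Each bin's value is the coverage-weighted mean of the signal over
    ``[b*resolution, (b+1)*resolution)``; bases not covered by any interval
    contribute 0 (the mean is over the full bin width). Intervals extending
    past ``n_bins * resolution`` are truncated with a logged warning.
    """
    if str(path).endswith((".bw", ".bigwig", ".bigWig")):
        return _read_bigwig(path, chrom, resolution, n_bins)
    return _read_bedgraph(path, chrom, resolution, n_bins)


def _read_bigwig(path: str, chrom: str, resolution: int, n_bins: int) -> AccessibilityTrack:
    import pyBigWig

    bw = pyBigWig.open(str(path))
    try:
        if chrom not in bw.chroms():
            raise KeyError(f"chromosome {chrom!r} not in {path}")
        end = min(n_bins * resolution, bw.chroms()[chrom])
        nb_avail = -(-end // resolution)
        mean = bw.stats(chrom, 0, end, type="mean", nBins=nb_avail, exact=True)
        cov = bw.stats(chrom, 0, end, type="coverage", nBins=nb_avail, exact=True)
        vals = np.zeros(n_bins)
        for b in range(nb_avail):
            if mean[b] is not None and cov[b] is not None:
                span = min(resolution, end - b * resolution)
                # covered-base mean * covered fraction of the full bin width
                vals[b] = mean[b] * cov[b] * span / resolution
        if np.any(vals < 0):
            raise ValueError("negative signal values in track")
        return AccessibilityTrack(chrom, resolution, vals)
    finally:
        bw.close()


def _read_bedgraph(path: str, chrom: str, resolution: int, n_bins: int) -> AccessibilityTrack:
    limit = n_bins * resolution
    mass = np.zeros(n_bins)
    n_trunc = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            c, start, stop, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if c != chrom:
                continue
            if val < 0:
                raise ValueError(f"{path}:{lineno}: negative signal value {val}")
            if stop > limit:
                n_trunc += 1
                stop = limit
            if start >= stop:
                continue
            b0, b1 = start // resolution, (stop - 1) // resolution
            if b0 == b1:
                mass[b0] += val * (stop - start)
            else:
                mass[b0] += val * ((b0 + 1) * resolution - start)
                if b1 > b0 + 1:
                    mass[b0 + 1 : b1] += val * resolution
                mass[b1] += val * (stop - b1 * resolution)
    if n_trunc:
        log.warning("%s: truncated %d interval(s) beyond %d bp", path, n_trunc, limit)
    return AccessibilityTrack(chrom, resolution, mass / resolution)


# ---------------------------------------------------------------------------
# interactions (BEDPE)
# ---------------------------------------------------------------------------

def _midpoint_bin(start: int, end: int, resolution: int) -> int:
    """Bin containing the interval midpoint; boundary ties go to the left bin."""
    mid2 = start + end  # midpoint * 2, avoids float
    b, rem = divmod(mid2, 2 * resolution)
    if rem == 0 and b > 0:
        return int(b) - 1
    return int(b)


def read_interactions(path: str, resolution: int) -> list[Interaction]:
    """Read intra-chromosomal interactions from BEDPE (6+ columns).

    Anchors are binned by midpoint and ordered so bin1 < bin2.
    Inter-chromosomal rows and rows whose anchors fall in the same bin are
    dropped, with logged counts.
    """
    out: list[Interaction] = []
    n_inter = n_same = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "chrom1\t")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 BEDPE columns")
            try:
                c1, s1, e1 = parts[0], int(parts[1]), int(parts[2])
                c2, s2, e2 = parts[3], int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if c1 != c2:
                n_inter += 1
                continue
            b1 = _midpoint_bin(s1, e1, resolution)
            b2 = _midpoint_bin(s2, e2, resolution)
            if b1 == b2:
                n_same += 1
                continue
            prob = float(parts[6]) if len(parts) > 6 else None
            out.append(Interaction(c1, min(b1, b2), max(b1, b2), probability=prob))
    if n_inter or n_same:
        log.info("%s: dropped %d inter-chromosomal and %d same-bin row(s)",
                 path, n_inter, n_same)
    return out


def write_loops(loops: list, resolution: int, path: str) -> None:
    """Write loops as 7-column BEDPE (anchors as [bin*res, (bin+1)*res) plus
    probability), sorted by (chrom, bin1, bin2). Accepts Interaction or any
    object with chrom/probability and either bin1/bin2 or i/j attributes."""
    rows = []
    for lp in loops:
        b1 = getattr(lp, "bin1", None)
        if b1 is None:
            b1, b2 = lp.i, lp.j
        else:
            b2 = lp.bin2
        p = lp.probability if lp.probability is not None else 1.0
        rows.append((lp.chrom, int(b1), int(b2), float(p)))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, b1, b2, p in rows:
            fh.write(
                f"{chrom}\t{b1 * resolution}\t{(b1 + 1) * resolution}\t"
                f"{chrom}\t{b2 * resolution}\t{(b2 + 1) * resolution}\t{p:.6g}\n"
            )
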