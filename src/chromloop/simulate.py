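"""Synthetic Hi-C study generator.

Emulates the structure of a real loop-calling study at desk scale: a
power-law distance-decay contact background with Poisson counting noise,
point loop enrichments spread by a small Gaussian kernel, an accessibility
track with peaks at loop anchors (plus decoy peaks elsewhere, since real
open-chromatin tracks have far more peaks than loop anchors), and a BEDPE
truth set. ``simulate_study`` writes everything in the formats the readers
consume (triplet text, cool-dialect HDF5, bedGraph, BEDPE, JSON manifest).

The background mean at bin distance d is ``mu(d) = c * (d + 1) ** -alpha``;
a loop at center (ci, cj) with strength s multiplies the local mean by
``1 + (s - 1) * G`` where G is a unit-peak Gaussian of width ``loop_sigma``
bins around the center. Loop centers are kept pairwise separated (Chebyshev)
so pooled calls map one-to-one onto planted loops.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .io import AccessibilityTrack, ContactMap, Interaction, write_cool

__all__ = ["SimParams", "SimBundle", "simulate_contact_map",
           "simulate_accessibility", "simulate_study"]


@dataclass
class SimParams:
    n_chroms: int = 3
    n_bins: int = 2000
    resolution: int = 10000
    decay_amplitude: float = 1200.0  # c: sets the read depth of the map
    decay_exponent: float = 1.3      # alpha
    max_sim_dist: int = 320          # bins; beyond this nothing is simulated
    n_loops: int = 30                # per chromosome
    loop_strength: float = 10.0      # s: fold enrichment at the loop pixel
    loop_sigma: float = 1.5          # bins; spatial width of the enrichment
    loop_min_dist: int = 3           # bins; planted anchor separation range
    loop_max_dist: int = 150
    min_loop_separation: int = 12    # bins, Chebyshev, between loop centers
    acc_baseline: float = 1.0
    acc_peak_height: float = 5.0
    acc_peak_width: float = 0.8      # bins; ATAC peaks are sub-bin at 10 kb
    acc_noise: float = 0.5
    acc_decoy_peaks: int = 40        # accessibility peaks not at loop anchors
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0 or self.decay_amplitude <= 0:
            raise ValueError("decay parameters must be positive")
        if self.loop_strength < 1 or self.loop_sigma <= 0:
            raise ValueError("require loop_strength >= 1 and loop_sigma > 0")
        if self.min_loop_separation <= 2 * self.loop_sigma:
            raise ValueError("loop centers must be separated by more than 2*sigma")
        if not 1 <= self.loop_min_dist < self.loop_max_dist <= self.max_sim_dist:
            raise ValueError("invalid loop distance range")

    def chrom_names(self) -> list[str]:
        return [f"chr{k + 1}" for k in range(self.n_chroms)]


@dataclass
class SimBundle:
    """Paths written by simulate_study, plus the in-memory truth."""

    directory: Path
    chroms: list[str]
    triplet_paths: dict[str, Path]
    cool_path: Path
    bedgraph_path: Path
    truth_path: Path
    manifest_path: Path
    truth: dict[str, list[Interaction]] = field(default_factory=dict)


def _chrom_index(p: SimParams, chrom: str) -> int:
    names = p.chrom_names()
    if chrom not in names:
        raise ValueError(f"unknown chromosome {chrom!r}")
    return names.index(chrom)


def _place_loops(p: SimParams, rng: np.random.Generator) -> list[tuple[int, int]]:
    half = 11  # keep default 23x23 windows in bounds
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < p.n_loops:
        tries += 1
        if tries > 200 * p.n_loops:
            raise ValueError("loop placement infeasible under spacing constraint")
        # log-uniform anchor distances: loop-distance distributions are
        # short-range heavy in real interaction data
        d = int(round(np.exp(rng.uniform(np.log(p.loop_min_dist), np.log(p.loop_max_dist)))))
        d = min(max(d, p.loop_min_dist), p.loop_max_dist)
        i = int(rng.integers(half, p.n_bins - half - d))
        j = i + d
        if all(max(abs(i - ci), abs(j - cj)) >= p.min_loop_separation for ci, cj in centers):
            centers.append((i, j))
    return sorted(centers)


def simulate_contact_map(p: SimParams, chrom: str) -> tuple[ContactMap, list[Interaction]]:
    """Poisson contact map with planted loops; deterministic per (seed, chrom)."""
    cid = _chrom_index(p, chrom)
    rng = np.random.default_rng([p.seed, 1, cid])
    centers = _place_loops(p, rng)

    dmax = min(p.max_sim_dist, p.n_bins - 1)
    # banded mean matrix: lam[i, d] is the mean at pixel (i, i + d)
    mu_d = p.decay_amplitude * np.power(np.arange(dmax + 1) + 1.0, -p.decay_exponent)
    lam = np.tile(mu_d, (p.n_bins, 1))
    reach = int(np.ceil(4 * p.loop_sigma))
    s, sig2 = p.loop_strength, 2 * p.loop_sigma**2
    for ci, cj in centers:
        for di in range(-reach, reach + 1):
            i = ci + di
            if i < 0 or i >= p.n_bins:
                continue
            for dj in range(-reach, reach + 1):
                j = cj + dj
                d = j - i
                if 1 <= d <= dmax and j < p.n_bins:
                    g = np.exp(-(di * di + dj * dj) / sig2)
                    lam[i, d] *= 1.0 + (s - 1.0) * g

    ii, jj, vv = [], [], []
    for d in range(1, dmax + 1):
        n = p.n_bins - d
        draws = rng.poisson(lam[:n, d])
        nz = np.flatnonzero(draws)
        ii.append(nz)
        jj.append(nz + d)
        vv.append(draws[nz])
    cmap = ContactMap(
        chrom, p.resolution, p.n_bins,
        np.concatenate(ii), np.concatenate(jj), np.concatenate(vv).astype(np.float64),
    )
    truth = [Interaction(chrom, ci, cj, label="positive") for ci, cj in centers]
    return cmap, truth


def simulate_accessibility(p: SimParams, truth: list[Interaction], chrom: str) -> AccessibilityTrack:
    """Baseline + Gaussian peaks at loop anchors (and decoy positions) +
    zero-truncated Gaussian noise; deterministic per (seed, chrom)."""
    cid = _chrom_index(p, chrom)
    rng = np.random.default_rng([p.seed, 2, cid])
    x = np.arange(p.n_bins, dtype=np.float64)
    values = np.full(p.n_bins, p.acc_baseline)
    anchor_bins = sorted({b for t in truth for b in (t.bin1, t.bin2)})
    decoys = []
    if p.acc_decoy_peaks:
        anchors = set(anchor_bins)
        pool = np.array([b for b in range(p.n_bins)
                         if min((abs(b - a) for a in anchors), default=p.n_bins) > 3])
        decoys = list(rng.choice(pool, size=min(p.acc_decoy_peaks, len(pool)), replace=False))
    sig2 = 2 * p.acc_peak_width**2
    for b in list(anchor_bins) + decoys:
        values += p.acc_peak_height * np.exp(-((x - b) ** 2) / sig2)
    values = np.maximum(0.0, values + rng.normal(0.0, p.acc_noise, p.n_bins))
    return AccessibilityTrack(chrom, p.resolution, values)


def simulate_study(p: SimParams, outdir: str) -> SimBundle:
    """Write a full study bundle: per-chromosome triplet maps, one cool
    container, a bedGraph track, a BEDPE truth set, and a JSON manifest.
    Byte-identical across reruns with the same parameters."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    chroms = p.chrom_names()
    maps, truth_all, tracks = [], {}, {}
    for chrom in chroms:
        cmap, truth = simulate_contact_map(p, chrom)
        maps.append(cmap)
        truth_all[chrom] = truth
        tracks[chrom] = simulate_accessibility(p, truth, chrom)

    triplet_paths = {}
    for cmap in maps:
        path = out / f"{cmap.chrom}.triplets.txt"
        with open(path, "w") as fh:
            for i, j, v in zip(cmap.bin1, cmap.bin2, cmap.value):
                fh.write(f"{i} {j} {int(v)}\n")
        triplet_paths[cmap.chrom] = path

    cool_path = out / "contacts.cool"
    write_cool(str(cool_path), maps)

    bedgraph_path = out / "accessibility.bedgraph"
    with open(bedgraph_path, "w") as fh:
        for chrom in chroms:
            vals = tracks[chrom].values
            for b, v in enumerate(vals):
                if v > 0:
                    fh.write(f"{chrom}\t{b * p.resolution}\t{(b + 1) * p.resolution}\t{v:.6f}\n")

    truth_path = out / "truth.bedpe"
    with open(truth_path, "w") as fh:
        for chrom in chroms:
            for t in truth_all[chrom]:
                r = p.resolution
                fh.write(f"{chrom}\t{t.bin1 * r}\t{(t.bin1 + 1) * r}\t"
                         f"{chrom}\t{t.bin2 * r}\t{(t.bin2 + 1) * r}\n")

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump({"params": asdict(p), "chroms": chroms,
                   "n_loops": {c: len(truth_all[c]) for c in chroms}}, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return SimBundle(out, chroms, triplet_paths, cool_path, bedgraph_path,
                     truth_path, manifest_path, truth_all)
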