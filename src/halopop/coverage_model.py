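"""Coverage statistics for replicon depth tracks.

The central model: metagenome read depth along a conserved replicon is
approximately normal around a primary mode, but carries a right tail (repeats,
conserved mobile elements, high-copy regions) and a left excess (genomic
islands — strain-variable content carried by only part of the population).
The mode-balanced fit estimates the background normal from the symmetric
monotone region around the histogram mode, excluding both tails by
construction; islands are then maximal >`min_island_len` runs of depth below
``mu - 3*sigma``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .genomics_io import DepthTrack, Interval

__all__ = [
    "BinnedTrack",
    "CoverageFit",
    "GenomicIsland",
    "ContigDepthPoint",
    "bin_median_coverage",
    "fit_mode_balanced_normal",
    "call_islands",
    "scale_rows",
    "gc_coverage_cluster",
]

#: default bin sizes for abundance binning, by replicon role
DEFAULT_BIN_SIZES = {"primary": 5000, "secondary": 1000}


@dataclass
class BinnedTrack:
    """Per-bin median depth along a replicon (bins tile [0, length))."""

    seq_id: str
    bin_size: int
    medians: np.ndarray
    length: int

    @property
    def bin_labels(self) -> list[str]:
        """`seqid:start-end` labels, 0-based half-open."""
        out = []
        for i in range(self.medians.size):
            end = min((i + 1) * self.bin_size, self.length)
            out.append(f"{self.seq_id}:{i * self.bin_size}-{end}")
        return out


@dataclass
class CoverageFit:
    """Mode-balanced normal fit of a depth distribution.

    ``cutoff = max(0, mu - 3*sigma)`` is the island-calling threshold.
    ``fit_window`` is the [lo, hi) depth range used for the MLE. Degenerate
    fits (too few in-window positions, or zero variance) never call islands.
    """

    seq_id: str
    mode: float
    mu: float
    sigma: float
    cutoff: float
    fit_window: tuple[float, float]
    n_fit: int
    degenerate: bool = False


@dataclass
class GenomicIsland:
    """A low-coverage region: flexible genome content carried by only part of
    the population."""

    interval: Interval
    mean_depth: float
    cutoff_used: float


@dataclass
class ContigDepthPoint:
    """One contig in GC/coverage space; `group` is the depth-cluster label
    (-1 = outlier)."""

    contig_id: str
    gc: float
    depth: float
    group: int = -1


def bin_median_coverage(track: DepthTrack, bin_size: int) -> BinnedTrack:
    """Median depth in consecutive `bin_size` windows (last bin may be
    partial and uses the available positions)."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n = track.length
    n_full = n // bin_size
    medians = []
    if n_full:
        medians.append(
            np.median(track.depth[: n_full * bin_size].reshape(n_full, bin_size), axis=1)
        )
    if n % bin_size:
        medians.append([np.median(track.depth[n_full * bin_size :])])
    return BinnedTrack(track.seq_id, bin_size, np.concatenate(medians), n)


def fit_mode_balanced_normal(
    track: DepthTrack,
    hist_bin_width: float = 1.0,
    min_fit_positions: int = 100,
    noise_tolerance: float = 5.0,
) -> CoverageFit:
    """Fit the background depth distribution around its primary mode.

    A histogram at `hist_bin_width` is built; the largest bin is the primary
    mode (ties break toward lower depth). The region around the mode is
    expanded left and right while bin counts are monotonically non-increasing
    away from it, then truncated symmetrically to ``w = min(left, right)``
    bins. mu and sigma are the plain Gaussian MLE (sample mean, 1/n SD) over
    positions whose depth falls in the balanced window.

    Monotonicity is judged against sampling noise: a side's extent ends at
    the first bin whose count rises more than ``noise_tolerance *
    sqrt(count)`` above the running minimum on that side (adjacent-bin
    differences near the mode are smaller than their multinomial noise, so a
    literal per-bin rule truncates almost immediately on real data).
    ``noise_tolerance=0`` recovers the strict per-bin rule.
    """
    depth = track.depth
    if depth.size == 0:
        raise ValueError("empty track")
    if not np.any(depth > 0):
        warnings.warn(f"all-zero depth track {track.seq_id}: degenerate fit")
        return CoverageFit(track.seq_id, 0.0, 0.0, 0.0, 0.0, (0.0, 0.0), 0, True)

    nbins = int(np.floor(depth.max() / hist_bin_width)) + 1
    edges = np.arange(nbins + 1) * hist_bin_width
    counts, _ = np.histogram(depth, bins=edges)
    mode_idx = int(np.argmax(counts))  # argmax takes the first = lowest depth
    mode = float(edges[mode_idx])

    def extent(step: int) -> int:
        i = mode_idx
        run_min = float(counts[mode_idx])
        while True:
            j = i + step
            if j < 0 or j >= nbins:
                break
            if counts[j] > run_min + noise_tolerance * np.sqrt(max(run_min, 1.0)):
                break
            run_min = min(run_min, float(counts[j]))
            i = j
        return abs(i - mode_idx)

    w = min(extent(-1), extent(+1))
    lo = edges[mode_idx - w]
    hi = edges[mode_idx + w + 1]
    sel = depth[(depth >= lo) & (depth < hi)]
    n_fit = int(sel.size)
    if n_fit < min_fit_positions:
        warnings.warn(
            f"{track.seq_id}: only {n_fit} positions in the balanced window; "
            "degenerate fit"
        )
        return CoverageFit(track.seq_id, mode, 0.0, 0.0, 0.0, (float(lo), float(hi)), n_fit, True)
    mu = float(sel.mean())
    sigma = float(sel.std(ddof=0))
    degenerate = sigma == 0.0
    cutoff = max(0.0, mu - 3.0 * sigma)
    return CoverageFit(track.seq_id, mode, mu, sigma, cutoff, (float(lo), float(hi)), n_fit, degenerate)


def call_islands(
    track: DepthTrack,
    fit: CoverageFit,
    min_island_len: int = 1000,
    smooth_window: int = 1,
    max_gap: int = 0,
) -> list[GenomicIsland]:
    """Call genomic islands: maximal runs of (optionally running-median
    smoothed) depth strictly below ``fit.cutoff``, longer than
    `min_island_len` (strict).

    `smooth_window` must be odd; 1 disables smoothing. Runs separated by at
    most `max_gap` above-cutoff positions are joined before the length
    filter. Mean depth is reported on the raw (unsmoothed) track.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    if fit.degenerate:
        warnings.warn(f"{track.seq_id}: degenerate fit; no islands called")
        return []
    depth = track.depth
    smoothed = depth if smooth_window == 1 else median_filter(depth, size=smooth_window, mode="nearest")
    below = smoothed < fit.cutoff
    edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    if max_gap > 0 and starts.size > 1:
        keep_s, keep_e = [starts[0]], [ends[0]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - keep_e[-1] <= max_gap:
                keep_e[-1] = e
            else:
                keep_s.append(s)
                keep_e.append(e)
        starts, ends = np.array(keep_s), np.array(keep_e)
    islands = []
    for s, e in zip(starts, ends):
        if e - s > min_island_len:
            islands.append(
                GenomicIsland(
                    interval=Interval(track.seq_id, int(s), int(e)),
                    mean_depth=float(depth[s:e].mean()),
                    cutoff_used=fit.cutoff,
                )
            )
    return islands


def scale_rows(matrix: np.ndarray) -> np.ndarray:
    """Centre and scale each row to mean 0, SD 1 (population SD), as for
    heat-map display of per-location binned coverage.

    All-constant rows become all-zero with a warning. Idempotent up to
    floating tolerance.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 1:
        raise ValueError("matrix must be 2-D and non-empty")
    mean = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True, ddof=0)
    const = (sd == 0).ravel()
    if const.any():
        warnings.warn(f"{const.sum()} constant row(s) scaled to zeros")
    sd = np.where(sd == 0, 1.0, sd)
    out = (m - mean) / sd
    out[const, :] = 0.0
    return out


def _optimal_1d_partition(values: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive optimal 1-D k-partition minimising within-group sum of
    squares (dynamic programme over sorted values). Returns group labels
    0..k-1 in increasing value order."""
    n = values.size
    order = np.argsort(values, kind="stable")
    x = values[order]
    # prefix sums for O(1) segment SSE
    ps = np.concatenate(([0.0], np.cumsum(x)))
    ps2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def sse(i: int, j: int) -> float:  # segment [i, j)
        n_ij = j - i
        s = ps[j] - ps[i]
        return (ps2[j] - ps2[i]) - s * s / n_ij

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best, arg = INF, m - 1
            for i in range(m - 1, j):
                c = cost[m - 1, i] + sse(i, j)
                if c < best:
                    best, arg = c, i
            cost[m, j] = best
            back[m, j] = arg
    labels_sorted = np.zeros(n, dtype=int)
    j = n
    for m in range(k, 0, -1):
        i = back[m, j]
        labels_sorted[i:j] = m - 1
        j = i
    labels = np.zeros(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def gc_coverage_cluster(points: list[ContigDepthPoint], k: int) -> list[ContigDepthPoint]:
    """Group contigs into `k` depth clusters (candidate replicons / copy-number
    classes) by exhaustive optimal 1-D partition of log2(depth).

    GC is carried for reporting/plotting only. Points more than 3 group SDs
    from every group mean (on the log2 scale) are labelled -1. Depths must be
    positive (log scale).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(points) < k:
        raise ValueError(f"need >= {k} points for k={k}")
    depths = np.array([p.depth for p in points], dtype=float)
    if np.any(depths <= 0):
        raise ValueError("depths must be > 0 for log2 clustering")
    x = np.log2(depths)
    labels = _optimal_1d_partition(x, k)
    means = np.array([x[labels == g].mean() for g in range(k)])
    sds = np.array([x[labels == g].std(ddof=0) for g in range(k)])
    out = []
    for p, xi, g in zip(points, x, labels):
        outlier = bool(np.all(np.abs(xi - means) > 3 * sds))
        out.append(ContigDepthPoint(p.contig_id, p.gc, p.depth, -1 if outlier else int(g)))
    return out
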