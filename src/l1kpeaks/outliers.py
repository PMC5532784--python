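"""Density-gap outlier detection for bead intensities.

Before any mixture fitting, each sample's beads of a color are screened for
stray measurements: a Gaussian kernel density estimate is computed on a fixed
grid, regions where the density falls below ``dy_thr`` are declared data-free
gaps, the gaps partition the beads into clusters, and any cluster smaller
than ``clustersize_thr`` beads is discarded as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OutlierConfig",
    "DensityCurve",
    "ClusterSplit",
    "OutlierResult",
    "DegenerateInputError",
    "estimate_density",
    "split_by_gaps",
    "detect_outliers",
]


class DegenerateInputError(ValueError):
    """Too few or zero-spread intensities for density estimation."""


@dataclass(frozen=True)
class OutlierConfig:
    """Tuning knobs of the density-gap screen.

    dy_thr : density below which a grid region counts as a data-free gap.
    clustersize_thr : minimum beads for a gap-separated cluster to be kept.
    grid_size : number of equally spaced KDE evaluation points.
    min_kept : samples keeping fewer beads than this are excluded from
        joint fitting (a 4-parameter two-component mixture is unidentifiable
        below 4 observations).
    """

    dy_thr: float = 1e-4
    clustersize_thr: int = 3
    grid_size: int = 512
    bandwidth_rule: str = "rule-of-thumb"
    min_kept: int = 4

    def __post_init__(self) -> None:
        if not self.dy_thr > 0:
            raise ValueError("dy_thr must be positive")
        if self.clustersize_thr < 1:
            raise ValueError("clustersize_thr must be >= 1")
        if self.grid_size < 64:
            raise ValueError("grid_size must be >= 64")
        if self.bandwidth_rule != "rule-of-thumb":
            raise ValueError(f"unknown bandwidth rule {self.bandwidth_rule!r}")


@dataclass(frozen=True)
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


@dataclass(frozen=True)
class ClusterSplit:
    """Gap-based partition of the input indices, ordered by intensity."""

    clusters: tuple[np.ndarray, ...]
    gap_intervals: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class OutlierResult:
    kept: np.ndarray
    outliers: np.ndarray
    split: ClusterSplit | None
    degenerate: bool = False

    @property
    def n_removed(self) -> int:
        return int(self.outliers.size)


def _bandwidth(x: np.ndarray) -> float:
    """Silverman rule-of-thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5).

    Falls back through sd, |x[0]| and 1 when the leading scale estimate is
    zero (ties can zero the IQR while the spread is real).
    """
    n = x.size
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    lo = min(sd, iqr / 1.34)
    if lo == 0.0:
        lo = sd or abs(float(x[0])) or 1.0
    return 0.9 * lo * n ** (-0.2)


def estimate_density(x, config: OutlierConfig = OutlierConfig()) -> DensityCurve:
    """Gaussian-kernel KDE on a regular grid spanning the data +/- 3 bandwidths.

    The curve is renormalized to integrate to 1 over the grid (trapezoidal
    rule), so thresholding against ``dy_thr`` is scale-consistent.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need at least 2 intensities for a KDE")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("zero spread: all intensities identical")
    h = _bandwidth(x)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, config.grid_size)
    z = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))
    dens /= np.trapezoid(dens, grid)
    return DensityCurve(grid=grid, density=dens, bandwidth=h)


def split_by_gaps(x, curve: DensityCurve, dy_thr: float = 1e-4) -> ClusterSplit:
    """Partition points by the data-free gaps of the density curve.

    Maximal runs of consecutive grid points with density < ``dy_thr`` form
    gap intervals; two data points are separated iff a below-threshold grid
    point lies strictly between them (so raising ``dy_thr`` can only split
    clusters further).  With no gap, a single cluster holds all indices.
    """
    x = np.asarray(x, dtype=float)
    below = curve.density < dy_thr
    gaps: list[tuple[float, float]] = []
    i = 0
    g = curve.grid
    while i < below.size:
        if below[i]:
            j = i
            while j + 1 < below.size and below[j + 1]:
                j += 1
            gaps.append((float(g[i]), float(g[j])))
            i = j + 1
        else:
            i += 1

    order = np.argsort(x, kind="stable")
    xs = x[order]
    g_below = g[below]
    labels = np.zeros(x.size, dtype=int)
    lab = 0
    for k in range(1, xs.size):
        a, b = xs[k - 1], xs[k]
        lo = np.searchsorted(g_below, a, side="right")
        hi = np.searchsorted(g_below, b, side="left")
        if hi > lo:  # a sub-threshold grid point strictly between a and b
            lab += 1
        labels[k] = lab
    clusters = tuple(
        np.sort(order[labels == c]) for c in range(lab + 1)
    )
    return ClusterSplit(clusters=clusters, gap_intervals=tuple(gaps))


def detect_outliers(x, config: OutlierConfig = OutlierConfig()) -> OutlierResult:
    """Flag beads in gap-separated clusters smaller than ``clustersize_thr``.

    Degenerate inputs (fewer than 2 beads, or zero spread) skip detection and
    keep everything.  If *every* cluster falls below the size threshold, the
    largest cluster is retained so downstream fitting always has data.
    """
    x = np.asarray(x, dtype=float)
    all_idx = np.arange(x.size)
    try:
        curve = estimate_density(x, config)
    except DegenerateInputError:
        return OutlierResult(
            kept=all_idx, outliers=np.empty(0, dtype=int), split=None, degenerate=True
        )
    split = split_by_gaps(x, curve, config.dy_thr)
    small = [c for c in split.clusters if c.size < config.clustersize_thr]
    if len(small) == len(split.clusters):
        # never empty the sample: keep the largest cluster
        largest = max(split.clusters, key=lambda c: c.size)
        kept = largest
        outliers = np.setdiff1d(all_idx, largest)
    else:
        outliers = (
            np.sort(np.concatenate(small)) if small else np.empty(0, dtype=int)
        )
        kept = np.setdiff1d(all_idx, outliers)
    return OutlierResult(kept=kept, outliers=outliers, split=split)
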