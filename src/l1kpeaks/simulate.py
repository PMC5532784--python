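"""Hierarchical simulator of bead-level two-gene color data.

Each color carries two latent peaks.  Their separation is drawn from a
Gamma distribution and their midpoint from a Gaussian — the two families
that peak separations and averages follow in real A375/luciferase
deconvolution output — then beads are drawn around each peak from Gaussians
with a common SD at a 2:1 bead ratio, and a Poisson-distributed number of
uniform stray beads is sprinkled over a widened intensity range.

Randomness is hierarchical: every color owns an independent generator seeded
by (seed, color index), so enlarging the panel never perturbs the draws of
earlier colors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BeadVector, ColorGroup, PeakCall

__all__ = ["SimHyperParams", "SimulatedDataset", "fit_hyperparams_from_peaks",
           "simulate_dataset"]

TRUTH_COLUMNS = (
    "color_id",
    "sample_id",
    "true_mu_high",
    "true_mu_low",
    "n_outliers_injected",
)


@dataclass(frozen=True)
class SimHyperParams:
    """Generator settings.

    Defaults emulate the LINCS L1000 replicate layout: 10 samples x 500
    colors, 60 beads per color per sample split 40:20 between the two genes,
    peak separations ~ Gamma(4, rate 4) (mean 1.0 on the log-intensity
    scale), peak midpoints ~ Normal(7, 1), bead SD 0.2, and on average 2
    uniform stray beads per color, scattered over its samples.
    ``sample_jitter_sd`` (default 0:
    peaks common to all replicates) adds per-sample wobble to both peak
    means.  ``jitter_bead_counts`` replaces the exact 40/20 split with
    Poisson counts of the same means.
    """

    n_samples: int = 10
    n_colors: int = 500
    beads_high: int = 40
    beads_low: int = 20
    diff_shape: float = 4.0
    diff_rate: float = 4.0
    avg_mean: float = 7.0
    avg_sd: float = 1.0
    bead_sd: float = 0.2
    outlier_poisson_mean: float = 2.0  # mean stray beads per color (all samples)
    outlier_margin: float = 2.0
    sample_jitter_sd: float = 0.0
    jitter_bead_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_colors, self.beads_high, self.beads_low) < 1:
            raise ValueError("counts must be positive")
        for name in ("diff_shape", "diff_rate", "avg_sd", "bead_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.outlier_poisson_mean < 0 or self.sample_jitter_sd < 0:
            raise ValueError("rates and SDs must be non-negative")


@dataclass(frozen=True, eq=False)
class SimulatedDataset:
    """Bead tables plus the ground-truth peak table used for scoring."""

    beads: tuple[ColorGroup, ...]
    truth: pd.DataFrame
    params: SimHyperParams

    def __post_init__(self) -> None:
        if list(self.truth.columns) != list(TRUTH_COLUMNS):
            raise ValueError(f"truth table must have columns {TRUTH_COLUMNS}")


def fit_hyperparams_from_peaks(peaks: list[PeakCall]) -> SimHyperParams:
    """Re-derive generator hyperparameters from a real peak table.

    Method-of-moments on the peak separations mu_high - mu_low
    (Gamma: shape = mean^2/var, rate = mean/var) and sample mean/SD of the
    peak averages (mu_high + mu_low)/2; every other field keeps its default.
    """
    if len(peaks) < 10:
        raise ValueError("need at least 10 peak calls to fit hyperparameters")
    diffs = np.array([p.mu_high - p.mu_low for p in peaks], dtype=float)
    avgs = np.array([0.5 * (p.mu_high + p.mu_low) for p in peaks], dtype=float)
    var = diffs.var(ddof=1)
    if var == 0.0:
        raise ValueError("zero variance of peak separations")
    mean = diffs.mean()
    return SimHyperParams(
        diff_shape=float(mean * mean / var),
        diff_rate=float(mean / var),
        avg_mean=float(avgs.mean()),
        avg_sd=float(avgs.std(ddof=1)),
    )


def _color_rng(seed: int, c: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(c,)))


def simulate_dataset(params: SimHyperParams = SimHyperParams()) -> SimulatedDataset:
    """Draw a full synthetic bead dataset with its ground-truth peak table."""
    groups: list[ColorGroup] = []
    rows: list[tuple] = []
    cw = len(str(params.n_colors - 1))
    sw = len(str(params.n_samples - 1))
    sample_ids = [f"s{j:0{sw}d}" for j in range(params.n_samples)]
    for c in range(params.n_colors):
        rng = _color_rng(params.seed, c)
        color_id = f"c{c:0{cw}d}"
        diff = rng.gamma(params.diff_shape, 1.0 / params.diff_rate)
        avg = rng.normal(params.avg_mean, params.avg_sd)
        mu_high = avg + 0.5 * diff
        mu_low = avg - 0.5 * diff
        lo_support = mu_low - diff - params.outlier_margin
        hi_support = mu_high + diff + params.outlier_margin
        # stray beads are sparse per color: a Poisson total for the color,
        # scattered uniformly over its samples
        k_total = int(rng.poisson(params.outlier_poisson_mean))
        outlier_sample = rng.integers(0, params.n_samples, size=k_total)
        vecs = []
        for s_index, sid in enumerate(sample_ids):
            if params.sample_jitter_sd > 0:
                jitter = rng.normal(0.0, params.sample_jitter_sd, size=2)
            else:
                jitter = np.zeros(2)
            hi_i = mu_high + jitter[0]
            lo_i = mu_low + jitter[1]
            if lo_i > hi_i:  # extreme jitter on a barely separated color
                hi_i, lo_i = lo_i, hi_i
            if params.jitter_bead_counts:
                n_hi = max(1, int(rng.poisson(params.beads_high)))
                n_lo = max(1, int(rng.poisson(params.beads_low)))
            else:
                n_hi, n_lo = params.beads_high, params.beads_low
            k = int((outlier_sample == s_index).sum())
            beads = np.concatenate(
                [
                    rng.normal(hi_i, params.bead_sd, size=n_hi),
                    rng.normal(lo_i, params.bead_sd, size=n_lo),
                    rng.uniform(lo_support, hi_support, size=k),
                ]
            )
            rng.shuffle(beads)
            vecs.append(BeadVector(sid, color_id, beads))
            rows.append((color_id, sid, float(hi_i), float(lo_i), k))
        groups.append(ColorGroup(color_id, tuple(vecs)))
    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    return SimulatedDataset(beads=tuple(groups), truth=truth, params=params)
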