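"""Domain containers and delimited-text readers/writers.

The native bead-level format is a long table with columns ``sample_id``,
``color_id``, ``intensity`` — one row per bead, intensities already on the
analysis scale (the package never transforms them).  Peak tables and truth
tables are TSV with one row per fitted peak pair / true peak pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeadVector",
    "ColorGroup",
    "PeakCall",
    "read_beads",
    "write_beads",
    "read_peaks",
    "write_peaks",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an input table violates the expected layout."""


@dataclass(frozen=True)
class BeadVector:
    """All bead intensities of one color channel in one sample."""

    sample_id: str
    color_id: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.intensities, dtype=float)
        if x.ndim != 1 or x.size < 1:
            raise ValueError("intensities must be a non-empty 1-D array")
        if not np.all(np.isfinite(x)):
            raise ValueError(
                f"non-finite intensity in sample {self.sample_id!r}, "
                f"color {self.color_id!r}"
            )
        object.__setattr__(self, "intensities", x)

    @property
    def n(self) -> int:
        return int(self.intensities.size)


@dataclass(frozen=True)
class ColorGroup:
    """The m replicate bead vectors of one color — the unit of joint fitting."""

    color_id: str
    samples: tuple[BeadVector, ...]

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        if len(samples) < 1:
            raise ValueError("a ColorGroup needs at least one sample")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample_ids in color {self.color_id!r}")
        for s in samples:
            if s.color_id != self.color_id:
                raise ValueError(
                    f"sample {s.sample_id!r} has color {s.color_id!r}, "
                    f"expected {self.color_id!r}"
                )
        object.__setattr__(self, "samples", samples)

    @property
    def m(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)


@dataclass(frozen=True)
class PeakCall:
    """One sample's deconvolution result: two peak means and mixture weights.

    ``mu_high``/``mu_low`` are the fitted peak locations sorted so that
    ``mu_high >= mu_low``.  ``lam`` is the proportion of beads attributed to
    the *high* peak (for k-medians: the fraction of beads in the cluster with
    the higher median, so the majority/minority gene identity is recoverable
    for all methods).  ``sigma`` is the shared within-peak standard deviation;
    it is None for k-medians, which fits no variance.
    """

    sample_id: str
    color_id: str
    method: str  # {"kmedians", "gmm", "agmm"}
    mu_high: float
    mu_low: float
    lam: float
    sigma: float | None = None
    n_used: int = 0
    n_outliers_removed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("kmedians", "gmm", "agmm"):
            raise ValueError(f"unknown method {self.method!r}")
        if not (self.mu_high >= self.mu_low):
            raise ValueError(
                f"mu_high ({self.mu_high}) < mu_low ({self.mu_low}) for "
                f"sample {self.sample_id!r} color {self.color_id!r}"
            )
        if not (0.0 < self.lam < 1.0):
            raise ValueError(f"lambda must lie in (0, 1), got {self.lam}")
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


_BEAD_COLUMNS = ("sample_id", "color_id", "intensity")

_PEAK_COLUMNS = (
    "sample_id",
    "color_id",
    "method",
    "mu_high",
    "mu_low",
    "lambda",
    "sigma",
    "n_used",
    "n_outliers_removed",
)


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")


def read_beads(path, dialect: str = "tsv") -> list[ColorGroup]:
    """Read a long-format bead table and group it by color, then sample.

    Bead order within a sample is preserved as file order; the returned list
    contains one :class:`ColorGroup` per distinct ``color_id``, in order of
    first appearance.
    """
    try:
        df = pd.read_csv(path, sep=_sep(dialect))
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty bead table: {path}") from None
    for col in _BEAD_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"bead table {path} is missing column {col!r}")
    if len(df) == 0:
        raise FormatError(f"bead table {path} has a header but no rows")
    intensities = pd.to_numeric(df["intensity"], errors="coerce")
    bad = np.flatnonzero(intensities.isna().to_numpy())
    if bad.size:
        # +2: header line plus 1-based numbering
        raise FormatError(
            f"non-numeric intensity at line {bad[0] + 2} of {path}: "
            f"{df['intensity'].iloc[bad[0]]!r}"
        )
    df = df.assign(intensity=intensities.to_numpy(dtype=float))

    groups: list[ColorGroup] = []
    for color_id, cdf in df.groupby("color_id", sort=False):
        vecs = tuple(
            BeadVector(str(sample_id), str(color_id), sdf["intensity"].to_numpy())
            for sample_id, sdf in cdf.groupby("sample_id", sort=False)
        )
        groups.append(ColorGroup(str(color_id), vecs))
    return groups


def write_beads(path, groups: Iterable[ColorGroup], dialect: str = "tsv") -> None:
    """Write color groups back to the long-format bead table."""
    records = []
    for g in groups:
        for s in g.samples:
            records.append(
                pd.DataFrame(
                    {
                        "sample_id": s.sample_id,
                        "color_id": s.color_id,
                        "intensity": s.intensities,
                    }
                )
            )
    if not records:
        raise ValueError("no color groups to write")
    pd.concat(records, ignore_index=True).to_csv(
        path, sep=_sep(dialect), index=False, float_format="%.10g"
    )


def write_peaks(path, calls: Sequence[PeakCall], dialect: str = "tsv") -> None:
    """Write peak calls as a delimited table (>= 6 significant digits)."""
    calls = list(calls)
    if not calls:
        raise ValueError("no peak calls to write")
    df = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "color_id": [c.color_id for c in calls],
            "method": [c.method for c in calls],
            "mu_high": [c.mu_high for c in calls],
            "mu_low": [c.mu_low for c in calls],
            "lambda": [c.lam for c in calls],
            "sigma": [c.sigma if c.sigma is not None else np.nan for c in calls],
            "n_used": [c.n_used for c in calls],
            "n_outliers_removed": [c.n_outliers_removed for c in calls],
        }
    )
    df.to_csv(path, sep=_sep(dialect), index=False, float_format="%.10g")


def read_peaks(path, dialect: str = "tsv") -> list[PeakCall]:
    """Read back a peak table written by :func:`write_peaks`."""
    df = pd.read_csv(path, sep=_sep(dialect))
    for col in _PEAK_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"peak table {path} is missing column {col!r}")
    df = df.rename(columns={"lambda": "lam"})
    calls = []
    for row in df.itertuples(index=False):
        sigma = float(row.sigma)
        calls.append(
            PeakCall(
                sample_id=str(row.sample_id),
                color_id=str(row.color_id),
                method=str(row.method),
                mu_high=float(row.mu_high),
                mu_low=float(row.mu_low),
                lam=float(row.lam),
                sigma=None if np.isnan(sigma) else sigma,
                n_used=int(row.n_used),
                n_outliers_removed=int(row.n_outliers_removed),
            )
        )
    return calls
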