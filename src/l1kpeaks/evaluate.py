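"""Benchmark metrics for peak calling accuracy.

Predictions are paired with truth *by rank* (predicted high peak vs true
high peak, low vs low), so a flipped call shows up as two large errors.
Flip counting instead uses *gene identity*: the component carrying the
majority bead proportion (lambda >= 0.5) is taken to be the majority gene
of the 2:1 bead design, and a sample is flipped when that majority-gene
predicted mean sits on the opposite side of the minority-gene mean relative
to truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import PeakCall
from .outliers import OutlierConfig
from .deconv import FitError, deconv_group
from .simulate import SimulatedDataset

__all__ = [
    "pair_predictions",
    "pcc",
    "williams_test",
    "true_predictions",
    "mean_absolute_error",
    "count_flips",
    "BenchmarkReport",
    "benchmark",
    "BENCHMARK_METHODS",
]

#: benchmark entries: (label, method, apply_outlier_filter)
BENCHMARK_METHODS = (
    ("kmedians", "kmedians", False),
    ("gmm", "gmm", False),
    ("agmm_nofilter", "agmm", False),
    ("agmm", "agmm", True),
)

TRUE_PREDICTION_THR = 0.05


def pair_predictions(truth: pd.DataFrame, calls: list[PeakCall]) -> pd.DataFrame:
    """Join peak calls to the truth table, pairing high<->high and low<->low.

    Returns one row per (color, sample, rank) with columns color_id,
    sample_id, peak_rank, true_value, predicted_value, method, lam.
    """
    if not calls:
        raise ValueError("no peak calls to pair")
    pred = pd.DataFrame(
        {
            "color_id": [c.color_id for c in calls],
            "sample_id": [c.sample_id for c in calls],
            "method": [c.method for c in calls],
            "mu_high": [c.mu_high for c in calls],
            "mu_low": [c.mu_low for c in calls],
            "lam": [c.lam for c in calls],
        }
    )
    merged = pred.merge(truth, on=["color_id", "sample_id"], how="left")
    missing = merged["true_mu_high"].isna()
    if missing.any():
        bad = merged.loc[missing, ["color_id", "sample_id"]].apply(tuple, axis=1)
        raise KeyError(f"no truth rows for: {sorted(set(bad))[:10]}")
    long = pd.concat(
        [
            merged.assign(
                peak_rank="high",
                true_value=merged["true_mu_high"],
                predicted_value=merged["mu_high"],
            ),
            merged.assign(
                peak_rank="low",
                true_value=merged["true_mu_low"],
                predicted_value=merged["mu_low"],
            ),
        ],
        ignore_index=True,
    )
    return long[
        [
            "color_id",
            "sample_id",
            "peak_rank",
            "true_value",
            "predicted_value",
            "method",
            "lam",
        ]
    ]


def pcc(a, b) -> float:
    """Pearson product-moment correlation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or a.size != b.size:
        raise ValueError("need >= 3 paired observations")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(a, b).statistic)


def williams_test(r13: float, r23: float, r12: float, n: int):
    """Williams's t-test for two dependent correlations sharing a variable.

    r13 and r23 are the correlations of methods A and B with the shared
    truth, r12 the correlation between the two methods, all over the same n
    paired observations.  Returns (t, p, df) with df = n - 3 and a
    two-sided p from Student's t:

        t = (r13 - r23) * sqrt( (n-1)(1+r12) /
              ( 2K(n-1)/(n-3) + rbar^2 (1-r12)^3 ) )

    with K = 1 - r12^2 - r13^2 - r23^2 + 2 r12 r13 r23 (the determinant of
    the 3x3 correlation matrix) and rbar = (r13 + r23)/2.
    """
    if n < 4:
        raise ValueError("Williams's test needs n >= 4")
    for r in (r13, r23, r12):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly in (-1, 1)")
    K = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if K <= 0:
        raise ValueError("inconsistent correlation matrix (determinant <= 0)")
    rbar = 0.5 * (r13 + r23)
    denom = 2 * K * (n - 1) / (n - 3) + rbar**2 * (1 - r12) ** 3
    t = (r13 - r23) * np.sqrt((n - 1) * (1 + r12) / denom)
    df = n - 3
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), int(df)


def true_predictions(paired: pd.DataFrame, thr: float = TRUE_PREDICTION_THR) -> int:
    """Count predictions whose absolute error is strictly below ``thr``."""
    if len(paired) == 0:
        raise ValueError("empty paired table")
    err = (paired["predicted_value"] - paired["true_value"]).abs()
    return int((err < thr).sum())


def mean_absolute_error(paired: pd.DataFrame) -> float:
    if len(paired) == 0:
        raise ValueError("empty paired table")
    return float((paired["predicted_value"] - paired["true_value"]).abs().mean())


def count_flips(paired: pd.DataFrame, reference: str = "within_color") -> pd.Series:
    """Per-color count of samples whose predicted peak order is flipped.

    Gene identity of a prediction is carried by the mixing proportion: the
    component with the majority bead share (lambda >= 0.5) is the majority
    gene of the 2:1 bead design.  Each sample's *order* is the sign of
    (majority-gene mean) - (minority-gene mean).

    reference="within_color" (default): a sample is flipped when its order
    disagrees with the majority order of the other samples of the same
    color — the across-replicate inconsistency that joint fitting with the
    delta >= 0 constraint eliminates by construction (a jointly fitted
    color always counts 0).

    reference="truth": a sample is flipped when its order opposes the sign
    of (true high) - (true low), i.e. the majority gene is predicted on the
    wrong side of the minority gene.
    """
    if reference not in ("within_color", "truth"):
        raise ValueError(f"unknown reference {reference!r}")
    need = {"high", "low"}
    wide = paired.pivot_table(
        index=["color_id", "sample_id", "lam"],
        columns="peak_rank",
        values=["true_value", "predicted_value"],
        aggfunc="first",
    )
    if set(wide["true_value"].columns) != need:
        raise ValueError("each (color, sample) needs both high and low rows")
    wide = wide.reset_index()
    lam = wide["lam"].to_numpy(float)
    pred_hi = wide[("predicted_value", "high")].to_numpy(float)
    pred_lo = wide[("predicted_value", "low")].to_numpy(float)
    true_hi = wide[("true_value", "high")].to_numpy(float)
    true_lo = wide[("true_value", "low")].to_numpy(float)
    # majority gene's predicted mean minus minority gene's predicted mean
    maj_minus_min = np.where(lam >= 0.5, pred_hi - pred_lo, pred_lo - pred_hi)
    order = np.sign(maj_minus_min)
    colors = pd.Series(wide["color_id"].to_numpy().ravel(), name="color_id")
    if reference == "truth":
        ref = np.sign(true_hi - true_lo)
    else:
        # majority order within the color; exact ties resolve to the
        # truth-like order +1
        per_color = pd.Series(order).groupby(colors).transform("sum")
        ref = np.where(per_color.to_numpy() >= 0, 1.0, -1.0)
    flipped = order * ref < 0
    return (
        pd.Series(flipped.astype(int))
        .groupby(colors)
        .sum()
        .rename("n_flips")
    )


@dataclass(frozen=True, eq=False)
class BenchmarkReport:
    """All Results-section metrics for one simulated dataset."""

    seed: int
    hyperparams: dict
    metrics: dict  # label -> {pcc, n_true_predictions, mean_absolute_error,
    #                          total_flips, n_failed_colors}
    flips_per_color: dict  # label -> {color_id: n}
    williams: dict  # "agmm_vs_<label>" -> {t, p, df, r13, r23, r12, n}
    n_paired_rows: int

    def to_json(self, path=None) -> str:
        payload = {
            "seed": self.seed,
            "hyperparams": self.hyperparams,
            "n_paired_rows": self.n_paired_rows,
            "metrics": self.metrics,
            "williams": self.williams,
            "flips_per_color": self.flips_per_color,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_table(self) -> str:
        """Text table: true-prediction counts and MAE per method."""
        labels = list(self.metrics)
        header = f"{'metric':<24}" + "".join(f"{l:>16}" for l in labels)
        rows = [header]
        rows.append(
            f"{'# true predictions':<24}"
            + "".join(
                f"{self.metrics[l]['n_true_predictions']:>16d}" for l in labels
            )
        )
        rows.append(
            f"{'mean absolute error':<24}"
            + "".join(
                f"{self.metrics[l]['mean_absolute_error']:>16.4f}" for l in labels
            )
        )
        rows.append(
            f"{'PCC':<24}"
            + "".join(f"{self.metrics[l]['pcc']:>16.4f}" for l in labels)
        )
        rows.append(
            f"{'total flips':<24}"
            + "".join(f"{self.metrics[l]['total_flips']:>16d}" for l in labels)
        )
        return "\n".join(rows)


def benchmark(
    dataset: SimulatedDataset,
    methods=BENCHMARK_METHODS,
    config: OutlierConfig = OutlierConfig(),
) -> BenchmarkReport:
    """Run every method on a simulated dataset and score it against truth.

    Per-color fit failures are excluded from that method's metrics and
    counted in ``n_failed_colors``.  Williams's test compares the
    outlier-filtered AGMM's pooled correlation with each other method's,
    with n = the number of pooled paired rows.
    """
    paired_by_label: dict[str, pd.DataFrame] = {}
    metrics: dict[str, dict] = {}
    flips_per_color: dict[str, dict] = {}
    for label, method, use_filter in methods:
        calls: list[PeakCall] = []
        failed = 0
        for group in dataset.beads:
            try:
                calls.extend(
                    deconv_group(group, method, config, apply_outlier_filter=use_filter)
                )
            except FitError:
                failed += 1
        paired = pair_predictions(dataset.truth, calls)
        flips = count_flips(paired)
        paired_by_label[label] = paired
        flips_per_color[label] = {str(k): int(v) for k, v in flips.items()}
        metrics[label] = {
            "pcc": pcc(paired["true_value"], paired["predicted_value"]),
            "n_true_predictions": true_predictions(paired),
            "mean_absolute_error": mean_absolute_error(paired),
            "total_flips": int(flips.sum()),
            "n_failed_colors": failed,
        }

    williams: dict[str, dict] = {}
    if "agmm" in paired_by_label:
        ref = paired_by_label["agmm"].set_index(
            ["color_id", "sample_id", "peak_rank"]
        )
        for label, other in paired_by_label.items():
            if label == "agmm":
                continue
            oth = other.set_index(["color_id", "sample_id", "peak_rank"])
            joined = ref.join(oth, how="inner", lsuffix="_a", rsuffix="_b")
            n = len(joined)
            r13 = pcc(joined["true_value_a"], joined["predicted_value_a"])
            r23 = pcc(joined["true_value_b"], joined["predicted_value_b"])
            r12 = pcc(joined["predicted_value_a"], joined["predicted_value_b"])
            t, p, df = williams_test(r13, r23, r12, n)
            williams[f"agmm_vs_{label}"] = {
                "t": t, "p": p, "df": df, "r13": r13, "r23": r23,
                "r12": r12, "n": n,
            }

    return BenchmarkReport(
        seed=dataset.params.seed,
        hyperparams=asdict(dataset.params),
        metrics=metrics,
        flips_per_color=flips_per_color,
        williams=williams,
        n_paired_rows=len(next(iter(paired_by_label.values()))),
    )
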