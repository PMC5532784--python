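"""Peak calling for two-gene bead colors.

Three deconvolution routes for the bead intensities of one color:

* :func:`kmedians_deconv` — 1-D two-cluster k-medians per sample (the
  default LINCS route); peak values are the two cluster medians.
* :func:`gmm_deconv` — per-sample two-component Gaussian mixture with a
  shared variance, fitted by EM.
* :class:`AGMM` — the aggregate Gaussian mixture model: the same mixture
  density, but fitted jointly across the m replicate samples of a color,
  with a shared standard deviation sigma and mixing proportion lambda, and
  per-sample peak midpoints mu_i and separations delta_i constrained to
  delta_i >= 0.  The sign constraint forces the higher-expressed gene to
  stay the higher peak in every replicate, which is what eliminates peak
  order flips across samples.

The AGMM log-likelihood over samples i = 1..m with beads x_{i,j} is

    L = sum_i sum_j log[ lam * f(x_ij; mu_i + delta_i/2, sigma)
                         + (1 - lam) * f(x_ij; mu_i - delta_i/2, sigma) ]

with f the Gaussian density.  (mu_i, delta_i) is a reparametrization of the
component means (mu1_i, mu2_i) = (mu_i + delta_i/2, mu_i - delta_i/2), which
turns the order constraint mu1_i >= mu2_i into the box constraint
delta_i >= 0 suitable for L-BFGS-B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.cluster import KMeans
from statsmodels.tools import numdiff

from .io import BeadVector, ColorGroup, PeakCall
from .outliers import OutlierConfig, detect_outliers

__all__ = [
    "FitError",
    "gaussian_pdf",
    "kmedians_deconv",
    "gmm_em",
    "gmm_deconv",
    "agmm_loglik",
    "AGMM",
    "AGMMResults",
    "agmm_fit",
    "deconv_group",
]

_SIGMA_FLOOR = 1e-3
_LAMBDA_BOUNDS = (0.01, 0.99)
_SINGLE_PEAK_DELTA = 0.02


class FitError(RuntimeError):
    """A deconvolution fit failed; the message carries sample/color tags."""


def gaussian_pdf(x, mu, sigma):
    """Gaussian density (1 / (sqrt(2 pi) sigma)) exp(-(x - mu)^2 / (2 sigma^2))."""
    if not np.all(np.asarray(sigma) > 0):
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sigma
    out = np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sigma)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# k-medians


def kmedians_deconv(
    x, sample_id: str = "", color_id: str = "", n_outliers_removed: int = 0
) -> PeakCall:
    """Two-cluster 1-D k-medians.

    Deterministic farthest-point seeding at the data extremes (min/max),
    then alternating nearest-median assignment (L1) and median updates until
    the assignment is stable — a plain Lloyd iteration, so like any k-means
    family method it converges to a local optimum and a far stray bead can
    capture one of the two clusters.  The reported lambda is the fraction of
    beads in the cluster with the *higher* median, so the majority-gene
    identity is recoverable downstream.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise FitError(f"k-medians needs >= 4 beads, got {x.size} "
                       f"(sample {sample_id!r}, color {color_id!r})")
    if np.unique(x).size < 2:
        raise FitError(f"k-medians needs >= 2 distinct values "
                       f"(sample {sample_id!r}, color {color_id!r})")
    m_lo, m_hi = float(x.min()), float(x.max())
    assign = None
    for _ in range(200):
        # nearest median; equidistant points go to the low cluster
        new = np.abs(x - m_hi) < np.abs(x - m_lo)
        if assign is not None and np.array_equal(new, assign):
            break
        if new.all() or not new.any():
            break  # one cluster emptied: keep previous medians
        assign = new
        m_lo = float(np.median(x[~assign]))
        m_hi = float(np.median(x[assign]))
    if assign is None:  # degenerate split from the start
        assign = x >= np.median(x)
        if assign.all() or not assign.any():
            raise FitError(f"k-medians could not split the beads "
                           f"(sample {sample_id!r}, color {color_id!r})")
        m_lo, m_hi = float(np.median(x[~assign])), float(np.median(x[assign]))
    mu_high, mu_low = max(m_hi, m_lo), min(m_hi, m_lo)
    frac_hi = assign.mean() if m_hi >= m_lo else 1.0 - assign.mean()
    lam = float(np.clip(frac_hi, 1e-9, 1 - 1e-9))
    return PeakCall(
        sample_id=sample_id,
        color_id=color_id,
        method="kmedians",
        mu_high=mu_high,
        mu_low=mu_low,
        lam=lam,
        sigma=None,
        n_used=int(x.size),
        n_outliers_removed=n_outliers_removed,
    )


# ---------------------------------------------------------------------------
# naive per-sample GMM (shared variance), fitted by EM


def _two_means(x: np.ndarray):
    """Deterministic 1-D 2-means, seeded at the 25th/75th percentiles.

    Returns (c_lo, c_hi, in_hi mask).  Quantile seeding keeps the start
    inside the main bead mass, so a single far stray bead cannot capture a
    center before the first iteration.
    """
    q25, q75 = np.percentile(x, [25, 75])
    if q25 == q75:
        q25, q75 = float(x.min()), float(x.max())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=2, init=np.array([[q25], [q75]]), n_init=1).fit(
            x.reshape(-1, 1)
        )
    centers = km.cluster_centers_.ravel()
    hi_cluster = int(np.argmax(centers))
    return float(centers.min()), float(centers.max()), km.labels_ == hi_cluster


def gmm_em(x, max_iter: int = 500, tol: float = 1e-8):
    """EM for the two-component shared-variance 1-D Gaussian mixture.

    Initialized from deterministic quantile-seeded 2-means (the same start
    the aggregate model uses per sample) with lambda = 0.5 and sigma =
    pooled within-cluster SD (floored at 1e-3).  Returns
    ``(mu1, mu2, sigma, lam, loglik, trace)`` with mu1 >= mu2, lam the
    weight of the mu1 component, and ``trace`` the per-iteration
    log-likelihood sequence (non-decreasing, as EM guarantees).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise FitError(f"GMM needs >= 4 beads, got {x.size}")
    if np.unique(x).size < 2:
        raise FitError("GMM needs >= 2 distinct values")
    mu2, mu1, in_hi = _two_means(x)
    dev = np.where(in_hi, x - mu1, x - mu2)
    sigma = max(float(np.sqrt(np.mean(dev * dev))), _SIGMA_FLOOR)
    lam = 0.5

    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        a = np.log(lam) - 0.5 * ((x - mu1) / sigma) ** 2
        b = np.log1p(-lam) - 0.5 * ((x - mu2) / sigma) ** 2
        lp = np.logaddexp(a, b) - np.log(np.sqrt(2 * np.pi) * sigma)
        ll = float(lp.sum())
        if not np.isfinite(ll):
            raise FitError("non-finite likelihood in EM")
        trace.append(ll)
        r1 = np.exp(a - np.logaddexp(a, b))
        w1 = r1.sum()
        w2 = x.size - w1
        if w1 > 0:
            mu1 = float((r1 * x).sum() / w1)
        if w2 > 0:
            mu2 = float(((1 - r1) * x).sum() / w2)
        var = float(
            (r1 * (x - mu1) ** 2 + (1 - r1) * (x - mu2) ** 2).sum() / x.size
        )
        sigma = max(np.sqrt(var), _SIGMA_FLOOR)
        lam = float(np.clip(w1 / x.size, 1e-9, 1 - 1e-9))
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    # the loop's last entry predates the final M-step: evaluate at the
    # parameters actually returned (ascent keeps the trace monotone)
    a = np.log(lam) - 0.5 * ((x - mu1) / sigma) ** 2
    b = np.log1p(-lam) - 0.5 * ((x - mu2) / sigma) ** 2
    lp = np.logaddexp(a, b) - np.log(np.sqrt(2 * np.pi) * sigma)
    trace.append(float(lp.sum()))
    if mu1 < mu2:
        mu1, mu2, lam = mu2, mu1, 1.0 - lam
    return mu1, mu2, sigma, lam, trace[-1], trace


def gmm_deconv(
    x,
    max_iter: int = 500,
    tol: float = 1e-8,
    sample_id: str = "",
    color_id: str = "",
    n_outliers_removed: int = 0,
) -> PeakCall:
    """Per-sample naive two-component shared-variance GMM peak call."""
    x = np.asarray(x, dtype=float)
    mu1, mu2, sigma, lam, _, _ = gmm_em(x, max_iter=max_iter, tol=tol)
    return PeakCall(
        sample_id=sample_id,
        color_id=color_id,
        method="gmm",
        mu_high=mu1,
        mu_low=mu2,
        lam=float(np.clip(lam, 1e-9, 1 - 1e-9)),
        sigma=sigma,
        n_used=int(x.size),
        n_outliers_removed=n_outliers_removed,
    )


# ---------------------------------------------------------------------------
# aggregate GMM


def _flatten(arrays: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    idx = np.repeat(np.arange(len(arrays)), [a.size for a in arrays])
    return np.concatenate(arrays), idx


def _agmm_nll_grad(theta, x, idx, m):
    """Negative joint log-likelihood and its gradient.

    theta = [mu_1..m, delta_1..m, sigma, lam]; per-bead terms are evaluated
    in log space (log-sum-exp) so widely separated peaks cannot underflow.
    """
    mu = theta[:m]
    delta = theta[m : 2 * m]
    sigma = theta[2 * m]
    lam = theta[2 * m + 1]
    mu1 = (mu + 0.5 * delta)[idx]
    mu2 = (mu - 0.5 * delta)[idx]
    z1 = (x - mu1) / sigma
    z2 = (x - mu2) / sigma
    a = np.log(lam) - 0.5 * z1 * z1
    b = np.log1p(-lam) - 0.5 * z2 * z2
    lp = np.logaddexp(a, b)
    ll = lp.sum() - x.size * np.log(np.sqrt(2 * np.pi) * sigma)

    r1 = np.exp(a - lp)
    r2 = 1.0 - r1
    g1 = r1 * z1 / sigma  # d ll / d mu1 per bead
    g2 = r2 * z2 / sigma
    dmu = np.bincount(idx, weights=g1 + g2, minlength=m)
    ddelta = 0.5 * np.bincount(idx, weights=g1 - g2, minlength=m)
    dsigma = (r1 * z1 * z1 + r2 * z2 * z2).sum() / sigma - x.size / sigma
    dlam = (r1 / lam - r2 / (1.0 - lam)).sum()
    grad = np.concatenate([dmu, ddelta, [dsigma, dlam]])
    return -ll, -grad


def agmm_loglik(group: ColorGroup, mu, delta, sigma, lam) -> float:
    """Joint AGMM log-likelihood at the given parameters.

    Identical, exactly, to the unconstrained parametrization evaluated at
    mu1_i = mu_i + delta_i/2 and mu2_i = mu_i - delta_i/2.
    """
    mu = np.asarray(mu, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if mu.size != group.m or delta.size != group.m:
        raise ValueError("mu and delta must have one entry per sample")
    if np.any(delta < 0):
        raise ValueError("delta must be >= 0 (peak order constraint)")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie in (0, 1)")
    x, idx = _flatten([s.intensities for s in group.samples])
    theta = np.concatenate([mu, delta, [sigma, lam]])
    nll, _ = _agmm_nll_grad(theta, x, idx, group.m)
    return -float(nll)


@dataclass(frozen=True, eq=False)
class AGMMResults:
    """Fitted AGMM for one color: estimates, uncertainties, diagnostics.

    Standard errors come from the inverse observed information (numerical
    Hessian of the negative log-likelihood at the optimum); entries touching
    an active box constraint are reported as NaN.
    """

    model: "AGMM"
    color_id: str
    sample_ids: tuple[str, ...]
    mu: np.ndarray
    delta: np.ndarray
    sigma: float
    lam: float
    loglik: float
    converged: bool
    n_used: tuple[int, ...]
    n_outliers_removed: tuple[int, ...]
    dropped_sample_ids: tuple[str, ...]
    bse: np.ndarray  # aligned with [mu, delta, sigma, lam]
    n_restarts: int = 0

    @property
    def m(self) -> int:
        return len(self.sample_ids)

    @property
    def mu_high(self) -> np.ndarray:
        return self.mu + 0.5 * self.delta

    @property
    def mu_low(self) -> np.ndarray:
        return self.mu - 0.5 * self.delta

    @property
    def single_peak(self) -> bool:
        """All separations below 0.02: effectively a one-peak color."""
        return bool(np.all(self.delta < _SINGLE_PEAK_DELTA))

    @property
    def peak_calls(self) -> list[PeakCall]:
        lam = float(np.clip(self.lam, 1e-9, 1 - 1e-9))
        return [
            PeakCall(
                sample_id=sid,
                color_id=self.color_id,
                method="agmm",
                mu_high=float(hi),
                mu_low=float(lo),
                lam=lam,
                sigma=self.sigma,
                n_used=nu,
                n_outliers_removed=nr,
            )
            for sid, hi, lo, nu, nr in zip(
                self.sample_ids,
                self.mu_high,
                self.mu_low,
                self.n_used,
                self.n_outliers_removed,
            )
        ]

    def summary(self) -> str:
        lines = [
            f"Aggregate Gaussian mixture fit — color {self.color_id}",
            f"  samples fitted: {self.m}"
            + (f"  (dropped: {', '.join(self.dropped_sample_ids)})"
               if self.dropped_sample_ids else ""),
            f"  log-likelihood: {self.loglik:.4f}"
            f"   converged: {self.converged}",
            f"  sigma  = {self.sigma:.5f}  (SE {self._fmt_se(2 * self.m)})",
            f"  lambda = {self.lam:.5f}  (SE {self._fmt_se(2 * self.m + 1)})",
        ]
        if self.single_peak:
            lines.append("  note: all separations < 0.02 — single-peak color")
        lines.append(f"  {'sample':>12} {'mu_high':>10} {'mu_low':>10} "
                     f"{'delta':>8} {'n':>4} {'removed':>7}")
        for i, sid in enumerate(self.sample_ids):
            lines.append(
                f"  {sid:>12} {self.mu_high[i]:>10.4f} {self.mu_low[i]:>10.4f} "
                f"{self.delta[i]:>8.4f} {self.n_used[i]:>4d} "
                f"{self.n_outliers_removed[i]:>7d}"
            )
        return "\n".join(lines)

    def _fmt_se(self, j: int) -> str:
        se = self.bse[j]
        return "n/a" if not np.isfinite(se) else f"{se:.5f}"


class AGMM:
    """Aggregate Gaussian mixture model for one color across m replicates.

    Parameters
    ----------
    group : ColorGroup
        The replicate bead vectors of one color.
    config : OutlierConfig
        Density-gap screen settings; also supplies ``min_kept``, the minimum
        beads a sample must retain to enter the joint fit.
    apply_outlier_filter : bool
        If True (default), run density-gap outlier detection per sample
        before fitting; False reproduces the no-filter ablation.
    """

    def __init__(
        self,
        group: ColorGroup,
        config: OutlierConfig = OutlierConfig(),
        apply_outlier_filter: bool = True,
    ):
        self.group = group
        self.config = config
        self.apply_outlier_filter = apply_outlier_filter

        kept_arrays: list[np.ndarray] = []
        sample_ids: list[str] = []
        n_used: list[int] = []
        n_removed: list[int] = []
        dropped: list[str] = []
        for s in group.samples:
            if apply_outlier_filter:
                res = detect_outliers(s.intensities, config)
                kept = s.intensities[res.kept]
                removed = res.n_removed
            else:
                kept = s.intensities
                removed = 0
            if kept.size < config.min_kept or np.unique(kept).size < 2:
                dropped.append(s.sample_id)
                continue
            kept_arrays.append(kept)
            sample_ids.append(s.sample_id)
            n_used.append(int(kept.size))
            n_removed.append(removed)
        if not kept_arrays:
            raise FitError(
                f"color {group.color_id!r}: no sample retains "
                f">= {config.min_kept} beads after outlier removal"
            )
        self.sample_ids = tuple(sample_ids)
        self.dropped_sample_ids = tuple(dropped)
        self.n_used = tuple(n_used)
        self.n_outliers_removed = tuple(n_removed)
        self._x, self._idx = _flatten(kept_arrays)
        self._kept_arrays = kept_arrays

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "AGMM":
        """Build from a long bead table (sample_id, color_id, intensity)."""
        colors = df["color_id"].unique()
        if colors.size != 1:
            raise ValueError("from_dataframe expects a single color")
        vecs = tuple(
            BeadVector(str(sid), str(colors[0]), sdf["intensity"].to_numpy(float))
            for sid, sdf in df.groupby("sample_id", sort=False)
        )
        return cls(ColorGroup(str(colors[0]), vecs), **kwargs)

    @property
    def m(self) -> int:
        return len(self.sample_ids)

    def loglik(self, mu, delta, sigma, lam) -> float:
        """Joint log-likelihood on the *kept* beads."""
        theta = np.concatenate(
            [np.asarray(mu, float), np.asarray(delta, float), [sigma, lam]]
        )
        nll, _ = _agmm_nll_grad(theta, self._x, self._idx, self.m)
        return -float(nll)

    def _initial_params(self) -> np.ndarray:
        """Deterministic start: per-sample 2-means seeded at the quartiles."""
        mu0, delta0, hi_frac, wss, n_tot = [], [], 0.0, 0.0, 0
        for x in self._kept_arrays:
            c_lo, c_hi, in_hi = _two_means(x)
            mu0.append(0.5 * (c_hi + c_lo))
            delta0.append(c_hi - c_lo)
            hi_frac += in_hi.sum()
            dev = np.where(in_hi, x - c_hi, x - c_lo)
            wss += float((dev * dev).sum())
            n_tot += x.size
        lam0 = float(np.clip(hi_frac / n_tot, 0.05, 0.95))
        sigma0 = max(np.sqrt(wss / n_tot), _SIGMA_FLOOR)
        return np.concatenate([mu0, delta0, [sigma0, lam0]])

    def fit(self, gtol: float = 1e-8, maxiter: int = 1000) -> AGMMResults:
        """Maximize the joint likelihood with box-constrained L-BFGS-B.

        delta is bounded below by 0 (the peak-order sign constraint), sigma
        by 1e-3 and lambda to [0.01, 0.99].  On optimizer failure the fit is
        restarted once from a perturbed start (delta scaled by 1.05,
        lambda reset to 0.5).
        """
        m = self.m
        theta0 = self._initial_params()
        bounds = (
            [(None, None)] * m
            + [(0.0, None)] * m
            + [(_SIGMA_FLOOR, None), _LAMBDA_BOUNDS]
        )

        def run(theta):
            return optimize.minimize(
                _agmm_nll_grad,
                theta,
                args=(self._x, self._idx, m),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "gtol": gtol},
            )

        res = run(theta0)
        n_restarts = 0
        if not res.success:
            theta1 = theta0.copy()
            theta1[m : 2 * m] *= 1.05
            theta1[2 * m + 1] = 0.5
            res2 = run(theta1)
            n_restarts = 1
            if res2.success or res2.fun < res.fun:
                res = res2
            if not res.success and not np.isfinite(res.fun):
                raise FitError(
                    f"AGMM optimizer failed for color "
                    f"{self.group.color_id!r}: {res.message}"
                )
        theta = res.x
        mu = theta[:m].copy()
        delta = theta[m : 2 * m].copy()
        sigma = float(theta[2 * m])
        lam = float(theta[2 * m + 1])
        bse = self._standard_errors(theta, bounds)
        return AGMMResults(
            model=self,
            color_id=self.group.color_id,
            sample_ids=self.sample_ids,
            mu=mu,
            delta=delta,
            sigma=sigma,
            lam=lam,
            loglik=-float(res.fun),
            converged=bool(res.success),
            n_used=self.n_used,
            n_outliers_removed=self.n_outliers_removed,
            dropped_sample_ids=self.dropped_sample_ids,
            bse=bse,
            n_restarts=n_restarts,
        )

    def _standard_errors(self, theta, bounds) -> np.ndarray:
        """Inverse observed information; NaN where a box constraint binds."""
        m = self.m
        active = np.zeros(theta.size, dtype=bool)
        for j, (lo, hi) in enumerate(bounds):
            if lo is not None and theta[j] - lo < 1e-8:
                active[j] = True
            if hi is not None and hi - theta[j] < 1e-8:
                active[j] = True
        bse = np.full(theta.size, np.nan)
        free = ~active
        if free.sum() == 0:
            return bse
        try:
            def nll_free(t_free):
                t = theta.copy()
                t[free] = t_free
                return _agmm_nll_grad(t, self._x, self._idx, m)[0]

            hess = numdiff.approx_hess2(theta[free], nll_free)
            cov = np.linalg.inv(hess)
            d = np.diag(cov)
            with np.errstate(invalid="ignore"):
                bse[free] = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        except (np.linalg.LinAlgError, FloatingPointError):
            pass
        return bse


def agmm_fit(
    group: ColorGroup,
    config: OutlierConfig = OutlierConfig(),
    apply_outlier_filter: bool = True,
    **fit_kwargs,
) -> AGMMResults:
    """Convenience wrapper: construct and fit the AGMM for one color."""
    return AGMM(group, config, apply_outlier_filter).fit(**fit_kwargs)


def deconv_group(
    group: ColorGroup,
    method: str,
    config: OutlierConfig = OutlierConfig(),
    apply_outlier_filter: bool = True,
) -> list[PeakCall]:
    """Deconvolve one color with the chosen method.

    k-medians and the naive GMM are fitted independently per sample; the
    AGMM is fitted jointly across all samples of the color.  With
    ``apply_outlier_filter`` the density-gap screen runs per sample first;
    ``method="agmm"`` with the filter off is the no-filter ablation.
    """
    if method == "agmm":
        return agmm_fit(group, config, apply_outlier_filter).peak_calls
    if method not in ("kmedians", "gmm"):
        raise ValueError(f"unknown method {method!r}")
    fitter = kmedians_deconv if method == "kmedians" else gmm_deconv
    calls = []
    for s in group.samples:
        if apply_outlier_filter:
            res = detect_outliers(s.intensities, config)
            x = s.intensities[res.kept]
            removed = res.n_removed
        else:
            x = s.intensities
            removed = 0
        if x.size < config.min_kept:
            continue
        try:
            calls.append(
                fitter(
                    x,
                    sample_id=s.sample_id,
                    color_id=s.color_id,
                    n_outliers_removed=removed,
                )
            )
        except FitError as err:
            raise FitError(
                f"{method} failed for sample {s.sample_id!r}, "
                f"color {s.color_id!r}: {err}"
            ) from err
    return calls
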