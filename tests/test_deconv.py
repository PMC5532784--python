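import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from l1kpeaks.deconv import (
    AGMM,
    FitError,
    agmm_fit,
    agmm_loglik,
    deconv_group,
    gaussian_pdf,
    gmm_deconv,
    gmm_em,
    kmedians_deconv,
)
from l1kpeaks.io import BeadVector, ColorGroup
from l1kpeaks.outliers import OutlierConfig

from conftest import make_group


def brute_force_kmedians(x):
    """Exhaustive scan of the n-1 contiguous cuts, minimizing total L1 loss."""
    xs = np.sort(np.asarray(x, dtype=float))
    best = None
    for c in range(1, xs.size):
        a, b = xs[:c], xs[c:]
        cost = np.abs(a - np.median(a)).sum() + np.abs(b - np.median(b)).sum()
        if best is None or cost < best[0] - 1e-12:
            best = (cost, float(np.median(a)), float(np.median(b)))
    return best[1], best[2]


def brute_force_mixture_loglik(xs_by_sample, mu1s, mu2s, sigma, lam):
    """Term-by-term direct summation, no vectorization or log-sum-exp."""
    total = 0.0
    for xs, m1, m2 in zip(xs_by_sample, mu1s, mu2s):
        for v in xs:
            f1 = math.exp(-0.5 * ((v - m1) / sigma) ** 2) / (
                math.sqrt(2 * math.pi) * sigma
            )
            f2 = math.exp(-0.5 * ((v - m2) / sigma) ** 2) / (
                math.sqrt(2 * math.pi) * sigma
            )
            total += math.log(lam * f1 + (1 - lam) * f2)
    return total


class TestGaussianPdf:
    def test_mode_and_one_sigma(self):
        assert gaussian_pdf(0.0, 0.0, 1.0) == pytest.approx(
            1 / math.sqrt(2 * math.pi), abs=1e-9
        )
        assert gaussian_pdf(3.0, 2.0, 1.0) == pytest.approx(
            math.exp(-0.5) / math.sqrt(2 * math.pi), abs=1e-9
        )

    def test_integrates_to_one(self):
        val, _ = quad(gaussian_pdf, 5 - 8 * 0.3, 5 + 8 * 0.3, args=(5.0, 0.3))
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            gaussian_pdf(0.0, 0.0, 0.0)


class TestKmedians:
    def test_separated_duplicates(self):
        pc = kmedians_deconv([1.0, 1.0, 1.0, 5.0, 5.0])
        assert (pc.mu_high, pc.mu_low) == (5.0, 1.0)
        assert pc.lam == pytest.approx(2 / 5)

    def test_two_triples(self):
        pc = kmedians_deconv([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        assert (pc.mu_high, pc.mu_low) == (11.0, 1.0)

    @given(a=st.floats(0.1, 5.0), b=st.floats(-10.0, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_equivariance(self, a, b):
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        pc0 = kmedians_deconv(x)
        pc1 = kmedians_deconv(a * x + b)
        assert pc1.mu_high == pytest.approx(a * pc0.mu_high + b, rel=1e-9, abs=1e-9)
        assert pc1.mu_low == pytest.approx(a * pc0.mu_low + b, rel=1e-9, abs=1e-9)

    def test_matches_exhaustive_cut_on_gapped_clusters(self):
        """On clearly gapped two-cluster inputs (gap wider than either
        cluster's diameter) the Lloyd iteration recovers the optimal cut."""
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = int(rng.integers(4, 13))
            n1 = int(rng.integers(2, n - 1))
            x = np.concatenate(
                [rng.uniform(0.0, 0.5, n1), rng.uniform(3.5, 4.0, n - n1)]
            )
            pc = kmedians_deconv(x)
            lo, hi = sorted(brute_force_kmedians(x))
            assert pc.mu_low == pytest.approx(lo, abs=1e-9)
            assert pc.mu_high == pytest.approx(hi, abs=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(FitError):
            kmedians_deconv([1.0, 2.0, 3.0])
        with pytest.raises(FitError):
            kmedians_deconv([2.0, 2.0, 2.0, 2.0])


class TestGmm:
    def test_separated_clusters_recovered(self, rng):
        x = np.concatenate(
            [np.zeros(30) + rng.normal(0, 0.01, 30), 10 + rng.normal(0, 0.01, 30)]
        )
        pc = gmm_deconv(x)
        assert pc.mu_high == pytest.approx(10.0, abs=0.05)
        assert pc.mu_low == pytest.approx(0.0, abs=0.05)
        assert pc.lam == pytest.approx(0.5, abs=0.05)
        assert pc.sigma == pytest.approx(0.01, abs=0.02)

    def test_loglik_matches_direct_summation(self, rng):
        x = rng.normal(7, 0.5, size=50)
        mu1, mu2, sigma, lam, ll, _ = gmm_em(x)
        oracle = brute_force_mixture_loglik([x], [mu1], [mu2], sigma, lam)
        assert ll == pytest.approx(oracle, abs=1e-9)

    def test_em_trace_non_decreasing(self, rng):
        """EM's monotone ascent, checked on a spread of random inputs."""
        for _ in range(100):
            sep = rng.uniform(0.0, 3.0)
            x = np.concatenate(
                [rng.normal(7 + sep, 0.2, 40), rng.normal(7, 0.2, 20)]
            )
            *_, trace = gmm_em(x)
            diffs = np.diff(trace)
            assert (diffs >= -1e-9).all()


class TestAgmmLoglik:
    def test_zero_delta_reduces_to_single_gaussian(self, rng):
        x = rng.normal(5, 1, size=20)
        group = ColorGroup("c0", (BeadVector("s0", "c0", x),))
        for lam in (0.1, 0.5, 0.9):
            ll = agmm_loglik(group, [5.0], [0.0], 1.0, lam)
            direct = np.sum(np.log(gaussian_pdf(x, 5.0, 1.0)))
            assert ll == pytest.approx(direct, abs=1e-10)

    def test_reparametrization_identity(self, rng):
        """(mu, delta) and (mu1, mu2) parametrizations agree exactly."""
        for _ in range(50):
            m = int(rng.integers(1, 4))
            xs = [rng.normal(7, 1, size=int(rng.integers(2, 8))) for _ in range(m)]
            group = ColorGroup(
                "c0", tuple(BeadVector(f"s{i}", "c0", x) for i, x in enumerate(xs))
            )
            mu = rng.normal(7, 1, size=m)
            delta = rng.uniform(0, 2, size=m)
            sigma = float(rng.uniform(0.2, 1.0))
            lam = float(rng.uniform(0.05, 0.95))
            ll = agmm_loglik(group, mu, delta, sigma, lam)
            oracle = brute_force_mixture_loglik(
                xs, mu + delta / 2, mu - delta / 2, sigma, lam
            )
            assert ll == pytest.approx(oracle, abs=1e-10)

    def test_rejects_invalid_parameters(self, two_peak_group):
        m = two_peak_group.m
        with pytest.raises(ValueError):
            agmm_loglik(two_peak_group, [7.0] * m, [-0.1] * m, 0.2, 0.5)
        with pytest.raises(ValueError):
            agmm_loglik(two_peak_group, [7.0] * m, [1.0] * m, -1.0, 0.5)
        with pytest.raises(ValueError):
            agmm_loglik(two_peak_group, [7.0] * m, [1.0] * m, 0.2, 1.5)


class TestAgmmFit:
    def test_parameter_recovery(self, two_peak_group):
        res = agmm_fit(two_peak_group)
        assert res.converged
        np.testing.assert_allclose(res.mu_high, 8.0, atol=0.1)
        np.testing.assert_allclose(res.mu_low, 6.0, atol=0.1)
        assert res.lam == pytest.approx(2 / 3, abs=0.1)
        assert res.sigma == pytest.approx(0.2, abs=0.05)

    def test_loglik_recomputable_and_ascending(self, two_peak_group):
        model = AGMM(two_peak_group)
        res = model.fit()
        assert res.loglik == pytest.approx(
            model.loglik(res.mu, res.delta, res.sigma, res.lam), abs=1e-6
        )
        theta0 = model._initial_params()
        m = model.m
        assert res.loglik >= model.loglik(
            theta0[:m], theta0[m : 2 * m], theta0[2 * m], theta0[2 * m + 1]
        ) - 1e-8

    def test_sign_constraint_orders_every_sample(self, rng):
        """delta >= 0: the high peak stays high in every replicate."""
        for seed in range(5):
            g = make_group(
                np.random.default_rng(seed), m=5, mu_high=7.2, mu_low=7.0, sd=0.2
            )
            res = agmm_fit(g)
            assert (res.mu_high >= res.mu_low).all()

    def test_single_sample_agrees_with_gmm(self, rng):
        """m=1 AGMM is a shared-sigma two-component fit, like the naive GMM."""
        g = make_group(rng, m=1, mu_high=9.0, mu_low=6.0, sd=0.2)
        res = agmm_fit(g, apply_outlier_filter=False)
        pc = gmm_deconv(g.samples[0].intensities)
        assert res.mu_high[0] == pytest.approx(pc.mu_high, abs=0.05)
        assert res.mu_low[0] == pytest.approx(pc.mu_low, abs=0.05)

    def test_standard_errors_finite_off_boundary(self, two_peak_group):
        res = agmm_fit(two_peak_group)
        m = res.m
        # interior parameters carry observed-information SEs
        assert np.isfinite(res.bse[:m]).all()
        assert np.isfinite(res.bse[2 * m])  # sigma
        assert np.isfinite(res.bse[2 * m + 1])  # lambda

    def test_summary_mentions_key_fields(self, two_peak_group):
        text = agmm_fit(two_peak_group).summary()
        assert "sigma" in text and "lambda" in text and "c0" in text

    def test_from_dataframe(self, rng, two_peak_group):
        import pandas as pd

        rows = [
            (s.sample_id, s.color_id, v)
            for s in two_peak_group.samples
            for v in s.intensities
        ]
        df = pd.DataFrame(rows, columns=["sample_id", "color_id", "intensity"])
        res = AGMM.from_dataframe(df).fit()
        np.testing.assert_allclose(res.mu_high, 8.0, atol=0.1)

    def test_all_samples_too_small_raises(self):
        g = ColorGroup(
            "c0",
            (BeadVector("s0", "c0", [1.0, 1.1]), BeadVector("s1", "c0", [2.0])),
        )
        with pytest.raises(FitError):
            agmm_fit(g)


class TestDeconvGroup:
    def test_agmm_shares_lambda_and_sigma(self, rng):
        g = make_group(rng, m=10)
        calls = deconv_group(g, "agmm")
        assert len(calls) == 10
        assert len({c.lam for c in calls}) == 1
        assert len({c.sigma for c in calls}) == 1
        assert all(c.method == "agmm" for c in calls)

    @pytest.mark.parametrize("method", ["kmedians", "gmm"])
    def test_per_sample_methods_fit_independently(self, rng, method):
        g = make_group(rng, m=10)
        calls = deconv_group(g, method)
        assert len(calls) == 10
        if method == "gmm":
            # independent per-sample mixing proportions (the joint AGMM, by
            # contrast, shares a single lambda)
            assert len({c.lam for c in calls}) > 1

    def test_filter_makes_agmm_robust_to_injected_outliers(self, rng):
        """Two far stray beads barely move the filtered joint fit."""
        seed_rng = np.random.default_rng(99)
        clean = make_group(seed_rng, m=5)
        dirty_rng = np.random.default_rng(99)
        dirty = make_group(dirty_rng, m=5, outliers=(14.0, 14.5))
        res_clean = agmm_fit(clean, apply_outlier_filter=True)
        res_dirty = agmm_fit(dirty, apply_outlier_filter=True)
        assert np.abs(res_dirty.mu_high - res_clean.mu_high).max() < 0.05
        assert np.abs(res_dirty.mu_low - res_clean.mu_low).max() < 0.05
        assert res_dirty.peak_calls[0].n_outliers_removed >= 2

    def test_no_filter_mode_reports_zero_removed(self, rng):
        g = make_group(rng, m=3, outliers=(14.0, 14.5))
        calls = deconv_group(g, "agmm", apply_outlier_filter=False)
        assert all(c.n_outliers_removed == 0 for c in calls)
        assert calls[0].n_used == 62

    def test_unknown_method_rejected(self, two_peak_group):
        with pytest.raises(ValueError):
            deconv_group(two_peak_group, "mclust")
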