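import numpy as np
import pytest
from scipy import stats

from isoniche.ellipse import (
    CHI2_95,
    STANDARD_COVERAGE,
    EllipseNiche,
    ellipse_area,
    ellipse_boundary,
    ellipse_intersection_area,
    fit_niche,
    percent_overlap,
    posterior_sea_draws,
)


def _niche(mean, cov, n=30, species="sp"):
    return EllipseNiche(species, np.asarray(mean, float), np.asarray(cov, float), n)


class TestFitNiche:
    def test_large_sample_isotropic_cloud_sea_approaches_pi(self, make_group):
        rng = np.random.default_rng(1)
        g = make_group(rng.standard_normal((20_000, 2)))
        niche = fit_niche(g)
        # sqrt(det) of the sample covariance concentrates at 1 => SEA -> pi
        assert niche.sea == pytest.approx(np.pi, rel=0.03)

    def test_collinear_points_degenerate_with_zero_area(self, make_group):
        g = make_group([(i, 2.0 * i) for i in range(5)])
        niche = fit_niche(g)
        assert niche.degenerate
        assert niche.sea == 0.0

    def test_small_groups_rejected(self, make_group):
        with pytest.raises(ValueError, match="n >= 3"):
            fit_niche(make_group([(0, 0), (1, 1)]))

    def test_seac_to_seab_scaling_matches_chi_square(self, make_group):
        rng = np.random.default_rng(2)
        g = make_group(rng.normal(size=(15, 2)))
        niche = fit_niche(g)
        assert niche.seac == pytest.approx(niche.sea * 14 / 13)
        assert niche.seab / niche.seac == pytest.approx(CHI2_95)


class TestEllipseArea:
    def test_identity_covariance_standard_ellipse_is_pi(self):
        niche = _niche((0, 0), np.eye(2))
        assert ellipse_area(niche, STANDARD_COVERAGE, corrected=False) == pytest.approx(np.pi)

    def test_95_to_standard_ratio_is_chi2_quantile(self):
        niche = _niche((3, -2), [[2.0, 0.5], [0.5, 1.0]])
        ratio = ellipse_area(niche, 0.95) / ellipse_area(niche, STANDARD_COVERAGE)
        assert ratio == pytest.approx(stats.chi2.ppf(0.95, 2), rel=1e-12)

    def test_coverage_bounds_enforced(self):
        niche = _niche((0, 0), np.eye(2))
        for bad in (0.0, 1.0, -0.2, 1.7):
            with pytest.raises(ValueError):
                ellipse_area(niche, bad)

    def test_monte_carlo_coverage_of_95_percent_ellipse(self):
        rng = np.random.default_rng(3)
        cov = np.array([[2.0, -0.8], [-0.8, 1.5]])
        mean = np.array([1.0, 4.0])
        niche = _niche(mean, cov)
        draws = rng.multivariate_normal(mean, cov, size=200_000)
        diff = draws - mean
        d2 = np.einsum("ij,ji->i", diff, np.linalg.solve(cov, diff.T))
        frac = np.mean(d2 <= stats.chi2.ppf(0.95, 2))
        assert frac == pytest.approx(0.95, abs=0.003)
        # and the polygonal boundary encloses the same area as the formula
        from shapely.geometry import Polygon

        poly = Polygon(ellipse_boundary(niche, 0.95, corrected=False))
        assert poly.area == pytest.approx(
            ellipse_area(niche, 0.95, corrected=False), rel=1e-3
        )


class TestIntersection:
    def test_self_intersection_equals_own_area(self):
        niche = _niche((0, 0), [[1.5, 0.3], [0.3, 0.8]])
        inter = ellipse_intersection_area(niche, niche, coverage=0.95)
        assert inter == pytest.approx(ellipse_area(niche, 0.95), rel=1e-3)

    def test_distant_means_give_zero(self):
        a = _niche((0, 0), np.eye(2))
        b = _niche((100, 0), np.eye(2))
        assert ellipse_intersection_area(a, b) == 0.0

    def test_symmetric_in_arguments(self):
        a = _niche((0, 0), [[2.0, 0.4], [0.4, 1.0]])
        b = _niche((1.0, 0.5), [[1.0, -0.2], [-0.2, 1.5]])
        ab = ellipse_intersection_area(a, b)
        ba = ellipse_intersection_area(b, a)
        assert ab == pytest.approx(ba, rel=1e-9)
        assert 0.0 < ab < min(ellipse_area(a, 0.95), ellipse_area(b, 0.95))

    @pytest.mark.parametrize("seed", range(4))
    def test_grid_agrees_with_rejection_sampling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = _niche(rng.normal(size=2), _random_cov(rng), n=10 + seed)
        b = _niche(rng.normal(size=2), _random_cov(rng), n=12 + seed)
        exact = ellipse_intersection_area(a, b, method="grid")
        n = 400_000
        mc = ellipse_intersection_area(
            a, b, method="montecarlo", seed=seed + 100, n_samples=n
        )
        # 3 MC standard errors of the rejection estimate
        box = _bounding_box_area(a, b)
        p = max(mc / box, 1e-12)
        se = box * np.sqrt(p * (1 - p) / n)
        assert abs(exact - mc) <= 3 * se + 1e-3 * exact

    def test_rotation_and_translation_invariance(self, make_group):
        rng = np.random.default_rng(9)
        pts_a = rng.normal(size=(20, 2)) @ np.diag([2.0, 0.7])
        pts_b = rng.normal((1.0, 0.5), 1.0, (17, 2))
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([5.0, -3.0])
        a0, b0 = fit_niche(make_group(pts_a)), fit_niche(make_group(pts_b))
        a1 = fit_niche(make_group(pts_a @ R.T + shift))
        b1 = fit_niche(make_group(pts_b @ R.T + shift))
        assert a1.seac == pytest.approx(a0.seac, rel=1e-9)
        assert ellipse_intersection_area(a1, b1) == pytest.approx(
            ellipse_intersection_area(a0, b0), rel=1e-6
        )


class TestPercentOverlap:
    def test_printed_pair_reproduces_published_percentage(self):
        # eel vs carp: intersection 3.88 of areas 14.52 and 11.88 -> 17.2%
        assert percent_overlap(3.88, 14.52, 11.88) == pytest.approx(17.2, abs=0.05)

    def test_zero_intersection_zero_percent(self):
        assert percent_overlap(0.0, 3.0, 5.0) == 0.0

    def test_identical_niches_hundred_percent(self):
        assert percent_overlap(4.2, 4.2, 4.2) == pytest.approx(100.0)

    def test_violated_precondition_raises(self):
        with pytest.raises(ValueError):
            percent_overlap(6.0, 3.0, 5.0)


def test_posterior_sea_draws_bracket_point_estimate(make_group):
    rng = np.random.default_rng(11)
    g = make_group(rng.multivariate_normal([0, 0], [[2, 0.5], [0.5, 1]], 40))
    draws = posterior_sea_draws(g, n_draws=4000, seed=1)
    point = fit_niche(g).sea
    lo, hi = np.percentile(draws, [1, 99])
    assert lo < point < hi


def _random_cov(rng):
    A = rng.normal(size=(2, 2))
    return A @ A.T + 0.3 * np.eye(2)


def _bounding_box_area(a, b):
    ba = ellipse_boundary(a, 0.95, 256)
    bb = ellipse_boundary(b, 0.95, 256)
    lo = np.minimum(ba.min(axis=0), bb.min(axis=0))
    hi = np.maximum(ba.max(axis=0), bb.max(axis=0))
    return float(np.prod(hi - lo))
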