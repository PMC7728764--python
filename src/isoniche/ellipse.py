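"""Covariance-ellipse isotopic niches, areas and pairwise overlaps.

A species' isotopic niche is summarized by the mean vector and covariance
matrix of its (d13C, d15N) points.  The *standard ellipse* is the
one-Mahalanobis-unit contour of the fitted bivariate normal; it covers
1 - exp(-1/2) ~ 39.35% of the distribution (conventionally reported as
"40% coverage") and has area

    SEA = pi * sqrt(det(cov)).

The small-sample-corrected form SEAc = SEA * (n-1)/(n-2) is the headline
per-species niche size; the 95%-coverage ellipse area SEAb carries the same
correction scaled by the chi-square(2 df) quantile, so

    SEAb / SEAc = chi2.ppf(0.95, 2) ~ 5.991

for every fitted niche.  Pairwise niche overlap is the geometric
intersection area of two coverage ellipses, reported as a percentage of
their union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from shapely.geometry import Polygon

from .io import SpeciesGroup

__all__ = [
    "EllipseNiche",
    "OverlapResult",
    "fit_niche",
    "ellipse_area",
    "ellipse_boundary",
    "ellipse_intersection_area",
    "percent_overlap",
    "posterior_sea_draws",
]

CHI2_95 = float(stats.chi2.ppf(0.95, df=2))
#: Exact coverage of the standard (1-Mahalanobis-unit) ellipse.
STANDARD_COVERAGE = float(stats.chi2.cdf(1.0, df=2))  # 1 - exp(-1/2)


@dataclass(frozen=True)
class EllipseNiche:
    species: str
    mean: np.ndarray  # (d13C, d15N)
    cov: np.ndarray  # 2x2, unbiased sample covariance
    n: int

    @property
    def sea(self) -> float:
        """Standard ellipse area, pi*sqrt(det(cov)) (permil^2)."""
        det = float(np.linalg.det(self.cov))
        return float(np.pi * np.sqrt(max(det, 0.0)))

    @property
    def correction(self) -> float:
        """(n-1)/(n-2) small-sample correction."""
        return (self.n - 1) / (self.n - 2)

    @property
    def seac(self) -> float:
        return self.sea * self.correction

    @property
    def seab(self) -> float:
        return self.seac * CHI2_95

    @property
    def degenerate(self) -> bool:
        return float(np.linalg.det(self.cov)) <= 0.0


@dataclass(frozen=True)
class OverlapResult:
    pair: tuple[str, str]
    intersection_area: float
    percent_of_union: float
    coverage: float


def fit_niche(group: SpeciesGroup) -> EllipseNiche:
    """Fit the covariance ellipse to a species group (needs n >= 3).

    Perfectly collinear data give a singular covariance and zero areas; the
    niche is flagged degenerate rather than raising.
    """
    if group.n < 3:
        raise ValueError(
            f"niche fit needs n >= 3, got n={group.n} for {group.species!r}"
        )
    xy = group.xy
    return EllipseNiche(
        species=group.species,
        mean=xy.mean(axis=0),
        cov=np.cov(xy, rowvar=False, ddof=1),
        n=group.n,
    )


def _chi2_scale(coverage: float) -> float:
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage must lie in (0, 1), got {coverage}")
    return float(stats.chi2.ppf(coverage, df=2))


def ellipse_area(
    niche: EllipseNiche, coverage: float = STANDARD_COVERAGE, corrected: bool = True
) -> float:
    """Area of the coverage ellipse: pi * k * sqrt(det(cov)) * correction.

    ``k`` is the chi-square(2) quantile at ``coverage``; the standard ellipse
    corresponds to ``coverage = 1 - exp(-1/2)`` where k = 1.  The (n-1)/(n-2)
    correction is applied by default so that areas at any two coverages keep
    the exact chi-square ratio.
    """
    corr = niche.correction if corrected else 1.0
    return niche.sea * _chi2_scale(coverage) * corr


def ellipse_boundary(
    niche: EllipseNiche,
    coverage: float = 0.95,
    n_vertices: int = 720,
    corrected: bool = True,
) -> np.ndarray:
    """(n_vertices, 2) polygonal discretization of the coverage-ellipse boundary."""
    k = _chi2_scale(coverage) * (niche.correction if corrected else 1.0)
    # cov = L L^T maps the unit circle onto the one-unit ellipse
    L = np.linalg.cholesky(niche.cov + 0.0)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    return niche.mean + np.sqrt(k) * circle @ L.T


def ellipse_intersection_area(
    a: EllipseNiche,
    b: EllipseNiche,
    coverage: float = 0.95,
    method: str = "grid",
    resolution: int = 720,
    seed: int | None = None,
    n_samples: int = 200_000,
    corrected: bool = True,
) -> float:
    """Geometric intersection area of two coverage ellipses (permil^2).

    ``method="grid"`` (default) clips 720-vertex boundary polygons exactly;
    the relative discretization error is below 1e-3 at that resolution.
    ``method="montecarlo"`` rejection-samples a bounding box and serves as an
    independent cross-check.
    """
    if a.degenerate or b.degenerate:
        raise ValueError("intersection of a degenerate (singular-covariance) niche")
    if method == "grid":
        pa = Polygon(ellipse_boundary(a, coverage, resolution, corrected))
        pb = Polygon(ellipse_boundary(b, coverage, resolution, corrected))
        return float(pa.intersection(pb).area)
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        ba = ellipse_boundary(a, coverage, 256, corrected)
        bb = ellipse_boundary(b, coverage, 256, corrected)
        lo = np.minimum(ba.min(axis=0), bb.min(axis=0))
        hi = np.maximum(ba.max(axis=0), bb.max(axis=0))
        pts = rng.uniform(lo, hi, size=(n_samples, 2))
        ka = _chi2_scale(coverage) * (a.correction if corrected else 1.0)
        kb = _chi2_scale(coverage) * (b.correction if corrected else 1.0)
        da = _mahalanobis_sq(pts, a.mean, a.cov)
        db = _mahalanobis_sq(pts, b.mean, b.cov)
        frac = np.mean((da <= ka) & (db <= kb))
        return float(frac * np.prod(hi - lo))
    raise ValueError(f"unknown method {method!r}")


def _mahalanobis_sq(pts: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    diff = pts - mean
    sol = np.linalg.solve(cov, diff.T)
    return np.einsum("ij,ji->i", diff, sol)


def percent_overlap(
    intersection_area: float, area_a: float, area_b: float
) -> float:
    """Percent-of-union overlap: 100 * I / (A + B - I)."""
    if intersection_area < 0 or intersection_area > min(area_a, area_b) * (1 + 1e-9):
        raise ValueError(
            f"intersection {intersection_area} exceeds smaller area "
            f"min({area_a}, {area_b})"
        )
    union = area_a + area_b - intersection_area
    if union <= 0:
        return 0.0
    return 100.0 * intersection_area / union


def posterior_sea_draws(
    group: SpeciesGroup, n_draws: int = 1000, seed: int | None = None
) -> np.ndarray:
    """Posterior draws of the standard ellipse area ("Bayesian SEA").

    The covariance is sampled from its conjugate inverse-Wishart posterior
    under a vague prior (df = 3, scale = scatter matrix); areas are
    pi*sqrt(det).  Point (unbiased) SEAc remains the default reported value.
    """
    if group.n < 3:
        raise ValueError("posterior SEA needs n >= 3")
    xy = group.xy
    scatter = (xy - xy.mean(axis=0)).T @ (xy - xy.mean(axis=0))
    nu = group.n - 1 + 3
    rng = np.random.default_rng(seed)
    draws = stats.invwishart.rvs(df=nu, scale=scatter + 1e-3 * np.eye(2),
                                 size=n_draws, random_state=rng)
    dets = np.linalg.det(np.asarray(draws).reshape(n_draws, 2, 2))
    return np.pi * np.sqrt(np.clip(dets, 0.0, None))
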