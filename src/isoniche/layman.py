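"""Layman metrics on the standardized d13C-d15N plane.

The six classic community descriptors of a point cloud in isotope space:

* NR — d15N range (trophic length of the web)
* CR — d13C range (basal resource diversity)
* TA — total area of the convex hull (overall niche space, permil^2)
* CD — mean Euclidean distance to the centroid (average trophic diversity)
* NND — mean nearest-neighbour distance (species packing)
* SDNND — standard deviation of NND (evenness of packing)

Metrics can be taken per species (over its individuals) or community-wide
over the pooled individual points of all included groups, baseline included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .io import CommunityDataset

__all__ = ["LaymanMetrics", "convex_hull_area", "layman_metrics", "community_metrics"]


@dataclass(frozen=True)
class LaymanMetrics:
    nr: float
    cr: float
    ta: float
    cd: float
    nnd: float
    sdnnd: float
    n_points: int


def convex_hull_area(points: Sequence | np.ndarray) -> float:
    """Area of the convex hull of (d13C, d15N) points, in permil^2.

    Collinear or fewer-than-three point sets have zero hull area.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("convex hull of an empty point set")
    if pts.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # "volume" is area in 2-D
    except QhullError:
        return 0.0  # degenerate (collinear / duplicate) input


def layman_metrics(points: Sequence | np.ndarray) -> LaymanMetrics:
    """All six Layman metrics of a point cloud (columns d13C, d15N)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError(f"Layman metrics need >= 2 points, got {pts.shape[0]}")
    d13c, d15n = pts[:, 0], pts[:, 1]
    centroid = pts.mean(axis=0)
    cd = float(np.mean(np.linalg.norm(pts - centroid, axis=1)))
    dm = squareform(pdist(pts))
    np.fill_diagonal(dm, np.inf)
    nnd_all = dm.min(axis=1)
    return LaymanMetrics(
        nr=float(d15n.max() - d15n.min()),
        cr=float(d13c.max() - d13c.min()),
        ta=convex_hull_area(pts),
        cd=cd,
        nnd=float(np.mean(nnd_all)),
        sdnnd=float(np.std(nnd_all, ddof=1)),
        n_points=pts.shape[0],
    )


def community_metrics(
    community: CommunityDataset, include: Iterable[str] | None = None
) -> LaymanMetrics:
    """Layman metrics over the pooled individuals of the included groups.

    ``include=None`` pools every group (the baseline too).  Pooling operates
    on individuals, not on species means, so the community carbon range is
    set by the single most extreme individuals across species.
    """
    names = list(include) if include is not None else list(community.groups)
    if not names:
        raise ValueError("empty species inclusion for community metrics")
    missing = [s for s in names if s not in community.groups]
    if missing:
        raise KeyError(f"species not in community: {missing}")
    pts = np.vstack([community.groups[s].xy for s in names])
    return layman_metrics(pts)
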