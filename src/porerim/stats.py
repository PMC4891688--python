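"""Summary statistics for rim-decoration analysis.

Region particle densities (particle area / non-particle area), particle
distance-to-edge distributions, interparticle spacing (circumference /
particle count — an upper bound on true molecular spacing, since touching
particles merge into one cluster), the particle-area-vs-circumference
regression, and a Mann-Whitney rank test that is exact (full enumeration)
for small samples.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import norm

from .detect import ParticleCluster, total_cluster_area
from .errors import (
    DegenerateRegionError,
    EmptyInputError,
    IllConditionedError,
    ValidationError,
)
from .geometry import Polyline, RoiPolygon, min_edge_distance, point_in_polygon, polygon_area

__all__ = [
    "DensityRecord",
    "PoreRecord",
    "RegressionResult",
    "RankTestResult",
    "EdgeDistanceSummary",
    "region_density",
    "edge_distance_summary",
    "interparticle_spacing",
    "density_vs_circumference_regression",
    "mann_whitney",
]

logger = logging.getLogger(__name__)

EXACT_TEST_MAX_N = 14  # full enumeration up to C(14, 7) = 3432 labelings


@dataclass(frozen=True)
class DensityRecord:
    region_label: str
    cluster_area: float  # nm²
    region_area: float  # nm²
    density: float  # dimensionless
    normalization: float = 1.0


@dataclass
class PoreRecord:
    """Per-pore summary feeding the regression and spacing estimates."""

    pore_id: str
    perimeter: float  # nm
    particle_area: float  # nm²
    particle_count: int
    tilt_class: str = "en_face"
    spacing: float = field(init=False)  # nm; NaN when no particles

    def __post_init__(self) -> None:
        if not self.perimeter > 0:
            raise ValidationError("perimeter: must be positive")
        if self.particle_count < 0:
            raise ValidationError("particle_count: must be non-negative")
        self.spacing = (
            self.perimeter / self.particle_count
            if self.particle_count > 0
            else float("nan")
        )


@dataclass(frozen=True)
class RegressionResult:
    slope: float  # nm²/nm
    intercept: float  # nm²
    r_squared: float
    n: int
    slope_through_origin: float


@dataclass(frozen=True)
class RankTestResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int


def region_density(
    clusters,
    roi: RoiPolygon,
    normalization: float = 1.0,
    caption_denominator: bool = False,
) -> DensityRecord:
    """Particle density in a region: normalized particle area divided by the
    non-particle area of the region.

    Clusters belong to the region when their centroid lies inside (boundary
    inclusive).  ``caption_denominator`` switches the denominator to the
    full region area instead of region minus particle area; the two differ
    by less than the particle fraction.  ``normalization`` rescales the
    particle area (e.g. to correct a control's lower gold concentration).
    """
    region_area = polygon_area(roi)
    members = [c for c in clusters if point_in_polygon(c.centroid, roi)]
    cluster_area = total_cluster_area(members)
    if cluster_area >= region_area:
        raise DegenerateRegionError(
            "cluster area meets or exceeds region area; density undefined"
        )
    denom = region_area if caption_denominator else region_area - cluster_area
    return DensityRecord(
        region_label=roi.label,
        cluster_area=cluster_area,
        region_area=region_area,
        density=normalization * cluster_area / denom,
        normalization=normalization,
    )


@dataclass
class EdgeDistanceSummary:
    """Distances from particle centers to the pore edge, binned."""

    distances: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray

    def fraction_within(self, threshold: float) -> float:
        return float(np.mean(self.distances <= threshold))


def edge_distance_summary(
    particles,
    edge: Polyline,
    bin_width: float = 0.5,
    orientation_class: str | None = None,
) -> EdgeDistanceSummary:
    """Histogram of shortest particle-center-to-edge distances.

    ``particles`` is a sequence of 2D centers in nm (or ParticleCluster
    objects, whose centroids are used).  En-face annotations are
    recommended; oblique/edge-on input triggers a warning because
    foreshortening biases the distances.
    """
    pts = [
        p.centroid if isinstance(p, ParticleCluster) else np.asarray(p, dtype=float)
        for p in particles
    ]
    if len(pts) == 0:
        raise EmptyInputError("edge_distance_summary needs at least one particle")
    if bin_width <= 0:
        raise ValidationError("bin_width: must be positive")
    if orientation_class is not None and orientation_class != "en_face":
        logger.warning(
            "edge distances measured on a %s pore; foreshortening may bias them",
            orientation_class,
        )
    d = np.array([min_edge_distance(p, edge) for p in pts])
    n_bins = max(int(math.ceil(d.max() / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    return EdgeDistanceSummary(distances=d, bin_edges=edges, counts=counts)


def interparticle_spacing(record: PoreRecord) -> float:
    """Mean spacing along the rim: perimeter / particle count.

    Zero particles yields NaN (undefined), not an exception.  Because
    touching particles are counted as one cluster, this is an upper bound
    on the true molecular spacing.
    """
    return record.spacing


def density_vs_circumference_regression(records) -> RegressionResult:
    """OLS of total particle area on pore perimeter, with intercept, plus
    the through-origin slope.  A near-zero intercept indicates that linear
    particle density is independent of pore size."""
    records = list(records)
    n = len(records)
    if n < 3:
        raise ValidationError("records: regression needs at least 3 pores")
    x = np.array([r.perimeter for r in records])
    y = np.array([r.particle_area for r in records])
    if np.ptp(x) == 0:
        raise IllConditionedError("all pore perimeters identical")
    sxx = float(np.sum((x - x.mean()) ** 2))
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    slope0 = float(np.sum(x * y) / np.sum(x ** 2))
    return RegressionResult(
        slope=float(slope),
        intercept=intercept,
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n=n,
        slope_through_origin=slope0,
    )


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # mean of ranks i+1..j+1
        i = j + 1
    return ranks


def mann_whitney(x, y, mode: str = "auto") -> RankTestResult:
    """Two-sided Mann-Whitney rank test with midranks for ties.

    U is the statistic of the first sample.  For n1 + n2 <= 14 (mode
    "auto") the p-value is exact: all C(n1+n2, n1) group labelings are
    enumerated and the fraction with |U - n1·n2/2| at least as extreme as
    observed is returned.  Larger samples use the normal approximation with
    continuity correction and tie-corrected variance.  p is capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("x/y: both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValidationError(f"mode: unknown {mode!r}")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0

    use_exact = mode == "exact" or (mode == "auto" and n1 + n2 <= EXACT_TEST_MAX_N)
    if use_exact:
        offset = n1 * (n1 + 1) / 2.0
        observed_dev = abs(u - mu)
        total = 0
        extreme = 0
        for combo in combinations(range(n1 + n2), n1):
            total += 1
            u_perm = ranks[list(combo)].sum() - offset
            if abs(u_perm - mu) >= observed_dev - 1e-9:
                extreme += 1
        p = extreme / total
        method = "exact"
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            cc = 0.5 if u != mu else 0.0
            z = (abs(u - mu) - cc) / math.sqrt(var)
            p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
        method = "normal_approx"
    return RankTestResult(u_statistic=u, p_value=float(min(p, 1.0)),
                          method=method, n1=n1, n2=n2)
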