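"""Tests of Complete Spatial Randomness and cluster detection.

Three complementary procedures:

* a chi-square dispersion test on quadrat counts over equal-area tiles,
* the Hopkins–Skellam clustering index with a Monte-Carlo null,
* a circular spatial scan statistic (likelihood-ratio test for a region of
  elevated intensity inside fixed-radius circles).

Monte-Carlo p-values use the rank convention p = (1 + #{null ≥ obs}) /
(1 + n_sim); with n_sim = 19 the attainable p-values are multiples of 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from shapely.geometry import Point, box

from .geometry import PointPattern, Window, nn_distances
from .synthetic import as_rng, csr_fixed_n, uniform_in_window


def mc_p_value(observed: float, null: np.ndarray, alternative: str = "greater") -> float:
    """Rank-based Monte-Carlo p-value of ``observed`` among ``null``."""
    null = np.asarray(null, float)
    n_sim = null.size
    if alternative == "greater":
        k = int(np.sum(null >= observed))
    elif alternative == "less":
        k = int(np.sum(null <= observed))
    elif alternative == "two-sided":
        hi = int(np.sum(null >= observed))
        lo = int(np.sum(null <= observed))
        return min(1.0, 2.0 * (1 + min(hi, lo)) / (1 + n_sim))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + k) / (1 + n_sim)


@dataclass(frozen=True)
class MonteCarloTest:
    """Result of a rank-based Monte-Carlo test."""

    statistic: float
    null_values: np.ndarray
    n_sim: int
    p_value: float
    alternative: str

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "n_sim": int(self.n_sim),
            "p_value": float(self.p_value),
            "alternative": self.alternative,
        }


@dataclass(frozen=True)
class QuadratTestResult:
    statistic: float
    df: int
    p_value: float
    counts: np.ndarray
    expected: np.ndarray
    cuts: np.ndarray

    def to_dict(self) -> dict:
        return {
            "test": "quadrat-chi2",
            "statistic": float(self.statistic),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "counts": self.counts.tolist(),
        }


def equal_area_cuts(window: Window, n_tiles: int) -> np.ndarray:
    """x positions splitting the window into vertical slabs of equal area.

    Cut positions are found by bisection on the cumulative-area function
    A(x) = |W ∩ {X ≤ x}|; slabs are reproducible on any simple polygon.
    """
    if n_tiles < 2:
        raise ValueError("need at least 2 tiles")
    xmin, ymin, xmax, ymax = window.bounds
    poly, total = window.polygon, window.area_m2
    pad = 1e-9 * (ymax - ymin + 1)

    def cum_area(x):
        return poly.intersection(box(xmin - 1, ymin - pad - 1, x, ymax + pad + 1)).area

    cuts = np.empty(n_tiles - 1)
    for j in range(1, n_tiles):
        target = total * j / n_tiles
        cuts[j - 1] = brentq(lambda x: cum_area(x) - target, xmin, xmax, xtol=1e-10)
    return cuts


def quadrat_test(pp: PointPattern, n_tiles: int = 5) -> QuadratTestResult:
    """Chi-square dispersion test on counts in equal-area vertical slabs.

    Under CSR the counts are multinomial with equal cell probabilities;
    X² = Σ (n_j − e_j)²/e_j is referred to χ² with n_tiles − 1 df.
    Requires an expected count of at least 1 per tile.
    """
    n = pp.n
    if n < n_tiles:
        raise ValueError("expected count per tile below 1; fewer tiles needed")
    cuts = equal_area_cuts(pp.window, n_tiles)
    # points exactly on a cut fall in the left slab (searchsorted side='left')
    tile = np.searchsorted(cuts, pp.coords[:, 0], side="left")
    counts = np.bincount(tile, minlength=n_tiles).astype(float)
    expected = np.full(n_tiles, n / n_tiles)
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = n_tiles - 1
    p = float(stats.chi2.sf(stat, df))
    return QuadratTestResult(stat, df, p, counts, expected, cuts)


def hopkins_skellam_statistic(pp: PointPattern, n_sample: int, rng) -> float:
    """A = Σ d_P(s)² / Σ d_E(s)².

    d_P: distances from ``n_sample`` uniform sample locations to the nearest
    event (empty-space distances); d_E: nearest-neighbour distances of
    ``n_sample`` randomly chosen events.  A ≈ 1 under CSR; clustering
    inflates the empty-space distances, so A > 1 indicates clustering.
    """
    n = pp.n
    tree = cKDTree(pp.coords)
    sample_pts = uniform_in_window(pp.window, n_sample, rng)
    d_p, _ = tree.query(sample_pts, k=1)
    if n_sample > n:
        idx = rng.choice(n, size=n_sample, replace=True)
    else:
        idx = rng.choice(n, size=n_sample, replace=False)
    d_all = nn_distances(pp, 1).nn_dist(1)
    d_e = d_all[idx]
    denom = (d_e**2).sum()
    if denom == 0:
        return math.inf
    return float((d_p**2).sum() / denom)


def hopkins_skellam(
    pp: PointPattern,
    n_sample: int | None = None,
    seed=0,
    n_sim: int = 199,
    alternative: str = "greater",
) -> MonteCarloTest:
    """Hopkins–Skellam test of CSR with a Monte-Carlo null.

    The null distribution is built by resimulating CSR patterns with the
    same number of points in the same window (avoids the edge-effect bias
    of the classical beta approximation in irregular windows).
    """
    if pp.n < 2:
        raise ValueError("need at least 2 points")
    rng = as_rng(seed)
    if n_sample is None:
        n_sample = min(pp.n, 100)
    if n_sample > pp.n:
        warnings.warn("n_sample exceeds n; sampling events with replacement")
    obs = hopkins_skellam_statistic(pp, n_sample, rng)
    null = np.empty(n_sim)
    for s in range(n_sim):
        sim = csr_fixed_n(pp.n, pp.window, rng)
        null[s] = hopkins_skellam_statistic(sim, n_sample, rng)
    p = mc_p_value(obs, null, alternative)
    return MonteCarloTest(obs, null, n_sim, p, alternative)


@dataclass(frozen=True)
class ScanGeometry:
    """Precomputed scan-circle geometry for one (window, radius, grid).

    Reusable across patterns and Monte-Carlo replicates, which keeps
    repeated scans cheap: only the circle counts change.
    """

    window: Window
    radius: float
    centers: np.ndarray
    expected_fraction: np.ndarray  # area(b(u,r) ∩ W) / |W| per centre


def prepare_scan(window: Window, radius: float, pixel: float | None = None) -> ScanGeometry:
    """Scan centres (in-window pixel centres) and clipped circle areas."""
    if not 0 < radius < window.diameter / 2:
        raise ValueError("radius must be in (0, window diameter / 2)")
    from .intensity import raster_grid

    if pixel is None:
        pixel = window.diameter / 32.0
    xs, ys, mask = raster_grid(window, pixel)
    xx, yy = np.meshgrid(xs, ys)
    centers = np.column_stack([xx[mask], yy[mask]])
    poly, total = window.polygon, window.area_m2
    frac = np.empty(len(centers))
    for i, (cx, cy) in enumerate(centers):
        frac[i] = Point(cx, cy).buffer(radius, quad_segs=48).intersection(poly).area / total
    return ScanGeometry(window, radius, centers, frac)


def _scan_lrt_max(coords: np.ndarray, geom: ScanGeometry):
    """Max scan LRT over the centre grid, and the argmax location."""
    n = len(coords)
    tree = cKDTree(coords)
    n_in = np.asarray(
        tree.query_ball_point(geom.centers, geom.radius, return_length=True), float
    )
    e_in = n * geom.expected_fraction
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(n_in > 0, n_in * np.log(n_in / e_in), 0.0)
        rest = n - n_in
        e_rest = np.maximum(n - e_in, 1e-300)
        t2 = np.where(rest > 0, rest * np.log(rest / e_rest), 0.0)
        lrt = 2.0 * (t1 + t2)
    lrt = np.where(n_in > e_in, lrt, 0.0)  # one-sided: elevated intensity only
    k = int(np.argmax(lrt))
    return lrt, float(lrt[k]), geom.centers[k]


@dataclass(frozen=True)
class ScanResult:
    radius: float
    lrt: np.ndarray
    centers: np.ndarray
    statistic: float
    location: np.ndarray
    p_value: float
    n_sim: int

    def to_dict(self) -> dict:
        return {
            "test": "scan-lrt",
            "radius": float(self.radius),
            "statistic": float(self.statistic),
            "location": [float(v) for v in self.location],
            "p_value": float(self.p_value),
            "n_sim": int(self.n_sim),
        }


def scan_test(
    pp: PointPattern,
    radius: float,
    n_sim: int = 19,
    seed=0,
    pixel: float | None = None,
    geometry: ScanGeometry | None = None,
) -> ScanResult:
    """Circular scan test for a region of elevated intensity.

    For every centre u on the analysis grid, with n_in points inside the
    clipped circle b(u, r) ∩ W and e_in = n·area(b∩W)/|W| expected under
    CSR, the one-sided likelihood-ratio statistic is

        LRT(u) = 2 [ n_in log(n_in/e_in) + (n−n_in) log((n−n_in)/(n−e_in)) ]

    when n_in > e_in and 0 otherwise.  The test statistic is the maximum
    over centres; its p-value comes from CSR resimulation with the same n.
    """
    if pp.n < 1:
        raise ValueError("scan test needs at least one point")
    rng = as_rng(seed)
    geom = geometry if geometry is not None else prepare_scan(pp.window, radius, pixel)
    lrt, stat, loc = _scan_lrt_max(pp.coords, geom)
    null = np.empty(n_sim)
    for s in range(n_sim):
        sim = uniform_in_window(pp.window, pp.n, rng)
        _, null[s], _ = _scan_lrt_max(sim, geom)
    p = mc_p_value(stat, null, "greater")
    return ScanResult(geom.radius, lrt, geom.centers, stat, np.asarray(loc), p, n_sim)


def significant_cluster_radii(
    pp: PointPattern,
    radii,
    n_sim: int = 19,
    seed=0,
    alpha: float = 0.05,
    pixel: float | None = None,
):
    """Sweep the scan radius and report radii whose max-LRT p ≤ alpha.

    This is the scan-based estimate of the size of a statistically
    significant cluster: the range of circle radii at which elevated
    intensity remains detectable.
    """
    rng = as_rng(seed)
    results = []
    for r in radii:
        results.append(scan_test(pp, r, n_sim=n_sim, seed=rng, pixel=pixel))
    significant = [res.radius for res in results if res.p_value <= alpha]
    return significant, results
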