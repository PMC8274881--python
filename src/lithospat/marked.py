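"""Multitype analysis of marked point patterns.

Spatially varying type probabilities (relative-risk surfaces) with
Monte-Carlo tolerance contours, the random-relabelling segregation test,
and the nearest-neighbour equality function.

The null model throughout is *random labelling*: point positions are held
fixed and the mark column is randomly permuted, preserving the multiset of
labels exactly.  With the conventional 19 relabelling simulations, rank
p-values are multiples of 1/20 = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .csr import mc_p_value, MonteCarloTest
from .geometry import PointPattern, nn_distances
from .intensity import raster_grid, bw_likelihood_cv
from .summaries import FunctionCurve
from .synthetic import as_rng

_CHUNK = 4096


def _resolve_bandwidth(pp: PointPattern, bandwidth) -> float:
    """A numeric bandwidth, selecting by pooled likelihood CV on request."""
    if bandwidth == "cv":
        return bw_likelihood_cv(pp).selected
    bw = float(bandwidth)
    if bw <= 0:
        raise ValueError("bandwidth must be positive")
    return bw


def _kernel_matrix(targets: np.ndarray, sources: np.ndarray, h: float) -> np.ndarray:
    """Gaussian kernel weights κ_h(t − s), (n_targets, n_sources)."""
    norm = 1.0 / (2.0 * math.pi * h * h)
    inv = 1.0 / (2.0 * h * h)
    out = np.empty((len(targets), len(sources)))
    for start in range(0, len(targets), _CHUNK):
        block = targets[start : start + _CHUNK]
        d2 = (
            (block[:, 0:1] - sources[None, :, 0]) ** 2
            + (block[:, 1:2] - sources[None, :, 1]) ** 2
        )
        out[start : start + _CHUNK] = norm * np.exp(-d2 * inv)
    return out


def _check_types(labels: np.ndarray, min_per_type: int = 1):
    levels, counts = np.unique(labels, return_counts=True)
    if levels.size < 2:
        raise ValueError("need at least 2 mark types")
    if np.any(counts < min_per_type):
        bad = levels[counts < min_per_type]
        raise ValueError(f"type(s) {bad.tolist()} have fewer than {min_per_type} points")
    return levels, counts


@dataclass(frozen=True)
class ProbabilityField:
    """Per-type probability rasters p̂_k(u) on a shared grid.

    ``probs`` is (K, ny, nx) with NaN outside the mask; probabilities sum
    to one at every masked-in pixel.  ``sig_masks`` (when present) flags the
    pixels where the observed probability of a type is significantly
    *higher* than its average proportion under the relabelling null -- the
    pixel set whose outline is the tolerance contour.
    """

    xmin: float
    ymin: float
    pixel: float
    mask: np.ndarray
    levels: tuple
    probs: np.ndarray
    proportions: np.ndarray
    bandwidth: float
    sig_masks: np.ndarray | None = None
    n_sim: int = 0
    alpha: float | None = None

    def prob(self, level) -> np.ndarray:
        return self.probs[self.levels.index(level)]

    def sig_mask(self, level) -> np.ndarray:
        if self.sig_masks is None:
            raise ValueError("no tolerance masks: run tolerance_contours")
        return self.sig_masks[self.levels.index(level)]

    def relative_risk(self, level) -> np.ndarray:
        """Odds form p̂_k / (1 − p̂_k) of the type-probability surface."""
        p = self.prob(level)
        with np.errstate(divide="ignore", invalid="ignore"):
            return p / (1.0 - p)


def _prob_grids(kmat: np.ndarray, indicators: np.ndarray) -> np.ndarray:
    """(K, m) type probabilities from kernel weights and label indicators."""
    lam = kmat @ indicators  # (m, K) unnormalised type intensities
    tot = lam.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, lam / tot, np.nan).T


def type_probability(
    pp: PointPattern,
    mark: str = "type",
    bandwidth="cv",
    pixel: float | None = None,
) -> ProbabilityField:
    """Spatially varying type probabilities p̂_k(u) = λ̂_k(u) / Σ_j λ̂_j(u).

    All types share one bandwidth (selected by likelihood CV on the pooled
    pattern when ``bandwidth='cv'``); the uniform edge correction is common
    to every type and cancels in the ratio.  Pixels where every type
    intensity underflows to zero are masked out.
    """
    labels = pp.mark(mark)
    levels, counts = _check_types(labels)
    bw = _resolve_bandwidth(pp, bandwidth)
    window = pp.window
    if pixel is None:
        pixel = window.diameter / 64.0
    xs, ys, mask = raster_grid(window, pixel)
    xx, yy = np.meshgrid(xs, ys)
    centers = np.column_stack([xx[mask], yy[mask]])
    kmat = _kernel_matrix(centers, pp.coords, bw)
    Z = (labels[:, None] == levels[None, :]).astype(float)
    pg = _prob_grids(kmat, Z)  # (K, m)
    ny, nx = mask.shape
    probs = np.full((levels.size, ny, nx), np.nan)
    probs[:, mask] = pg
    xmin, ymin, _, _ = window.bounds
    return ProbabilityField(
        xmin, ymin, pixel, mask, tuple(levels), probs, counts / pp.n, bw
    )


def tolerance_contours(
    pp: PointPattern,
    mark: str = "type",
    bandwidth="cv",
    n_sim: int = 19,
    alpha: float = 0.05,
    seed=0,
    pixel: float | None = None,
) -> ProbabilityField:
    """Pixelwise Monte-Carlo test of the type-probability surfaces.

    The pattern is repeatedly relabelled (marks permuted, positions fixed)
    and the type probabilities recomputed with the same bandwidth; at each
    pixel the observed p̂_k is ranked against the simulated ones
    (one-sided, elevated probability).  Pixels with rank p ≤ alpha form the
    significance mask of type k.  With ``n_sim=19`` the attainable pixel
    p-values are multiples of 0.05.
    """
    if alpha < 1.0 / (n_sim + 1):
        raise ValueError(
            f"alpha={alpha} unattainable with {n_sim} simulations "
            f"(minimum p is {1 / (n_sim + 1):.4g})"
        )
    rng = as_rng(seed)
    field = type_probability(pp, mark, bandwidth, pixel)
    labels = pp.mark(mark)
    levels = np.asarray(field.levels)
    window = pp.window
    xs, ys, mask = raster_grid(window, field.pixel)
    xx, yy = np.meshgrid(xs, ys)
    centers = np.column_stack([xx[mask], yy[mask]])
    kmat = _kernel_matrix(centers, pp.coords, field.bandwidth)
    obs = field.probs[:, mask]  # (K, m)
    exceed = np.zeros_like(obs, dtype=int)
    for _ in range(n_sim):
        perm = rng.permutation(pp.n)
        Z = (labels[perm][:, None] == levels[None, :]).astype(float)
        sim = _prob_grids(kmat, Z)
        exceed += (sim >= obs).astype(int)
    p_pix = (1 + exceed) / (1 + n_sim)
    sig = p_pix <= alpha
    ny, nx = mask.shape
    sig_masks = np.zeros((levels.size, ny, nx), bool)
    sig_masks[:, mask] = sig
    return ProbabilityField(
        field.xmin,
        field.ymin,
        field.pixel,
        field.mask,
        field.levels,
        field.probs,
        field.proportions,
        field.bandwidth,
        sig_masks,
        n_sim,
        alpha,
    )


def segregation_statistic(kmat: np.ndarray, indicators: np.ndarray) -> float:
    """T = Σ_i Σ_k (p̂_k(x_i) − p̄_k)² with leave-one-out probabilities.

    ``kmat`` must have a zero diagonal (the self-kernel is excluded so that
    each point does not vote for its own type).
    """
    lam = kmat @ indicators
    tot = lam.sum(axis=1, keepdims=True)
    pbar = indicators.mean(axis=0)
    p_hat = np.where(tot > 0, lam / np.maximum(tot, 1e-300), pbar)
    return float(((p_hat - pbar) ** 2).sum())


def segregation_test(
    pp: PointPattern,
    mark: str = "type",
    bandwidth="cv",
    n_sim: int = 19,
    seed=0,
) -> MonteCarloTest:
    """Monte-Carlo test of spatial segregation of mark types.

    The statistic sums, over data points and types, the squared deviation
    of the leave-one-out type probability from the overall type proportion;
    large values mean the local type composition strays from the global mix
    (segregation).  The null distribution comes from random relabelling
    with positions fixed; the kernel weight matrix depends only on the
    positions and is computed once.
    """
    labels = pp.mark(mark)
    levels, _ = _check_types(labels, min_per_type=2)
    bw = _resolve_bandwidth(pp, bandwidth)
    rng = as_rng(seed)
    kmat = _kernel_matrix(pp.coords, pp.coords, bw)
    np.fill_diagonal(kmat, 0.0)
    Z = (labels[:, None] == levels[None, :]).astype(float)
    obs = segregation_statistic(kmat, Z)
    null = np.empty(n_sim)
    for s in range(n_sim):
        perm = rng.permutation(pp.n)
        null[s] = segregation_statistic(kmat, Z[perm])
    p = mc_p_value(obs, null, "greater")
    return MonteCarloTest(obs, null, n_sim, p, "greater")


def nn_equality(
    pp: PointPattern,
    mark: str,
    from_type,
    to_type,
    k_max: int = 10,
    cumulative: bool = False,
    n_sim: int = 19,
    seed=0,
) -> FunctionCurve:
    """Nearest-neighbour equality function with relabelling envelopes.

    The non-cumulative curve Ê(k) is the fraction of ``from_type`` points
    whose k-th nearest neighbour has ``to_type`` (k = 1 recovers the
    nearest-neighbour type-match proportion); the cumulative curve is the
    fraction of ``to_type`` among the first k neighbours.  The function
    never uses inter-point distances beyond the neighbour ordering, so it
    is insensitive to the intensity of the pattern.  Envelopes come from
    permuting the labels while keeping positions (and hence the neighbour
    structure) fixed.
    """
    labels = pp.mark(mark)
    if from_type not in labels:
        raise ValueError(f"from_type {from_type!r} not present")
    if to_type not in labels:
        raise ValueError(f"to_type {to_type!r} not present")
    if k_max >= pp.n:
        raise ValueError(f"k_max={k_max} must be smaller than n={pp.n}")
    rng = as_rng(seed)
    ds = nn_distances(pp, k_max)

    def curve(lab: np.ndarray) -> np.ndarray:
        src = lab == from_type
        if not src.any():
            return np.full(k_max, np.nan)
        neigh_is_b = (lab[ds.indices[src]] == to_type).astype(float)  # (n_a, k)
        if cumulative:
            frac = np.cumsum(neigh_is_b, axis=1) / np.arange(1, k_max + 1)
            return frac.mean(axis=0)
        return neigh_is_b.mean(axis=0)

    obs = curve(labels)
    n_b = int(np.sum(labels == to_type))
    expected = (n_b - (1 if from_type == to_type else 0)) / (pp.n - 1)
    theo = np.full(k_max, expected)
    sims = np.empty((n_sim, k_max))
    for s in range(n_sim):
        sims[s] = curve(labels[rng.permutation(pp.n)])
    lo = np.nanmin(sims, axis=0)
    hi = np.nanmax(sims, axis=0)
    # grand mean includes the observed curve: exact exchangeable rank test
    stack = np.vstack([obs, sims])
    mean = np.nanmean(stack, axis=0)
    dev = np.nanmax(np.abs(stack - mean), axis=1)
    p = (1 + int(np.sum(dev[1:] >= dev[0]))) / (1 + n_sim)
    ks = np.arange(1, k_max + 1)
    return FunctionCurve(
        ks, obs, theo, lo, hi, n_sim, float(p), arg_name="k",
        label=f"nn_equality[{from_type}->{to_type}]",
    )
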