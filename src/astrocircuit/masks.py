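"""Activation masks and spatial overlap analytics.

An activation threshold is derived from a grid image by 1-D k-means on the
in-nucleus cell values (k = 5 for afferent reporter channels, k = 6 for
photoconverted-red astrocyte channels); the threshold is the smallest
value assigned to the highest-centroid cluster, so the binary mask equals
that cluster's cells.  Paired afferent/astrocyte masks yield overlap areas
(% of nucleus), a bivariate similarity index
(overlap/astrocyte-area, overlap/afferent-area), a MANOVA comparison of
the bivariate points between subregions, pixel-by-pixel Pearson
correlation between maps, and per-cell overlap probability maps across
slices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .prq import GridImage

__all__ = [
    "ActivationMask",
    "OverlapReport",
    "ProbabilityMap",
    "BivariateTestReport",
    "kmeans_threshold",
    "make_mask",
    "overlap_stats",
    "compare_bivariate",
    "pixel_correlation",
    "probability_map",
]

K_AFFERENT = 5
K_CAMPARI_RED = 6


@dataclass
class ActivationMask:
    mask: np.ndarray
    threshold: float
    k: int
    source: str = ""
    slice_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class OverlapReport:
    """Mask-pair area relations, whole-nucleus and per subregion.

    ``bivariate_x`` = overlap area / astrocyte area and ``bivariate_y`` =
    overlap area / afferent area, both in [0, 1]; values near (1, 1) mean
    the two activation territories coincide, values near an axis mean one
    territory is embedded inside the other.  Percentages are relative to
    the cell count of the region over which they are computed (nucleus, or
    the subregion for subregion entries).  Zero-area denominators yield
    ``None``.
    """

    region: str
    n_region_cells: int
    overlap_pct: float
    afferent_pct: float
    astrocyte_pct: float
    bivariate_x: float | None
    bivariate_y: float | None


@dataclass
class ProbabilityMap:
    values: np.ndarray
    n_slices: int


@dataclass
class BivariateTestReport:
    """One-way MANOVA comparison of two clouds of bivariate-index points."""

    d: int
    statistic: float
    p_value: float
    n_per_group: tuple[int, int]


def _optimal_1d_kmeans_boundaries(x_sorted: np.ndarray, k: int) -> list[int]:
    """Exact 1-D k-means by dynamic programming on sorted values.

    In one dimension the optimal clusters are contiguous runs of the
    sorted data, so the within-cluster sum of squares can be minimised
    exactly (O(k n^2) with prefix sums).  Returns the start indices of
    each cluster in the sorted array.  Ties in the minimisation are broken
    toward the smaller start index.
    """
    n = x_sorted.size
    p1 = np.concatenate([[0.0], np.cumsum(x_sorted)])
    p2 = np.concatenate([[0.0], np.cumsum(x_sorted * x_sorted)])
    D = np.full((k + 1, n + 1), np.inf)
    arg = np.zeros((k + 1, n + 1), dtype=int)
    D[0, 0] = 0.0
    idx = np.arange(n + 1)
    for c in range(1, k + 1):
        prev = D[c - 1]
        for j in range(c, n + 1):
            i = idx[c - 1 : j]
            m = j - i
            s = p1[j] - p1[i]
            sse = (p2[j] - p2[i]) - s * s / m
            tot = prev[c - 1 : j] + sse
            b = int(np.argmin(tot))
            D[c, j] = tot[b]
            arg[c, j] = c - 1 + b
    bounds = []
    j = n
    for c in range(k, 0, -1):
        i = int(arg[c, j])
        bounds.append(i)
        j = i
    return bounds[::-1]


def kmeans_threshold(grid: GridImage, k: int, seed: int = 0, n_restarts: int = 25) -> float:
    """Activation threshold by 1-D k-means on in-nucleus cell values.

    Clusters are ordered by centroid; the threshold is the minimum value
    assigned to the top cluster, so ``value >= threshold`` reproduces that
    cluster exactly.  The 1-D k-means objective is solved exactly by
    dynamic programming (in one dimension optimal clusters are contiguous
    in sorted order), so the result is deterministic; ``seed`` and
    ``n_restarts`` are accepted for interface stability but the exact
    solver does not need them.
    """
    vals = grid.values[grid.nucleus_mask]
    vals = vals[np.isfinite(vals)]
    if np.unique(vals).size < k:
        raise ValueError(
            f"need at least {k} distinct in-nucleus values for k={k} clustering; "
            f"got {np.unique(vals).size}"
        )
    x = np.sort(vals)
    bounds = _optimal_1d_kmeans_boundaries(x, k)
    return float(x[bounds[-1]])


def make_mask(
    grid: GridImage, threshold: float, k: int = 0, source: str = "", slice_id: str = ""
) -> ActivationMask:
    """Binary activation mask: active (1) iff value >= threshold, in-nucleus."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    with np.errstate(invalid="ignore"):
        mask = (grid.values >= threshold) & grid.nucleus_mask
    return ActivationMask(mask=mask, threshold=threshold, k=k, source=source, slice_id=slice_id)


def _region_report(
    region: str,
    region_mask: np.ndarray,
    afferent: np.ndarray,
    astrocyte: np.ndarray,
) -> OverlapReport:
    n = int(region_mask.sum())
    aff = afferent & region_mask
    ast = astrocyte & region_mask
    ov = aff & ast
    pct = lambda m: 100.0 * m.sum() / n if n else float("nan")
    return OverlapReport(
        region=region,
        n_region_cells=n,
        overlap_pct=pct(ov),
        afferent_pct=pct(aff),
        astrocyte_pct=pct(ast),
        bivariate_x=float(ov.sum() / ast.sum()) if ast.sum() else None,
        bivariate_y=float(ov.sum() / aff.sum()) if aff.sum() else None,
    )


def overlap_stats(
    afferent_mask: ActivationMask,
    astrocyte_mask: ActivationMask,
    nucleus_mask: np.ndarray,
    subregion_masks: dict[str, np.ndarray] | None = None,
) -> dict[str, OverlapReport]:
    """Overlap areas and bivariate index, whole-nucleus and per subregion."""
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if afferent_mask.mask.shape != astrocyte_mask.mask.shape or (
        afferent_mask.mask.shape != nucleus_mask.shape
    ):
        raise ValueError("mask shapes differ")
    reports = {
        "nucleus": _region_report(
            "nucleus", nucleus_mask, afferent_mask.mask, astrocyte_mask.mask
        )
    }
    for name, m in (subregion_masks or {}).items():
        reports[name] = _region_report(
            name, np.asarray(m, dtype=bool), afferent_mask.mask, astrocyte_mask.mask
        )
    return reports


def _manova_sequential(groups: Sequence[np.ndarray]) -> tuple[int, float, float]:
    """One-way MANOVA with the sequential dimensionality test.

    Tests dim <= k for k = 0, 1, ... using Bartlett's chi-square
    approximation on Wilks' lambda of the trailing eigenvalues of
    W^-1 B; d is the smallest k not rejected at alpha = 0.05.  Returns
    (d, chi2 statistic for k=0, p-value for k=0).
    """
    p = groups[0].shape[1]
    g = len(groups)
    n = sum(len(x) for x in groups)
    grand = np.vstack(groups).mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for x in groups:
        mu = x.mean(axis=0)
        d0 = x - mu
        W += d0.T @ d0
        dm = (mu - grand)[:, None]
        B += len(x) * (dm @ dm.T)
    try:
        solve = np.linalg.solve(W, B)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate within-group covariance: {exc}") from None
    if np.linalg.cond(W) > 1e12:
        raise ValueError("degenerate within-group covariance (condition number too large)")
    eig = np.sort(np.real(np.linalg.eigvals(solve)))[::-1]
    eig = np.clip(eig, 0.0, None)
    s = min(p, g - 1)
    scale = n - 1 - (p + g) / 2.0
    d = s
    stat0 = 0.0
    p0 = 1.0
    for k in range(s):
        lam = np.prod(1.0 / (1.0 + eig[k:s]))
        chi2 = -scale * np.log(max(lam, np.finfo(float).tiny))
        dof = (p - k) * (g - 1 - k)
        pval = float(stats.chi2.sf(chi2, dof))
        if k == 0:
            stat0, p0 = float(chi2), pval
        if pval > 0.05:
            d = k
            break
    return d, stat0, p0


def compare_bivariate(
    group_a: np.ndarray, group_b: np.ndarray
) -> BivariateTestReport:
    """MANOVA between two clouds of 2-D bivariate-index points.

    ``d`` is the dimensionality along which the group means differ
    (0 means the clouds are statistically indistinguishable); the reported
    statistic and p-value are for the d = 0 test.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("bivariate points must be 2-D")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 points per group")
    d, stat, p = _manova_sequential([a, b])
    return BivariateTestReport(d=d, statistic=stat, p_value=p, n_per_group=(len(a), len(b)))


def pixel_correlation(
    map_a: GridImage,
    map_b: GridImage,
    above_threshold_only: bool = False,
    threshold_a: float | None = None,
    threshold_b: float | None = None,
) -> tuple[float, float]:
    """Pixel-by-pixel Pearson correlation between two grid maps.

    Cells must be valid (finite, in-nucleus) in both maps.  With
    ``above_threshold_only`` each map is thresholded by its own activation
    threshold and only cells surviving in *both* maps are paired.
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share a shape")
    a, b = map_a.values, map_b.values
    valid = np.isfinite(a) & np.isfinite(b)
    if above_threshold_only:
        if threshold_a is None or threshold_b is None:
            raise ValueError("thresholds required when above_threshold_only is set")
        with np.errstate(invalid="ignore"):
            valid &= (a >= threshold_a) & (b >= threshold_b)
    if valid.sum() < 3:
        raise ValueError(f"need >= 3 jointly valid cells; got {int(valid.sum())}")
    r, p = stats.pearsonr(a[valid], b[valid])
    return float(r), float(p)


def probability_map(overlap_masks: Sequence[np.ndarray | ActivationMask]) -> ProbabilityMap:
    """Per-cell overlap probability across slices (exact fraction count/n)."""
    if not overlap_masks:
        raise ValueError("need at least one overlap mask")
    arrs = [
        (m.mask if isinstance(m, ActivationMask) else np.asarray(m, dtype=bool))
        for m in overlap_masks
    ]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes differ: {sorted(shapes)}")
    stack = np.stack(arrs)
    return ProbabilityMap(values=stack.mean(axis=0), n_slices=len(arrs))
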