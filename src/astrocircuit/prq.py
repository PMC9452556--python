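"""Partition-in-regular-quadrants (PRQ) spatial normalization.

Registered slice images are divided into square grid cells (50 µm by
default), each summarised by its mean fluorescence.  Per cell, an
autofluorescence reference built from no-virus control slices is
subtracted and the result is divided by the image's own background signal
(an ROI outside the nucleus):

    G[i, j] = (mean fluorescence in cell - R[i, j]) / F0

Basal/stimulated pairs are then placed on a common scale by dividing both
members by the basal in-nucleus mean, so results read as change from
basal (basal nucleus mean == 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GridImage",
    "ReferenceField",
    "LineProfile",
    "partition_grid",
    "build_reference",
    "normalize_grid",
    "normalize_pair",
    "average_prq",
    "line_profile",
    "afferent_density",
]


@dataclass
class GridImage:
    """Grid-binned image: one mean-fluorescence value per 50 µm cell.

    ``values`` is NaN outside the nucleus (missing by convention);
    ``raw_values`` keeps every complete cell, inside or out, so the
    background ROI — which lies outside the nucleus — can be read.
    """

    values: np.ndarray
    nucleus_mask: np.ndarray
    subregion_masks: dict[str, np.ndarray]
    pixel_size_um: float = 50.0
    condition: str = "basal"
    slice_id: str = ""
    raw_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        if self.values.shape != self.nucleus_mask.shape:
            raise ValueError("values and nucleus_mask shapes differ")
        for name, m in self.subregion_masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.values.shape:
                raise ValueError(f"subregion mask '{name}' shape differs from values")
            if (m & ~self.nucleus_mask).any():
                raise ValueError(f"subregion mask '{name}' leaves the nucleus mask")
            self.subregion_masks[name] = m

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def nucleus_mean(self) -> float:
        return float(np.nanmean(self.values[self.nucleus_mask]))

    def subregion_mean(self, name: str) -> float:
        return float(np.nanmean(self.values[self.subregion_masks[name]]))


@dataclass
class ReferenceField:
    """Per-cell autofluorescence reference (mean over control slices)."""

    values: np.ndarray
    n_control: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_control < 1:
            raise ValueError("n_control must be >= 1")


@dataclass
class LineProfile:
    """Fluorescence sampled along a stored polyline of grid cells."""

    positions: np.ndarray     # 0, 1, 2, ... (grid-cell steps)
    values: np.ndarray
    subregion: str

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))


def _block_reduce_mean(image: np.ndarray, factor: int) -> np.ndarray:
    r, c = image.shape
    nr, nc = r // factor, c // factor
    if nr == 0 or nc == 0:
        raise ValueError("grid cell larger than the image")
    trimmed = image[: nr * factor, : nc * factor]
    return trimmed.reshape(nr, factor, nc, factor).mean(axis=(1, 3))


def partition_grid(
    image: np.ndarray,
    pixel_size_um: float,
    image_scale_um_per_px: float,
    nucleus_mask: np.ndarray,
    subregion_masks: dict[str, np.ndarray] | None = None,
    condition: str = "basal",
    slice_id: str = "",
) -> GridImage:
    """Grid-bin a registered source-resolution image.

    Each grid value is the mean of the source pixels it covers; trailing
    partial rows/columns are dropped.  Masks are supplied at source
    resolution and coarsened with the >= 50% area rule: a grid cell belongs
    to the nucleus (or a subregion) iff at least half its source pixels do.
    """
    image = np.asarray(image, dtype=float)
    if pixel_size_um < image_scale_um_per_px:
        raise ValueError("grid size must be >= the source pixel size")
    factor = pixel_size_um / image_scale_um_per_px
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("grid size must be an integer multiple of the source pixel size")
    factor = int(round(factor))
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if nucleus_mask.shape != image.shape:
        raise ValueError(
            "mask shape differs from image shape — inputs must be registered "
            "to the common reference frame"
        )
    raw = _block_reduce_mean(image, factor)
    grid_nucleus = _block_reduce_mean(nucleus_mask.astype(float), factor) >= 0.5
    grid_subs: dict[str, np.ndarray] = {}
    for name, m in (subregion_masks or {}).items():
        m = np.asarray(m, dtype=bool)
        if m.shape != image.shape:
            raise ValueError(f"subregion mask '{name}' shape differs from image")
        gm = _block_reduce_mean(m.astype(float), factor) >= 0.5
        grid_subs[name] = gm & grid_nucleus
    values = np.where(grid_nucleus, raw, np.nan)
    return GridImage(
        values=values,
        nucleus_mask=grid_nucleus,
        subregion_masks=grid_subs,
        pixel_size_um=pixel_size_um,
        condition=condition,
        slice_id=slice_id,
        raw_values=raw,
    )


def build_reference(controls: Sequence[GridImage]) -> ReferenceField:
    """Elementwise mean of control (no-virus) grid images."""
    if not controls:
        raise ValueError("need at least one control grid image")
    shapes = {c.shape for c in controls}
    if len(shapes) != 1:
        raise ValueError(f"control grid shapes differ: {sorted(shapes)}")
    stack = np.stack([
        c.raw_values if c.raw_values is not None else c.values for c in controls
    ])
    return ReferenceField(values=stack.mean(axis=0), n_control=len(controls))


def _background_mean(grid: GridImage, background_roi: tuple[int, int, int, int]) -> float:
    r0, r1, c0, c1 = background_roi
    if grid.nucleus_mask[r0:r1, c0:c1].any():
        raise ValueError("background ROI must lie entirely outside the nucleus")
    raw = grid.raw_values if grid.raw_values is not None else grid.values
    return float(np.nanmean(raw[r0:r1, c0:c1]))


def normalize_grid(
    grid: GridImage,
    reference: ReferenceField,
    background_roi: tuple[int, int, int, int],
) -> GridImage:
    """Reference-subtract and background-normalize one grid image.

    ``background_roi`` is ``(row0, row1, col0, col1)`` in grid coordinates,
    outside the nucleus; F0 is the mean raw grid value inside it.
    """
    if reference.values.shape != grid.shape:
        raise ValueError("reference shape differs from grid shape")
    f0 = _background_mean(grid, background_roi)
    if f0 <= 0:
        raise ValueError(f"background signal F0 must be > 0; got {f0}")
    raw = grid.raw_values if grid.raw_values is not None else grid.values
    g = (raw - reference.values) / f0
    return replace(
        grid,
        values=np.where(grid.nucleus_mask, g, np.nan),
        raw_values=g,
    )


def normalize_pair(basal: GridImage, stim: GridImage) -> tuple[GridImage, GridImage]:
    """Scale both members of a pair by the basal in-nucleus mean.

    After this the basal nucleus mean is exactly 1 and the stimulated
    image reads as fluorescence change from basal.
    """
    if basal.shape != stim.shape:
        raise ValueError("pair members must share a shape")
    m = basal.nucleus_mean()
    if not np.isfinite(m) or m <= 0:
        raise ValueError(f"basal in-nucleus mean must be > 0; got {m}")

    def scaled(g: GridImage) -> GridImage:
        return replace(
            g,
            values=g.values / m,
            raw_values=None if g.raw_values is None else g.raw_values / m,
        )

    return scaled(basal), scaled(stim)


def average_prq(grids: Sequence[GridImage]) -> GridImage:
    """Elementwise mean over slices, ignoring missing cells.

    Cells missing in every input stay missing; per-cell counts are not
    retained on the image but the union nucleus mask is.
    """
    if not grids:
        raise ValueError("need at least one grid image")
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError(f"grid shapes differ: {sorted(shapes)}")
    stack = np.stack([g.values for g in grids])
    finite = np.isfinite(stack)
    counts = finite.sum(axis=0)
    total = np.where(finite, stack, 0.0).sum(axis=0)
    mean = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    nucleus = np.logical_or.reduce([g.nucleus_mask for g in grids])
    subs: dict[str, np.ndarray] = {}
    for name in grids[0].subregion_masks:
        subs[name] = np.logical_or.reduce(
            [g.subregion_masks.get(name, np.zeros(g.shape, bool)) for g in grids]
        )
    return GridImage(
        values=mean,
        nucleus_mask=nucleus,
        subregion_masks=subs,
        pixel_size_um=grids[0].pixel_size_um,
        condition=grids[0].condition,
        slice_id="average",
    )


def line_profile(
    grid: GridImage, line_rc: Sequence[tuple[int, int]], subregion: str = ""
) -> LineProfile:
    """Sample grid values along an explicit polyline of (row, col) cells.

    The quantification lines start at a dorsal position (position 0) and
    follow the nucleus anatomy; they are stored explicitly rather than
    inferred.  Every cell must lie inside the nucleus mask.
    """
    cells = [(int(r), int(c)) for r, c in line_rc]
    offenders = [rc for rc in cells if not grid.nucleus_mask[rc]]
    if offenders:
        raise ValueError(f"line leaves the nucleus mask at cells {offenders}")
    vals = np.array([grid.values[rc] for rc in cells])
    return LineProfile(
        positions=np.arange(len(cells)), values=vals, subregion=subregion
    )


def afferent_density(
    subregion_dff: dict[str, float], injection_transfection_dff: float
) -> dict[str, float]:
    """Innervation density normalised by transfection degree.

    Each subregion's afferent fluorescence (ΔF/F0) is divided by the
    transfection degree (ΔF/F0) measured at its injection site, so
    densities are comparable across animals with different expression.
    """
    if injection_transfection_dff <= 0:
        raise ValueError("transfection degree must be > 0")
    return {k: v / injection_transfection_dff for k, v in subregion_dff.items()}
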