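"""Programmatic biofilm footprint generators for 2D runs.

These reproduce the geometries used in the flow-cell scenarios: a free disc,
a wall-attached half-disc, and the three-biofilm layout (one large biofilm
on the bottom wall and two smaller ones above it) used to study
synchronization between separated biofilms.
"""

from __future__ import annotations

import numpy as np

from .model2d import GeometryError, Grid2D, ShapeSpec

__all__ = ["disc", "wall_half_disc", "three_biofilm_layout",
           "mask_from_png", "polygon_from_csv", "generate_fixture"]


def _check_inside(mask: np.ndarray, grid: Grid2D) -> None:
    if not mask.any():
        raise GeometryError("generated shape is empty at this resolution")
    if mask[:, 0].any() or mask[:, -1].any():
        raise GeometryError("shape extends to the inlet/outlet boundary")


def disc(grid: Grid2D, radius: float = 0.2,
         center: tuple[float, float] | None = None) -> ShapeSpec:
    """A free disc of ``radius`` mm (default: centered in the cell)."""
    cx, cy = center if center is not None else (grid.Lx / 2, grid.Ly / 2)
    X, Y = grid.cell_centers()
    mask = (X - cx) ** 2 + (Y - cy) ** 2 < radius**2
    _check_inside(mask, grid)
    return ShapeSpec(mask=mask)


def wall_half_disc(grid: Grid2D, radius: float = 0.25,
                   x_center: float | None = None,
                   wall: str = "bottom") -> ShapeSpec:
    """A half-disc attached to the bottom (or top) wall."""
    cx = x_center if x_center is not None else grid.Lx / 2
    X, Y = grid.cell_centers()
    if wall == "bottom":
        mask = (X - cx) ** 2 + Y**2 < radius**2
    elif wall == "top":
        mask = (X - cx) ** 2 + (grid.Ly - Y) ** 2 < radius**2
    else:
        raise GeometryError(f"unknown wall {wall!r}")
    _check_inside(mask, grid)
    return ShapeSpec(mask=mask)


def three_biofilm_layout(grid: Grid2D,
                         large_radius: float = 0.5,
                         small_radius: float = 0.28) -> list[ShapeSpec]:
    """One large wall-attached biofilm at the bottom, two smaller discs
    above and downstream of it (the multi-biofilm synchronization layout).

    The large biofilm is deeper than the glutamate penetration length
    (≈0.26 mm) and initiates the oscillation; the smaller discs sit in the
    potassium plume it releases (downstream, with flow left to right), so
    each biofilm can oscillate at its initial size — the stated design
    intent of the scenario.
    """
    X, Y = grid.cell_centers()
    big = (X - 1.35) ** 2 + Y**2 < large_radius**2
    s1 = (X - 1.95) ** 2 + (Y - 1.35) ** 2 < small_radius**2
    s2 = (X - 2.35) ** 2 + (Y - 2.05) ** 2 < small_radius**2
    shapes = []
    for m in (big, s1, s2):
        _check_inside(m, grid)
        shapes.append(ShapeSpec(mask=m))
    return shapes


def mask_from_png(path: str, grid: Grid2D) -> ShapeSpec:
    """Read an 8-bit PNG mask (non-zero = biofilm) sized to the grid."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    if img.shape != grid.shape:
        raise GeometryError(
            f"PNG mask shape {img.shape} does not match grid {grid.shape}")
    return ShapeSpec(mask=img > 0)


def polygon_from_csv(path: str, grid: Grid2D) -> ShapeSpec:
    """Read a polygon as CSV rows of (x_mm, y_mm) and rasterize it."""
    verts = np.loadtxt(path, delimiter=",", ndmin=2)
    if verts.shape[1] != 2:
        raise GeometryError("polygon CSV must have two columns (x_mm, y_mm)")
    return ShapeSpec.from_polygon(verts, grid)


_GENERATORS = {"disc": disc, "wall_half_disc": wall_half_disc,
               "three_biofilm_layout": three_biofilm_layout}


def generate_fixture(name: str, grid: Grid2D, **params):
    """Dispatch to a named generator (``disc``, ``wall_half_disc``,
    ``three_biofilm_layout``)."""
    try:
        gen = _GENERATORS[name]
    except KeyError:
        raise GeometryError(
            f"unknown fixture shape {name!r}; choose from "
            f"{sorted(_GENERATORS)}") from None
    return gen(grid, **params)
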