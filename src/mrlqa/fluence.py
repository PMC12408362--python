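"""Aperture rasterization and MU-weighted fluence reconstruction.

A step-and-shoot segment is modelled as a strictly binary 2D mask at the
isocenter plane: a pixel is open iff its center lies inside the X jaw window
and inside the open Y interval of the leaf pair whose X band contains it.
No penumbra, leaf-end curvature, transmission or output-factor modelling is
applied — the fluence unit is MU of beam-on time through an open pixel.

The fluence map for one gantry angle is the MU-weighted sum of its segment
masks:

    F(x, y) = sum_j  MU_j * mask_j(x, y)

computed on a grid (default 0.1 mm) auto-cropped to the union bounding box
of the contributing apertures plus a margin; the identical operation serves
plan-derived and log-derived segments so the two maps are directly
comparable.

Intervals are half-open ``[low, high)`` and membership is judged at pixel
centers, which resolves edge ties deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import UsageError
from .geometry import MachineGeometry

__all__ = [
    "GridSpec",
    "FluenceGrid",
    "Aperture",
    "aperture_of",
    "grid_for_apertures",
    "rasterize_segment",
    "compute_fluence",
]


@dataclass(frozen=True)
class GridSpec:
    """Pixel-center grid at the isocenter plane.

    ``x0_mm``/``y0_mm`` are the coordinates of the center of pixel (0, 0);
    arrays are indexed ``[row=y, col=x]``.
    """

    x0_mm: float
    y0_mm: float
    nx: int
    ny: int
    resolution_mm: float

    def x_coords(self) -> np.ndarray:
        return self.x0_mm + self.resolution_mm * np.arange(self.nx)

    def y_coords(self) -> np.ndarray:
        return self.y0_mm + self.resolution_mm * np.arange(self.ny)


@dataclass
class FluenceGrid:
    """2D fluence map in MU for one gantry angle (rows = Y, columns = X)."""

    values: np.ndarray
    resolution_mm: float
    x0_mm: float
    y0_mm: float
    gantry_deg: float = 0.0

    @property
    def spec(self) -> GridSpec:
        ny, nx = self.values.shape
        return GridSpec(self.x0_mm, self.y0_mm, nx, ny, self.resolution_mm)

    def x_coords(self) -> np.ndarray:
        return self.spec.x_coords()

    def y_coords(self) -> np.ndarray:
        return self.spec.y_coords()

    def integral_mu_mm2(self) -> float:
        """Total fluence integral, MU * mm^2."""
        return float(self.values.sum()) * self.resolution_mm**2

    # -- plain-text persistence (matrix + JSON sidecar) --------------------

    def save_text(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.values, fmt="%.9g")
        sidecar = {
            "resolution_mm": self.resolution_mm,
            "x0_mm": self.x0_mm,
            "y0_mm": self.y0_mm,
            "gantry_deg": self.gantry_deg,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load_text(cls, path: str | Path) -> "FluenceGrid":
        path = Path(path)
        values = np.atleast_2d(np.loadtxt(path))
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(values=values, **meta)

    def render_png(self, path: str | Path, title: str | None = None) -> None:
        """Heatmap with the isocenter marked by a dashed crosshair."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        xs, ys = self.x_coords(), self.y_coords()
        extent = [xs[0], xs[-1], ys[0], ys[-1]]
        im = ax.imshow(self.values, origin="lower", extent=extent, cmap="viridis")
        ax.axhline(0.0, color="red", ls="--", lw=0.8)
        ax.axvline(0.0, color="red", ls="--", lw=0.8)
        ax.set_xlabel("X (mm)")
        ax.set_ylabel("Y (mm)")
        ax.set_title(title or f"Fluence, gantry {self.gantry_deg:g} deg")
        fig.colorbar(im, ax=ax, label="MU")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass(frozen=True)
class Aperture:
    """Aperture parameters of one segment: MU weight, leaf banks, jaws."""

    mu: float
    y1_mm: np.ndarray
    y2_mm: np.ndarray
    x1_mm: float
    x2_mm: float


def aperture_of(segment) -> Aperture:
    """Extract aperture parameters from a planned or delivered segment."""
    if isinstance(segment, Aperture):
        return segment
    if hasattr(segment, "y1_mean_mm"):  # delivered
        return Aperture(segment.mu, segment.y1_mean_mm, segment.y2_mean_mm,
                        segment.x1_mean_mm, segment.x2_mean_mm)
    return Aperture(segment.mu, segment.y1_mm, segment.y2_mm,
                    segment.x1_mm, segment.x2_mm)


def grid_for_apertures(
    apertures: Sequence[Aperture],
    geometry: MachineGeometry,
    resolution_mm: float = 0.1,
    margin_mm: float = 10.0,
    full_field: bool = False,
) -> GridSpec:
    """Common grid covering the union of the open apertures plus a margin.

    The origin is snapped to an integer multiple of the resolution so that
    grids built for different segment sets of the same delivery differ only
    by whole pixels (exact integer re-gridding downstream).
    """
    if resolution_mm <= 0:
        raise UsageError("resolution must be positive")
    if full_field:
        xlo, xhi = -geometry.half_x_mm, geometry.half_x_mm
        ylo, yhi = -geometry.half_y_mm, geometry.half_y_mm
    else:
        xlo = xhi = ylo = yhi = None
        edges = geometry.leaf_edges_x_mm
        for ap in apertures:
            open_pairs = np.asarray(ap.y2_mm) > np.asarray(ap.y1_mm)
            # X extent: jaw window intersected with the open pairs' bands
            if not open_pairs.any():
                continue
            first, last = np.argmax(open_pairs), len(open_pairs) - 1 - np.argmax(open_pairs[::-1])
            ax_lo = max(ap.x1_mm, edges[first])
            ax_hi = min(ap.x2_mm, edges[last + 1])
            if ax_hi <= ax_lo:
                continue
            ay_lo = float(np.min(np.asarray(ap.y1_mm)[open_pairs]))
            ay_hi = float(np.max(np.asarray(ap.y2_mm)[open_pairs]))
            xlo = ax_lo if xlo is None else min(xlo, ax_lo)
            xhi = ax_hi if xhi is None else max(xhi, ax_hi)
            ylo = ay_lo if ylo is None else min(ylo, ay_lo)
            yhi = ay_hi if yhi is None else max(yhi, ay_hi)
        if xlo is None:  # every segment fully closed: small grid around isocenter
            xlo = xhi = ylo = yhi = 0.0
        xlo, xhi = max(xlo - margin_mm, -geometry.half_x_mm), min(xhi + margin_mm, geometry.half_x_mm)
        ylo, yhi = max(ylo - margin_mm, -geometry.half_y_mm), min(yhi + margin_mm, geometry.half_y_mm)

    x0 = np.floor(xlo / resolution_mm) * resolution_mm
    y0 = np.floor(ylo / resolution_mm) * resolution_mm
    nx = int(np.ceil((xhi - x0) / resolution_mm)) + 1
    ny = int(np.ceil((yhi - y0) / resolution_mm)) + 1
    return GridSpec(float(x0), float(y0), nx, ny, resolution_mm)


def rasterize_segment(
    y1_mm: np.ndarray,
    y2_mm: np.ndarray,
    x1_mm: float,
    x2_mm: float,
    geometry: MachineGeometry,
    grid: GridSpec,
) -> np.ndarray:
    """Binary mask of one aperture on ``grid`` (bool, shape ``(ny, nx)``).

    A pixel is open iff its center (x, y) satisfies ``x1 <= x < x2`` and
    ``y1[p] <= y < y2[p]`` for the leaf pair p whose half-open X band
    contains x.  A fully closed segment yields an all-zero mask.

    Aperture coordinates are snapped to a 1e-6 mm lattice first, so positions
    that differ only by float round-off (e.g. a plan value versus the mean of
    error-free log samples of it) rasterize identically even when a pixel
    center lies exactly on an edge.
    """
    xs = grid.x_coords()
    ys = grid.y_coords()
    edges = geometry.leaf_edges_x_mm
    pair = np.searchsorted(edges, xs, side="right") - 1
    in_field = (pair >= 0) & (pair < geometry.n_leaf_pairs)
    pair_safe = np.clip(pair, 0, geometry.n_leaf_pairs - 1)
    ylo = np.round(np.asarray(y1_mm, float), 6)[pair_safe]
    yhi = np.round(np.asarray(y2_mm, float), 6)[pair_safe]
    x1_mm, x2_mm = round(float(x1_mm), 6), round(float(x2_mm), 6)
    col_ok = in_field & (xs >= x1_mm) & (xs < x2_mm)
    ycol = ys[:, None]
    return col_ok[None, :] & (ycol >= ylo[None, :]) & (ycol < yhi[None, :])


def compute_fluence(
    segments: Iterable,
    geometry: MachineGeometry,
    resolution_mm: float = 0.1,
    grid: GridSpec | None = None,
    gantry_deg: float | None = None,
    margin_mm: float = 10.0,
    full_field: bool = False,
) -> FluenceGrid:
    """MU-weighted sum of segment masks for one gantry angle.

    ``segments`` may be planned segments, delivered segments, or bare
    :class:`Aperture` tuples; all must belong to the same gantry angle.
    If ``grid`` is omitted it is auto-sized to the union of the apertures
    plus ``margin_mm``.
    """
    apertures = [aperture_of(s) for s in segments]
    if not apertures:
        raise UsageError("compute_fluence requires at least one segment")
    if grid is None:
        grid = grid_for_apertures(apertures, geometry, resolution_mm, margin_mm, full_field)
    elif abs(grid.resolution_mm - resolution_mm) > 1e-12:
        resolution_mm = grid.resolution_mm

    values = np.zeros((grid.ny, grid.nx), float)
    for ap in apertures:
        mask = rasterize_segment(ap.y1_mm, ap.y2_mm, ap.x1_mm, ap.x2_mm, geometry, grid)
        if mask.any():
            values += ap.mu * mask
    if gantry_deg is None:
        keys = {round(getattr(s, "beam_key", 0.0), 6) for s in segments if hasattr(s, "beam_key")}
        gantry_deg = keys.pop() if len(keys) == 1 else 0.0
    return FluenceGrid(values=values, resolution_mm=grid.resolution_mm,
                       x0_mm=grid.x0_mm, y0_mm=grid.y0_mm, gantry_deg=float(gantry_deg))
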