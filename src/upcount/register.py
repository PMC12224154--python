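"""Co-registration of microscopy spot localizations with ICP-MS count maps.

The two modalities image the same gel area at very different lateral
resolutions (sub-micrometre spots vs 15 μm pixels), with an unknown small
shift and rotation between their coordinate frames and no distinctive
features to anchor on.  Both frames are metrically calibrated, so a rigid
transform (rotation + shift, scale fixed at 1) suffices.  Registration bins
the spots to the map's pixel grid and maximises the normalized
cross-correlation (NCC) over a coarse rotation/shift grid, then refines by
step halving down to 0.1 μm / 0.05°.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mapping import ParticleMap
from .ucm import SpotSet

__all__ = ["RigidTransform2D", "spots_to_density", "register", "overlay_report"]


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation (degrees, about a given centre) followed by a shift (μm)."""

    rotation_deg: float
    shift_x_um: float
    shift_y_um: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, x: np.ndarray, y: np.ndarray,
              center: tuple[float, float] = (0.0, 0.0)) -> tuple[np.ndarray, np.ndarray]:
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        dx, dy = np.asarray(x) - center[0], np.asarray(y) - center[1]
        xr = self.scale * (c * dx - s * dy) + center[0] + self.shift_x_um
        yr = self.scale * (s * dx + c * dy) + center[1] + self.shift_y_um
        return xr, yr

    def inverse(self) -> "RigidTransform2D":
        """Exact inverse about the same centre."""
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        sx, sy = self.shift_x_um, self.shift_y_um
        return RigidTransform2D(-self.rotation_deg,
                                -(c * sx + s * sy) / self.scale,
                                -(-s * sx + c * sy) / self.scale,
                                1.0 / self.scale)


def spots_to_density(spots: SpotSet, pixel_size_um: float | tuple[float, float],
                     shape: tuple[int, int] | None = None,
                     origin_um: tuple[float, float] = (0.0, 0.0),
                     x: np.ndarray | None = None,
                     y: np.ndarray | None = None) -> np.ndarray:
    """Bin spot positions into a 2D count grid at map resolution.

    ``x``/``y`` override the spot coordinates (used to bin transformed
    positions); spots outside the grid are dropped from the grid but not
    from the set.
    """
    px, py = (pixel_size_um if isinstance(pixel_size_um, tuple)
              else (pixel_size_um, pixel_size_um))
    if px <= 0 or py <= 0:
        raise ValueError("pixel sizes must be positive")
    x = spots.x_um if x is None else x
    y = spots.y_um if y is None else y
    if shape is None:
        w, h = spots.source_area_um
        shape = (max(1, int(np.ceil(h / py))), max(1, int(np.ceil(w / px))))
    ny, nx = shape
    grid, _, _ = np.histogram2d(
        np.asarray(y) - origin_um[1], np.asarray(x) - origin_um[0],
        bins=(ny, nx), range=((0, ny * py), (0, nx * px)))
    return grid


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise ValueError("flat grid: correlation undefined")
    return float((a * b).sum() / denom)


def register(spots: SpotSet, pmap: ParticleMap,
             rotation_range_deg: float = 5.0,
             shift_range_um: float | None = None,
             rotation_step_deg: float = 0.5,
             shift_step_um: float | None = None,
             tol_shift_um: float = 0.1, tol_rot_deg: float = 0.05,
             ) -> tuple[RigidTransform2D, float]:
    """Find the rigid transform aligning spot positions to a count map.

    Exhaustive search over rotations (about the map centre) and shifts,
    scoring each candidate by the NCC between the binned, transformed spots
    and the map counts, followed by step-halving refinement around the best
    candidate down to ``tol_shift_um`` / ``tol_rot_deg``.  Returns the best
    transform and its score in [-1, 1].
    """
    if spots.count == 0:
        raise ValueError("empty spot set")
    counts = pmap.counts.astype(float)
    if counts.std() == 0:
        raise ValueError("flat map: correlation undefined")
    ny, nx = counts.shape
    px, py = pmap.pixel_size_x_um, pmap.pixel_size_y_um
    if shift_range_um is None:
        shift_range_um = 3.0 * max(px, py)
    if shift_step_um is None:
        shift_step_um = min(px, py)
    center = (pmap.origin_um[0] + nx * px / 2.0,
              pmap.origin_um[1] + ny * py / 2.0)

    def score(rot: float, sx: float, sy: float) -> float:
        t = RigidTransform2D(rot, sx, sy)
        tx, ty = t.apply(spots.x_um, spots.y_um, center)
        grid = spots_to_density(spots, (px, py), (ny, nx), pmap.origin_um, tx, ty)
        return _ncc(grid, counts)

    best = (-2.0, 0.0, 0.0, 0.0)  # score, rot, sx, sy
    rots = np.arange(-rotation_range_deg, rotation_range_deg + 1e-9,
                     rotation_step_deg)
    shifts = np.arange(-shift_range_um, shift_range_um + 1e-9, shift_step_um)
    for rot in rots:
        for sx in shifts:
            for sy in shifts:
                sc = score(rot, sx, sy)
                if sc > best[0]:
                    best = (sc, rot, sx, sy)

    sc, rot, sx, sy = best
    dr, ds = rotation_step_deg, shift_step_um
    while dr > tol_rot_deg or ds > tol_shift_um:
        dr, ds = max(dr / 2, tol_rot_deg / 2), max(ds / 2, tol_shift_um / 2)
        improved = True
        while improved:
            improved = False
            for r in (rot - dr, rot, rot + dr):
                for x_ in (sx - ds, sx, sx + ds):
                    for y_ in (sy - ds, sy, sy + ds):
                        s_ = score(r, x_, y_)
                        if s_ > sc:
                            sc, rot, sx, sy = s_, r, x_, y_
                            improved = True
    return RigidTransform2D(rot, sx, sy), sc


def overlay_report(spots: SpotSet, pmap: ParticleMap,
                   transform: RigidTransform2D, match_radius_px: int = 0,
                   render: bool = True):
    """Fraction of spots landing on occupied map pixels, plus an overlay.

    A spot is coincident when its transformed position falls in a pixel
    with count >= 1, or within ``match_radius_px`` pixels of one.  Returns
    ``(fraction_coincident, overlay_rgb)`` where the overlay is an RGB
    array (grayscale map with spot markers) or None when ``render=False``.
    """
    if spots.count == 0:
        raise ValueError("empty spot set: coincidence fraction undefined")
    ny, nx = pmap.counts.shape
    px, py = pmap.pixel_size_x_um, pmap.pixel_size_y_um
    center = (pmap.origin_um[0] + nx * px / 2.0,
              pmap.origin_um[1] + ny * py / 2.0)
    tx, ty = transform.apply(spots.x_um, spots.y_um, center)
    occupied = pmap.counts >= 1
    if match_radius_px > 0:
        occupied = ndimage.maximum_filter(occupied.astype(np.uint8),
                                          size=2 * match_radius_px + 1) > 0
    ix = np.floor((tx - pmap.origin_um[0]) / px).astype(int)
    iy = np.floor((ty - pmap.origin_um[1]) / py).astype(int)
    inb = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    hits = np.zeros(spots.count, dtype=bool)
    hits[inb] = occupied[iy[inb], ix[inb]]
    fraction = float(hits.mean())

    overlay = None
    if render:
        import matplotlib
        matplotlib.use("Agg")
        from matplotlib.backends.backend_agg import FigureCanvasAgg
        from matplotlib.figure import Figure
        fig = Figure(figsize=(6, 6), dpi=100)
        FigureCanvasAgg(fig)
        ax = fig.add_subplot(111)
        extent = (pmap.origin_um[0], pmap.origin_um[0] + nx * px,
                  pmap.origin_um[1] + ny * py, pmap.origin_um[1])
        ax.imshow(pmap.counts, cmap="gray", extent=extent, interpolation="nearest")
        ax.scatter(tx, ty, s=12, facecolors="none", edgecolors="lime",
                   linewidths=0.6)
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
        fig.tight_layout()
        fig.canvas.draw()
        overlay = np.asarray(fig.canvas.buffer_rgba())[..., :3].copy()
    return fraction, overlay
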