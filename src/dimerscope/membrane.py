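"""Lipid order-parameter and bilayer-thickness analysis.

The second-rank order parameter S = 1/2 (3 <cos^2 theta> - 1) is computed
from the angle theta between each tail bond vector and the membrane normal
(+z).  Thickness is the gap between the upper- and lower-leaflet headgroup
surfaces.  Both are mapped on a 2-D grid over the membrane plane; cells with
no samples are masked, never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class MembraneError(ValueError):
    pass


@dataclass
class LipidFrame:
    """One stored frame of lipid bead coordinates.

    leaflet: (L,) array of +1 (upper) / -1 (lower).
    head_positions: (L, 3) headgroup bead coordinates, nm.
    tail_positions: (L, T, 3) ordered tail bead coordinates, nm.
    """

    leaflet: np.ndarray
    head_positions: np.ndarray
    tail_positions: np.ndarray
    time_us: float = 0.0

    def __post_init__(self):
        self.leaflet = np.asarray(self.leaflet, dtype=int)
        self.head_positions = np.asarray(self.head_positions, dtype=float)
        self.tail_positions = np.asarray(self.tail_positions, dtype=float)
        if self.tail_positions.shape[1] < 2:
            raise MembraneError("need >= 2 tail beads per lipid")
        if not np.all(
            np.sign(self.head_positions[:, 2]) == np.sign(self.leaflet)
        ):
            raise MembraneError("leaflet labels inconsistent with headgroup z sign")

    @property
    def n_lipids(self) -> int:
        return len(self.leaflet)

    def bond_angles(self) -> np.ndarray:
        """(L, T-1) angle (deg) between each tail bond and the membrane normal."""
        bonds = np.diff(self.tail_positions, axis=1)
        norms = np.linalg.norm(bonds, axis=2)
        cos = bonds[..., 2] / np.where(norms > 0, norms, 1.0)
        return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


@dataclass
class GridMap:
    values: np.ndarray          # (ny, nx), nan where unsampled
    counts: np.ndarray          # samples per cell
    origin: tuple[float, float]  # lower-left corner, nm
    cell: float                  # cell edge, nm
    units: str = ""

    @property
    def mask(self) -> np.ndarray:
        """True where the cell has no samples."""
        return self.counts == 0

    def cell_centers(self):
        ny, nx = self.values.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.cell
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.cell
        return x, y


@dataclass
class OrderParameterMap(GridMap):
    units: str = "dimensionless"


@dataclass
class ThicknessMap(GridMap):
    units: str = "nm"
    bulk: float = 0.0
    deviation: np.ndarray = field(default=None)  # thickness - bulk


def order_parameter(angles_deg) -> float:
    """S = 1/2 (3 <cos^2 theta> - 1); the average runs over all given bonds."""
    a = np.asarray(angles_deg, dtype=float).ravel()
    if a.size == 0:
        raise MembraneError("order parameter undefined for an empty angle list")
    c2 = np.cos(np.deg2rad(a)) ** 2
    return float(0.5 * (3.0 * c2.mean() - 1.0))


def _window_frames(frames, window):
    if window == "second_half":
        return frames[len(frames) // 2:]
    if window == "all":
        return list(frames)
    raise MembraneError(f"unknown window {window!r}")


def _grid_geometry(xy, cell):
    lo = np.floor(xy.min(axis=0) / cell) * cell
    hi = np.ceil(xy.max(axis=0) / cell) * cell
    nx = max(1, int(round((hi[0] - lo[0]) / cell)))
    ny = max(1, int(round((hi[1] - lo[1]) / cell)))
    return (float(lo[0]), float(lo[1])), nx, ny


def _cell_indices(xy, origin, cell, nx, ny):
    ix = np.clip(((xy[:, 0] - origin[0]) / cell).astype(int), 0, nx - 1)
    iy = np.clip(((xy[:, 1] - origin[1]) / cell).astype(int), 0, ny - 1)
    return ix, iy


def order_map(frames, grid_cell: float = 0.4, window: str = "second_half") -> OrderParameterMap:
    """Per-cell order parameter over the selected frames.

    Bonds are pooled per cell, binned by the lipid headgroup in-plane
    position (per-bond pooling, not per-lipid averaging).
    """
    frames = _window_frames(frames, window)
    if not frames:
        raise MembraneError("no lipid frames in the requested window")
    xy_all, cos2_all, nb = [], [], None
    for f in frames:
        ang = f.bond_angles()
        nb = ang.shape[1]
        xy_all.append(f.head_positions[:, :2])
        cos2_all.append(np.cos(np.deg2rad(ang)) ** 2)
    xy = np.vstack(xy_all)
    cos2 = np.vstack(cos2_all)

    origin, nx, ny = _grid_geometry(xy, grid_cell)
    ix, iy = _cell_indices(xy, origin, grid_cell, nx, ny)
    flat = iy * nx + ix
    counts = np.bincount(flat, minlength=nx * ny) * nb
    sums = np.zeros(nx * ny)
    for b in range(nb):
        sums += np.bincount(flat, weights=cos2[:, b], minlength=nx * ny)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = 0.5 * (3.0 * sums / counts - 1.0)
    s[counts == 0] = np.nan
    return OrderParameterMap(
        values=s.reshape(ny, nx),
        counts=counts.reshape(ny, nx),
        origin=origin,
        cell=grid_cell,
    )


def _leaflet_surface(xy, z, origin, cell, nx, ny):
    """Per-cell mean headgroup z; empty cells filled by inverse-distance
    interpolation from the 8-neighborhood, else left nan."""
    ix, iy = _cell_indices(xy, origin, cell, nx, ny)
    flat = iy * nx + ix
    counts = np.bincount(flat, minlength=nx * ny).astype(float)
    sums = np.bincount(flat, weights=z, minlength=nx * ny)
    with np.errstate(invalid="ignore", divide="ignore"):
        surf = (sums / counts).reshape(ny, nx)
    counts = counts.reshape(ny, nx)
    filled = surf.copy()
    empty = np.argwhere(counts == 0)
    for cy, cx in empty:
        ws, vs = [], []
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                yy, xx = cy + dy, cx + dx
                if 0 <= yy < ny and 0 <= xx < nx and counts[yy, xx] > 0:
                    w = 1.0 / np.hypot(dx, dy)
                    ws.append(w)
                    vs.append(surf[yy, xx])
        filled[cy, cx] = np.average(vs, weights=ws) if ws else np.nan
    return filled, counts


def thickness_map(
    frames,
    grid_cell: float = 0.4,
    window: str = "second_half",
    bulk: float | None = None,
) -> ThicknessMap:
    """Upper minus lower leaflet headgroup surface, per cell.

    ``bulk`` defaults to the sample-weighted mean thickness, so the deviation
    map averages to ~0 for balanced perturbations.
    """
    frames = _window_frames(frames, window)
    if not frames:
        raise MembraneError("no lipid frames in the requested window")
    heads = np.vstack([f.head_positions for f in frames])
    leaf = np.concatenate([f.leaflet for f in frames])
    if not (np.any(leaf > 0) and np.any(leaf < 0)):
        raise MembraneError("both leaflets must be sampled")
    origin, nx, ny = _grid_geometry(heads[:, :2], grid_cell)
    up, cu = _leaflet_surface(heads[leaf > 0, :2], heads[leaf > 0, 2],
                              origin, grid_cell, nx, ny)
    lo, cl = _leaflet_surface(heads[leaf < 0, :2], heads[leaf < 0, 2],
                              origin, grid_cell, nx, ny)
    thick = up - lo
    counts = cu + cl
    sampled = ~np.isnan(thick)
    if bulk is None:
        bulk = float(np.average(thick[sampled], weights=counts[sampled]))
    return ThicknessMap(
        values=thick,
        counts=counts,
        origin=origin,
        cell=grid_cell,
        bulk=bulk,
        deviation=thick - bulk,
    )


def _distance_to_footprint(gmap: GridMap, centers, radius: float) -> np.ndarray:
    x, y = gmap.cell_centers()
    xx, yy = np.meshgrid(x, y)
    dist = np.full(xx.shape, np.inf)
    for cx, cy in np.atleast_2d(centers):
        dist = np.minimum(dist, np.hypot(xx - cx, yy - cy) - radius)
    return np.clip(dist, 0.0, None)


def annular_shells(
    gmap: GridMap,
    footprint_centers,
    footprint_radius: float,
    shell_width: float = 0.5,
    use_deviation: bool = False,
) -> pd.DataFrame:
    """Mean map value per distance shell around the protein footprint."""
    dist = _distance_to_footprint(gmap, footprint_centers, footprint_radius)
    vals = gmap.deviation if use_deviation else gmap.values
    ok = ~np.isnan(vals)
    shell = (dist / shell_width).astype(int)
    rows = []
    for s in range(int(shell[ok].max()) + 1):
        sel = ok & (shell == s)
        if not sel.any():
            continue
        rows.append((s, (s + 0.5) * shell_width, float(vals[sel].mean()),
                     int(sel.sum())))
    return pd.DataFrame(rows, columns=["shell", "distance_nm", "mean", "n_cells"])


def interface_mismatch(
    tmap: ThicknessMap,
    com_a,
    com_b,
    sector_radius: float = 2.5,
) -> float:
    """Thickness-mismatch score across the dimer interface.

    The two half-disks of radius ``sector_radius`` around the interface
    midpoint, split by the plane normal to the A->B axis, are averaged over
    the thickness *deviation*; the score is -(mean_A * mean_B), positive when
    the deviations have opposite signs across the interface (the mismatch
    signature) and negative when they match.
    """
    com_a = np.asarray(com_a, float)[:2]
    com_b = np.asarray(com_b, float)[:2]
    axis = com_b - com_a
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise MembraneError("coincident protomer centers: interface axis undefined")
    u = axis / norm
    mid = 0.5 * (com_a + com_b)
    x, y = tmap.cell_centers()
    xx, yy = np.meshgrid(x, y)
    rel = np.stack([xx - mid[0], yy - mid[1]], axis=-1)
    r = np.linalg.norm(rel, axis=-1)
    proj = rel @ u
    dev = tmap.deviation
    ok = (~np.isnan(dev)) & (r <= sector_radius)
    side_a = ok & (proj < 0)
    side_b = ok & (proj > 0)
    if not side_a.any() or not side_b.any():
        raise MembraneError("unsampled interface sector: mismatch undefined")
    return float(-(dev[side_a].mean() * dev[side_b].mean()))
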