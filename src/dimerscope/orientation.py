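"""Relative-orientation coordinates, toroidal density maps and dimer
cluster detection.

beta is the in-plane angle from protomer A's reference vector to the A->B
center-of-mass direction; chi is the angle from protomer B's reference vector
to the B->A direction.  Both live on [0, 360), so the pair (beta, chi) is a
point on a torus and relabeling the protomers swaps the coordinates — the
origin of the diagonal symmetry of converged homodimer orientation plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from dimerscope._geom import (
    circular_mean_deg,
    min_image,
    signed_angle_deg,
    toroidal_dist_deg,
    wrap_deg,
    wrap_signed_deg,
)

DEFAULT_DIMER_CUTOFF = 1.0  # nm, min bead-bead dimer inclusion cutoff;
# generous enough to cover the angular variation of the bead surface radius
DEFAULT_GRID_N = 72         # 5 degree cells
DEFAULT_DIAG_TOL = 15.0
DEFAULT_PAIR_TOL = 20.0
DEFAULT_MIN_ENRICHMENT = 2.0


class OrientationError(ValueError):
    pass


@dataclass(frozen=True)
class OrientationFrame:
    replicate: int
    time_us: float
    beta: float
    chi: float
    com_distance: float
    min_bead_distance: float


def reference_vector(template, pose) -> np.ndarray:
    """Lab-frame in-plane unit reference vector for a protomer pose."""
    from dimerscope._geom import rot2

    v3 = np.zeros(3)
    v3[:2] = template.refvec_body
    lab = rot2(pose[2]) @ v3[:2]
    n = np.linalg.norm(lab)
    if n < 1e-6:
        raise OrientationError("degenerate orientation: reference vector has "
                               "no in-plane component")
    return lab / n


def beta_chi(template, pose_a, pose_b, box=None) -> tuple[float, float]:
    """Relative-orientation angles (deg, in [0, 360)) of a protomer pair."""
    ra = np.asarray(pose_a[:2], float)
    rb = np.asarray(pose_b[:2], float)
    delta = rb - ra
    if box is not None:
        delta = min_image(delta, box)
    d = np.linalg.norm(delta)
    if d < 1e-9:
        raise OrientationError("coincident centers of mass: direction undefined")
    u_ab = delta / d
    beta = signed_angle_deg(reference_vector(template, pose_a), u_ab)
    chi = signed_angle_deg(reference_vector(template, pose_b), -u_ab)
    return float(wrap_deg(beta)), float(wrap_deg(chi))


@dataclass
class OrientationDensity:
    counts: np.ndarray                    # (n, n); rows = beta bins
    bin_centers: np.ndarray               # (n,), deg
    time_us: float
    n_frames: int
    empty: bool = False
    smoothed: np.ndarray | None = None
    frame_points: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def grid_n(self) -> int:
        return self.counts.shape[0]

    @property
    def enrichment(self) -> np.ndarray:
        """counts / uniform expectation; mean over cells is exactly 1."""
        if self.n_frames == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts * (self.counts.size / self.n_frames)

    @property
    def smoothed_enrichment(self) -> np.ndarray:
        if self.smoothed is None or self.n_frames == 0:
            return self.enrichment
        return self.smoothed * (self.counts.size / self.n_frames)


def select_frames_at(frames: pd.DataFrame, at_time: float,
                     time_tol: float | None = None) -> pd.DataFrame:
    """Rows of the frame table at the stored time nearest ``at_time``."""
    times = np.sort(frames["time_us"].unique())
    idx = int(np.argmin(np.abs(times - at_time)))
    t = times[idx]
    if time_tol is not None and abs(t - at_time) > time_tol:
        raise OrientationError(f"no frames within {time_tol} us of t={at_time}")
    return frames[frames["time_us"] == t]


def orientation_density(
    frames: pd.DataFrame,
    at_time: float,
    dimer_cutoff: float = DEFAULT_DIMER_CUTOFF,
    grid_n: int = DEFAULT_GRID_N,
    bandwidth_deg: float | None = None,
) -> OrientationDensity:
    """Toroidal 2-D histogram of (beta, chi) over dimer frames at one time.

    Only frames with min bead distance below ``dimer_cutoff`` contribute.
    """
    if dimer_cutoff <= 0:
        raise OrientationError("dimer_cutoff must be positive")
    at = select_frames_at(frames, at_time)
    sel = at[at["min_bead_distance"] < dimer_cutoff]
    cell = 360.0 / grid_n
    centers = (np.arange(grid_n) + 0.5) * cell
    counts = np.zeros((grid_n, grid_n))
    if len(sel):
        ib = (wrap_deg(sel["beta"].to_numpy()) / cell).astype(int) % grid_n
        ic = (wrap_deg(sel["chi"].to_numpy()) / cell).astype(int) % grid_n
        np.add.at(counts, (ib, ic), 1.0)
    smoothed = None
    if bandwidth_deg is not None and len(sel):
        smoothed = ndimage.gaussian_filter(counts, sigma=bandwidth_deg / cell,
                                           mode="wrap")
    density = OrientationDensity(
        counts=counts,
        bin_centers=centers,
        time_us=float(at["time_us"].iloc[0]),
        n_frames=int(len(sel)),
        empty=len(sel) == 0,
        smoothed=smoothed,
        frame_points=sel[["replicate", "beta", "chi"]].reset_index(drop=True),
    )
    return density


@dataclass
class Cluster:
    id: int
    center_beta: float
    center_chi: float
    members: list[int]            # replicate ids
    population: int
    symmetry_class: str           # "symmetric" | "asymmetric"
    partner: int | None = None


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    diag_tol: float = DEFAULT_DIAG_TOL
    pair_tol: float = DEFAULT_PAIR_TOL

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self):
        return len(self.clusters)

    def n_merged(self) -> int:
        """Cluster count with each symmetry-related off-diagonal pair merged."""
        n = 0
        seen = set()
        for c in self.clusters:
            if c.id in seen:
                continue
            seen.add(c.id)
            if c.partner is not None:
                seen.add(c.partner)
            n += 1
        return n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.id, c.center_beta, c.center_chi, c.population,
              c.symmetry_class, c.partner) for c in self.clusters],
            columns=["id", "center_beta_deg", "center_chi_deg", "population",
                     "symmetry_class", "partner"],
        )


def _toroidal_components(mask: np.ndarray) -> np.ndarray:
    """Connected-component labels with wrap-around (toroidal) adjacency."""
    labels, n = ndimage.label(mask)
    if n == 0:
        return labels
    parent = list(range(n + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    nb, nc = mask.shape
    for j in range(nc):
        a, b = labels[0, j], labels[-1, j]
        if a and b:
            union(a, b)
    for i in range(nb):
        a, b = labels[i, 0], labels[i, -1]
        if a and b:
            union(a, b)
    out = labels.copy()
    for lbl in range(1, n + 1):
        out[labels == lbl] = find(lbl)
    return out


def detect_clusters(
    density: OrientationDensity,
    min_enrichment: float = DEFAULT_MIN_ENRICHMENT,
    min_population: int = 3,
    diag_tol: float = DEFAULT_DIAG_TOL,
    pair_tol: float = DEFAULT_PAIR_TOL,
) -> ClusterSet:
    """Connected high-enrichment regions of the orientation density.

    Components are found on the smoothed enrichment when available (raw
    otherwise) with toroidal adjacency; centers are count-weighted circular
    means.  Off-diagonal clusters are paired with their swapped-coordinate
    twin when one exists within ``pair_tol``.
    """
    if density.empty:
        return ClusterSet([], diag_tol, pair_tol)
    enr = density.smoothed_enrichment
    mask = enr >= min_enrichment
    labels = _toroidal_components(mask)
    clusters: list[Cluster] = []
    pts = density.frame_points
    cell = 360.0 / density.grid_n
    if pts is not None and len(pts):
        pb = (wrap_deg(pts["beta"].to_numpy()) / cell).astype(int) % density.grid_n
        pc = (wrap_deg(pts["chi"].to_numpy()) / cell).astype(int) % density.grid_n
    for lbl in np.unique(labels):
        if lbl == 0:
            continue
        cells = labels == lbl
        w = density.counts[cells]
        ib, ic = np.nonzero(cells)
        if w.sum() <= 0:
            continue
        cb = circular_mean_deg(density.bin_centers[ib], weights=w)
        cc = circular_mean_deg(density.bin_centers[ic], weights=w)
        members: list[int] = []
        if pts is not None and len(pts):
            in_cluster = cells[pb, pc]
            members = sorted(pts["replicate"].to_numpy()[in_cluster].tolist())
        population = len(members)
        if population < min_population:
            continue
        sym = ("symmetric"
               if abs(wrap_signed_deg(cb - cc)) <= diag_tol else "asymmetric")
        clusters.append(Cluster(
            id=len(clusters), center_beta=cb, center_chi=cc,
            members=members, population=population, symmetry_class=sym,
        ))

    for c in clusters:
        if c.symmetry_class != "asymmetric" or c.partner is not None:
            continue
        swapped = (c.center_chi, c.center_beta)
        best, best_d = None, pair_tol
        for other in clusters:
            if other.id == c.id or other.symmetry_class != "asymmetric":
                continue
            d = toroidal_dist_deg((other.center_beta, other.center_chi), swapped)
            if d <= best_d:
                best, best_d = other, d
        if best is not None:
            c.partner = best.id
            best.partner = c.id
    return ClusterSet(clusters, diag_tol, pair_tol)


def symmetry_ratio(clusters: ClusterSet) -> float:
    """Population above the diagonal over population below, off-diagonal
    clusters only.  Converges to 1 for a fully symmetric ensemble."""
    n_above = n_below = 0
    for c in clusters:
        if c.symmetry_class != "asymmetric":
            continue
        if wrap_signed_deg(c.center_chi - c.center_beta) > 0:
            n_above += c.population
        else:
            n_below += c.population
    if n_above == 0 and n_below == 0:
        raise OrientationError("no off-diagonal clusters: ratio undefined")
    if n_below == 0:
        warnings.warn("no members below the diagonal: infinite symmetry ratio",
                      stacklevel=2)
        return float("inf")
    return n_above / n_below


def assign_replicates(
    clusters: ClusterSet,
    frames: pd.DataFrame,
    at_time: float,
    angular_radius: float = 30.0,
    dimer_cutoff: float = DEFAULT_DIMER_CUTOFF,
) -> dict[int, int | None]:
    """Nearest-cluster assignment of each replicate at one time.

    Monomeric replicates (min bead distance >= cutoff) and replicates farther
    than ``angular_radius`` from every center stay unassigned (None).  Ties
    go to the lower cluster id.
    """
    at = select_frames_at(frames, at_time)
    centers = np.array([(c.center_beta, c.center_chi) for c in clusters])
    out: dict[int, int | None] = {}
    for _, row in at.iterrows():
        rep = int(row["replicate"])
        if row["min_bead_distance"] >= dimer_cutoff or len(centers) == 0:
            out[rep] = None
            continue
        d = toroidal_dist_deg(np.array([row["beta"], row["chi"]]), centers)
        j = int(np.argmin(d))  # argmin returns the first (lowest id) on ties
        out[rep] = clusters.clusters[j].id if d[j] <= angular_radius else None
    return out
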