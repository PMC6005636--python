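"""Model bilayer generator with planted protein-induced perturbations.

Lipids sit on a jittered grid in each leaflet.  Tail tilt encodes a target
order parameter that can deviate per annular shell around the protein, and
the local thickness can deviate in angular sectors of the protomer surface;
both perturbations decay linearly to zero at a stated annulus radius, so the
downstream maps have exact planted answers to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dimerscope.membrane import LipidFrame


class BilayerConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ThicknessSector:
    """Signed thickness perturbation on an angular sector of one protomer."""
    center: tuple[float, float]   # protomer COM, nm
    angle_start: float            # deg, sector in lab frame
    angle_end: float              # deg
    delta_nm: float               # signed thickness change at the footprint edge


@dataclass
class MembraneModel:
    lipids_per_leaflet: int = 180
    bulk_thickness: float = 4.0          # nm; headgroups at +-2.0
    tail_beads_per_lipid: int = 4
    bond_length: float = 0.47            # nm
    bulk_tilt_deg: float = 25.0          # bulk tail tilt from the normal
    thickness_sectors: list[ThicknessSector] = field(default_factory=list)
    order_shell_deltas: list[float] = field(default_factory=list)  # dS per shell
    shell_width: float = 0.5             # nm
    annulus_radius: float = 2.0          # nm; perturbations are zero beyond

    def __post_init__(self):
        if self.tail_beads_per_lipid < 3:
            raise BilayerConfigError("need >= 3 tail beads per lipid")
        if not 172 <= self.lipids_per_leaflet <= 190:
            if self.lipids_per_leaflet < 4:
                raise BilayerConfigError("too few lipids per leaflet")

    @property
    def headgroup_z(self) -> float:
        return self.bulk_thickness / 2.0

    @property
    def bulk_order(self) -> float:
        c2 = np.cos(np.deg2rad(self.bulk_tilt_deg)) ** 2
        return 0.5 * (3.0 * c2 - 1.0)


def _tilt_for_order(s: float) -> float:
    """Tail tilt (deg) whose bonds give order parameter ``s`` exactly."""
    c2 = (2.0 * s + 1.0) / 3.0
    if not 0.0 <= c2 <= 1.0:
        raise BilayerConfigError(f"order parameter {s} out of [-0.5, 1]")
    return float(np.degrees(np.arccos(np.sqrt(c2))))


def _sector_contains(sector: ThicknessSector, angles_deg: np.ndarray) -> np.ndarray:
    a0 = sector.angle_start % 360.0
    a1 = sector.angle_end % 360.0
    a = angles_deg % 360.0
    if a0 <= a1:
        return (a >= a0) & (a < a1)
    return (a >= a0) | (a < a1)


def _local_fields(model, xy, protein_centers, footprint_radius):
    """(thickness, order) at each lipid position, with planted perturbations."""
    n = len(xy)
    thickness = np.full(n, model.bulk_thickness)
    order = np.full(n, model.bulk_order)
    if protein_centers is None or len(protein_centers) == 0:
        return thickness, order
    centers = np.atleast_2d(protein_centers)
    dist = np.min(
        np.linalg.norm(xy[:, None, :] - centers[None, :, :], axis=2), axis=1
    ) - footprint_radius
    dist = np.clip(dist, 0.0, None)
    decay = np.clip(1.0 - dist / model.annulus_radius, 0.0, None)

    for sec in model.thickness_sectors:
        c = np.asarray(sec.center, float)
        rel = xy - c
        ang = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
        in_sector = _sector_contains(sec, ang)
        # decay is anchored to this sector's own protomer so neighbouring
        # protomers' sectors never bleed into each other
        d_sec = np.clip(np.linalg.norm(rel, axis=1) - footprint_radius,
                        0.0, None)
        decay_sec = np.clip(1.0 - d_sec / model.annulus_radius, 0.0, None)
        thickness = thickness + np.where(in_sector,
                                         sec.delta_nm * decay_sec, 0.0)

    if model.order_shell_deltas:
        shell = (dist / model.shell_width).astype(int)
        deltas = np.asarray(model.order_shell_deltas, float)
        in_range = shell < len(deltas)
        order = order + np.where(in_range, deltas[np.clip(shell, 0, len(deltas) - 1)], 0.0)
    return thickness, order


def generate_lipid_frames(
    model: MembraneModel,
    box: tuple[float, float],
    protein_centers=None,
    footprint_radius: float = 2.3,
    n_frames: int = 1,
    seed: int = 0,
    position_jitter: float = 0.05,
) -> list[LipidFrame]:
    """Build ``n_frames`` lipid frames with exactly ``lipids_per_leaflet``
    lipids in each leaflet, excluding the protein footprint."""
    rng = np.random.default_rng(seed)
    lx, ly = box
    n_target = model.lipids_per_leaflet
    # oversampled grid, then trim to the requested count
    n_side = int(np.ceil(np.sqrt(n_target * 1.6)))
    gx = (np.arange(n_side) + 0.5) * lx / n_side
    gy = (np.arange(n_side) + 0.5) * ly / n_side
    base = np.array([(x, y) for y in gy for x in gx])
    if protein_centers is not None and len(protein_centers) > 0:
        centers = np.atleast_2d(protein_centers)
        d = np.min(np.linalg.norm(base[:, None, :] - centers[None, :, :], axis=2),
                   axis=1)
        base = base[d > footprint_radius]
    if len(base) < n_target:
        raise BilayerConfigError(
            f"box too small: only {len(base)} lipid sites for {n_target} lipids"
        )

    frames = []
    tb = model.tail_beads_per_lipid
    for fi in range(n_frames):
        frame_lipids = []
        for leaflet in (+1, -1):
            sel = rng.choice(len(base), size=n_target, replace=False)
            xy = base[sel] + rng.normal(0.0, position_jitter, (n_target, 2))
            thickness, order = _local_fields(model, xy, protein_centers,
                                             footprint_radius)
            head_z = leaflet * thickness / 2.0
            tilt = np.array([_tilt_for_order(s) for s in order])
            azimuth = rng.uniform(0.0, 2.0 * np.pi, n_target)
            # tail bonds descend from the headgroup toward the midplane at
            # the planted tilt; every bond of a lipid shares the same angle
            st = np.sin(np.deg2rad(tilt))
            ct = np.cos(np.deg2rad(tilt))
            step = model.bond_length * np.stack(
                [st * np.cos(azimuth), st * np.sin(azimuth),
                 -leaflet * ct], axis=1
            )
            heads = np.column_stack([xy, head_z])
            tails = (heads[:, None, :]
                     + step[:, None, :] * np.arange(1, tb + 1)[None, :, None])
            frame_lipids.append((np.full(n_target, leaflet), heads, tails))
        leaf = np.concatenate([f[0] for f in frame_lipids])
        heads = np.vstack([f[1] for f in frame_lipids])
        tails = np.vstack([f[2] for f in frame_lipids])
        frames.append(LipidFrame(leaflet=leaf, head_positions=heads,
                                 tail_positions=tails, time_us=float(fi)))
    return frames
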