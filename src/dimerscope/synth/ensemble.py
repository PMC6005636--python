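"""Rigid-body two-protomer ensemble generator.

Each replicate evolves two rigid protomers by overdamped in-plane Brownian
dynamics (x, y translation + rotation about the membrane normal) in a
periodic box, with forces and torques from an
:class:`~dimerscope.synth.imap.InteractionMap`.  Replicate ``r`` is fully
reproducible from ``(seed, r)`` via spawned RNG streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from dimerscope._geom import min_image, wrap_deg
from dimerscope.synth.imap import KB_KJMOL, InteractionMap
from dimerscope.synth.template import ProtomerTemplate

logger = logging.getLogger(__name__)

_MAX_PLACEMENT_ATTEMPTS = 100


class PlacementError(RuntimeError):
    """Initial placement kept overlapping after the retry cap."""


@dataclass
class EnsembleConfig:
    """Run parameters for the Brownian-dynamics ensemble.

    Diffusion constants are per microsecond-equivalent; the integrator scales
    them by the timestep, so statistics are timestep-robust.
    """

    n_replicates: int = 512
    duration_us: float = 2.0
    timestep_us: float = 1e-3
    d_trans: float = 4.0        # nm^2 / us
    d_rot: float = 8000.0       # deg^2 / us
    box: tuple[float, float] = (17.0, 17.0)
    start_com_separation: float = 8.4  # nm
    frame_stride_us: float = 0.02
    temperature: float = 310.0  # K
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.duration_us < 0 or self.timestep_us <= 0:
            raise ValueError("invalid duration/timestep")
        if self.start_com_separation > min(self.box) / 2.0 + 1e-9:
            raise ValueError(
                "start_com_separation exceeds the minimum-image half box"
            )

    @property
    def kt(self) -> float:
        return KB_KJMOL * self.temperature

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_us / self.timestep_us))


@dataclass
class EnsembleResult:
    """Stored-frame output of :func:`generate_daft_ensemble`."""

    template: ProtomerTemplate
    imap: InteractionMap
    config: EnsembleConfig
    times: np.ndarray                 # (F,) us
    poses: np.ndarray                 # (R, F, 6): xA yA thA xB yB thB
    frames: pd.DataFrame = field(repr=False)  # replicate,time_us,beta,chi,...
    energies: pd.DataFrame = field(repr=False)

    @property
    def n_replicates(self) -> int:
        return self.poses.shape[0]

    @property
    def n_frames(self) -> int:
        return self.poses.shape[1]

    def bead_coords(self, replicate: int, frame: int):
        """(coords_A, coords_B) in nm for one stored frame.

        Protomer B is placed at the minimum-image position relative to A, so
        inter-protomer distances are correct in the periodic box.
        """
        xa, ya, tha, xb, yb, thb = self.poses[replicate, frame]
        box = np.asarray(self.config.box)
        delta = min_image(np.array([xb - xa, yb - ya]), box)
        a = self.template.transform((xa, ya, tha))
        b = self.template.transform((xa + delta[0], ya + delta[1], thb))
        return a, b

    def frame_index_at(self, time_us: float) -> int:
        idx = int(np.argmin(np.abs(self.times - time_us)))
        if abs(self.times[idx] - time_us) > self.config.frame_stride_us / 2 + 1e-9:
            raise ValueError(f"no stored frame near t={time_us} us")
        return idx


def _relative_coords(state: np.ndarray, refvec_angle: float, box: np.ndarray):
    """(beta, chi, d, delta) from pose state array (R, 6)."""
    delta = min_image(state[:, 3:5] - state[:, 0:2], box)
    d = np.linalg.norm(delta, axis=1)
    phi = np.degrees(np.arctan2(delta[:, 1], delta[:, 0]))
    beta = wrap_deg(phi - state[:, 2] - refvec_angle)
    chi = wrap_deg(phi + 180.0 - state[:, 5] - refvec_angle)
    return beta, chi, d, delta


def _initial_states(template, cfg, rngs) -> np.ndarray:
    """Random initial poses; retries orientations that start in bead overlap."""
    state = np.empty((cfg.n_replicates, 6))
    cx, cy = cfg.box[0] / 2.0, cfg.box[1] / 2.0
    for r, rng in enumerate(rngs):
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            direction = rng.uniform(0.0, 2.0 * np.pi)
            half = 0.5 * cfg.start_com_separation
            xa = cx - half * np.cos(direction)
            ya = cy - half * np.sin(direction)
            xb = cx + half * np.cos(direction)
            yb = cy + half * np.sin(direction)
            tha, thb = rng.uniform(0.0, 360.0, 2)
            a = template.transform((xa, ya, tha))
            b = template.transform((xb, yb, thb))
            if cdist(a, b).min() > 2.0:
                state[r] = (xa, ya, tha, xb, yb, thb)
                break
            logger.info("replicate %d: initial overlap, retry %d", r, attempt + 1)
        else:
            raise PlacementError(f"replicate {r}: no valid placement in "
                                 f"{_MAX_PLACEMENT_ATTEMPTS} attempts")
    return state


def generate_daft_ensemble(
    template: ProtomerTemplate,
    imap: InteractionMap,
    cfg: EnsembleConfig,
) -> EnsembleResult:
    """Run the full replicate ensemble and return stored frames + energies.

    The per-frame interaction energy in the returned table is the
    InteractionMap potential evaluated at that frame's (beta, chi, distance),
    exactly.
    """
    box = np.asarray(cfg.box, dtype=float)
    refvec_angle = float(
        np.degrees(np.arctan2(template.refvec_body[1], template.refvec_body[0]))
    )
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(cfg.seed).spawn(cfg.n_replicates)]
    state = _initial_states(template, cfg, rngs)

    n_steps = cfg.n_steps
    stride = max(1, int(round(cfg.frame_stride_us / cfg.timestep_us)))
    store_steps = np.arange(0, n_steps + 1, stride)
    if store_steps[-1] != n_steps:
        store_steps = np.append(store_steps, n_steps)
    times = store_steps * cfg.timestep_us

    # per-replicate noise streams keep (seed, r) reproducibility while the
    # integrator itself is vectorized over replicates
    noise = (np.stack([rng.standard_normal((n_steps, 6)) for rng in rngs])
             if n_steps > 0 else np.zeros((cfg.n_replicates, 0, 6)))

    dt = cfg.timestep_us
    kt = cfg.kt
    sig_t = np.sqrt(2.0 * cfg.d_trans * dt)
    sig_r = np.sqrt(2.0 * cfg.d_rot * dt)
    mob_t = cfg.d_trans * dt / kt
    mob_r = cfg.d_rot * dt / kt
    rad2deg = 180.0 / np.pi

    poses = np.empty((cfg.n_replicates, len(store_steps), 6))
    store_idx = {s: i for i, s in enumerate(store_steps)}
    poses[:, 0] = state

    for step in range(n_steps):
        beta, chi, d, delta = _relative_coords(state, refvec_angle, box)
        gb, gc, gd = imap.gradients(beta, chi, d)
        d_safe = np.maximum(d, 1e-9)
        # dphi/dxB etc. in deg/nm; beta and chi share the COM-direction term
        dphi_dx = -rad2deg * delta[:, 1] / d_safe**2
        dphi_dy = rad2deg * delta[:, 0] / d_safe**2
        g_ang = gb + gc
        fx_b = -(g_ang * dphi_dx + gd * delta[:, 0] / d_safe)
        fy_b = -(g_ang * dphi_dy + gd * delta[:, 1] / d_safe)
        tau_a = -gb   # dU/dthetaA = -dU/dbeta
        tau_b = -gc

        eta = noise[:, step, :]
        state[:, 0] += -mob_t * fx_b + sig_t * eta[:, 0]
        state[:, 1] += -mob_t * fy_b + sig_t * eta[:, 1]
        state[:, 2] += -mob_r * tau_a + sig_r * eta[:, 2]
        state[:, 3] += mob_t * fx_b + sig_t * eta[:, 3]
        state[:, 4] += mob_t * fy_b + sig_t * eta[:, 4]
        state[:, 5] += -mob_r * tau_b + sig_r * eta[:, 5]
        state[:, 0] %= box[0]
        state[:, 1] %= box[1]
        state[:, 3] %= box[0]
        state[:, 4] %= box[1]
        state[:, 2] = wrap_deg(state[:, 2])
        state[:, 5] = wrap_deg(state[:, 5])

        if (step + 1) in store_idx:
            poses[:, store_idx[step + 1]] = state

    # frame tables: orientation coordinates, distances and exact energies
    records = []
    for fi in range(len(store_steps)):
        st = poses[:, fi, :]
        beta, chi, d, delta = _relative_coords(st, refvec_angle, box)
        energy = np.asarray(imap.energy(beta, chi, d))
        for r in range(cfg.n_replicates):
            a = template.transform((st[r, 0], st[r, 1], st[r, 2]))
            b = template.transform(
                (st[r, 0] + delta[r, 0], st[r, 1] + delta[r, 1], st[r, 5])
            )
            mind = cdist(a, b).min()
            records.append((r, times[fi], beta[r], chi[r], d[r], mind, energy[r]))

    frames = pd.DataFrame.from_records(
        records,
        columns=["replicate", "time_us", "beta", "chi",
                 "com_distance", "min_bead_distance", "E_interaction_kJmol"],
    )
    energies = frames[["replicate", "time_us", "E_interaction_kJmol"]].copy()
    return EnsembleResult(
        template=template, imap=imap, config=cfg,
        times=times, poses=poses, frames=frames, energies=energies,
    )
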