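"""Trajectory-file round trip for two-protomer ensembles and lipid frames.

``write_ensemble_trajectories`` stores one multi-model PDB (or per-frame GRO
series) per replicate; ``FileEnsemble`` reads them back and presents the same
interface the in-memory ensemble offers (times, bead_coords, frames table),
so every analysis stage runs identically on files and on fresh simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from dimerscope._geom import signed_angle_deg, wrap_deg
from dimerscope.io.structures import Structure, read_structure, write_structure
from dimerscope.membrane import LipidFrame


def ensemble_frame_structure(ensemble, replicate: int) -> Structure:
    """All stored frames of one replicate as a multi-model Structure."""
    res = ensemble.template.residue_index
    n = len(res)
    coords = np.empty((ensemble.n_frames, 2 * n, 3))
    for fi in range(ensemble.n_frames):
        a, b = ensemble.bead_coords(replicate, fi)
        coords[fi, :n] = a
        coords[fi, n:] = b
    return Structure(
        chains=np.array(["A"] * n + ["B"] * n),
        residues=np.concatenate([res, res]),
        atom_names=np.array(["BB"] * (2 * n)),
        coords=coords,
        box=(ensemble.config.box[0], ensemble.config.box[1], 10.0),
        times_us=np.asarray(ensemble.times, dtype=float),
        title=f"replicate {replicate}",
    )


def write_ensemble_trajectories(ensemble, directory, fmt: str = "pdb") -> list[Path]:
    """One multi-model PDB per replicate, or one GRO per frame per replicate."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for r in range(ensemble.n_replicates):
        s = ensemble_frame_structure(ensemble, r)
        if fmt == "pdb":
            paths.append(write_structure(directory / f"rep_{r:04d}.pdb", s))
        elif fmt == "gro":
            sub = directory / f"rep_{r:04d}"
            sub.mkdir(exist_ok=True)
            for fi in range(s.n_models):
                frame = Structure(
                    chains=s.chains, residues=s.residues,
                    atom_names=s.atom_names, coords=s.coords[fi],
                    box=s.box, times_us=s.times_us[fi:fi + 1], title=s.title,
                )
                paths.append(write_structure(sub / f"frame_{fi:04d}.gro", frame))
        else:
            raise ValueError(f"unsupported trajectory format {fmt!r}")
    return paths


@dataclass
class FileEnsemble:
    """Ensemble adapter over trajectory files; mirrors EnsembleResult's
    analysis-facing surface."""

    template: object
    times: np.ndarray
    structures: list[Structure]
    config: object = None

    @property
    def n_replicates(self) -> int:
        return len(self.structures)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def bead_coords(self, replicate: int, frame: int):
        s = self.structures[replicate]
        ia = s.chain_indices("A")
        ib = s.chain_indices("B")
        return s.coords[frame, ia], s.coords[frame, ib]

    @property
    def frames(self) -> pd.DataFrame:
        if not hasattr(self, "_frames"):
            self._frames = _frames_table(self)
        return self._frames


def _chain_refvec(coords_chain: np.ndarray, refvec_beads) -> np.ndarray:
    i, j = refvec_beads
    v = coords_chain[j, :2] - coords_chain[i, :2]
    n = np.linalg.norm(v)
    if n < 1e-6:
        raise ValueError("degenerate reference vector in trajectory frame")
    return v / n


def _frames_table(ens: FileEnsemble) -> pd.DataFrame:
    rows = []
    rv = ens.template.refvec_beads
    for r in range(ens.n_replicates):
        for fi in range(ens.n_frames):
            a, b = ens.bead_coords(r, fi)
            com_a = a[:, :2].mean(axis=0)
            com_b = b[:, :2].mean(axis=0)
            delta = com_b - com_a
            d = float(np.linalg.norm(delta))
            u = delta / d
            beta = wrap_deg(signed_angle_deg(_chain_refvec(a, rv), u))
            chi = wrap_deg(signed_angle_deg(_chain_refvec(b, rv), -u))
            rows.append((r, float(ens.times[fi]), float(beta), float(chi),
                         d, float(cdist(a, b).min())))
    return pd.DataFrame(rows, columns=["replicate", "time_us", "beta", "chi",
                                       "com_distance", "min_bead_distance"])


def load_file_ensemble(traj_dir, template) -> FileEnsemble:
    """Read every rep_*.pdb (or rep_*/ GRO series) under ``traj_dir``."""
    traj_dir = Path(traj_dir)
    structures = []
    pdbs = sorted(traj_dir.glob("rep_*.pdb"))
    if pdbs:
        structures = [read_structure(p) for p in pdbs]
    else:
        for sub in sorted(d for d in traj_dir.glob("rep_*") if d.is_dir()):
            frames = [read_structure(p) for p in sorted(sub.glob("frame_*.gro"))]
            if not frames:
                continue
            coords = np.stack([f.coords[0] for f in frames])
            times = np.array([f.times_us[0] if f.times_us is not None else i
                              for i, f in enumerate(frames)])
            structures.append(Structure(
                chains=frames[0].chains, residues=frames[0].residues,
                atom_names=frames[0].atom_names, coords=coords,
                box=frames[0].box, times_us=times,
            ))
    if not structures:
        raise FileNotFoundError(f"no trajectories under {traj_dir}")
    times = structures[0].times_us
    if times is None:
        times = np.arange(structures[0].n_models, dtype=float)
    return FileEnsemble(template=template, times=np.asarray(times, float),
                        structures=structures)


# --- lipid frames ------------------------------------------------------

def lipid_frame_to_structure(frame: LipidFrame, box=(20.0, 20.0, 10.0)) -> Structure:
    """Lipids on chain L: headgroup bead HD then tail beads T1..Tn per lipid."""
    n_l, n_t = frame.tail_positions.shape[:2]
    per = 1 + n_t
    chains = np.array(["L"] * (n_l * per))
    residues = np.repeat(np.arange(1, n_l + 1), per)
    names = np.tile(["HD"] + [f"T{k+1}" for k in range(n_t)], n_l)
    coords = np.empty((n_l * per, 3))
    coords[0::per] = frame.head_positions
    for k in range(n_t):
        coords[k + 1::per] = frame.tail_positions[:, k]
    return Structure(chains=chains, residues=residues, atom_names=names,
                     coords=coords, box=box,
                     times_us=np.array([frame.time_us]), title="lipid frame")


def structure_to_lipid_frame(s: Structure, model: int = 0) -> LipidFrame:
    il = s.chain_indices("L")
    if len(il) == 0:
        raise ValueError("no chain-L lipid beads in structure")
    res = s.residues[il]
    names = s.atom_names[il]
    coords = s.coords[model, il]
    heads, tails, leaflets = [], [], []
    for resid in np.unique(res):
        sel = res == resid
        c = coords[sel]
        nm = names[sel]
        head = c[nm == "HD"]
        if len(head) != 1:
            raise ValueError(f"lipid residue {resid}: expected one HD bead")
        order = np.argsort([int(n[1:]) for n in nm[nm != "HD"]])
        heads.append(head[0])
        tails.append(c[nm != "HD"][order])
        leaflets.append(1 if head[0][2] > 0 else -1)
    t = s.times_us[model] if s.times_us is not None else 0.0
    return LipidFrame(leaflet=np.array(leaflets),
                      head_positions=np.array(heads),
                      tail_positions=np.array(tails), time_us=float(t))
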