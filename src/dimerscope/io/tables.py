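"""CSV / text table writers and readers for every pipeline artifact.

All numeric columns carry units in their headers and every file written here
is re-readable by the functions in this module.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dimerscope.synth.umbrella import UmbrellaWindow


# --- energies ---------------------------------------------------------

def write_energy_table(path, energies: pd.DataFrame) -> Path:
    path = Path(path)
    energies.to_csv(path, index=False,
                    columns=["replicate", "time_us", "E_interaction_kJmol"])
    return path


def read_energy_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"replicate", "time_us", "E_interaction_kJmol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# --- umbrella windows -------------------------------------------------

def write_windows(directory, windows: list[UmbrellaWindow],
                  dt_ps: float = 1.0) -> Path:
    """One two-column (time, xi nm) text file per window + a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(windows):
        fname = f"window_{i:03d}.txt"
        t = np.arange(len(w.samples)) * dt_ps
        np.savetxt(directory / fname, np.column_stack([t, w.samples]),
                   fmt="%.6f", header="time_ps xi_nm")
        rows.append((fname, w.center, w.k_bias, len(w.samples),
                     w.equilibration_fraction))
    manifest = pd.DataFrame(rows, columns=[
        "file", "center_nm", "k_kJmol_nm2", "n_samples", "equil_fraction"])
    manifest.to_csv(directory / "windows.csv", index=False)
    return directory / "windows.csv"


def read_windows(manifest_path) -> list[UmbrellaWindow]:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    windows = []
    for _, row in manifest.iterrows():
        data = np.loadtxt(manifest_path.parent / row["file"], ndmin=2)
        windows.append(UmbrellaWindow(
            center=float(row["center_nm"]),
            k_bias=float(row["k_kJmol_nm2"]),
            samples=data[:, 1] if data.size else np.empty(0),
            equilibration_fraction=float(row.get("equil_fraction", 0.0)),
        ))
    return windows


# --- orientation artifacts --------------------------------------------

def write_density(path, density) -> Path:
    """Density counts as a CSV matrix; header row/column are bin centers."""
    path = Path(path)
    df = pd.DataFrame(density.counts,
                      index=np.round(density.bin_centers, 4),
                      columns=np.round(density.bin_centers, 4))
    df.index.name = "beta_deg\\chi_deg"
    df.to_csv(path)
    return path


def write_cluster_table(path, clusters) -> Path:
    path = Path(path)
    clusters.to_frame().to_csv(path, index=False)
    return path


# --- contacts ----------------------------------------------------------

def write_contact_map(path_dense, cmap, path_sparse=None,
                      min_count: int = 0) -> Path:
    path_dense = Path(path_dense)
    cmap.to_frame().to_csv(path_dense, index_label="res_i\\res_j")
    if path_sparse is not None:
        ii, jj = np.nonzero(cmap.counts > min_count)
        sparse = pd.DataFrame({
            "res_i": cmap.residues[ii],
            "res_j": cmap.residues[jj],
            "count": cmap.counts[ii, jj],
        })
        sparse.to_csv(Path(path_sparse), index=False)
    return path_dense


# --- membrane maps ------------------------------------------------------

def write_grid_map(path_csv, gmap) -> Path:
    """Map values as CSV matrix plus a JSON sidecar with grid geometry."""
    path_csv = Path(path_csv)
    np.savetxt(path_csv, gmap.values, delimiter=",", fmt="%.6f")
    sidecar = path_csv.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "origin_nm": list(gmap.origin),
        "cell_nm": gmap.cell,
        "units": gmap.units,
        "shape": list(gmap.values.shape),
    }, indent=2))
    return path_csv


# --- PMF profile ---------------------------------------------------------

def write_profile(path, profile) -> Path:
    path = Path(path)
    df = profile.to_frame()
    df.to_csv(path, index=False)
    return path


# --- protomer template ----------------------------------------------------

def write_template_json(path, template) -> Path:
    path = Path(path)
    payload = {
        "bead_positions_nm": template.bead_positions.tolist(),
        "residue_index": template.residue_index.tolist(),
        "helix_of_residue": {str(k): v for k, v in template.helix_of_residue.items()},
        "domain_of_helix": dict(template.domain_of_helix),
        "refvec_beads": list(template.refvec_beads),
    }
    path.write_text(json.dumps(payload))
    return path


def read_template_json(path):
    from dimerscope.synth.template import ProtomerTemplate

    payload = json.loads(Path(path).read_text())
    return ProtomerTemplate(
        bead_positions=np.array(payload["bead_positions_nm"]),
        residue_index=np.array(payload["residue_index"]),
        helix_of_residue={int(k): v
                          for k, v in payload["helix_of_residue"].items()},
        domain_of_helix=payload["domain_of_helix"],
        refvec_beads=tuple(payload["refvec_beads"]),
    )
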