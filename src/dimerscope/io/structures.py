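"""GRO and multi-model PDB readers/writers for coarse bead structures.

Coordinates are always nanometers in memory; the PDB dialect stores
angstroms and the conversion is applied on read/write.  Chain identity is a
first-class label: protomers are chains A and B, lipids chain L.  The GRO
format has no chain field, so this dialect stores the chain letter as the
residue name.  Writing then reading then writing again is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class StructureIOError(ValueError):
    """Malformed structure file; message carries the offending line number."""


@dataclass
class Structure:
    """Labeled bead coordinates; ``coords`` is (n_models, n_atoms, 3) nm."""

    chains: np.ndarray            # (N,) str
    residues: np.ndarray          # (N,) int
    atom_names: np.ndarray        # (N,) str
    coords: np.ndarray            # (M, N, 3) nm
    box: tuple[float, float, float] = (0.0, 0.0, 0.0)
    times_us: np.ndarray | None = None   # (M,) per-model time stamps
    title: str = "dimerscope structure"

    def __post_init__(self):
        self.chains = np.asarray(self.chains)
        self.residues = np.asarray(self.residues, dtype=int)
        self.atom_names = np.asarray(self.atom_names)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.shape[1] != len(self.chains):
            raise StructureIOError("coords/label length mismatch")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def chain_indices(self, chain: str) -> np.ndarray:
        return np.flatnonzero(self.chains == chain)


def _write_gro(path: Path, s: Structure) -> None:
    if s.n_models != 1:
        raise StructureIOError("GRO holds one model; use PDB for multi-model")
    t = s.times_us[0] if s.times_us is not None else 0.0
    lines = [f"{s.title} t= {t:.6f} us", f"{s.n_atoms:5d}"]
    for k in range(s.n_atoms):
        x, y, z = s.coords[0, k]
        lines.append(
            f"{int(s.residues[k]) % 100000:5d}{str(s.chains[k]):<5s}"
            f"{str(s.atom_names[k]):>5s}{(k + 1) % 100000:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    lines.append(f"{s.box[0]:10.5f}{s.box[1]:10.5f}{s.box[2]:10.5f}")
    path.write_text("\n".join(lines) + "\n")


def _read_gro(path: Path) -> Structure:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise StructureIOError(f"{path}: truncated GRO file (line {len(lines)})")
    title = lines[0]
    time_us = None
    if " t= " in title:
        try:
            time_us = float(title.split(" t= ")[1].split()[0])
            title = title.split(" t= ")[0]
        except (IndexError, ValueError):
            pass
    try:
        n_atoms = int(lines[1])
    except ValueError as e:
        raise StructureIOError(f"{path}: bad atom count on line 2") from e
    if len(lines) < n_atoms + 3:
        raise StructureIOError(
            f"{path}: truncated at line {len(lines)}; expected {n_atoms + 3}"
        )
    chains, residues, names = [], [], []
    coords = np.empty((n_atoms, 3))
    for k in range(n_atoms):
        ln = lines[2 + k]
        lineno = 3 + k
        try:
            residues.append(int(ln[0:5]))
            chains.append(ln[5:10].strip())
            names.append(ln[10:15].strip())
            coords[k] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        except (ValueError, IndexError) as e:
            raise StructureIOError(f"{path}: malformed record on line {lineno}") from e
    box_fields = lines[2 + n_atoms].split()
    try:
        box = tuple(float(v) for v in box_fields[:3])
    except ValueError as e:
        raise StructureIOError(
            f"{path}: malformed box on line {3 + n_atoms}"
        ) from e
    times = np.array([time_us]) if time_us is not None else None
    return Structure(chains=np.array(chains), residues=np.array(residues),
                     atom_names=np.array(names), coords=coords[None],
                     box=box, times_us=times, title=title)


def _write_pdb(path: Path, s: Structure) -> None:
    lines = [f"TITLE     {s.title}"]
    lines.append(
        f"CRYST1{s.box[0] * 10:9.3f}{s.box[1] * 10:9.3f}{s.box[2] * 10:9.3f}"
        "  90.00  90.00  90.00 P 1           1"
    )
    for m in range(s.n_models):
        lines.append(f"MODEL     {m + 1:4d}")
        if s.times_us is not None:
            lines.append(f"REMARK 250 TIME_US {s.times_us[m]:.6f}")
        for k in range(s.n_atoms):
            x, y, z = s.coords[m, k] * 10.0  # nm -> Angstrom
            name = str(s.atom_names[k])[:4]
            lines.append(
                f"ATOM  {(k + 1) % 100000:5d} {name:<4s} BEA "
                f"{str(s.chains[k])[:1]}{int(s.residues[k]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _read_pdb(path: Path) -> Structure:
    lines = path.read_text().splitlines()
    box = (0.0, 0.0, 0.0)
    models: list[list[tuple]] = []
    times: list[float] = []
    current: list[tuple] | None = None
    saw_model = False
    for lineno, ln in enumerate(lines, start=1):
        rec = ln[:6]
        if rec == "CRYST1":
            try:
                box = (float(ln[6:15]) / 10, float(ln[15:24]) / 10,
                       float(ln[24:33]) / 10)
            except ValueError as e:
                raise StructureIOError(f"{path}: bad CRYST1 on line {lineno}") from e
        elif rec == "MODEL ":
            saw_model = True
            current = []
        elif rec.startswith("REMARK") and "TIME_US" in ln:
            try:
                times.append(float(ln.split("TIME_US")[1]))
            except ValueError as e:
                raise StructureIOError(f"{path}: bad time on line {lineno}") from e
        elif rec == "ENDMDL":
            if current is None:
                raise StructureIOError(f"{path}: ENDMDL without MODEL, line {lineno}")
            models.append(current)
            current = None
        elif rec in ("ATOM  ", "HETATM"):
            if current is None:
                if saw_model:
                    raise StructureIOError(
                        f"{path}: atom outside MODEL block on line {lineno}"
                    )
                current = []
            try:
                current.append((
                    ln[12:16].strip(), ln[21:22], int(ln[22:26]),
                    float(ln[30:38]) / 10, float(ln[38:46]) / 10,
                    float(ln[46:54]) / 10,
                ))
            except (ValueError, IndexError) as e:
                raise StructureIOError(
                    f"{path}: malformed ATOM record on line {lineno}"
                ) from e
    if current:
        models.append(current)
    if not models:
        raise StructureIOError(f"{path}: no atoms found")
    n_atoms = len(models[0])
    for m, model in enumerate(models):
        if len(model) != n_atoms:
            raise StructureIOError(
                f"{path}: model {m + 1} has {len(model)} atoms, expected {n_atoms}"
            )
    first = models[0]
    coords = np.array([[(a[3], a[4], a[5]) for a in model] for model in models])
    return Structure(
        chains=np.array([a[1] for a in first]),
        residues=np.array([a[2] for a in first]),
        atom_names=np.array([a[0] for a in first]),
        coords=coords,
        box=box,
        times_us=np.array(times) if len(times) == len(models) else None,
    )


def write_structure(path, structure: Structure) -> Path:
    """Write GRO (.gro) or multi-model PDB (.pdb), dispatching on suffix."""
    path = Path(path)
    if path.suffix.lower() == ".gro":
        _write_gro(path, structure)
    elif path.suffix.lower() == ".pdb":
        _write_pdb(path, structure)
    else:
        raise StructureIOError(f"unsupported structure format: {path.suffix}")
    return path


def read_structure(path) -> Structure:
    """Read a GRO or PDB file into nm-unit labeled coordinates."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".gro":
        return _read_gro(path)
    if path.suffix.lower() == ".pdb":
        return _read_pdb(path)
    raise StructureIOError(f"unsupported structure format: {path.suffix}")
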