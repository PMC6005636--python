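"""Ideal helix geometry and the per-residue radial direction.

Used to show how much successive residues rotate about the helix axis, which
sets the alternating (heptad-like) pattern of interfacial residues on a
packed transmembrane helix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# canonical alpha-helix backbone internal coordinates (nm / deg)
_BOND_N_CA = 0.1458
_BOND_CA_C = 0.1525
_BOND_C_N = 0.1329
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_PHI = -57.0
_PSI = -47.0
_OMEGA = 180.0


class HelixError(ValueError):
    pass


@dataclass
class IdealHelix:
    coords: np.ndarray        # (n, 3) C-alpha positions, nm
    axis_point: np.ndarray    # point on the helix axis
    axis_dir: np.ndarray      # unit axis direction
    radial_dirs: np.ndarray   # (n, 3) unit vectors axis -> residue, normal to axis

    @property
    def n_residues(self) -> int:
        return len(self.coords)

    def successive_offsets(self) -> np.ndarray:
        """Signed rotation (deg) about the axis between consecutive residues."""
        a = self.axis_dir
        u = self.radial_dirs[:-1]
        v = self.radial_dirs[1:]
        cross = np.cross(u, v)
        sin = cross @ a
        cos = np.sum(u * v, axis=1)
        return np.degrees(np.arctan2(sin, cos))

    def mean_offset(self) -> float:
        """Mean magnitude of the successive rotation, deg."""
        return float(np.mean(np.abs(self.successive_offsets())))


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement of atom d bonded to c, given chain a-b-c."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(dihedral),
        np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone_ca(n_residues, phi, psi, omega) -> np.ndarray:
    """C-alpha coordinates of a poly-backbone with fixed dihedrals, nm."""
    ang = np.deg2rad(_ANG_N_CA_C)
    n0 = np.zeros(3)
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    c0 = ca0 + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    atoms = [n0, ca0, c0]
    for _ in range(1, n_residues):
        a, b, c = atoms[-3], atoms[-2], atoms[-1]
        n_next = _place_atom(a, b, c, _BOND_C_N, _ANG_CA_C_N, psi)
        ca_next = _place_atom(b, c, n_next, _BOND_N_CA, _ANG_C_N_CA, omega)
        c_next = _place_atom(c, n_next, ca_next, _BOND_CA_C, _ANG_N_CA_C, phi)
        atoms.extend([n_next, ca_next, c_next])
    return np.array(atoms[1::3])


def _fit_axis(coords: np.ndarray):
    """Axis of a near-ideal helix from second differences of C-alphas.

    The second difference P[i+1] - 2 P[i] + P[i-1] points radially inward
    toward the axis; cross products of consecutive inward vectors align with
    the axis exactly for a perfect helix.
    """
    s = coords[2:] - 2.0 * coords[1:-1] + coords[:-2]
    crosses = np.cross(s[:-1], s[1:])
    axis = crosses.sum(axis=0)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise HelixError("cannot determine helix axis (degenerate geometry)")
    return axis / norm


def build_ideal_helix(
    n_residues: int,
    rise_per_residue: float = 0.15,
    residues_per_turn: float | None = None,
    canonical_dihedrals: bool = False,
    radius: float = 0.23,
) -> IdealHelix:
    """Build an ideal helix at C-alpha resolution.

    With ``canonical_dihedrals=True`` the helix is constructed atom by atom
    from canonical alpha-helical backbone dihedrals (phi=-57, psi=-47,
    omega=180) and standard bond geometry; otherwise a parametric helix with
    ``residues_per_turn`` (default 3.6) is used.
    """
    if n_residues < 4:
        raise HelixError("n_residues must be >= 4 (axis undefined otherwise)")
    if canonical_dihedrals:
        coords = _backbone_ca(n_residues, _PHI, _PSI, _OMEGA)
    else:
        rpt = 3.6 if residues_per_turn is None else float(residues_per_turn)
        if rpt <= 0:
            raise HelixError("residues_per_turn must be positive")
        i = np.arange(n_residues)
        t = 2.0 * np.pi * i / rpt
        coords = np.column_stack(
            [radius * np.cos(t), radius * np.sin(t), rise_per_residue * i]
        )

    axis_dir = _fit_axis(coords)
    axis_point = coords.mean(axis=0)
    rel = coords - axis_point
    radial = rel - np.outer(rel @ axis_dir, axis_dir)
    norms = np.linalg.norm(radial, axis=1)
    if np.any(norms < 1e-9):
        raise HelixError("residue lies on the helix axis")
    radial /= norms[:, None]
    return IdealHelix(
        coords=coords, axis_point=axis_point, axis_dir=axis_dir, radial_dirs=radial
    )
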