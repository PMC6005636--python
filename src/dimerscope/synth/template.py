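"""Coarse bead template of a 12-helix transporter protomer.

The template is a rigid body: bead coordinates live in a body frame whose
origin is the in-plane center of mass.  A reference vector, defined by two
bead indices, points from the core toward the TMH4 centroid and anchors the
relative-orientation angles downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dimerscope._geom import rot2

BUNDLE_HELICES = ("TMH1", "TMH2", "TMH6", "TMH7")
SCAFFOLD_HELICES = (
    "TMH3", "TMH4", "TMH5", "TMH8", "TMH9", "TMH10", "TMH11", "TMH12",
)

# Body-frame layout for the 12-helix default: (ring radius nm, angle deg).
# Bundle helices occupy the contiguous 155-215 deg arc of the outer surface;
# TMH4 sits at 0 deg so the reference vector points along body +x.
_HDAT_LAYOUT = {
    "TMH4": (1.9, 0.0),
    "TMH9": (1.9, 45.0),
    "TMH11": (1.9, 90.0),
    "TMH1": (1.9, 155.0),
    "TMH2": (1.9, 175.0),
    "TMH6": (1.9, 195.0),
    "TMH7": (1.9, 215.0),
    "TMH5": (1.9, 270.0),
    "TMH12": (1.9, 315.0),
    "TMH3": (0.9, 60.0),
    "TMH8": (0.9, 180.0),
    "TMH10": (0.9, 300.0),
}

# Loop / terminus bead groups: (anchor helix, z offset nm, n beads).
_HDAT_LOOPS = {
    "EL2": ("TMH3", 1.8, 3),
    "EL3": ("TMH6", 1.8, 3),
    "CTERM": ("TMH12", -1.8, 3),
}

FIRST_RESIDUE = 44  # hDAT-like numbering starts at residue 44
_SEQUENCE_ORDER = (
    "TMH1", "TMH2", "TMH3", "EL2", "TMH4", "TMH5", "TMH6", "EL3",
    "TMH7", "TMH8", "TMH9", "TMH10", "TMH11", "TMH12", "CTERM",
)


class TemplateError(ValueError):
    """Invalid template configuration."""


@dataclass
class ProtomerTemplate:
    """Rigid-body bead model of one protomer.

    Attributes
    ----------
    bead_positions : (N, 3) float array, nm, body frame.
    residue_index : (N,) int array, residue number of each bead.
    helix_of_residue : residue number -> helix/loop label.
    domain_of_helix : helix label -> {"bundle", "scaffold", "other"}.
    refvec_beads : (i, j); in-plane component of position[j] - position[i]
        defines the reference vector.
    """

    bead_positions: np.ndarray
    residue_index: np.ndarray
    helix_of_residue: dict[int, str]
    domain_of_helix: dict[str, str]
    refvec_beads: tuple[int, int]
    helix_of_bead: np.ndarray = field(init=False)
    domain_of_bead: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.bead_positions = np.asarray(self.bead_positions, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if self.bead_positions.ndim != 2 or self.bead_positions.shape[1] != 3:
            raise TemplateError("bead_positions must be (N, 3)")
        if len(self.residue_index) != len(self.bead_positions):
            raise TemplateError("residue_index length mismatch")
        missing = set(self.residue_index) - set(self.helix_of_residue)
        if missing:
            raise TemplateError(f"residues without a helix label: {sorted(missing)[:5]}")
        self.helix_of_bead = np.array(
            [self.helix_of_residue[r] for r in self.residue_index]
        )
        self.domain_of_bead = np.array(
            [self.domain_of_helix.get(h, "other") for h in self.helix_of_bead]
        )
        if np.linalg.norm(self.refvec_body) < 1e-6:
            raise TemplateError("reference vector has no in-plane component")

    @property
    def n_beads(self) -> int:
        return len(self.bead_positions)

    @property
    def refvec_body(self) -> np.ndarray:
        """In-plane unit reference vector in the body frame."""
        i, j = self.refvec_beads
        v = self.bead_positions[j, :2] - self.bead_positions[i, :2]
        n = np.linalg.norm(v)
        if n < 1e-6:
            return np.zeros(2)
        return v / n

    @property
    def radius(self) -> float:
        """Largest in-plane bead distance from the body origin, nm."""
        return float(np.max(np.linalg.norm(self.bead_positions[:, :2], axis=1)))

    @property
    def residues(self) -> np.ndarray:
        return np.unique(self.residue_index)

    def residues_of_helix(self, helix: str) -> np.ndarray:
        return np.unique(self.residue_index[self.helix_of_bead == helix])

    def bundle_residues(self) -> np.ndarray:
        return np.unique(self.residue_index[self.domain_of_bead == "bundle"])

    def transform(self, pose) -> np.ndarray:
        """Bead coordinates in the lab frame for pose (x, y, theta_deg)."""
        x, y, theta = pose
        out = self.bead_positions.copy()
        out[:, :2] = out[:, :2] @ rot2(theta).T
        out[:, 0] += x
        out[:, 1] += y
        return out


def _default_domain_map() -> dict[str, str]:
    d = {h: "bundle" for h in BUNDLE_HELICES}
    d.update({h: "scaffold" for h in SCAFFOLD_HELICES})
    d.update({"EL2": "other", "EL3": "other", "CTERM": "other", "LOOP": "other"})
    return d


def _helix_beads(center_xy, beads_per_helix, rng, z_extent=1.4, jitter=0.08):
    z = np.linspace(-z_extent, z_extent, beads_per_helix)
    pos = np.empty((beads_per_helix, 3))
    pos[:, 0] = center_xy[0] + rng.normal(0.0, jitter, beads_per_helix)
    pos[:, 1] = center_xy[1] + rng.normal(0.0, jitter, beads_per_helix)
    pos[:, 2] = z
    return pos


def build_protomer_template(
    n_helices: int = 12,
    beads_per_helix: int = 8,
    seed: int = 0,
    include_loops: bool = True,
) -> ProtomerTemplate:
    """Build a protomer bead template.

    With ``n_helices=12`` the hDAT-like layout is used: bundle helices
    (TMH1, 2, 6, 7) fill a contiguous angular sector of the outer surface and
    the reference vector points toward the TMH4 centroid.  Other helix counts
    produce a single ring of all-scaffold helices (useful as a degenerate
    control in which the bundle screen can never fire).

    Parameters are deterministic given ``seed``.
    """
    if n_helices < 4:
        raise TemplateError("n_helices must be >= 4")
    if beads_per_helix < 2:
        raise TemplateError("beads_per_helix must be >= 2")
    rng = np.random.default_rng(seed)

    positions: list[np.ndarray] = []
    residue_index: list[int] = []
    helix_of_residue: dict[int, str] = {}
    next_res = FIRST_RESIDUE
    centers: dict[str, np.ndarray] = {}

    if n_helices == 12:
        layout = _HDAT_LAYOUT
        order = [h for h in _SEQUENCE_ORDER if h in layout or h in _HDAT_LOOPS]
        domain_of_helix = _default_domain_map()
    else:
        angles = 360.0 * np.arange(n_helices) / n_helices
        layout = {f"TMH{k + 1}": (1.9, angles[k]) for k in range(n_helices)}
        order = list(layout)
        domain_of_helix = {h: "scaffold" for h in layout}
        include_loops = False

    for label in order:
        if label in _HDAT_LOOPS:
            if not include_loops:
                continue
            anchor, z_off, n_loop = _HDAT_LOOPS[label]
            r, a = layout[anchor]
            base = r * np.array([np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a))])
            pos = np.empty((n_loop, 3))
            pos[:, :2] = base * 1.1 + rng.normal(0.0, 0.15, (n_loop, 2))
            pos[:, 2] = z_off
            n_beads = n_loop
        else:
            r, a = layout[label]
            center = r * np.array([np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a))])
            pos = _helix_beads(center, beads_per_helix, rng)
            centers[label] = center
            n_beads = beads_per_helix
        positions.append(pos)
        for k in range(n_beads):
            residue_index.append(next_res)
            helix_of_residue[next_res] = label
            next_res += 1

    bead_positions = np.vstack(positions)
    residue_arr = np.array(residue_index)
    # recenter in-plane COM on the body origin
    bead_positions[:, :2] -= bead_positions[:, :2].mean(axis=0)

    # reference vector: from the central bead of the helix opposite TMH4
    # to the central bead of TMH4, so it points toward the TMH4 centroid
    helix_of_bead = np.array([helix_of_residue[r] for r in residue_arr])
    tm4_beads = np.flatnonzero(helix_of_bead == "TMH4")
    opposite = "TMH8" if n_helices == 12 else f"TMH{(3 + n_helices // 2) % n_helices + 1}"
    opp_beads = np.flatnonzero(helix_of_bead == opposite)
    j = int(tm4_beads[len(tm4_beads) // 2])
    i = int(opp_beads[len(opp_beads) // 2])

    return ProtomerTemplate(
        bead_positions=bead_positions,
        residue_index=residue_arr,
        helix_of_residue=helix_of_residue,
        domain_of_helix=domain_of_helix,
        refvec_beads=(i, j),
    )
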