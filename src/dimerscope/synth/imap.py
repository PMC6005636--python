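"""Planted orientation-attractor interaction model.

The pair potential is a sum of toroidal Gaussian wells in the relative
orientation coordinates (beta, chi), each multiplied by a smooth switching
function of the center-of-mass distance, plus a harmonic core repulsion.
Off-diagonal attractors (beta != chi) implicitly generate their symmetry
partner at the swapped coordinates, mirroring the label-swap symmetry of a
homodimer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dimerscope._geom import wrap_signed_deg

KB_KJMOL = 0.008314462618  # kJ/mol/K

_K_REPULSION = 500.0  # kJ/mol/nm^2, harmonic core wall


@dataclass(frozen=True)
class Attractor:
    beta: float          # deg
    chi: float           # deg
    depth: float         # kJ/mol, > 0
    angular_width: float  # deg, Gaussian sigma
    distance_min: float  # nm, switching is fully on below this distance

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("attractor depth must be positive")

    @property
    def is_diagonal(self) -> bool:
        return abs(wrap_signed_deg(self.beta - self.chi)) < 1e-9


@dataclass
class InteractionMap:
    """Orientation attractors + distance envelope for the pair potential."""

    attractors: list[Attractor] = field(default_factory=list)
    repulsion_core: float = 4.1     # nm
    encounter_distance: float = 6.5  # nm

    def __post_init__(self):
        for a in self.attractors:
            if a.distance_min < self.repulsion_core:
                raise ValueError(
                    f"attractor distance_min {a.distance_min} below repulsion core"
                )

    def expanded_attractors(self) -> list[Attractor]:
        """Attractors with implicit symmetry partners materialized."""
        out: list[Attractor] = []
        for a in self.attractors:
            out.append(a)
            if not a.is_diagonal:
                out.append(
                    Attractor(a.chi, a.beta, a.depth, a.angular_width, a.distance_min)
                )
        return out

    # --- potential -----------------------------------------------------

    def _switch(self, d, d_min):
        """Smoothstep from 1 at d <= d_min to 0 at d >= encounter_distance."""
        span = self.encounter_distance - d_min
        t = np.clip((self.encounter_distance - np.asarray(d, float)) / span, 0.0, 1.0)
        s = t * t * (3.0 - 2.0 * t)
        ds_dt = 6.0 * t * (1.0 - t)
        ds_dd = -ds_dt / span
        return s, ds_dd

    def energy(self, beta, chi, d):
        """Potential energy in kJ/mol at relative pose (beta, chi, d)."""
        beta = np.asarray(beta, float)
        chi = np.asarray(chi, float)
        d = np.asarray(d, float)
        u = np.zeros(np.broadcast(beta, chi, d).shape)
        for a in self.expanded_attractors():
            db = wrap_signed_deg(beta - a.beta)
            dc = wrap_signed_deg(chi - a.chi)
            g = np.exp(-(db * db + dc * dc) / (2.0 * a.angular_width**2))
            s, _ = self._switch(d, a.distance_min)
            u = u - a.depth * g * s
        core = np.clip(self.repulsion_core - d, 0.0, None)
        u = u + 0.5 * _K_REPULSION * core * core
        return u if u.shape else float(u)

    def gradients(self, beta, chi, d):
        """(dU/dbeta, dU/dchi, dU/dd) in kJ/mol per deg, deg, nm."""
        beta = np.asarray(beta, float)
        chi = np.asarray(chi, float)
        d = np.asarray(d, float)
        shape = np.broadcast(beta, chi, d).shape
        gb = np.zeros(shape)
        gc = np.zeros(shape)
        gd = np.zeros(shape)
        for a in self.expanded_attractors():
            db = wrap_signed_deg(beta - a.beta)
            dc = wrap_signed_deg(chi - a.chi)
            w2 = a.angular_width**2
            g = np.exp(-(db * db + dc * dc) / (2.0 * w2))
            s, ds_dd = self._switch(d, a.distance_min)
            gb += a.depth * g * s * db / w2
            gc += a.depth * g * s * dc / w2
            gd += -a.depth * g * ds_dd
        core = np.clip(self.repulsion_core - d, 0.0, None)
        gd += -_K_REPULSION * core
        return gb, gc, gd


# Default planted layout: four symmetric (diagonal) and four asymmetric
# attractors; the asymmetric ones get their swapped partners implicitly,
# giving eight distinct dimer conformations after pair merging.  Every
# coordinate sits on a scaffold-helix surface angle of the default template
# ({0, 45, 90, 270, 315} deg: TMH4/9/11/5/12), so contact distances are tight
# at every planted pose, and all stay >= 55 deg from the bundle sector
# (155-215 deg), keeping the bundle screen negative.  The twelve expanded
# centers are pairwise >= 63 deg apart on the torus, so wells never merge.
_DEFAULT_ATTRACTORS = [
    Attractor(0.0, 0.0, 28.0, 16.0, 4.4),
    Attractor(45.0, 45.0, 27.0, 16.0, 4.4),
    Attractor(270.0, 270.0, 27.0, 16.0, 4.4),
    Attractor(315.0, 315.0, 28.0, 16.0, 4.4),
    Attractor(0.0, 90.0, 25.0, 16.0, 4.4),
    Attractor(45.0, 315.0, 25.0, 16.0, 4.4),
    Attractor(90.0, 270.0, 25.0, 16.0, 4.4),
    Attractor(0.0, 270.0, 25.0, 16.0, 4.4),
]


def default_interaction_map() -> InteractionMap:
    """Eight-conformation attractor layout used by the default ensemble."""
    return InteractionMap(attractors=list(_DEFAULT_ATTRACTORS))
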