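"""Analytic 1-D potentials and biased (umbrella) sampling from them.

These stand in for the steered-MD / umbrella-window trajectories: each window
draws from the Boltzmann density of truth-plus-harmonic-bias by Metropolis
sampling, giving the downstream WHAM solver fixtures with a known answer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from dimerscope.synth.imap import KB_KJMOL

logger = logging.getLogger(__name__)

FORMS = ("harmonic_well", "gaussian_well_plus_wall", "flat")


@dataclass(frozen=True)
class AnalyticPMF:
    """Ground-truth free-energy profile along a separation coordinate.

    form:
      - "flat": U = 0 everywhere (zero mean force).
      - "harmonic_well": U = 0.5 * k_well * (xi - minimum)^2 with
        k_well = depth / width**2.
      - "gaussian_well_plus_wall": U = -depth * exp(-(xi-minimum)^2/(2 width^2))
        plus a quartic repulsive wall below ``wall_at``.
    """

    form: str = "gaussian_well_plus_wall"
    depth: float = 60.0        # kJ/mol
    width: float = 0.25        # nm
    minimum: float = 4.8       # nm
    wall_at: float = 4.5       # nm
    wall_k: float = 5000.0     # kJ/mol/nm^4
    temperature: float = 310.0

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}; one of {FORMS}")

    @property
    def kt(self) -> float:
        return KB_KJMOL * self.temperature

    def potential(self, xi):
        xi = np.asarray(xi, dtype=float)
        if self.form == "flat":
            u = np.zeros_like(xi)
        elif self.form == "harmonic_well":
            k = self.depth / self.width**2
            u = 0.5 * k * (xi - self.minimum) ** 2
        else:
            u = -self.depth * np.exp(-((xi - self.minimum) ** 2)
                                     / (2.0 * self.width**2))
            over = np.clip(self.wall_at - xi, 0.0, None)
            u = u + self.wall_k * over**4
        return u if u.shape else float(u)

    def free_energy(self, xi, xi_ref: float):
        """Truth profile gauged to zero at ``xi_ref`` (max separation)."""
        return self.potential(xi) - self.potential(xi_ref)


@dataclass
class UmbrellaWindow:
    """One biased window: harmonic restraint at ``center`` plus samples."""

    center: float               # nm
    k_bias: float               # kJ/mol/nm^2
    samples: np.ndarray         # (n,) xi values, nm
    equilibration_fraction: float = 0.0

    def __post_init__(self):
        if self.k_bias <= 0:
            raise ValueError("k_bias must be positive")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def production(self) -> np.ndarray:
        """Samples after the equilibration discard."""
        n0 = int(len(self.samples) * self.equilibration_fraction)
        return self.samples[n0:]

    def bias(self, xi):
        return 0.5 * self.k_bias * (np.asarray(xi, float) - self.center) ** 2


def _metropolis(log_density, x0, n_samples, step, rng, burn=200, thin=4):
    x = float(x0)
    lp = log_density(x)
    out = np.empty(n_samples)
    total = burn + n_samples * thin
    prop = rng.normal(0.0, step, total)
    logu = np.log(rng.uniform(size=total))
    j = 0
    for i in range(total):
        xn = x + prop[i]
        lpn = log_density(xn)
        if lpn - lp > logu[i]:
            x, lp = xn, lpn
        if i >= burn and (i - burn) % thin == 0:
            out[j] = x
            j += 1
    return out


def generate_umbrella_samples(
    truth: AnalyticPMF,
    centers,
    k_bias: float = 1000.0,
    n_samples: int = 2000,
    seed: int = 0,
) -> list[UmbrellaWindow]:
    """Draw biased samples for each window center.

    Samples in window ``i`` follow exp(-(U(xi) + bias_i(xi))/kT) via
    Metropolis sampling.  Emits a warning naming any pair of adjacent windows
    whose sample histograms do not overlap at the requested force constant.
    """
    centers = np.asarray(centers, dtype=float)
    if np.any(np.diff(centers) <= 0):
        raise ValueError("centers must be sorted strictly ascending")
    if k_bias <= 0:
        raise ValueError("k_bias must be positive")
    kt = truth.kt
    rngs = np.random.SeedSequence(seed).spawn(len(centers))
    windows: list[UmbrellaWindow] = []
    # proposal scale from the bias spring alone (upper bound on stiffness
    # unless the well dominates)
    step = max(np.sqrt(kt / k_bias), 1e-4)
    for c, ss in zip(centers, rngs):
        rng = np.random.default_rng(ss)

        def log_density(x, _c=c):
            return -(truth.potential(x) + 0.5 * k_bias * (x - _c) ** 2) / kt

        if n_samples == 0:
            samples = np.empty(0)
        else:
            samples = _metropolis(log_density, c, n_samples, step, rng)
        windows.append(UmbrellaWindow(center=c, k_bias=k_bias, samples=samples))

    for left, right in zip(windows[:-1], windows[1:]):
        if len(left.samples) == 0 or len(right.samples) == 0:
            continue
        if left.samples.max() < right.samples.min():
            warnings.warn(
                f"no histogram overlap between windows at {left.center:.3f} nm "
                f"and {right.center:.3f} nm (k_bias={k_bias})",
                stacklevel=2,
            )
    return windows
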