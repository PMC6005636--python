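"""Ensemble convergence diagnostics: vigintile bands of the interaction
energy, plateau detection on the ensemble mean, and the dimerized fraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_LEVELS = 21  # vigintiles: 0, 5, ..., 100 percent


class ConvergenceError(ValueError):
    pass


@dataclass
class QuantileBands:
    times: np.ndarray          # (T,)
    levels: np.ndarray         # (T, 21), non-decreasing along axis 1
    mean: np.ndarray           # (T,)
    quantiles: np.ndarray      # (21,) the probabilities 0..1

    def to_frame(self) -> pd.DataFrame:
        cols = {f"q{int(round(100 * q))}": self.levels[:, i]
                for i, q in enumerate(self.quantiles)}
        return pd.DataFrame({"time_us": self.times, **cols, "mean": self.mean})


def _energy_matrix(energies: pd.DataFrame):
    """Pivot the (replicate, time_us, E) table onto a common time grid."""
    wide = energies.pivot(index="replicate", columns="time_us",
                          values="E_interaction_kJmol")
    if wide.isna().any().any():
        raise ConvergenceError("replicates do not share a common time grid")
    return wide.columns.to_numpy(float), wide.to_numpy(float)


def vigintile_bands(energies: pd.DataFrame) -> QuantileBands:
    """The 21 five-percent quantile levels plus the mean, per time point.

    Quantiles use linear interpolation between order statistics.
    """
    times, e = _energy_matrix(energies)
    if e.shape[0] < N_LEVELS:
        raise ConvergenceError(
            f"need >= {N_LEVELS} replicates for vigintiles, got {e.shape[0]}"
        )
    probs = np.linspace(0.0, 1.0, N_LEVELS)
    levels = np.quantile(e, probs, axis=0, method="linear").T
    return QuantileBands(times=times, levels=levels, mean=e.mean(axis=0),
                         quantiles=probs)


def plateau_check(
    bands: QuantileBands,
    tail_fraction: float = 0.25,
    slope_tol: float | None = None,
) -> dict:
    """Least-squares slope of the ensemble mean over the trailing fraction.

    Default tolerance: 1% of the full mean-energy range per tail duration.
    Verdict "leveled" when |slope| < tolerance.
    """
    n = len(bands.times)
    n_tail = max(int(np.ceil(n * tail_fraction)), 4)
    if n_tail > n:
        raise ConvergenceError("too few time points for the plateau check")
    t = bands.times[-n_tail:]
    m = bands.mean[-n_tail:]
    span = t[-1] - t[0]
    if slope_tol is None:
        e_range = float(np.ptp(bands.mean))
        slope_tol = 0.01 * max(e_range, 1e-12) / max(span, 1e-12)
    slope = float(np.polyfit(t, m, 1)[0])
    return {"leveled": abs(slope) < slope_tol, "slope": slope,
            "slope_tol": slope_tol, "n_tail": n_tail}


def dimer_fraction(frames: pd.DataFrame, at_time: float,
                   dimer_cutoff: float = 1.0) -> float:
    """Fraction of replicates with min bead distance below the cutoff."""
    from dimerscope.orientation import select_frames_at

    at = select_frames_at(frames, at_time)
    if len(at) == 0:
        raise ConvergenceError(f"no frames at t={at_time}")
    return float((at["min_bead_distance"] < dimer_cutoff).mean())
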