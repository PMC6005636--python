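"""In-plane geometry helpers shared by the generator and the analysis stages.

All angles are degrees unless a name says otherwise.  The lab frame uses the
standard mathematical convention: the membrane normal is +z and positive
angles rotate counterclockwise about +z (x toward y).  Every producer and
consumer in the package uses this one convention, so relative-orientation
statistics are independent of the choice of handedness.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_deg(a):
    """Reduce angle(s) to [0, 360)."""
    return np.mod(a, 360.0)


def wrap_signed_deg(a):
    """Reduce angle(s) to (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(a), 360.0)


def ang_dist_deg(a, b):
    """Shortest angular distance |a - b| on the circle, in [0, 180]."""
    return np.abs(wrap_signed_deg(np.asarray(a) - np.asarray(b)))


def toroidal_dist_deg(p, q):
    """Euclidean distance between two points on the (360, 360) torus."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = wrap_signed_deg(p - q)
    return np.sqrt(np.sum(d * d, axis=-1))


def rot2(theta_deg: float) -> np.ndarray:
    """2x2 counterclockwise rotation matrix."""
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


def signed_angle_deg(a, b):
    """Signed CCW angle from 2-vector(s) ``a`` to ``b``, in (-180, 180]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cross = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    dot = a[..., 0] * b[..., 0] + a[..., 1] * b[..., 1]
    return np.degrees(np.arctan2(cross, dot))


def circular_mean_deg(angles, weights=None) -> float:
    """Vector-average mean of angles in degrees, reduced to [0, 360)."""
    a = np.deg2rad(np.asarray(angles, dtype=float))
    if weights is None:
        weights = np.ones_like(a)
    w = np.asarray(weights, dtype=float)
    s = np.sum(w * np.sin(a))
    c = np.sum(w * np.cos(a))
    if s == 0.0 and c == 0.0:
        raise ValueError("circular mean undefined: resultant vector is zero")
    return float(wrap_deg(np.degrees(np.arctan2(s, c))))


def min_image(delta, box):
    """Minimum-image convention for in-plane displacement(s) in a periodic box.

    ``box`` is (Lx, Ly) in nm; ``delta`` has shape (..., 2).
    """
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)
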