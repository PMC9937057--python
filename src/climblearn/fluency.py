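"""Per-trial climbing-fluency metrics computed from a hip trajectory.

A climbing trial is summarized by the planar (wall-plane) trajectory of the
climber's hip. Four scalar scores describe how fluent the climb was; for all
of them, lower is better:

* ``GE`` — geometric index of entropy, ``log2(2 L / c)`` where ``L`` is the
  path length and ``c`` the perimeter of the convex hull of the visited
  positions. Measures spatial tortuosity in bits; 0 for a straight climb.
* ``JE`` — dimensionless jerk, the integrated squared third derivative of
  position normalized by duration and net displacement,
  ``\\int ||x'''||^2 dt * T^5 / L^2``. Spatio-temporal smoothness; it is
  invariant to amplitude scaling and time rescaling, and equals 720 for the
  classic one-dimensional minimum-jerk profile.
* ``IM`` — immobility ratio, the fraction of trial time the hip speed stays
  below a threshold (default 0.05 m/s). Purely temporal fluency.
* ``CT`` — climb duration in seconds, an auxiliary measure.

Degenerate inputs (a stationary hip, zero net displacement) make individual
scores undefined; those come back as ``nan`` with a warning while the other
scores are still computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "Trajectory",
    "FluencyScores",
    "path_length",
    "hull_perimeter",
    "geometric_entropy",
    "dimensionless_jerk",
    "immobility_ratio",
    "climb_duration",
    "score_trial",
]

#: Default hip-speed threshold (m/s) below which the climber counts as
#: immobile. Deliberately configurable everywhere it is used.
DEFAULT_V_THRESHOLD = 0.05

_DT_ATOL = 1e-9


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled planar hip positions for one trial.

    Parameters
    ----------
    t : array of timestamps in seconds, strictly increasing with constant
        spacing (within 1e-9 s).
    xy : (n, 2) array of positions in meters in the wall plane.
    """

    t: np.ndarray
    xy: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xy", xy)
        if t.ndim != 1 or xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("trajectory needs 1-D timestamps and (n, 2) positions")
        if len(t) != len(xy):
            raise ValueError("timestamps and positions differ in length")
        if len(t) < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(xy))):
            raise ValueError("trajectory contains non-finite values")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > _DT_ATOL:
            raise ValueError("timestamps must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class FluencyScores:
    """The four per-trial scores; ``nan`` marks an undefined (missing) value."""

    ge: float = np.nan
    je: float = np.nan
    im: float = np.nan
    ct: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {"GE": self.ge, "JE": self.je, "IM": self.im, "CT": self.ct}


def path_length(traj: Trajectory) -> float:
    """Total Euclidean length of the sampled path, in meters."""
    steps = np.linalg.norm(np.diff(traj.xy, axis=0), axis=1)
    return float(steps.sum())


def hull_perimeter(traj: Trajectory) -> float:
    """Perimeter of the convex hull of the visited positions, in meters.

    Collinear point sets have a degenerate (flat) hull; by convention the
    perimeter is then twice the extent of the segment, so a straight climb
    has GE exactly 0. All-identical points give 0.
    """
    pts = traj.xy
    centered = pts - pts.mean(axis=0)
    # rank < 2 means collinear (or a single point): Qhull cannot build a 2-D hull
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] <= 0:
        return 0.0
    if sv[1] / sv[0] > 1e-12:
        try:
            hull = ConvexHull(pts)
            return float(hull.area)  # in 2-D, .area is the perimeter
        except QhullError:
            pass
    # degenerate hull: project on the principal direction
    u = np.linalg.svd(centered, compute_uv=True)[2][0]
    proj = centered @ u
    return float(2.0 * (proj.max() - proj.min()))


def geometric_entropy(traj: Trajectory) -> float:
    """Geometric index of entropy, ``log2(2 L / c)`` in bits.

    Invariant to rigid motions and uniform scaling of the trajectory.
    Returns ``nan`` (with a warning) when the hull is a point.
    """
    c = hull_perimeter(traj)
    if c <= 0:
        warnings.warn("geometric entropy undefined for a stationary trajectory",
                      stacklevel=2)
        return float("nan")
    return float(np.log2(2.0 * path_length(traj) / c))


def dimensionless_jerk(traj: Trajectory) -> float:
    """Time- and amplitude-normalized integrated squared jerk.

    Third derivatives are taken by repeated central finite differences
    (one-sided at the boundaries); the squared norm is integrated with the
    trapezoid rule and scaled by ``T^5 / L^2`` where ``T`` is the duration
    and ``L`` the net (endpoint) displacement. Returns ``nan`` with a
    warning when the net displacement is zero.
    """
    if len(traj) < 8:
        raise ValueError("dimensionless jerk needs at least 8 samples")
    L = float(np.linalg.norm(traj.xy[-1] - traj.xy[0]))
    if L <= 0:
        warnings.warn("dimensionless jerk undefined for zero net displacement",
                      stacklevel=2)
        return float("nan")
    T = float(traj.t[-1] - traj.t[0])
    d3 = traj.xy
    for _ in range(3):
        d3 = np.gradient(d3, traj.t, axis=0)
    sq = np.sum(d3 * d3, axis=1)
    integral = float(np.trapezoid(sq, traj.t))
    return integral * T**5 / L**2


def immobility_ratio(traj: Trajectory, v_threshold: float = DEFAULT_V_THRESHOLD) -> float:
    """Fraction of trial time spent with hip speed below ``v_threshold``.

    Speed comes from central finite differences of position. The ratio is
    non-decreasing in the threshold and always lies in [0, 1].
    """
    if v_threshold <= 0:
        raise ValueError("v_threshold must be positive")
    vel = np.gradient(traj.xy, traj.t, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    return float(np.mean(speed < v_threshold))


def climb_duration(traj: Trajectory) -> float:
    """Total trial time: last minus first timestamp, in seconds."""
    return float(traj.t[-1] - traj.t[0])


def score_trial(traj: Trajectory, v_threshold: float = DEFAULT_V_THRESHOLD) -> FluencyScores:
    """Bundle all four fluency scores for one trial.

    Undefined components come back as ``nan`` (their warnings propagate);
    the remaining scores are still computed.
    """
    ge = geometric_entropy(traj)
    try:
        je = dimensionless_jerk(traj)
    except ValueError as exc:
        warnings.warn(f"jerk unavailable: {exc}", stacklevel=2)
        je = float("nan")
    im = immobility_ratio(traj, v_threshold)
    ct = climb_duration(traj)
    return FluencyScores(ge=ge, je=je, im=im, ct=ct)
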