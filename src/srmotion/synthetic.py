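"""Seeded generators of reaching kinematics and tuning-curve fixtures.

Two planar reaching paradigms are emulated:

* a single straight **centre-out** reach with a quartic bell-shaped speed
  profile (peak at the temporal midpoint of the reach), and
* a **random target pursuit** path: straight segments between successive
  targets, each with its own bell-shaped speed scaled to the segment
  length, speed (and tangential acceleration) exactly zero at every
  target, and an instantaneous heading change there.

Every generated trajectory lives in the admissible set of the kinematic
model: direction along the velocity, ``a = dv/dt``, so the horizontal
one-forms annihilate the discrete tangent up to O(dt^2).  Ground-truth
fragment labels (segment index x acceleration/deceleration phase) are
exported with pursuit trajectories for scoring of clustering results.

Also provides the lift of a raw planar path ``(t, x, y)`` into the full
feature space by finite differences, and random polynomial fixtures for
the preferred-direction fitting machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fit import BellProfile, bell_velocity, bell_acceleration, bell_position
from .space import Trajectory, wrap_angle

__all__ = [
    "PursuitSpec",
    "gen_center_out",
    "gen_random_pursuit",
    "kinematics_from_path",
    "gen_pd_curves",
    "speed_extrema_times",
]

#: Default sampling step (s) of the generators.
DEFAULT_DT = 0.01


@dataclass
class PursuitSpec:
    """Configuration of a random-target-pursuit trajectory.

    ``targets`` are the successive way-points in metres (the first is the
    start of the movement); per-segment peak speeds are drawn uniformly
    from ``v0_range`` (m/s) with the given seed.
    """

    targets: Sequence[tuple[float, float]]
    v0_range: tuple[float, float] = (0.6, 1.4)
    dt: float = DEFAULT_DT
    seed: int = 0

    def __post_init__(self) -> None:
        self.targets = [(float(x), float(y)) for x, y in self.targets]
        if len(self.targets) < 2:
            raise ValueError("PursuitSpec needs at least two targets")
        for (x0, y0), (x1, y1) in zip(self.targets, self.targets[1:]):
            if math.hypot(x1 - x0, y1 - y0) < 1e-12:
                raise ValueError("consecutive targets must be distinct")
        lo, hi = self.v0_range
        if not (0 < lo <= hi):
            raise ValueError("v0_range must be positive with min <= max")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def gen_center_out(start: tuple[float, float] = (0.0, 0.0),
                   heading: float = 0.0,
                   profile: BellProfile | None = None,
                   dt: float = DEFAULT_DT,
                   seed: int = 0) -> Trajectory:
    """A straight centre-out reach with a bell-shaped speed profile.

    The hand moves from ``start`` along the constant direction ``heading``
    for ``t`` in ``[-T, T]``, with speed ``v0 (1 - (t/T)^2)^2`` (peak at
    t = 0) and analytic tangential acceleration.  The generator is
    deterministic; ``seed`` is recorded in the metadata for provenance.
    """
    if profile is None:
        profile = BellProfile()
    if dt > profile.T / 5 + 1e-15:
        raise ValueError(f"dt={dt} too coarse for half-duration T={profile.T}: "
                         "require dt <= T/5")
    n = int(round(profile.T / dt))
    t = np.arange(-n, n + 1) * dt
    s = bell_position(t, profile)
    x = start[0] + s * math.cos(heading)
    y = start[1] + s * math.sin(heading)
    v = bell_velocity(t, profile)
    a = bell_acceleration(t, profile)
    theta = np.full_like(t, wrap_angle(heading))
    data = np.column_stack([t, x, y, theta, v, a])
    meta = {"generator": "gen_center_out", "seed": seed,
            "v0": profile.v0, "T": profile.T, "dt": dt,
            "start": list(start), "heading": heading}
    return Trajectory(data, meta)


def gen_random_pursuit(spec: PursuitSpec) -> Trajectory:
    """A multi-target pursuit path of straight bell-speed segments.

    Each segment's duration is set so the bell speed integrates exactly to
    the segment length at the drawn peak speed (rounded to a whole number
    of sampling steps, with the peak rescaled accordingly, so the
    trajectory is uniformly sampled).  Speed and acceleration vanish at
    the targets; the heading changes discontinuously there (admissible,
    since the speed is zero).

    Metadata carries the ground-truth decomposition: per-sample ``segment``
    index, ``phase`` (0 acceleration, 1 deceleration) and the combined
    ``truth_labels`` (segment * 2 + phase) used for ARI scoring, plus the
    times of the true speed extrema.
    """
    rng = np.random.default_rng(spec.seed)
    dt = spec.dt
    rows = []
    segment_ids = []
    phases = []
    extrema_times = []
    t_start = 0.0
    for si, ((x0, y0), (x1, y1)) in enumerate(zip(spec.targets, spec.targets[1:])):
        length = math.hypot(x1 - x0, y1 - y0)
        heading = math.atan2(y1 - y0, x1 - x0)
        v_peak = rng.uniform(*spec.v0_range)
        # half-duration from the bell arc length, rounded to the dt grid
        half = 15.0 * length / (16.0 * v_peak)
        n_half = max(3, int(round(half / dt)))
        half = n_half * dt
        v_peak = 15.0 * length / (16.0 * half)
        prof = BellProfile(v0=v_peak, T=half)
        tau = np.arange(-n_half, n_half + 1) * dt  # local clock, peak at 0
        s = bell_position(tau, prof)
        keep = slice(1, None) if rows else slice(None)
        t_glob = t_start + (tau + half)
        seg = np.column_stack([
            t_glob,
            x0 + s * math.cos(heading),
            y0 + s * math.sin(heading),
            np.full_like(tau, wrap_angle(heading)),
            bell_velocity(tau, prof),
            bell_acceleration(tau, prof),
        ])
        rows.append(seg[keep])
        phase = (tau > 0).astype(int)
        segment_ids.append(np.full(len(tau), si, int)[keep])
        phases.append(phase[keep])
        extrema_times.append(t_start + half)          # speed maximum
        t_start += 2 * half
        if si < len(spec.targets) - 2:
            extrema_times.append(t_start)             # interior minimum
    data = np.vstack(rows)
    segment_ids = np.concatenate(segment_ids)
    phases = np.concatenate(phases)
    meta = {
        "generator": "gen_random_pursuit",
        "seed": spec.seed,
        "dt": dt,
        "targets": list(spec.targets),
        "v0_range": list(spec.v0_range),
        "segment": segment_ids,
        "phase": phases,
        "truth_labels": segment_ids * 2 + phases,
        "extrema_times": np.array(extrema_times),
    }
    return Trajectory(data, meta)


def speed_extrema_times(traj: Trajectory) -> np.ndarray:
    """Times of the interior local extrema of the speed profile.

    Ground truth for pursuit trajectories is taken from the generator
    metadata when present; otherwise extrema are located by a sign change
    of the discrete speed difference.
    """
    if "extrema_times" in traj.meta:
        return np.asarray(traj.meta["extrema_times"], float)
    v = traj.v
    dv = np.diff(v)
    sign = np.sign(dv)
    # ignore flat stretches by carrying the previous sign forward
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    change = np.nonzero(sign[1:] * sign[:-1] < 0)[0] + 1
    return traj.t[change]


def kinematics_from_path(t: Sequence[float], x: Sequence[float],
                         y: Sequence[float]) -> Trajectory:
    """Lift a raw planar path into the 6D feature space.

    Speed, direction and tangential acceleration are computed by central
    differences (one-sided at the ends): ``v = |(dx/dt, dy/dt)|``,
    ``theta = atan2(dy/dt, dx/dt)`` (unwrapped along the path, wrapped on
    storage), ``a = dv/dt``.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(t) < 5:
        raise ValueError("need at least 5 samples to lift a path")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing (no duplicates)")
    xdot = np.gradient(x, t)
    ydot = np.gradient(y, t)
    v = np.hypot(xdot, ydot)
    theta = np.unwrap(np.arctan2(ydot, xdot))
    a = np.gradient(v, t)
    data = np.column_stack([t, x, y, wrap_angle(theta), v, a])
    return Trajectory(data, {"generator": "kinematics_from_path", "lifted": True})


def gen_pd_curves(n_curves: int, orders: Sequence[int] = (2, 3, 4, 5),
                  noise_sd: float = 0.01, seed: int = 0,
                  n_samples: int = 60,
                  window: tuple[float, float] = (-0.07, 0.07)) -> dict:
    """Random polynomial preferred-direction curves with additive noise.

    Curves are polynomials of the requested orders on the reliable tuning
    window (default 70 ms either side of the strongest-tuning instant),
    all passing through ``theta(0) = 0`` (the fan convention), with iid
    Gaussian noise of standard deviation ``noise_sd`` (rad).

    Returns ``{name: (t, theta, coeffs)}`` where ``coeffs`` are the true
    ascending-power coefficients.
    """
    orders = list(orders)
    if not orders:
        raise ValueError("orders must be non-empty")
    if any(not 1 <= o <= 5 for o in orders):
        raise ValueError("orders must lie in 1..5")
    rng = np.random.default_rng(seed)
    t = np.linspace(window[0], window[1], n_samples)
    # coefficient scale chosen so that theta spans an O(1) range of radians
    # over the +-70 ms window (matching the spread of measured PD fans)
    half = max(abs(window[0]), abs(window[1]))
    curves = {}
    for i in range(n_curves):
        order = orders[i % len(orders)]
        coeffs = np.zeros(order + 1)
        coeffs[1:] = rng.uniform(-1.0, 1.0, order) / half ** np.arange(1, order + 1)
        theta = np.polynomial.polynomial.polyval(t, coeffs)
        theta = theta + rng.normal(0.0, noise_sd, n_samples)
        curves[f"curve_{i:02d}_ord{order}"] = (t.copy(), theta, coeffs)
    return curves
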