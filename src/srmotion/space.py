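"""The 6D kinematic feature space of motor-cortex movement coding.

A tuning point of the arm area of primary motor cortex is modelled as

    eta = (t, x, y, theta, v, a)

living on ``M = R^3_(t,x,y) x S^1_theta x R^2_(v,a)``: time, planar hand
position, movement direction, speed and tangential acceleration.  The
kinematic constraints (velocity points along ``theta``, ``a`` is the
derivative of ``v``) single out a rank-3 *horizontal* distribution spanned
by the vector fields

    X1 = v cos(theta) d/dx + v sin(theta) d/dy + a d/dv + d/dt
    X2 = d/dtheta
    X3 = d/da

Admissible tuning curves (time-varying preferred directions of single
neurons) are integral curves of ``X1 + p(t) X2 + q(t) X3`` with polynomial
controls ``p`` (degree <= 4) and ``q`` (degree <= 2).  Together with the
Lie brackets X4, X5, X6 the frame spans the full tangent space wherever
``v != 0`` (Hoermander / bracket-generating condition), so the space
carries a finite sub-Riemannian distance.

Coordinate order is fixed everywhere as ``(t, x, y, theta, v, a)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "COORD_NAMES",
    "FIELD_NAMES",
    "KinPoint",
    "CurveSpec",
    "Trajectory",
    "horizontal_frame",
    "vector_field",
    "lie_bracket",
    "hormander_rank",
    "integrate_curve",
    "generate_fan",
    "curve_family_parameters",
    "wrap_angle",
]

COORD_NAMES = ("t", "x", "y", "theta", "v", "a")

#: The horizontal frame and its brackets, in the order the theory names them.
FIELD_NAMES = ("X1", "X2", "X3", "X4", "X5", "X6")

#: Rank tolerance on singular values; well above double-precision noise
#: for O(1) matrix entries.
RANK_TOL = 1e-10


def wrap_angle(theta):
    """Wrap an angle (scalar or array) to ``[0, 2*pi)``."""
    return np.mod(theta, 2.0 * np.pi)


def _check_finite(name: str, *values) -> None:
    for val in values:
        if not np.all(np.isfinite(val)):
            raise ValueError(f"{name} must be finite, got {val!r}")


@dataclass(frozen=True)
class KinPoint:
    """A point ``eta = (t, x, y, theta, v, a)`` of the feature space.

    Units: seconds, metres, radians, m/s, m/s^2 (the homogeneous distance
    is not unit-invariant; metres keep speeds O(1)).  ``theta`` is
    wrapped to ``[0, 2*pi)`` on construction.  Speed is not constrained
    here (raw imported data may be noisy); generators only emit ``v >= 0``.
    """

    t: float
    x: float
    y: float
    theta: float
    v: float
    a: float

    def __post_init__(self) -> None:
        _check_finite("KinPoint", self.t, self.x, self.y, self.theta, self.v, self.a)
        object.__setattr__(self, "theta", float(wrap_angle(self.theta)))

    def as_array(self) -> np.ndarray:
        return np.array([self.t, self.x, self.y, self.theta, self.v, self.a], float)

    @staticmethod
    def from_array(arr: Sequence[float]) -> "KinPoint":
        t, x, y, theta, v, a = (float(c) for c in arr)
        return KinPoint(t, x, y, theta, v, a)


# ---------------------------------------------------------------------------
# Horizontal frame and Lie brackets
# ---------------------------------------------------------------------------

def _field_components(name: str, t, x, y, theta, v, a):
    """Closed-form components of the named field, order (t,x,y,theta,v,a)."""
    if name == "X1":
        return (1.0, v * math.cos(theta), v * math.sin(theta), 0.0, a, 0.0)
    if name == "X2":
        return (0.0, 0.0, 0.0, 1.0, 0.0, 0.0)
    if name == "X3":
        return (0.0, 0.0, 0.0, 0.0, 0.0, 1.0)
    if name == "X4":  # [X1, X2]
        return (0.0, v * math.sin(theta), -v * math.cos(theta), 0.0, 0.0, 0.0)
    if name == "X5":  # [X3, X1]
        return (0.0, 0.0, 0.0, 0.0, 1.0, 0.0)
    if name == "X6":  # [X5, X1]
        return (0.0, math.cos(theta), math.sin(theta), 0.0, 0.0, 0.0)
    raise ValueError(f"unknown vector field {name!r}; expected one of {FIELD_NAMES}")


def vector_field(name: str, p: KinPoint) -> np.ndarray:
    """Evaluate one of the named fields X1..X6 at ``p``."""
    return np.array(_field_components(name, *p.as_array()), float)


def horizontal_frame(p: KinPoint) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the horizontal frame (X1, X2, X3) at ``p``.

    X2 and X3 are the constant coordinate fields in ``theta`` and ``a``;
    X1 carries the kinematic constraints.
    """
    return vector_field("X1", p), vector_field("X2", p), vector_field("X3", p)


@lru_cache(maxsize=None)
def _symbolic_bracket(f: str, g: str) -> Callable:
    """Lambdified closed form of [f, g], computed symbolically once."""
    import sympy as sp

    coords = sp.symbols("t x y theta v a", real=True)
    t, x, y, theta, v, a = coords
    exprs = {
        "X1": sp.Matrix([1, v * sp.cos(theta), v * sp.sin(theta), 0, a, 0]),
        "X2": sp.Matrix([0, 0, 0, 1, 0, 0]),
        "X3": sp.Matrix([0, 0, 0, 0, 0, 1]),
        "X4": sp.Matrix([0, v * sp.sin(theta), -v * sp.cos(theta), 0, 0, 0]),
        "X5": sp.Matrix([0, 0, 0, 0, 1, 0]),
        "X6": sp.Matrix([0, sp.cos(theta), sp.sin(theta), 0, 0, 0]),
    }
    if f not in exprs or g not in exprs:
        raise ValueError(f"unknown vector field in bracket ({f!r}, {g!r})")
    F, G = exprs[f], exprs[g]
    JF = F.jacobian(coords)
    JG = G.jacobian(coords)
    bracket = sp.simplify(JG * F - JF * G)
    return sp.lambdify(coords, list(bracket), modules="numpy")


def lie_bracket(f: str, g: str, p: KinPoint) -> np.ndarray:
    """Lie bracket [f, g] of two named fields X1..X6, evaluated at ``p``.

    The bracket is derived symbolically from the closed-form fields (exact,
    no numerical differentiation).  The structural identities are

        [X1, X2] = X4,   [X3, X1] = X5,   [X5, X1] = X6.
    """
    fn = _symbolic_bracket(f, g)
    return np.asarray(fn(*p.as_array()), float)


def hormander_rank(p: KinPoint) -> int:
    """Rank of the 6x6 matrix stacking X1..X6 at ``p``.

    Equals 6 (the bracket-generating condition) on the open set ``v != 0``;
    X4 vanishes where ``v = 0`` and the rank drops to 5.  Rank is counted
    as the number of singular values above ``RANK_TOL``.
    """
    rows = np.array([vector_field(name, p) for name in FIELD_NAMES])
    svals = np.linalg.svd(rows, compute_uv=False)
    return int(np.sum(svals > RANK_TOL))


# ---------------------------------------------------------------------------
# Integral curves of the horizontal structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveSpec:
    """One admissible tuning curve: polynomial controls plus initial data.

    The curve solves ``gamma' = alpha1*X1 + p(t)*X2 + q(t)*X3`` with
    ``p(t) = k0 + k1 t + ... + k4 t^4`` (the preferred-direction speed
    ``dtheta/dt``) and ``q(t) = j0 + j1 t + j2 t^2`` (the jerk ``da/dt``),
    started from ``eta0`` at ``t = eta0.t`` and integrated symmetrically
    over ``[t0 - horizon, t0 + horizon]`` (or forward over
    ``[t0, t0 + horizon]`` with ``span="forward"``).

    ``alpha1`` modulates internal versus external time; the model's
    default identifies the two (``alpha1 = 1``).
    """

    theta_dot_coeffs: tuple[float, float, float, float, float]
    a_dot_coeffs: tuple[float, float, float]
    eta0: KinPoint
    horizon: float
    step: float
    span: str = "symmetric"
    alpha1: float = 1.0

    def __post_init__(self) -> None:
        if len(self.theta_dot_coeffs) != 5:
            raise ValueError("theta_dot_coeffs must have 5 entries (k0..k4)")
        if len(self.a_dot_coeffs) != 3:
            raise ValueError("a_dot_coeffs must have 3 entries (j0..j2)")
        _check_finite("CurveSpec", self.theta_dot_coeffs, self.a_dot_coeffs,
                      self.horizon, self.step, self.alpha1)
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.step > self.horizon / 10 + 1e-15:
            raise ValueError(
                f"step {self.step} too large for horizon {self.horizon}: "
                "require step <= horizon/10")
        if self.span not in ("symmetric", "forward"):
            raise ValueError("span must be 'symmetric' or 'forward'")
        object.__setattr__(self, "theta_dot_coeffs",
                           tuple(float(k) for k in self.theta_dot_coeffs))
        object.__setattr__(self, "a_dot_coeffs",
                           tuple(float(j) for j in self.a_dot_coeffs))

    def theta_dot(self, t):
        """The control p(t) = dtheta/dt."""
        return np.polynomial.polynomial.polyval(t, self.theta_dot_coeffs)

    def a_dot(self, t):
        """The control q(t) = da/dt."""
        return np.polynomial.polynomial.polyval(t, self.a_dot_coeffs)

    def to_dict(self) -> dict:
        return {
            "theta_dot": list(self.theta_dot_coeffs),
            "a_dot": list(self.a_dot_coeffs),
            "eta0": list(self.eta0.as_array()),
            "horizon": self.horizon,
            "step": self.step,
            "span": self.span,
            "alpha1": self.alpha1,
        }

    @staticmethod
    def from_dict(d: dict) -> "CurveSpec":
        return CurveSpec(
            theta_dot_coeffs=tuple(d["theta_dot"]),
            a_dot_coeffs=tuple(d["a_dot"]),
            eta0=KinPoint.from_array(d["eta0"]),
            horizon=float(d["horizon"]),
            step=float(d["step"]),
            span=d.get("span", "symmetric"),
            alpha1=float(d.get("alpha1", 1.0)),
        )


def curve_family_parameters() -> tuple[str, ...]:
    """Free parameters of the admissible curve family in a fan experiment.

    With initial time and position pinned at the fan's meeting point,
    the family is parametrised by the remaining initial components
    (theta0, v0, a0), the half-window T, the five coefficients of
    ``dtheta/dt`` and the three of ``da/dt`` -- a 12-dimensional space,
    matching the dimensionality found by principal-component analyses of
    measured preferred-direction trajectories.
    """
    initial = ("theta0", "v0", "a0")
    window = ("T",)
    theta_dot = tuple(f"k{i}" for i in range(5))
    a_dot = tuple(f"j{i}" for i in range(3))
    return initial + window + theta_dot + a_dot


@dataclass
class Trajectory:
    """A time-ordered, uniformly sampled sequence of feature-space points.

    ``data`` is an (n, 6) array in coordinate order (t, x, y, theta, v, a)
    with theta wrapped to [0, 2*pi).  ``meta`` records provenance
    (generator, seed, parameters).
    """

    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2 or self.data.shape[1] != 6:
            raise ValueError("Trajectory data must be (n, 6)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Trajectory contains non-finite values")
        t = self.data[:, 0]
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("Trajectory times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12 * max(1.0, abs(dt[0]))):
                raise ValueError("Trajectory must be uniformly sampled")
        self.data[:, 3] = wrap_angle(self.data[:, 3])

    def __len__(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, i: int) -> KinPoint:
        return KinPoint.from_array(self.data[i])

    @property
    def t(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def x(self) -> np.ndarray:
        return self.data[:, 1]

    @property
    def y(self) -> np.ndarray:
        return self.data[:, 2]

    @property
    def theta(self) -> np.ndarray:
        return self.data[:, 3]

    @property
    def v(self) -> np.ndarray:
        return self.data[:, 4]

    @property
    def a(self) -> np.ndarray:
        return self.data[:, 5]

    @property
    def dt(self) -> float:
        return float(self.data[1, 0] - self.data[0, 0]) if len(self) > 1 else 0.0

    def points(self) -> list[KinPoint]:
        return [KinPoint.from_array(row) for row in self.data]


def _rk4_step(state: np.ndarray, h: float, spec: CurveSpec) -> np.ndarray:
    def rhs(s):
        t, x, y, theta, v, a = s
        p = spec.theta_dot(t)
        q = spec.a_dot(t)
        a1 = spec.alpha1
        return np.array([
            a1,
            a1 * v * math.cos(theta),
            a1 * v * math.sin(theta),
            p,
            a1 * a,
            q,
        ])

    k1 = rhs(state)
    k2 = rhs(state + 0.5 * h * k1)
    k3 = rhs(state + 0.5 * h * k2)
    k4 = rhs(state + h * k3)
    return state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def integrate_curve(spec: CurveSpec) -> Trajectory:
    """Integrate one admissible tuning curve with a classical RK4 scheme.

    The state satisfies ``dt/ds = alpha1``, ``dx = v cos(theta)``,
    ``dy = v sin(theta)``, ``dtheta = p(t)``, ``dv = a``, ``da = q(t)``.
    ``theta`` is integrated unwrapped (no 2*pi jumps) and wrapped only on
    storage.  With ``span="symmetric"`` the curve covers
    ``[t0 - T, t0 + T]`` with the initial condition met exactly at ``t0``.
    """
    n = int(round(spec.horizon / spec.step))
    state0 = spec.eta0.as_array()

    def march(h: float, steps: int) -> list[np.ndarray]:
        out = []
        s = state0.copy()
        for _ in range(steps):
            s = _rk4_step(s, h, spec)
            out.append(s.copy())
        return out

    forward = march(spec.step, n)
    if spec.span == "symmetric":
        backward = march(-spec.step, n)
        rows = backward[::-1] + [state0] + forward
    else:
        rows = [state0] + forward
    data = np.array(rows)
    meta = {"generator": "integrate_curve", "spec": spec.to_dict()}
    return Trajectory(data, meta)


def generate_fan(specs: Sequence[CurveSpec]) -> list[Trajectory]:
    """Integrate a family of curves sharing the same initial point.

    All members meet at ``eta0``'s (x, y, theta) at the common initial
    time, reproducing the fan of time-dependent preferred-direction
    curves through a single cortical tuning point.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("generate_fan requires at least one CurveSpec")
    ref = specs[0]
    for s in specs[1:]:
        if s.eta0 != ref.eta0:
            raise ValueError("all CurveSpecs in a fan must share eta0")
        if not math.isclose(s.horizon, ref.horizon, rel_tol=1e-12):
            raise ValueError("all CurveSpecs in a fan must share the horizon")
    return [integrate_curve(s) for s in specs]
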