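"""Static motor-cortex tuning model and the neuronal population vector.

Single arm-area cells are cosine-tuned to movement direction,
``f(theta) = b + k cos(theta - theta_PD)``, and linearly tuned to hand
position, ``g(x, y) = b + alpha x + beta y``.  A population of cells
estimates the direction of hand movement through the population vector:
each cell contributes its preferred direction as a unit vector, weighted
by ``cos(theta - theta_PD)``.  In the continuum limit over a hypercolumn
the cosine weight is replaced by a Gaussian of the circular distance, and
the recovered direction is exact by symmetry.

The module also provides the time-dependent population activity estimate
on the 6D feature space: a kernel-weighted sum of single-cell spike
probabilities, with the connectivity weight given by the sub-Riemannian
heat kernel of :mod:`srmotion.distance`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .space import KinPoint, wrap_angle
from .distance import wrap_difference

__all__ = [
    "DirectionalTuning",
    "PositionalTuning",
    "CellEnsemble",
    "directional_rate",
    "positional_rate",
    "population_vector",
    "population_vector_continuous",
    "one_form_residual",
    "embed_point",
    "population_activity",
]


@dataclass(frozen=True)
class DirectionalTuning:
    """Cosine directional tuning: baseline b, modulation depth k, PD (rad)."""

    b: float
    k: float
    theta_pd: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("modulation depth k must be non-negative")
        object.__setattr__(self, "theta_pd", float(wrap_angle(self.theta_pd)))


@dataclass(frozen=True)
class PositionalTuning:
    """Linear positional gradient tuning: rate b at the origin, slopes alpha, beta."""

    b: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for val in (self.b, self.alpha, self.beta):
            if not math.isfinite(val):
                raise ValueError("PositionalTuning parameters must be finite")


@dataclass
class CellEnsemble:
    """A population of cells: positions, preferred directions, optional tuning.

    ``positions`` is (n, 2); ``theta_pd`` is (n,) wrapped to [0, 2*pi).
    """

    positions: np.ndarray
    theta_pd: np.ndarray
    b: np.ndarray | None = None
    k: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.theta_pd = wrap_angle(np.atleast_1d(np.asarray(self.theta_pd, float)))
        if self.positions.shape != (len(self.theta_pd), 2):
            raise ValueError("positions must be (n, 2) matching theta_pd")

    def __len__(self) -> int:
        return len(self.theta_pd)

    @staticmethod
    def uniform(n: int) -> "CellEnsemble":
        """n cells at the origin with PDs uniformly covering the circle."""
        pds = np.arange(n) * 2.0 * np.pi / n
        return CellEnsemble(np.zeros((n, 2)), pds)


def directional_rate(tuning: DirectionalTuning, theta: float) -> float:
    """Firing rate ``b + k cos(theta - theta_PD)``; maximal at the PD."""
    return tuning.b + tuning.k * math.cos(theta - tuning.theta_pd)


def positional_rate(tuning: PositionalTuning, x: float, y: float) -> float:
    """Firing rate ``b + alpha x + beta y`` of the positional gradient model."""
    return tuning.b + tuning.alpha * x + tuning.beta * y


def population_vector(ensemble: CellEnsemble, theta: float) -> np.ndarray:
    """Discrete population vector for movement direction ``theta``.

    Each cell contributes its unit PD vector weighted by
    ``cos(theta - theta_PD)``; for a dense uniform ensemble the direction
    of the sum recovers ``theta``.
    """
    if len(ensemble) == 0:
        raise ValueError("population_vector requires a non-empty ensemble")
    weights = np.cos(theta - ensemble.theta_pd)
    return np.array([
        np.sum(np.cos(ensemble.theta_pd) * weights),
        np.sum(np.sin(ensemble.theta_pd) * weights),
    ])


def population_vector_continuous(theta: float, quadrature_n: int = 1024) -> np.ndarray:
    """Continuum population vector over a full hypercolumn of directions.

    Quadrature of ``int_0^2pi e^{i theta'} exp(-dist(theta, theta')^2 / 2)
    dtheta'`` with the circular distance; returned as (Re, Im).  By
    rotational symmetry its direction equals ``theta`` and its magnitude
    does not depend on ``theta``.
    """
    if quadrature_n < 16:
        raise ValueError("quadrature_n must be at least 16")
    thetap = np.arange(quadrature_n) * 2.0 * np.pi / quadrature_n
    dist = wrap_difference(theta - thetap)
    weight = np.exp(-0.5 * dist**2)
    h = 2.0 * np.pi / quadrature_n
    return np.array([np.sum(np.cos(thetap) * weight) * h,
                     np.sum(np.sin(thetap) * weight) * h])


def one_form_residual(theta: float, displacement: Sequence[float]) -> float:
    """Pairing of the direction one-form with a planar displacement.

    ``omega = -sin(theta) dx + cos(theta) dy`` vanishes exactly on motion
    along the preferred direction ``(cos theta, sin theta)``: spiking is
    maximal when the displacement orthogonal to the PD is zero.
    """
    dx, dy = displacement
    return -math.sin(theta) * dx + math.cos(theta) * dy


def embed_point(eta: KinPoint, t_norm: float = 1.0,
                scales: Sequence[float] | None = None) -> np.ndarray:
    """Embed a feature point for the spike-probability inner product.

    A raw inner product of 6-tuples mixes units and is ill-defined on the
    circle, so the point is embedded as
    ``(t/t_norm, x, y, cos(theta), sin(theta), v, a)`` with optional
    per-component scales (default all 1).
    """
    vec = np.array([eta.t / t_norm, eta.x, eta.y,
                    math.cos(eta.theta), math.sin(eta.theta), eta.v, eta.a])
    if scales is not None:
        scales = np.asarray(scales, float)
        if scales.shape != (7,):
            raise ValueError("scales must have 7 components")
        vec = vec * scales
    return vec


def population_activity(eta0: KinPoint, samples: Sequence[KinPoint],
                        distance_fn: Callable[[KinPoint, KinPoint], float],
                        sigma: float = 1.0 / math.sqrt(2.0),
                        d_eta: float = 1.0,
                        t_norm: float = 1.0,
                        scales: Sequence[float] | None = None) -> float:
    """Discrete time-dependent population activity around ``eta0``.

    Sum over the sample set of ``h(eta) * exp(-d(eta0, eta)^2/(2 sigma^2))
    * d_eta`` where ``h(eta) = exp(<eta0, eta>)`` is the single-cell spike
    probability in the embedded inner product and the exponential kernel is
    the local connectivity weight.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("population_activity requires a non-empty sample set")
    v0 = embed_point(eta0, t_norm, scales)
    total = 0.0
    for eta in samples:
        h = math.exp(float(np.dot(v0, embed_point(eta, t_norm, scales))))
        d = distance_fn(eta0, eta)
        kern = 0.0 if math.isinf(d) else math.exp(-d * d / (2.0 * sigma**2))
        total += h * kern * d_eta
    return total
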