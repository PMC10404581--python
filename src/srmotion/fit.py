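"""Polynomial models of time-dependent tuning curves and bell-shaped speed.

Time-varying preferred-direction curves of single M1 neurons are well
described, over the ~140 ms window around the time of strongest tuning,
by polynomials of degree up to five (the derivative ``dtheta/dt`` being a
quartic).  This module provides the ordinary-least-squares machinery, the
goodness-of-fit metrics used to validate those models (R^2 and a
range-normalised RMSE), and the idealised quartic bell speed profile

    v(t) = v0 * ((t/T)^4 - 2 (t/T)^2 + 1) = v0 * (1 - (t/T)^2)^2

which matches measured centre-out speed profiles for v0 = 1.4 m/s
(140 cm/s) and T = 0.07 s.

NRMSE convention: RMSE divided by the observed range of the response
(max - min), which is dimensionless and well-behaved on bounded angle
curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PolyFit",
    "FitReport",
    "BellProfile",
    "polynomial_fit",
    "bell_velocity",
    "bell_acceleration",
    "fit_pd_table",
]


@dataclass(frozen=True)
class PolyFit:
    """A fitted polynomial in the original time domain.

    ``coefficients`` are ascending powers (c0 + c1 t + ...).  ``stderr``
    are the OLS standard errors of the coefficients (same order), from the
    unbiased residual-variance estimate.
    """

    order: int
    coefficients: np.ndarray
    stderr: np.ndarray
    domain: tuple[float, float]

    def __call__(self, t):
        return np.polynomial.polynomial.polyval(np.asarray(t, float),
                                                self.coefficients)


@dataclass(frozen=True)
class FitReport:
    """Goodness of fit: R^2, range-normalised RMSE, residuals."""

    r2: float
    nrmse: float
    residuals: np.ndarray


@dataclass(frozen=True)
class BellProfile:
    """Quartic bell speed profile: peak speed v0 (m/s), half-duration T (s).

    Defaults reproduce the measured centre-out profile (peak 140 cm/s).
    """

    v0: float = 1.4
    T: float = 0.07

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.T <= 0:
            raise ValueError("BellProfile requires v0 > 0 and T > 0")

    @property
    def path_length(self) -> float:
        """Arc length of one reach: integral of v over [-T, T] = 16 v0 T / 15."""
        return 16.0 * self.v0 * self.T / 15.0


def bell_velocity(t, profile: BellProfile):
    """Speed ``v0 ((t/T)^4 - 2 (t/T)^2 + 1)``; maximal v0 at t = 0, zero at +-T."""
    u = np.asarray(t, float) / profile.T
    return profile.v0 * (u**4 - 2.0 * u**2 + 1.0)


def bell_acceleration(t, profile: BellProfile):
    """Tangential acceleration dv/dt of the bell profile."""
    u = np.asarray(t, float) / profile.T
    return profile.v0 * (4.0 * u**3 - 4.0 * u) / profile.T


def bell_position(t, profile: BellProfile):
    """Arc length travelled since -T: the antiderivative of the bell speed."""
    T = profile.T
    u = np.asarray(t, float)

    def antider(s):
        return profile.v0 * (s**5 / (5 * T**4) - 2 * s**3 / (3 * T**2) + s)

    return antider(u) - antider(-T)


def polynomial_fit(t: Sequence[float], y: Sequence[float],
                   order: int) -> tuple[PolyFit, FitReport]:
    """Ordinary least squares in the monomial basis.

    The fit is performed on the domain rescaled to [-1, 1] for
    conditioning and mapped back; coefficients and their standard errors
    are reported in the original domain.  R^2 = 1 - SS_res / SS_tot,
    NRMSE = RMSE / (max y - min y).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if not 1 <= order <= 5:
        raise ValueError("order must be between 1 and 5")
    if len(t) < order + 2:
        raise ValueError(f"need at least order+2={order + 2} samples, got {len(t)}")
    t_lo, t_hi = float(np.min(t)), float(np.max(t))
    if t_hi <= t_lo:
        raise ValueError("degenerate design: all abscissae equal")

    # shift/scale to [-1, 1]
    mid, half = 0.5 * (t_lo + t_hi), 0.5 * (t_hi - t_lo)
    u = (t - mid) / half
    X = np.vander(u, order + 1, increasing=True)
    rank = np.linalg.matrix_rank(X)
    if rank < order + 1:
        raise ValueError(
            f"rank-deficient design matrix (rank {rank} < {order + 1}): "
            "abscissae do not support this polynomial order")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted

    dof = len(t) - (order + 1)
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov_u = sigma2 * np.linalg.inv(X.T @ X)

    # map coefficients (and their covariance) back to the t domain:
    # u = (t - mid)/half, so compose with the affine change of basis
    poly_u = np.polynomial.Polynomial(beta, domain=[t_lo, t_hi], window=[-1, 1])
    coeffs_t = poly_u.convert().coef
    coeffs_t = np.pad(coeffs_t, (0, order + 1 - len(coeffs_t)))
    # Jacobian of the basis change: row k of M gives t-basis coefficients
    # of u^k expanded in powers of t
    M = np.zeros((order + 1, order + 1))
    shift = np.polynomial.Polynomial([-mid / half, 1.0 / half])
    acc = np.polynomial.Polynomial([1.0])
    for k in range(order + 1):
        M[k, : len(acc.coef)] = acc.coef
        acc = acc * shift
    cov_t = M.T @ cov_u @ M
    stderr_t = np.sqrt(np.maximum(np.diag(cov_t), 0.0))

    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    rng = float(np.max(y) - np.min(y))
    rmse = math.sqrt(ss_res / len(t))
    nrmse = rmse / rng if rng > 0 else 0.0

    fit = PolyFit(order=order, coefficients=coeffs_t, stderr=stderr_t,
                  domain=(t_lo, t_hi))
    return fit, FitReport(r2=r2, nrmse=nrmse, residuals=resid)


def fit_pd_table(curves: Mapping[str, tuple[Sequence[float], Sequence[float]]],
                 orders: Sequence[int] = (2, 3, 4, 5)) -> pd.DataFrame:
    """Per-curve, per-order R^2 and NRMSE table with a final mean row.

    ``curves`` maps a curve name to its ``(t, theta)`` samples; each curve
    needs at least 7 samples.  The layout mirrors the standard report of
    polynomial approximations of preferred-direction curves: one row per
    curve, columns ``(metric, order)``, plus a ``"mean"`` row of column
    averages.
    """
    if not curves:
        raise ValueError("fit_pd_table requires at least one curve")
    orders = list(orders)
    rows = {}
    for name, (t, theta) in curves.items():
        if len(t) < 7:
            raise ValueError(f"curve {name!r} has fewer than 7 samples")
        row = {}
        for order in orders:
            _, report = polynomial_fit(t, theta, order)
            row[("r2", order)] = report.r2
            row[("nrmse", order)] = report.nrmse
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.columns = pd.MultiIndex.from_tuples(table.columns,
                                              names=["metric", "order"])
    table.loc["mean"] = table.mean(axis=0)
    return table
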