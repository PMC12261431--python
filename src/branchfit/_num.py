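"""Shared numerics: exponential-polynomial integrals, linear birth-death
transition laws, and numerical Laplace-transform inversion.

Everything here is vectorized over numpy arrays; these routines sit in the
inner loop of both the likelihood and the analytic sampling-time law.
"""

from __future__ import annotations

import numpy as np
from scipy.special import comb

__all__ = [
    "exp_poly_integral",
    "bd_p0_b",
    "bd_moment_coeffs",
    "euler_inversion_density",
    "euler_inversion_cdf",
]


def exp_poly_integral_scalar(t: float, a: float, r: int) -> float:
    """Scalar fast path of :func:`exp_poly_integral` (pure math ops)."""
    at = a * t
    if abs(at) < 1e-4:
        acc, term = 0.0, 1.0
        for m_ in range(8):
            if m_ > 0:
                term *= at / m_
            acc += term * (r / (r + m_))
        return t**r / r * acc
    import math

    J = math.expm1(at) / a
    eat = math.exp(at)
    for k in range(2, r + 1):
        J = (t ** (k - 1) * eat - (k - 1) * J) / a
    return J


def exp_poly_integral(t, a, r: int):
    """Integral of ``s^(r-1) * exp(a*s)`` over ``[0, t]`` for integer ``r >= 1``.

    ``t`` and ``a`` may be arrays (broadcast together); ``a`` may be any real
    including 0 and negative values.  Uses the stable upward recursion

        J_1 = expm1(a t) / a,   J_r = (t^(r-1) e^{a t} - (r-1) J_{r-1}) / a,

    with a power series fallback for ``|a t| < 1e-4``.
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(a, dtype=float)
    t, a = np.broadcast_arrays(t, a)
    at = a * t
    small = np.abs(at) < 1e-4
    a_safe = np.where(small, 1.0, a)

    # recursion branch
    J = np.expm1(a_safe * t) / a_safe
    eat = np.exp(a_safe * t)
    for k in range(2, r + 1):
        J = (t ** (k - 1) * eat - (k - 1) * J) / a_safe

    # series branch: J_r = t^r/r * sum_m (at)^m * r / ((r+m) m!)
    if np.any(small):
        acc = np.zeros_like(t)
        term = np.ones_like(t)
        for m in range(0, 8):
            if m > 0:
                term = term * at / m
            acc = acc + term * (r / (r + m))
        Js = t**r / r * acc
        J = np.where(small, Js, J)
    return J


def bd_p0_b(alpha, beta, u):
    """Extinction and geometric parameters of a linear birth-death process.

    For a process with per-cell birth rate ``alpha`` and death rate ``beta``
    started from one cell, the population after time ``u`` is 0 with
    probability ``p0`` and otherwise ``1 + NegBinomial(1, 1-b)`` (geometric
    with success probability ``1-b``):

        p0 = beta (w - 1) / (alpha w - beta),   b = alpha (w - 1) / (alpha w - beta)

    with ``w = exp((alpha-beta) u)``; the critical case uses the limit
    ``p0 = b = alpha u / (1 + alpha u)``.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    u = np.asarray(u, dtype=float)
    lam = alpha - beta
    crit = np.abs(lam) * np.maximum(u, 1.0) < 1e-10
    lam_safe = np.where(crit, 1.0, lam)
    w = np.exp(lam_safe * u)
    denom = alpha * w - beta
    p0 = np.where(crit, alpha * u / (1 + alpha * u), beta * (w - 1) / denom)
    b = np.where(crit, alpha * u / (1 + alpha * u), alpha * (w - 1) / denom)
    return p0, b


def bd_moment_coeffs(alpha: float, lam: float):
    """Coefficients of E[Z(u)^j] as polynomials in ``w = exp(lam*u)``.

    Returns ``(c1, c2, c3)`` where ``E[Z^j](u) = sum_k c_j[k] * w^(k+1)``
    (powers w, w^2, w^3).  Only valid for ``lam != 0``; the critical case is
    handled by the caller with polynomial-in-u forms
    E[Z]=1, E[Z^2]=2 alpha u + 1, E[Z^3]=6 alpha^2 u^2 + 6 alpha u + 1.
    """
    a, l = alpha, lam
    c1 = np.array([1.0, 0.0, 0.0])
    c2 = np.array([1.0 - 2 * a / l, 2 * a / l, 0.0])
    c3 = np.array(
        [1.0 - 6 * a / l + 6 * a**2 / l**2,
         6 * a / l - 12 * a**2 / l**2,
         6 * a**2 / l**2]
    )
    return c1, c2, c3


# ---------------------------------------------------------------------------
# Laplace inversion: Abate-Whitt Euler-summation algorithm on the Bromwich
# line.  The transform is only evaluated at Re(theta) > 0, which keeps every
# transform in this package inside its domain of analyticity.
# ---------------------------------------------------------------------------


def _euler_weights(M: int):
    xi = np.ones(2 * M + 1)
    xi[0] = 0.5
    xi[2 * M] = 2.0 ** (-M)
    for j in range(1, M):
        xi[2 * M - j] = xi[2 * M - j + 1] + 2.0 ** (-M) * comb(M, j)
    k = np.arange(2 * M + 1)
    beta_k = 10.0 ** (M / 3.0) * (-1.0) ** k * xi
    theta_k = M * np.log(10.0) / 3.0 + 1j * np.pi * k
    return beta_k, theta_k


_WEIGHT_CACHE: dict = {}


def _weights(M: int):
    if M not in _WEIGHT_CACHE:
        _WEIGHT_CACHE[M] = _euler_weights(M)
    return _WEIGHT_CACHE[M]


def euler_inversion_density(laplace, x, M: int = 16):
    """Invert a Laplace transform to a density at the points ``x > 0``.

    ``laplace`` must accept a complex numpy array and return the transform
    values elementwise.  Accuracy is roughly ``10^-M`` digits relative to the
    density scale for smooth densities.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x <= 0):
        raise ValueError("inversion points must be positive")
    beta_k, theta_k = _weights(M)
    theta = theta_k[None, :] / x[:, None]
    vals = laplace(theta)
    f = (beta_k[None, :] * np.real(vals)).sum(axis=1) / x
    return f


def euler_inversion_cdf(laplace, x, M: int = 16):
    """Invert a Laplace transform of a law to its CDF at the points ``x > 0``."""

    def lap_over_theta(theta):
        return laplace(theta) / theta

    return euler_inversion_density(lap_over_theta, x, M=M)
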