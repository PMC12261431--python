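"""Large-time limit laws of subclone sizes and the sampling-time law.

Model background
----------------
Each mutant subclone v grows as a linear birth-death process (birth alpha_v,
death beta) continuously seeded from its parent at rate nu_v per parent
cell, with the wild-type root held constant at C0 cells.  In the large-time
limit the size decomposes as

    C_v(t)  ~  C~_v * t^(r_v - 1) * exp(delta_v * t)

with (delta_v, r_v) the running-max growth pair of the lineage and C~_v a
time-independent random variable:

* root children:  C~_v is Gamma(C0 rho_v, scale phi_v) when lambda_v >= 0
  and Negative-Binomial(C0 rho_v, p = 1/phi_v) when lambda_v < 0, with
  rho_v = nu_v / alpha_v and phi_v the piecewise scale;
* deeper nodes:  the law of C~_v given the parent's C~ is characterized by
  a Laplace exponent h_v,  E[exp(-theta C~_v) | C~_pa = c] = exp(-h_v(theta) c),
  which is a genuine integral transform when the subclone is fitter than
  every ancestor (lambda_v > delta_pa) and degenerates to a linear exponent
  (a deterministic, hitchhiking child) when it is equally or less fit.

Conditioning on the parent uses the parent's *mean trajectory profile*
g_pa(s) — the exact conditional mean shape per unit C~_pa, e.g.
``exp(lambda s) - 1`` for a supercritical root child — rather than the bare
back-extrapolated factor ``s^(r-1) exp(delta s)``.  The two agree as
``s -> infinity`` but the profile keeps conditional means exact at all
orders of the lineage; profiles stay inside a small closed algebra of
``coef * s^k * exp(a s)`` terms, so every integral below is closed-form or
a single fixed-node quadrature.

The sampling event is an inhomogeneous Poisson process with hazard
Ctumor(t)/C_sampling; its survival function is the joint Laplace transform
of all C~_v evaluated at integrated-profile arguments, computed by folding
the exponents h_v leaf-to-root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from ._num import (
    bd_moment_coeffs,
    bd_p0_b,
    euler_inversion_cdf,
    euler_inversion_density,
    exp_poly_integral,
)
from .rates import ModelParams, SubcloneRates, shape_scale, tree_rates

__all__ = [
    "Profile",
    "SubcloneLaw",
    "deterministic_scale",
    "root_child_law",
    "child_law",
    "make_laplace_h",
    "finite_time_h",
    "conditional_cumulants",
    "conditional_density",
    "conditional_cdf",
    "LawTree",
    "sampling_survival",
    "sampling_density",
    "lifetime_risk_analytic",
]

_TIE_TOL = 1e-12


def deterministic_scale(t, delta, r):
    """Deterministic growth factor ``t^(r-1) * exp(delta t)``."""
    t = np.asarray(t, dtype=float)
    return t ** (r - 1) * np.exp(delta * t)


# -- mean-trajectory profiles -------------------------------------------------


@dataclass(frozen=True)
class Profile:
    """A function ``sum_j c_j s^(k_j) exp(a_j s)`` on ``s >= 0``.

    Closed under the seeding convolution ``int_0^s g(x) e^{lam (s-x)} dx``,
    which is how a child's mean trajectory arises from its parent's.
    """

    terms: tuple  # of (coef: float, a: float, k: int)

    @classmethod
    def constant(cls, value: float = 1.0) -> "Profile":
        return cls(((float(value), 0.0, 0),))

    def __call__(self, s):
        s = np.asarray(s, dtype=float)
        out = np.zeros_like(s)
        for c, a, k in self.terms:
            out = out + c * s**k * np.exp(a * s)
        return out

    def value(self, s: float) -> float:
        """Scalar evaluation (fast path for the likelihood inner loop)."""
        return sum(c * s**k * math.exp(a * s) for c, a, k in self.terms)

    def integral_to_scalar(self, t: float) -> float:
        from ._num import exp_poly_integral_scalar

        return sum(c * exp_poly_integral_scalar(t, a, k + 1)
                   for c, a, k in self.terms)

    def damped(self, s, d: float):
        """``g(s) * exp(-d s)`` evaluated overflow-safely (requires d >= max a)."""
        s = np.asarray(s, dtype=float)
        out = np.zeros_like(s)
        for c, a, k in self.terms:
            out = out + c * s**k * np.exp((a - d) * s)
        return out

    def dominant(self) -> tuple:
        """(coef, a, k) of the asymptotically leading term."""
        return max(self.terms, key=lambda t: (t[1], t[2]))

    def scaled(self, factor: float) -> "Profile":
        return Profile(tuple((c * factor, a, k) for c, a, k in self.terms))

    def integral_to(self, t):
        """``int_0^t g(s) ds`` (closed form, vectorized over ``t``)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c, a, k in self.terms:
            out = out + c * exp_poly_integral(t, a, k + 1)
        return out

    def laplace_at(self, theta: float) -> float:
        """``int_0^inf g(s) e^{-theta s} ds`` for ``theta > max a``."""
        out = 0.0
        for c, a, k in self.terms:
            b = theta - a
            if b <= 0:
                raise ValueError("profile Laplace transform diverges")
            out += c * math.factorial(k) / b ** (k + 1)
        return out

    def convolve_exp(self, lam: float, b_tol: float = 1e-9) -> "Profile":
        """``int_0^s g(x) e^{lam (s-x)} dx`` as a new Profile.

        ``b_tol`` is the threshold below which an exponent difference is
        treated as an exact tie (producing an ``s^{k+1}`` secular term);
        callers should scale it to the inverse of the relevant time horizon.
        """
        new: dict = {}

        def add(c, a, k):
            key = (round(a, 12), k)
            new[key] = new.get(key, (0.0, a, k))
            new[key] = (new[key][0] + c, a, k)

        for c, a, k in self.terms:
            b = a - lam
            if abs(b) <= b_tol:
                # near-tied exponents are snapped to lam so that secular
                # terms merge consistently with the exact-branch output
                add(c / (k + 1), lam, k + 1)
                continue
            # int_0^s x^k e^{b x} dx = e^{b s} sum_i (-1)^i k!/(k-i)! s^{k-i}/b^{i+1}
            #                          - (-1)^k k!/b^{k+1}
            for i in range(k + 1):
                coef = c * (-1.0) ** i * math.factorial(k) / math.factorial(k - i) / b ** (i + 1)
                add(coef, a, k - i)
            add(-c * (-1.0) ** k * math.factorial(k) / b ** (k + 1), lam, 0)
        terms = tuple((c, a, k) for (c, a, k) in new.values() if c != 0.0)
        return Profile(terms if terms else ((0.0, lam, 0),))


def child_profile(parent_profile: Profile, nu: float, lam: float,
                  b_tol: float = 1e-9) -> tuple:
    """(normalized child profile, conditional-mean slope m).

    ``m = nu * int g_pa(x) e^{-lam x} dx``-style leading coefficient: the
    asymptotic conditional mean of the child's C~ per unit of the parent's.
    """
    raw = parent_profile.convolve_exp(lam, b_tol=b_tol).scaled(nu)
    m, _, _ = raw.dominant()
    if m <= 0:
        raise ValueError("degenerate child profile (non-positive leading term)")
    return raw.scaled(1.0 / m), m


# -- Laplace exponents h ------------------------------------------------------

_LAGUERRE_CACHE: dict = {}
_LEGENDRE_CACHE: dict = {}


def _laggauss(n):
    if n not in _LAGUERRE_CACHE:
        _LAGUERRE_CACHE[n] = np.polynomial.laguerre.laggauss(n)
    return _LAGUERRE_CACHE[n]


def _leggauss(n):
    if n not in _LEGENDRE_CACHE:
        _LEGENDRE_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _LEGENDRE_CACHE[n]


def make_laplace_h(child: SubcloneRates, parent_delta: float, parent_r: int,
                   parent_profile: Profile | None = None,
                   n_quad: int = 48) -> Callable:
    """Asymptotic Laplace exponent of a non-root-child subclone.

    Returns ``h`` with ``E[exp(-theta C~_v) | C~_pa = c] = exp(-h(theta) c)``,
    selected by comparing the subclone's net growth rate with the parent's
    running max.  ``h`` accepts real or complex arrays with ``Re(theta) >= 0``.
    """
    nu, lam, alpha = child.nu, child.lam, child.alpha
    if parent_profile is None:
        dom = (1.0, parent_delta, parent_r - 1)
        parent_profile = Profile((dom,))

    if lam > parent_delta + _TIE_TOL:
        # fitter than every ancestor: single-seed limit contributions
        # W e^{-lam s} integrated against the parent mean profile
        omega = lam / alpha
        c = lam - parent_delta
        x, w = _laggauss(n_quad)
        s = x / c
        gdamp = parent_profile.damped(s, parent_delta)
        pref = nu * omega / c * w * gdamp
        decay = np.exp(-c * s)  # e^{-lam s} = e^{-c s} * e^{-delta_pa s}
        decay_full = decay * np.exp(-parent_delta * s)

        def h(theta):
            theta = np.asarray(theta)
            th = theta[..., None]
            vals = pref * th / (th * decay_full + omega)
            return vals.sum(axis=-1)

        h.kind = "fitter"
        h.slope = nu * parent_profile.laplace_at(lam)
        return h

    if abs(lam - parent_delta) <= _TIE_TOL:
        k = nu / parent_r
        kind = "equally_fit"
    else:
        k = nu / (parent_delta - lam)
        kind = "less_fit"

    def h(theta):
        return k * np.asarray(theta)

    h.kind = kind
    h.slope = k
    return h


def finite_time_h(child: SubcloneRates, beta: float, t: float,
                  parent_profile: Profile,
                  child_scale: float | None = None,
                  n_quad: int = 96) -> Callable:
    """Exact finite-time Laplace exponent given the parent's mean profile.

    Treats the parent trajectory on ``[0, t]`` as ``c~ g_pa(s)`` and uses the
    exact linear birth-death transition transform for each seeded clone, so
    the conditional law of the *rescaled* child size ``C_v(t)/child_scale``
    is ``exp(-h(theta) c~)`` with no large-time approximation.  Converges to
    :func:`make_laplace_h` as ``t`` grows.
    """
    if child_scale is None:
        child_scale = deterministic_scale(t, child.delta, child.r)
    nu, alpha = child.nu, child.alpha
    x, w = _leggauss(n_quad)
    s = 0.5 * t * (x + 1.0)
    wq = 0.5 * t * w
    u = t - s
    p0, b = bd_p0_b(alpha, beta, u)
    pref = nu * wq * parent_profile(s) * (1 - p0)

    def h(theta):
        theta = np.asarray(theta)
        z = np.exp(-theta[..., None] / child_scale)
        vals = pref * (1 - z) / (1 - b * z)
        return vals.sum(axis=-1)

    h.kind = "finite_time"
    return h


def conditional_cumulants(child: SubcloneRates, parent_profile: Profile,
                          t: float, child_scale: float | None = None) -> tuple:
    """First three cumulants of the rescaled child size per unit parent C~.

    Exact for compound-Poisson seeding from the parent mean profile on
    ``[0, t]``; multiply by ``c~_pa`` for the conditional cumulants.
    """
    if child_scale is None:
        child_scale = deterministic_scale(t, child.delta, child.r)
    from ._num import exp_poly_integral_scalar as J

    nu, alpha, lam = child.nu, child.alpha, child.lam
    kappa = []
    if abs(lam) * max(t, 1.0) > 1e-8:
        coeffs = bd_moment_coeffs(alpha, lam)
        for j, cj in enumerate(coeffs, start=1):
            total = 0.0
            for kpow, ck in enumerate(cj, start=1):
                if ck == 0.0:
                    continue
                # int_0^t g_pa(s) e^{kpow lam (t-s)} ds, term by term
                ekt = math.exp(kpow * lam * t)
                for c, a, k in parent_profile.terms:
                    total += ck * c * ekt * J(t, a - kpow * lam, k + 1)
            kappa.append(nu * total / child_scale**j)
    else:
        polys = [(1.0,), (1.0, 2 * alpha), (1.0, 6 * alpha, 6 * alpha**2)]
        for j, pj in enumerate(polys, start=1):
            total = 0.0
            for m, cm in enumerate(pj):
                if cm == 0.0:
                    continue
                for c, a, k in parent_profile.terms:
                    for q in range(m + 1):
                        total += (
                            cm * c * math.comb(m, q) * t ** (m - q) * (-1.0) ** q
                            * J(t, a, k + q + 1)
                        )
            kappa.append(nu * total / child_scale**j)
    return tuple(kappa)


def conditional_density(c_child, c_parent: float, h: Callable, M: int = 16):
    """Density of the child's rescaled size given the parent's, by inversion.

    For a linear exponent (non-fitter subclone) the conditional law is a
    point mass at ``slope * c_parent`` and the inversion returns a smoothed
    spike; callers needing a usable likelihood should use the finite-time
    cumulant route instead (see :mod:`branchfit.likelihood`).
    """
    if c_parent <= 0:
        raise ValueError("parent size must be positive")

    def lap(theta):
        return np.exp(-h(theta) * c_parent)

    return euler_inversion_density(lap, c_child, M=M)


def conditional_cdf(c_child, c_parent: float, h: Callable, M: int = 16):
    if c_parent <= 0:
        raise ValueError("parent size must be positive")

    def lap(theta):
        return np.exp(-h(theta) * c_parent)

    return euler_inversion_cdf(lap, c_child, M=M)


# -- subclone laws ------------------------------------------------------------


@dataclass
class SubcloneLaw:
    """Limiting law of one subclone's rescaled size ``C~_v``.

    ``kind`` is ``negative_binomial`` / ``gamma`` for root children and
    ``laplace_implicit`` for deeper subclones, whose law is reached through
    the exponent ``h`` and the parent's law.
    """

    kind: str
    delta: float
    r: int
    shape: float | None = None
    scale: float | None = None
    h: Callable | None = None
    parent: "SubcloneLaw | None" = None
    profile: Profile | None = None
    slope: float | None = None  # asymptotic conditional mean per unit parent C~
    rates: "SubcloneRates | None" = None
    C0: float | None = None
    beta: float | None = None

    def __post_init__(self):
        if self.kind in ("negative_binomial", "gamma"):
            if self.shape is None or self.shape <= 0 or self.scale is None or self.scale <= 0:
                raise ValueError(f"{self.kind} law needs positive shape and scale")
        elif self.kind == "laplace_implicit":
            if self.h is None or self.parent is None:
                raise ValueError("implicit law needs h and a parent law")
        else:
            raise ValueError(f"unknown law kind {self.kind!r}")

    # Laplace transform of the *marginal* law of C~_v
    def laplace(self, theta):
        theta = np.asarray(theta)
        if self.kind == "gamma":
            return (1.0 + self.scale * theta) ** (-self.shape)
        if self.kind == "negative_binomial":
            p = 1.0 / self.scale
            return (p / (1.0 - (1.0 - p) * np.exp(-theta))) ** self.shape
        return self.parent.laplace(self.h(theta))

    def mean(self) -> float:
        if self.kind == "gamma":
            return self.shape * self.scale
        if self.kind == "negative_binomial":
            p = 1.0 / self.scale
            return self.shape * (1.0 - p) / p
        return self.h.slope * self.parent.mean()

    def cdf(self, x, M: int = 16):
        """Marginal CDF of C~_v.

        Root children are closed-form.  A hitchhiking (non-fitter) subclone
        is asymptotically a deterministic multiple of its parent, so its CDF
        is the parent's at ``x / slope``.  A fitter subclone's marginal is
        obtained by numerically inverting the exact clone-cascade transform
        (every descendant clone resolved recursively, see
        :func:`cascade_laplace`), which correctly carries the parent-path
        randomness that the plain conditional composition would lose.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.kind == "gamma":
            return stats.gamma.cdf(x, self.shape, scale=self.scale)
        if self.kind == "negative_binomial":
            return stats.nbinom.cdf(np.floor(x), self.shape, 1.0 / self.scale)
        if self.h.kind in ("equally_fit", "less_fit"):
            return self.parent.cdf(x / self.h.slope, M=M)
        path, law = [], self
        while law is not None:
            path.append(law.rates)
            law = law.parent
        path = path[::-1]
        # the ODE-integrated transform carries ~1e-8 noise, which the Euler
        # inversion amplifies by 10^(M/3): cap the order accordingly
        lap = cascade_laplace(path, self.C0, self.beta, tau_step=0.01)
        out = np.zeros_like(x)
        pos = x > 0
        if np.any(pos):
            out[pos] = euler_inversion_cdf(lap, x[pos], M=min(M, 10))
        return np.clip(out, 0.0, 1.0)


def root_child_law(C0: float, rates: SubcloneRates, beta: float,
                   b_tol: float = 1e-9) -> SubcloneLaw:
    """Size law of a subclone seeded directly from the constant wild-type pool."""
    rho, scale = shape_scale(rates.lam, rates.alpha, beta, rates.nu)
    shape = C0 * rho
    if shape <= 0:
        raise ValueError("non-positive shape C0 * nu / alpha")
    kind = "negative_binomial" if rates.lam < 0 else "gamma"
    profile, m = child_profile(Profile.constant(), rates.nu, rates.lam, b_tol=b_tol)
    return SubcloneLaw(kind=kind, delta=rates.delta, r=rates.r,
                       shape=shape, scale=scale, profile=profile, slope=m,
                       rates=rates, C0=C0, beta=beta)


class _LazyFitterH:
    """Defers the quadrature setup of a fitter exponent until first use.

    Tree likelihood evaluations rarely need the fitter h itself (they use
    finite-time cumulants), so the Gauss-Laguerre preparation would be
    wasted work in the MCMC inner loop.
    """

    kind = "fitter"

    def __init__(self, rates, parent_delta, parent_r, parent_profile):
        self._args = (rates, parent_delta, parent_r, parent_profile)
        self.slope = rates.nu * parent_profile.laplace_at(rates.lam)
        self._real = None

    def __call__(self, theta):
        if self._real is None:
            self._real = make_laplace_h(*self._args[:3],
                                        parent_profile=self._args[3])
        return self._real(theta)


def child_law(parent: SubcloneLaw, rates: SubcloneRates,
              b_tol: float = 1e-9) -> SubcloneLaw:
    if rates.lam > parent.delta + _TIE_TOL:
        h = _LazyFitterH(rates, parent.delta, parent.r, parent.profile)
    else:
        h = make_laplace_h(rates, parent.delta, parent.r,
                           parent_profile=parent.profile)
    profile, m = child_profile(parent.profile, rates.nu, rates.lam, b_tol=b_tol)
    return SubcloneLaw(kind="laplace_implicit", delta=rates.delta, r=rates.r,
                       h=h, parent=parent, profile=profile, slope=m,
                       rates=rates, C0=parent.C0, beta=parent.beta)


# -- exact marginal transform of a fitter subclone ----------------------------


def cascade_laplace(path, C0: float, beta: float, tau_step: float = 0.02):
    """Exact marginal Laplace transform of a fitter subclone's C~.

    ``path`` lists the :class:`SubcloneRates` from the root child down to
    the target v, whose net growth rate ``delta = lambda_v`` strictly
    exceeds every ancestor's.  Let ``D_j`` be the contribution of a single
    type-``u_j`` cell (present at time 0) to ``C~_v`` through its entire
    descendant cascade, and ``f_j(x) = E[exp(-x D_j)]``.  A first-event
    decomposition (split / death / seed of the next type on the path) gives
    the Riccati-type system

        delta * x * f_j'(x) = alpha_j f_j^2 - (alpha_j + beta + nu_{j+1}) f_j
                              + beta + nu_{j+1} f_j f_{j+1},

    with the closed-form single-clone limit transform as the base case for
    the target.  The marginal transform then integrates root seeding:

        L(theta) = exp(-(C0 nu_1 / delta) * int_0^theta (1 - f_1(y))/y dy).

    The system is integrated in log-radius along complex rays (one per
    distinct phase of ``theta``), which is what the Bromwich-line inversion
    in :meth:`SubcloneLaw.cdf` requests.  Returns a callable mapping a
    complex array to ``L(theta)``.
    """
    path = list(path)
    target = path[-1]
    delta = target.lam
    alphas = np.array([r.alpha for r in path[:-1]])
    nus_next = np.array([path[j + 1].nu for j in range(len(path) - 1)])
    omega = target.lam / target.alpha
    a_t, b_t = beta / target.alpha, target.lam / target.alpha

    # linearization slopes m_j = E[D_j] for the small-x start
    m = [1.0]
    for j in range(len(path) - 2, -1, -1):
        m.insert(0, nus_next[j] * m[0] / (delta - path[j].lam))
    m = np.array(m)

    def f_target(x):
        return a_t + b_t * omega / (x + omega)

    def rhs(x, f):
        # f: (n_inner, n_rays) complex; returns df/dtau = RHS / delta
        nxt = np.empty_like(f)
        if f.shape[0] > 1:
            nxt[:-1] = f[1:]
        nxt[-1] = f_target(x)
        al = alphas[:, None]
        nu = nus_next[:, None]
        return (al * f * f - (al + beta + nu) * f + beta + nu * f * nxt) / delta

    def laplace(theta):
        theta = np.asarray(theta, dtype=complex)
        flat = theta.ravel()
        out = np.ones_like(flat)
        nz = np.abs(flat) > 0
        if not nz.any():
            return out.reshape(theta.shape)
        th = flat[nz]
        phases = np.round(np.angle(th), 10)
        res = np.empty_like(th)
        for ph in np.unique(phases):
            sel = phases == ph
            radii = np.abs(th[sel])
            d = np.exp(1j * ph)
            tau0 = math.log(min(1e-6 / max(m.max(), 1e-300), radii.min()))
            tau1 = math.log(radii.max())
            n_steps = max(int(math.ceil((tau1 - tau0) / tau_step)), 8)
            taus = np.linspace(tau0, tau1, n_steps + 1)
            dh = taus[1] - taus[0]
            x0 = np.exp(tau0) * d
            f = (1.0 - m[:-1, None] * x0).astype(complex)
            I_knots = np.empty(n_steps + 1, dtype=complex)
            if len(path) == 1:
                # target is itself a root child (closed form exists; kept
                # for uniformity): integrate (1 - f_target)/y directly
                vals = 1.0 - f_target(np.exp(taus) * d)
                I_knots = np.concatenate([[0.0], np.cumsum(
                    0.5 * (vals[1:] + vals[:-1]) * dh)])
            else:
                I_acc = 0.0 + 0j
                I_knots[0] = I_acc
                x = x0
                for i in range(n_steps):
                    g1 = 1.0 - f[0, 0]
                    k1 = rhs(x, f)
                    xm = np.exp(taus[i] + 0.5 * dh) * d
                    k2 = rhs(xm, f + 0.5 * dh * k1)
                    k3 = rhs(xm, f + 0.5 * dh * k2)
                    x = np.exp(taus[i + 1]) * d
                    k4 = rhs(x, f + dh * k3)
                    f = f + dh / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
                    g2 = 1.0 - f[0, 0]
                    I_acc = I_acc + 0.5 * (g1 + g2) * dh
                    I_knots[i + 1] = I_acc
            Ivals = np.interp(np.log(radii), taus, I_knots.real) + 1j * np.interp(
                np.log(radii), taus, I_knots.imag)
            res[sel] = np.exp(-(C0 * path[0].nu / delta) * Ivals)
        out[nz] = res
        return out.reshape(theta.shape)

    return laplace


# -- per-tree assembly --------------------------------------------------------


class LawTree:
    """All subclone laws of one mutation tree, with fold-based functionals."""

    def __init__(self, tree, params: ModelParams, rates: dict | None = None,
                 order=None):
        self.tree = tree
        self.params = params
        self.order = order if order is not None else tree.topological_order()
        if rates is None:
            rates = tree_rates(tree, params, order=self.order)
        self.rates = rates
        # exponent-tie threshold scaled to the observation horizon
        self.b_tol = 0.02 / max(params.t_max, 1.0)
        self.laws: dict = {}
        root = self.order[0]
        self.root_id = root
        for nid in self.order:
            if nid == root:
                continue
            if tree.parents[nid] == root:
                self.laws[nid] = root_child_law(params.C0, self.rates[nid],
                                                params.beta, b_tol=self.b_tol)
            else:
                self.laws[nid] = child_law(self.laws[tree.parents[nid]],
                                           self.rates[nid], b_tol=self.b_tol)
        self.profiles = {nid: law.profile for nid, law in self.laws.items()}
        self.slope = {nid: law.slope for nid, law in self.laws.items()}

    def marginal_cdf(self, nid: str, x, t: float, M: int = 16):
        """Analytic approximation of ``P(C_v(t) <= x)`` for raw counts ``x``.

        The rescaling uses the node's mean profile ``g_v(t)`` — equal to
        ``t^(r-1) exp(delta t)`` to leading order but with the finite-time
        subleading terms retained.
        """
        law = self.laws[nid]
        s = float(law.profile(np.asarray(t, dtype=float)))
        return law.cdf(np.asarray(x, dtype=float) / s, M=M)

    def joint_laplace(self, theta: dict) -> float:
        """``E[exp(-sum_v theta_v C~_v)]`` folded leaf-to-root.

        ``theta`` maps node id -> non-negative scalar; omitted nodes get 0.
        """
        tree = self.tree
        root = self.root_id
        eff = {nid: float(theta.get(nid, 0.0)) for nid in tree.nodes if nid != root}
        out = 1.0
        for nid in reversed(self.order):
            if nid == root:
                continue
            parent = tree.parents[nid]
            if parent == root:
                out *= float(self.laws[nid].laplace(np.array([eff[nid]]))[0])
            else:
                eff[parent] += float(self.laws[nid].h(np.array([eff[nid]]))[0])
        return out

    def ts_survival(self, t) -> np.ndarray:
        """Marginal ``P(Ts > t)``: sampling-time law folded over subclone laws."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t)
        Cs = self.params.C_sampling
        for i, ti in enumerate(t):
            theta = {
                nid: float(law.profile.integral_to(ti)) / Cs
                for nid, law in self.laws.items()
            }
            out[i] = self.joint_laplace(theta)
        return out


# -- plug-in sampling-time terms ---------------------------------------------


def sampling_survival(sizes, profiles, ts: float, C_sampling: float, t) -> np.ndarray:
    """``P(Ts > t)`` for deterministically back-extrapolated trajectories.

    ``sizes`` are subclone sizes at the reference time ``ts``; each
    trajectory is ``C~_v g_v(s)`` with ``C~_v = C_v(ts)/g_v(ts)`` and the
    integrated hazard is evaluated in closed form.
    """
    sizes = np.asarray(sizes, dtype=float)
    if np.any(sizes < 0):
        raise ValueError("negative trajectory values")
    t = np.asarray(t, dtype=float)
    lam_int = np.zeros_like(t, dtype=float)
    for size, g in zip(sizes, profiles):
        if size == 0:
            continue
        tilde = size / float(g(np.asarray(ts)))
        lam_int = lam_int + tilde * g.integral_to(t)
    return np.exp(-lam_int / C_sampling)


def sampling_density(sizes, profiles, ts: float, C_sampling: float) -> float:
    """Density of Ts at the sampling time: hazard times survival."""
    surv = float(sampling_survival(sizes, profiles, ts, C_sampling, ts))
    hazard = float(np.sum(np.asarray(sizes, dtype=float))) / C_sampling
    return hazard * surv


# -- analytic lifetime risk ---------------------------------------------------


def lifetime_risk_analytic(params: ModelParams, max_mutations: int = 2,
                           genes=None) -> float:
    """``P(Ts <= t_max)`` under the complete candidate tree of genotypes.

    Builds the tree of all single mutants plus, for ``max_mutations >= 2``,
    every ordered (parent mutation, second mutation) channel, and folds the
    sampling-time law through it.  Triple and higher mutants are neglected:
    with realistic per-mutation rates their expected contribution to tumor
    size at diagnosis is orders of magnitude below the double mutants'.
    """
    tree = _candidate_tree(params.n, tuple(genes) if genes is not None else None,
                           max_mutations)
    lt = LawTree(tree, params)
    return float(1.0 - lt.ts_survival(params.t_max)[0])


_CANDIDATE_CACHE: dict = {}


def _candidate_tree(n: int, genes, max_mutations: int):
    from .trees import MutationTree

    key = (n, genes, max_mutations)
    if key not in _CANDIDATE_CACHE:
        gene_list = list(range(1, n + 1)) if genes is None else list(genes)
        edges = [(None, "root", frozenset())]
        for i in gene_list:
            edges.append(("root", f"s{i}", frozenset([i])))
            if max_mutations >= 2:
                for j in gene_list:
                    if j != i:
                        edges.append((f"s{i}", f"d{i}_{j}", frozenset([j])))
        _CANDIDATE_CACHE[key] = MutationTree.from_edges(edges)
    return _CANDIDATE_CACHE[key]
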