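"""Per-tree probability and the selection-bias-corrected cohort likelihood.

The probability of observing a tree ``T`` at sampling time ``ts`` factorizes
over the tree:

    p(T, ts) =  prod_{root children} p(c_v)          (explicit size laws)
              * prod_{deeper nodes}  p(c_v | c_pa)   (conditional size laws)
              * p(ts | c_T)                          (sampling-time density)
              * p(c'_T | c_T)                        (sequencing subsample)

with latent subclone sizes plugged in from the observed cell fractions.
The cohort log-likelihood sums tree terms and subtracts ``N log zeta`` with
``zeta = P(Ts <= t_max)``, correcting for the fact that only diagnosed
(observable) patients enter a cohort.

Numerical treatment of the conditional terms
--------------------------------------------
The asymptotic conditional law of a subclone that is not fitter than its
ancestors is a point mass, which cannot enter a likelihood.  Deep-node
conditionals are therefore evaluated under the finite-time compound-Poisson
law of seeds from the parent's mean trajectory: its first three cumulants
are closed-form, and the density is a moment-matched Pearson-III
(shifted-gamma) kernel, falling back to numerical Laplace inversion of the
exact finite-time transform when the skewness is extreme.  This converges
to the asymptotic theory at large times, stays finite for every observed
configuration, and is continuous in the fitness matrix across
equal-fitness boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from ._num import euler_inversion_density
from .laws import LawTree, conditional_cumulants, finite_time_h
from .rates import ModelParams

__all__ = [
    "LatentCounts",
    "LikelihoodConfig",
    "TreeLikelihoodBreakdown",
    "estimate_true_counts",
    "seq_log_prob",
    "tree_log_prob",
    "lifetime_risk",
    "cohort_log_likelihood",
]


class LikelihoodError(ValueError):
    pass


@dataclass
class LatentCounts:
    """Estimated true subclone sizes at sampling, one per mutant node."""

    sizes: dict                 # node id -> int latent cells
    c_tumor: float

    def total(self) -> float:
        return float(sum(self.sizes.values()))


@dataclass(frozen=True)
class LikelihoodConfig:
    """Numerical knobs of the tree likelihood.

    skew_normal_below : use a plain normal kernel when the conditional
        skewness is below this (the Pearson-III shape would be enormous).
    skew_invert_above : switch from Pearson-III to numerical inversion of
        the finite-time transform above this skewness.
    inversion_M : Euler-summation order of the Laplace inversion.
    ts_quadrature_nodes : Gauss-Legendre nodes for integrating out a
        missing sampling time over (0, t_max].
    zeta_mode : "analytic" (fold of the sampling-time law), "mc"
        (simulation-based lifetime risk) or "fixed" (user constant).
    zeta_sims : replicates for the "mc" mode.
    """

    skew_normal_below: float = 0.02
    skew_invert_above: float = 6.0
    inversion_M: int = 10
    cond_quad_nodes: int = 40
    ts_quadrature_nodes: int = 64
    zeta_mode: str = "analytic"
    zeta_sims: int = 200
    zeta_seed: int = 0


DEFAULT_CONFIG = LikelihoodConfig()


@dataclass
class TreeLikelihoodBreakdown:
    """Log-probability of one tree, split into its factors."""

    node_terms: dict = field(default_factory=dict)
    sampling_term: float = 0.0
    seq_term: float = 0.0

    @property
    def total(self) -> float:
        return float(sum(self.node_terms.values()) + self.sampling_term + self.seq_term)

    def flagged_nodes(self) -> list:
        return [nid for nid, v in self.node_terms.items() if not np.isfinite(v)]


# -- latent sizes -------------------------------------------------------------


def estimate_true_counts(tree, order=None) -> LatentCounts:
    """Scale observed fractions to tumor size with largest-remainder rounding.

    ``C_v = round(C'_v / C_seq * C_tumor)`` such that the latent sizes sum
    exactly to the (rounded) tumor size; zero-count nodes stay at zero.
    """
    if tree.c_tumor is None:
        raise LikelihoodError(
            f"tree {tree.patient_id!r}: C_tumor is required to scale counts"
        )
    c_seq = tree.c_seq
    if c_seq is None or c_seq <= 0:
        raise LikelihoodError(f"tree {tree.patient_id!r}: C_seq missing or zero")
    target = int(round(tree.c_tumor))
    nids = tree.mutant_nodes() if order is None else [
        nid for nid in order[1:]
    ]
    raw = np.array([tree.nodes[nid].count / c_seq * target for nid in nids])
    floors = np.floor(raw).astype(np.int64)
    short = target - int(floors.sum())
    order = np.argsort(-(raw - floors), kind="stable")
    sizes = floors.copy()
    for i in range(short):
        sizes[order[i % len(nids)]] += 1
    out = {nid: int(s) for nid, s in zip(nids, sizes)}
    return LatentCounts(sizes=out, c_tumor=float(target))


def _log_choose(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def seq_log_prob(latent: LatentCounts, observed: dict, c_seq: int) -> float:
    """Multivariate hypergeometric log-probability of the sequenced counts.

    Evaluated with log-gamma so non-integer latent sizes are accepted.
    """
    total_obs = sum(observed.values())
    if total_obs != c_seq:
        raise LikelihoodError(f"observed counts sum to {total_obs}, expected C_seq={c_seq}")
    lp = -_log_choose(latent.c_tumor, c_seq)
    for nid, k in observed.items():
        n = latent.sizes.get(nid, 0)
        if k > n:
            raise LikelihoodError(f"node {nid!r}: observed {k} exceeds latent {n}")
        lp += _log_choose(n, k)
    return float(lp)


# -- conditional node terms ---------------------------------------------------


def _gamma_logpdf(x: float, shape: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return float((shape - 1.0) * math.log(x) - x / scale
                 - shape * math.log(scale) - gammaln(shape))


def _pearson3_logpdf(x: float, k1: float, k2: float, k3: float,
                     config: LikelihoodConfig) -> float:
    def normal():
        return float(-0.5 * math.log(2 * math.pi * k2) - 0.5 * (x - k1) ** 2 / k2)

    gamma1 = k3 / k2**1.5
    if gamma1 < config.skew_normal_below:
        return normal()
    shape = 4.0 / gamma1**2
    scale = k3 / (2.0 * k2)
    shift = k1 - shape * scale
    if x <= shift:
        # below the matched-gamma support: the true compound-Poisson left
        # tail is astronomically thin but not empty; score it with the
        # normal kernel so the likelihood stays finite for bad proposals
        return normal()
    return _gamma_logpdf(x - shift, shape, scale)


def _root_child_logpdf(law, latent_size: float, ts: float) -> float:
    g_ts = law.profile.value(ts)
    c_tilde = latent_size / g_ts
    if law.kind == "gamma":
        return _gamma_logpdf(c_tilde, law.shape, law.scale) - math.log(g_ts)
    # stationary negative binomial on the raw-count scale
    k = round(latent_size)
    p = 1.0 / law.scale
    n = law.shape
    return float(gammaln(k + n) - gammaln(n) - gammaln(k + 1)
                 + n * math.log(p) + k * math.log1p(-p))


def tree_log_prob(tree, ts: float, params: ModelParams,
                  config: LikelihoodConfig = DEFAULT_CONFIG,
                  latent: LatentCounts | None = None,
                  phi_cache: dict | None = None) -> TreeLikelihoodBreakdown:
    """Log-probability breakdown of one tree at a known sampling time.

    Zero-latent (unobserved internal or augmented) nodes contribute no size
    term; their observed descendants condition on the nearest ancestor with
    positive latent size, with the intermediates' sizes replaced by their
    conditional means.
    """
    if ts is None or ts <= 0:
        raise LikelihoodError("sampling time must be positive; integrate it out otherwise")
    from .rates import tree_rates

    order = tree.topological_order()
    rates = tree_rates(tree, params, order=order, phi_cache=phi_cache)
    lt = LawTree(tree, params, rates=rates, order=order)
    if latent is None:
        latent = estimate_true_counts(tree, order=order)
    root = lt.root_id
    mutants = [nid for nid in lt.order if nid != root]
    bd = TreeLikelihoodBreakdown()

    for nid in mutants:
        size = latent.sizes.get(nid, 0)
        if size <= 0:
            continue
        parent = tree.parents[nid]
        if parent == root:
            bd.node_terms[nid] = _root_child_logpdf(lt.laws[nid], size, ts)
            continue
        # nearest ancestor with positive latent size; plug in conditional
        # means (slope products) for the zero-size intermediates
        anc, slope_prod = parent, 1.0
        while anc != root and latent.sizes.get(anc, 0) <= 0:
            slope_prod *= lt.slope[anc]
            anc = tree.parents[anc]
        if anc == root:
            c_anchor = params.C0
        else:
            c_anchor = latent.sizes[anc] / lt.profiles[anc].value(ts)
        c_eff = c_anchor * slope_prod  # effective parent C~ (direct parent units)
        rates_v = lt.rates[nid]
        parent_profile = lt.profiles[parent]
        k1, k2, k3 = conditional_cumulants(rates_v, parent_profile, ts, child_scale=1.0)
        k1, k2, k3 = k1 * c_eff, k2 * c_eff, k3 * c_eff
        if k2 <= 0 or not np.isfinite(k2):
            bd.node_terms[nid] = -np.inf
            continue
        gamma1 = k3 / k2**1.5
        term = None
        if gamma1 > config.skew_invert_above:
            # strongly skewed: invert the exact finite-time transform; fall
            # back to the moment-matched kernel when the density is below
            # the inversion noise floor (deep tails)
            h = finite_time_h(rates_v, params.beta, ts, parent_profile,
                              child_scale=1.0, n_quad=config.cond_quad_nodes)

            def lap(theta, _h=h, _c=c_eff):
                return np.exp(-_h(theta) * _c)

            dens = float(euler_inversion_density(lap, np.array([float(size)]),
                                                 M=config.inversion_M)[0])
            if dens > 0 and np.isfinite(dens):
                term = math.log(dens)
        if term is None:
            term = _pearson3_logpdf(float(size), k1, k2, k3, config)
        bd.node_terms[nid] = term

    # plug-in sampling-time density: hazard times back-extrapolated survival
    lam_int, total = 0.0, 0.0
    for nid in mutants:
        s = latent.sizes.get(nid, 0)
        if s > 0:
            g = lt.profiles[nid]
            lam_int += s / g.value(ts) * g.integral_to_scalar(ts)
            total += s
    if total > 0:
        bd.sampling_term = (math.log(total / params.C_sampling)
                            - lam_int / params.C_sampling)
    else:
        bd.sampling_term = -np.inf

    observed = {nid: tree.nodes[nid].count for nid in mutants}
    c_seq = tree.c_seq if tree.c_seq else sum(observed.values())
    bd.seq_term = seq_log_prob(latent, observed, c_seq)
    return bd


def _tree_log_prob_marginal_ts(tree, params: ModelParams,
                               config: LikelihoodConfig) -> float:
    """Tree log-probability with the sampling time integrated over (0, t_max]."""
    from .laws import _leggauss

    x, w = _leggauss(config.ts_quadrature_nodes)
    lo, hi = 1e-3 * params.t_max, params.t_max
    ts_nodes = 0.5 * (hi - lo) * (x + 1.0) + lo
    wq = 0.5 * (hi - lo) * w
    logs = np.empty_like(ts_nodes)
    for i, ts in enumerate(ts_nodes):
        logs[i] = tree_log_prob(tree, float(ts), params, config).total
    return float(logsumexp(logs, b=wq))


# -- lifetime risk and cohort likelihood --------------------------------------


def lifetime_risk(params: ModelParams, rule=None, n_sim: int = 200,
                  seed: int = 0) -> tuple:
    """Monte-Carlo ``P(Ts <= t_max | params)`` with its standard error.

    Deterministic given ``seed``; forward-simulates patients and counts the
    fraction whose sampling event precedes ``t_max``.
    """
    from .simulate import SimConfig, simulate_tree
    from .trees import ISA

    rule = rule if rule is not None else ISA
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sim):
        res = simulate_tree(SimConfig(params=params, rule=rule), rng=rng)
        hits += res.sampling_time is not None
    zeta = hits / n_sim
    se = math.sqrt(max(zeta * (1 - zeta), 1.0 / n_sim) / n_sim)
    return zeta, se


def cohort_log_likelihood(cohort, params: ModelParams,
                          zeta_hat: float | None = None,
                          config: LikelihoodConfig = DEFAULT_CONFIG) -> float:
    """Selection-bias-corrected cohort log-likelihood.

    ``sum_j w_j log p(T_j, ts_j | params) - (sum_j w_j) log zeta_hat``;
    trees without a sampling time contribute their ts-marginalized
    probability.  ``zeta_hat = None`` disables the observability correction
    (equivalent to ``zeta_hat = 1``).
    """
    if zeta_hat is not None and not 0.0 < zeta_hat <= 1.0:
        raise LikelihoodError("zeta_hat must lie in (0, 1]")
    total, wsum = 0.0, 0.0
    phi_cache: dict = {}  # shared across trees within this evaluation of F
    for tree in cohort:
        w = tree.weight
        wsum += w
        if tree.sampling_time is not None:
            total += w * tree_log_prob(tree, tree.sampling_time, params,
                                       config, phi_cache=phi_cache).total
        else:
            total += w * _tree_log_prob_marginal_ts(tree, params, config)
    if zeta_hat is not None:
        total -= wsum * math.log(zeta_hat)
    return float(total)
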