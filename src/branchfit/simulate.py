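"""Stochastic simulation of the tree-structured branching process.

The generative process: a constant wild-type pool of ``C0`` cells seeds
mutant subclones; each mutant cell divides at rate ``alpha_v``, dies at the
common rate ``beta``, and seeds admissible child subclones at the child's
mutation rate; diagnosis (the sampling event) arrives as an inhomogeneous
Poisson event with hazard ``Ctumor(t) / C_sampling``; the process stops at
the sampling time or at ``t_max``.

Stepping scheme
---------------
Time advances in fixed increments ``dt``.  Within a step every subclone's
birth-death dynamics are advanced with the *exact* linear birth-death
transition law (binomial survivors plus negative-binomial offspring), so
there is no tau-leaping error in the growth channels at any population
size; only the mutation-seeding flux and the sampling hazard are frozen at
the step's average populations, giving O(dt) coupling error.  New subclone
types are created when their first cell appears, subject to the expansion
rule; the infinite-sites rule admits only mutations unused anywhere in the
tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .rates import (
    ModelParams,
    log_birth_death_ratio,
    net_growth,
)
from .trees import ISA, Cohort, ExpansionRule, MutationTree, SubcloneNode, prune_unobserved

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_tree",
    "sequence_cells",
    "simulate_cohort",
    "simulate_fixed_topology",
    "benchmark_scenario",
    "BenchmarkResult",
]


@dataclass
class SimConfig:
    """Simulation controls: model parameters, expansion rule, step size."""

    params: ModelParams
    rule: ExpansionRule = ISA
    dt: float = 0.05
    seed: int | None = None
    keep_censored: bool = False  # cohort mode: keep trees with ts > t_max

    def __post_init__(self):
        if not 0 < self.dt:
            raise ValueError("dt must be positive")


@dataclass
class SimResult:
    """Full simulated tree with true counts and the sampling outcome."""

    tree: MutationTree
    sampling_time: float | None
    t_end: float
    n_events: int = 0


class _BDCache:
    """Per-(alpha, dt) exact birth-death transition parameters."""

    def __init__(self, beta: float, dt: float):
        self.beta, self.dt = beta, dt
        self.cache: dict = {}

    def get(self, alpha: float):
        if alpha not in self.cache:
            from ._num import bd_p0_b

            p0, b = bd_p0_b(alpha, self.beta, self.dt)
            self.cache[alpha] = (float(p0), float(b))
        return self.cache[alpha]


def _bd_step(rng, x: int, p0: float, b: float) -> int:
    """Exact one-step transition of a linear birth-death population."""
    if x == 0:
        return 0
    surv = rng.binomial(x, 1.0 - p0)
    if surv == 0:
        return 0
    return int(surv + rng.negative_binomial(surv, 1.0 - b))


def simulate_tree(config: SimConfig, rng=None) -> SimResult:
    """Simulate one patient's tumor until sampling or ``t_max``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.params
    mu, beta, dt = p.mu, p.beta, config.dt
    bd = _BDCache(beta, dt)
    bd_half = _BDCache(beta, dt / 2.0)  # matures seeds born mid-step

    # node records: parallel lists; extinct childless nodes are tombstoned
    # and release their mutation, so a failed early seed does not block the
    # genotype space forever
    genos: list = [frozenset()]
    counts: list = [0]  # root count unused; wild-type fixed at C0
    alphas: list = [beta]
    parent_idx: list = [-1]
    nus: list = [0.0]
    children: list = [[]]
    alive: list = [True]
    used: set = set()
    n_events = 0

    t = 0.0
    hazard_acc = 0.0
    hazard_target = rng.exponential()
    ts: float | None = None
    while t < p.t_max:
        step = min(dt, p.t_max - t)
        if step < dt:
            bd = _BDCache(beta, step)
        tumor_old = sum(c for v, c in enumerate(counts) if v and alive[v])
        old_counts = counts.copy()
        for v in range(1, len(counts)):
            if not alive[v]:
                continue
            p0, b = bd.get(alphas[v])
            counts[v] = _bd_step(rng, counts[v], p0, b)
        # seeding: existing channels then new-type creation
        n_existing = len(genos)
        for v in range(n_existing):
            if not alive[v]:
                continue
            x_par = p.C0 if v == 0 else 0.5 * (old_counts[v] + counts[v])
            if x_par <= 0:
                continue
            for c in children[v]:
                if not alive[c]:
                    continue
                k = rng.poisson(nus[c] * x_par * step)
                if k:
                    p0h, bh = bd_half.get(alphas[c])
                    counts[c] += _bd_step(rng, int(k), p0h, bh)
                    n_events += 1
            for m in range(1, p.n + 1):
                if config.rule.name == "ISA":
                    if m in used:
                        continue
                elif m in genos[v]:
                    continue
                k = rng.poisson(mu[m - 1] * x_par * step)
                if k:
                    genos.append(genos[v] | {m})
                    alpha_new = net_growth(
                        log_birth_death_ratio(genos[-1], p.F), beta)[2]
                    p0h, bh = bd_half.get(alpha_new)
                    counts.append(_bd_step(rng, int(k), p0h, bh))
                    alphas.append(alpha_new)
                    parent_idx.append(v)
                    nus.append(float(mu[m - 1]))
                    children.append([])
                    children[v].append(len(genos) - 1)
                    alive.append(True)
                    used.add(m)
                    n_events += 1
        # tombstone extinct childless subclones, freeing their mutations
        changed = True
        while changed:
            changed = False
            for v in range(1, len(genos)):
                if not alive[v] or counts[v] > 0:
                    continue
                if any(alive[c] for c in children[v]):
                    continue
                alive[v] = False
                used.difference_update(genos[v] - genos[parent_idx[v]])
                changed = True
        tumor_new = sum(c for v, c in enumerate(counts) if v and alive[v])
        inc = step * 0.5 * (tumor_old + tumor_new) / p.C_sampling
        if hazard_acc + inc >= hazard_target and inc > 0:
            frac = (hazard_target - hazard_acc) / inc
            ts = t + frac * step
            t = ts
            break
        hazard_acc += inc
        t += step

    tree = MutationTree(patient_id="sim")
    tree.nodes["root"] = SubcloneNode(id="root", genotype=frozenset())
    tree.parents["root"] = None
    ids = ["root"]
    for v in range(1, len(genos)):
        nid = "n" + "_".join(map(str, sorted(genos[v])))
        if nid in tree.nodes:  # relaxed rules can repeat a genotype
            nid = f"{nid}.{v}"
        ids.append(nid)
        if not alive[v]:
            continue
        tree.nodes[nid] = SubcloneNode(
            id=nid,
            new_mutations=genos[v] - genos[parent_idx[v]],
            count=int(counts[v]),
            genotype=genos[v],
        )
        tree.parents[nid] = ids[parent_idx[v]]
    tree.sampling_time = ts
    tree.c_tumor = float(sum(c for v, c in enumerate(counts) if v and alive[v]))
    tree.c_seq = None
    return SimResult(tree=tree, sampling_time=ts, t_end=t, n_events=n_events)


def _mv_hypergeometric(rng, colors: np.ndarray, nsample: int) -> np.ndarray:
    """Multivariate hypergeometric draw; multinomial limit for huge urns."""
    total = int(colors.sum())
    if nsample > total:
        raise ValueError(f"cannot sample {nsample} cells from {total}")
    if total <= 10**8:
        return rng.multivariate_hypergeometric(colors, nsample, method="marginals")
    # sampling fraction is negligible: without-replacement ~ with-replacement
    return rng.multinomial(nsample, colors / total)


def sequence_cells(result: SimResult, c_seq: int, rng=None,
                   seed: int | None = None) -> MutationTree:
    """Subsample ``c_seq`` cells without replacement and prune empty leaves."""
    if rng is None:
        rng = np.random.default_rng(seed)
    tree = result.tree
    nids = tree.mutant_nodes()
    colors = np.array([tree.nodes[nid].count for nid in nids], dtype=np.int64)
    obs = _mv_hypergeometric(rng, colors, c_seq)
    out = tree.copy()
    for nid, k in zip(nids, obs):
        node = out.nodes[nid]
        out.nodes[nid] = SubcloneNode(
            id=nid, new_mutations=node.new_mutations, count=int(k),
            genotype=node.genotype,
        )
    out.c_seq = int(c_seq)
    out.c_tumor = float(colors.sum())
    out.sampling_time = result.sampling_time
    return prune_unobserved(out)


def simulate_cohort(config: SimConfig, n_observed: int, c_seq: int | None = None,
                    rng=None, max_attempts_factor: int = 1000) -> tuple:
    """Simulate patients until ``n_observed`` observable trees are collected.

    A patient is observable when the sampling event arrives before ``t_max``
    and the tumor holds at least ``c_seq`` cells.  Returns the cohort and a
    statistics dict whose ``zeta_hat`` (acceptance fraction) is an unbiased
    estimate of the lifetime risk.  With ``keep_censored`` every attempt is
    returned (censored trees carry ``sampling_time=None`` and are sequenced
    from the ``t_max`` state).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.params
    c_seq = c_seq if c_seq is not None else p.C_seq
    trees, attempts, sampled = [], 0, 0
    cap = max_attempts_factor * n_observed
    while len(trees) < n_observed:
        if attempts >= cap:
            raise RuntimeError(
                f"acceptance too low: {len(trees)} observable trees in {attempts} attempts"
            )
        attempts += 1
        res = simulate_tree(config, rng=rng)
        observable = res.sampling_time is not None and res.tree.c_tumor >= c_seq
        if observable:
            sampled += 1
        if observable or config.keep_censored:
            if res.tree.c_tumor >= c_seq:
                tree = sequence_cells(res, c_seq, rng=rng)
            else:
                tree = res.tree.copy()
                tree.c_seq = 0
            tree.patient_id = f"P{len(trees):04d}"
            trees.append(tree)
    zeta_hat = sampled / attempts
    stats = {
        "attempts": attempts,
        "accepted": sampled,
        "zeta_hat": zeta_hat,
        "zeta_se": math.sqrt(max(zeta_hat * (1 - zeta_hat), 1 / attempts) / attempts),
    }
    return Cohort(trees=trees, n=p.n), stats


# -- fixed-topology vectorized simulator (validation workloads) ---------------


def simulate_fixed_topology(parents, lams, nus, C0: float, beta: float,
                            t_end: float, dt: float, n_reps: int, rng,
                            C_sampling: float | None = None,
                            capture_at_sampling: bool = False) -> tuple:
    """Vectorized replicates of a fixed small subclone topology.

    ``parents[v]`` is the index of subclone v's parent (-1 = wild-type
    root), ``lams`` the net growth rates, ``nus`` the seeding rates per
    parent cell.  Returns ``(counts, ts)``: subclone sizes at ``t_end`` with
    shape (n_reps, V), and per-replicate sampling times (NaN when the
    integrated hazard has not yet crossed its unit-exponential threshold).
    The sampling event is recorded without stopping the dynamics, so one
    run yields both the size laws and the sampling-time law.  With
    ``capture_at_sampling`` a third array holds each replicate's subclone
    sizes at its sampling step.
    """
    from ._num import bd_p0_b

    parents = np.asarray(parents, dtype=int)
    V = len(parents)
    alphas = beta + np.asarray(lams, dtype=float)
    p0s, bs, p0h, bh = [], [], [], []
    for a in alphas:
        p0, b = bd_p0_b(a, beta, dt)
        p0s.append(float(p0))
        bs.append(float(b))
        # half-step transition used to mature newly seeded cells, whose
        # birth times are uniform within the step (dt/2 on average)
        p0, b = bd_p0_b(a, beta, dt / 2.0)
        p0h.append(float(p0))
        bh.append(float(b))
    X = np.zeros((n_reps, V), dtype=np.int64)
    steps = int(round(t_end / dt))
    hazard = np.zeros(n_reps)
    target = rng.exponential(size=n_reps)
    ts = np.full(n_reps, np.nan)
    X_ts = np.zeros((n_reps, V), dtype=np.int64) if capture_at_sampling else None
    t = 0.0
    for _ in range(steps):
        X_old = X.copy()
        tumor_old = X.sum(axis=1)
        for v in range(V):
            col = X[:, v]
            surv = rng.binomial(col, 1.0 - p0s[v])
            nb = np.zeros_like(surv)
            mask = surv > 0
            if mask.any():
                nb[mask] = rng.negative_binomial(surv[mask], 1.0 - bs[v])
            X[:, v] = surv + nb
        for v in range(V):
            if parents[v] == -1:
                par = np.full(n_reps, float(C0))
            else:
                par = 0.5 * (X_old[:, parents[v]] + X[:, parents[v]])
            seeds = rng.poisson(nus[v] * par * dt)
            mask = seeds > 0
            if mask.any():
                surv = rng.binomial(seeds[mask], 1.0 - p0h[v])
                grown = surv.copy()
                m2 = surv > 0
                if m2.any():
                    grown[m2] = surv[m2] + rng.negative_binomial(surv[m2], 1.0 - bh[v])
                X[mask, v] += grown
        if C_sampling is not None:
            tumor = X.sum(axis=1)
            inc = dt * 0.5 * (tumor_old + tumor) / C_sampling
            new_haz = hazard + inc
            cross = np.isnan(ts) & (new_haz >= target) & (inc > 0)
            if cross.any():
                frac = (target[cross] - hazard[cross]) / inc[cross]
                ts[cross] = t + frac * dt
                if capture_at_sampling:
                    X_ts[cross] = X[cross]
            hazard = new_haz
        t += dt
    if capture_at_sampling:
        return X, ts, X_ts
    return X, ts


# -- benchmark cohorts --------------------------------------------------------


@dataclass
class BenchmarkResult:
    cohort: Cohort
    params: ModelParams
    truth: "object"           # DataFrame: genotype, phi, delta
    stats: dict = field(default_factory=dict)


def default_benchmark_params(n: int, rng, F=None) -> ModelParams:
    """Study-like parameter draw for synthetic cohorts.

    Base fitness effects Uniform(0.1, 0.3); 20% of pairwise interactions
    nonzero, Uniform(-0.2, 0.2); per-mutation rates log-uniform in
    [3e-5, 3e-4] per stem cell per year over a C0 = 1e3 wild-type pool —
    the regime where seeding from an expanded subclone competes with
    seeding from the wild-type pool, so observed trees mix star and chain
    topologies and a substantial fraction of patients is never diagnosed
    (selection bias is real).  Diagnosis scale 1e8 cells, 500 sequenced
    cells, 80-year horizon, unit death rate.
    """
    from .rates import FitnessMatrix

    if F is None:
        vals = np.zeros((n, n))
        diag = rng.uniform(0.1, 0.3, size=n)
        np.fill_diagonal(vals, diag)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.2:
                    vals[i, j] = rng.uniform(-0.2, 0.2)
        F = FitnessMatrix(vals)
    mu = np.exp(rng.uniform(np.log(3e-5), np.log(3e-4), size=n))
    return ModelParams(C0=1e3, C_sampling=1e8, C_seq=500, t_max=80.0,
                       mu=mu, beta=1.0, F=F)


def benchmark_scenario(n: int, N: int, seed: int, params: ModelParams | None = None,
                       dt: float = 0.05, max_truth_mutations: int = 2) -> BenchmarkResult:
    """Ground-truth fitness landscape plus an observable synthetic cohort.

    The emitted truth table lists phi for every genotype with up to
    ``max_truth_mutations`` mutations together with any larger genotype
    observed in the cohort.
    """
    import pandas as pd

    from itertools import combinations

    rng = np.random.default_rng(seed)
    if params is None:
        params = default_benchmark_params(n, rng)
    cohort, stats = simulate_cohort(SimConfig(params=params, dt=dt), N, rng=rng)
    genotypes = set()
    for k in range(1, max_truth_mutations + 1):
        genotypes.update(frozenset(c) for c in combinations(range(1, n + 1), k))
    for tree in cohort:
        for nid in tree.mutant_nodes():
            genotypes.add(tree.genotype_of(nid))
    rows = []
    for g in sorted(genotypes, key=lambda g: (len(g), sorted(g))):
        phi = log_birth_death_ratio(g, params.F)
        rows.append({"genotype": "+".join(map(str, sorted(g))), "phi": phi})
    truth = pd.DataFrame(rows)
    return BenchmarkResult(cohort=cohort, params=params, truth=truth, stats=stats)
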