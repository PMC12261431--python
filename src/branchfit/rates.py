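"""Fitness parameterization and per-subclone demographic rates.

The fitness landscape is a triangular matrix ``F``: diagonal entries are
base (single-mutation) effects on the log birth-to-death ratio, strict
upper-triangle entries are pairwise epistatic effects.  For a subclone with
genotype ``g`` the log birth-to-death ratio is

    phi(g) = max_{i in g} f_ii + sum_{{i,j} subset g, i<j} f_ij,

i.e. only the most advantageous mutation sets the base growth while all
interactions act additively on top.  Birth and death rates follow from a
common death rate ``beta`` shared by all cell types:

    alpha = beta * exp(phi),   lambda = alpha - beta.

The large-time growth exponent of a subclone is governed by the running
maximum ``delta`` of the net growth rates along its lineage (the wild-type
root contributes lambda = 0) and by the multiplicity ``r`` with which that
maximum is attained: C_v(t) ~ C~_v * t^(r-1) * exp(delta * t).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FitnessMatrix",
    "ModelParams",
    "SubcloneRates",
    "log_birth_death_ratio",
    "net_growth",
    "subclone_mutation_rate",
    "running_max",
    "shape_scale",
    "tree_rates",
]


class RatesError(ValueError):
    pass


@dataclass(frozen=True)
class FitnessMatrix:
    """Upper-triangular n x n fitness matrix (lower triangle forced to zero)."""

    values: np.ndarray

    def __post_init__(self):
        F = np.asarray(self.values, dtype=float)
        if F.ndim != 2 or F.shape[0] != F.shape[1]:
            raise RatesError("fitness matrix must be square")
        if not np.all(np.isfinite(F)):
            raise RatesError("fitness matrix entries must be finite")
        object.__setattr__(self, "values", np.triu(F))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def zeros(cls, n: int) -> "FitnessMatrix":
        return cls(np.zeros((n, n)))

    def base_effect(self, i: int) -> float:
        return float(self.values[i - 1, i - 1])

    def epistasis(self, i: int, j: int) -> float:
        i, j = min(i, j), max(i, j)
        return float(self.values[i - 1, j - 1])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"n": self.n, "F": self.values.tolist()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FitnessMatrix":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["F"], dtype=float))

    def to_tsv(self, path, labels=None) -> None:
        """Heat-map style export: base effects as a separate first column."""
        import pandas as pd

        labels = labels or [f"M{i}" for i in range(1, self.n + 1)]
        off = self.values.copy()
        np.fill_diagonal(off, 0.0)
        df = pd.DataFrame(off, index=labels, columns=labels)
        df.insert(0, "base", np.diag(self.values))
        df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class ModelParams:
    """Scalar model constants plus mutation rates and the fitness matrix.

    Attributes
    ----------
    C0 : wild-type (stem cell) population size, cells.
    C_sampling : tumor size scale at which diagnosis becomes likely, cells.
    C_seq : number of sequenced cells per sample (default; per-tree values win).
    t_max : maximum observation time (lifetime horizon), years.
    mu : per-mutation rates, one per mutation, per wild-type division-time unit.
    beta : common death rate of all cell types, 1/years.
    F : the fitness matrix.
    """

    C0: float
    C_sampling: float
    C_seq: int
    t_max: float
    mu: np.ndarray
    beta: float
    F: FitnessMatrix

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "mu", mu)
        if min(self.C0, self.C_sampling, self.C_seq, self.t_max, self.beta) <= 0:
            raise RatesError("C0, C_sampling, C_seq, t_max, beta must all be positive")
        if mu.shape != (self.F.n,):
            raise RatesError(f"mu must have length n={self.F.n}")
        if np.any(mu < 0) or np.any(mu >= 1):
            raise RatesError("mutation rates must lie in [0, 1)")

    @property
    def n(self) -> int:
        return self.F.n

    def with_F(self, F: FitnessMatrix) -> "ModelParams":
        return ModelParams(self.C0, self.C_sampling, self.C_seq, self.t_max,
                           self.mu, self.beta, F)


@dataclass(frozen=True)
class SubcloneRates:
    """Demographic rates of one subclone and its running-max growth pair."""

    nu: float          # subclone mutation (seeding) rate
    alpha: float       # birth rate
    lam: float         # net growth rate alpha - beta
    s: float           # relative increase over wild-type division rate
    phi: float         # log birth-to-death ratio
    delta: float       # running-max net growth rate along the lineage
    r: int             # multiplicity of the running max


def log_birth_death_ratio(genotype, F: FitnessMatrix) -> float:
    """phi(g): dominant base effect plus the sum of pairwise interactions."""
    g = sorted(genotype)
    if not g:
        raise RatesError("wild-type has no phi; its net growth rate is 0 by definition")
    if g[-1] > F.n:
        raise RatesError(f"mutation index {g[-1]} exceeds n={F.n}")
    V = F.values
    idx = np.array(g) - 1
    phi = float(np.max(V[idx, idx]))
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            phi += V[idx[a], idx[b]]
    return phi


def net_growth(phi: float, beta: float) -> tuple:
    """Return (lambda, s, alpha) from the log birth-to-death ratio."""
    if beta <= 0:
        raise RatesError("beta must be positive")
    alpha = beta * np.exp(phi)
    s = np.expm1(phi)
    return beta * s, s, alpha


def subclone_mutation_rate(new_mutations, mu) -> float:
    """nu_v: product of the rates of the subclone's new mutations."""
    pi = sorted(new_mutations)
    if not pi:
        raise RatesError("root has no mutation rate (empty new-mutation set)")
    mu = np.asarray(mu, dtype=float)
    return float(np.prod(mu[np.array(pi) - 1]))


def running_max(lineage_lams, tol: float = 1e-12) -> tuple:
    """(delta, r) over a root-to-node lineage of net growth rates.

    ``lineage_lams`` are the mutant nodes' lambdas ordered root-child first;
    the wild-type root contributes lambda = 0 and is prepended implicitly,
    so delta is never negative.  ``r`` counts lineage nodes (including the
    root) whose lambda ties the maximum within ``tol``.
    """
    lams = [0.0] + [float(x) for x in lineage_lams]
    if len(lams) == 1:
        raise RatesError("lineage must contain at least one mutant node")
    delta = max(lams)
    r = sum(1 for x in lams if abs(x - delta) <= tol)
    return delta, r


def shape_scale(lam: float, alpha: float, beta: float, nu: float) -> tuple:
    """(rho, phi_scale): shape factor nu/alpha and the scale of the size law."""
    if alpha <= 0:
        raise RatesError("alpha must be positive")
    rho = nu / alpha
    if lam < 0:
        scale = -beta / lam
    elif lam == 0:
        scale = alpha
    else:
        scale = alpha / lam
    return rho, scale


def tree_rates(tree, params: ModelParams, tol: float = 1e-12,
               order=None, phi_cache: dict | None = None) -> dict:
    """Per-node :class:`SubcloneRates` for every mutant node of a tree.

    Genotypes must be computed.  The running max is accumulated root-first,
    so each node's (delta, r) is consistent with its ancestors'.
    """
    out: dict = {}
    if order is None:
        order = tree.topological_order()
    lam_of = {order[0]: 0.0}
    dr_of = {order[0]: (0.0, 1)}
    root = order[0]
    for nid in order:
        if nid == root:
            continue
        node = tree.nodes[nid]
        g = tree.genotype_of(nid)
        if phi_cache is not None and g in phi_cache:
            phi = phi_cache[g]
        else:
            phi = log_birth_death_ratio(g, params.F)
            if phi_cache is not None:
                phi_cache[g] = phi
        lam, s, alpha = net_growth(phi, params.beta)
        nu = subclone_mutation_rate(node.new_mutations, params.mu)
        pd_, pr = dr_of[tree.parents[nid]]
        if lam > pd_ + tol:
            delta, r = lam, 1
        elif abs(lam - pd_) <= tol:
            delta, r = pd_, pr + 1
        else:
            delta, r = pd_, pr
        lam_of[nid] = lam
        dr_of[nid] = (delta, r)
        out[nid] = SubcloneRates(nu=nu, alpha=alpha, lam=lam, s=s, phi=phi,
                                 delta=delta, r=r)
    return out
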