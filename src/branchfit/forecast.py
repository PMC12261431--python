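"""Posterior-predictive ranking of the next mutational events of a tree.

A candidate event is a (parent subclone, new mutation) pair admissible
under the expansion rule.  Its predicted propensity is the instantaneous
growth rate: the parent subclone's size at sampling, times the new
mutation's rate, times the running-max net growth rate of the would-be new
subclone (its own lineage maximum, including itself).  Ranks are mid-rank
percentiles among all candidates; a posterior sample of fitness matrices
turns each candidate's rank into a distribution summarized by its median
and a credible band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import estimate_true_counts
from .rates import ModelParams, log_birth_death_ratio, net_growth, tree_rates
from .trees import ISA, ExpansionRule, MutationTree

__all__ = [
    "CandidateEvent",
    "EventForecast",
    "enumerate_events",
    "instantaneous_growth_rate",
    "percentile_ranks",
    "posterior_rank_distribution",
]


@dataclass(frozen=True)
class CandidateEvent:
    parent_id: str
    parent_genotype: frozenset
    mutation: int
    genotype: frozenset


@dataclass
class EventForecast:
    event: CandidateEvent
    rate: float | None            # under a point estimate, if computed
    rank_median: float
    rank_low: float
    rank_high: float
    ranks: np.ndarray | None = None


def enumerate_events(tree: MutationTree, rule: ExpansionRule = ISA,
                     max_mutations: int = 2, n: int | None = None) -> list:
    """All admissible (node, new mutation) pairs not already in the tree."""
    if n is None:
        n = max(tree.all_mutations(), default=0)
    present = {tree.genotype_of(nid) for nid in tree.topological_order()}
    events = []
    for nid in tree.topological_order():
        g = tree.genotype_of(nid)
        if len(g) >= max_mutations:
            continue
        for m in range(1, n + 1):
            if not rule.admits(tree, nid, frozenset([m])):
                continue
            new_g = g | {m}
            if new_g in present:
                continue
            events.append(CandidateEvent(nid, g, m, new_g))
    return events


def instantaneous_growth_rate(event: CandidateEvent, parent_size: float,
                              mu, F, beta: float,
                              lineage_delta: float) -> float:
    """parent size x mutation rate x running-max growth rate of the event.

    ``lineage_delta`` is the running max of the parent's lineage; the
    candidate's own net growth rate enters the max since the new subclone
    extends the lineage.
    """
    lam = net_growth(log_birth_death_ratio(event.genotype, F), beta)[0]
    delta = max(lineage_delta, lam)
    return float(parent_size) * float(np.asarray(mu)[event.mutation - 1]) * delta


def percentile_ranks(rates) -> np.ndarray:
    """Mid-rank percentile (0-100) of each rate among all candidates."""
    rates = np.asarray(rates, dtype=float)
    n = len(rates)
    ranks = np.empty(n)
    for i, r in enumerate(rates):
        smaller = np.sum(rates < r)
        ties = np.sum(rates == r)
        ranks[i] = 100.0 * (smaller + 0.5 * ties) / n
    return ranks


def _event_rates_for_F(tree, events, latent, params: ModelParams, F) -> np.ndarray:
    rates = tree_rates(tree, params.with_F(F))
    out = np.empty(len(events))
    for k, ev in enumerate(events):
        if ev.parent_id == tree.root_id:
            parent_size, lineage_delta = params.C0, 0.0
        else:
            parent_size = latent.sizes.get(ev.parent_id, 0)
            lineage_delta = rates[ev.parent_id].delta
        out[k] = instantaneous_growth_rate(ev, parent_size, params.mu, F,
                                           params.beta, lineage_delta)
    return out


def posterior_rank_distribution(tree: MutationTree, params: ModelParams,
                                sample, max_mutations: int = 2,
                                n_posterior: int = 500,
                                credibility: float = 0.95,
                                rule: ExpansionRule = ISA) -> list:
    """Per-candidate percentile-rank distributions over posterior draws.

    ``sample`` is a :class:`branchfit.mcmc.PosteriorSample` paired with the
    model that produced it (``sample.names`` encode the free entries), or
    any object with ``flat()`` returning draws and a matching ``unpack``
    convention via ``params.n`` upper-triangular names ``f_i_j``.
    """
    from .rates import FitnessMatrix

    events = enumerate_events(tree, rule, max_mutations=max_mutations, n=params.n)
    if not events:
        return []
    latent = estimate_true_counts(tree)
    flat = sample.flat()
    if n_posterior < flat.shape[0]:
        idx = np.linspace(0, flat.shape[0] - 1, n_posterior).astype(int)
        flat = flat[idx]
    # decode free entries from names like "f_i_j"
    entries = [tuple(int(p) for p in name.split("_")[1:]) for name in sample.names]
    all_ranks = np.empty((flat.shape[0], len(events)))
    for d, row in enumerate(flat):
        vals = np.zeros((params.n, params.n))
        for (i, j), v in zip(entries, row):
            vals[i - 1, j - 1] = v
        F = FitnessMatrix(vals)
        all_ranks[d] = percentile_ranks(_event_rates_for_F(tree, events, latent,
                                                           params, F))
    lo_q = (1 - credibility) / 2
    out = []
    for k, ev in enumerate(events):
        r = all_ranks[:, k]
        out.append(EventForecast(
            event=ev, rate=None,
            rank_median=float(np.median(r)),
            rank_low=float(np.quantile(r, lo_q)),
            rank_high=float(np.quantile(r, 1 - lo_q)),
            ranks=r,
        ))
    return out
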