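"""Benchmark metrics for fitness-landscape recovery, and the
average-frequency baseline.

Both error metrics are two-level means: first within each tree, then
across trees, so small and large trees weigh equally.  Rank correlation is
computed once over the cohort's distinct genotypes, because fitness
estimates are functions of the genotype and per-tree duplication would
overweight common genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trees import Cohort, ISA, augment_tree

__all__ = [
    "FitnessEvaluation",
    "build_evaluation",
    "mean_absolute_error",
    "sign_agreement",
    "spearman_eval",
    "frequency_baseline",
]


@dataclass
class FitnessEvaluation:
    """Paired (estimate, truth) fitness values per tree.

    ``per_tree`` is a list (one entry per tree) of lists of
    ``(genotype, estimate, truth)`` triples; ``scope`` records whether
    unobserved (augmented) subclones are included.
    """

    per_tree: list
    scope: str  # "observed_only" | "with_unobserved"

    def pooled_genotypes(self) -> list:
        seen = {}
        for rows in self.per_tree:
            for g, est, tru in rows:
                seen[g] = (est, tru)
        return [(g, est, tru) for g, (est, tru) in seen.items()]


def build_evaluation(cohort: Cohort, estimates: dict, truth: dict,
                     scope: str = "observed_only",
                     max_mutations: int = 2) -> FitnessEvaluation:
    """Assemble evaluation pairs for a cohort.

    ``estimates`` and ``truth`` map genotype frozensets to fitness values;
    genotypes missing from ``estimates`` score 0 (the baseline convention
    for subclones absent from all trees).
    """
    if scope not in ("observed_only", "with_unobserved"):
        raise ValueError(f"unknown scope {scope!r}")
    per_tree = []
    for tree in cohort:
        if scope == "with_unobserved":
            tree = augment_tree(tree, ISA, max_mutations=max_mutations, n=cohort.n)
        rows = []
        for nid in tree.mutant_nodes():
            node = tree.nodes[nid]
            if scope == "observed_only" and node.count == 0:
                continue
            g = tree.genotype_of(nid)
            if g not in truth:
                continue
            rows.append((g, float(estimates.get(g, 0.0)), float(truth[g])))
        if rows:
            per_tree.append(rows)
    return FitnessEvaluation(per_tree=per_tree, scope=scope)


def mean_absolute_error(ev: FitnessEvaluation) -> float:
    """Mean over trees of the within-tree mean absolute fitness error."""
    if not ev.per_tree:
        raise ValueError("empty evaluation")
    tree_means = []
    for rows in ev.per_tree:
        errs = [abs(est - tru) for _, est, tru in rows]
        tree_means.append(np.mean(errs))
    return float(np.mean(tree_means))


def _sign(x: float) -> int:
    return 0 if x == 0 else (1 if x > 0 else -1)


def sign_agreement(ev: FitnessEvaluation) -> float:
    """Two-level mean of 1(sign(estimate) == sign(truth)); sign(0) = 0."""
    if not ev.per_tree:
        raise ValueError("empty evaluation")
    tree_means = []
    for rows in ev.per_tree:
        hits = [float(_sign(est) == _sign(tru)) for _, est, tru in rows]
        tree_means.append(np.mean(hits))
    return float(np.mean(tree_means))


def spearman_eval(ev: FitnessEvaluation) -> float:
    """Spearman rank correlation pooled over distinct genotypes."""
    pooled = ev.pooled_genotypes()
    if len(pooled) < 2:
        raise ValueError("need at least two genotypes for a rank correlation")
    est = np.array([e for _, e, _ in pooled])
    tru = np.array([t for _, _, t in pooled])
    if np.all(est == est[0]) or np.all(tru == tru[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, _ = stats.spearmanr(est, tru)
    return float(rho)


def frequency_baseline(cohort: Cohort) -> dict:
    """Average observed cell fraction per genotype across the cohort.

    A genotype absent from a tree contributes 0 to its average, so the
    scores are ranking scores over the union of observed genotypes, not
    absolute fitness values.
    """
    totals: dict = {}
    for tree in cohort:
        c_seq = tree.c_seq or max(tree.observed_total(), 1)
        for nid in tree.mutant_nodes():
            g = tree.genotype_of(nid)
            totals[g] = totals.get(g, 0.0) + tree.nodes[nid].count / c_seq
    N = max(len(cohort.trees), 1)
    return {g: v / N for g, v in totals.items()}
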