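"""Model/results facade: fit a fitness landscape to a cohort of trees.

:class:`FitnessModel` bundles a cohort, the fixed model constants, the
prior and the likelihood configuration; ``fit()`` runs MCMC over the free
fitness-matrix entries and returns a :class:`FitnessResults` carrying the
posterior draws, summaries, diagnostics, and downstream functionality
(per-genotype fitness estimates, forecasting, simulation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .likelihood import (
    DEFAULT_CONFIG,
    LikelihoodConfig,
    cohort_log_likelihood,
    lifetime_risk,
)
from .laws import lifetime_risk_analytic
from .mcmc import PosteriorSample, PriorSpec, log_prior, run_mcmc, summarize
from .rates import FitnessMatrix, ModelParams, log_birth_death_ratio
from .trees import Cohort

__all__ = ["FitnessModel", "FitnessResults"]


class FitnessModel:
    """Bayesian fitness-landscape model for a cohort of tumor mutation trees.

    Parameters
    ----------
    cohort
        The observed trees.
    params
        Model constants (C0, sampling scale, sequencing depth, horizon,
        mutation rates, death rate); the fitness matrix inside is used only
        for its dimension.
    prior
        Normal prior scale for the fitness entries and the optional
        lifetime-risk prior.
    epistasis_genes
        Mutations whose pairwise interactions are inferred; off-diagonal
        entries involving other genes are fixed at zero (their base effects
        are still inferred).  Default: all genes.
    zeta_mode
        "analytic" (default): lifetime risk from the folded sampling-time
        law, recomputed for every proposed F.  "mc": Monte-Carlo forward
        simulation with common random numbers.  "fixed": a user constant
        (``zeta_value``).  "off": no observability correction.
    """

    def __init__(self, cohort: Cohort, params: ModelParams,
                 prior: PriorSpec | None = None,
                 epistasis_genes=None,
                 config: LikelihoodConfig = DEFAULT_CONFIG,
                 zeta_mode: str = "analytic",
                 zeta_value: float | None = None):
        self.cohort = cohort
        self.params = params
        self.prior = prior if prior is not None else PriorSpec()
        self.config = config
        if zeta_mode not in ("analytic", "mc", "fixed", "off"):
            raise ValueError(f"unknown zeta_mode {zeta_mode!r}")
        if zeta_mode == "fixed" and zeta_value is None:
            raise ValueError("zeta_mode='fixed' requires zeta_value")
        self.zeta_mode = zeta_mode
        self.zeta_value = zeta_value
        n = params.n
        genes = set(epistasis_genes) if epistasis_genes is not None else set(
            range(1, n + 1))
        self.free_entries = [(i, i) for i in range(1, n + 1)]
        self.free_entries += [
            (i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)
            if i in genes and j in genes
        ]
        self.names = [f"f_{i}_{j}" for i, j in self.free_entries]
        self.is_offdiag = np.array([i != j for i, j in self.free_entries])

    # -- parameter packing ----------------------------------------------------

    def pack(self, F: FitnessMatrix) -> np.ndarray:
        return np.array([F.values[i - 1, j - 1] for i, j in self.free_entries])

    def unpack(self, x) -> FitnessMatrix:
        vals = np.zeros((self.params.n, self.params.n))
        for (i, j), v in zip(self.free_entries, x):
            vals[i - 1, j - 1] = v
        return FitnessMatrix(vals)

    def initial_point(self, data_driven: bool = True) -> np.ndarray:
        """Starting point for the sampler.

        The default seeds each free entry from a crude per-genotype growth
        estimate, ``lambda_hat = log(latent size) / ts`` averaged over the
        cohort (ignoring the stochastic prefactor, so biased but in the
        right region); base effects without data, and all entries with
        ``data_driven=False``, start at 0.05 / 0.
        """
        x = np.zeros(len(self.free_entries))
        x[~self.is_offdiag] = 0.05
        if not data_driven or not len(self.cohort.trees):
            return x
        from .likelihood import estimate_true_counts

        lam_hat: dict = {}
        for tree in self.cohort:
            if tree.sampling_time is None or tree.c_tumor is None:
                continue
            try:
                latent = estimate_true_counts(tree)
            except Exception:
                continue
            for nid in tree.mutant_nodes():
                size = latent.sizes.get(nid, 0)
                if size > 0:
                    g = tree.genotype_of(nid)
                    lam_hat.setdefault(g, []).append(
                        math.log(max(size, 2.0)) / tree.sampling_time)
        phi_hat = {g: math.log1p(max(min(np.mean(v), 2.0), 0.01) / self.params.beta)
                   for g, v in lam_hat.items()}
        base = {}
        for k, (i, j) in enumerate(self.free_entries):
            if i == j and frozenset([i]) in phi_hat:
                x[k] = min(max(phi_hat[frozenset([i])], 0.01), 0.5)
            if i == j:
                base[i] = x[k]
        for k, (i, j) in enumerate(self.free_entries):
            if i != j and frozenset([i, j]) in phi_hat:
                x[k] = min(max(phi_hat[frozenset([i, j])]
                               - max(base.get(i, 0.05), base.get(j, 0.05)),
                               -0.3), 0.3)
        return x

    # -- posterior ------------------------------------------------------------

    def zeta(self, params: ModelParams) -> float | None:
        if self.zeta_mode == "off":
            return None
        if self.zeta_mode == "fixed":
            return self.zeta_value
        if self.zeta_mode == "mc":
            z, _ = lifetime_risk(params, n_sim=self.config.zeta_sims,
                                 seed=self.config.zeta_seed)
            return min(max(z, 1e-10), 1.0)
        z = lifetime_risk_analytic(params)
        return min(max(z, 1e-10), 1.0)

    def log_likelihood(self, x) -> float:
        params = self.params.with_F(self.unpack(x))
        return cohort_log_likelihood(self.cohort, params, self.zeta(params),
                                     config=self.config)

    def log_posterior(self, x) -> float:
        x = np.asarray(x, dtype=float)
        params = self.params.with_F(self.unpack(x))
        zeta_corr = self.zeta(params)
        zeta_for_prior = zeta_corr
        if zeta_for_prior is None and self.prior.risk_center is not None:
            zeta_for_prior = min(max(lifetime_risk_analytic(params), 1e-10), 1.0)
        try:
            ll = cohort_log_likelihood(self.cohort, params, zeta_corr,
                                       config=self.config)
        except (ValueError, FloatingPointError, OverflowError):
            return -np.inf
        if not np.isfinite(ll):
            return -np.inf
        return ll + log_prior(x, self.prior, zeta_for_prior)

    def fit(self, draws: int = 1000, warmup: int = 1000, chains: int = 4,
            seed: int = 0, thin: int = 1) -> "FitnessResults":
        sample = run_mcmc(self.log_posterior, self.initial_point(),
                          n_draws=draws, warmup=warmup, chains=chains,
                          seed=seed, thin=thin, names=self.names)
        return FitnessResults(self, sample)


@dataclass
class FitnessResults:
    """Posterior over the fitness landscape, with summaries and forecasts."""

    model: FitnessModel
    sample: PosteriorSample

    def summary(self, credibility: float = 0.95):
        """Per-entry median, shortest HDI, sd and display mask."""
        return summarize(self.sample, credibility=credibility,
                         is_offdiag=self.model.is_offdiag).table

    def diagnostics(self) -> dict:
        return self.sample.diagnostics()

    def median_fitness_matrix(self) -> FitnessMatrix:
        med = np.median(self.sample.flat(), axis=0)
        return self.model.unpack(med)

    def phi_estimates(self, genotypes) -> dict:
        """Posterior-median log birth-to-death ratio per genotype."""
        flat = self.sample.flat()
        out = {}
        for g in genotypes:
            g = frozenset(g)
            phis = np.array([
                log_birth_death_ratio(g, self.model.unpack(row)) for row in flat
            ])
            out[g] = float(np.median(phis))
        return out

    def zeta_estimate(self) -> float | None:
        params = self.model.params.with_F(self.median_fitness_matrix())
        return self.model.zeta(params)

    def save_draws(self, path) -> None:
        self.sample.to_dataframe().to_csv(path, index=False)

    def forecast(self, tree, max_mutations: int = 2, n_posterior: int = 500,
                 credibility: float = 0.95):
        """Rank candidate next mutational events for one patient's tree."""
        from .forecast import posterior_rank_distribution

        return posterior_rank_distribution(
            tree, self.model.params, self.sample, max_mutations=max_mutations,
            n_posterior=n_posterior, credibility=credibility,
        )

    def simulate(self, n_patients: int, seed: int = 0, **kwargs):
        """Forward-simulate patients under the posterior-median landscape."""
        from .simulate import SimConfig, simulate_cohort

        params = self.model.params.with_F(self.median_fitness_matrix())
        cfg = SimConfig(params=params, seed=seed, **kwargs)
        return simulate_cohort(cfg, n_patients)
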