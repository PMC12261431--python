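"""Adaptive random-walk Metropolis sampling and posterior summaries.

The posterior over the free fitness-matrix entries is explored with a
Gaussian random-walk Metropolis sampler whose proposal covariance is
adapted (Haario-style) during warmup only, leaving the post-warmup chains
exactly Markovian.  The sampler is gradient-free because the likelihood
contains numerically inverted Laplace transforms.  Convergence is reported
through split-R-hat and effective sample sizes (via arviz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PriorSpec", "PosteriorSample", "PosteriorSummary", "run_mcmc",
           "log_prior", "summarize"]


@dataclass(frozen=True)
class PriorSpec:
    """Normal prior on every distinct free fitness entry, plus an optional
    informative prior on the lifetime risk.

    sigma : standard deviation of the N(0, sigma^2) prior per entry.
    risk_center : if set, center of a normal prior on logit(zeta_hat).
    risk_width : standard deviation of the risk prior on the logit scale.
    """

    sigma: float = 1.0
    risk_center: float | None = None
    risk_width: float = 0.05

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("prior sigma must be positive")
        if self.risk_center is not None and not 0 < self.risk_center < 1:
            raise ValueError("risk prior center must lie in (0, 1)")


def _logit(p: float) -> float:
    return math.log(p) - math.log1p(-p)


def log_prior(free_values, prior: PriorSpec, zeta_hat: float | None = None) -> float:
    """Log prior density of the free entries (and, if enabled, the risk)."""
    x = np.asarray(free_values, dtype=float)
    s = prior.sigma
    lp = float(-0.5 * np.sum(x**2) / s**2 - x.size * math.log(s * math.sqrt(2 * math.pi)))
    if prior.risk_center is not None:
        if zeta_hat is None:
            raise ValueError("risk prior enabled but no zeta_hat supplied")
        z = _logit(min(max(zeta_hat, 1e-12), 1 - 1e-12))
        mu = _logit(prior.risk_center)
        w = prior.risk_width
        lp += -0.5 * (z - mu) ** 2 / w**2 - math.log(w * math.sqrt(2 * math.pi))
    return lp


@dataclass
class PosteriorSample:
    """Post-warmup MCMC draws of the free fitness entries."""

    draws: np.ndarray        # (chains, draws, k)
    log_post: np.ndarray     # (chains, draws)
    names: list
    accept_rate: float
    seed: int

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.flat(), columns=self.names)

    def diagnostics(self):
        """Split-R-hat and bulk ESS per free entry."""
        import arviz as az

        data = az.convert_to_dataset(self.draws)
        rhat = az.rhat(data)["x"].values
        ess = az.ess(data)["x"].values
        return {"rhat": dict(zip(self.names, np.atleast_1d(rhat))),
                "ess": dict(zip(self.names, np.atleast_1d(ess)))}


def run_mcmc(log_post, x0, n_draws: int = 1000, warmup: int = 1000,
             chains: int = 4, seed: int = 0, thin: int = 1,
             names=None, init_scale: float = 0.02,
             max_init_retries: int = 50) -> PosteriorSample:
    """Sample with warmup-adaptive random-walk Metropolis.

    Deterministic given ``seed``.  The proposal is N(0, s^2 * Sigma_hat)
    with s = 2.38/sqrt(d); Sigma_hat and a global step multiplier (targeting
    ~30% acceptance) adapt during warmup only.  A non-finite posterior at
    the (jittered) initial point is retried a bounded number of times.
    """
    x0 = np.asarray(x0, dtype=float)
    d = x0.size
    names = list(names) if names is not None else [f"x{i}" for i in range(d)]
    all_draws = np.empty((chains, n_draws, d))
    all_lp = np.empty((chains, n_draws))
    acc_total, prop_total = 0, 0
    for c in range(chains):
        rng = np.random.default_rng([seed, c])
        x = x0.copy()
        lp = log_post(x)
        retries = 0
        while not np.isfinite(lp):
            retries += 1
            if retries > max_init_retries:
                raise RuntimeError("could not find a finite-posterior initial point")
            x = x0 + init_scale * rng.standard_normal(d)
            lp = log_post(x)
        scale = 2.38 / math.sqrt(d)
        log_mult = 0.0
        cov = np.eye(d) * init_scale**2
        chol = np.linalg.cholesky(cov)
        run_mean = np.zeros(d)
        run_cov = np.zeros((d, d))
        n_seen = 0
        rm_clock = 0

        def _geo_scale(L):
            return float(np.exp(np.mean(np.log(np.abs(np.diag(L)) + 1e-300))))
        total = warmup + n_draws * thin
        kept = 0
        for it in range(total):
            step = math.exp(log_mult) * scale
            prop = x + step * (chol @ rng.standard_normal(d))
            lp_prop = log_post(prop)
            log_u = math.log(rng.random())
            accept = np.isfinite(lp_prop) and (lp_prop - lp > log_u)
            if accept:
                x, lp = prop, lp_prop
            if it < warmup:
                # Robbins-Monro step-size adaptation; covariance is
                # estimated only over the second half of warmup so the
                # initial transient does not inflate the proposal.  Each
                # covariance swap preserves the effective step size and
                # restarts the step-size clock.
                gamma = 1.0 / (1 + rm_clock) ** 0.6
                rm_clock += 1
                log_mult += gamma * ((1.0 if accept else 0.0) - 0.3)
                if it >= warmup // 2:
                    n_seen += 1
                    delta = x - run_mean
                    run_mean += delta / n_seen
                    run_cov += np.outer(delta, x - run_mean)
                    if n_seen >= max(20, d) and it % 25 == 0:
                        cov_hat = run_cov / (n_seen - 1) + 1e-10 * np.eye(d)
                        new_chol = np.linalg.cholesky(cov_hat)
                        log_mult += math.log(_geo_scale(chol)
                                             / _geo_scale(new_chol))
                        chol = new_chol
                        rm_clock = max(rm_clock // 4, 10)
            else:
                prop_total += 1
                acc_total += bool(accept)
                j = it - warmup
                if (j + 1) % thin == 0:
                    all_draws[c, kept] = x
                    all_lp[c, kept] = lp
                    kept += 1
        assert kept == n_draws
    return PosteriorSample(
        draws=all_draws, log_post=all_lp, names=names,
        accept_rate=acc_total / max(prop_total, 1), seed=seed,
    )


@dataclass
class PosteriorSummary:
    """Per-entry posterior medians, HDIs, and the display mask."""

    table: "object"  # DataFrame: name, median, hdi_low, hdi_high, sd, mask

    def __repr__(self):
        return repr(self.table)


def summarize(sample: PosteriorSample, credibility: float = 0.95,
              is_offdiag=None) -> PosteriorSummary:
    """Median, shortest-interval HDI and display mask per free entry.

    The mask mirrors heat-map conventions: an off-diagonal (epistatic)
    entry is masked when |median| < 0.05 or when its HDI covers zero;
    diagonal entries are masked only when the HDI covers zero.
    """
    import arviz as az
    import pandas as pd

    flat = sample.flat()
    if flat.shape[0] < 2:
        raise ValueError("need at least two draws to summarize")
    med = np.median(flat, axis=0)
    sd = flat.std(axis=0, ddof=1)
    hdi = az.hdi(sample.draws, hdi_prob=credibility)
    hdi = np.asarray(hdi["x"]) if hasattr(hdi, "keys") else np.asarray(hdi)
    rows = []
    for i, name in enumerate(sample.names):
        lo, hi = float(hdi[i, 0]), float(hdi[i, 1])
        covers_zero = lo <= 0.0 <= hi
        offd = bool(is_offdiag[i]) if is_offdiag is not None else False
        mask = covers_zero or (offd and abs(med[i]) < 0.05)
        rows.append({"name": name, "median": med[i], "hdi_low": lo,
                     "hdi_high": hi, "sd": sd[i], "mask": mask})
    return PosteriorSummary(table=pd.DataFrame(rows))
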