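"""Distribution-theory validation: simulated vs analytic CDFs.

Seven three-subclone settings exercise every branch of the limit laws —
increasing, decreasing and equal fitness along a chain, a neutral and a
deleterious first subclone, a branching topology, and a non-monotone chain
— at the two per-mutation rates 0.001 and 0.01.  For each setting the
empirical CDFs of all subclone sizes at the evaluation time, and of the
sampling time, are compared (sup-distance) against the analytic laws.

The wild-type pool, sampling scale and evaluation horizon of each setting
are fixed design constants placing the process in the asymptotic regime
the limit theory describes (growth-rate gaps times the horizon of order
ten); they are documented in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .laws import LawTree
from .rates import FitnessMatrix, ModelParams
from .simulate import simulate_fixed_topology
from .trees import MutationTree

__all__ = ["ValidationSetting", "SETTINGS", "run_validation"]


@dataclass(frozen=True)
class ValidationSetting:
    """One simulation scenario: topology, growth rates, rates and scales."""

    name: str
    parents: tuple          # parent index per subclone (-1 = wild-type root)
    lams: tuple             # net growth rates
    mu: float               # per-mutation (seeding) rate
    C0: float = 1e4
    C_sampling: float = 1e10
    t_eval: float = 90.0
    beta: float = 1.0

    def model_params(self) -> ModelParams:
        """Encode the per-subclone growth rates as a fitness matrix.

        Uses the first mutation's base effect plus pairwise interaction
        terms so that each subclone's log birth-to-death ratio reproduces
        the requested net growth rate.
        """
        V = len(self.lams)
        phis = [math.log1p(l / self.beta) for l in self.lams]
        F = np.zeros((V, V))
        for v in range(V):
            p = self.parents[v]
            if p == -1:
                F[v, v] = phis[v]
            else:
                # phi(child) = phi(parent) + f_{p,v} (base effects chosen
                # not to override the running max)
                F[min(p, v), max(p, v)] = phis[v] - phis[p]
                F[v, v] = min(0.0, phis[v]) - 1.0  # dominated base effect
        mu = np.full(V, self.mu)
        return ModelParams(C0=self.C0, C_sampling=self.C_sampling, C_seq=100,
                           t_max=self.t_eval, mu=mu, beta=self.beta,
                           F=FitnessMatrix(F))

    def tree(self) -> MutationTree:
        edges = [(None, "root", [])]
        for v, p in enumerate(self.parents):
            parent_id = "root" if p == -1 else f"v{p + 1}"
            edges.append((parent_id, f"v{v + 1}", [v + 1]))
        return MutationTree.from_edges(edges)


SETTINGS = (
    ValidationSetting("A_increasing", (-1, 0, 1), (0.1, 0.2, 0.3), 0.001, t_eval=90),
    ValidationSetting("B_decreasing", (-1, 0, 1), (0.3, 0.2, 0.1), 0.001,
                      t_eval=52, C_sampling=1e10),
    ValidationSetting("C_equal", (-1, 0, 1), (0.2, 0.2, 0.2), 0.01,
                      t_eval=130, C_sampling=1e15),
    ValidationSetting("D_neutral_first", (-1, 0, 1), (0.0, 0.2, 0.1), 0.001,
                      t_eval=90, C_sampling=1e9),
    ValidationSetting("E_branching", (-1, 0, 0), (0.2, 0.3, 0.1), 0.001,
                      t_eval=80, C_sampling=1e13),
    ValidationSetting("F_deleterious_first", (-1, 0, 1), (-0.1, 0.25, 0.1), 0.01,
                      t_eval=70, C_sampling=1e9),
    ValidationSetting("G_non_monotone", (-1, 0, 1), (0.2, 0.1, 0.3), 0.01,
                      t_eval=85, C_sampling=1e13),
)


def _ecdf_ks(sample: np.ndarray, cdf_fn, n_grid: int = 200) -> float:
    """Sup-distance between an empirical CDF and an analytic CDF."""
    xs = np.sort(sample)
    n = len(xs)
    sel = np.unique(np.linspace(0, n - 1, n_grid).astype(int))
    grid = xs[sel]
    cdf = np.asarray(cdf_fn(grid))
    hi = np.searchsorted(xs, grid, side="right") / n
    lo = np.searchsorted(xs, grid, side="left") / n
    return float(np.max(np.maximum(np.abs(cdf - hi), np.abs(cdf - lo))))


def run_validation(settings=SETTINGS, n_reps: int = 1500, dt: float = 0.05,
                   seed: int = 0, progress: bool = False):
    """Simulate every setting and tabulate KS distances per cell type and Ts.

    Returns a pandas DataFrame with one row per (setting, quantity).
    """
    import pandas as pd

    rows = []
    for setting in settings:
        rng = np.random.default_rng([seed, abs(hash(setting.name)) % 2**31])
        params = setting.model_params()
        tree = setting.tree()
        lt = LawTree(tree, params)
        nus = [setting.mu] * len(setting.lams)
        X, ts = simulate_fixed_topology(
            list(setting.parents), list(setting.lams), nus, setting.C0,
            setting.beta, setting.t_eval, dt, n_reps, rng,
            C_sampling=setting.C_sampling,
        )
        for v in range(len(setting.lams)):
            nid = f"v{v + 1}"
            ks = _ecdf_ks(
                X[:, v].astype(float),
                lambda g, nid=nid: lt.marginal_cdf(nid, g, setting.t_eval),
            )
            rows.append({"setting": setting.name, "quantity": f"C{v + 1}",
                         "ks": ks, "replicates": n_reps})
        # sampling time: censored replicates enter through the horizon
        tgrid = np.linspace(0.05 * setting.t_eval, setting.t_eval, 60)
        surv = lt.ts_survival(tgrid)
        emp = np.array([(ts[~np.isnan(ts)] <= t).sum() / len(ts) for t in tgrid])
        ks_ts = float(np.max(np.abs((1.0 - surv) - emp)))
        rows.append({"setting": setting.name, "quantity": "Ts",
                     "ks": ks_ts, "replicates": n_reps})
        if progress:
            print(f"{setting.name}: " + ", ".join(
                f"{r['quantity']}={r['ks']:.3f}" for r in rows[-4:]))
    return pd.DataFrame(rows)


def plot_validation(settings=SETTINGS, n_reps: int = 1000, dt: float = 0.05,
                    seed: int = 0, path=None):
    """CDF overlay plots (simulation vs analytic) per setting."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(settings), 4, figsize=(14, 2.4 * len(settings)))
    for row, setting in enumerate(settings):
        rng = np.random.default_rng([seed, abs(hash(setting.name)) % 2**31])
        params = setting.model_params()
        lt = LawTree(setting.tree(), params)
        nus = [setting.mu] * len(setting.lams)
        X, ts = simulate_fixed_topology(
            list(setting.parents), list(setting.lams), nus, setting.C0,
            setting.beta, setting.t_eval, dt, n_reps, rng,
            C_sampling=setting.C_sampling,
        )
        for v in range(3):
            ax = axes[row, v]
            xs = np.sort(X[:, v].astype(float))
            ax.step(xs, np.arange(1, len(xs) + 1) / len(xs), where="post",
                    label="simulated")
            grid = np.unique(np.quantile(xs, np.linspace(0.001, 0.999, 80)))
            ax.plot(grid, lt.marginal_cdf(f"v{v + 1}", grid, setting.t_eval),
                    "--", label="analytic")
            ax.set_xscale("symlog")
            ax.set_title(f"{setting.name} C{v + 1}", fontsize=8)
        ax = axes[row, 3]
        tgrid = np.linspace(0.05 * setting.t_eval, setting.t_eval, 60)
        emp = np.array([(ts[~np.isnan(ts)] <= t).sum() / len(ts) for t in tgrid])
        ax.step(tgrid, emp, where="post", label="simulated")
        ax.plot(tgrid, 1.0 - lt.ts_survival(tgrid), "--", label="analytic")
        ax.set_title(f"{setting.name} Ts", fontsize=8)
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
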