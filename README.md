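# branchfit

Bayesian inference of fitness landscapes from single-cell tumor mutation
trees, via a tree-structured multi-type branching process.

## The problem

Single-cell sequencing of a tumor yields a *mutation tree*: a rooted tree
whose nodes are subclones labelled by the mutations they newly acquired,
each with an observed number of sequenced cells.  Across a cohort of
patients these trees encode how mutation and selection shaped each
tumor — but tree topologies alone cannot separate the two forces, and
classical population-genetics estimators ignore the trees.  `branchfit`
models the full generative process: a static wild-type pool of `C0` stem
cells seeds mutant subclones, each subclone grows as a birth–death
process whose log birth-to-death ratio is

&nbsp;&nbsp;&nbsp;&nbsp;φ(g) = max<sub>i∈g</sub> f<sub>ii</sub> + Σ<sub>i&lt;j∈g</sub> f<sub>ij</sub>,

with a triangular fitness matrix **F** (diagonal: base fitness effects;
off-diagonal: pairwise epistasis), diagnosis arrives with hazard
proportional to tumor size (scale `C_sampling`), and `C_seq` cells are
then sampled without replacement.  Patients never diagnosed before the
horizon `t_max` are invisible, and the likelihood corrects for this
selection bias through the lifetime risk ζ = P(T<sub>s</sub> ≤ t<sub>max</sub>).

The package provides the large-time limit laws of this process (gamma /
negative-binomial root-child laws, Laplace-exponent conditionals for
deeper subclones, the sampling-time law), a tractable tree likelihood,
adaptive-Metropolis posterior sampling of **F** with HDI summaries, an
exact-transition stochastic simulator, recovery benchmarks against an
average-frequency baseline, and posterior-predictive ranking of a
tumor's next mutational events.  It is aimed at researchers analysing
cross-sectional single-cell cohorts of liquid cancers, where a
well-mixed-population branching process is a sensible approximation.

## Worked example

Simulate a small observable cohort under a known landscape, fit the
model, and compare:

```python
import numpy as np
from branchfit import FitnessModel, PriorSpec, benchmark_scenario

res = benchmark_scenario(n=3, N=40, seed=1)      # synthetic cohort + truth
print(res.params.F.values.round(3))
print("acceptance fraction (lifetime-risk estimate):",
      round(res.stats["zeta_hat"], 2))

model = FitnessModel(res.cohort, res.params, prior=PriorSpec(sigma=1.0),
                     zeta_mode="analytic")
fit = model.fit(draws=500, warmup=400, chains=2, seed=0)
print(fit.summary().round(3))
```

Output (seeds as above):

```
[[0.202 0.    0.   ]
 [0.    0.29  0.   ]
 [0.    0.    0.129]]
acceptance fraction (lifetime-risk estimate): 0.67
    name  median  hdi_low  hdi_high     sd   mask
0  f_1_1   0.224    0.210     0.240  0.008  False
1  f_2_2   0.290    0.278     0.302  0.006  False
2  f_3_3   0.147    0.132     0.164  0.009  False
3  f_1_2   0.004   -0.012     0.016  0.008   True
4  f_1_3  -0.016   -0.029    -0.003  0.007   True
5  f_2_3  -0.006   -0.016     0.006  0.006   True
```

The three base effects (true 0.202, 0.290, 0.129) are recovered to
within ~0.02 with tight 95% HDIs — subclone sizes together with sampling
times pin the net growth rates sharply even from 40 trees.  The three
epistatic interactions, all truly zero, are estimated near zero and
masked (HDI covering zero or below the 0.05 display threshold),
mirroring how a fitness-matrix heat map would display them.
`fit.forecast(tree)` then
ranks the tree's candidate next mutations by instantaneous growth rate
with credible bands, and `branchfit validate/simulate/fit/evaluate/forecast`
expose the same steps on the command line.

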