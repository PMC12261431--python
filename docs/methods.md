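# Methods

## Model

`branchfit` models tumor evolution as a tree-structured multi-type
branching process observed through single-cell mutation trees.  A static
wild-type pool of `C0` cells seeds mutant subclones; each subclone `v`
(a set of cells sharing a genotype `g_v`) grows as a linear birth–death
process with birth rate `alpha_v`, common death rate `beta`, and seeds
admissible child subclones at the child's mutation rate per cell.  The
fitness landscape enters through the log birth-to-death ratio

    phi(g) = max_{i in g} f_ii + sum_{i<j in g} f_ij,

with `F = (f_ij)` an upper-triangular matrix: diagonal entries are base
effects of single mutations, off-diagonal entries pairwise epistasis.
Only the most advantageous mutation sets the base growth of a genotype;
interactions act additively on top.  Net growth is
`lambda = beta (e^phi − 1)`; its sign classifies a genotype as
advantageous, neutral or deleterious.  Diagnosis is an inhomogeneous
Poisson "sampling" event with hazard `Ctumor(t)/C_sampling`, after which
`C_seq` cells are drawn without replacement (multivariate
hypergeometric) and zero-count leaf subclones are pruned.  Patients whose
sampling event misses the horizon `t_max` are never observed, so cohorts
are biased toward faster tumors; the cohort log-likelihood subtracts
`N log zeta` with `zeta = P(Ts <= t_max)` (the lifetime risk) to undo
this.

Time is measured in years; `beta` is a user-supplied constant shared by
all cell types (identifiability), mutation rates are per cell per year.

## Large-time limit laws

Writing `delta_v` for the running maximum of net growth rates along the
lineage of `v` (the wild-type root contributes `lambda = 0`, so a
deleterious root child has `delta = 0`) and `r_v` for the number of times
that maximum is attained, subclone sizes decompose as
`C_v(t) ≈ C~_v t^(r_v−1) e^(delta_v t)` with `C~_v` time-independent:

* a root child is `Gamma(C0 nu/alpha, scale alpha/lambda)` when
  `lambda >= 0` (for `lambda = 0`: scale `alpha`, linear growth in `t`)
  and stationary `NegativeBinomial(C0 nu/alpha, p = (beta−alpha)/beta)`
  when `lambda < 0`.  The parameterization was fixed by moment matching
  against the exact compound-Poisson transform (e.g. the mean must be
  `C0 nu / |lambda|`), which resolves the shape/scale-slot ambiguity of
  the usual notation;
* a deeper subclone's `C~_v` given its parent's is characterized by a
  Laplace exponent, `E[e^{−θ C~_v} | C~_pa = c] = e^{−h_v(θ) c}`, with a
  trichotomy: *fitter* than every ancestor (`lambda_v > delta_pa`) gives
  a genuine integral transform obtained by integrating single-seed clone
  limits against the parent's mean profile; *equally fit* gives the
  linear `h(θ) = nu θ / r_pa`; *less fit* gives
  `h(θ) = nu θ / (delta_pa − lambda_v)`.  Linear exponents mean the
  rescaled child is asymptotically a deterministic multiple of its parent
  (hitchhiking).

Two refinements matter in practice and are used everywhere:

1. **Mean profiles.** Conditioning uses the parent's exact mean
   trajectory shape per unit `C~` (e.g. `e^{lambda s} − 1` for a
   supercritical root child, `s` for a neutral one), not the bare
   back-extrapolated `s^{r−1} e^{delta s}`.  Profiles live in a closed
   algebra of `c s^k e^{a s}` terms, so seeding convolutions, integrated
   hazards, and conditional cumulants are closed-form.  Without this
   refinement conditional means of grandchildren are wrong by factors of
   order `lambda_parent / lambda_child`.
2. **Clone-cascade marginals.** For a *fitter* subclone the naive
   composition `L_v = L_pa ∘ h_v` loses the parent-path randomness and
   underdisperses the marginal.  The exact marginal transform follows
   from a first-event decomposition of every cell's descendant cascade,
   a Riccati-type ODE system along the lineage integrated in log-radius
   along complex rays; its mean telescopes to the profile-slope chain
   (an internal consistency check).  Marginal CDFs invert this transform
   numerically; hitchhiker marginals are scaled copies of their
   parent's.

The sampling-time law folds the per-node exponents leaf-to-root: the
survival function is the joint Laplace transform of all `C~_v` evaluated
at integrated-profile arguments (closed form per node).  The same fold
over the complete candidate tree of single- and double-mutant genotypes
gives an analytic lifetime risk `zeta(Theta)`; triple mutants are
neglected because their expected contribution to tumor size at diagnosis
is orders of magnitude below the double mutants' at realistic mutation
rates.  A Monte-Carlo `zeta` (forward simulation) is provided and agrees
with the analytic fold within simulation error; the analytic version is
the default inside MCMC where a per-iteration simulation would be
prohibitive.

## Likelihood

The probability of a tree at its sampling time factorizes into root-child
size terms, deeper conditional size terms, the sampling-time density
given the (back-extrapolated) trajectories, and the hypergeometric
sequencing term.  Latent subclone sizes are plugged in from observed
fractions (largest-remainder rounding so they sum exactly to the tumor
size); zero-count internal nodes keep latent size zero, contribute no
size term, and their observed descendants condition on the nearest
positive-size ancestor with the intermediates replaced by their
conditional means.

The asymptotic conditional law of a non-fitter subclone is a point mass
and cannot score data.  Deep-node conditionals are therefore evaluated
under the finite-time compound-Poisson law of seeds from the parent's
mean profile, which is exact given the parent trajectory: its first
three cumulants are closed-form (birth–death moments are polynomials in
`e^{lambda u}`), and the density is a moment-matched Pearson-III
(shifted-gamma) kernel.  For strongly skewed conditionals (skewness
above 6, i.e. few effective seeds) the exact finite-time transform is
inverted numerically instead, with the Pearson-III (or, below the
shifted-gamma support, a normal) kernel as a finite fallback in the deep
tails.  This keeps the likelihood finite for arbitrary proposals and
continuous in `F` across equal-fitness boundaries, and it converges to
the asymptotic theory as `t` grows.  The assembled likelihood was
verified against binned Monte-Carlo joint frequencies of (sizes,
sampling time) for one-mutation, two-mutation-chain and branching toy
models (see `tests/test_acceptance.py`).

Missing sampling times are integrated out by 64-node Gauss–Legendre
quadrature over `(0, t_max]` (checked against a dense-grid oracle to
1e−4 relative).  Missing tumor sizes fall back to `C_sampling`.

## Numerics

* Laplace inversion: Abate–Whitt Euler summation on the Bromwich line
  (order `M`, `2M+1` transform evaluations).  The Euler weights amplify
  transform noise by `10^{M/3}`, so inversions of ODE-integrated
  transforms cap `M` at 10 while closed-form transforms use `M = 16`.
* Exponent ties: growth-rate differences below `0.02 / t_max` are
  treated as exact ties in the profile algebra (secular `s^{k+1}` terms);
  the running-max trichotomy uses an absolute tolerance of 1e−12.
* `int_0^t s^{r−1} e^{a s} ds` uses a stable upward recursion with a
  series fallback for `|a t| < 1e−4`.

## Inference

The posterior over the free entries of `F` (all diagonal entries, plus
off-diagonal pairs among the genes selected for epistasis inference;
other off-diagonals are fixed at zero) combines the cohort likelihood
with independent `N(0, sigma^2)` priors (default `sigma = 1`) and an
optional informative prior on `logit(zeta(Theta))` centered at a known
lifetime risk (default width 0.05).  Sampling is adaptive random-walk
Metropolis: proposal covariance and a global step size (targeting ~30%
acceptance) adapt during warmup only, leaving post-warmup chains exactly
Markovian; the sampler is gradient-free because the likelihood contains
numerical inversion.  Initialization puts base effects at 0.05 and
epistasis at 0.  Split-R-hat and bulk ESS come from arviz; HDIs are
shortest intervals; summary masks mirror heat-map conventions (HDI
covering zero, or |median| < 0.05 for epistatic entries).

## Synthetic data

The simulator advances time in fixed steps but uses the *exact* linear
birth–death transition law within each step (binomial survivors plus
negative-binomial offspring), so growth dynamics carry no tau-leaping
error at any population size; only mutation seeding and the sampling
hazard are frozen at step-average populations (O(dt) coupling error, with
newly seeded cells matured through a half-step transition).  Under the
infinite-sites rule a mutation labels at most one living subclone;
extinct childless subclones release their mutation.  Cohort generation
rejects patients whose sampling event misses `t_max` (the acceptance
fraction is an unbiased lifetime-risk estimate).

Benchmark cohorts draw base effects `Uniform(0.1, 0.3)`, make 20% of
pairwise interactions nonzero `Uniform(−0.2, 0.2)`, and use per-mutation
rates log-uniform in `[3e−5, 3e−4]` per year over a `C0 = 1e3` wild-type
pool, sampling scale 1e8 cells, 500 sequenced cells, an 80-year horizon
and `beta = 1/yr`.  This places the process in the regime where seeding
from expanded subclones competes with seeding from the wild-type pool,
so observed trees mix star and chain topologies and a substantial
fraction of patients is never diagnosed — both features the inference is
supposed to exploit.  What the generator does *not* emulate: mutation
trees are observed without reconstruction error, sample fractions
reflect true fractions exactly at sequencing, populations are well mixed
(no spatial structure), and rates are constant in time.  Passing
recovery benchmarks therefore demonstrates correctness of the inference
under the model's own assumptions, not robustness to the additional
noise of real single-cell data.

The seven distribution-validation settings are three-subclone topologies
(linear chains, one branching) with net growth profiles increasing
(0.1, 0.2, 0.3), decreasing (0.3, 0.2, 0.1), equal (0.2, 0.2, 0.2),
neutral-first (0, 0.2, 0.1), branching (0.2; 0.3, 0.1), deleterious-first
(−0.1, 0.25, 0.1) and non-monotone (0.2, 0.1, 0.3), at mutation rates
0.001 (first five) and 0.01 (last two).  Wild-type pool, sampling scale
and evaluation horizon per setting are fixed so that growth-rate gaps
times the horizon are of order ten, i.e. inside the asymptotic regime
the limit theorems describe — chosen from analytic comparisons of exact
finite-time versus asymptotic laws, not from simulation outcomes.

## Benchmarks and forecasting

Recovery is scored by the two-level mean absolute error and sign
agreement on `phi` (within-tree mean, then across trees) and by Spearman
correlation pooled over distinct genotypes, against an average-frequency
baseline (mean observed cell fraction per genotype, absent trees
counting zero).  Both observed-only and augmented (all unobserved
genotypes with up to two mutations attached as empty subclones) scopes
are reported.  Candidate next events of a tree are ranked by the
instantaneous growth rate — parent subclone size at sampling times the
new mutation's rate times the running-max growth rate including the
candidate itself — as mid-rank percentiles among all admissible events,
with posterior draws supplying credible bands.

Problem sizes in the test suite — 2000 validation replicates per
setting, 4000-replicate likelihood oracles, two MCMC chains of a few
hundred warmup and draw iterations, recovery cohorts of n=5/N=200 and
bias cohorts of n=3/N=60 — are the package's scaled-down versions of the
full study design; the scientific comparisons are unchanged at these
sizes.

## Known limitations

* Epistasis above pairwise order, time-varying rates, treatment effects
  and patient covariates are out of scope.
* The likelihood conditions each subclone only on its parent's rescaled
  size (the model's own factorization); residual parent-path randomness
  is carried exactly in marginals but only through the profile plug-in
  in conditionals.
* The analytic lifetime risk truncates the candidate genotype tree at
  double mutants.
* Relaxed (non-infinite-sites) expansion rules are accepted on input and
  in the simulator, but augmentation, forecasting enumeration and the
  candidate tree for `zeta` use infinite-sites semantics.
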