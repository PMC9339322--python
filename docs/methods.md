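# Methods

## The model

Genomic GC content is treated as a single continuous trait evolving along a
rooted phylogeny whose branch lengths are substitutions per site.  Three
nested descriptions are compared:

* **Brownian motion (BM).** Independent Gaussian increments accumulate at
  rate σ₀² (GC%² per unit branch length); tip values are jointly normal
  with mean x₀ (the root GC%) and covariance σ₀²·C, where C_ij is the
  root-to-MRCA shared path length of tips i and j.
* **Single-optimum Ornstein-Uhlenbeck (OU).** BM plus a pull of strength
  α_ou toward an optimum θ.  The root state is constrained to the optimum,
  and because the trees are non-ultrametric the fixed-root (non-stationary)
  covariance is used:
  Cov(i,j) = σ²/(2α_ou)·e^(−α_ou(d_i+d_j−2t_a))·(1−e^(−2α_ou·t_a)),
  with d the tip depths and t_a the MRCA depth.  As α_ou→0 this reduces
  continuously to BM.
* **Lévy jumps.** BM plus a compound-Poisson component: branch i carries
  n_i ~ Poisson(λ·t_i) jumps, each an independent Normal(0, α·σ₀²)
  displacement.  Conditional on the jump configuration n the tips are
  multivariate normal with covariance σ₀²·V(n), where V(n) accumulates
  *effective* branch lengths t_i + α·n_i — one jump is equivalent to α
  extra units of branch length.  The marginal likelihood sums this Gaussian
  over the Poisson prior on n.

α (per-jump variance as a multiple of the Brownian rate; dimensionless) and
λ (jumps per unit branch length) are partially confounded along a ridge of
constant jump variance contribution λ·α, so α is profiled over the fixed
grid {0.1, 0.25, 0.5, 1, 2, 4} while (σ₀², λ, x₀) are estimated at each
grid value; the grid value with the largest estimated marginal
log-likelihood wins, with a warning if the maximum sits on the grid edge.
Note that the OU constraint strength and the jump-size multiplier are
different parameters that are conventionally both written α; they are
separate fields (`alpha_ou` vs `alpha`) here.

## Likelihood computation

All Gaussian tree likelihoods go through Felsenstein's pruning algorithm on
a binary encoding of the tree (polytomies are folded with zero-length
branches, which leaves the tip covariance unchanged).  Pruning gives the
restricted statistics (contrast sum of squares, GLS root mean, root
variance, log-determinant) in O(n), so the BM fit is closed-form and a
jump-configuration likelihood costs O(n).  These kernels are numba-compiled.

The Lévy marginal likelihood is computed three ways, by preference:

1. **Exact truncated enumeration** when the per-branch Poisson truncation
   (mass ≥ 1−1e-6) yields at most ~10⁶–10⁵ configurations (guarded).  This
   is the correctness anchor; it is monotone in the truncation bound.
2. **Thermodynamic integration (TI)** over the jump rate for larger trees:
   d log p(x; λ)/dλ = E[N_tot | x, λ]/λ − L (L = total tree length), so
   log p is the BM log-likelihood plus an integral of posterior mean jump
   counts down a geometric rate ladder.  The posterior means come from the
   jump-count MCMC; the ladder descends adaptively (fine steps where
   E[N_tot] moves, up to 32× coarser on plateaus) until E[N_tot] < 0.1,
   where a linear small-rate closure finishes the integral.  Validated to
   < 0.6 nats against exact enumeration on strong-jump fixtures.
3. **Prior Monte Carlo** (`levy_marginal_loglik_mc`): configurations drawn
   from the Poisson prior, Gaussian densities averaged in log-sum-exp form,
   delta-method standard error.  Exposed because it is simple and unbiased
   with quantified error on small problems; on trees with hundreds of
   branches its log-estimate degenerates (ESS collapse), which is why the
   fitting path reports TI instead.

## EM + MCMC fitting

With α fixed, (σ₀², λ, x₀) are fitted by a stochastic EM:

* **E-step.** Metropolis-Hastings over jump configurations: single-branch
  ±1 proposals (a −1 proposal at zero is rejected, keeping the kernel
  symmetric on the non-negative lattice).  A proposal only changes pruning
  quantities on the branch-to-root path, so one evaluation is O(depth).
  Default 10 retained configurations per iteration, 5 sweeps apart,
  warm-started across iterations.
* **M-step.** λ ← (mean sampled total jumps)/L; x₀ and σ₀² maximize the
  sample-averaged complete-data Gaussian log-likelihood in closed form from
  the pruning statistics of each retained configuration.
* **Initialization.** The BM fit absorbs the total variance rate
  σ₀²(1+λα); starting from an even split (σ₀² = σ²_BM/2, λ = 1/α capped at
  one expected jump per branch) places the chain on the ridge so EM only
  slides along it.
* **Convergence.** Monte-Carlo E-steps keep raw iterates fluctuating a few
  percent indefinitely, so convergence is judged — and the returned
  estimates computed — on trailing 5-iteration running means (stochastic-EM
  averaging): relative change < 1e-3 for 3 consecutive iterations, capped
  at `em_max_iter` (an unconverged cap returns the trailing averages,
  flagged).  With the default iteration budgets the flag is usually
  "unconverged" while the averaged estimates are already stable to a few
  percent; tests therefore assert estimates, not the flag.

Branch posteriors (`branch_jump_posteriors`) run the same sampler at fixed
(empirical Bayes) parameters; pp(branch) = fraction of post-burn-in
configurations with n_i ≥ 1, averaged over two independent chains, with the
maximum between-chain disagreement reported and > 0.05 flagged (never
silently dropped).

## Threshold calibration

Five datasets are simulated under the fitted parameters, posteriors
re-inferred from the simulated tip values only, and candidate thresholds
(0.05 grid plus 0.75/0.9/0.95) swept.  A called branch is a true jump
estimate iff the simulation planted ≥ 1 jump there; precision and recall
(percent) pool numerators and denominators across the simulations, with the
recall denominator counting branches carrying ≥ 1 simulated jump (multiple
jumps on one branch are one detectable event; raw event counting is
available).  The chosen threshold maximizes pooled recall subject to
pooled precision ≥ 90%, ties toward the lower threshold; if no threshold
qualifies, the highest-precision one is returned flagged unattainable.
Thresholds at which nothing is called have undefined (not 0 or 100)
precision and are excluded from the rule.

## Jump analysis

Calls are branches with pp strictly greater than the chosen threshold,
serially indexed in preorder.  The magnitude of a call is the median GC% of
tips under the called branch minus the median under its sister branch,
after removing — on both sides — tips under any *other* called branch
properly nested within that side; a call on the sister branch itself is not
"nested" and does not exclude it.  Calls whose affected or sister side
empties out are reported magnitude-unavailable rather than dropped.  The
depth distribution of calls is tested against placement proportional to
branch length by a Monte-Carlo KS test on branch-midpoint depths
(two-sided in the sense that any distributional difference inflates the
statistic).

## Ecology

Host status (host_dependent / host_associated / not_host_dependent /
unknown) and an ordered oxygen scale (anaerobic < facultative < aerobic =
obligately_aerobic, the last two sharing a rank) are majority-rule clade
annotations; unknowns propagate and are excluded from tallies, never
guessed.  Direction-by-switch association is tested with a from-scratch
two-sided Fisher's exact test (log-factorial hypergeometric enumeration,
minimum-likelihood two-sided rule, 1e-12 relative tie tolerance); the odds
ratio is the sample (ad)/(bc) with inf/NaN zero-cell conventions.

## Synthetic data

`simulate_yule_tree` implements the pure-birth process directly (n−1 birth
events plus one final exponential waiting time so pendant edges are
strictly positive), with optional multiplicative lognormal branch jitter
(median 1) to break ultrametricity the way rate variation does in real
substitution trees, and rescaling to a target mean root-to-tip depth.

`generate_dataset` emulates one order-level bacterial clade.  Defaults:
300 tips; mean depth 0.5 substitutions/site; σ₀² = 50 GC%²/unit;
λ = 2.5 jumps/unit (the low end of the fitted range across real clades);
α = 0.8, i.e. per-jump sd ≈ 6.3 GC% so planted jumps are individually
visible, with λα = 2 inside the observed ~0.5–3× jump-to-Brownian variance
ratio.  Under these conditions a self-simulated clade reproduces the
qualitative findings end to end: fat-tailed contrasts (excess kurtosis ≈ 2–3),
a Lévy-vs-BM likelihood-ratio p at the 1e-16 reporting floor, a calibrated
threshold near 0.65–0.95 with pooled precision ≈ 91% and recall ≈ 15–30%,
and call depths indistinguishable from length-proportional placement.

An optional reflecting boundary (e.g. GC ∈ [25, 75]) is applied per branch
increment; reflection is the simplest mechanism reproducing the observed
relationship between ancestral GC and jump direction (more upward jumps
from low-GC ancestors and vice versa) without extra parameters.  Ecological
annotations attach to planted-jump branches with
P(host gain | downward jump) tilted by `ecology_effect` (0 = independence),
enabling both null and power testing of the ecology stage.  Everything is
deterministic given (seed, configuration); the truth is written to a JSON
sidecar that inference stages never read.

What the generator does **not** emulate: GTDB-scale taxon sampling
heterogeneity and de-replication artifacts, phylogenetic error (topology
and branch-length uncertainty), among-clade rate heterogeneity, directional
jump-size asymmetry (real downward jumps are larger than upward ones), and
any correlation structure between ecology and tree position.  Green tests
on synthetic data therefore demonstrate correctness of the machinery under
the model's own assumptions, not robustness to their violation.

## Numerical choices and degenerate inputs

* p-values reported by the LRT are floored at 1e-16.  λ-vs-BM tests use
  df = 2 (λ and α added) by default, configurable.
* When the alternative log-likelihood is a stochastic estimate, the LRT
  statistic may come out slightly negative by estimator noise; the pipeline
  clamps it at 0 (`clamp=True`).  For deterministic fits a negative
  statistic raises, since it signals a broken optimization.
* The OU fit profiles (θ, σ²) in closed form and searches α_ou on a
  log-grid over [1e-8, 10/tree height] with bounded 1-D refinement, then
  evaluates the exact α_ou = 0 boundary so the OU likelihood can never fall
  below BM by approximation error.  On Brownian-like data the boundary
  estimate α̂_ou = 0 occurs on a substantial share of datasets and small
  positive values elsewhere, the textbook behaviour of a boundary MLE —
  which is also why the OU-vs-BM and Lévy-vs-BM LRT p-values under the null
  are conservative (an atom near p = 1), not uniform.
* Zero-length branches are legal everywhere except as contrast
  denominators; they can never carry jumps (Poisson rate 0).
* De-replication (`subsample_tree`) collapses clades younger than the
  threshold (age = maximum node-to-tip path; representative =
  lexicographically smallest label) and iterates to a fixed point, because
  pruning can shorten a surviving node below the threshold; the result is
  idempotent.
* Sample excess kurtosis uses raw central moments (m₄/m₂² − 3) with no
  small-sample correction.
* All randomness descends from one explicit integer seed through
  `numpy.random.SeedSequence` spawning; numba kernels receive 32-bit
  sub-seeds.

## Known limitations

* The EM's marginal-likelihood ranking across the α grid carries TI noise
  of a few nats; with weak jump regimes the profiled α can land on a
  neighbouring grid value.
* Posterior MCMC uses single-branch moves only; on very strong-signal data
  mixing across alternative jump placements that explain the same shift
  (parent vs child branch) is slow, which the two-chain disagreement flag
  surfaces.
* Precision/recall calibration inherits Monte-Carlo noise from five
  simulations, as in the original design; the chosen threshold can move
  between adjacent grid points across seeds.
* Magnitude estimates are sister-clade median differences, a biased
  estimator when sister clades themselves drift; exact only in the
  noise-free limit (which the tests pin at 1e-9).
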