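# Methods

## The scientific problem

Children acquiring arithmetic shift from slow counting procedures to direct
memory retrieval of facts. Observable accuracy and reaction time conflate the
two strategies, so this package infers them latently: every verification
trial (e.g. "3 + 4 = 7, true or false?") is attributed probabilistically to a
memory-retrieval or a counting process, and a signed functional brain-network
analysis links the resulting latent change scores — in particular retrieval
efficiency gains — to reorganization of hippocampal circuitry.

## The strategy-mixture diffusion model

Each trial's joint (choice, RT) outcome is a two-component mixture of Wiener
first-passage distributions. For child *i* on item *k*:

* Strategy selection is logistic in the difference between the child's
  retrieval propensity and the item's retrieval difficulty:
  `P(memory) = 1 / (1 + exp(-(rho_i - rho_k)))`; counting is the complement.
  `rho_k` is a group-level item-response parameter (items are assumed
  objectively stable over the 8-week interval; `rho_k` is shared across
  sessions).
* The memory process drifts at `delta_M_i / (1 + exp(rho_k))` — the child's
  retrieval efficiency attenuated by item difficulty. The counting process
  drifts at `delta_C_i / n_k`, where `n_k` is the smaller addend (min
  counting: count up `n_k` steps from the larger addend).
* Both processes share the decision threshold `alpha_i` and start unbiased
  (bias fixed at 0.5 — the verification task has no stated response
  asymmetry; the parameter is exposed for completeness). Counting incurs the
  extra non-decision component `tau_switch_i` on top of the base `tau_i`,
  representing the time spent persisting with retrieval before switching.
  The mixture is a plain two-component mixture with the shifted counting
  non-decision time; the memory component is not truncated or conditioned at
  the switching time. The upper boundary is the correct response for both
  strategies.

Trial-level strategy attribution is the posterior responsibility
`P(memory) f_M / [P(memory) f_M + P(counting) f_C]`, and "retrieval use" per
participant-session is by default the mean responsibility over valid trials
(continuous); a classified-proportion variant (responsibility > 0.5) is a
config switch, since either convention is defensible and they track each
other closely.

RTs under 300 ms are anticipatory and treated as missing at random (the
record is kept, the RT excluded from the likelihood). RTs above the 9.5 s
deadline are invalid records, not missingness, and are dropped.

### Wiener density evaluation

The defective first-passage density uses the dual small-time / large-time
series with truncation chosen adaptively per evaluation to an absolute
tolerance of 1e-10, evaluated in log space. Boundary masses have closed
forms from the scale function. The independent simulation oracle is an
Euler–Maruyama path simulator (default step 1e-4 s) with the
Broadie–Glasserman–Kou boundary correction (boundaries shrunk by
0.5826·sqrt(dt)) so that discrete-monitoring bias is O(dt) rather than
O(sqrt(dt)); the oracle shares no code with the series density.

## Hierarchical inference

Pre-level parameters and pre-to-post changes of `rho_i`, `delta_M_i`,
`delta_C_i`, `alpha_i` and the change of `tau_switch_i` get hierarchical
normal priors; `tau_i` and the pre-level `tau_switch_i` get uniform priors
(bounds (0.01, 2) s and (0, 3) s); item difficulties `rho_k` get a
hierarchical normal. Hypermeans jointly carry a multivariate normal prior
whose covariance has an inverse-Wishart prior (df = dimension + 1, identity
scale); hierarchical SDs carry uniform(0, 5) priors. These hyperprior
constants are weakly informative defaults — the quantities they control are
all order-1 on their natural scales — and every one is exposed in
`PriorSpec`.

Positivity of the efficiencies and threshold (at both sessions, i.e. of
`pre` and `pre + change`) is enforced as a joint feasibility indicator inside
the Metropolis target rather than by per-family analytic truncation: the
post-session constraint couples the pre and change parameters, so no clean
per-family normalizer exists. The neglected normalizer's dependence on the
hyperparameters is negligible when group means sit well inside the feasible
region, which holds at the scales of this task.

The sampler is adaptive Metropolis-within-Gibbs:

* participant and item parameters — random-walk Metropolis against the
  exact trial likelihood, proposal scales tuned toward 0.44 acceptance
  during burn-in only (Robbins–Monro), frozen afterwards;
* hypermeans — exact multivariate-normal Gibbs;
* hierarchical SDs — exact Gibbs via the truncated inverse-gamma
  conditional of the variance;
* hypermean covariance — conjugate inverse-Wishart Gibbs;
* joint-regression coefficients and residual scale — conjugate Gibbs.

Defaults are 3 chains of 10,000 sweeps with 5,000 burn-in and no thinning;
`FitConfig.ci()` (3 × 1,000 / 500) is the reduced profile the test suite and
the acceptance script use. Runs are bit-reproducible given the seed.
Convergence is assessed by split-R-hat (< 1.1) and bulk ESS on every scalar
parameter; failures are flagged in the result and warned about, never
silently accepted. Chains that are exact copies of one another are reported
as R-hat = 1 by convention (no between-chain disagreement). At the reduced
profile some weakly identified parameters (notably the common location of
`rho_i`/`rho_k`, which is anchored only through the drift attenuation) can
exceed the threshold; the recovery analyses rest on between-participant
contrasts, which mix much faster than the common location.

### Posterior predictive and model comparison

Posterior predictive checks resimulate replicate datasets from evenly thinned
draws with the package's own generative simulator and compare per
participant-session mean RT and error rate against 95% predictive intervals.
Model comparison fits three candidates — a plain hierarchical DDM, a
single-strategy DDM with item difficulty, and the full strategy-dissociation
model — and ranks them by WAIC computed from the pointwise log-likelihood of
thinned draws (elpd, effective parameter count, SE, and pairwise difference
SE are reported; the criterion choice is recorded in the output).

### Joint brain–behavior model

The latent regression extends the hierarchy with
`d_diversity_i = sum_p beta_p * d_param_{p,i} + eps_i` over the five change
parameters, fitted jointly so that measurement error in the latent changes
is propagated. `beta_p ~ N(0, 1)` (scale exposed); the closed-form prior
density at zero feeds the Savage–Dickey Bayes factor
`BF10 = p(beta=0 | prior) / p(beta=0 | posterior)`, with the posterior
density at zero estimated by Gaussian KDE (Scott bandwidth) and
cross-checked by a normal approximation; both are reported with an
instability flag when they disagree by more than 20%. Evidence labels: BF >
3 moderate for the alternative, 1/3–3 insufficient, < 1/3 evidence of
absence.

## Network analysis

Edges are PPI interaction coefficients: each target node is regressed by OLS
on [intercept, seed signal, task contrast, seed × task]; the interaction
coefficient is the edge weight, the matrix is symmetrized by averaging both
directions, the diagonal zeroed, and no threshold applied. Seed-signal
deconvolution is out of scope — the regression runs on the supplied signals
directly.

Community detection greedily optimizes the asymmetric signed modularity Q*
(positive-channel modularity at full weight minus the negative-channel term
down-weighted by total strength) with Louvain passes; the default is the
best of 100 seeded restarts, ties broken by fewer modules then lexicographic
affiliation, making the stochastic heuristic a deterministic function of
(matrix, seed). Each participant-session matrix is partitioned independently
with the same policy (required for the per-child partition distance). An
exhaustive oracle verifies exact Q* optimality on all tested instances up to
8 nodes.

Global reorganization is the partition distance `1 - NMI` with the
arithmetic normalization `2 I / (H1 + H2)` (the convention under which the
mutual-information term ranges over [0, 1]; recorded in output metadata),
tested against zero with a two-tailed one-sample t-test. Regional
reorganization is the diversity coefficient — the normalized entropy of a
node's per-module strength, computed per sign channel with the node's own
module included (toolbox convention) and the positive channel reported by
default; isolated nodes get 0. Node-wise pre/post changes use paired
two-sided Wilcoxon signed-rank tests with Benjamini–Hochberg adjustment
across nodes, with optional pooling of bilateral nodes (e.g. left/right
intraparietal sulcus averaged before testing).

## Behavioral statistics

Paired t-tests report both Cohen's d conventions: `d_z` (mean difference /
SD of differences) and the headline `d_av` (mean difference / average of the
pre and post SDs) — the average-variance convention is the one consistent
with printed effect sizes of this size at these t values, and reporting both
avoids a silent guess. Spearman correlations use average ranks with the
t-approximation p-value; an exact-enumeration option exists for n ≤ 8
(Monte-Carlo permutations for n ≤ 10). Dependent correlations sharing an
outcome are compared by a within-participant label-swapping permutation test
with Steiger's Z reported as an analytic cross-check (the comparison method
is not standardized in the field; the permutation test is the primary
inference). The Region × Time repeated-measures ANOVA interaction comes from
a standard two-way within-subjects decomposition.

## The synthetic cohort

The generator mirrors the study conditions: 35 children, single-digit
addition verification with operands 2–9 (36 unordered pairs), a 9.5 s
deadline, 24 trials per session by default (the scanner task's count) and
200 for recovery studies (the hierarchical fit pools information; the larger
count makes individual-level recovery measurable), hierarchically
distributed individual parameters with training shifts, and 30-node signed
networks with a 2-block (cortical vs medial-temporal) pre structure and a
3-block post structure. Default generative hyperparameters place mean RTs
near 1.5 s, pre-training accuracy near 75%, a positive mean retrieval
propensity shift (+0.5), and a retrieval-efficiency gain (+0.5 on a base of
1.3) — values a developmental training cohort of this kind would plausibly
produce. Edge noise is i.i.d. Gaussian before symmetrization (the simplest
structure satisfying the analysis's assumptions), block means +0.35 within /
+0.05 between with SD 0.15.

The designated hippocampal node's post-training positive weights are
rewritten so its diversity-coefficient change equals
`beta * d_delta_M + eps` (default beta = -0.8, residual SD 0.04), by solving
the own-module-share that yields the target entropy; infeasible targets are
clipped with a warning. Behavior is simulated by the two-step process
(strategy Bernoulli, then Euler–Maruyama diffusion with the boundary
correction) — deliberately the path-level route, independent of the
analytic density it is used to validate.

What the generator does **not** emulate: hemodynamics and BOLD noise
structure (edges are clean block models, not PPI outputs of real time
series), RT contaminants other than fast guesses, item-difficulty drift
across sessions, strategy mixtures beyond the two modeled, and any
dependence structure between behavioral and network noise beyond the single
planted coupling. Passing tests therefore demonstrate internal consistency
and recoverability under the model's own assumptions, not robustness to the
violations real data would bring.

## Problem sizes in the test suite

The suite exercises the density oracle at 1e6 simulated paths per parameter
set (step 1e-4), the mixture oracle at 1e5 trials per case, parameter
recovery at the study scale (35 × 200 trials/session) under the reduced
MCMC profile, and model-recovery across 10 replicate cohorts of 10
participants × 60 trials/session at further-reduced draws — sizes chosen so
the whole suite completes on a single CPU while keeping every check
informative. The acceptance script uses 2e5 paths for the density oracle
and the same 1e5 mixture trials.

## Known limitations

* The Metropolis-within-Gibbs sampler mixes slowly over the common
  `rho_i`/`rho_k` location; absolute propensity levels carry more posterior
  uncertainty than contrasts.
* Censored trials (deadline hits) are treated as missing rather than
  likelihood-censored; at the default conditions they are well under 1% of
  trials.
* The joint model's coefficient for the planted coupling is attenuated when
  individual change parameters are weakly identified (hierarchical
  shrinkage); the credible interval remains calibrated, which is what the
  recovery check asserts.
* Savage–Dickey KDE estimates are unstable when the posterior places almost
  no mass near zero; the normal-approximation value and an instability flag
  are reported for exactly this case.
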