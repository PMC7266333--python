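# Methods

## Model overview

`devtraj` chains three components: (1) per-child beta-Bernoulli sequential
updating of milestone achievement, (2) a rescaled area between each child's
posterior-mean step function and a gold-standard reference, and (3) a
Dirichlet process mixture model (DPMM) over the logit-transformed areas,
post-processed into a single consensus clustering.  The design assumes
milestones within a child are conditionally independent Bernoulli trials
(dependence is captured through the sequentially updated prior), that
deviation from typical development is well summarised by one scalar per
functional domain, and that the population of deviation profiles is a
countable mixture of Gaussian clusters in logit-area space.

## Sequential updating

Each observation updates a Beta(a, b) state: a success increments `a`, a
failure `b`; the trace entry for observation *i* is the posterior *after*
incorporating it.  This convention makes a child who matches the reference
on its first milestones accrue exactly zero area there, which the
predictive (prior-before-observation) convention cannot.  All children
start from Beta(1, 1).

HPD intervals (default mass 0.95) are the shortest intervals containing
the target mass.  For monotone Beta densities one endpoint is pinned at 0
or 1; for `a <= 1` and `b <= 1` (flat or bathtub densities, where the HPD
region is non-unique) the equal-tailed interval is used — only the
starting Beta(1, 1) is affected.  Interior-mode cases minimise the
interval width over the lower tail mass with a bounded scalar optimiser
(`xatol = 1e-10` on the tail mass, i.e. ~1e-8 on the CDF scale).  Results
are memoised: cohort traces revisit the same integer (a, b) pairs
constantly.

Children with milestones missing mid-sequence are rejected in the core
path, mirroring a complete-case restriction; `allow_gaps=True` skips and
continues, and the pipeline excludes such children with a warning naming
them.

## Deviation areas

The reference trace for *n* milestones has means (i + 1)/(i + 2).  Both
traces are step functions over the milestone-index axis with unit spacing;
defining the terminal step t_{n+1} := t_n + 1 makes the area formula
well-posed, and with w = n observed milestones the rescaled area reduces
to the mean absolute difference of posterior means.  The milestone index
(1..58 per domain), not the calendar month, is the time axis — under this
convention the terminal tail term (w − t_n) of the area formula vanishes
exactly.  Children are each compared to a reference truncated to their own
length, so late entry into the program is handled by aligning starting
points.

Areas are clamped to [eps, 1 − eps], eps = 1e-3 by default, before the
logit.  Smaller eps turns exact-zero areas into extreme outliers in
feature space; 1e-3 matches the resolution at which such area tables are
usually reported.  Note the flip side: at eps = 1e-3 a child with zero
failures in a domain sits ~3 logit units below a child with a single
failure, so near-perfect children can form their own tight clusters — an
effect visible in real cohorts as separate "achieved all" vs "achieved
most" groups.

## Dirichlet process mixture

Components are multivariate normals with a conjugate
normal-inverse-Wishart base measure.  Defaults anchor the priors to the
data: b0 = feature column means, C0 = sample covariance (ridged to
positive definiteness if degenerate), N0 = 0.1, c0 = p + 1 degrees of
freedom (3 for bivariate scenarios, 7 for the six-domain feature matrix),
and alpha ~ Gamma(1, 1).  N0 controls the dispersion of cluster means
around b0 and matters most when clusters overlap; values in [0.1, 0.5]
behave well in the simulation scenarios.

Sampling follows Walker's uniform slice construction.  Per iteration:

1. conjugate NIW draws of (mu_k, Sigma_k) for every represented component
   (empty components draw from the prior; inverse-Wishart draws use the
   Bartlett decomposition, covariances are symmetrised, and Cholesky
   failures add 1e-10 diagonal jitter with a warning);
2. stick fractions V_k ~ Beta(1 + n_k, alpha + sum_{j>k} n_j);
3. slice variables u_i ~ U(0, C_{z_i}); sticks are extended lazily
   (fractions from the Beta(1, alpha) prior, parameters from the base
   measure) until the unbroken mass falls below min u_i, making the
   candidate set finite; allocations are then drawn with probability
   proportional to 1{C_k > u_i} times the component density;
4. Escobar–West auxiliary-variable update of alpha, keyed to the occupied
   component count (verified against 1-D quadrature of
   p(alpha | K, n) to < 2% in the tests) — the concentration update is not
   pinned down by the citation trail, and this is the standard scheme;
5. two Metropolis–Hastings label-switching moves: swapping the
   parameters and members of two random components given the weights
   (acceptance (C_l/C_k)^{n_k − n_l}) and swapping an adjacent pair
   wholesale including its sticks (acceptance
   (1 − V_{k+1})^{n_k} / (1 − V_k)^{n_{k+1}}).  Their correctness is
   enforced by a joint-density-ratio check and an empirical
   detailed-balance test on an enumerable toy state space, not by trusting
   any transcription.

K is recorded per iteration as the number of *occupied* components, the
quantity whose convergence is monitored.  Chains initialise allocations by
K-means (default plan: three chains at K = 5, 10, 15); chain seeds derive
from the master seed by a fixed offset (7919 per chain), so runs are
bit-for-bit reproducible.  Trailing unoccupied components are trimmed each
iteration; interior unoccupied components are kept because stick positions
matter.

## Post-processing

The posterior similarity matrix pools post-burn-in allocations across
chains (default burn-in: the first 50% of each chain — the original
analyses do not state a burn-in, so a conventional half is used).  PAM
(BUILD + SWAP, implemented here and cross-checked against R's
`cluster::pam` and exhaustive search) partitions 1 − PSM for k = 2..20;
the k with the largest average silhouette width wins, ties broken toward
smaller k.  Singleton clusters contribute silhouette 0 (Rousseeuw's
convention).  PAM guarantees only a single-swap local optimum; on
unstructured dissimilarities it can sit measurably above the global
optimum (R's implementation returns the same solution), while on clearly
separated consensus structure it attains it.  The Gelman-Rubin statistic
is applied to the discrete K trace as if continuous.

## Synthetic data

The milestone generator emulates a real assessment schedule: per domain,
three milestones per month in months 1–12, two in months 13–18, one in
months 19–25 and single milestones at 28, 31, 34 — 58 per domain, 348
total.  Children draw milestones independently from a change-point
Bernoulli profile (p_before until a per-domain onset index, p_after from
then on).  Default archetypes: typical (p = 0.95 throughout), global delay
(onset at milestone 10, 0.9 → 0.25 across all domains), isolated speech
delay (speech onset 8, 0.9 → 0.15; other domains 0.95).  The typical rate
0.95 keeps the zero-failure point mass small (P ≈ 0.05 per domain) so that
typical children form one coherent cluster rather than an eps-driven
lattice of point masses; a cohort dominated by typical children yields the
strongly right-skewed area distribution characteristic of community
samples.  What the generator does **not** emulate: orderedness of real
milestones (real achievement probabilities decay smoothly rather than
jump), within-month dependence, attrition and missingness, and
child-specific severity gradients.  Passing recovery tests therefore show
the pipeline recovers change-point-style group structure, not that it
resolves every clinically meaningful distinction in real data.

Gaussian scenarios place three cluster means at the vertices of an
origin-centred equilateral triangle with unit isotropic noise; side
lengths 8 / 6 / 4 give the "separated" / "adjacent" / "overlapping"
presets.  The exact geometry of the original simulation tool is not
recoverable, so these presets are a visual match, and accuracy targets on
them are stochastic rather than exact.  For the overlapping preset the
Bayes-rule ceiling, computed by Monte-Carlo against the generating
densities, is ≈ 96%.

## Problem sizes and numerical choices

Recovery studies in the tests and the acceptance script run 3 chains of
20,000 iterations on 150 bivariate observations (~2 minutes per study on
one CPU); the package supports arbitrarily long runs and segment-and-resume
via `run_chain(init_state=...)`.  Slice samplers mix slowly over K on
higher-dimensional, near-degenerate features: on six-domain milestone
features, chains initialised at different K can stay in distinct K bands
for tens of thousands of iterations (the consensus clustering, which pools
chains, is far more stable than K itself).  Production analyses of
milestone cohorts should use orders of magnitude more iterations and
verify GR < 1.1 for K and alpha, exactly as the diagnostics report.

## Known limitations

- No covariates, no within-month binomial aggregation, no functional-data
  smoothing of traces.
- Missing data handling is exclusion (or naive skip-and-continue); the
  area metric overestimates delay when gaps are skipped.
- Component likelihoods are Gaussian only; truncated/retrospective
  samplers and alternative consensus methods (Binder loss, adjusted-Rand,
  hierarchical consensus, least-squares clustering) are out of scope.
- The silhouette-over-PAM selection inherits PAM's local-optimality
  caveat.
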