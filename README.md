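# devtraj

Identifying latent subgroups of children with developmental delay from
binary milestone records.

Screening programs track whether a child displays expected behaviours
("milestones") at scheduled ages across functional domains — vision,
auditory, tactile, movement, speech and hand function.  `devtraj`
implements a three-stage ensemble that turns these noisy binary sequences
into interpretable subgroups of children with similar deviations from
typical development, for researchers and clinicians analysing cohort data
from milestone-tracking programs.

## The method

**1. Beta-Bernoulli sequential updating.**  Each child's milestone record
within a domain is an ordered sequence of Bernoulli trials.  Starting from
a uniform Beta(1, 1) prior, the posterior after observing *z* successes in
*N* trials is Beta(*z* + 1, *N* − *z* + 1); each new observation adds one
to a shape parameter.  The sequence of posterior means
*a*/(*a* + *b*) — with 95% highest-posterior-density intervals — is the
child's developmental profile.

**2. Deviation areas.**  A gold-standard profile is built for a
hypothetical child achieving every milestone (its *i*-th posterior mean is
(*i* + 1)/(*i* + 2)).  The area between the child's posterior-mean step
function *F*₁ and the reference *F*₂, rescaled by the number of observed
milestones *w*,

&nbsp;&nbsp;&nbsp;&nbsp;area = (1/*w*) Σᵢ |*F*₂(*tᵢ*) − *F*₁(*tᵢ*)| (*tᵢ*₊₁ − *tᵢ*),

lies in [0, 1]: 0 for a child tracking the reference exactly.  The six
per-domain areas are logit-transformed into each child's feature vector.

**3. Dirichlet process mixture clustering.**  The feature vectors are
modelled as a DP mixture of multivariate normals with stick-breaking
weights *C*ₖ = *V*ₖ ∏ⱼ₍ₖ (1 − *V*ⱼ), *V*ⱼ ~ Beta(1, α), a conjugate
normal-inverse-Wishart base measure (Σₖ ~ IW(*c*₀, *C*₀), μₖ | Σₖ ~
MVN(*b*₀, Σₖ/*N*₀)) and a Gamma(η₁, η₂) hyperprior on α.  Sampling uses
Walker's slice sampler with Metropolis–Hastings label-switching moves and
Escobar–West resampling of α.  Because labels switch, chains are
summarised by the posterior similarity matrix (pairwise co-clustering
frequencies); partitioning around medoids on 1 − PSM for k = 2..20,
compared by average silhouette width, yields the consensus clustering.
Convergence is monitored by the Gelman-Rubin statistic for the occupied
cluster count K and for α (< 1.1).

## Worked example

```python
from devtraj import (DirichletProcessMixture, classification_accuracy,
                     generate_gaussian_clusters, TYPICAL, GLOBAL_DELAY)

# three slightly-overlapping bivariate Gaussian clusters, 50 points each
y, truth = generate_gaussian_clusters("overlapping", seed=1)
model = DirichletProcessMixture(y)          # data-anchored default priors
results = model.fit(n_iter=20_000, init_K=(5, 10, 15), seed=1)
print(results.summary())
consensus = results.consensus()
print("accuracy:", classification_accuracy(truth, consensus.assignment))
```

```
Dirichlet process mixture (slice sampler)
=========================================================
Observations: 150    Dimensions: 2
Chains: 3    Iterations/chain: 20000    Burn-in: 50%
Priors: N0=0.1, c0=3.0, alpha ~ Gamma(1.0, 1.0)
Gelman-Rubin: K = 1.002, alpha = 1.000  (converged at 1.1)
Posterior of K (pooled, post burn-in):
    K = 3      0.258
    K = 4      0.400
    K = 5      0.225
    K = 6      0.085
    K = 7      0.024
    K = 8      0.006
    K = 9      0.002
    K = 10     0.000
    K = 11     0.000
Consensus clustering: k = 3, average silhouette = 0.882
accuracy: 95.33333333333333
```

The sampler explores partitions with 3–6 occupied components (extra
components are mostly small and transient), the chains agree
(Gelman-Rubin ≈ 1), and the label-free consensus recovers the three
simulated clusters, classifying 95.3% of points correctly — close to the
≈ 96% Bayes-rule ceiling for this overlap.

For milestone data, the same model runs end to end from a cohort table:

```bash
devtraj simulate cohort --n-typical 40 --n-delayed 40 --seed 1 --out cohort.csv
devtraj cluster --cohort cohort.csv --seed 1 --out run/
devtraj report --run-dir run/
```

which writes posterior traces, per-domain areas, the logit feature matrix,
per-chain MCMC traces, the posterior similarity matrix, the consensus
partition and a per-cluster mean/sd area table.  `devtraj grid` compares
prior variants (e.g. different *N*₀) on one feature matrix.

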