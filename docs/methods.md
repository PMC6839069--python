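# Methods

## Model

A study comprises $n$ cases; case $j$ contributes the set $G_j$ of loci
mutated in at least one of its two tumors, each locus with a known
occurrence probability $p_i \in (0,1)$ and a status (shared in both tumors,
or private to one). The generative model:

1. $C_j \sim \mathrm{Bernoulli}(\pi)$ — the pair is clonally related or not.
2. If $C_j = 1$, a clonality signal $\xi_j \in [0,1)$ with
   $u_j = \log(-\log(1-\xi_j)) \sim N(\mu, \sigma^2)$; if $C_j = 0$,
   $\xi_j = 0$. The signal is the expected fraction of the case's observed
   mutations that are matches, a proxy for the fraction of tumor evolution
   shared by the pair.
3. Given $(\xi_j, C_j)$, each locus in $G_j$ is independently shared with
   probability $\{\xi_j + (1-\xi_j)p_i\}/\{\xi_j + (1-\xi_j)(2-p_i)\}$
   (reducing to $p_i/(2-p_i)$ at $\xi_j=0$), private otherwise.

The "lognormal with mean $\mu$ and sd $\sigma$" parameterization is read on
the log scale (i.e. $\mu,\sigma$ are the moments of the underlying normal of
$u_j$). This is the only reading consistent with the built-in scenarios: the
strong-signal scenario $(\mu,\sigma)=(0.7,0.3)$ then concentrates the signal
around a median $\xi = 1-\exp(-e^{0.7}) \approx 0.867$ (most mutations of a
clonal case matched), and the weak scenario $(-2, 1.5)$ around
$\xi \approx 0.127$; a natural-scale reading would not even admit
$\mu = -2$.

Assumptions worth stating: the $p_i$ are known constants (their estimation
error is ignored); loci are conditionally independent given the signal; a
single signal distribution is shared by all clonal cases; cases are
independent. Cases with no observed mutations are retained and contribute a
likelihood factor of 1 (their posterior clonality equals $\pi$).

## Marginal likelihood and quadrature

Per case, the observed-data likelihood mixes the signal-marginalized clonal
branch with the independent branch:
$L_j = \pi \int P(Y_j \mid \xi, C{=}1)\, g(\xi)\, d\xi + (1-\pi) P(Y_j \mid C{=}0)$.
The integral is evaluated by Gauss–Hermite quadrature on the $u$ scale,
where the signal density is exactly normal and the integrand smooth, with
nodes re-centered on the current $(\mu, \sigma)$ and weights renormalized to
sum to one. All accumulation is in log space with log-sum-exp; the private
kernel's $\log(1-\xi)$ term is computed as $-e^u$ directly, so cases with
hundreds of loci and $p_i$ down to $10^{-6}$ neither underflow nor lose the
far-signal tail.

Node count: the fitting default is $K = 64$; `build_grid` accepts any $K$.
Measured against adaptive quadrature (`scipy.integrate.quad`) on a stress
suite (up to 10 loci, $p$ down to $10^{-5}$, $\sigma$ up to 1.5), $K=64$ is
accurate to ~$3\times10^{-4}$ log-likelihood units in the worst corner
(very rare loci under a wide signal distribution) and far better in typical
regions; $K=256$ is uniformly accurate to ~$10^{-9}$ and is the
accuracy-grade setting used where sub-$10^{-6}$ agreement matters. The
$K=64$ default is a deliberate speed/accuracy trade for iterative fitting —
a $10^{-4}$ wobble in a log-likelihood of order $10^2$ moves no estimate
materially — and the test suite pins both tiers.

## Estimators

**One-step**: L-BFGS-B maximization of the summed marginal log-likelihood
over $(\pi, \mu, \sigma)$ with box constraints $\pi \in [0,1]$,
$\mu \in [-10, 10]$, $\sigma \in [0.05, 10]$. The bounds comfortably contain
all three study scenarios. A fitted $\pi$ within $10^{-8}$ of 0 or 1 sets
the `boundary` flag; a boundary estimate forces every case's posterior
clonality to the same extreme, which is the estimator's known failure mode
on sparse data.

**EM**: treats $(C_j, \xi_j)$ as latent. E-step, per case:
$w_j = \pi M_j / (\pi M_j + (1-\pi) I_j)$ with $M_j$ the quadrature clonal
marginal and $I_j$ the independent likelihood, plus the posterior mean and
second moment of $u_j$ given clonality (quadrature expectations under the
node posterior). M-step, closed form: $\hat\pi = \bar w$;
$\hat\mu, \hat\sigma^2$ the $w$-weighted mean and variance of the posterior
$u$ moments, with $\hat\sigma$ floored at 0.05 (prevents a degenerate
point-mass signal when almost no weight is clonal; exposed as
`sigma_min`). If all $w_j = 0$ the signal parameters are left unchanged
(flat direction; logged). $\pi$ is never clipped: EM can reach a boundary
only if every individual posterior does, which is precisely why it rescues
most one-step boundary failures.

Initialization defaults to $(\pi_0, \mu_0, \sigma_0) = (0.5, -1, 1)$ (the
intermediate scenario); `multistart=True` additionally tries
$\pi_0 \in \{0.1, 0.3, 0.5, 0.7, 0.9\}$ and keeps the best final
log-likelihood — mixture likelihoods here are multimodal and the restarts
are cheap at study scale. Convergence requires both $|\Delta \ell| < 10^{-6}$
and a maximum parameter change below $10^{-5}$, capped at 1000 iterations
with the full log-likelihood trace exposed. One numerical safeguard: because
the quadrature grid moves with $(\mu,\sigma)$, the evaluated log-likelihood
carries a parameter-dependent error of order $10^{-5}$ near flat ridges; if
an iteration fails to ascend by more than $10^{-10}$ the fit stops and keeps
the previous iterate, so the reported trace is nondecreasing by
construction and the stop is reported explicitly.

Degenerate inputs: an all-empty dataset has a flat likelihood; both
estimators return the starting parameters, converged, with a logged warning
(any value is a maximizer; determinism is preferred).

## Identifiability caveat (flat ridges)

When the data contain few matches, the likelihood develops a near-flat ridge
on which a small signal ($\mu$ very negative, so $\xi$ near 0) trades off
against a large, weakly identified $\pi$: a clonal component concentrated
near $\xi = 0$ mimics the independent component, yet a single rare match
(e.g. one $p = 10^{-3}$ shared locus) still earns a large likelihood ratio
from a tiny signal. On such data the maximum can sit far from where a
coarser integration scheme — one unable to resolve signal mass below its
lowest node — would place it, and any reported point estimate is sensitive
to the optimizer's path and stopping rule. `clonalmix` reports these
situations honestly: EM flags non-convergence when the crawl along the
ridge outlasts the iteration cap, the trace is available for inspection,
and the per-case posteriors (which remain stable and interpretable) are the
output to trust. The packaged study minus its two strongest clonal cases is
exactly such a dataset and is discussed in the README.

## Synthetic data

The generator draws exactly the process the likelihood assumes, so
parameter-recovery results are a clean test of the estimators, not of model
misspecification. What the likelihood does not fix — the mutation profile —
is an explicit `LociModel`: loci per case $\sim 1 + \mathrm{Poisson}(6)$
(matching the packaged study's per-case totals, mostly 3–18), occurrence
probabilities log-uniform on $[10^{-4}, 10^{-2}]$ with probability 0.9
(rare panel variants) and uniform on $[0.05, 0.15]$ with probability 0.1
(hotspots, bracketing *PIK3CA* H1047R's 0.137). Truth records
($C_j, \xi_j$) are always emitted alongside the observables, in a separate
sidecar, since real data never contain them.

Features of real data the generator does **not** emulate: estimation error
and subtype dependence in $p_i$, dependence between loci (mutational
signatures, copy-number co-occurrence), panel-dependent locus counts, and
sequencing false negatives that can destroy true matches. Passing recovery
tests therefore demonstrate estimator correctness under the model, not
robustness to these violations.

The study runner fits every replicate of a (sample size × clonal proportion
× scenario) grid with both estimators and tabulates mean, sd, range,
exact-boundary counts (tolerance $10^{-8}$ — floating-point maximizers
rarely return a literal 0.0), and the EM summary restricted to replicates
where the one-step estimate hit a boundary. Default 200 replicates per cell
(a desk-scale compromise; the CLI flag restores more), with a counter-based
RNG split (`[seed, cell, replicate]`) so each replicate is reproducible
independent of execution order. The test suite exercises 200-replicate
cells at $n = 100$, a 100-replicate weak-signal cell at $n = 25$, and
20-replicate recovery at $n = 500$.

## Known limitations

* Estimates on ridge-afflicted datasets (see above) are reported with
  non-convergence flags but remain stopping-rule-sensitive; profile
  likelihood or penalization would be the principled extensions.
* No standard errors or confidence intervals for real-data fits.
* $p_i$ estimation from mutation catalogs, LOH/copy-number-based clonality
  tests, and direct VCF/MAF ingestion are out of scope; the input is the
  derived per-case mutation-match table.
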