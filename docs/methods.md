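# Methods

## Transport model

The solver minimizes, over nonnegative couplings $\pi$ between the
target embedding (rows) and the source embedding (columns),

$$\Phi(\pi) = \sum_{i,j} d(a_i, b_j)^p\, \pi_{ij}
  + \frac{1}{\lambda}\sum_{i,j} (\pi_{ij}\log \pi_{ij} - \pi_{ij})
  + \rho\,\mathrm{KL}(\pi_A \mid \mu_A) + \rho\,\mathrm{KL}(\pi_B \mid \mu_B),$$

with Euclidean ground cost, $p = 1$, and the generalized KL divergence
$\mathrm{KL}(\alpha \mid \beta) = \sum_i \alpha_i \log(\alpha_i/\beta_i)
- \alpha_i + \beta_i$ on the marginals.

Two conventions deserve explicit statement:

* **Entropy weight.** The configuration stores $\lambda$ with the
  $-\frac{1}{\lambda}H(\pi)$ convention: *larger* $\lambda$ means
  *weaker* smoothing.  The common $\varepsilon$-convention of the
  Sinkhorn literature is recovered as $\varepsilon = 1/\lambda$; the
  default $\lambda = 0.1$ therefore corresponds to a strongly smoothed
  plan ($\varepsilon = 10$) on embedding-scale distances.
* **Unnormalized extensions.** Entropy and KL are used in their
  generalized (unnormalized-measure) forms, $-\sum \pi(\log\pi - 1)$
  and $\sum \alpha\log(\alpha/\beta) - \alpha + \beta$.  These agree
  with the textbook forms on probability couplings and are the standard
  extension when total mass is free.  They are also the only choice
  under which a zero-cost singleton problem with unit masses has its
  optimum at coupling mass exactly 1 (mass preservation); with the
  plain $-\sum\pi\log\pi$ entropy the optimum would sit at $e^{-1}$.

One consequence worth knowing: the entropy reference here is the unit
measure on each cell, so when $\varepsilon$ is large relative to $\rho$
(e.g. the defaults on a $100 \times 120$ problem) the optimal coupling
carries total mass well above 1 and the marginal gap ("unbalancedness")
is large.  Barycentric projection normalizes rows, so transported
points — and hence predictions — are unaffected by the overall mass
scale; the unbalancedness term simply makes the error bound more
conservative.  For near-hard marginals set $\rho \gg \varepsilon$.

## Solver

KL-relaxed Sinkhorn scaling iterations in the log domain: the coupling
is parameterized as $\pi_{ij} = \exp((f_i + g_j - C_{ij})/\varepsilon)$
and each potential update is damped by $\rho/(\rho + \varepsilon)$ (the
exact fixed point of the one-sided KL-penalized problem).  Balanced
mode ($\mathrm{damp} = 1$) recovers classical Sinkhorn with hard
marginals and requires equal total masses.  Convergence is declared
when the sup-norm change of the log-scaling vectors $f/\varepsilon,
g/\varepsilon$ falls below `tol` ($10^{-8}$) within `max_iter` (5000);
otherwise the plan is returned with `converged=False` and a warning.
Non-convergence at extreme settings (e.g. $\rho = 10^4$, where the
damping factor approaches 1) is a slow-tail effect: the returned plan
is accurate to far better than the quantities it feeds (the marginal
gap at that setting is below $10^{-4}$).  Zero-mass support points are
handled via $-\infty$ potentials and receive no coupling mass.

The Gromov-Wasserstein variant uses the inner loss
$L(u, v) = (u - v)^2$ on intra-domain Euclidean distances and
alternating linearization: starting from the independent product
coupling $\mu_A \otimes \mu_B$, the quadratic term is linearized at the
current plan ($M_{ij} = \sum_{kl}(d^A_{ik} - d^B_{jl})^2 \pi_{kl}$,
clipped at zero against float noise) and the unbalanced entropic
problem is re-solved with $M$ as cost, until the coupling change falls
below `tol`.  The scheme is non-convex; the reported objective is the
full quadratic value at the returned plan.  Tests check it against a
multi-start coordinate-descent oracle at $3\times 3$ and against exact
invariants (isometry invariance, never worse than its own starting
coupling).

Barycentric projection returns rows of the plan with zero total mass as
NaN with a logged count — never silently imputed — and the pipeline
skips them in prediction while reporting the skip count.  A row coupled
to a single source point is mapped to that point exactly, bypassing the
weighted average's float round-trip.

## Embedding

PCA (full SVD) on the dense indicator matrix; at the cohort sizes this
package targets (up to a few thousand admissions, up to ~900 codes)
densification is never a concern.  Component signs follow the
largest-magnitude-loading-positive convention so repeated fits are
bit-identical.  "Approximately 75% of the variance" is implemented as
the smallest $k$ whose cumulative explained-variance ratio reaches
0.75 — the only monotone, unambiguous reading — and the repeated
experiments override it with $k = 50$.  The source-fitted map is used
for both sides in the shared-vocabulary scenario (fit on source only;
applying a source-fitted map to the target is the defining feature of
the scenario).  Vocabulary alignment reorders target columns to the
source order, drops target-only codes with a logged count, and
zero-fills source codes absent from the target, so the source map
applies unchanged.  A single-admission source cohort (a degenerate case
exercised in tests) falls back to an identity embedding, since PCA is
undefined on one row.

## Pipeline

The transported side is always the target: plan rows index target
points, and barycentric projection lands them in the source embedding
domain where the source model predicts.  Masses are uniform per cohort
(no admission-level weights exist in the data model).  Each repeat of
the experiment harness draws an independent subsample (seed + repeat
index), refits embedding and model on the subsample — the only reading
consistent with a per-repeat sampling protocol — and runs the transfer;
the no-transfer baseline applies the same source model to the raw
(un-transported) target embedding in the shared scenario.  Reported log
metrics use the natural log.  Binary classification is supported
(logistic model, thresholded at probability 0.5) but the harness
defaults to regression on duration in hours.

## Error bound

All terms are computed per experiment: target error
$\sum_x \phi_T(x) |h'(x) - f_T(x)|$, source-model error on the target,
$K = \lVert w\rVert_2$, the plan's unbalancedness
$\sum_x |\sum_y \pi^*(x,y) - \phi_T(x)|$, the maximal support distance
$M$, and the labeling divergence.  Because the regularized objective
$\Phi(\pi^*)$ contains entropy and KL terms beyond the pure transport
cost, two readings of the Wasserstein term are evaluated side by side:
reading A uses $\Phi(\pi^*)$ (which can be negative when the entropy
term dominates — observed routinely at $\lambda = 0.1$), reading B
uses $\langle \pi^*, d\rangle$ alone.  Reading B is the conservative
choice — it is the quantity that actually majorizes the mean transport
displacement $\sum_x \phi_T(x)\lVert T(x) - x\rVert$ up to the
$M\cdot$unbalancedness correction — and the empirical verification is
keyed to it; the reading-A rate is reported alongside (roughly half the
battery at the default hyperparameters).  Inequality checks carry an
absolute slack of $10^{-9}$ for float error.

In synthetic mode the exact generator labeling functions supply
$f_S, f_T$; in estimate mode $f_S$ is taken to be $h^*$ itself (making
the first term identically zero) and $f_T$ is refit on target labels
with the same model class.  The mode is explicit, never auto-detected.

## Synthetic generator

Each admission draws codes independently with group-specific
prevalences; target prevalences are
$\sigma(\sigma^{-1}(p) + s\,u)$ for a seeded direction $u \sim N(0,1)^q$
and covariate-shift magnitude $s$.  Default prevalences follow a
Beta(0.7, 30) profile clipped to [0.002, 0.3] (~18 active codes per
admission among $q = 800$, matching sparse ICD extracts at the
experiment scale).  Outcomes are linear in a latent projection
$c = V^\top x \in \mathbb{R}^{20}$:
$f_S(x) = \beta^\top c + 240$ hours, $f_T = f_S + \delta\, c_0$, plus
$N(0, 100^2)$ noise in hours.  The scales (240 h mean stay, ~50 h of
code-driven signal, 100 h noise) mimic hospital-duration regressions
where diagnosis codes explain a minority of the variance.  The
designated coordinate $c_0$ has positive loadings (scaled
half-normal), so label shift moves target outcomes in a consistent
direction, the way a systematic between-group outcome gap would.
Planted disparities add a fixed offset to the *observed* outcomes of a
seeded fraction of target admissions only — a treatment-level effect
invisible to the features, which transport should adjust around rather
than remove.

What the generator does **not** emulate: heavy-tailed duration
distributions (noise is Gaussian, so a few negative durations occur at
these scales), ICD code co-occurrence structure, and admission-level
mass weights.  Tests passing on this generator therefore demonstrate
the mechanics and the bound's validity, not performance on real EHR
marginals.

## Batteries and problem sizes

The bound-verification battery is a 200-instance grid: covariate shift
$\in \{0, 1, 2, 3\}$, label shift $\in \{0, 1, 2, 4, 8\}$ h/unit,
$\rho \in \{0.5, 1, 5\}$, $\lambda \in \{0.1, 1, 10\}$ (180 grid
points, topped up to 200 by re-running the first 20 combinations under
fresh seeds; all seeds distinct), at the protocol cohort sizes of 120
source / 100 target admissions with one run per instance.  The
self-transfer and label-shift studies use 20 repeats per condition;
these sizes give medians stable to a few percent while keeping the
full verification suite in the tens of seconds.

## Known limitations

* The grid oracles used in tests rely on the convexity of the entropic
  objective (coordinate descent reaches the global minimum); for the
  non-convex Gromov objective the multi-start oracle certifies only a
  strong local optimum.
* Hyperparameters $\lambda, \rho$ are configuration values; no
  cross-validation loop is provided.
* No semi-relaxed or partial-OT variants, no minibatch/GPU kernels,
  no multi-class bounds.
* Disparity fractions are point estimates with per-repeat spread; no
  inferential machinery is attached to them.
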