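# Methods

`fidtol` analyses observer tolerance in habituated wild animals using
flight-initiation-distance (FID) methodology within a personality framework.
This note documents the model, the synthetic-data generator, the sampler,
and the numerical and design choices a user should know about.

## The measurement setting

An observer approaches a focal animal at constant speed from a start
distance **SD**. Two behavioural distances are recorded: the **visual
orientation distance** (**VOD**, the distance at which the animal first
directs its gaze at the approaching observer — the habituated-animal
analogue of alert distance) and the **flight initiation distance** (**FID**,
the distance at which it moves away). By protocol approaches are not started
on animals already looking, so every trial satisfies the *constrained
envelope*

```
0 < FID <= VOD < SD.
```

Two derived covariates control the envelope statistically in the models:
**VODD** = SD − VOD (distance covered before orientation) and
**VODI** = VOD − FID (distance between orientation and flight). Field
protocols define these only graphically; the package adopts the algebraic
reading above everywhere and enforces it as a table invariant.

An animal's propensity to endure observer proximity without orienting is its
*visual tolerance*; without displacing, its *displacement tolerance*. The
analysis asks whether these are repeatable, individually distinct, and
mutually correlated — i.e. whether tolerance behaves as a personality trait.

## The models

Each response y (VOD or FID, metres) is modelled log-normally; on the log
scale this is a Gaussian mixed model

```
log y_i = x_i' beta + d_{date(i)} + z_i' u_{ind(i)} + eps_i,
eps_i ~ N(0, sigma^2),   d_j ~ N(0, tau^2),   u_g ~ N_5(0, D C D),
```

with treatment-coded fixed effects (envelope covariate; behavioural
compatibility — *looking* / *not engaged not looking* against the *engaged*
reference — for VOD, an *engaged* indicator for FID; habitat, height,
neighbour count, neighbour-fled-first, external events; observer identity,
trial number 1–12 entered raw, and their interaction) and a correlated
5-term individual random-effect block: intercept, envelope-covariate slope,
observer contrast, trial number, observer × trial number. `D = diag(s)`
holds the individual SDs and `C` their correlation matrix.

Priors: `beta ~ N(0, 100)` elementwise; `s_k, tau ~ half-Student-t(3, 10)`;
`C ~ LKJ(1)` (uniform over correlation matrices); `sigma ~
half-Student-t(3, 2.5)` (a weakly informative default, recorded in the fit
metadata). The bivariate model stacks the VOD and FID blocks on one shared
10-term individual block — all cross-response correlations are estimated,
and the intercept–intercept correlation is the *convergent validity*
quantity. Residuals are conditionally independent across the two responses
given that block (no residual cross-correlation parameter); the
among-individual correlation is derived solely from the individual-level
covariance, standardised per posterior draw as
`r = cov(int_VOD, int_FID) / sqrt(var_VOD * var_FID)`.

Sampler settings default to a desk scale (4 chains × 2000 iterations, 500
warmup) suitable for tests and reanalysis; `SamplerSettings.heavyweight()`
gives the heavyweight final-inference configuration (6 × 15000/5000). The
convergence flag requires split-Rhat ≤ 1.01 and bulk ESS ≥ 400 on every
monitored parameter and is reported, never silently passed. Individuals with
fewer than two rows are retained (partial pooling) with a note.

## The MCMC engine

No probabilistic-programming backend is used; the engine
(`fidtol.sampler`) is a blocked Gibbs sampler with slice-sampling and
Metropolis components, exploiting the Gaussian structure on the log scale:

* exact conjugate draws for `beta`, the date effects, and the individual
  effects (batched per-group precision solves);
* slice updates on log scales for `tau`, `sigma` and the individual SDs;
* an *interweaving* (ancillarity–sufficiency) pair of SD updates — centred
  (given u) and non-centred (given u/s and the data) — which removes the
  slow mixing either parameterisation suffers when a component is small;
* *translation moves* between each fixed effect and the mean of its random
  counterpart (the columns coincide, so the likelihood is invariant and the
  shift has a Gaussian prior-conditional); these decouple e.g. the envelope
  coefficient from the envelope random slope;
* per-entry slice updates of `C` in both centred and whitened (non-centred)
  parameterisations — in the whitened coordinates `(v_tilde, C)` the prior
  factorises exactly, so no Jacobian term appears;
* *collapsed* moves with the individual effects integrated out analytically
  (Woodbury identities per group): a coordinate scan over `(s, C)` every
  fifth sweep, and, for bivariate fits, a one-parameter rescaling of the
  whole cross-response correlation block every sweep (a radial move whose
  `|t|^(d-1)` volume element is included). The cross-block coupling strength
  is the slowest direction of the posterior; this move traverses it
  directly;
* a joint independence-MH move on the full covariance, proposing from the
  conjugate inverse-Wishart — effective for the univariate block, rarely
  accepted for the 10-dimensional bivariate block, and therefore only one
  kernel among several.

The engine's stationary distribution is validated in the test suite against
an independent route: on a small two-response intercept-only dataset the
individual effects can be marginalised analytically and the resulting
low-dimensional posterior sampled with `emcee`; the Gibbs posterior of the
among-individual correlation matches it to well within Monte-Carlo error.
Diagnostics (split-Rhat, bulk/tail ESS) come from `arviz`.

The pointwise log-likelihood matrix (log-normal density including the
`-log y` Jacobian) is accumulated during sampling for cross-validation; at
heavyweight settings it is large (draws × observations) and can be disabled
via `store_loglik=False`.

## The synthetic-data generator

No trial data were deposited by the study this design emulates, so the
generator is the package's test bed: 69 individuals × 12 trials per
observer × 2 observers (familiar/unfamiliar) over 58 dates, at most two
approaches per individual per date (both observers' trial *k* of an
individual share a date, staggered across individuals), SD uniform on
2.5–33.8 m, and log-normal responses from exactly the hierarchical
structure the models fit. Default fixed effects, variance components,
within-response correlations and the residual SDs mirror the field-study
estimates (e.g. individual intercept SDs 0.24 / 0.49, residual SDs
0.31 / 0.36, date SD 0.14); the cross-response intercept correlation is
0.875.

Covariate frequencies are not reported by number in the study; defaults are
chosen once for realism: compatibility (engaged 0.50, looking 0.25, neither
0.25), open habitat 0.5, on-ground 0.8, neighbours within 5 m Poisson(1.5),
neighbour-fled-first 0.1 given at least one neighbour, external events 0.05.
Response categories are drawn from the published tally (98.85% passive
displacement, 0.97% geck displacement, 0.18% flinch).

**Joint individual correlation.** The study reports within-response
correlation matrices and the 0.875 intercept correlation, but no other
cross-response entries. Assembling the 10×10 matrix with a zero cross block
except the intercepts is not positive semidefinite. The generator instead
mediates all cross-response dependence through the intercepts — the
tolerance trait itself: `Cross[i,j] = r * C_vod[i,1] * C_fid[1,j]` — which
is positive definite for any PSD within-response blocks and preserves the
intercept correlation exactly.

**Self-consistent envelope generation.** The envelope covariate VODD is a
function of the response it predicts, so the generative equation is
implicit. Each row solves the fixed point

```
log V = m + eps + c (SD - V),    c = beta_VODD + u_VODD,g ,
```

by bisection (the root is unique below any point where the defining function
is positive). The envelope `V < SD` is *exactly* equivalent to truncating
the residual at `log SD − m`, implemented as vectorised rejection sampling
with a retry cap and an inverse-CDF fallback; a row whose admissible
residual mass underflows raises an explicit error naming the offending
parameters. FID is generated the same way below the realised VOD. Because
the emitted covariate equals the generative one exactly, fitted models see
correctly specified rows. (An earlier draft-covariate scheme — generate
from a provisional VODD, recompute after truncation — was rejected: the
provisional/exact mismatch acts as covariate measurement error, visibly
attenuating the random envelope slope and inflating the fitted intercept
SD.)

**What the generator does not emulate.** Real approach data couple the two
distances within a trial (the same momentary state drives orientation and
flight); the generator draws the two residuals independently, as the fitted
bivariate model assumes. Real campaigns also have uneven per-individual SD
distributions, abandoned trials, and observer-specific day loads; none are
modelled. Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the stated generative model, not robustness to
every feature of field data.

**Envelope-slack recovery geometry.** At the default (field-fitted)
locations the VOD and FID distributions overlap enough that the FID
truncation is *active* for a large minority of rows — not just the ~3% of
rows finally pinned near the bound, but every row whose admissible residual
band is within ~2 SD of the bound receives a shifted conditional mean. The
shifts vary across individuals (through the VOD-side envelope slope), which
inflates the fitted FID intercept SD and distorts the envelope coefficient:
the generative values are then *not recoverable by construction*, a known
pathology of constrained-envelope data. The defaults are kept (they are the
realistic study conditions); for parameter-recovery work,
`SimulationConfig.recovery_geometry()` lowers only the FID intercept (to
−1.8 log-m), a location change on which no variance ratio, ICC or
correlation depends, until the per-individual truncation-shift SD is below
0.05 (under 1% of the intercept variance). Recovery replicates and the
reproduction script use this geometry.

## Variance decomposition and repeatability

All components live on the latent (log) scale, where SDs square to
variances. Per posterior draw: `V_fixed` is the population variance of
`X beta` over the fitted rows; `V_individual` is the design-averaged
quadratic form `mean_i z_i' Sigma z_i` (random slopes contribute through the
observed covariate values; an intercept-only variant reduces to
`sd(Intercept)^2`); `V_date = tau^2`; `V_residual = sigma^2`. The
enhanced-agreement ICC for individual identity is

```
ICC = V_individual / (V_individual + V_date + V_fixed + V_residual),
```

with options to drop the date and fixed terms. Two variants are exposed
throughout because they answer different questions: the design-averaged
enhanced ICC (default) measures how much of the total latent variance the
whole individual block explains on the observed design; the intercept-only
`s0^2 / (s0^2 + sigma^2)` variant is the classical agreement repeatability
of the trait level itself and is the quantity comparable with conventional
published repeatabilities (with the field-fitted components it evaluates to
0.375 for VOD and 0.649 for FID). HDIs are narrowest-contiguous-interval
(sorted-sample sweep); draws with a degenerate denominator are excluded and
counted, never propagated as NaN.

Conditional modes (per-individual tolerance estimates, the BLUP analogues)
default to the posterior mean of the intercept deviation — stable for MCMC
output and equal to the conditional mode in the Gaussian case — with a
kernel-density-mode option.

A caution on correlation recovery: with ~69 individuals, the posterior of an
among-individual correlation whose true value is extreme (0.875) centres
noticeably below the truth — correlation estimation from noisy latent
intercepts under a flat/LKJ(1) prior attenuates extreme values, an effect
reproduced exactly by the marginalised-oracle posterior in the tests. This
is a property of the estimator, not of the implementation; published
posterior means near 0.9 imply realized latent correlations higher still.

## Predictive comparison

PSIS-LOO: for each observation the importance ratios `1/p(y_i | theta_s)`
are Pareto-smoothed — the largest `min(0.2 S, 3 sqrt(S))` ratios (floor 5)
are replaced by expected order statistics of a generalized Pareto
distribution fitted to the tail by the Zhang–Stephens profile estimator
with its weak-prior regularisation — and `elpd_i` is the log weighted
average predictive density. The fitted shape k-hat flags unreliable
observations (threshold 0.7, configurable); an all-equal tail yields
uniform weights and a NaN k-hat sentinel. Stacking weights maximise the
summed log score of the pointwise LOO predictive densities over the simplex
(softmax-parametrised BFGS with analytic gradient, gradient tolerance
1e-8); identical models trigger the documented uniform tie rule. The
identity comparison fits the maximal model and the same model without the
individual block and reports both LOO results and the weights.

High-leverage rows (extreme envelope covariate × extreme neighbour counts)
can legitimately produce k-hat > 0.7 at moderate sample sizes and draw
counts; the zero-high-k-hat contract is asserted on a low-leverage design.

## Numerical notes

* Bisection for the envelope fixed point runs 80 halvings (absolute
  precision ~`SD * 2^-80`); with the envelope disabled (diagnostic mode)
  the implicit equation need not have a root and the envelope term is
  evaluated at a one-step draft instead — exact when the envelope slope is
  zero, which is what the diagnostic (moment-check) configurations use.
* The envelope covariates are endogenous (functions of the response), as in
  the field protocol itself; the implied common slope bias is of order
  `-V sigma^2 / Var(VODD)` ≈ 0.003 — well inside the posterior SD.
* Degenerate configs (all variances zero) generate exactly deterministic
  rows; the individual-effect Cholesky jitter is scaled relative to the
  largest variance and vanishes with it.
* Correlation slice updates reject non-positive-definite proposals via
  Cholesky failure; marginally-PD states skip an update rather than abort.
* Simulation randomness is split into independent named streams
  (design/effects/VOD/FID/response) seeded from the config seed, so the
  design is bit-reproducible independently of the response draws.

## Known limitations

* The sampler is validated for this model family, not a general-purpose
  PPL; changing the model structure requires engine work.
* Weakly identified correlation entries (components with SDs near zero) mix
  slowly; at desk-scale settings their ESS can sit below the convergence
  thresholds, and the convergence flag reports this honestly. The
  scientifically load-bearing quantities (fixed effects, intercept SDs,
  ICCs, the intercept correlation) mix far faster.
* Observation-scale (back-transformed) ICCs are out of scope; all variance
  partitioning is latent-scale.
* The split-half (even/odd trial) bivariate analysis is supported
  (`BivariateToleranceModel(vod_data=even, fid_data=odd)` or the CLI's
  `convergent --split-parity`) but halves the per-individual information;
  expect wider intervals.
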