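# fidtol

**Observer-tolerance personality analysis for flight-initiation-distance
(FID) trials.**

Behavioural ecologists habituate wild animals so that observers can be
treated as a neutral stimulus — but habituation is rarely tested per
individual. `fidtol` implements a complete analysis pipeline for repeated
human-approach trials on habituated animals: it simulates
constrained-envelope trial campaigns with known individual structure, fits
Bayesian log-normal mixed models for the distance at which animals visually
orient toward (VOD) and displace from (FID) an approaching observer, and
derives the statistics that decide whether *tolerance* is a personality
trait:

* **repeatability** — the intraclass correlation (ICC) of individual
  identity, with 95% highest-density intervals;
* **convergent validity** — the among-individual correlation between
  visual and displacement tolerance from a bivariate model with a shared
  individual random-effect block;
* **conditional modes** — per-individual tolerance estimates (BLUP
  analogues);
* **predictive evidence** — PSIS-LOO cross-validation and log-score
  stacking of the models with and without individual identity.

## The model

Each distance response y (metres) is log-normal; on the log scale

```
log y ~ Normal( X beta + Z u_individual + d_date , sigma )
```

with treatment-coded fixed effects (envelope-control covariate VODD = SD −
VOD or VODI = VOD − FID, behavioural compatibility/engagement, habitat,
height, neighbours, neighbour flight, external events, observer, trial
number, observer × trial number), a date random intercept, and a correlated
five-term individual block (intercept, envelope slope, observer, trial
number, observer × trial number). Priors: Normal(0, 100) fixed effects,
half-Student-t(3, 10) random-effect SDs, LKJ(1) correlations,
half-Student-t(3, 2.5) residual SD. Trials obey the constrained envelope
0 < FID ≤ VOD < SD by protocol, and the simulator enforces it exactly.

Sampling uses a purpose-built blocked Gibbs engine (conjugate draws plus
slice sampling, interweaved parameterisations, and collapsed covariance
moves), validated in the test suite against an analytically marginalised
posterior sampled with `emcee`. See `docs/methods.md` for the full account.

## Worked example

```python
import fidtol as ft

# a study-scale campaign: 69 individuals x 12 trials x 2 observers
cfg = ft.SimulationConfig.recovery_geometry(seed=1)
trials, truth = ft.simulate_dataset(cfg)        # 1656 envelope-valid rows

fit = ft.ToleranceModel(trials, response="vod").fit(
    ft.SamplerSettings(chains=2, iterations=1200, warmup=400, seed=1,
                       min_ess=1, max_rhat=10)
)
print(fit.summary().head(4).to_string(index=False))

icc = ft.enhanced_icc(
    ft.variance_components(fit, intercept_only=True),
    include_fixed=False, include_date=False,
)
print(f"VOD repeatability: {icc.mean:.3f}  "
      f"[{icc.hdi_low:.3f}, {icc.hdi_high:.3f}] 95% HDI")
```

prints (abridged):

```
response            group               parameter  Estimate  Est. error  l-95% CI  u-95% CI   Rhat  Bulk_ESS
     vod Population-level               Intercept  1.020420    0.051486  0.924010  1.119519  1.010       384
     vod Population-level                    VODD -0.025141    0.004122 -0.033109 -0.016932  1.005       309
     vod Population-level                 Looking  0.223534    0.020725  0.183194  0.262887  1.001      1093
     vod Population-level Not engaged not looking  0.120689    0.019858  0.081568  0.159667  1.001      1390
VOD repeatability: 0.216  [0.095, 0.343] 95% HDI
```

The summary rows read like a conventional mixed-model table: posterior mean
(`Estimate`), posterior SD, central 95% interval, split-Rhat and effective
sample sizes per parameter. Here animals that were already *looking* when
the approach began oriented at distances about `exp(0.22) ≈ 1.25×` longer
than engaged animals, and the envelope-control coefficient (VODD) is small
and negative, as expected. The repeatability line is the proportion of
latent-scale variance attributable to consistent differences among
individuals; the flight response carries the stronger personality signal
(its repeatability on the same run is ≈ 0.63). The bivariate model
(`ft.BivariateToleranceModel(trials).fit(...)` followed by
`ft.among_individual_correlation(...)`) then quantifies how strongly the
two tolerance measures correlate at the individual level, and
`ft.compare_identity_models(...)` reports the stacking weight of the
identity model (≈ 1 when individual identity dominates prediction).

## Command line

```bash
fidtol init-config config.yaml       # write a default, editable config
fidtol all -c config.yaml -o out/    # simulate -> fit -> ICC -> bivariate
                                     #   -> stacking -> report.json
fidtol convergent --split-parity ... # even/odd split-half validation
```

Each stage writes plain CSV/JSON artifacts plus a manifest with the seed,
a stable config hash and package versions, so runs are fully reproducible.

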