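# distressdyn

Bayesian system-dynamics modelling of psychological-distress prevalence
with treatment-dependent recovery.

## The problem

In several high-income countries the prevalence of common mental disorders
has stayed flat or risen even as treatment provision expanded sharply. Two
competing explanations are (1) a rising individual-level risk of developing
a disorder, and (2) declining effectiveness of care as services saturate.
`distressdyn` implements a compact stock-and-flow model that separates
these mechanisms and fits it to four yearly count streams: survey counts of
adults with high/very-high psychological distress (K10 ≥ 22), mid-year
adult population, total adult deaths, and adults with high/very-high
distress receiving subsidised mental-health care.

## The model

A single stock *M(t)* — people currently in high/very-high distress —
evolves as

    dM/dt = i(t) (P − M) − γ k M − s M − r(t) C(t)

with population *P(t) = P₀ + g t*, treatment volume *C(t) = C₀ + u t*, and
total deaths *D(t) = D₀ + h t* linear in time; per-capita incidence
*i(t) = i₀ e^{δ_i t}* and treatment effectiveness *r(t) = r₀ e^{δ_r t}*
changing at constant fractional rates. The background mortality rate *k(t)*
is defined by the identity *k (P − M) + γ k M = D*, with hazard ratio
γ ≥ 1 for the distressed stock; *s* is the natural recovery rate.

Each observed count *y* is negative-binomial with mean equal to the
matching model output and inverse-scale dispersion β (variance
*m (1 + 1/β)*). The posterior over all dynamic parameters and per-stream
dispersions is sampled by MCMC (affine-invariant ensemble by default,
adaptive Metropolis as an alternative) on an unconstrained
reparameterisation, initialised from a Laplace approximation.

On top of the fit, the package provides:

* **counterfactual simulation** — re-simulate every posterior draw with
  the incidence trend removed (δ_i := 0) and summarise the prevalence
  difference, persons averted and relative reduction;
* **constrained fits** — refit with δ_i = 0 or δ_r = 0 pinned, for model
  comparison;
* **posterior predictive checks** — Bayesian p-values from a χ²
  discrepancy;
* **a synthetic-data generator** with the exact statistical structure the
  analysis assumes, so the whole pipeline is testable end to end.

## Worked example

```python
import distressdyn as dd

# synthetic data at the study's observation design: 6 biennial survey
# points plus 12 yearly points each for population, mortality and services
obs = dd.generate_observations(dd.GeneratorConfig(seed=1))

model = dd.PsychDistressModel(obs)          # shipped default priors
res = model.fit(chains=4, iterations=2000, seed=1)

print(res.summary().loc[["i0", "delta_i", "delta_r", "r0"]].round(4))
print("P(delta_i > 0) =", res.posterior_probability("delta_i > 0"))

cf = res.counterfactual(n_draws=1000, seed=2)
d = cf.summaries()["prevalence_difference"]
print(f"counterfactual prevalence decrease: {100*d['median']:.2f} pp "
      f"(95% CrI {100*d['ci95'][0]:.2f}-{100*d['ci95'][1]:.2f})")
```

prints

```
             mean      sd  median  ci95_low  ci95_high    rhat
i0         0.0619  0.0091  0.0610    0.0472     0.0868  1.0627
delta_i    0.0188  0.0018  0.0187    0.0157     0.0222  1.0945
delta_r   -0.0061  0.0117 -0.0053   -0.0333     0.0145  1.0647
r0         0.1719  0.0378  0.1703    0.1009     0.2497  1.0415
P(delta_i > 0) = 1.0
counterfactual prevalence decrease: 1.11 pp (95% CrI 0.68-1.61)
```

The generator's ground truth has δ_i = 0.02 (rising individual-level risk)
and δ_r = 0 (stable treatment effectiveness): the fit recovers a clearly
positive incidence trend, an effectiveness trend consistent with zero, and
the counterfactual says prevalence would have *fallen* by about 1.1
percentage points over 2008–2019 had incidence stayed constant — rising
treatment volume was masking a real benefit.

The same steps are available from the shell:

```bash
distressdyn generate --seed 1 --out obs.csv --truth-out truth.json
distressdyn fit --data obs.csv --chains 4 --iters 2000 --seed 1 --out fit/
distressdyn counterfactual --samples fit/posterior.csv --out cf.json
distressdyn ppc --samples fit/posterior.csv --data obs.csv --stream distress
distressdyn report --data obs.csv --seed 1 --out bundle/   # everything
```

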