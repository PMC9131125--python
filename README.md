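# endokin

Cell-to-cell variability in antibody internalization, inferred from
flow-cytometry snapshot data.

## The problem

Internalization assays with a dual-labelled antibody (a quenchable probe
whose surface-bound fluorescence a quencher dye switches off, plus an
unquenchable reference probe) yield per-cell snapshots of total and
internalized antibody at a handful of incubation times. The observed
spread mixes three things: trafficking kinetics, genuine cell-to-cell
biological variability, and measurement noise (photomultiplier shot noise
and cellular autofluorescence). Summarizing each snapshot by its geometric
mean discards the biology in the spread; `endokin` is for researchers who
want to *quantify* that biology, with uncertainty.

## The model

Per cell, receptor fractions follow a linear compartment model

    dT/dt = -βT,   dS/dt = βT - λS + pβE,
    dE/dt = λS - pβE,   dF/dt = pβE,

with internalization rate λ (min⁻¹), recycling rate β (min⁻¹),
disassociation probability p, equilibrium start S(0) = β/(λ+β), total
bound antibody A = S + E + F and internal antibody I = E + F. Cell
properties ξᵢ = (Rᵢ, λᵢ, βᵢ) — relative receptor count and rates — vary
across the population: shifted log-normal R (E(R) = 1), shifted-Gamma
rates parametrized by mean/SD/skewness, coupled by a Gaussian copula.
Observed fluorescence adds constant-CV shot noise and empirical
autofluorescence; quenched samples retain a fraction (1-η) of the surface
signal.

Because the likelihood of the full snapshot distributions is intractable,
parameters are inferred by distribution-matching approximate Bayesian
computation: a simulated dataset is compared to the data through a
weighted sum of two-sample Anderson–Darling distances (each snapshot, each
channel) and between-channel correlation discrepancies; an SMC pilot sets
the tolerance ε, and tuned ABC-MCMC chains sample the posterior
p(θ | d(X, Y(θ)) < ε). The calibrated model then predicts quantities no
cytometer can measure, such as the per-cell internalized fraction
I(t)/A(t) and the dependence of a cell's early and late signals.

See `docs/methods.md` for the full model, algorithmic choices and
limitations.

## Worked example

```python
import numpy as np
from endokin import (
    StudyDesign, default_population, default_measurement, generate_dataset,
    GmfiSeries, fit_homogeneous, estimate_quench_efficiency,
)

# synthetic study: 7 times x 2 quench conditions x 1000 cells, known truth
ds = generate_dataset(default_population(), default_measurement(),
                      StudyDesign(seed=7))

eta = estimate_quench_efficiency(ds.quench_control[0], ds.quench_control[1],
                                 ds.autofluorescence.gmfi_Q())
print(f"quench efficiency: {eta:.3f}")

series = GmfiSeries.from_dataset(ds)
fit = fit_homogeneous(series, E_Q=ds.autofluorescence.gmfi_Q(), eta=eta,
                      starts=10, seed=1)
for name in ("lam", "beta", "p"):
    lo, hi = fit.ci95[name]
    print(f"{name:5s} {fit.estimates[name]:.3f}  95% CI ({lo:.3f}, {hi:.3f})")
print(f"equilibrium surface fraction S(0) = {fit.surface_fraction():.2f}")
```

Output:

```
quench efficiency: 0.933
lam   0.088  95% CI (0.080, 0.096)
beta  0.046  95% CI (0.039, 0.054)
p     0.052  95% CI (0.037, 0.068)
equilibrium surface fraction S(0) = 0.34
```

The 4 °C control recovers the generating quench efficiency (0.94, minus
the small background-subtraction bias discussed in `docs/methods.md`).
The recycling rate matches the generating mean (β = 0.047 min⁻¹), but the
homogeneous fit *underestimates* λ (0.088 vs the generating mean 0.106)
because GMFI curves of a heterogeneous population are not the homogeneous
model evaluated at the mean parameters — the bias the heterogeneous
analysis exists to avoid. The full heterogeneous inference runs through
the pipeline:

```sh
endokin run --config config.yaml --outdir runs/demo --seed 1
# stages: simulate, fit-gmfi, calibrate-weights, abc-smc, abc-mcmc,
#         best-fit, predict  (each also available as its own subcommand)
```

Artifacts (dataset CSVs, chain CSV, YAML manifests with seeds, acceptance
rates, ESS and R-hat) land in the run directory; a rerun with the same
config and seed reproduces them byte-for-byte.

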