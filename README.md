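# rsmkit

Design-of-experiments and response-surface tooling for fermentation and
bioprocess optimization. `rsmkit` constructs Box–Behnken designs, fits full
second-order response models by least squares in coded units, decomposes
variation with an ANOVA that splits residual error into lack of fit and pure
error, and locates and classifies the fitted surface's optimum. It also
carries the small wet-lab statistics that surround such an experiment: the
DNS glucose standard curve and activity conversion, Congo-red D/d clearance
ranking of cellulolytic isolates, and single-factor screening summaries.

It is written for microbiologists and bioprocess engineers who run
three-level factorial optimizations — the kind of study where a few
controllable variables (shaker speed, temperature, incubation time, pH, …)
are screened one at a time and then jointly optimized around the screening
optimum.

## The model

A Box–Behnken design for k factors places runs at the midpoints of the
factor-cube edges — every factor pair crossed at (±1, ±1) with the rest at
0 — plus replicated center runs, 2k(k−1) + n₀ runs in all. Factors are
rescaled to coded units (low/center/high → −1/0/+1) and the response is
modelled by the full second-order polynomial

    y = β₀ + Σᵢ βᵢxᵢ + Σᵢ<ⱼ βᵢⱼxᵢxⱼ + Σᵢ βᵢᵢxᵢ² + ε,   ε ~ N(0, σ²),

fitted by ordinary least squares. Term significance uses partial (Type III)
sums of squares — SS(term) = SSE(model without the term) − SSE(full model) —
tested against the residual mean square. The replicated centers give a
model-free pure-error estimate, so the residual splits into lack of fit and
pure error, whose F ratio tests model adequacy. The fitted surface's
stationary point solves ∇y = 0; the Hessian's eigenvalue signs classify it
as a maximum, minimum, or saddle, and a bounded multi-start search over the
coded cube [−1, 1]^k covers the non-interior and ridge cases.

## Worked example

The package bundles a published 17-run cellulase (CMCase) optimization: a
cellulolytic *Bacillus* isolate fermented at shaker speeds of 100–200 r/min,
29–37 °C, and 18–36 h, response in U/mL by the DNS assay.

```python
import rsmkit as rk

design, responses = rk.cellulase_experiment()
model = rk.fit_quadratic(design, responses)
print(rk.format_equation(model, "Yca"))
print("R^2 =", round(rk.r_squared(model), 4))
print(rk.stationary_point(model).describe(design.factors))
```

prints

```
Yca = 10.61 + 0.70 A + 1.50 B + 0.79 C - 0.065 AB + 0.015 AC + 0.33 BC - 3.78 A^2 - 2.11 B^2 - 2.99 C^2
R^2 = 0.9858
maximum at shaker_speed = 154.510 r/min, temperature = 34.460 degC, incubation_time = 28.371 h; predicted response 10.975
```

The equation is the fitted quadratic in coded units (A = shaker speed,
B = temperature, C = incubation time): activity rises with all three factors
near the center but the strong negative quadratic terms make the surface
concave, so an interior optimum exists. R² = 0.9858 says the model explains
98.6 % of the response variation across the 17 runs. The stationary point is
an interior maximum: the model predicts peak activity of 10.975 U/mL at
about 154.5 r/min, 34.5 °C, and 28.4 h. The ANOVA
(`rk.anova_partition(model, design, responses)`) shows all linear and
quadratic terms significant, interactions not, and a non-significant lack of
fit (F = 6.42 on (3, 4) df, p = 0.0522) from the five center replicates.

The same workflow is available from the shell:

```sh
rsmkit run --config config.json        # fit -> ANOVA -> optimize -> report
rsmkit design --factors factors.json --n-center 5 -o design.csv
rsmkit fit --factors factors.json --run-table runs.csv -o model.json
rsmkit optimize --model model.json
```

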