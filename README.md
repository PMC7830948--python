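# nanoform

Design-of-experiments tooling for nanoparticle formulation development:
Box–Behnken design construction, quadratic response-surface modelling, and
Derringer–Suich desirability optimization, plus the small arithmetic that
surrounds a formulation study — encapsulation efficiency, cumulative
in-vitro release with withdraw-and-replace correction, the sink-condition
rule, and comparative-Ct (2^−ΔΔCt) gene-expression fold changes.

It is written for formulation scientists who screen polymer–lipid hybrid
nanoparticles (or any three-factor system) and want the optimization
pipeline of commercial DoE software as an open, scriptable, testable
library. The packaged reference dataset is a 15-run Box–Behnken screen of
5-fluorouracil–loaded PLGA–lecithin nanoparticles: PLGA amount (X₁),
lecithin amount (X₂) and poloxamer 188 level (X₃) against mean particle
size Y₁ (nm) and entrapment efficiency Y₂ (%).

## The model

Factor settings are coded so low/centre/high map to −1/0/+1, and each
response is fitted by ordinary least squares to the full second-order
polynomial

    Y = b₀ + b₁x₁ + b₂x₂ + b₃x₃ + b₁₂x₁x₂ + b₁₃x₁x₃ + b₂₃x₂x₃
        + b₁₁x₁² + b₂₂x₂² + b₃₃x₃²

For multi-response optimization each predicted response is mapped onto a
desirability d ∈ [0, 1] (one-sided Derringer–Suich ramps for minimize /
maximize goals) and the overall desirability

    D = (∏ dᵢ^rᵢ)^(1/Σrᵢ)

is maximized over the factor cuboid by seeded multi-start bounded
L-BFGS-B, with an overlay ("design space") grid for constraint regions.

## Worked example

```python
import nanoform as nf

design = nf.pln_design()                       # 15-run reference screen
size = nf.fit_quadratic(design, "particle_size")
ee = nf.fit_quadratic(design, "ee")

print(round(size.coefficients[0], 1))          # 150.0  (centre-run mean, nm)
print(round(nf.predict_response(size, (67.5, 69.9, 1.5)), 3))  # 141.157
print(round(nf.predict_response(ee, (67.5, 69.9, 1.5)), 4))    # 75.6029

best = nf.optimize_desirability([size, ee], nf.pln_goals(), n_starts=64, seed=0)[0]
print({k: round(v, 2) for k, v in best.actual_settings.items()})
# {'PLGA': 72.05, 'lecithin': 86.76, 'poloxamer': 1.5}
print(round(best.predicted["particle_size"], 2), round(best.predicted["ee"], 2))
# 139.09 75.6
```

The intercept of a Box–Behnken quadratic fit equals the centre-run mean
(150.0 nm here). Predicting at the selected formulation's settings — PLGA
67.5 mg, lecithin 69.9 mg, poloxamer 1.5 % w/v — gives 141.16 nm and
75.60 % entrapment, and the desirability optimum lands where entrapment
reaches its ceiling (75.6 %) at the smallest attainable particle size
(139.1 nm), at a high surfactant level.

The same steps are available from the shell:

```
nanoform design --factors factors.csv -o bbd.csv
nanoform fit --factors factors.csv --design bbd.csv --response particle_size
nanoform optimize --factors factors.csv --design design.csv \
    --response particle_size --response ee --goals goals.csv -o solutions.csv
```

plus `space`, `ee`, `release`, `ddct` and seeded `sim design|release|ct`
generators.

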