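# Methods

## Design construction and coding

The package implements the three-factor, three-level Box–Behnken design
(BBD): 12 edge runs — every (±1, ±1) combination over each of the three
factor pairs with the remaining factor at its centre — plus a configurable
number of centre replicates (default 3, giving the classical 15-run
layout). Only the 3-factor construction is supported; other factor counts
are rejected rather than approximated. Edge runs are emitted in factor-pair
order (1–2, 1–3, 2–3) with corners in (−−, +−, −+, ++) order; BBD run
order carries no statistical meaning, so a fixed deterministic order is
used and any randomization is left to the user.

Coding is linear about the centre: x = (A − A₀) / ((A_high − A_low)/2).
This keeps the centre at exactly 0 — which the fitted intercept and the
optimizer both rely on — at the cost that an asymmetric printed ladder
(e.g. lecithin 66.67/133.34/200 mg) codes its low level to −1.000075
rather than −1. Coded magnitudes up to 1 + 10⁻³ are accepted as inside the
design region (`CODED_EDGE_TOL`); the coding/decoding pair is an exact
inverse and is property-tested as such.

## Response-surface fitting

Each response is fitted independently by ordinary least squares to the
full 10-term quadratic polynomial on the coded scale, via
`statsmodels.OLS`. There is no term selection or model reduction: the full
model is always reported, with R², adjusted R², residual SD, residual df
and the overall F statistic as plain diagnostics. Fitting on coded rather
than actual units makes coefficients directly comparable across factors
and matches DoE-software convention; predictions are invariant to the
choice. Responses are per-run means; replicate SD columns are carried as
metadata only, since replicate-level data are typically not available —
a weighted fit is deliberately not offered.

Rank deficiency (fewer than 10 usable runs, or runs that do not span the
quadratic terms) raises a dedicated error rather than returning a
pseudo-inverse solution. Predictions more than two half-ranges outside the
cuboid warn (`ExtrapolationWarning`) but still return a value, since
checkpoint analysis legitimately evaluates off-design points.

The test suite cross-checks every fit against an independent
normal-equations solve (explicit 10×10 XᵀX system) to 10⁻⁸, and verifies
the closed-form sampling SD of the linear coefficients, σ/√8, by Monte
Carlo — for a 3-factor BBD each coded column has sum of squares 8 and is
orthogonal to every other model column.

## Desirability optimization

Individual desirabilities use the one-sided Derringer–Suich ramps with a
weight exponent (curvature) per goal; the ramp argument is clipped to
[0, 1] before exponentiation so out-of-band values saturate cleanly.
Two-sided "target-is-best" goals are not implemented (no such goal arises
in the intended workflows). The overall desirability is the
importance-weighted geometric mean with integer importances 1–5.

In-range goals on *factors* are treated as hard box constraints: they clip
the optimizer's bounds, contribute d = 1 inside, and by default their
importances still enter the Σr denominator (`include_range_importances`),
matching common DoE-software behaviour. Because their d is identically 1
within bounds, this choice only rescales D monotonically and cannot change
the solution ranking; a flag switches it off.

The search is multi-start bounded L-BFGS-B from a seeded Latin-hypercube
sample of the coded cuboid (default 64 starts — on smooth 3-factor
quadratic problems the returned D is seed-stable to well under 10⁻³ at
that count). Converged points closer than 0.02 coded units are merged,
solutions are ranked by D descending, and near-ties (ΔD < 10⁻⁶) are broken
by the first minimize-goal prediction ascending — "smaller particles win".
An exhaustive grid evaluation at 0.01 coded resolution serves as the
oracle in the acceptance tests. The design-space overlay evaluates
response constraints (≤ / ≥ thresholds) on a regular actual-units grid and
reports the feasible mask and volume fraction.

## Formulation arithmetic

Encapsulation efficiency is 100·(W_total − W_free)/W_total, clamped to
[0, 100] against last-ulp rounding; W_free > W_total is rejected as an
assay/blank problem rather than clipped. Cumulative release applies the
additive withdraw-and-replace correction mₙ = CₙV + v·Σ_{i<n} Cᵢ — without
it every 1 mL withdrawal biases the cumulative percentage low. A
non-monotone cumulative sequence is reported as computed with a warning
(it signals noise, not arithmetic), while exceeding 110 % of the dose
raises a mass-balance error (it signals wrong units). The sink condition
follows the 10× rule: medium volume at least ten times the volume needed
to dissolve the dose at saturation; the margin is reported alongside the
boolean. Release-kinetics model fitting (Higuchi, Korsmeyer–Peppas, …) is
out of scope; the first-order signal in the simulator is a test signal
only.

## Comparative Ct

ΔCt = Ct_target − Ct_reference per sample; the calibrator is the
arithmetic mean ΔCt of the control group (a defensible default when no
single calibrator sample is designated); fold = 2^−ΔΔCt. This makes the
geometric mean of control-group folds exactly 1, and any constant shift
applied to all Ct values cancels — both are tested properties. Group
summaries are mean ± SD of per-sample folds. Efficiency-corrected (Pfaffl)
quantification and cross-group testing are out of scope.

## Synthetic data generators

Three seeded generators mirror the structure of the real inputs: (a)
quadratic surfaces evaluated on the generated BBD with additive Gaussian
response noise; (b) first-order dissolution (released mass
dose·f·(1 − e^(−kt)), default k = 0.35 h⁻¹, plateau 0.95, dose 33.3 mg in
50 mL with 1 mL withdrawals over 0.5–24 h — a realistic hydrophilic-drug
dialysis setup) with explicit per-sampling withdrawal bookkeeping and
constant-CV concentration noise, exposing the true released-mass
trajectory as an oracle; (c) grouped qPCR Ct values (target base 26,
reference base 18 cycles, Gaussian cycle noise) with per-group log2
expression shifts. Noise models are i.i.d. Gaussian / constant-CV — the
simplest structures consistent with mean ± SD reporting. They do not
emulate instrument drift, heteroscedastic DLS error, plate effects or
amplification-efficiency differences, so passing recovery tests show the
estimators are correct under their stated assumptions, not that real data
meet those assumptions.

## Numerical choices and problem sizes

Monte-Carlo checks use 500 design-noise replicates for the coefficient-SD
property and 200 × (2 × 50 samples) Ct replicates for fold-change
recovery — enough for the 15 % and 5 % bands being asserted while keeping
the default suite fast. The grid oracle uses 201³ coded points evaluated
in chunks. All randomness flows through `numpy.random.default_rng` seeds;
every generator run twice with the same seed yields identical tables.

## Known limitations

Only 3-factor BBDs; no D-optimal/CCD families, no blocking. Full 10-term
fits only — no stepwise reduction, weighting or transforms. One-sided
desirability only. The packaged reference dataset records particle size
and entrapment responses; polydispersity and zeta potential are not
modelled as design responses.
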