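# Methods

## The space-for-time model and its assumptions

The central object is the per-window linear mixture y = Xβ relating
monthly climatological cloud fractional cover (CFrC, unitless in [0,1]) to
land-cover class fractions. Reading the fitted contrast between pure
vegetation covers as the effect of a *transition* assumes that (i) within
a ~35 km window all pixels share the same meteorology, so cover is the
only systematic difference; (ii) the cloud response is linear in cover
fractions; and (iii) spatial contrasts are a valid surrogate for temporal
change. None of these hold exactly in nature — cloud advection smears the
signal toward zero and orography violates (i) — which is why the estimate
is best interpreted as a lower bound on the local effect and why the
orography mask exists.

Compositional closure (rows of X sum to 1) makes the raw design singular
and any class-subset regression ambiguous, so the fit is performed on the
column-centered SVD basis, keeping every dimension whose singular value
exceeds 1e-10 times the largest ("all the variance", up to floating
point). A window whose centered design has no variance at all (all
compositions identical) is flagged degenerate and skipped; this threshold
is absolute (1e-12 on the largest singular value) because fractions are
O(1) quantities.

Var[β] is the homoscedastic OLS estimator σ̂²(ZᵗZ)⁻¹ with
σ̂² = RSS/(n−z−1). Nothing in the estimation re-weights pixels.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| window size | 7 cells (0.35°) | moving-window extent for unmixing, I_c and orography stats |
| valid-pixel floor | 60% of window | minimum observed, non-water pixels |
| distinct-composition floor | 40% of valid rows | rows distinct after rounding to 6 decimals |
| water threshold | 0.5 | pixel excluded when water fraction ≥ 0.5 (coastline buffer) |
| I_c retention | ≥ 0.5 | minimum class co-occurrence for a transition estimate |
| orography rule | v₁<50 m, v₂<100 m, v₃<100 m | all three required |
| aggregation block | 7×7 cells (0.35°) | non-overlapping tiles aligned to the grid origin |
| support filter | ≥ 20% | share of block centers that contributed |
| variance filter | σ²_Δȳ ≤ 0.1 | methodological uncertainty cap |
| percentile trim | [1st, 99th] | per transition, months pooled, linear interpolation |
| temporal method | 21×21 window, \|Δf\|<0.05 reference, \|Δf\|≥0.1 change, ≥10 reference pixels | the residual-removal configuration |
| station filters | water ≤5%, ≥2555 records (~7 yr), same v-rule | validation-station screening |
| pair distances | 30–100 km | region-of-influence separation vs shared weather |
| snow split | Δα < −0.15 | energy-balance stratum boundary (−0.1 is a documented variant) |

The distinct-composition share is computed over valid rows (not the full
window), and the support filter counts window centers (not underlying fine
pixels); both are choices where the written rule is ambiguous.
Octa-coded station records are converted by /8 with code 9 (obscured sky)
dropped.

## The synthetic world

`synthetic_world` generates all inputs with known truth. Land cover is a
softmax of per-class Gaussian log-abundance fields with two scales:
patches (correlation length 4 cells) and pixel-scale texture (sd 1.2 on
the logits). The texture emulates the strong cell-to-cell scatter of
fraction grids aggregated from fine categorical maps; it also keeps every
window's design well conditioned, so methodological σ values are physical
(~0.01 rather than >1). The mosaic is dominated by herbaceous plus two
forest classes with seven minor classes at low cover — the afforestation-
frontier situation the method targets; worlds without herbaceous/forest
co-occurrence are (correctly) masked to nothing. Cloud fields are the
exact mixture of pure-class responses plus white noise on the response
only (never on the fractions), clipped to [0,1]; planted responses should
stay interior (0.2–0.8) because clipping biases recovery near the bounds.
A spatially correlated noise option exists (`noise_correlation_length`)
but the default is white: correlated noise violates the OLS residual
model and degrades the σ calibration, which is worth knowing before using
it.

Station records use a paired network: couples 40–90 km apart, couples
~220 km from each other, so accepted pairs share no station and the
forced-origin SE's independence assumption holds. Noise is per-record
(sd 0.15, day-to-day weather and observer variability) plus a small
persistent offset (sd 0.01) — small because the validation filters exist
to remove stations with strong persistent local drivers. Yearly-change
worlds ramp a fixed share of eligible cells linearly from herbaceous to
forest and add `effect × accumulated gain` plus a uniform per-year drift.

What the generator does **not** emulate: real geography, seasonality of
land cover, snow albedo cycles, cloud advection, retrieval artefacts, or
spatially structured observation error. Passing tests therefore show the
*algorithms* are correct under their own assumptions, not that the method
is unbiased on real satellite archives.

## Numerical choices

- Negative radicands in σ_{A→B} (floating point) clamp to 0.
- Per-center σ is floored at 1e-6 before building Σ_a; a singular Σ_a
  receives a 1e-12·max(diag) ridge.
- Degenerate or invalid windows yield missing cells with a reason code
  (`MaskReason`), never exceptions, so full-map runs always complete.
- The SVD reduction is computed once per window center and reused across
  monthly layers sharing the same valid-pixel set (the composition does
  not change with month); this is exactly equivalent to refitting and is
  what makes 200×200×12 runs take seconds.
- Monthly climatologies average days→(year,month)→month so each year
  weighs equally regardless of daily coverage.
- Aggregation blocks drop trailing partial tiles; block coordinates are
  the mean of member-cell coordinates.

## Known limitations

**Aggregated variance is anticonservative on densely estimated blocks.**
The overlap model takes the correlation between two window estimates to be
their shared-pixel fraction. Empirically (standardised errors on synthetic
worlds) the true correlation is ~8% lower: neighbouring windows estimate
slightly different column means and covariances, which decorrelates their
prediction weights. With equal per-center σ the weights stay near-uniform
and the formula is robust to this misfit (simulated coverage ≈95% even at
a 0.85× correlation shrink), but with heteroscedastic σ the generalised
inverse-variance weights become large and oscillating (|w|₁ up to ~10)
and exploit correlation that is not there: simulated 2σ coverage collapses
to ~50% under the same shrink. On full pipelines the planted effect is
still recovered without bias (grand mean within ±0.005 of truth), but the
per-block ±2σ intervals cover the truth only ~70% of the time at high
support, improving to ~90% when blocks hold ≤8 centers. One acceptance
test asserts the 90–99% calibration band and fails by design, documenting
this behaviour rather than hiding it. Users needing honest interval
coverage should treat σ²_Δȳ as a lower bound, or aggregate with plain
inverse-variance weights on a thinned (non-overlapping) subset of centers.

**Other limitations.** The forced-origin station SE assumes independent
pairs; in networks where one station serves many pairs the residuals are
correlated (ρ=0.5 per shared station) and the 2·SE rule over-rejects. The
temporal method's thresholds are configuration, not estimates; its
residual removal cancels only spatially uniform climate signals within
the 21×21 window. No reprojection is provided: all grids must already
share a geographic lat-lon frame.
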