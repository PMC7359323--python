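# Methods

`granumix` implements a three-stage surrogate workflow for predicting the
agitation time needed to reach uniform powder mixing in an agitated filter
dryer (AFD): a desk-scale discrete element method (DEM) simulator produces
segregation-index time series; an ARIMA engine forecasts the time of first
crossing of the uniform-mixing cutoff; and a machine-learning stage maps
the nine material/process descriptors to that mixing time and ranks their
importance. This note records the models, their assumptions, the numerical
choices, and what the synthetic generators do and do not emulate.

## DEM contact model

Particles are monodisperse soft spheres integrated with velocity Verlet.
The contact law is Hertz–Mindlin:

- **Normal force.** Hertzian elasticity
  `F_n = (4/3) E* sqrt(R*) δ^{3/2}` plus a nonlinear dashpot
  `F_d = -2 sqrt(5/6) β sqrt(S_n m*) v_n` with `S_n = 2 E* sqrt(R* δ)` and
  `β = ln e / sqrt(ln² e + π²)`. This calibration reproduces the configured
  restitution coefficient to better than 1% in two-body tests (checked
  against event-resolved ODE integration of the same law).
- **Tangential force.** A Mindlin spring with per-contact history
  (`k_t = 8 G* sqrt(R* δ)`, plus a matching dashpot) capped by the Coulomb
  limit `μ_f |F_n^{el}|`; on slip the stored displacement is rescaled so the
  spring holds exactly the capped force. Contact history lives on the
  lower-indexed particle of each pair; walls keep one history slot per
  particle per wall entity.
- **Cohesion.** Simplified-JKR: an attractive normal force
  `F_coh = γ_cohesion · π δ R*`, the model family parameterised by a
  cohesive energy density in J/m³. Cohesion acts between particles only,
  not against walls.
- **Walls.** Flat floor, cylindrical shell, and `blade_count` flat vertical
  blades spanning the radius from the axis, extending from the floor to
  `blade_height`, rotating at the impeller speed. Walls are rigid: the
  particle–wall effective modulus is `E/(1-ν²)`, twice the sphere–sphere
  value. Blade faces are frictional; blade edges are not rounded (face
  contact only), acceptable at the blade speeds used here.
- **Rotation.** Particle spin is integrated (solid-sphere inertia); rolling
  friction is omitted.

Poisson's ratio defaults to 0.3 (configurable). The timestep defaults to
0.2 × the Rayleigh surface-wave time computed from `E`, `ρ`, `R`; at the
default desk material (3 mm, 1100 kg/m³, 5 MPa) this is ≈ 4.9 × 10⁻⁵ s.
Neighbor search uses a uniform cell list (cell = 2.05 R); when scattered
particles would blow up the grid size the cells are coarsened rather than
falling back to an all-pairs sweep. All loops run in a fixed order, so a
given `(parameters, seed, dt)` reproduces trajectories bitwise.

**Bed preparation.** Particles are poured from a staggered, strongly
jittered lattice (1.3 diameters spacing) and relaxed under gravity with the
blade stationary until the kinetic energy falls below 10⁻⁵ N m g R; residual
velocities are then zeroed. The settled bed is a disordered packing with
coordination ≈ 4. Capacity is checked against the *settled* bed height at
packing fraction 0.6, not the pour column. Labels 1/2 are assigned by the
median-x plane, giving two vertical half-cylinder layers with counts equal
to within one particle.

**Energy audit.** `mechanical_energy()` sums kinetic, gravitational and
stored Hertzian normal elastic energy (pairs, floor, shell). Tangential
spring energy and blade-contact elastic storage are excluded; tests of
energy monotonicity therefore carry a 10⁻⁷ relative slack.

## Segregation index

Mixing quality is the contact-based segregation index

    ψ = C11/(C11 + C12) + C22/(C22 + C21),

where `C_ij` counts *ordered* contacts between labels i and j: each
unordered same-label pair credits its diagonal count twice, each cross pair
credits C12 and C21 once each. Under this normalisation ψ = 2 for a fully
unmixed bed, 1 in expectation for uniform random mixing, and 0 for a
perfectly alternating arrangement. A contact is geometric — centre distance
≤ (r_i + r_j)(1 + tolerance), default tolerance 10⁻³ — decoupled from the
force-model overlap so the census is robust to snapshot rounding. Radial
profiles partition contacts into equal-width annuli by contact midpoint;
a label with zero contacts in a region yields a missing value (NaN), never
an interpolated one, and an undefined bulk ψ raises with the timestamp.

## Endpoint forecasting

ARIMA(p, d, q) models are fitted by exact maximum likelihood (statsmodels)
with the Box–Jenkins trend convention: a constant level for d = 0, no
deterministic term for d ≥ 1 (a drift model is available via
`trend="t"`). AIC is computed as `2k − 2 log L` with k counting every
estimated parameter including the innovation variance. Order selection
searches p ∈ [0, 100], d ∈ [0, 2], q ∈ [0, 2]; the default stepwise mode
expands p per (d, q) line and stops after 10 consecutive non-improvements,
with an exhaustive mode available. Ties break toward parsimony: lower
p + q, then lower p. Non-converging fits are flagged and excluded, never
silently used; if nothing converges the attempted orders are reported.

Validation follows the half-split protocol: select and fit on the first
half of the series, forecast the second half, report the mean absolute
percentage error (the error-margin metric; the maximum APE is also
reported). The mixing endpoint `T_end` is the first time the forecast mean
descends to the cutoff ψ = 1.1, linearly interpolated between forecast
steps; if the observed series already crosses, the observed crossing is
returned and flagged. The crossing times of the 95% prediction-interval
bounds are reported as `[t_early, t_late]`. The forecast horizon is capped
(default 100 × the training length) and a non-crossing within the cap is an
explicit result, never a fabricated time.

Three numerical caveats, all visible in the test suite: exact MLE is
ill-posed on strictly noiseless series (the innovation variance collapses
and AIC comparisons between near-perfect fits are numerical noise), so
forecast-accuracy checks use low-noise rather than zero-noise curves; AIC
is not a consistent selector, so on pure white noise the mean-only model
is the modal but not near-certain selection (~50% of replicates); and
half-split *multi-step* accuracy is well-posed only when the observed
window's decay is modest relative to its level. Far from the asymptote
the mean-reversion level lies outside the observed range and is
unidentifiable — AIC then often prefers over-differenced or drift models
whose long-horizon extrapolation overshoots — so half-split validation
claims (both DEM and synthetic) are made on gently decaying windows, the
same regime as a short observation of a long industrial transient.
Forecasting the *cutoff crossing* is different and more forgiving: there
the crossing point interpolates a trend that remains within the model's
competence much longer, and recovery is within a few percent even from
windows reaching 80% of the way to the cutoff.

## Desk-scale study conditions

The reference rig is an 8 cm-radius flat-bottomed vessel loaded with
2,000 mildly cohesive 3 mm granules (ρ = 1100 kg/m³, e = 0.6, μ_f = 0.1,
γ = 2 × 10⁴ J/m³, E = 5 × 10⁶ N/m²; settled bed ≈ 19 mm). Two blade
configurations serve two distinct purposes:

- **Forecast validation** uses full-height blades at 60 RPM for 2.5 s
  (2.5 revolutions). The dense bed rotates nearly rigidly with the blades
  and the two-layer interface erodes gently (ψ ≈ 1.95 → 1.90, roughly 13×
  the census noise), so the observed window is a small fraction of the
  full mixing transient. That is the operating regime of half-split
  forecasting — a model trained on the first half can only be expected to
  track the second half when both sit inside one smoothly evolving
  regime — and there the forecast error is robustly far below the 2.5%
  margin across seeds (measured 0.2–1.2%).
- **Mixing demonstration** (the pipeline's DEM stage) uses blades
  submerged in the cake (12 mm against the 19 mm bed), which shear the bed
  vertically and mix to ψ ≈ 1 within a revolution or two. These runs
  compress the *entire* transient — spin-up, acceleration, saturation —
  into the window; the curvature reversal in the second half is genuinely
  absent from the first half's information set, and measured half-split
  errors there are 2–9%. This is a structural property of shallow desk
  beds, not a forecasting defect; forecast-validation claims are therefore
  made only in the gentle-erosion regime above.

## Synthetic generators

The curve generator emulates the one robust qualitative law of bladed-bed
mixing — relaxation toward the random-mixing asymptote driven by the
*revolution count*:

    ψ(t) = 1 + (ψ0 − 1) exp(−k · RPM · t / 60) + N(0, σ²),  clipped to [0, 2],

with the analytic cutoff-crossing time attached as metadata. Doubling RPM
exactly halves every crossing time in seconds. What it does not emulate:
spin-up transients, regime changes (decay → plateau), census noise that
grows as the bed homogenises, or any radial structure — so tests passing on
these curves certify the forecasting machinery, not DEM realism.

The design-table generator samples the nine descriptors uniformly over
ranges mirroring the study design space (radius 1.5–4.5 mm, density
800–2000 kg/m³, restitution 0.3–0.9, cohesion 0–10⁵ J/m³, friction
0.05–0.7, modulus 5–50 MPa, 1.35 × 10⁵–10⁶ particles, 2–60 RPM, cake
height 0.7–21 cm) and plants a documented response:

- `paper_like` — a multiplicative surface dominated by fill level, then
  impeller speed, then particle radius; the other six descriptors inert.
- `planted_ranking` — linear effects 4 : 2 : 1 on standardized h, RPM, R
  (a 2× separation per rank, chosen so the planted order is identifiable
  at the 65-row corpus size).
- `interaction` — a corner interaction: rows with deep cake AND slow
  impeller take disproportionately long. A pure product interaction of
  symmetric standardized descriptors is invisible to greedy tree
  splitting (its marginal effects vanish), so the corner form is the
  honest way to plant nonadditivity that distinguishes forests from
  additive linear models.
- `linear` and `null` for recoverability and null-calibration checks.

## Surrogate stage

Four regressors — random forest, RBF support-vector regression, partial
least squares, elastic net — are evaluated by leave-one-out
cross-validation with hyperparameter grid search nested inside every
training fold (3-fold inner CV, mean-squared-error scoring); R² is
`1 − SSE/SST` on the pooled out-of-fold predictions and may be negative.
The scaled methods standardize inside a Pipeline so no test-fold statistics
leak into the fit; the forest sees raw descriptors. Default grids are
conventional small-data choices (forest: features-per-split
{2, 3, 5, 9} × depth {3, 5, 10, ∞}, 500 trees; SVR: C {0.1–100} ×
γ {scale, 0.01, 0.1}; PLS components 1–5; elastic net: mixing
{0.1, 0.5, 0.9} × penalty on a log grid). Monte-Carlo tests use reduced
grids and smaller forests so replicated runs stay cheap; the estimators
and protocol are identical.

Descriptor importance is the percent increase in out-of-fold mean-squared
error after permuting one descriptor column: the table is split into five
folds, a forest is fitted per training fold, and each held-out block is
scored with each descriptor permuted (all permutation variants batched
into a single predict call). Importances are averaged over ≥ 10
permutations with their spread reported; zero-variance descriptors are
defined to have importance 0 and flagged. Sums are not normalised — the
percent-MSE scale is preserved.

## Known limitations

- Monodisperse spheres only; no liquid bridging, electrostatics, attrition,
  agglomeration, breakage or heat transfer. Blade faces are unrounded.
- Desk scale (≤ a few thousand particles, seconds of agitation): mixing
  times and their descriptor sensitivities are not quantitative predictions
  for manufacturing-scale dryers.
- ARIMA extrapolation cannot anticipate regime changes absent from the
  training window (the spin-up cut above); prediction intervals inherit
  Gaussian-innovation assumptions.
- LOOCV R² on tens of rows has high variance; method rankings on real
  corpora of this size should be read qualitatively.
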