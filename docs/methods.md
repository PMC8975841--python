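# Methods

This note records the models, numerical methods, and parameter choices behind
`mucogel`, in enough detail to reproduce or audit each analysis.

## 1. Diffusion into the gel

### Physical model

A tracer reservoir contacts a gel-filled channel at `x = 0` at `t = 0`.
Transport inside the gel is one-dimensional Fickian diffusion with constant
effective diffusivity `D_eff`:

∂C/∂t = D_eff · ∂²C/∂x²,  C(x, 0) = 0,  C(0, t) = C₀.

For a semi-infinite channel the solution is the complementary error function
profile; the package fits the normalized fluorescence as

F(x, t) = A · erfc( x / (2 √(D_eff t)) ) + B.

The amplitude `A` absorbs imperfect normalization and partitioning at the
interface and is free by default (bounded in (0, 2]); the offset `B` is fixed
at 0 unless explicitly enabled. Fitting on normalized data makes `D_eff`
invariant to rescaling of the raw intensities (checked by test).

### Image-to-profile pipeline (`diffusion_profiles`)

- **Interface detection:** column-mean intensity is smoothed with a Gaussian
  (σ = 2 px) and the interface placed at the maximum absolute gradient. The
  peak must exceed 5× the median gradient magnitude (a crude SNR floor) or an
  error is raised; a manual override always wins.
- **Profile extraction:** intensities are averaged over the central 60% of the
  channel width (edge rows suffer wall effects and vignetting); positions are
  pixel centers, `x = (i + 0.5) · pixel_size`.
- **Normalization:** each frame is divided by a per-frame reference intensity
  (reservoir region). A drift of more than 20% in the reference across frames
  flags those frames and the fit excludes them (bleaching/evaporation guard).
- **Frame selection:** the default analysis window is 30 frames at 4-minute
  intervals (2 h), which keeps the diffusion front well inside a ~2 mm field
  of view for `D_eff` in the 10⁻⁸–10⁻⁵ cm²/s range.

### Closed-form fit (`fit_erfc`)

Nonlinear least squares (`scipy.optimize.least_squares`) over all pixels and
frames jointly. `D_eff` is optimized as log₁₀ D (bounds [−14, 2] in the data's
own units) so the search is scale-free; the initial guess comes from the
half-maximum crossing of the latest usable frame, `x₅₀ ≈ 2·erfcinv(0.5)·√(D t)`
with the crossing linearly interpolated between pixels. Two additional
restarts from jittered guesses protect against local minima. Convergence
requires the optimizer to succeed and the solution to be non-degenerate.

Uncertainty is a bootstrap over frames (default 200 resamples, percentile
2.5/97.5 interval). Resampling frames rather than pixels respects the strong
within-frame correlation of residuals. In the zero-noise limit the interval
collapses onto the point estimate (checked by test).

### Finite-difference model fit (`fit_pde`)

For conditions where the semi-infinite/constant-boundary assumptions fail, the
forward model is the same PDE solved by a Crank–Nicolson scheme (two initial
backward-Euler steps — Rannacher startup — damp the oscillations the initial
concentration discontinuity would otherwise excite). Boundary conditions:
Dirichlet at the reservoir, zero-flux mirror at the far end.

- **Depleting reservoir:** the reservoir is a well-mixed compartment of
  effective length `R·L + dx/2` (volume ratio `R` relative to the channel,
  with the interface half-cell absorbed into the reservoir so the discrete
  mass balance closes to machine precision, ~10⁻¹³ relative per step). Its
  concentration falls as tracer enters the gel.
- **Adaptive internal grid:** for each candidate `D` the solver extends the
  domain to `L = max(1.5·window, window + 6√(D·t_max))` so the far boundary
  never influences the observed window, and chooses
  `dx = √(D·t_min)/6` (clamped to at most 2000 nodes) so the earliest,
  sharpest front is resolved; sub-stepping keeps the parabolic mesh ratio
  bounded. Predictions are interpolated onto the observed pixel grid.
- Fitting, restarts, and bootstrap are shared with the closed form.

On semi-infinite data the two fits agree to <1% across three decades of `D`
(checked by test). With a depleting reservoir the numerical model recovers the
generating `D` within 5%, while the constant-boundary closed form with the
amplitude fixed at its nominal value underestimates `D` (the front advances
more slowly than the constant-source model expects). Note the sign of this
bias depends on the amplitude treatment: with `A` free, the fit can trade
amplitude against diffusivity and land slightly high instead.

### Synthetic generator (`synthetic_data`)

`simulate_diffusion_pde` produces ground-truth concentration fields (same
solver, independently validated against the closed form to L∞ < 10⁻³·C₀ at
dx = L/1000). `render_image_stack` converts a field into a uint16 image stack:
intensity proportional to concentration, optional exponential photobleaching,
Poisson shot noise (gain-scaled) and additive Gaussian read noise, all driven
by a single `numpy.random.default_rng(seed)`. These emulate the dominant
noise sources of widefield fluorescence time-lapses; they do not model optical
blur, illumination flatness drift, or stage jitter.

## 2. Sessile-droplet geometry (`geometry`)

A droplet on a flat substrate is modeled as a circular cap: base half-width
`a`, sphere radius `R = a/sin θ`, cap height `h = a·tan(θ/2)`.

- **Segmentation:** Otsu (or fixed) threshold, largest connected component,
  sub-pixel contour via marching squares, Gaussian contour smoothing
  (σ = 2 samples, periodic) to suppress pixelation noise.
- **Baseline:** the longest near-horizontal run of bottom contour points
  (≥ 30% of the droplet width within 1.5 px); a tilted substrate raises an
  error rather than silently measuring against the wrong line. A fixed row
  may be supplied instead.
- **Contact angle, circle fit (default):** algebraic (Kåsa) circle fit to the
  contour above the baseline; θ = arccos((y_center − baseline)/R). Mean
  absolute error ≈ 0.06° over 30–120° at 2% image noise.
- **Contact angle, polynomial tangent (fallback):** quadratic fit of `x(h)`
  near each contact point, slope → angle. Contour smoothing rounds the
  baseline corner, so points below 4 px height are excluded and the fit
  window adapts to `clip(0.35·cap_height, 8, 40)` px. Accuracy is ~5°; it
  exists for droplets that are not circular caps, where the circle fit's
  assumption fails outright.
- **Circularity:** 4πA/P² from the smoothed contour (shoelace area,
  polyline perimeter); values ≤ 1.05 are accepted to allow discretization
  overshoot.

## 3. Plate counts, viability, cell counting (`assay_metrics`)

- **CFU/ml:** per spot, `count / (volume · 10^(−exponent))`. Only spots in
  the countable range 6–60 enter; the default estimate is the mean over
  usable rows (a `most_dilute` mode keeps only the highest usable dilution).
  If every spot is below range the result is left-censored at the detection
  limit `6 / (volume · 10^(−max exponent))`.
- **Viability:** `100 · (total − dead) / total`.
- **`count_cells`:** difference-of-Gaussians band-pass matched to the
  expected spot size, `skimage.feature.peak_local_max`, with a KD-tree match
  step used in tests to verify detections against planted ground truth.
- **Generator:** spot counts are Poisson draws with mean
  `cfu/ml · volume · 10^(−exponent)`, the standard model for dilution plating.

## 4. Rheology (`assay_metrics`, `synthetic_data`)

- **Loss tangent:** tan δ = G″/G′ per frequency; a query frequency is matched
  to the nearest measured point within 5% or linearly interpolated.
- **LVE region:** the storage-modulus plateau is the median G′ over the
  lowest strain decade; the LVE limit is the end of the maximal initial run
  staying within 5% of that plateau.
- **Generator:** single-mode Maxwell element with an optional parallel
  elastic plateau: G′ = Gₑ + G ω²τ²/(1+ω²τ²), G″ = G ωτ/(1+ω²τ²). With
  Gₑ = 0 this gives the analytic identities tan δ = 1/(ωτ) and a G′/G″
  crossover at ω = 1/τ, used as oracles.

## 5. Formulation arithmetic (`assay_metrics.recipe`)

For a total volume `V` (default 900 µl): alginate stock volume
`V·target/stock`, mucin stock volume likewise, CaCl₂ solution a fixed volume
fraction (default ½, 11 mM stock → 5.5 mM final), PBS absorbs the remainder.
Volumes are integer microliters and must sum exactly to `V`; an infeasible
composition (negative PBS) raises an error. `ug_per_ml_to_mM(c, M) = c/M`
converts stain concentrations (5 µg/ml at 616 g/mol → 8.1×10⁻³ mM).

## 6. Reproducibility

Every stochastic routine takes an explicit seed and uses
`numpy.random.default_rng`; no global random state is touched. CLI commands
record configuration, seed, package version, and SHA-256 input checksums in a
`manifest.json`, and identical inputs yield byte-identical outputs.
`scripts/acceptance.py` derives all of its randomness from a single `--seed`.

## 7. Limitations

- The diffusion model is one-dimensional with constant `D_eff`; swelling,
  binding, anomalous (non-Fickian) transport, and concentration-dependent
  diffusivity are out of scope.
- The image generators model shot/read noise and bleaching but not optical
  blur or illumination drift; interface detection on heavily blurred real
  data may need the manual override.
- The polynomial-tangent angle method is a ~5°-accuracy fallback; the circle
  fit should be preferred whenever the cap assumption holds.
- Bootstrap intervals quantify sampling variability over frames, not model
  misspecification; `goodness_of_fit` (R², RMSE) should be inspected
  alongside them.
- The Maxwell generator is a single relaxation mode; real gels show broad
  relaxation spectra, and the oracle identities apply only to the synthetic
  sweeps.
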