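# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `iplscan`.

## Coordinate conventions

IPL depth is expressed in ChAT units: the On cholinergic band is 0, the Off
band 1, the ganglion-cell-layer border ≈ −1 and the inner-nuclear-layer border
≈ +2 (defaults −1.1 and 1.9 when bands are inferred from borders). After
per-field alignment the polarity switch sits at 0.5. All traces live on a
64 Hz grid; one 32-s chirp presentation is T = 2048 samples.

## Chirp stimulus

The exact chirp waveform is configurable; the default is 2 s dark baseline,
3 s full-intensity On step, 2 s half intensity, 8 s frequency sweep
(0.5→8 Hz, full contrast), 2 s half, 8 s contrast ramp (0→100 % at 2 Hz),
2 s half, 5 s dark tail — 32 s total, intensities in [0, 1]. Before
convolution in the encoding model the stimulus is z-scored; intensity units
are arbitrary, and the transform is idempotent.

## Encoding model

Each ROI's response is `ŷᵢ = g(βᵢ + aᵢ (fᵢ ∗ x))` with a causal 64-tap kernel
(1 s at 64 Hz) in a truncated Fourier basis, frequencies k = 0…21 cycles per
kernel length (one constant basis function at k = 0, its partner fixed at 0 —
so 43 free coefficients). The per-ROI stretch αᵢ multiplies all basis
frequencies; a decreasing sigmoid mask `1/(1+exp((t−1/α)/s))` with sharpness
s = 1/64 (one tap) zeroes the kernel beyond one stretched cycle so compressed
kernels do not wrap. The output nonlinearity is the standard exponential
linear unit (identity for v ≥ 0, eᵛ−1 below) — monotone, as an output
nonlinearity must be for the scale/flip interpretation of aᵢ to hold.

Model classes, nested from most to least flexible: per-ROI kernel (α ≡ 1);
shared kernel with per-ROI stretch, scale and offset; and shared-kernel
variants whose stretch is a function of covariates — per-batch depth profiles
ω_{b,j} (interaction), depth-bin weights plus additive batch shifts ξⱼ + ψ_b,
or depth alone ξⱼ. Depth cells are the same (polarity × 10-bin) cells as the
linear depth design, equal-width over [−1, 2]; cells without ROIs keep their
initial value and are flagged (`n_roi = 0`) in the speed profile.

### Fitting

All parameters are fitted jointly by full-batch Adam (default step 0.05, up
to 2500 iterations, patience 400) on the mean squared error, with analytic
gradients — the convolution is a lag-matrix product, so one iteration is a
handful of matrix multiplications. Stretch positivity uses a softplus
parameterization for the per-ROI variant and a floor (10⁻², with warning) for
covariate sums. Initialization: α = 1, aᵢ = ±1 by polarity, β = 0, kernel
coefficients small seeded Gaussians. The best iterate is tracked and returned;
a fit that stops before the loss plateaus warns.

Two refinements matter for the per-ROI stretch variant:

* **Stretch grid search** (every 250 iterations): per-ROI stretches are
  re-evaluated on a log grid (0.4–2.5), escaping phase-aliasing local minima.
* **Gauge search** (at polish time): the model is nearly degenerate under
  rescaling every stretch by a common factor while compressing the kernel by
  its inverse (exactly degenerate only at factor 1, because basis frequencies
  are integers). Gradient descent settles at an arbitrary point in this
  shallow valley, so candidate gauges (0.7–1.43) are each jumped to, the
  kernel briefly re-fitted with stretches frozen, and the best re-fitted loss
  kept. The current parameters seed the comparison, so the search never
  worsens the fit. Without this step, recovered stretches can share a common
  ×1.1–1.5 bias; with it, noiseless recovery is exact.

For the covariate variants the stretch structure (ξ, ψ, ω) is reported as
fitted; the additive decomposition has the usual gauges (ξ + c with ψ − c,
and the global stretch gauge above), so batch shifts and depth profiles
should be compared via correlations, which is what the tests do.

`fit_variant_chain` fits the variants from most to least constrained and
warm-starts each richer model from the previous solution (interaction from
ξ + ψ, per-ROI stretch from the interaction's stretches, per-ROI kernels from
least-squares projections of each ROI's realized kernel). Together with
best-iterate tracking this makes the attained explained variance respect the
model-class nesting up to a small tolerance (`ev_tolerance`, default 0.02).

Explained variance is E.V. = 1 − E[(y−ŷ)²]/Var[y] per ROI (training data;
a held-out-repeat evaluation can be built from the simulator's repeats), and
is aggregated as mean ± 2 SEM across ROIs.

## Linear batch models

Fixed-effects dummy regressions of the N×T matrix on: polarity (N×2); depth,
10 equal-width bins per polarity over [−1, 2] (N×20; out-of-range ROIs are
clipped to the end bins with a warning, empty bins keep zero columns and are
flagged); batch, one predictor per (batch, polarity) with the
lexicographically first batch as reference (N×2B); and batch + depth. In the
combined model the batch design is first orthogonalized against the depth
design by projecting out span(X_depth) via least squares, so that any
variance expressible by depth alone is ascribed to depth — the conservative
direction when the question is how much variance is experimental. Indicator
designs make the OLS weights group-mean traces; rank deficiency is handled by
the pseudoinverse (minimum-norm solution, with a warning when P > N).

## ROI extraction

The per-pixel local correlation is the mean Pearson correlation with the
8 neighbours (border pixels use available neighbours; constant pixels are
invalid and 0). Seeding thresholds are per z-line percentiles (default 70th,
linear interpolation); ROIs are 4-connected components of the supra-threshold
set, ordered by descending seed correlation with ties broken in (z, x) scan
order, filtered to 1–4 µm effective diameter (d = 2√(area/π)), and scored by
the quality index: variance over time of the repeat-mean trace divided by the
mean per-repeat variance, clipped to [0, 1] (1 for perfectly repeatable
responses, ≈1/R for noise; inclusion threshold 0.3). The first
`artefact_lines` z-lines of each frame (ETL settling, ~10 ms) are excluded
from all correlation and trace computations.

The quality index is computed on synchronized, resampled repeats *before*
detrending: zero-phase high-pass filtering inflates the variance of the
reliability estimator for noise traces (Monte Carlo: P(QI > 0.3) rises from
~0.3 % to ~4 % for pure noise at 4 repeats), which would cost specificity.

Whether the original grouping used 4- or 8-connectivity, and how multiple
seeds interact, is not specified anywhere we could check; the deterministic
scheme above is a documented choice.

## Depth registration

Raw depth is the affine map sending the On ChAT band to 0 and the Off band to
1; when only IPL borders are visible, band positions solve the affine map
placing the borders at −1.1/1.9. Functional alignment per scan field: the
first principal component of the row-centred trace matrix separates On from
Off; its sign is anchored by requiring the component to rise during the
stimulus On step (PCA sign is otherwise arbitrary). Polarity is the sign of
each ROI's projection; the switch depth is the 50 %-point of a logistic fit
of polarity on depth (scikit-learn, mild ridge C = 10³ so perfectly separable
fields stay well-defined and deterministic); aligned depth = raw − switch
+ 0.5. Single-polarity fields fall back to the population default 0.24 with a
warning. The switch estimate's accuracy is limited by the depth gap between
the innermost Off and outermost On ROI, so dense fields (≥100 ROIs) are
needed for ~0.05 ChAT-unit accuracy.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed:

* Depths uniform on [−1, 2]; polarity On below the centre (0.5); amplitudes
  lognormal (σ = 0.25) with On positive, Off negative; offsets N(0, 0.05).
* Truth speed profile ξ over 10 depth bins: Gaussian peak (width 0.6,
  base 0.7, amplitude 0.7) at the IPL centre, plateau on the On side beyond
  the On ChAT band, continued decline on the Off side — peak stretch ≈ 1.36,
  borders ≈ 0.7.
* Batch shifts ψ_b ~ N(0, 0.15); each batch is guaranteed at least one ROI.
* Truth kernel: integral-normalized difference of two gamma-like lobes
  (τ = 0.05/0.12 s, weight 0.8 on the slow lobe), projected once onto the
  masked Fourier basis — transient, biphasic, with a small net-positive DC so
  a light increment drives an On terminal up both at onset and sustained.
* Traces: the same prediction code path as the fitted model (so noiseless
  simulator output equals model predictions to machine precision), plus
  i.i.d. Gaussian noise per 64 Hz sample and repeat (default σ = 0.5,
  4 repeats).
* Movies: 64×56 px (1.6 ms/line → 11.16 Hz frames), 6 artefact lines of
  high-variance noise, a linear labelling gradient (0.8–1.2) along z,
  per-pixel noise σ = 0.1 around baselines. Target ROIs are 4-connected blobs
  of 3–7 px placed without overlap in a z band (lines 8–44); the rest of the
  band is filled to ~50 % coverage per line with "neuropil": weakly coherent,
  stimulus-independent structures (smoothed noise, amplitude 0.18). This
  density is what makes the per-line 70th-percentile threshold meaningful —
  in a sparse field that threshold is a noise quantile and admits 30 % of
  background pixels by construction, exactly as it would on real data without
  dense labelling.

What the simulator does **not** emulate: optical point-spread blur,
photobleaching, shot noise, eye movements, indicator (iGluSnFR) kinetics, or
kernel-shape diversity beyond temporal stretch. Passing tests therefore show
that the pipeline recovers the structure this generative family produces —
segmentation under depth-dependent SNR, speed gradients, additive batch
shifts — not that the LN-stretch family is an adequate model of any given
recording. Explained variances on synthetic data (≳0.9) are accordingly much
higher than on real recordings.

## Numerical choices and degenerate inputs

* Percentiles use the linear-interpolation convention; fixed for
  reproducibility.
* Detrending is an order-2 Butterworth high-pass at 0.1 Hz applied
  forward-backward (zero phase — no group delay, which would bias the speed
  analysis). Its edge transients span ~10 s; amplitude checks use interior
  RMS. Detrend and repeat-average commute (both linear); fits consume
  repeat-averaged traces (T = 2048 is exactly one presentation).
* Resampling is linear interpolation onto [0, duration) grids; markers
  beyond the recording drop that repeat with a warning.
* Kernel zero crossings: first sign change after the absolute-maximum tap,
  linearly interpolated between taps; kernels that never change sign return
  an undefined marker (NaN).
* Infinite ETL focal length (zero optical power) maps to Δz = 0; f_ETL = 0 is
  rejected. n_air is fixed at 1.
* All-constant movies yield an all-invalid correlation image (warning, not
  error); z-lines with no valid pixels get +∞ thresholds (no seeds).
* Every generator and fit is deterministic given its seed; pipeline stage
  seeds are spawned from one top-level seed, and every report table carries a
  hash of the full configuration.

## Problem sizes

Test and acceptance runs use: 60 ROIs/4 batches for variant-chain
comparisons, 300 ROIs/6 batches (noiseless) for parameter recovery, 120
ROIs/6 batches for the linear-model tables, one 64×56 px movie with 30
planted terminals for segmentation recovery, and 150-ROI fields for switch
alignment — sizes at which the statistical claims stabilize while a full run
completes in minutes on one CPU.

## Known limitations

* The stretch model's covariate decomposition is identified only up to the
  additive (ξ/ψ) and global stretch gauges; recovered profiles should be read
  up to these transformations (correlations, ranks, peak locations).
* The polarity switch localization assumes a monotone On→Off transition in
  depth; fields violating this (mixed stratification) will produce a poor
  logistic fit.
* The linear models are training-fit comparisons, as in the figure they
  reproduce; they are not cross-validated.
* Reported per-ROI kernels at α ≡ 1 cannot represent frequencies above
  21 cycles/s; strongly compressed true kernels (α ≳ 1.5) lose a little
  high-frequency content in that variant.
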