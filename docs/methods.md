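# Methods

This note describes the models and procedures implemented in `lfpdyn`, the
assumptions behind them, the synthetic-data generator used to validate the
pipeline, and the numerical choices that were genuinely open.

## Scientific setting

During slow, ostensibly continuous isometric movements, motor output is
discretized into rhythmic submovements at roughly 3 Hz, and multichannel
motor-cortical local field potentials (LFPs) carry a low-frequency
oscillation phase-locked to them. After low-pass filtering, within-area mean
referencing, and PCA, the multichannel LFP reduces to a 2-3 dimensional
trajectory x(t) that rotates once per submovement cycle. `lfpdyn` implements
the quantitative machinery for this picture:

1. **Trajectory geometry.** The areal velocity
   `v(t) = 1/2 x(t) x x'(t)` (vector cross product; area swept per unit time
   about the origin) summarizes rotation strength. On a circular orbit of
   radius r and frequency f, `|v| = 1/2 r^2 * 2 pi f`, so
   `f(t) = |v| / (pi |x|^2)` reads off the instantaneous rotation frequency.
2. **Kinematic decoding.** Each submovement i contributes a 3D areal-velocity
   vector v_i (time-averaged over +-200 ms around the speed peak). The model
   `v_i = s_i b(theta_i)` with
   `b(theta) = b0 + b1 cos(theta) + b2 sin(theta) + b3 cos(2 theta) + b4 sin(2 theta)`
   (15 scalar parameters, linear least squares) links v_i to peak speed s_i
   and direction theta_i. Speed is decoded as `|v_j| / |b0|`, direction by a
   0.5-degree grid argmax of the normalized projection `v_j . b / |b|`.
   Performance is scored by `CoD(speed) = 1 - sum (s - s_hat)^2 / sum s^2`
   (note the raw sum-of-squares normalization: predicting zero scores 0) and
   `CoD(direction) = mean cos(theta - theta_hat)`; significance comes from
   re-running the full leave-one-out procedure on label-shuffled surrogates
   and taking the 95th percentile.
3. **Trace-zero linear dynamics.** The model `x'(t) = A x(t)` with
   `trace(A) = 0` (3 free parameters) is the minimal linear system with
   stable rotational solutions; for `det(A) > 0` its orbits are closed
   ellipses of frequency `sqrt(det A) / 2 pi`. A is fitted by least squares
   of the sampled derivative on the trajectory; fit quality is the vector
   `CoD = 1 - sum |A x - x'|^2 / sum |x'|^2` over the whole recording. A
   model fitted in one behavioral state can be scored on another state's
   data projected onto the *same* task-derived PC basis (generalization),
   and a white-noise null calibrates how much apparent fit the
   preprocessing chain alone can produce.
4. **Phase statistics.** Event-relative LFP phases are Hilbert angles of
   event-triggered averages at the event time (phase 0 at a cosine peak);
   spike phases default to the polar angle in the PC plane after rotating
   it so that the submovement-triggered average trajectory has zero phase
   at peak speed. Phase locking is tested with the Rayleigh statistic, and
   cross-state phase consistency with a circular-circular correlation.

## Preprocessing choices

- Filters are 4-pole Butterworth applied forward-backward (`sosfiltfilt`,
  reflective padding), i.e. zero phase and squared magnitude response:
  delta = low-pass at 5 Hz, beta = 10-30 Hz band-pass (2 poles per edge).
  "Delta" is a pure low-pass, not a band-pass with a high-pass edge.
- Mean referencing subtracts the instantaneous mean across channels of the
  same cortical area; single-channel areas are rejected rather than passed
  through.
- PCA is computed over the full recording (no trial gating). Component
  signs are fixed by two conventions: every component's largest-magnitude
  loading is positive, and PC2 is flipped if needed so the mean areal
  velocity in the PC1-PC2 plane is positive (anticlockwise). This makes
  rotation sense comparable across sessions and conditions.
- Derivatives are central differences (one-sided at the ends); at 488
  samples/s the relative bias on a 3 Hz component is ~2.5e-4.

## Event detection

Submovements are local maxima of radial cursor speed strictly above 30 %/s
with a 100 ms refractory rule (keep the larger peak); the refractory gap is
set well below the ~300 ms cycle so genuine rhythmic events are never
merged. Direction is the angle of the instantaneous torque-velocity vector
at the peak; the peak-speed time is used as the trajectory-averaging anchor
throughout. K complexes are positive deflections above 250 uV on a single
surface-referenced channel with 1 s minimum separation. Rhythmicity is
quantified by the pairwise-interval histogram divided by the analytic
expectation for a homogeneous Poisson process with the same per-trial
counts (triangular finite-window correction), so Poisson timing gives a
flat profile at 1.

## The synthetic-data generator

No public recordings exist for this setting, so the generator provides
sessions with known ground truth. It is phenomenological: a single latent
oscillator at constant frequency f (default 3 Hz) drives a 2D rotation
`(A(t) cos phi, A(t) sin phi)` whose squared envelope is a constant
baseline plus one raised-cosine burst (half-width 200 ms) per submovement,
scaled by that submovement's peak speed. Because the areal velocity of such
a trajectory is `pi f A(t)^2` *independently of how A varies*, burst
scaling transfers linearly to areal velocity — the property the decoder
assumes.

Key default choices and why:

- **Submovement timing**: a phase-locked renewal process — one candidate
  per oscillator cycle, emitted with probability rate/f (default rate
  1.5/s) — so intersubmovement intervals peak at one cycle (~333 ms) with
  harmonics at multiples, and every peak occurs at the same oscillator
  phase.
- **Peak speeds**: log-normal (median 70 %/s, log-SD 0.35), wide but almost
  entirely above the 30 %/s detection threshold.
- **Direction coding**: event directions are uniform over 8 target angles;
  a third latent dimension receives
  `tan(tilt) * A(t) cos(phi - theta_i)` during event i, which tilts the
  rotation plane's normal by exactly `tilt` radians (default 0.3) toward
  direction theta_i. The resulting areal-velocity vector is
  `coupling * s_i * (-tan(tilt) cos theta_i, -tan(tilt) sin theta_i, 1)` —
  a pure first-harmonic Fourier series, so the decoder's model class
  contains the truth.
- **Baseline rotation**: the oscillation persists between bursts at 0.7 of
  the burst-driven RMS amplitude. This reflects the continuously visible
  low-frequency oscillation during task performance, and it matters
  numerically: one-cycle bursts locked at a fixed phase are spectrally
  broad, and without an ongoing narrowband component the 5 Hz low-pass
  truncates their upper sideband enough to bias the fitted rotation
  frequency ~10% low. With the baseline, frequency recovery is within ~3%.
- **Coupling calibration**: the generator promises that regressing
  window-averaged areal velocity on peak speed recovers `speed_coupling`
  (default 400 score-units^2/s per %/s). The internal latent scale
  therefore divides out the analytically known regression inflation from
  the baseline offset and from adjacent-cycle burst tails inside the
  +-200 ms window.
- **Channel mixing**: channel c carries `A(t) cos(phi + psi_c)` with fixed
  per-channel phases psi_c, evenly spaced around the cycle by default (a
  travelling-wave pattern); the tilt latent maps through a `cos(2 psi_c)`
  spatial pattern orthogonal to the plane columns. Mixing norms are chosen
  so PCA scores preserve the areal-velocity calibration.
- **Noise**: pink (1/f) background plus white sensor noise (5 uV SD each).
  Pure white noise would leave the delta band unrealistically clean; the
  pink component puts noise power where the analysis lives.
- **Spiking**: inhomogeneous point processes with von Mises phase
  modulation `rate ~ exp(kappa cos(phi - phi_pref))`, kappa = 1.5,
  preferred phases leading the peak-speed phase by 0.52 rad (+-0.2 rad
  across units). With kappa = 0 spikes are homogeneous Poisson and their
  phases are uniform.
- **Sedation mode**: the same oscillator and the same psi_c, but amplitude
  comes in 1-3-cycle bursts flanking K complexes (>250 uV
  difference-of-Gaussians transients, common-mode across channels, at
  phase-locked Poisson times with 1.5 s refractory spacing), with
  mean-referenced delta-band variance 10x the task mode (configurable
  ratio). Spiking is gated onto the bursts, emulating firing concentrated
  on the K-complex rising phase and peak.

What the generator does **not** emulate: biophysical mechanisms, electrode
drift and artifacts, mains noise, non-stationary oscillator frequency,
beta-band oscillatory sources (the beta band contains only noise, which is
what makes the delta-fit/beta-fit contrast clean), spindles, and
behavioral trial structure. Tests passing on these sessions therefore
validate the *machinery* — calibration, equivariances, detection
thresholds, statistical nulls — not the biological claims, which require
real recordings.

## Numerical choices

- Direction argmax on a fixed 0.5-degree grid (deterministic; ties go to
  the smaller angle). Leave-one-out fits use rank-one downdates of the
  5x5 Gram matrix, solved in batch, which keeps 1,000-surrogate shuffle
  runs tractable.
- Events with zero areal velocity or degenerate folds are excluded from
  CoDs and counted, not imputed.
- Trace-zero fits use the closed-form normal equations of the stacked
  3-parameter linear system; degenerate (zero-variance) trajectories are
  rejected.
- The white-noise null uses 10 channels x 10 minutes x 200 replicates by
  default; its 95th percentile scales inversely with recording length
  (the effective sample count of the 0-5 Hz band), so the configured
  session length is part of the null's definition.
- Cross-correlogram extrema are refined by parabolic interpolation;
  estimates whose extrema fall below 0.1 normalized correlation are
  rejected as unreliable.
- Welch/coherence estimators use 2,048-sample rectangular segments without
  overlap (0.238 Hz resolution at 488 samples/s); the magnitude-squared
  coherence of independent signals has mean ~1/L for L segments, and the
  95% floor `1 - 0.05^(1/(L-1))` is reported alongside.
- Circular-circular correlation defaults to the uniform-corrected
  (pairwise-difference) form because the mean-centered form is undefined
  for uniformly spread marginals — exactly the regime of travelling-wave
  channel phases; the mean-centered form remains available and errors on
  zero-resultant inputs.
- The Rayleigh p-value uses the standard finite-n approximation
  `exp(sqrt(1 + 4n + 4 n^2 (1 - R^2)) - (1 + 2n))`.
- Spike phases from the PC plane use the polar angle by default (the
  Hilbert angle of PC1 is available); samples with radius below 25% of the
  RMS radius are masked as phase-undefined, and units with more than half
  their spikes masked are rejected.

## Known limitations

- The speed-decoding rule `|v|/|b0|` is exact only when `|b(theta)|` is
  direction-independent; with strong direction harmonics it is biased, and
  the speed CoD's raw-sum-of-squares normalization makes its shuffle null
  high (a mean-speed predictor already scores `E[s]^2 / E[s^2]`).
  Significance statements must therefore always reference the shuffle
  threshold, never the CoD's absolute value.
- PCA leaves the within-plane rotation of near-degenerate components
  arbitrary; all geometry downstream is rotation-invariant, but raw PC1/PC2
  coordinates are not comparable across sessions unless the plane is
  rotated to the zero-phase-at-peak-speed convention.
- The dynamics fit treats every sample equally; amplitude bursts dominate
  the regression, so the fitted frequency is a variance-weighted summary,
  not an unbiased spectral estimate.
- `read_nwb_like` maps only a raw `acquisition/<series>` electrical series
  into a session container; it is a convenience for NWB-style HDF5 layouts,
  not an NWB implementation.
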