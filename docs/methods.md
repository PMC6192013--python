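# Methods

This note documents the models, parameters, and numerical choices behind
procspec, and what the synthetic data generator does and does not emulate.

## Time-domain variable smoothing

Each spectral variable (one wavelength channel) is a time series within one
batch. The smoother replaces point i by the centered mean of k consecutive
points of that channel. Near the series ends, where a full centered window
does not fit, the point at ordinal l from the end (l = 1 is the end point)
uses a reduced symmetric window of (l−1)·2+1 points; end points therefore
pass through unchanged, and k = 1 is the identity. The symmetric reading of
the end rule is deliberate: it keeps every window centered, so the smoothed
trajectory is not phase-shifted anywhere in the batch.

Two facts about the window width k matter operationally:

* **Delay.** In-line, a centered window emits point i only after its
  (k−1)/2 future points have arrived: the delay is (k−1)/2 · dt seconds and
  the full window spans (k−1) · dt. For k = 15 on a 5-s acquisition grid:
  35 s delay, 70 s span. (A full span comparable to the material circulation
  period of the dryer is desirable: each granulate portion then has a good
  chance of passing the probe within one window, so the average approximates
  the bulk.)
* **Linearity.** The smoother is linear and averaging, so column means are
  preserved, output values stay within each column's range, and smoothing
  commutes with linear combinations — properties the test suite asserts by
  fuzzing.

Smoothing is applied per batch stream, never across batch boundaries
(batches are separate processes), and always before pairing with reference
values. It uses no reference information, so it cannot leak across
cross-validation folds; learned sample-wise transformers (the MSC reference)
are re-fit inside each training fold instead.

## Scatter corrections (comparison baselines)

* **MSC**: each spectrum is regressed on a reference spectrum over
  wavelengths (OLS, x ≈ a + b·ref) and corrected to (x − a)/b. The reference
  is the mean spectrum of the fitting set, stored by the transformer and
  reused for new data. Slopes |b| < 1e-12 raise an error naming the row.
* **SNV**: per-spectrum standardization to mean 0 and sample SD 1 (n−1
  denominator, so the identity asserted in tests is exact).
* **Savitzky–Golay derivative**: scipy's filter along the wavelength axis,
  default first derivative / second-order polynomial / 15-point window
  ("1D2.15"). Derivatives are per channel index, not per nm. Edges use the
  polynomial fit within the truncated window.

## PLS calibration and validation

The regression is PLS1 via NIPALS with X-deflation: w = E'f normalized,
t = Ew, p = E't/t't, q = f't/t't, then E ← E − tp', f ← f − qt. Data are
mean-centered, never autoscaled (spectral channels share units). For a
single response the weight vector is analytic per component; the inner loop
(tolerance 1e-10, max 500 iterations) exits immediately and exists for
robustness. Prediction coefficients are B = W(P'W)⁻¹q. Requesting more
components than the effective rank of X raises an error; successive scores
are mutually orthogonal (asserted to 1e-8), and at full rank the predictions
coincide with OLS (oracle-tested to 1e-6).

RMSE is root-mean-square error in moisture %, and R² uses SS_tot about the
mean of the evaluated set (so validation R² is relative to the validation
set's own spread).

Validation schemes: leave-one-sample-out CV; leave-a-batch-out CV (folds are
whole batches — the conservative scheme, since batch-to-batch variation is
the dominant generalization obstacle in batch processes); and external
validation on a preselected, disjoint batch subset. Latent-variable scans
fit each fold once at the maximum A and reuse the decomposition for all
smaller A.

## Window scan and dynamic focusing

The scan evaluates the entire pipeline (smooth → pair → restrict → PLS →
validate) for every odd k in the requested bounds, and selects the smallest
k whose RMSE is within a relative tolerance (default 2%) of the minimum —
encoding the preference for light smoothing given the delay cost.

Range-model families are fit by strict restriction lod < threshold
(thresholds given full-range-first, strictly decreasing). The focusing
cascade predicts the stream with the active stage's model and advances to
the next (drier) stage after `debounce` (default 3) consecutive predictions
below that stage's threshold. Switching is one-way: drying is monotone at
the process scale, and reverting to a wetter-range model on a noisy
prediction would cause chattering near thresholds. The debounce guards
against single-point dips. The streamed predictions use the same centered
smoother; at the start of a stream the reduced end windows apply, and each
point is understood to become available (k−1)/2 acquisition steps after its
nominal time.

## The synthetic campaign generator

Real campaigns of in-line drying spectra with LOD references are not
publicly available, so the generator produces data with the statistical
structure the methods exploit, with ground truth retained for
parameter-recovery tests.

Model, per batch:

* **Trajectory**: m(t) = m_end + (m₀ − m_end)·exp(−t/τ), with m₀ ~ U(24, 26)%,
  m_end ~ U(2.4, 3.5)% and τ = duration / U(3.5, 4.5) by default, so every
  batch ends near its dry endpoint regardless of length. The exponential is
  the simplest monotone model with a time constant; distinct drying phases
  (e.g. a constant-rate period) are deliberately omitted.
* **Clean spectrum**: A₀(λ,t) = b(λ) + α·m(t) + S(m(t))·Σ amp·G(λ; center, width),
  with Gaussian water bands at 1440 and 1930 nm (widths 45/55 nm, the
  1930 nm band 3× stronger) and the flat watermark term α = 0.004 lg(1/R)
  per % LOD. The band response S(m) = m_sat(1 − e^(−m/m_sat)) with
  m_sat = 200% is mildly sub-linear, as strong NIR bands are; this small
  curvature is what makes narrow-range models genuinely more accurate than
  the full-range model on dry samples — with a perfectly linear response the
  range-focusing gain would vanish, contradicting the behaviour the cascade
  is built for. The static baseline b(λ) is a fixed slope plus broad
  moisture-independent features; its structure matters, because it anchors
  the MSC regression slope the way real excipient absorbance does (with a
  featureless baseline, MSC's slope locks onto the water band and the
  comparison becomes unfairly catastrophic for MSC).
* **Observation**: A = f_t·A₀ + o_t + ε, with f_t = exp(N(0, σ_f²))
  (lognormal keeps the multiplicative turbulence factor positive),
  o_t ~ N(0, σ_o²) flat offsets, and iid channel noise ε ~ N(0, σ_ε²).
  Multiplicative-plus-offset is exactly the distortion family MSC/SNV are
  designed to invert, which keeps the comparison fair. The magnitudes
  σ_f = 0.022, σ_o = 0.0095, σ_ε = 0.003 are set so the raw wavelength-wise
  correlation of intensity with moisture bottoms out near r ≈ 0.8 (its
  weakest at the short-wave end, far from both bands), the regime in which
  all three phenomena — informative flat variance, masking turbulence, and
  the gain from time-smoothing — are simultaneously visible.
* **References**: n ~ U{5..26} samples per batch at stratified-uniform times;
  LOD = m(t) + N(0, 0.06²) truncated at 0 — the 0.06% is the reproducibility
  of gravimetric moisture analyzers.

Campaign geometry defaults: 25 batches, the last 8 in the validation role,
396–1213 spectra per batch at 5-s intervals on a linear 256-channel grid
from 1091.8 to 2106.5 nm. The channel grid is assumed evenly spaced. Tests
and the acceptance script shorten batches to 150–300 spectra — the problem
sizes chosen for the shipped analyses — which preserves every structural
property while keeping simulations light. Per-batch streams derive child
seeds from the master seed (SeedSequence spawn keys), so batch i is
bit-reproducible independently of how many batches are generated.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: probe-fouling artifacts and cleaning-cycle spikes
(the flat-noise model subsumes mild fouling only), particle-size dynamics,
temperature-dependent band shifts, detector nonlinearity beyond the band
saturation term, API concentration effects, and non-exponential drying
phases. Conclusions from the simulator are structural (orderings,
mechanisms, contracts), not quantitative forecasts of industrial accuracy.

## Numerical choices and degenerate inputs

* Nearest-in-time pairing breaks ties toward the earlier spectrum (the one
  already observed when the sample was drawn); pairing gaps beyond 60 s
  (configurable) warn but keep the row.
* Range restriction uses strict inequality (lod < threshold) and is
  idempotent and monotone in the threshold.
* PCA is column-mean-centered (sklearn SVD backend); component signs are
  fixed so the largest-magnitude loading element is positive, making scores
  reproducible across SVD implementations. Undefined correlations
  (zero-variance channels) are reported as missing, never as 0.
* Outlier handling is a manual per-sample `excluded` flag in the reference
  files; no automatic rule is invented.
* CSV round-trips are lossless to 1e-12 (17-significant-digit formatting).
* Constant rows (SNV), zero slopes (MSC), rank-exceeding component counts
  (PLS/PCA) and empty streams raise errors naming the offending row or
  range rather than propagating NaNs.

## Known limitations

* PLS1 only (single response); no PLS2, kernel or sparse variants, and no
  uncertainty intervals on predictions.
* The cascade shares one smoothing window and one latent-variable count
  across stages by default (per-stage overrides are possible through the
  API); switching relies on predicted moisture, the only signal available
  in-line.
* The smoother assumes a uniform acquisition grid within a batch; time
  stamps are used for pairing and delay accounting, not for irregular-grid
  weighting.
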