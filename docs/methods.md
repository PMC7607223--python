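# Methods

## Warping model

A warping function maps normalized structural time `t ∈ [0, 1]` to an
individual response's own normalized time.  Its logarithmic derivative
`w(t) = ln h′(t)` is expanded in `K` linear B-splines on equally spaced
knots; `h` is then recovered as `h(t) = A + B ∫₀ᵗ exp{w(u)} du` with
`A = 0` and `B = 1/∫₀¹ exp{w}` forced by the endpoint constraints
`h(0) = 0`, `h(1) = 1`.  Monotonicity is structural: `exp{w} > 0` for every
finite coefficient vector, so the optimizer can never produce a
non-invertible warp.  Defaults: `K = 13` on a 0–12 ms window (1-ms knot
spacing), warp evaluated on the response's own sample grid
(197 samples at 16.384 kHz; a finer grid is available via `n_grid` when
quadrature accuracy matters more than speed).

Numerical conventions: integrals use the left-endpoint rectangle rule
(at ~197 grid points the rectangle-rule variants differ far below every
tolerance used here, but the choice is fixed for reproducibility);
derivatives use the forward difference quotient with the last value
replicated; responses are warped by linear interpolation, which cannot
extrapolate because the endpoints are pinned.  Fitted coefficients are
bounded to ±5 — `exp(5) ≈ 148`-fold local stretch, far beyond anything
physiological — purely to keep the optimizer in a numerically safe region.

## Fitting criteria

Four penalized criteria compare the warped response `x*` with the target
`y` over normalized time: squared difference (`psd`), squared difference of
the forward-difference derivatives (`psdd`), negative Pearson correlation
(`pmc`), and negative correlation of the derivatives (`pmcd`); each adds
`λ ∫ w′(t)² dt`, the roughness penalty on the warp's relative curvature
(closed form `Σ (c_{k+1} − c_k)²/Δt` for linear splines).  Integrating over
normalized time makes λ comparable across sampling rates.  The λ grid
{0, 0.001, 0.01, 0.1, 1} with the four criteria gives 20 loss functions,
and 40 registration conditions across the two procedures.  Derivative
criteria differentiate *after* warping (`x*′`, not a warped `x′`).
Correlation criteria raise an error on zero-variance input rather than
silently returning 0, which would corrupt a minimization.

## Registration procedures

* **Average-target (`at`)**: two passes — fit every response to the
  cross-sectional average of the target condition, then fit the
  once-warped responses to the structural average of the once-warped
  target responses.  Further passes change the structural average by less
  than the first pass's alignment gain and are off by default.  Each
  pass's fitted warps are composed with the inverse of their
  target-condition pointwise mean before being applied.  This centering
  resolves a genuine ambiguity: any common warp `g` applied to all
  individual warps aligns the set equally well, so the structural time
  axis is otherwise defined only implicitly by the target — and warping to
  a fixed target biases it toward that target's timing.  After centering,
  warps average to the identity over the target condition, structural
  latencies read as population-average latencies, and fitted warps are
  directly comparable with externally defined (e.g. simulated) ones.
* **Pairwise (`pw`)**: each response is fitted to every other subject's
  target-condition response and the warps averaged pointwise (the mean of
  strictly increasing, endpoint-pinned maps is again one); the averaging
  over targets plays the same axis-fixing role there.

Fits start from the identity (all coefficients 0) and use a bounded
quasi-Newton minimizer (L-BFGS-B, numeric gradients, `ftol = 1e-6`, 200
iterations).  A failed fit — or one that somehow ends above the identity
loss — falls back to the identity warp with `converged=False` and a logged
warning, so a batch run never crashes or degrades below its starting
point.  Optimization is deterministic; all stochasticity lives in the data
generator.

## Pre-processing

Fixed stage order: 4th-order Butterworth band-pass (100 or 150 Hz to
2 kHz; zero-phase by default so group delay cannot masquerade as neural
latency — a causal mode exists), epoch selection by smallest maximum
|voltage|, inverse-variance weighted averaging over consecutive 250-trial
blocks (with odd/even-trial replicate halves), linear pre-alignment of
condition averages by integer-sample cross-correlation lag over the
warping window (ties break toward the smaller |lag|; the stored lag is
re-added to extracted latencies), cross-fade of the 150-Hz-filtered
version (≤ 4 ms, the wave-I range) into the 100-Hz version (≥ 6 ms, the
wave-V range) with a 2-ms linear ramp centred on 5 ms, and mean/RMS
normalization over the warping window with the removed factors stored for
exact de-normalization.

## Extraction

Waves are picked once on the structural grand average (mean of the
per-condition structural averages): the largest local maximum in the
wave's peak window and the smallest local minimum after it in the trough
window; a window containing no local extremum raises an "unpicked" error
rather than silently returning a window edge, and equal-height extrema
break toward the earlier latency.  User-supplied picks are accepted
verbatim.  Individual amplitudes are read off the aligned responses at
the structural latencies (normalized units by default; multiplied by the
stored RMS factor when µV are wanted); individual latencies are
`h_i(t_peak)` mapped back to milliseconds plus the condition's
pre-alignment lag.  Every subject gets a row for every picked wave — by
construction there is no search-window exclusion and no selection bias.

## Validation metrics

Response deviation: pointwise cross-subject SD of mean-corrected,
RMS-normalized responses, averaged over the window and (equally) across
conditions.  Replicate cross-validation registers each alternate-half
replicate separately (targets rebuilt from each replicate set, so the two
fits see independent noise) and applies the warps same- and crosswise;
`noise_alignment = dev(cross) − dev(same)` isolates noise over-fitting and
`abr_alignment = dev(original) − dev(cross)` genuine response alignment.
Warp accuracy is `ρ(ĥ(t)−t, h(t)−t)`; two identity warps return a flagged
1.0 (aggregation stability), one identity a flagged NaN.  SNR is the RMS
ratio in dB over the window.  The selection-bias check is the exact
two-sided binomial test with null probability 0.5 (the sensible null for
"which side of the search window was a subject excluded on"; the
probability is a parameter).

## Synthetic data generator

The generator emulates a parameter-recovery design: a parametric
structural template is de-aligned through inverses of random warps and
embedded in noise at a controlled SNR sweep.

* **Template**: Gaussian peak/trough pairs for waves I (2 ms), III
  (4.5 ms) and V (6.5 ms, largest), each trough one wave-width after its
  peak, plus a broad positive slow-wave recovery centred at 11 ms.  The
  recovery term reflects that recorded responses are not signal-free after
  the wave-V trough; without it the warp is unconstrained over the last
  ~2.5 ms and no method could estimate it there.
* **Warps**: i.i.d. uniform spline coefficients on ±`magnitude`;
  `magnitude = 0.3` (default) produces latency shifts of roughly ±0.5 ms
  on the 12-ms window, comparable to adult inter-subject ABR variability.
* **Noise**: Gaussian, band-limited to 100–2000 Hz, with in-band spectrum
  falling as 1/f² — the usual model for scalp EEG/EMG background above
  ~100 Hz, and the spectrum the plus-minus reference of replicate averages
  inherits.  Unit RMS over the window; exactly zero with `noise_rms=0`.
  (A flat band, `psd_slope=0`, is available; note that flat noise is
  substantially harsher on derivative-domain criteria than real
  recordings at the same nominal SNR.)
* **SNR sweep**: `x̂_i = 10^(Δsnr/20)·s_i + n_i` with Δsnr from −21 to
  0 dB in 3-dB steps (8 conditions); one noise trace per subject is shared
  across the sweep, so only the signal scale varies.  The template gain is
  set so the per-response SNR at Δsnr = 0 is 10.7 dB, placing the sweep
  over roughly −10…+11 dB — the supra-threshold range of real high-pass
  masking series.  Replicates share `s_i` with independent noises of
  √2-higher RMS (half-trial averages).
* **Seeding**: one global seed fans out through independent child streams
  (warps / overall noise / replicate noise), so regeneration is
  bit-identical and subject subsets reproducible.

What the generator does *not* emulate: heavier-tailed and non-stationary
real EEG noise, trial-level artifacts, condition-dependent latency shifts
(pre-alignment is exercised on constructed shifts instead), and
template-shape variability across subjects (warps are the only individual
difference).  Passing tests therefore demonstrate correctness of the
machinery and the qualitative SNR/over-alignment phenomenology, not
performance guarantees on any particular recording system.

## Problem sizes and tolerances

The verification suites use 10 subjects, `K = 13`, 197-sample windows;
the SNR-degradation check pools 8 Δsnr conditions × 3 seeds and tests the
Spearman trend of mean warp accuracy (and of the deviation reduction)
across the sweep; the over-/under-alignment contrast compares
`noise_alignment` between a greedy (`psd`, `at`, λ=0) and a conservative
(`psdd`, `at`, λ=1) condition on replicates simulated at Δsnr = −15 dB
(per-response SNR ≈ −4 dB, inside the low end of the realistic range).
Oracle equivalences are held to: closed-form roughness penalty vs numeric
quadrature ≤ 1e−4 relative; optimizer loss ≤ brute-force grid minimum
+ 1e−3 on a 2-free-parameter problem; warp inversion round trip ≤ 2 grid
steps.  Noiseless warp recovery under the default conditions typically
yields mean accuracy 0.90–0.99; the residual error concentrates where the
template carries little energy (before wave I), which is an identifiability
property of the data, not of the implementation.

## Known limitations

Latency resolution is bounded by the sample grid and linear interpolation;
pre-alignment lags are integer samples by design.  The derivative criteria
use forward differences without smoothing, so they are the right choice
only for adequately low-passed inputs (the 2-kHz low-pass of the standard
pipeline).  Amplitude back-scaling to µV relies on the stored RMS factors
and is only as consistent as the pre-processing that produced them.
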