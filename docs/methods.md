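# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `rgcpipe`. It is written for users who want to know
what the numbers mean and what passing tests do and do not establish.

## The LN-Poisson generative model

Every simulated retinal ganglion cell is a linear–nonlinear cascade:

- **Temporal filter.** A difference of two Gaussians over a 500 ms causal
  window, sampled at the stimulus frame interval (16.7 ms at 60 Hz) with
  lag times at bin centers, and normalized to unit L2 norm. The first
  lobe sits at the cell's latency with width `width_factor × latency`;
  the opposing lobe trails it by 2.2 first-lobe widths at 1.6× the width,
  with relative amplitude equal to the biphasic index. ON cells have a
  positive first lobe, OFF cells a negative one.
- **Static nonlinearity.** A logistic gain
  `rate(g) = floor + amp·σ(k(g−m))` of the filter projection `g`,
  parameterized by (max_rate, midpoint m, steepness k, baseline) with the
  floor/amplitude pair solved so that `rate(0) = baseline` exactly: the
  baseline **is** the neutral rate, the firing maintained for stimuli
  orthogonal to the filter. Rates are clipped at zero. Under binary
  white noise the projection is approximately standard normal (unit
  filter norm, ±1 frames), which makes the midpoint directly comparable
  with estimates on the normalized-STA axis.
- **Spiking.** Per-frame Poisson counts with uniform jitter inside the
  frame — an exact inhomogeneous Poisson process for a frame-wise
  constant rate (the time-rescaling test against Exponential(1) passes
  exactly), rather than Bernoulli thinning, which would cap rates at one
  spike per frame and distort the high-rate awake regime. An absolute
  refractory period (default 2 ms) is enforced by deletion.
- **OFF-suppressive cells** are ON-filter cells with a high baseline
  (62 ± 32 Hz), a *negative* sigmoid midpoint and a saturation barely
  above baseline: their firing sits near saturation at rest, so light
  decrements suppress firing while increments barely raise it. This
  reproduces the negative ramp-fit amplitude with OFF-like phase that
  defines the class in the analysis.
- **Direction tuning.** A fraction of cells carries cosine tuning
  `1 + depth·cos(order·(θ − θ_pref))` (order 1 DS, order 2 OS) applied as
  a rate factor during grating epochs. Gratings are never rasterized:
  all grating analyses use only per-direction mean rates.

## Condition presets

The four presets pin their centers to the reported population statistics
of each regime; spreads use the printed dispersions where available and
conservative choices otherwise (baselines are lognormal to reproduce the
strong skew; bounded parameters use rejection-truncated normals).

| parameter (center)        | awake | isoflurane | FMM  | exvivo |
|---------------------------|-------|-----------|------|--------|
| baseline / neutral (Hz)   | 20    | 2         | 2    | 2      |
| first-peak latency (ms)   | 47    | 77        | 87   | 64     |
| sigmoid midpoint          | 0.8   | 1.1       | 1.1  | 1.6    |
| evoked lift = dyn. range (Hz) | 56 | 26       | 29   | 12     |
| biphasic index            | 0.70  | 0.30      | 0.25 | 0.20   |
| lobe width factor         | 0.275 | 0.30      | 0.30 | 0.325  |
| OFF-suppressive fraction  | 0.13  | 0.006     | 0.01 | 0      |
| tuned fraction            | 0.10  | 0.25      | 0.25 | 0.20   |

Two deliberate calibrations:

- The **evoked lift** (sigmoid saturation above baseline) equals the
  reported gain-function dynamic range of each condition. This is the
  printed statistic that governs evoked amplitudes, and it is what makes
  the coding-model contrasts (rate-code information, decoding
  saturation) point the right way. A consequence is that the four
  printed statistics (baseline, midpoint, dynamic range, white-noise
  mean rate) are not mutually satisfiable under a single logistic gain:
  with the first three pinned, the awake flicker mean emerges at ~34 Hz
  (reported 34.9) but isoflurane/FMM/ex vivo land near 8/8.5/4 Hz versus
  the reported 13.0/10.9/6.9 Hz. The shortfall is a model limitation,
  not a data-fitting error.
- The **filter-shape pair** (biphasic index, width factor) per condition
  is calibrated against the reported spectral peak frequencies jointly
  with the latencies (targets 8.5/4.6/3.7/4.3 Hz; the emulated
  populations land at roughly 7.6/4.2/3.5/3.8 Hz). The awake preset is
  therefore strongly biphasic (transient), which also gives awake cells
  rebound responses to wrong-sign contrast steps.

The ex-vivo preset has no reported ramp-protocol baseline (that protocol
was not run ex vivo); 2 Hz was chosen to match the anesthetized regime,
consistent with its low reported neutral rates.

## Estimators and numerical choices

- **Quality index.** Population (divide-by-N) variances in both the
  numerator and denominator. The denominator is the mean over trials of
  each trial's variance over time, which bounds the index by ~1 for
  repeatable responses; conventions: 0/0 → 0, positive/0 → +∞.
- **Curve fits** (even-power sine, sigmoid-envelope ramp, DoG, gain
  sigmoid, saturation curve) use bounded trust-region least squares with
  multi-start initialization (phase grid × amplitude sign; for the ramp
  also the envelope midpoint). The sine exponent is chosen by scanning
  q = 2n, n = 1..10, refitting continuous parameters per n and keeping
  the best explained variance. Phases are wrapped to [−π, π); with the
  convention `contrast(t) = sin(2πht)` a response peaking at the
  brightest stimulus gives φ = −π/2, at the darkest +π/2.
- **Ramp-fit identifiability.** At the awake parameter regime (baseline
  20 Hz, amplitude 45 Hz, midpoint 7 s of a 10 s ramp, steepness
  0.44 /s, 10 Poisson trials) the envelope does not saturate inside the
  window and the likelihood has a flat amplitude–midpoint–steepness
  ridge: the midpoint's intrinsic uncertainty is ~1–1.5 s regardless of
  fitting strategy (consistent with the wide reported midpoint
  dispersion). Recovery to within 5% of the ramp duration holds in the
  median across the three in vivo regimes, not for the awake corner
  alone.
- **STA.** Spike-count-weighted mean of the preceding stimulus windows
  (multiple spikes per frame count multiply), with per-bin two-sided
  p-values against Normal(0, 1/C). Cells are dropped when no bin reaches
  p ≤ 1e−18 or the DoG fit has R² < 0.8. The first-peak latency is the
  earliest extremum of the fitted curve exceeding 20% of the global
  extremum on a 0.5 ms grid; the spectral peak is the argmax of the
  fitted curve's power spectrum zero-padded to 4096 samples, always
  excluding DC (a 0 Hz "peak" is meaningless for the statistic).
- **Gain function.** Projection histogram at bin width 0.1; the rate per
  bin is spike count / prior count / frame interval, which conserves
  total spike mass exactly. The sigmoid fit weights bins by √(prior)
  and excludes bins with fewer than 20 stimulus samples (their rate
  estimates are sampling noise); the binned curve itself keeps all bins.
  Because the estimated STA axis correlates ρ < 1 with the true filter,
  the measured transition sits at midpoint/ρ; `midpoint_debiased`
  multiplies by ρ̂ estimated from the STA's own noise level (per-tap
  variance 1/C). The raw midpoint keeps the conventional scale; the
  debiased one is for parameter recovery.
- **Filter-shape classes.** PCA on the normalized STAs; the two leading
  components are sign-oriented against canonical monophasic-OFF and
  biphasic-OFF kernels, and the quadrant→label map is calibrated by
  where the four canonical kernels land in the oriented biplot. With
  strongly correlated mono/bi shape axes the leading PCs are mixtures
  (sum and difference) of the two shapes; the calibrated map keeps
  labels attached to the right archetypes and reduces to the fixed
  quadrant map when the PCs align with the pure shapes.
- **Single-spike information.** Discretized with 0·log 0 = 0, computed on
  a bin-size grid (default 2, 4, 8, 16, 33 ms) and extrapolated to
  Δt → 0 by an OLS line over the most linear contiguous triple
  (maximal R²), falling back to the full grid when degenerate. The
  finite-data bias of the PSTH estimator (≈ log₂e/(2·K·r̄·Δt) for K
  trials) is hyperbolic rather than linear in Δt, so the extrapolation
  reduces but does not remove it: stimulus-unlocked cells retain a small
  positive intercept, and absolute bits/spike values from few-trial
  PSTHs are upward-biased while cross-condition orderings are preserved.
  For synthetic sessions the pipeline uses a repeated-presentation PSTH
  (10 repeats by default); single-pass mode is available but
  bias-dominated at realistic firing rates.
- **Coding models.** Steps of ±0.1..±1.0 contrast (20 levels, equal
  priors), 1 s duration on a 1 ms grid; the step projection is the
  filter's running sum linearly interpolated between frames. Rate-code
  conditionals are Gaussians (sd = 2.5% of the peak, 1e−3 Hz floor)
  integrated on per-level local grids (±8 sd) so that peaks spanning
  decades are resolved equally. Latency-code thresholds are drawn
  (10 ± 2.5% of baseline, 10,000 seeded draws, 0.5 Hz floor for silent
  baselines) against the running maximum of |rate − baseline| — absolute
  deviation, so suppression can trigger detection; non-crossing draws
  form a discrete infinite-latency symbol. Latencies are histogrammed at
  2 ms.
- **Decoder.** Ordinary least squares (minimum-norm on rank deficiency)
  on causal lagged counts (20 bins of 16.7 ms; the response follows the
  stimulus), 10-fold cross-validation over contiguous time blocks, R on
  the concatenated held-out predictions.
- **Behavior cross-correlation.** Correlations are normalized per lag by
  the overlap length and restricted to |lag| ≤ T/4; the significance
  statistic is variance-equalized (z = ρ·√overlap). The default p
  compares the in-window peak against individual outside-lag values
  (anti-conservative for a maximum statistic); `null="blockmax"`
  compares it against outside block maxima of matching window width,
  which is calibrated (approximately uniform under independence).

## What the synthetic data does and does not establish

The generator reproduces the statistical structure the analyses assume:
stationary LN responses to full-field stimuli, Poisson variability,
condition-dependent baselines, kinetics, gain, and tuning, optional
shared gain noise and behavior couplings. Passing recovery tests shows
the estimators are correct and well-conditioned at realistic signal
levels. It does not show robustness to what real recordings add:
nonstationarity (adaptation, state changes), non-Poisson variability,
spike-sorting contamination, eye movements, spatial structure, or
cell-to-cell diversity beyond the preset distributions. Cross-condition
contrasts on synthetic populations are direction-only statements about
the presets, not reproductions of the recorded effect sizes; in
particular the reported information rates and decoding saturation
constants are not recoverable at this scale and are treated as ordering
targets only.

## Problem sizes

Default validation scales, chosen to characterize the estimators well on
a single CPU: 300 s of 60 Hz flicker per cell, 50 cells per condition
for recovery studies, 10 trials for trial-based protocols, 150 s
sessions of 24 cells for decoding, and 1000 bootstrap repetitions for
selectivity. All randomness flows from explicit integer seeds; rerunning
any stage with the same seed is bit-reproducible.
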