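# rgcpipe

Analysis pipeline for retinal ganglion cell (RGC) spike trains recorded
under full-field visual stimulation, aimed at comparing retinal coding
across recording regimes — awake, anesthetized (isoflurane or
fentanyl/medetomidine/midazolam, "FMM"), and ex vivo. It implements the
complete chain from raw spike times and a stimulus contrast trace to
per-cell functional characterization and population-level decoding,
together with a linear–nonlinear (LN) Poisson simulator whose condition
presets emulate the four regimes, so every stage can be validated by
parameter recovery without recorded data.

## What it computes

**Response indices.** Trial-to-trial reliability (quality index)
`SNR = var_t[⟨r(t)⟩] / ⟨var_t[r(t)]⟩` with a 0.15 threshold for reliably
responsive cells; the polarity index `(r_ON − r_OFF)/(r_ON + r_OFF)` with
±0.25 class boundaries; direction/orientation selectivity
`‖Σ_k e^{−iαω_k} r_k‖ / Σ_k r_k` (α = 1 for DS, 2 for OS) with a
label-shuffling bootstrap (index > 0.15, p < 0.2).

**Flicker curve fits.** Responses to sinusoidal flicker at frequency *h*
are fitted with an even power of sine,
`s(t) = A·sin^q(πht − φ/2) + B`, and ramped-contrast responses with the
same oscillation under a sigmoid envelope
`S(t) = A/(1+e^{−λ(t−t0)})·sin^q(πht − φ/2) + B`, from which contrast
sensitivity (evoked rate at 10% contrast, midpoint slope |Aλ/4|) and the
OFF-suppressive class (significantly negative amplitude) are derived.
Fit quality is the explained variance R²; k-means on the circle splits
response phases into ON-like and OFF-like clusters.

**Reverse correlation.** The spike-triggered average (STA) of a binary
random flicker over a 500 ms window, per-bin significance against the
Normal(0, 1/C) null, a difference-of-Gaussians fit giving the first-peak
latency and spectral peak frequency, the static nonlinear gain function
`P(response|stimulus) = N(stimulus|response)/N(stimulus)/Δt` on the
L2-normalized STA axis with a sigmoid fit (neutral rate, midpoint,
dynamic range), and PCA-based classification of filter shapes into
mono-/biphasic ON/OFF quadrants.

**Information and coding models.** Single-spike information
`I_spike = (1/T)∫dt (r/r̄)log₂(r/r̄)` with linear extrapolation of the bin
size Δt → 0, and the information rate `r̄·I_spike`; LN step-response
simulation at 20 contrast levels with stimulus information (Eq. of the
form `I = Σ_s ∫dx p(s) p(x|s) log₂[p(x|s)/p(x)]`) computed for a peak-rate
code and a first-crossing latency code (with an infinite-latency atom).

**Population decoding.** The optimal linear decoder of the flicker
stimulus from binned population spike counts (333 ms window, 16.7 ms
bins), 10-fold cross-validated Pearson R, and the saturation fit
`f(n) = 1 − (1−a)e^{−(n−1)/b}` describing how performance grows with the
number of cells.

**Photometry.** Photon flux at the retina
`I_λ = T_λ·F_λ·A_pupil/A_retina` with `F_λ = E_λ/(hc/λ)`, and
photoisomerization rates `a·Σ_λ I_λ s_λ` per photoreceptor class, with
the mouse two-LED (365/454 nm) setup constants as defaults.

## Worked example

```python
import numpy as np
from rgcpipe import protocols, synthdata
from rgcpipe.reverse_correlation import compute_sta, fit_kinetics, estimate_gain_function
from rgcpipe.information import extrapolate_information

stim = protocols.make_random_flicker(60.0, 300.0, seed=1)        # 5 min binary flicker
preset = synthdata.make_condition_preset("awake")
neuron = synthdata.sample_ln_neuron(preset, seed=2)              # ground-truth LN cell
train = synthdata.simulate_spike_train(neuron, stim, seed=1)

filt = compute_sta(train, stim)                                  # 500 ms STA
kin = fit_kinetics(filt)
gain = estimate_gain_function(train, stim, filt)
info = extrapolate_information(
    synthdata.simulate_spike_train(neuron, stim, n_trials=10, seed=2)
)
print(f"mean rate      {train.mean_rate():5.1f} Hz")
print(f"peak latency   {kin.peak_latency_ms:5.1f} ms")
print(f"neutral rate   {gain.neutral_rate_hz:5.1f} Hz")
print(f"bits per spike {info.bits_per_spike:5.2f}")
```

prints

```
mean rate       37.3 Hz
peak latency    46.5 ms
neutral rate    25.3 Hz
bits per spike  0.44
```

— an awake-like cell: high sustained firing, fast kinetics (first STA peak
near 45 ms), a high neutral rate (the firing maintained for stimuli
orthogonal to the cell's filter), and little information per spike, the
dense-coding signature of the awake retina. Sampling from the
`"exvivo"` preset instead yields sparse low-baseline cells with slower
filters and several times more bits per spike.

The command line mirrors the library:

```bash
rgcpipe simulate --condition awake --n-cells 30 --seed 1 --out-dir session/
rgcpipe analyze  --condition awake --n-cells 30 --seed 1 --out-dir out/
rgcpipe decode   --condition exvivo --n-cells 20
rgcpipe photometry
rgcpipe report   --conditions awake,exvivo --n-cells 20
```

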