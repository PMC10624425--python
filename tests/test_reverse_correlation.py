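"""STA estimation, DoG kinetics, gain function, and PCA shape classes."""

import numpy as np
import pytest

from rgcpipe import protocols, synthdata
from rgcpipe.reverse_correlation import (
    TemporalFilter,
    classify_filter_shapes,
    compute_sta,
    estimate_gain_function,
    fit_kinetics,
)
from rgcpipe.synthdata import GainSigmoid, LNNeuron, dog_filter, simulate_spike_train

from conftest import make_poisson_train


def ln_neuron(latency=0.047, biphasic=0.4, sign=1, max_rate=90.0, midpoint=0.8,
              steepness=5.0, baseline=20.0):
    taps, lags = dog_filter(60.0, latency, biphasic, sign=sign)
    return LNNeuron(
        filter=taps, lags_s=lags,
        gain=GainSigmoid(max_rate, midpoint, steepness, baseline),
        polarity="ON" if sign > 0 else "OFF", refractory_s=0.0,
    )


def filter_from_taps(taps, frame_rate=60.0, n_spikes=10_000):
    """Wrap a noiseless kernel as a TemporalFilter (for kinetics tests)."""
    lags = (np.arange(taps.size) + 0.5) / frame_rate
    return TemporalFilter(
        sta_raw=taps, sta_norm=taps / np.linalg.norm(taps), lags_s=lags,
        n_spikes=n_spikes, p_values=np.zeros(taps.size), frame_rate=frame_rate,
    )


class TestComputeSTA:
    def test_null_calibration_poisson_cell(self, flicker_300s):
        train = make_poisson_train(25.0, 300.0, seed=0)
        filt = compute_sta(train, flicker_300s)
        frac = np.mean(filt.p_values < 0.05)
        # binomial 3-sigma band around 0.05 with 30 bins
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 30)
        assert not filt.significant

    def test_ln_cell_filter_recovery(self, flicker_300s):
        neuron = ln_neuron()
        train = simulate_spike_train(neuron, flicker_300s, seed=8)
        filt = compute_sta(train, flicker_300s)
        assert np.corrcoef(filt.sta_norm, neuron.filter)[0, 1] > 0.9
        assert filt.significant

    def test_insufficient_spikes(self, flicker_300s):
        train = make_poisson_train(0.1, 300.0, seed=1)
        with pytest.raises(ValueError):
            compute_sta(train, flicker_300s)

    def test_recovery_improves_with_duration(self):
        neuron = ln_neuron(max_rate=40.0, baseline=10.0)
        corrs = []
        for dur in (75.0, 150.0, 300.0):
            stim = protocols.make_random_flicker(60.0, dur, seed=5)
            cs = []
            for seed in range(4):
                train = simulate_spike_train(neuron, stim, seed=seed)
                cs.append(np.corrcoef(compute_sta(train, stim).sta_norm, neuron.filter)[0, 1])
            corrs.append(np.median(cs))
        assert corrs[2] >= corrs[0]


class TestKinetics:
    def test_dog_generated_latency_recovery(self):
        taps, _ = dog_filter(60.0, 0.047, 0.4)
        kin = fit_kinetics(filter_from_taps(taps))
        truth = 1e3 * synthdata.first_extremum_lag(
            np.arange(0, 0.5, 5e-4), synthdata.dog_curve(np.arange(0, 0.5, 5e-4), 0.047, 0.4)
        )
        assert kin.r2 > 0.99
        assert kin.peak_latency_ms == pytest.approx(truth, abs=1.0)

    def test_single_gaussian_latency(self):
        lags = (np.arange(30) + 0.5) / 60.0
        taps = np.exp(-0.5 * ((lags - 0.060) / 0.015) ** 2)
        kin = fit_kinetics(filter_from_taps(taps))
        assert kin.peak_latency_ms == pytest.approx(60.0, abs=1.0)

    def test_power_spectrum_time_reversal_invariance(self):
        taps, _ = dog_filter(60.0, 0.047, 0.6)
        a = fit_kinetics(filter_from_taps(taps))
        b = fit_kinetics(filter_from_taps(taps[::-1]))
        # the Fourier modulus ignores time reversal
        assert a.peak_frequency_hz == pytest.approx(b.peak_frequency_hz, abs=0.3)

    def test_biphasic_filter_has_positive_peak_frequency(self):
        taps, _ = dog_filter(60.0, 0.047, 0.8)
        kin = fit_kinetics(filter_from_taps(taps))
        assert kin.peak_frequency_hz > 2.0


class TestGainFunction:
    def test_mass_conservation(self, flicker_300s):
        neuron = ln_neuron()
        train = simulate_spike_train(neuron, flicker_300s, seed=2)
        filt = compute_sta(train, flicker_300s)
        gf = estimate_gain_function(train, flicker_300s, filt)
        pop = gf.prior_counts > 0
        recovered = np.sum(gf.rate_hz[pop] * gf.prior_counts[pop] * gf.dt_s)
        used = gf.spike_counts.sum()
        assert recovered == pytest.approx(used, rel=1e-9)

    def test_stimulus_independent_cell_is_flat(self, flicker_300s):
        train = make_poisson_train(20.0, 300.0, seed=3)
        filt = compute_sta(train, flicker_300s)
        gf = estimate_gain_function(train, flicker_300s, filt)
        well = gf.prior_counts >= 50
        assert np.nanmean(gf.rate_hz[well]) == pytest.approx(20.0, abs=2.0)
        # no genuine stimulus dependence: fitted span stays well below the rate
        assert gf.dynamic_range_hz < 0.5 * 20.0

    def test_midpoint_recovery(self, flicker_300s):
        neuron = ln_neuron(midpoint=0.8)
        train = simulate_spike_train(neuron, flicker_300s, seed=4)
        filt = compute_sta(train, flicker_300s)
        gf = estimate_gain_function(train, flicker_300s, filt)
        sign = np.sign(np.corrcoef(filt.sta_norm, neuron.filter)[0, 1])
        assert sign * gf.midpoint_debiased == pytest.approx(0.8, abs=0.1)

    def test_neutral_rate_matches_generative_baseline(self, flicker_300s):
        neuron = ln_neuron(baseline=20.0)
        train = simulate_spike_train(neuron, flicker_300s, seed=6)
        filt = compute_sta(train, flicker_300s)
        gf = estimate_gain_function(train, flicker_300s, filt)
        assert gf.neutral_rate_hz == pytest.approx(20.0, abs=3.0)

    def test_too_few_bins_rejected(self, flicker_300s):
        neuron = ln_neuron()
        train = simulate_spike_train(neuron, flicker_300s, seed=2)
        filt = compute_sta(train, flicker_300s)
        tiny = protocols.make_random_flicker(60.0, 0.55, seed=0)  # 3 usable windows
        tiny_train = synthdata.SpikeTrain("u", np.linspace(0.5, 0.54, 5), 0.55)
        with pytest.raises(ValueError):
            estimate_gain_function(tiny_train, tiny, filt)


def template_population(rng, n_per=25, noise=0.06):
    """Four DoG archetypes (mono/bi x ON/OFF) with jitter and noise."""
    filters, labels = [], []
    specs = [
        ("mono-ON", +1, 0.15), ("mono-OFF", -1, 0.15),
        ("bi-ON", +1, 0.85), ("bi-OFF", -1, 0.85),
    ]
    for label, sign, biph in specs:
        for _ in range(n_per):
            lat = rng.normal(0.055, 0.006)
            taps, _ = dog_filter(60.0, lat, biph + rng.normal(0, 0.05), sign=sign)
            f = taps + noise * rng.standard_normal(taps.size)
            filters.append(f / np.linalg.norm(f))
            labels.append(label)
    return np.vstack(filters), labels


class TestShapeClassification:
    def test_recovers_generating_archetypes(self):
        rng = np.random.default_rng(0)
        filters, labels = template_population(rng)
        shapes = classify_filter_shapes(filters)
        agreement = np.mean([s.label == l for s, l in zip(shapes, labels)])
        assert agreement >= 0.95

    def test_negation_swaps_on_off(self):
        rng = np.random.default_rng(1)
        filters, _ = template_population(rng)
        shapes = classify_filter_shapes(filters)
        swapped = classify_filter_shapes(-filters)
        swap = {"mono-ON": "mono-OFF", "mono-OFF": "mono-ON",
                "bi-ON": "bi-OFF", "bi-OFF": "bi-ON"}
        agree = np.mean([sw.label == swap[s.label] for s, sw in zip(shapes, swapped)])
        assert agree >= 0.95

    def test_variance_explained_band(self, awake_preset, flicker_300s):
        filters = []
        for i in range(40):
            neuron = synthdata.sample_ln_neuron(awake_preset, seed=i)
            train = simulate_spike_train(neuron, flicker_300s, seed=300 + i)
            try:
                filters.append(compute_sta(train, flicker_300s).sta_norm)
            except ValueError:
                continue
        shapes = classify_filter_shapes(np.vstack(filters))
        assert 0.5 <= shapes[0].variance_explained <= 0.99

    def test_identical_filters_refused(self):
        taps, _ = dog_filter(60.0, 0.05, 0.3)
        with pytest.raises(ValueError):
            classify_filter_shapes(np.tile(taps, (12, 1)))
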