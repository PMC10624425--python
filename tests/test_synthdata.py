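"""LN-Poisson simulator: presets, filters, and spiking statistics."""

import numpy as np
import pytest
from scipy import stats

from rgcpipe import protocols, synthdata
from rgcpipe.synthdata import (
    GainSigmoid,
    LNNeuron,
    dog_filter,
    make_condition_preset,
    sample_ln_neuron,
    simulate_population_session,
    simulate_spike_train,
)

from conftest import make_poisson_train  # noqa: F401  (helper reused below)


class TestPresets:
    def test_centers_match_population_statistics(self):
        awake = make_condition_preset("awake")
        assert awake.baseline_hz.center == 20.0
        assert awake.latency_ms.center == 47.0
        assert make_condition_preset("isoflurane").latency_ms.center == 77.0
        assert make_condition_preset("FMM").latency_ms.center == 87.0
        assert make_condition_preset("exvivo").latency_ms.center == 64.0

    def test_unknown_condition(self):
        with pytest.raises(ValueError):
            make_condition_preset("ketamine")

    def test_preset_determinism(self):
        a = make_condition_preset("awake")
        b = make_condition_preset("awake")
        assert a == b

    def test_mean_latency_over_draws(self, awake_preset):
        lats = [
            sample_ln_neuron(awake_preset, seed=i).first_peak_latency_s() * 1e3
            for i in range(200)
        ]
        assert np.mean(lats) == pytest.approx(47.0, abs=4.0)


class TestFilters:
    def test_unit_l2_norm(self, awake_cell):
        assert np.linalg.norm(awake_cell.filter) == pytest.approx(1.0, abs=1e-9)

    def test_monophasic_degenerate(self):
        taps, _ = dog_filter(60.0, 0.05, biphasic_index=0.0)
        dominant = np.abs(taps[taps > 0]).sum()
        assert dominant >= 0.9 * np.abs(taps).sum()

    def test_off_sign(self):
        on, lags = dog_filter(60.0, 0.05, 0.3, sign=+1)
        off, _ = dog_filter(60.0, 0.05, 0.3, sign=-1)
        np.testing.assert_allclose(on, -off)
        # first lobe sits at the requested latency
        assert lags[np.argmax(np.abs(on))] == pytest.approx(0.05, abs=1.0 / 60)


class TestGainSigmoid:
    def test_neutral_rate_is_baseline(self):
        g = GainSigmoid(80.0, 0.8, 5.0, 20.0)
        assert g(0.0) == pytest.approx(20.0, abs=1e-9)

    def test_flat_when_max_equals_baseline(self):
        g = GainSigmoid(20.0, 0.8, 5.0, 20.0)
        x = np.linspace(-3, 3, 50)
        np.testing.assert_allclose(g(x), 20.0, atol=1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            GainSigmoid(10.0, 0.5, 5.0, 20.0)  # max below baseline


class TestSpiking:
    def test_zero_contrast_gives_baseline_rate(self):
        taps, lags = dog_filter(60.0, 0.05, 0.3)
        neuron = LNNeuron(
            filter=taps, lags_s=lags,
            gain=GainSigmoid(80.0, 0.8, 5.0, 20.0),
            polarity="ON", refractory_s=0.0,
        )
        n_frames = 60 * 100
        stim = protocols.StimulusTrace(
            np.arange(n_frames) / 60.0, np.zeros(n_frames), 60.0,
            [protocols.Segment("gray", 0, 0.0, n_frames / 60.0)],
        )
        train = simulate_spike_train(neuron, stim, seed=5)
        tol = 3.0 * np.sqrt(20.0 / stim.duration)
        assert train.mean_rate() == pytest.approx(20.0, abs=tol)

    def test_reproducible_from_seed(self, awake_cell, flicker_300s):
        a = simulate_spike_train(awake_cell, flicker_300s, seed=11)
        b = simulate_spike_train(awake_cell, flicker_300s, seed=11)
        np.testing.assert_array_equal(a.times, b.times)

    def test_refractory_enforced(self, awake_cell, flicker_300s):
        train = simulate_spike_train(awake_cell, flicker_300s, seed=3)
        assert awake_cell.refractory_s > 0
        assert np.min(np.diff(train.times)) >= awake_cell.refractory_s

    def test_time_rescaling_exponential(self, flicker_300s):
        """With no refractory period, rescaled ISIs are Exponential(1)."""
        taps, lags = dog_filter(60.0, 0.047, 0.4)
        neuron = LNNeuron(
            filter=taps, lags_s=lags,
            gain=GainSigmoid(90.0, 0.8, 5.0, 20.0),
            polarity="ON", refractory_s=0.0,
        )
        train = simulate_spike_train(neuron, flicker_300s, seed=21)
        lam = synthdata.rate_trace(neuron, flicker_300s)
        dt = flicker_300s.frame_interval
        cum = np.concatenate([[0.0], np.cumsum(lam * dt)])
        frames = np.minimum((train.times / dt).astype(int), lam.size - 1)
        frac = train.times / dt - frames
        rescaled = cum[frames] + frac * lam[frames] * dt
        isis = np.diff(rescaled)
        p = stats.kstest(isis, "expon").pvalue
        assert p > 0.01

    def test_mean_rate_near_condition_target(self, awake_preset, flicker_300s):
        rates = [
            simulate_spike_train(
                sample_ln_neuron(awake_preset, seed=i), flicker_300s, seed=500 + i
            ).mean_rate()
            for i in range(30)
        ]
        # white-noise population mean is calibrated to the awake target
        assert np.mean(rates) == pytest.approx(
            awake_preset.mean_rate_target_hz, rel=0.25
        )


class TestDirectionTrials:
    def test_tuned_cell_prefers_its_direction(self, awake_preset):
        neuron = sample_ln_neuron(awake_preset, seed=0)
        tuned = LNNeuron(
            filter=neuron.filter, lags_s=neuron.lags_s, gain=neuron.gain,
            polarity=neuron.polarity,
            tuning=synthdata.DirectionTuning(np.pi / 2, 0.8, order=1),
            refractory_s=0.0,
        )
        proto = protocols.make_direction_protocol(n_trials=20, trial_duration=2.0)
        rates = synthdata.simulate_direction_trials(tuned, proto, seed=1)
        mean_by_dir = rates.mean(axis=0)
        assert proto.directions[int(np.argmax(mean_by_dir))] == pytest.approx(np.pi / 2)


class TestPopulationSession:
    def test_independent_thinning_has_no_noise_correlation(self):
        stim = protocols.make_random_flicker(60.0, 150.0, seed=2)
        preset = make_condition_preset("awake")
        session = simulate_population_session(
            8, stim, preset, noise_corr=0.0, seed=4, n_trials=2
        )
        bin_s, n_bins = 0.1, int(150.0 / 0.1)
        edges = np.arange(n_bins + 1) * bin_s
        corrected = []
        counts = []
        for tr in session.trains:
            per_trial = [np.histogram(t, bins=edges)[0] for t in tr.fold_trials()]
            counts.append(per_trial)
        for i in range(8):
            for j in range(i + 1, 8):
                same = np.corrcoef(counts[i][0], counts[j][0])[0, 1]
                cross = np.corrcoef(counts[i][0], counts[j][1])[0, 1]
                corrected.append(same - cross)  # stimulus-shuffle correction
        sem = np.std(corrected) / np.sqrt(len(corrected))
        assert abs(np.mean(corrected)) < 3 * sem + 0.01

    def test_shared_gain_noise_induces_correlations(self):
        stim = protocols.make_random_flicker(60.0, 150.0, seed=2)
        preset = make_condition_preset("awake")
        kwargs = dict(n_trials=2, seed=4)
        quiet = simulate_population_session(6, stim, preset, noise_corr=0.0, **kwargs)
        noisy = simulate_population_session(6, stim, preset, noise_corr=0.5, **kwargs)

        def mean_corrected_corr(session):
            bin_s = 0.1
            edges = np.arange(int(150.0 / bin_s) + 1) * bin_s
            counts = [
                [np.histogram(t, bins=edges)[0] for t in tr.fold_trials()]
                for tr in session.trains
            ]
            vals = []
            for i in range(len(counts)):
                for j in range(i + 1, len(counts)):
                    same = np.corrcoef(counts[i][0], counts[j][0])[0, 1]
                    cross = np.corrcoef(counts[i][0], counts[j][1])[0, 1]
                    vals.append(same - cross)
            return np.mean(vals)

        assert mean_corrected_corr(noisy) > mean_corrected_corr(quiet) + 0.02

    def test_single_cell_session_decodes(self):
        from rgcpipe import population_decoding

        stim = protocols.make_random_flicker(60.0, 100.0, seed=3)
        preset = make_condition_preset("awake")
        session = simulate_population_session(1, stim, preset, seed=0)
        r = population_decoding.evaluate_decoding_cv(session)
        assert np.isfinite(r)

    def test_session_reproducibility(self, flicker_300s, awake_preset):
        a = simulate_population_session(3, flicker_300s, awake_preset, seed=9)
        b = simulate_population_session(3, flicker_300s, awake_preset, seed=9)
        for ta, tb in zip(a.trains, b.trains):
            np.testing.assert_array_equal(ta.times, tb.times)
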