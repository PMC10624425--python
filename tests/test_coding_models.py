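"""Step-response simulation and rate/latency coding information."""

import numpy as np
import pytest
from scipy.integrate import quad

from rgcpipe.coding_models import (
    DEFAULT_CONTRAST_LEVELS,
    StepResponseSet,
    discrete_stimulus_information,
    latency_code_information,
    rate_code_information,
    simulate_step_responses,
)
from rgcpipe.synthdata import GainSigmoid, dog_filter


def ln_pair(sign=1, midpoint=0.5, steepness=5.0, max_rate=80.0, baseline=10.0,
            biphasic=0.3):
    taps, _ = dog_filter(60.0, 0.05, biphasic, sign=sign)
    return taps, GainSigmoid(max_rate, midpoint, steepness, baseline)


class TestStepResponses:
    def test_zero_contrast_step_stays_at_baseline(self):
        taps, gain = ln_pair()
        out = simulate_step_responses(taps, gain, levels=[0.0])
        np.testing.assert_allclose(out.traces[0], out.baseline_hz, atol=1e-9)
        assert out.peak_rates[0] == pytest.approx(out.baseline_hz)

    def test_locally_linear_doubling(self):
        # around midpoint 0 the sigmoid is locally linear, so doubling a
        # small step doubles the evoked peak
        taps, _ = dog_filter(60.0, 0.05, 0.3)
        gain = GainSigmoid(80.0, 0.0, 1.0, 40.0)
        out = simulate_step_responses(taps, gain, levels=[0.05, 0.10])
        d1 = out.peak_rates[0] - out.baseline_hz
        d2 = out.peak_rates[1] - out.baseline_hz
        assert d2 == pytest.approx(2.0 * d1, rel=0.01)

    def test_off_cell_prefers_decrements(self):
        taps, gain = ln_pair(sign=-1)
        out = simulate_step_responses(taps, gain, levels=[+0.5, -0.5])
        assert out.peak_rates[1] > out.peak_rates[0]

    def test_level_count_and_priors(self):
        taps, gain = ln_pair()
        out = simulate_step_responses(taps, gain)
        assert len(out.levels) == 20
        assert len(set(out.levels)) == 20

    def test_missing_nonlinearity_rejected(self):
        taps, _ = ln_pair()
        with pytest.raises(ValueError):
            simulate_step_responses(taps, gain=None)


def mixture_info_oracle(means, sds, p_s=None):
    """High-resolution quadrature oracle for Gaussian-conditional info."""
    means, sds = np.asarray(means, float), np.asarray(sds, float)
    n = means.size
    p_s = np.full(n, 1.0 / n) if p_s is None else np.asarray(p_s)

    def pdf(x, m, s):
        return np.exp(-0.5 * ((x - m) / s) ** 2) / (np.sqrt(2 * np.pi) * s)

    total = 0.0
    for i in range(n):
        def integrand(x, i=i):
            pi = pdf(x, means[i], sds[i])
            if pi <= 0:
                return 0.0
            mix = np.sum(p_s * pdf(x, means, sds))
            return pi * np.log2(pi / mix)

        lo, hi = means[i] - 9 * sds[i], means[i] + 9 * sds[i]
        val, _ = quad(integrand, lo, hi, limit=200)
        total += p_s[i] * val
    return total


class TestStimulusInformation:
    def test_identical_conditionals_zero_bits(self):
        x = np.linspace(-5, 5, 801)
        dx = x[1] - x[0]
        d = np.exp(-0.5 * x**2) / np.sqrt(2 * np.pi)
        d = d / (d.sum() * dx)
        dens = np.tile(d, (20, 1))
        assert discrete_stimulus_information(dens, dx) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_gaussians_one_bit(self):
        x = np.linspace(-10, 110, 24001)
        dx = x[1] - x[0]
        dens = np.stack([
            np.exp(-0.5 * (x - 0.0) ** 2) / np.sqrt(2 * np.pi),
            np.exp(-0.5 * (x - 100.0) ** 2) / np.sqrt(2 * np.pi),
        ])
        dens = dens / (dens.sum(axis=1, keepdims=True) * dx)
        assert discrete_stimulus_information(dens, dx) == pytest.approx(1.0, abs=1e-6)

    def test_twenty_disjoint_symbols(self):
        # 20 non-overlapping unit-mass histograms -> log2(20) bits
        dens = np.eye(20)
        assert discrete_stimulus_information(dens, 1.0) == pytest.approx(
            np.log2(20), abs=1e-12
        )

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            discrete_stimulus_information(np.full((3, 4), 0.1), 1.0)

    def test_matches_quadrature_oracle_on_random_mixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            means = rng.uniform(0, 30, size=6)
            sds = rng.uniform(0.5, 3.0, size=6)
            x = np.linspace(means.min() - 10 * sds.max(), means.max() + 10 * sds.max(), 8001)
            dx = x[1] - x[0]
            dens = np.exp(-0.5 * ((x[None] - means[:, None]) / sds[:, None]) ** 2) / (
                np.sqrt(2 * np.pi) * sds[:, None]
            )
            dens = dens / (dens.sum(axis=1, keepdims=True) * dx)
            mine = discrete_stimulus_information(dens, dx)
            assert mine == pytest.approx(mixture_info_oracle(means, sds), abs=1e-4)


class TestRateCode:
    def test_identical_peaks_zero_bits(self):
        resp = StepResponseSet(
            tuple(DEFAULT_CONTRAST_LEVELS),
            np.linspace(0, 1, 100),
            np.full((20, 100), 30.0),
            30.0,
        )
        assert rate_code_information(resp).bits == pytest.approx(0.0, abs=1e-9)

    def test_separable_peaks_reach_log2_20(self):
        peaks = 10.0 * 1.6 ** np.arange(20)  # geometric: +-3 sd bands disjoint
        traces = np.tile(peaks[:, None], (1, 50))
        resp = StepResponseSet(
            tuple(DEFAULT_CONTRAST_LEVELS), np.linspace(0, 1, 50), traces, 5.0
        )
        assert rate_code_information(resp).bits == pytest.approx(np.log2(20), abs=0.01)

    def test_relabeling_invariance(self):
        taps, gain = ln_pair()
        resp = simulate_step_responses(taps, gain)
        perm = np.random.default_rng(0).permutation(20)
        shuffled = StepResponseSet(
            tuple(np.asarray(resp.levels)[perm]), resp.time_s,
            resp.traces[perm], resp.baseline_hz,
        )
        assert rate_code_information(shuffled).bits == pytest.approx(
            rate_code_information(resp).bits, abs=1e-9
        )


class TestLatencyCode:
    def test_flat_traces_all_mass_on_atom(self):
        resp = StepResponseSet(
            tuple(DEFAULT_CONTRAST_LEVELS),
            np.linspace(0, 1, 200),
            np.full((20, 200), 25.0),
            25.0,
        )
        info = latency_code_information(resp, seed=0)
        np.testing.assert_allclose(info.atom_mass, 1.0)
        assert info.bits == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_crossing_times_reach_log2_20(self):
        t = np.linspace(0, 1, 1000)
        base = 10.0
        traces = []
        for k in range(20):
            onset = 0.03 + 0.045 * k
            tr = np.where(t >= onset, base + 50.0, base)
            traces.append(tr)
        resp = StepResponseSet(
            tuple(DEFAULT_CONTRAST_LEVELS), t, np.asarray(traces, float), base
        )
        info = latency_code_information(resp, seed=1)
        assert info.bits == pytest.approx(np.log2(20), abs=0.05)

    def test_monte_carlo_stability(self):
        taps, gain = ln_pair()
        resp = simulate_step_responses(taps, gain)
        small = latency_code_information(resp, n_draws=1000, seed=2).bits
        large = latency_code_information(resp, n_draws=10_000, seed=2).bits
        assert abs(small - large) < 0.05

    def test_information_bounded_by_log2_nlevel(self):
        taps, gain = ln_pair()
        resp = simulate_step_responses(taps, gain)
        info = latency_code_information(resp, seed=3)
        assert 0.0 <= info.bits <= np.log2(20) + 1e-9
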