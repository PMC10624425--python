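"""Linear-nonlinear Poisson simulator with recording-condition presets.

Each synthetic retinal ganglion cell is an LN cascade: a signed temporal
filter with unit L2 norm (difference of Gaussians over a 500 ms causal
window), followed by a static sigmoid gain function mapping the filter
projection of the stimulus to an instantaneous firing rate.  Spikes are an
inhomogeneous Poisson process (per-frame Poisson counts with uniform
in-frame jitter, exact for a frame-wise constant rate), optionally with an
absolute refractory period enforced by deletion.

Condition presets emulate four recording regimes that differ in baseline
firing (awake high, anesthetized/ex-vivo low), filter peak latency (awake
fastest), sigmoid midpoint (ex vivo most rectified), and the fraction of
direction/orientation tuned and OFF-suppressive cells.  Each cell's sigmoid
saturation sits one evoked lift above its baseline; the lift is pinned to
the condition's reported gain-function dynamic range, so step and flicker
response amplitudes scale the way the four regimes do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.special import expit

from .protocols import DirectionProtocol, StimulusTrace

__all__ = [
    "Dist",
    "GainSigmoid",
    "LNNeuron",
    "DirectionTuning",
    "ConditionPreset",
    "SpikeTrain",
    "SyntheticSession",
    "CONDITIONS",
    "make_condition_preset",
    "dog_filter",
    "sample_ln_neuron",
    "rate_trace",
    "simulate_spike_train",
    "simulate_direction_trials",
    "simulate_population_session",
]

CONDITIONS = ("awake", "isoflurane", "FMM", "exvivo")

FILTER_WINDOW_S = 0.5  #: causal filter window length


@dataclass(frozen=True)
class Dist:
    """Small bounded distribution spec used by the presets.

    ``kind`` is ``"truncnorm"`` (mean ``center``, sd ``spread``, clipped by
    rejection to [low, high]) or ``"lognorm"`` (median ``center``,
    log-sd ``spread``, clipped to [low, high]).
    """

    center: float
    spread: float
    low: float
    high: float
    kind: str = "truncnorm"

    def __post_init__(self) -> None:
        if self.spread < 0:
            raise ValueError("spread must be >= 0")
        if not self.low <= self.center <= self.high:
            raise ValueError("center must lie within [low, high]")

    def sample(self, rng: np.random.Generator, size=None):
        n = 1 if size is None else int(size)
        if self.kind == "truncnorm":
            out = np.empty(n)
            filled = 0
            while filled < n:
                draw = rng.normal(self.center, self.spread, size=2 * (n - filled) + 8)
                ok = draw[(draw >= self.low) & (draw <= self.high)]
                take = min(ok.size, n - filled)
                out[filled : filled + take] = ok[:take]
                filled += take
        elif self.kind == "lognorm":
            out = np.clip(
                self.center * np.exp(self.spread * rng.standard_normal(n)),
                self.low,
                self.high,
            )
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        return float(out[0]) if size is None else out


@dataclass(frozen=True)
class GainSigmoid:
    """Static nonlinearity: rate = floor + amp * logistic(steepness*(g - midpoint)).

    The floor/amplitude pair is derived from (max_rate, baseline_rate) under
    the constraint rate(0) = baseline_rate, so the baseline is exactly the
    neutral rate (the firing rate for stimuli orthogonal to the filter).
    Negative rates arising from a negative floor are clipped to zero at
    evaluation time.
    """

    max_rate: float
    midpoint: float
    steepness: float
    baseline_rate: float

    def __post_init__(self) -> None:
        if not self.max_rate >= self.baseline_rate >= 0:
            raise ValueError("require max_rate >= baseline_rate >= 0")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")

    def _amp_floor(self) -> tuple[float, float]:
        # max_rate == baseline_rate degenerates to a flat nonlinearity
        l0 = expit(-self.steepness * self.midpoint)
        amp = (self.max_rate - self.baseline_rate) / (1.0 - l0)
        return amp, self.max_rate - amp

    def __call__(self, g: np.ndarray | float) -> np.ndarray | float:
        amp, floor = self._amp_floor()
        return np.maximum(floor + amp * expit(self.steepness * (np.asarray(g) - self.midpoint)), 0.0)

    def mean_rate(self, g_sd: float = 1.0, n_quad: int = 101) -> float:
        """Expected rate for a Gaussian projection g ~ N(0, g_sd^2)."""
        x, w = np.polynomial.hermite_e.hermegauss(n_quad)
        return float(np.sum(w * self(x * g_sd)) / np.sum(w))


@dataclass(frozen=True)
class DirectionTuning:
    preferred_rad: float
    depth: float  # modulation depth in [0, 1]
    order: int = 1  # 1 = direction selective, 2 = orientation selective

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("depth must lie in [0, 1]")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 (DS) or 2 (OS)")

    def modulation(self, direction_rad: float) -> float:
        return 1.0 + self.depth * math.cos(self.order * (direction_rad - self.preferred_rad))


@dataclass(frozen=True)
class LNNeuron:
    """Ground-truth LN cascade for one simulated cell."""

    filter: np.ndarray  # unit-L2 taps, most recent frame first
    lags_s: np.ndarray  # lag of each tap (bin centers), seconds
    gain: GainSigmoid
    polarity: str  # ON | OFF | ON/OFF | OFF-suppressive
    tuning: DirectionTuning | None = None
    refractory_s: float = 0.0
    latency_s: float = float("nan")  # generative first-lobe center
    biphasic_index: float = float("nan")
    width_factor: float = 0.3

    def __post_init__(self) -> None:
        f = np.asarray(self.filter, dtype=float)
        object.__setattr__(self, "filter", f)
        object.__setattr__(self, "lags_s", np.asarray(self.lags_s, dtype=float))
        if abs(np.linalg.norm(f) - 1.0) > 1e-9:
            raise ValueError("filter must have unit L2 norm")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be >= 0")

    def first_peak_latency_s(self) -> float:
        """First-extremum lag of the continuous generative kernel.

        Evaluated on a dense (0.5 ms) grid of the closed-form difference of
        Gaussians, with the same rule used when estimating kinetics from
        data: the earliest local extremum whose magnitude exceeds 20% of
        the global extremum.
        """
        t = np.arange(0.0, FILTER_WINDOW_S, 5e-4)
        f = dog_curve(t, self.latency_s, self.biphasic_index, self.width_factor)
        return first_extremum_lag(t, f)


@dataclass(frozen=True)
class ConditionPreset:
    """Generative parameter distributions for one recording condition."""

    condition: str
    baseline_hz: Dist
    latency_ms: Dist
    biphasic_index: Dist
    midpoint: Dist
    steepness: float
    width_factor: float
    evoked_center_hz: float  # saturation lift above baseline (dynamic range)
    evoked_logsd: float
    mean_rate_target_hz: float
    frac_on: float
    frac_off: float
    frac_suppressive: float
    frac_tuned: float
    suppressive_baseline_hz: Dist | None = None
    refractory_s: float = 0.002

    def __post_init__(self) -> None:
        fracs = (self.frac_on, self.frac_off, self.frac_suppressive, self.frac_tuned)
        if any(f < 0 for f in fracs):
            raise ValueError("fractions must be >= 0")
        if self.frac_on + self.frac_off > 1.0 + 1e-12:
            raise ValueError("polarity fractions must sum to <= 1")


def first_extremum_lag(t: np.ndarray, f: np.ndarray) -> float:
    """Earliest local extremum of |f| exceeding 20% of the global extremum."""
    mag = np.abs(f)
    thresh = 0.2 * mag.max()
    interior = np.where(
        (mag[1:-1] >= mag[:-2]) & (mag[1:-1] >= mag[2:]) & (mag[1:-1] >= thresh)
    )[0]
    if interior.size:
        return float(t[interior[0] + 1])
    return float(t[int(np.argmax(mag))])


def dog_curve(
    t: np.ndarray, latency_s: float, biphasic_index: float, width_factor: float = 0.3
) -> np.ndarray:
    """Continuous (unnormalized) difference-of-Gaussians kernel shape.

    ``width_factor`` scales the first-lobe width with the latency; together
    with the biphasic index it sets the kernel's spectral peak.
    """
    sigma1 = max(0.008, width_factor * latency_s)
    mu2 = latency_s + 2.2 * sigma1
    sigma2 = 1.6 * sigma1
    return np.exp(-0.5 * ((t - latency_s) / sigma1) ** 2) - biphasic_index * np.exp(
        -0.5 * ((t - mu2) / sigma2) ** 2
    )


# (no numeric calibration step: the evoked lift is pinned directly to each
# condition's printed gain-function dynamic range; see _PRESET_TABLE)


# Centers follow the printed population statistics of the four regimes:
# ramp-fit baseline B (awake 20 Hz vs anesthetized 2 Hz), first-peak latency
# (47/77/87/64 ms), sigmoid midpoint (0.8/1.1/1.1/1.6), and the saturation
# lift above baseline pinned to the gain-function dynamic range
# (56/26/29/12 Hz median).  The printed white-noise mean rates
# (34.9/13.0/10.9/6.9 Hz) are kept as descriptive targets; with the
# baseline, midpoint and dynamic range all pinned they are emergent, and
# the anesthetized/ex-vivo means land below the printed values.
_PRESET_TABLE: dict[str, dict] = {
    "awake": dict(
        baseline_hz=Dist(20.0, 0.9, 0.5, 120.0, "lognorm"),
        latency_ms=Dist(47.0, 18.0, 11.0, 83.0),
        biphasic_index=Dist(0.70, 0.15, 0.3, 0.95),
        width_factor=0.275,
        midpoint=Dist(0.8, 0.4, 0.2, 2.5),
        steepness=5.0,
        evoked_center_hz=56.0,
        mean_rate_target_hz=34.9,
        frac_on=0.5,
        frac_off=0.5,
        frac_suppressive=0.13,
        frac_tuned=0.10,
    ),
    "isoflurane": dict(
        baseline_hz=Dist(2.0, 1.1, 0.05, 40.0, "lognorm"),
        latency_ms=Dist(77.0, 19.0, 39.0, 115.0),
        biphasic_index=Dist(0.30, 0.15, 0.05, 0.8),
        width_factor=0.30,
        midpoint=Dist(1.1, 0.45, 0.3, 3.0),
        steepness=5.0,
        evoked_center_hz=26.0,
        mean_rate_target_hz=13.0,
        frac_on=0.5,
        frac_off=0.5,
        frac_suppressive=0.006,
        frac_tuned=0.25,
    ),
    "FMM": dict(
        baseline_hz=Dist(2.0, 1.1, 0.05, 40.0, "lognorm"),
        latency_ms=Dist(87.0, 24.0, 39.0, 135.0),
        biphasic_index=Dist(0.25, 0.12, 0.05, 0.7),
        width_factor=0.30,
        midpoint=Dist(1.1, 0.45, 0.3, 3.0),
        steepness=5.0,
        evoked_center_hz=29.0,
        mean_rate_target_hz=10.9,
        frac_on=0.5,
        frac_off=0.5,
        frac_suppressive=0.01,
        frac_tuned=0.25,
    ),
    "exvivo": dict(
        baseline_hz=Dist(2.0, 1.0, 0.05, 30.0, "lognorm"),
        latency_ms=Dist(64.0, 28.0, 8.0, 120.0),
        biphasic_index=Dist(0.20, 0.10, 0.05, 0.5),
        width_factor=0.325,
        midpoint=Dist(1.6, 0.7, 0.4, 4.0),
        steepness=5.0,
        evoked_center_hz=12.0,
        mean_rate_target_hz=6.9,
        frac_on=0.5,
        frac_off=0.5,
        frac_suppressive=0.0,
        frac_tuned=0.20,
    ),
}

_SUPPRESSIVE_BASELINE = Dist(62.0, 32.0, 10.0, 150.0)


@lru_cache(maxsize=8)
def make_condition_preset(condition: str) -> ConditionPreset:
    """Build the generative preset for one of the four recording regimes."""
    if condition not in _PRESET_TABLE:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    spec = dict(_PRESET_TABLE[condition])
    return ConditionPreset(
        condition=condition,
        evoked_logsd=0.5,
        suppressive_baseline_hz=_SUPPRESSIVE_BASELINE,
        **spec,
    )


def dog_filter(
    frame_rate: float,
    latency_s: float,
    biphasic_index: float,
    sign: int = 1,
    window_s: float = FILTER_WINDOW_S,
    width_factor: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Difference-of-Gaussians temporal kernel, unit L2 norm.

    The first lobe is centered at ``latency_s`` with width scaling with
    latency; the opposing lobe trails it with amplitude ``biphasic_index``
    relative to the first.  ``sign=+1`` makes the first lobe positive (ON),
    ``-1`` negative (OFF).  Returns (taps, lag centers in seconds).
    """
    n_taps = int(round(window_s * frame_rate))
    lags = (np.arange(n_taps) + 0.5) / frame_rate
    f = sign * dog_curve(lags, latency_s, biphasic_index, width_factor)
    return f / np.linalg.norm(f), lags


def sample_ln_neuron(
    preset: ConditionPreset, seed: int, frame_rate: float = 60.0
) -> LNNeuron:
    """Draw one LN neuron from the preset's parameter distributions."""
    rng = np.random.default_rng(seed)
    latency_s = preset.latency_ms.sample(rng) / 1000.0
    biphasic = preset.biphasic_index.sample(rng)
    u = rng.uniform()
    suppressive = u < preset.frac_suppressive
    if suppressive:
        polarity = "OFF-suppressive"
        sign = +1  # ON-like filter; decrements suppress firing
        baseline = preset.suppressive_baseline_hz.sample(rng)
        midpoint = -abs(preset.midpoint.sample(rng)) * 0.6
        steepness = 3.0
        max_rate = 1.1 * baseline
    else:
        on = rng.uniform() < preset.frac_on / max(preset.frac_on + preset.frac_off, 1e-12)
        polarity = "ON" if on else "OFF"
        sign = +1 if on else -1
        baseline = preset.baseline_hz.sample(rng)
        midpoint = preset.midpoint.sample(rng)
        steepness = preset.steepness
        evoked = preset.evoked_center_hz * math.exp(
            preset.evoked_logsd * rng.standard_normal()
        )
        max_rate = baseline + max(evoked, 1.0)
    taps, lags = dog_filter(
        frame_rate, latency_s, biphasic, sign, width_factor=preset.width_factor
    )
    tuning = None
    if rng.uniform() < preset.frac_tuned:
        tuning = DirectionTuning(
            preferred_rad=float(rng.uniform(0.0, 2.0 * math.pi)),
            depth=float(rng.uniform(0.3, 0.8)),
            order=1 if rng.uniform() < 0.5 else 2,
        )
    gain = GainSigmoid(max_rate, midpoint, steepness, baseline)
    return LNNeuron(
        filter=taps,
        lags_s=lags,
        gain=gain,
        polarity=polarity,
        tuning=tuning,
        refractory_s=preset.refractory_s,
        latency_s=latency_s,
        biphasic_index=biphasic,
        width_factor=preset.width_factor,
    )


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one unit over a session (seconds)."""

    unit_id: str
    times: np.ndarray
    t_stop: float
    condition: str = ""
    session_id: str = ""
    n_trials: int = 1
    trial_duration_s: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (np.any(np.diff(t) < 0) or t[0] < 0 or t[-1] > self.t_stop):
            raise ValueError("spike times must be sorted and within [0, t_stop]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def mean_rate(self) -> float:
        return self.n_spikes / self.t_stop if self.t_stop > 0 else 0.0

    def fold_trials(self) -> list[np.ndarray]:
        """Per-trial spike times, relative to each trial's start."""
        if self.n_trials == 1 or self.trial_duration_s is None:
            return [self.times]
        d = self.trial_duration_s
        return [
            self.times[(self.times >= k * d) & (self.times < (k + 1) * d)] - k * d
            for k in range(self.n_trials)
        ]


def rate_trace(
    neuron: LNNeuron, stim: StimulusTrace, gain_noise: np.ndarray | None = None
) -> np.ndarray:
    """Instantaneous rate per stimulus frame: sigmoid(filter * contrast)."""
    if stim.n_frames == 0:
        raise ValueError("empty stimulus")
    if stim.n_frames < neuron.filter.size:
        raise ValueError("stimulus must be longer than the filter window")
    # causal FIR: tap j multiplies the contrast j frames earlier
    g = np.convolve(stim.contrast, neuron.filter)[: stim.n_frames]
    lam = np.asarray(neuron.gain(g), dtype=float)
    if gain_noise is not None:
        lam = lam * gain_noise
    return lam


def _spikes_from_rate(
    lam: np.ndarray, frame_interval: float, rng: np.random.Generator,
    refractory_s: float,
) -> np.ndarray:
    counts = rng.poisson(lam * frame_interval)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    frames = np.repeat(np.nonzero(counts)[0], counts[counts > 0])
    times = np.sort((frames + rng.uniform(size=total)) * frame_interval)
    if refractory_s > 0 and times.size > 1:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refractory_s:
                kept.append(t)
        times = np.asarray(kept)
    return times


def simulate_spike_train(
    neuron: LNNeuron,
    stim: StimulusTrace,
    n_trials: int = 1,
    seed: int = 0,
    unit_id: str = "u0",
    condition: str = "",
    gain_noise: np.ndarray | None = None,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes for ``n_trials`` repeats of the stimulus.

    ``gain_noise``, if given, is an ``(n_trials, n_frames)`` multiplicative
    factor on the rate (shared gain fluctuations across a population).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    lam0 = rate_trace(neuron, stim)
    rng = np.random.default_rng(seed)
    dur = stim.duration
    all_times = []
    for k in range(n_trials):
        lam = lam0 if gain_noise is None else lam0 * gain_noise[k]
        all_times.append(
            _spikes_from_rate(lam, stim.frame_interval, rng, 0.0) + k * dur
        )
    times = np.concatenate(all_times)
    if neuron.refractory_s > 0 and times.size > 1:
        # refractory deletion across the whole concatenated train
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= neuron.refractory_s:
                kept.append(t)
        times = np.asarray(kept)
    return SpikeTrain(
        unit_id=unit_id,
        times=times,
        t_stop=n_trials * dur,
        condition=condition,
        n_trials=n_trials,
        trial_duration_s=dur,
    )


def simulate_direction_trials(
    neuron: LNNeuron, protocol: DirectionProtocol, seed: int = 0
) -> np.ndarray:
    """Mean firing rate (Hz) per grating epoch, shape (n_trials, 8).

    The grating drive is the cell's expected white-noise rate, scaled by the
    cosine-type tuning ``1 + depth*cos(order*(direction - preferred))`` for
    tuned cells; spike counts per epoch are Poisson.  Columns follow
    ``protocol.directions`` order, not presentation order.
    """
    rng = np.random.default_rng(seed)
    drive = neuron.gain.mean_rate()
    dir_index = {w: k for k, w in enumerate(protocol.directions)}
    rates = np.zeros((protocol.n_trials, 8))
    counters = {w: 0 for w in protocol.directions}
    for direction, start, end in protocol.schedule:
        mod = neuron.tuning.modulation(direction) if neuron.tuning else 1.0
        dur = end - start
        count = rng.poisson(drive * mod * dur)
        rates[counters[direction], dir_index[direction]] = count / dur
        counters[direction] += 1
    return rates


def _ou_process(
    n: int, dt: float, tau: float, rng: np.random.Generator
) -> np.ndarray:
    a = math.exp(-dt / tau)
    noise = rng.standard_normal(n) * math.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    for i in range(1, n):
        x[i] = a * x[i - 1] + noise[i]
    return x


@dataclass(frozen=True)
class SyntheticSession:
    """A simulated recording: stimulus, ground-truth neurons, spike trains."""

    stim: StimulusTrace
    neurons: tuple[LNNeuron, ...]
    trains: tuple[SpikeTrain, ...]
    condition: str
    seed: int
    behavior: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.trains)


def simulate_population_session(
    n_cells: int,
    stim: StimulusTrace,
    preset: ConditionPreset,
    noise_corr: float = 0.0,
    seed: int = 0,
    n_trials: int = 1,
    behavior_coupling: float = 0.0,
) -> SyntheticSession:
    """Simulate ``n_cells`` LN neurons sharing one stimulus.

    ``noise_corr`` in [0, 1) sets the log-sd of a shared multiplicative
    gain-noise process (Ornstein-Uhlenbeck, 500 ms timescale), inducing
    pairwise spike-count correlations of matching magnitude; 0 gives
    conditionally independent spiking.  Behavior traces (running speed,
    pupil size) are smoothed OU noise; ``behavior_coupling`` additionally
    scales the shared gain by ``exp(coupling * running)``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 <= noise_corr < 1.0:
        raise ValueError("noise_corr must lie in [0, 1)")
    master = np.random.default_rng(seed)
    behav_rng = np.random.default_rng(master.integers(2**31))
    running = _ou_process(stim.n_frames, stim.frame_interval, 2.0, behav_rng)
    pupil = _ou_process(stim.n_frames, stim.frame_interval, 5.0, behav_rng)
    gain_noise = None
    if noise_corr > 0.0 or behavior_coupling != 0.0:
        shared = np.empty((n_trials, stim.n_frames))
        for k in range(n_trials):
            z = _ou_process(stim.n_frames, stim.frame_interval, 0.5, behav_rng)
            logg = noise_corr * z + behavior_coupling * running
            shared[k] = np.exp(logg - 0.5 * np.var(logg))
        gain_noise = shared
    neurons, trains = [], []
    for i in range(n_cells):
        neuron = sample_ln_neuron(preset, seed=int(master.integers(2**31)))
        train = simulate_spike_train(
            neuron,
            stim,
            n_trials=n_trials,
            seed=int(master.integers(2**31)),
            unit_id=f"u{i:03d}",
            condition=preset.condition,
            gain_noise=gain_noise,
        )
        neurons.append(neuron)
        trains.append(replace(train, session_id=f"{preset.condition}-s{seed}"))
    return SyntheticSession(
        stim=stim,
        neurons=tuple(neurons),
        trains=tuple(trains),
        condition=preset.condition,
        seed=seed,
        behavior={"running_speed": running, "pupil_size": pupil},
    )
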