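"""Rate-code versus latency-code information for LN step responses.

Each cell (a temporal filter plus a static gain function, either generative
or estimated) is driven with step changes in contrast at 20 levels (10
increments, 10 decrements, equal priors).  Stimulus information is then
computed for two response characteristics via

    I = sum_s integral dx p(s) p(x|s) log2[ p(x|s) / p(x) ],

with p(x) the equal-weight mixture of the conditionals.  For the rate code
x is the peak firing rate, Gaussian per level with sd equal to 2.5% of the
peak.  For the latency code x is the first time the response deviates from
baseline by a threshold drawn as Gaussian (mean 10%, sd 2.5% of baseline);
step levels whose response never crosses contribute to a discrete
"no-response" (infinite latency) atom.  Absolute deviation is used, so
firing suppression can also trigger detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "StepResponseSet",
    "CodeInfo",
    "simulate_step_responses",
    "discrete_stimulus_information",
    "rate_code_information",
    "latency_code_information",
    "DEFAULT_CONTRAST_LEVELS",
]

DEFAULT_CONTRAST_LEVELS = tuple(
    np.concatenate([np.arange(1, 11) / 10.0, -np.arange(1, 11) / 10.0]).tolist()
)

N_LEVELS = 20


@dataclass(frozen=True)
class StepResponseSet:
    """Simulated responses to contrast steps at every stimulus level."""

    levels: tuple[float, ...]
    time_s: np.ndarray
    traces: np.ndarray  # (n_levels, n_time) firing rate in Hz
    baseline_hz: float

    @property
    def peak_rates(self) -> np.ndarray:
        return self.traces.max(axis=1)


def simulate_step_responses(
    filter_taps: np.ndarray,
    gain: Callable[[np.ndarray], np.ndarray],
    frame_rate: float = 60.0,
    levels: Sequence[float] = DEFAULT_CONTRAST_LEVELS,
    step_duration_s: float = 1.0,
    grid_s: float = 0.001,
) -> StepResponseSet:
    """LN response traces to a step from zero contrast to each level.

    The filter projection of a step of size c is c times the running sum of
    the filter taps; the staircase is linearly interpolated onto a dense
    (default 1 ms) grid before the static nonlinearity is applied.
    """
    taps = np.asarray(filter_taps, dtype=float)
    if taps.ndim != 1 or taps.size == 0:
        raise ValueError("filter taps must be a non-empty 1-D array")
    if not callable(gain):
        raise ValueError("a static nonlinearity callable is required")
    dt_frame = 1.0 / frame_rate
    t = np.arange(0.0, step_duration_s, grid_s)
    # projection of a unit step after k full frames have elapsed
    csum = np.concatenate([[0.0], np.cumsum(taps)])
    frame_t = np.arange(csum.size) * dt_frame
    proj_unit = np.interp(t, frame_t, csum, right=csum[-1])
    baseline = float(np.asarray(gain(0.0)))
    traces = np.stack([np.asarray(gain(c * proj_unit), dtype=float) for c in levels])
    return StepResponseSet(tuple(levels), t, traces, baseline)


@dataclass(frozen=True)
class CodeInfo:
    kind: str  # "rate" | "latency"
    bits: float
    x_grid: np.ndarray
    p_x_given_s: np.ndarray  # (n_levels, n_grid) densities or bin masses
    atom_mass: np.ndarray  # (n_levels,) discrete no-response mass


def discrete_stimulus_information(
    p_x_given_s: np.ndarray,
    dx: float | np.ndarray = 1.0,
    atoms: np.ndarray | None = None,
    p_s: np.ndarray | None = None,
    tol: float = 1e-6,
) -> float:
    """Mutual information (bits) between stimulus level and response variable.

    ``p_x_given_s`` holds one conditional density per row, evaluated on a
    shared grid with spacing ``dx`` (or per-point weights); ``atoms`` is an
    optional discrete probability per row (e.g. infinite latency).  Every
    row must normalize to 1 (continuous part plus atom).
    """
    p = np.asarray(p_x_given_s, dtype=float)
    n_s = p.shape[0]
    p_s = np.full(n_s, 1.0 / n_s) if p_s is None else np.asarray(p_s, dtype=float)
    atoms = np.zeros(n_s) if atoms is None else np.asarray(atoms, dtype=float)
    w = np.broadcast_to(np.asarray(dx, dtype=float), p.shape[1:])
    total = p @ w + atoms
    if np.any(np.abs(total - 1.0) > tol):
        raise ValueError("each conditional must normalize to 1 (density + atom)")
    mix = p_s @ p  # mixture density on the grid
    mix_atom = float(p_s @ atoms)
    info = 0.0
    for s in range(n_s):
        # mix >= p_s*p mathematically; the extra guard only drops bins whose
        # subnormal density underflows in the mixture (zero contribution)
        pos = (p[s] > 0) & (mix > 0)
        if pos.any():
            info += p_s[s] * np.sum(
                w[pos] * p[s][pos] * np.log2(p[s][pos] / mix[pos])
            )
        if atoms[s] > 0:
            info += p_s[s] * atoms[s] * np.log2(atoms[s] / mix_atom)
    return float(info)


def rate_code_information(
    responses: StepResponseSet, rel_sd: float = 0.025, n_local: int = 1201
) -> CodeInfo:
    """Information in the peak firing rate across step levels.

    Each level's peak rate is Gaussian with sd equal to ``rel_sd`` times
    the peak (1e-3 Hz floor for silent levels).  The integral over x is
    evaluated per level on a local grid spanning that conditional's +-8 sd
    support, so narrow and wide conditionals are resolved equally well
    even when the peaks span several decades.
    """
    peaks = responses.peak_rates
    n_s = peaks.size
    sds = np.maximum(rel_sd * peaks, 1e-3)

    def norm_pdf(x, m, s):
        return np.exp(-0.5 * ((x - m) / s) ** 2) / (np.sqrt(2 * np.pi) * s)

    bits = 0.0
    for s in range(n_s):
        x = np.linspace(peaks[s] - 8 * sds[s], peaks[s] + 8 * sds[s], n_local)
        dx = x[1] - x[0]
        p = norm_pdf(x, peaks[s], sds[s])
        mix = np.mean([norm_pdf(x, peaks[j], sds[j]) for j in range(n_s)], axis=0)
        pos = (p > 0) & (mix > 0)
        bits += (1.0 / n_s) * np.sum(dx * p[pos] * np.log2(p[pos] / mix[pos]))
    # a coarse shared grid kept for inspection/reporting only
    grid = np.linspace(float(np.min(peaks - 6 * sds)), float(np.max(peaks + 6 * sds)), 512)
    dens = norm_pdf(grid[None, :], peaks[:, None], sds[:, None])
    return CodeInfo("rate", float(bits), grid, dens, np.zeros(n_s))


def latency_code_information(
    responses: StepResponseSet,
    rel_threshold: float = 0.10,
    rel_sd: float = 0.025,
    n_draws: int = 10_000,
    seed: int = 0,
    bin_s: float = 0.002,
    abs_threshold_floor_hz: float = 0.5,
) -> CodeInfo:
    """Information in the first-crossing latency across step levels.

    For each Monte-Carlo draw the detection threshold on |rate - baseline|
    is Normal(rel_threshold * baseline, rel_sd * baseline); draws whose
    trace never crosses land in the infinite-latency atom.  A zero (or
    near-zero) baseline falls back to an absolute threshold floor.  The
    continuous latency part is histogrammed at ``bin_s`` resolution and the
    information evaluated as a sum over bins plus the atom term.
    """
    rng = np.random.default_rng(seed)
    base = responses.baseline_hz
    mu = max(rel_threshold * base, abs_threshold_floor_hz)
    sd = max(rel_sd * base, 0.25 * abs_threshold_floor_hz)
    thresholds = np.maximum(rng.normal(mu, sd, size=n_draws), 1e-6)
    dev = np.abs(responses.traces - base)  # (n_levels, n_time)
    t = responses.time_s
    n_levels = dev.shape[0]
    edges = np.arange(0.0, t[-1] + 2 * bin_s, bin_s)
    masses = np.zeros((n_levels, edges.size - 1))
    atom = np.zeros(n_levels)
    # first index where the deviation exceeds theta, via the running maximum
    runmax = np.maximum.accumulate(dev, axis=1)
    for s in range(n_levels):
        peak = runmax[s, -1]
        crossed = thresholds < peak
        atom[s] = 1.0 - crossed.mean()
        if crossed.any():
            idx = np.searchsorted(runmax[s], thresholds[crossed], side="left")
            lat = t[np.minimum(idx, t.size - 1)]
            h, _ = np.histogram(lat, bins=edges)
            masses[s] = h / n_draws
    bits = discrete_stimulus_information(masses, 1.0, atoms=atom)
    return CodeInfo("latency", bits, 0.5 * (edges[:-1] + edges[1:]), masses, atom)
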