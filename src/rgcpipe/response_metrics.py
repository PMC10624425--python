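"""Trial-based response indices and behavior cross-correlations.

The quality index (SNR) measures trial-to-trial reliability of the PSTH as
the time-variance of the trial-averaged rate divided by the trial-averaged
time-variance of single-trial rates; it is bounded by [0, 1] for repeated
identical trials up to noise, and cells with SNR >= 0.15 are treated as
reliably responsive.  The ON-OFF index contrasts mean rates in the ON and
second OFF epochs of the contrast-inversion sequence.  Direction and
orientation selectivity project per-direction mean rates onto a complex
exponential of order 1 (DS) or 2 (OS), with significance from a
label-shuffling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocols import StimulusTrace
from .synthdata import SpikeTrain

__all__ = [
    "TrialEnsemble",
    "SelectivityResult",
    "bin_spike_counts",
    "trial_ensemble_from_train",
    "compute_snr",
    "compute_on_off_index",
    "selectivity_index",
    "compute_selectivity",
    "behavior_crosscorrelation",
    "SNR_THRESHOLD",
    "ON_OFF_THRESHOLD",
    "DSOS_INDEX_THRESHOLD",
    "DSOS_P_THRESHOLD",
]

SNR_THRESHOLD = 0.15
ON_OFF_THRESHOLD = 0.25
DSOS_INDEX_THRESHOLD = 0.15
DSOS_P_THRESHOLD = 0.2

DEFAULT_BIN_S = 1 / 60.0  # 16.7 ms, one stimulus frame


@dataclass(frozen=True)
class TrialEnsemble:
    """Rate matrix (trial x time-bin) in Hz, rectangular binning."""

    rates: np.ndarray
    bin_s: float
    label: str = ""

    def __post_init__(self) -> None:
        r = np.atleast_2d(np.asarray(self.rates, dtype=float))
        object.__setattr__(self, "rates", r)
        if np.any(r < 0):
            raise ValueError("rates must be non-negative")
        if self.bin_s <= 0:
            raise ValueError("bin_s must be positive")

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    def psth(self) -> np.ndarray:
        """Trial-averaged rate, Hz."""
        return self.rates.mean(axis=0)


def bin_spike_counts(times: np.ndarray, t0: float, t1: float, bin_s: float) -> np.ndarray:
    """Spike counts in rectangular bins of [t0, t1)."""
    n = max(int(round((t1 - t0) / bin_s)), 1)
    edges = t0 + np.arange(n + 1) * bin_s
    counts, _ = np.histogram(times, bins=edges)
    return counts


def trial_ensemble_from_train(
    train: SpikeTrain,
    stim: StimulusTrace,
    label: str,
    bin_s: float = DEFAULT_BIN_S,
    window: tuple[float, float] | None = None,
) -> TrialEnsemble:
    """Align one unit's spikes to every segment with ``label``.

    Spike times are interpreted on the repeated-stimulus clock: trial ``k``
    of the train replays the stimulus, so a segment at [s, e) recurs at
    ``k * stim.duration + [s, e)``.  ``window`` optionally restricts to a
    sub-interval (seconds, relative to segment start).
    """
    segs = stim.find_segments(label)
    if not segs:
        raise ValueError(f"no segment labelled {label!r} in the stimulus")
    rows = []
    for k in range(train.n_trials):
        off = k * stim.duration
        for seg in segs:
            a, b = seg.start_s, seg.end_s
            if window is not None:
                a, b = seg.start_s + window[0], seg.start_s + window[1]
            counts = bin_spike_counts(train.times, off + a, off + b, bin_s)
            rows.append(counts / bin_s)
    n_bins = min(len(r) for r in rows)
    return TrialEnsemble(np.vstack([r[:n_bins] for r in rows]), bin_s, label)


def compute_snr(ens: TrialEnsemble) -> float:
    """Trial-to-trial reliability: var_t[mean-over-trials PSTH] divided by
    the mean over trials of each trial's variance over time.

    Population (divide-by-N) variances throughout.  Conventions: 0/0 -> 0;
    positive/0 -> +inf.
    """
    if ens.n_trials < 2 or ens.n_bins < 2:
        raise ValueError("need at least 2 trials and 2 time bins")
    num = float(np.var(ens.psth()))
    den = float(np.mean(np.var(ens.rates, axis=1)))
    if den == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return num / den


def compute_on_off_index(r_on: float, r_off: float) -> float:
    """(r_ON - r_OFF) / (r_ON + r_OFF); 0 when both rates are zero."""
    if r_on < 0 or r_off < 0:
        raise ValueError("rates must be non-negative")
    total = r_on + r_off
    if total == 0.0:
        return 0.0
    return (r_on - r_off) / total


@dataclass(frozen=True)
class SelectivityResult:
    ds_index: float
    os_index: float
    p_ds: float
    p_os: float
    mean_rates: np.ndarray
    n_bootstrap: int


def selectivity_index(r_k: np.ndarray, omega_k: np.ndarray, alpha: int) -> float:
    """|sum_k exp(-i*alpha*omega_k) r_k| / sum_k r_k."""
    r_k = np.asarray(r_k, dtype=float)
    total = r_k.sum()
    if total <= 0:
        raise ValueError("selectivity index undefined for all-zero rates")
    return float(np.abs(np.sum(np.exp(-1j * alpha * np.asarray(omega_k)) * r_k)) / total)


def compute_selectivity(
    trial_rates: np.ndarray,
    omega_k: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> SelectivityResult:
    """DS/OS indices from per-trial per-direction rates, with bootstrap p.

    ``trial_rates`` has shape (n_trials, 8).  The null shuffles direction
    labels independently within each trial (1000 seeded repetitions by
    default); p is the one-sided fraction of shuffled indices at or above
    the observed one.
    """
    trial_rates = np.atleast_2d(np.asarray(trial_rates, dtype=float))
    omega_k = np.asarray(omega_k, dtype=float)
    if trial_rates.shape[1] != omega_k.size:
        raise ValueError("trial_rates columns must match omega_k")
    mean_rates = trial_rates.mean(axis=0)
    obs = {a: selectivity_index(mean_rates, omega_k, a) for a in (1, 2)}
    rng = np.random.default_rng(seed)
    exceed = {1: 0, 2: 0}
    n_trials, n_dir = trial_rates.shape
    for _ in range(n_boot):
        shuffled = np.take_along_axis(
            trial_rates, rng.permuted(np.tile(np.arange(n_dir), (n_trials, 1)), axis=1), axis=1
        )
        mu = shuffled.mean(axis=0)
        if mu.sum() <= 0:
            continue
        for a in (1, 2):
            if selectivity_index(mu, omega_k, a) >= obs[a]:
                exceed[a] += 1
    return SelectivityResult(
        ds_index=obs[1],
        os_index=obs[2],
        p_ds=exceed[1] / n_boot,
        p_os=exceed[2] / n_boot,
        mean_rates=mean_rates,
        n_bootstrap=n_boot,
    )


def _normalized_xcorr(
    a: np.ndarray, b: np.ndarray, max_lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson-type correlation at integer-bin lags up to ``max_lag``.

    Series are standardized globally and each lag is normalized by its
    overlap length, so correlations at different lags are comparable.
    """
    from scipy.signal import fftconvolve

    n = a.size
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    full = fftconvolve(a, b[::-1], mode="full")
    lags = np.arange(-n + 1, n)
    overlap = n - np.abs(lags)
    rho = full / overlap
    keep = np.abs(lags) <= max_lag
    # variance-equalized statistic: under independence z ~ N(0, 1) at every lag
    z = rho * np.sqrt(overlap)
    return lags[keep], rho[keep], z[keep]


def behavior_crosscorrelation(
    rate: np.ndarray,
    behavior: np.ndarray,
    bin_s: float = 0.1,
    max_lag_s: float = 5.0,
    null: str = "tail",
) -> tuple[float, float, float]:
    """Peak cross-correlation between a firing-rate and a behavior series.

    Both series must already be binned at ``bin_s``.  The peak is the
    extremum of |rho| within |lag| <= ``max_lag_s``; its p-value comes from
    the correlation values outside that range: ``null="tail"`` compares the
    peak against individual outside-lag values (two-sided empirical tail),
    ``null="blockmax"`` compares it against maxima of contiguous outside
    blocks of the same width as the search window, which calibrates the
    maximum statistic.  Returns (peak rho, peak lag in s, p).
    """
    rate = np.asarray(rate, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    if rate.shape != behavior.shape or rate.ndim != 1:
        raise ValueError("series must be 1-D and aligned")
    if rate.size * bin_s < 60.0:
        raise ValueError("need at least 60 s of data")
    if rate.std() == 0 or behavior.std() == 0:
        raise ValueError("correlation undefined for a constant series")
    # lags beyond a quarter of the series have too little overlap to be
    # comparable; they are excluded from both the peak search and the null
    lags, rho, z = _normalized_xcorr(rate, behavior, max_lag=rate.size // 4)
    w = int(round(max_lag_s / bin_s))
    inside = np.abs(lags) <= w
    i_peak = np.argmax(np.abs(rho[inside]))
    peak = float(rho[inside][i_peak])
    peak_lag = float(lags[inside][i_peak] * bin_s)
    peak_z = abs(z[inside][i_peak])
    outside = np.abs(z[~inside])
    if null == "tail":
        p = float(np.mean(outside >= peak_z))
    elif null == "blockmax":
        width = 2 * w + 1
        n_blocks = outside.size // width
        if n_blocks < 5:
            raise ValueError("too few outside blocks for the blockmax null")
        block_max = outside[: n_blocks * width].reshape(n_blocks, width).max(axis=1)
        p = float((1 + np.sum(block_max >= peak_z)) / (n_blocks + 1))
    else:
        raise ValueError("null must be 'tail' or 'blockmax'")
    return peak, peak_lag, p
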