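"""LN-model estimation from random-flicker responses.

The linear stage is the spike-triggered average (STA) of the binary
contrast stimulus over a 500 ms causal window; each time bin gets a
two-sided p-value against the null that the STA is Normal(0, 1/C) where C
is the spike count.  Kinetics are summarized by a difference-of-Gaussians
(DoG) fit: the first-peak latency is the earliest extremum of the fitted
curve, and the spectral peak frequency is the argmax of its power spectrum
(DC excluded).  Cells whose STA is nowhere significant (p > 1e-18 in every
bin) or whose DoG fit has R^2 < 0.8 are flagged for exclusion.

The static nonlinearity follows from Bayes' rule: binning the stimulus
projections onto the L2-normalized STA (bin width 0.1), the firing rate per
bin is the ratio of spike-triggered to raw stimulus counts divided by the
frame interval.  A sigmoid is fitted for smoothing; the neutral rate is its
value at projection zero and the dynamic range its span over the populated
projection axis.

Filter shapes are classified by PCA over a population of normalized STAs:
after sign-orienting the first two components against canonical
monophasic-OFF and biphasic-OFF templates, the four biplot quadrants map to
mono-OFF, bi-OFF, mono-ON, and bi-ON.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import least_squares
from scipy.stats import norm
from sklearn.decomposition import PCA

from .flicker_analysis import explained_variance
from .protocols import StimulusTrace
from .synthdata import SpikeTrain, dog_filter, first_extremum_lag

__all__ = [
    "TemporalFilter",
    "KineticsFit",
    "GainFunction",
    "ShapeClass",
    "compute_sta",
    "fit_kinetics",
    "estimate_gain_function",
    "classify_filter_shapes",
    "STA_P_THRESHOLD",
    "DOG_R2_THRESHOLD",
]

STA_P_THRESHOLD = 1e-18
DOG_R2_THRESHOLD = 0.8
DEFAULT_WINDOW_S = 0.5
GAIN_BIN_WIDTH = 0.1


@dataclass(frozen=True)
class TemporalFilter:
    """STA over the causal window, raw and L2-normalized, with per-bin p."""

    sta_raw: np.ndarray  # lag-ordered, tap 0 = spike frame
    sta_norm: np.ndarray
    lags_s: np.ndarray
    n_spikes: int
    p_values: np.ndarray
    frame_rate: float

    @property
    def significant(self) -> bool:
        """At least one bin rejects the Normal(0, 1/C) null at p <= 1e-18."""
        return bool(np.min(self.p_values) <= STA_P_THRESHOLD)


def _frame_counts_and_stim(
    train: SpikeTrain, stim: StimulusTrace, label: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame spike counts and contrasts over all labelled segments/trials."""
    segs = stim.find_segments(label)
    if not segs:
        raise ValueError(f"no segment labelled {label!r}")
    counts_list, stim_list = [], []
    for k in range(train.n_trials):
        off = k * stim.duration
        for seg in segs:
            sl = stim.segment_slice(seg)
            edges = stim.times[sl.start] + off + np.arange(sl.stop - sl.start + 1) / stim.frame_rate
            c, _ = np.histogram(train.times, bins=edges)
            counts_list.append(c)
            stim_list.append(stim.contrast[sl])
    return counts_list, stim_list


def compute_sta(
    train: SpikeTrain,
    stim: StimulusTrace,
    window_s: float = DEFAULT_WINDOW_S,
    segment_label: str = "flicker",
    min_spikes: int = 100,
) -> TemporalFilter:
    """Spike-count-weighted average of the preceding stimulus window.

    Stimulus windows are weighted by the spike count of their end frame, so
    multiple spikes in one frame count multiply.  Only windows fully inside
    a flicker segment contribute.
    """
    counts_list, stim_list = _frame_counts_and_stim(train, stim, segment_label)
    n_taps = int(round(window_s * stim.frame_rate))
    acc = np.zeros(n_taps)
    c_total = 0
    for c, s in zip(counts_list, stim_list):
        if s.size < n_taps:
            continue
        X = sliding_window_view(s, n_taps)  # row i = s[i .. i+n_taps-1]
        w = c[n_taps - 1 :].astype(float)
        acc += w @ X
        c_total += int(w.sum())
    if c_total < min_spikes:
        raise ValueError(
            f"insufficient spikes for STA: {c_total} < {min_spikes} required"
        )
    sta = (acc / c_total)[::-1]  # reverse so index j = lag of j frames
    lags = (np.arange(n_taps) + 0.5) / stim.frame_rate
    p = 2.0 * norm.sf(np.abs(sta) * np.sqrt(c_total))
    return TemporalFilter(
        sta_raw=sta,
        sta_norm=sta / np.linalg.norm(sta),
        lags_s=lags,
        n_spikes=c_total,
        p_values=p,
        frame_rate=stim.frame_rate,
    )


@dataclass(frozen=True)
class KineticsFit:
    peak_latency_ms: float
    peak_frequency_hz: float
    params: tuple  # (a1, mu1, s1, a2, mu2, s2), amplitudes signed
    r2: float
    converged: bool = True

    @property
    def passes_quality(self) -> bool:
        return self.converged and self.r2 >= DOG_R2_THRESHOLD


def _dog_model(t, a1, mu1, s1, a2, mu2, s2):
    return a1 * np.exp(-0.5 * ((t - mu1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((t - mu2) / s2) ** 2
    )


def _extrema_indices(y: np.ndarray) -> np.ndarray:
    mag = np.abs(y)
    idx = np.where((mag[1:-1] >= mag[:-2]) & (mag[1:-1] >= mag[2:]))[0] + 1
    return idx[np.argsort(mag[idx])[::-1]] if idx.size else np.array([int(np.argmax(mag))])


def fit_kinetics(filt: TemporalFilter) -> KineticsFit:
    """Difference-of-Gaussians fit of the STA plus derived kinetics.

    Latency is the earliest extremum of the fitted curve exceeding 20% of
    its global extremum (evaluated on a 0.5 ms grid); the spectral peak is
    the argmax of the power spectrum of the fitted curve, zero-padded to
    4096 samples, DC excluded.
    """
    y, t = filt.sta_raw, filt.lags_s
    ext = _extrema_indices(y)
    i1 = ext[0]
    i2 = ext[1] if ext.size > 1 else min(i1 + 2, y.size - 1)
    x0 = (y[i1], t[i1], 0.015, y[i2] if ext.size > 1 else -0.3 * y[i1], t[i2], 0.02)
    lo = [-np.inf, 0.0, 0.002, -np.inf, 0.0, 0.002]
    hi = [np.inf, t[-1], 0.2, np.inf, t[-1], 0.2]
    x0 = np.clip(x0, lo, hi)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = least_squares(lambda p: _dog_model(t, *p) - y, x0, bounds=(lo, hi), max_nfev=5000)
    except Exception:
        return KineticsFit(np.nan, np.nan, (), -np.inf, converged=False)
    fit = _dog_model(t, *res.x)
    r2 = explained_variance(y, fit)
    dense_t = np.arange(0.0, t[-1], 5e-4)
    dense = _dog_model(dense_t, *res.x)
    latency_ms = 1000.0 * first_extremum_lag(dense_t, dense)
    # power spectrum of the fitted curve on a uniform 2 ms grid
    grid = np.arange(0.0, t[-1], 0.002)
    spec = np.abs(np.fft.rfft(_dog_model(grid, *res.x), n=4096)) ** 2
    freqs = np.fft.rfftfreq(4096, d=0.002)
    peak_freq = float(freqs[1:][np.argmax(spec[1:])])
    return KineticsFit(latency_ms, peak_freq, tuple(res.x), r2)


@dataclass(frozen=True)
class GainFunction:
    """Binned static nonlinearity (Bayes ratio) plus its sigmoid fit."""

    bin_centers: np.ndarray
    prior_counts: np.ndarray
    spike_counts: np.ndarray
    rate_hz: np.ndarray  # NaN where the prior bin is empty
    dt_s: float
    sigmoid: tuple[float, float, float, float]  # (floor, amp, steepness, midpoint)
    neutral_rate_hz: float
    dynamic_range_hz: float
    attenuation: float = 1.0  # estimated corr between the STA axis and the true filter

    @property
    def midpoint(self) -> float:
        return self.sigmoid[3]

    @property
    def midpoint_debiased(self) -> float:
        """Midpoint corrected for projection-axis estimation noise.

        The STA axis correlates rho < 1 with the true filter, so the
        measured transition sits at midpoint/rho (errors-in-variables
        attenuation); multiplying by the estimated rho undoes this when
        recovering a generative midpoint.
        """
        return self.sigmoid[3] * self.attenuation

    def sigmoid_rate(self, g: np.ndarray | float) -> np.ndarray | float:
        floor, amp, k, m = self.sigmoid
        return floor + amp / (1.0 + np.exp(-k * (np.asarray(g) - m)))


def estimate_gain_function(
    train: SpikeTrain,
    stim: StimulusTrace,
    filt: TemporalFilter,
    bin_width: float = GAIN_BIN_WIDTH,
    segment_label: str = "flicker",
    min_prior: int = 20,
) -> GainFunction:
    """Rate vs filter projection, estimated as a ratio of histograms.

    Projections of the stimulus history onto the normalized STA are binned
    at ``bin_width``; the rate per bin is (spike-triggered count / raw
    count) / frame interval.  A four-parameter sigmoid is fitted by least
    squares weighted by sqrt(prior count); bins with fewer than
    ``min_prior`` stimulus samples are kept in the binned curve but
    excluded from the fit, since their rate estimates are dominated by
    sampling noise.
    """
    counts_list, stim_list = _frame_counts_and_stim(train, stim, segment_label)
    n_taps = filt.sta_norm.size
    kernel = filt.sta_norm[::-1]
    g_all, c_all = [], []
    for c, s in zip(counts_list, stim_list):
        if s.size < n_taps:
            continue
        X = sliding_window_view(s, n_taps)
        g_all.append(X @ kernel)
        c_all.append(c[n_taps - 1 :].astype(float))
    g = np.concatenate(g_all)
    c = np.concatenate(c_all)
    lo = np.floor(g.min() / bin_width) * bin_width
    hi = np.ceil(g.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    prior, _ = np.histogram(g, bins=edges)
    spikes, _ = np.histogram(g, bins=edges, weights=c)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dt = 1.0 / stim.frame_rate
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(prior > 0, spikes / np.maximum(prior, 1) / dt, np.nan)
    if np.sum(prior > 0) < 5:
        raise ValueError("fewer than 5 populated projection bins")
    pop = prior >= min_prior
    if pop.sum() < 5:
        pop = prior > 0
    x, y, w = centers[pop], rate[pop], np.sqrt(prior[pop])

    def resid(p):
        floor, amp, k, m = p
        return w * (floor + amp / (1.0 + np.exp(-k * (x - m))) - y)

    ymin, yptp = float(np.min(y)), float(np.ptp(y)) or 1.0
    best = None
    for amp0 in (yptp, -yptp):
        for m0 in (-0.5, 0.0, 0.5, 1.0):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = least_squares(
                        resid,
                        (max(ymin, 0.0), amp0, 3.0, m0),
                        bounds=([0.0, -np.inf, 0.05, -10.0], [np.inf, np.inf, 100.0, 10.0]),
                        max_nfev=3000,
                    )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    floor, amp, k, m = best.x
    sig = lambda gg: floor + amp / (1.0 + np.exp(-k * (gg - m)))
    neutral = float(sig(0.0))
    span = sig(np.array([x.min(), x.max()]))
    # attenuation of the projection axis: per-tap STA noise variance is 1/C
    n_taps_f = filt.sta_raw.size
    a2 = max(float(np.sum(filt.sta_raw**2)) - n_taps_f / filt.n_spikes, 1e-12)
    rho = float(np.sqrt(a2 / (a2 + n_taps_f / filt.n_spikes)))
    return GainFunction(
        bin_centers=centers,
        prior_counts=prior,
        spike_counts=spikes,
        rate_hz=rate,
        dt_s=dt,
        sigmoid=(float(floor), float(amp), float(k), float(m)),
        neutral_rate_hz=neutral,
        dynamic_range_hz=float(abs(span[1] - span[0])),
        attenuation=rho,
    )


@dataclass(frozen=True)
class ShapeClass:
    label: str  # mono-OFF | bi-OFF | mono-ON | bi-ON
    pc1: float
    pc2: float
    variance_explained: float  # by PC1 + PC2, whole population


_FIXED_QUADRANT_LABELS = {
    (1, 1): "mono-OFF",
    (-1, 1): "bi-OFF",
    (-1, -1): "mono-ON",
    (1, -1): "bi-ON",
}


def _quadrant(s1: float, s2: float) -> tuple[int, int]:
    return (1 if s1 >= 0 else -1, 1 if s2 >= 0 else -1)


def classify_filter_shapes(
    filters: np.ndarray, frame_rate: float = 60.0
) -> list[ShapeClass]:
    """Quadrant classification of normalized STAs in the PCA biplot.

    Components are sign-oriented so that a canonical monophasic-OFF
    template scores positive on PC1 and a canonical biphasic-OFF template
    scores positive on PC2.  The quadrant-to-label map is calibrated by
    where the four canonical kernels (mono/bi x ON/OFF) themselves land in
    the oriented biplot: when the leading components align with the pure
    monophasic and biphasic shapes this reduces to the fixed map
    (I: mono-OFF, II: bi-OFF, III: mono-ON, IV: bi-ON), and when the
    components mix the two correlated shape axes the calibrated map keeps
    the labels attached to the correct archetypes.
    """
    filters = np.asarray(filters, dtype=float)
    if filters.ndim != 2 or filters.shape[0] < 10:
        raise ValueError("need at least 10 filters")
    if np.allclose(np.var(filters, axis=0), 0.0):
        raise ValueError("degenerate population: identical filters")
    pca = PCA(n_components=2).fit(filters)
    var2 = float(np.sum(pca.explained_variance_ratio_[:2]))
    window_s = filters.shape[1] / frame_rate
    mono_on, _ = dog_filter(frame_rate, 0.06, 0.15, sign=+1, window_s=window_s)
    bi_on, _ = dog_filter(frame_rate, 0.05, 0.85, sign=+1, window_s=window_s)
    comps = pca.components_.copy()
    if -mono_on @ comps[0] < 0:  # canonical mono-OFF on the positive PC1 side
        comps[0] = -comps[0]
    if -bi_on @ comps[1] < 0:  # canonical bi-OFF on the positive PC2 side
        comps[1] = -comps[1]
    templates = {
        "mono-ON": mono_on,
        "mono-OFF": -mono_on,
        "bi-ON": bi_on,
        "bi-OFF": -bi_on,
    }
    tmpl_quadrants = {
        label: _quadrant(*((t - pca.mean_) @ comps.T)) for label, t in templates.items()
    }
    if len(set(tmpl_quadrants.values())) == 4:
        quadrant_labels = {q: label for label, q in tmpl_quadrants.items()}
    else:
        quadrant_labels = _FIXED_QUADRANT_LABELS
    scores = (filters - pca.mean_) @ comps.T
    return [
        ShapeClass(quadrant_labels[_quadrant(s1, s2)], float(s1), float(s2), var2)
        for s1, s2 in scores
    ]
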