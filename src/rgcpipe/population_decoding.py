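"""Optimal linear stimulus reconstruction from population spike trains.

The decoder estimates the flickering stimulus at each 16.7 ms bin from the
binned spike counts of every cell over a causal 333 ms window (20 lag bins,
the response following the stimulus), by ordinary least squares.
Performance is the Pearson correlation R between the presented and
reconstructed stimulus over concatenated held-out predictions of a 10-fold
cross-validation with contiguous time blocks.  Across populations of
different sizes, R(n) is summarized by the saturating exponential
f(n) = 1 - (1 - a) * exp(-(n - 1)/b), where a = f(1) is the single-cell
performance and b the saturation constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .protocols import StimulusTrace
from .synthdata import SpikeTrain, SyntheticSession

__all__ = [
    "DecoderModel",
    "SaturationFit",
    "build_design",
    "fit_linear_decoder",
    "evaluate_decoding_cv",
    "decoding_vs_population_size",
    "fit_saturation_curve",
    "N_LAGS",
]

N_LAGS = 20  # 333 ms window at 16.7 ms bins
DECODER_BIN_S = 1 / 60.0


@dataclass(frozen=True)
class DecoderModel:
    weights: np.ndarray  # (n_cells * n_lags + 1,), intercept last
    n_cells: int
    n_lags: int
    fold: int = -1


def _binned_counts(
    trains: list[np.ndarray], t0: float, t1: float, bin_s: float
) -> np.ndarray:
    n = int(np.floor((t1 - t0) / bin_s))
    edges = t0 + np.arange(n + 1) * bin_s
    return np.stack([np.histogram(t, bins=edges)[0] for t in trains]).T.astype(float)


def build_design(
    counts: np.ndarray, n_lags: int = N_LAGS
) -> tuple[np.ndarray, slice]:
    """Lagged design matrix: row t holds counts at t .. t+n_lags-1 per cell.

    Returns the (n_valid, n_cells*n_lags) matrix and the slice of stimulus
    bins it predicts (the last n_lags-1 bins have incomplete windows and
    are dropped).
    """
    n_bins, n_cells = counts.shape
    n_valid = n_bins - n_lags + 1
    if n_valid < 1:
        raise ValueError("fewer time bins than decoder lags")
    cols = [counts[j : j + n_valid, i] for i in range(n_cells) for j in range(n_lags)]
    return np.stack(cols, axis=1), slice(0, n_valid)


def fit_linear_decoder(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares weights (with intercept); minimum-norm if rank deficient."""
    A = np.column_stack([X, np.ones(X.shape[0])])
    w, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn("rank-deficient decoder design; minimum-norm solution used")
    return w


def _session_counts_and_stim(
    session: SyntheticSession | tuple,
    cells: np.ndarray | None,
    segment_label: str,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(session, SyntheticSession):
        stim: StimulusTrace = session.stim
        trains = [tr.times for tr in session.trains]
    else:
        stim, spike_trains = session
        trains = [tr.times if isinstance(tr, SpikeTrain) else np.asarray(tr) for tr in spike_trains]
    if cells is not None:
        trains = [trains[i] for i in cells]
    segs = stim.find_segments(segment_label)
    if not segs:
        raise ValueError(f"no segment labelled {segment_label!r}")
    seg = segs[0]
    sl = stim.segment_slice(seg)
    counts = _binned_counts(trains, seg.start_s, seg.end_s, 1.0 / stim.frame_rate)
    y = stim.contrast[sl][: counts.shape[0]]
    return counts, y


def evaluate_decoding_cv(
    session: SyntheticSession | tuple,
    folds: int = 10,
    seed: int = 0,
    cells: np.ndarray | None = None,
    n_lags: int = N_LAGS,
    segment_label: str = "flicker",
) -> float:
    """Cross-validated Pearson R between presented and estimated stimulus.

    Folds are contiguous blocks of time bins; the decoder is refit on each
    training set and R is computed once over the concatenated out-of-fold
    predictions.
    """
    counts, y_full = _session_counts_and_stim(session, cells, segment_label)
    X, sl = build_design(counts, n_lags)
    y = y_full[sl]
    n = X.shape[0]
    if np.std(y) == 0:
        raise ValueError("constant stimulus: correlation undefined")
    if n < folds * 10:
        raise ValueError("need at least 10 usable bins per fold")
    bounds = np.linspace(0, n, folds + 1).astype(int)
    y_hat = np.empty(n)
    for k in range(folds):
        test = slice(bounds[k], bounds[k + 1])
        train_idx = np.r_[0 : bounds[k], bounds[k + 1] : n]
        w = fit_linear_decoder(X[train_idx], y[train_idx])
        y_hat[test] = X[test] @ w[:-1] + w[-1]
    return float(np.corrcoef(y, y_hat)[0, 1])


def decoding_vs_population_size(
    session: SyntheticSession | tuple,
    sizes: list[int],
    reps: int = 3,
    seed: int = 0,
    folds: int = 10,
    n_lags: int = N_LAGS,
) -> list[tuple[int, float]]:
    """Mean cross-validated R over random cell subsets of each size."""
    if isinstance(session, SyntheticSession):
        n_avail = session.n_cells
    else:
        n_avail = len(session[1])
    rng = np.random.default_rng(seed)
    points = []
    for n in sizes:
        if n > n_avail:
            raise ValueError(f"requested {n} cells, only {n_avail} available")
        rs = []
        for _ in range(reps if n < n_avail else 1):
            cells = rng.choice(n_avail, size=n, replace=False)
            rs.append(evaluate_decoding_cv(session, folds, seed, cells, n_lags))
        points.append((n, float(np.mean(rs))))
    return points


@dataclass(frozen=True)
class SaturationFit:
    a: float  # single-cell performance, f(1)
    b: float  # saturation constant (cells)
    a_ci: tuple[float, float]
    b_ci: tuple[float, float]
    converged: bool = True

    def __call__(self, n: np.ndarray | float) -> np.ndarray | float:
        return 1.0 - (1.0 - self.a) * np.exp(-(np.asarray(n) - 1.0) / self.b)


def fit_saturation_curve(points: list[tuple[int, float]]) -> SaturationFit:
    """Fit f(n) = 1 - (1-a) exp(-(n-1)/b) to (population size, R) points."""
    pts = np.asarray(points, dtype=float)
    n, r = pts[:, 0], pts[:, 1]
    if np.unique(n).size < 3:
        raise ValueError("need at least 3 distinct population sizes")

    def f(n_, a, b):
        return 1.0 - (1.0 - a) * np.exp(-(n_ - 1.0) / b)

    a0 = float(np.clip(r[np.argmin(n)], 0.01, 0.99))
    b0 = max(float(n.max()) / 3.0, 1.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                f, n, r, p0=(a0, b0), bounds=([0.0, 1e-6], [1.0, 1e6]), maxfev=10000
            )
    except Exception:
        return SaturationFit(np.nan, np.nan, (np.nan, np.nan), (np.nan, np.nan), False)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    a, b = popt
    return SaturationFit(
        float(a),
        float(b),
        (float(a - 1.96 * se[0]), float(a + 1.96 * se[0])),
        (float(b - 1.96 * se[1]), float(b + 1.96 * se[1])),
    )
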