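"""Curve fits to sinusoidal-flicker responses.

Responses to a full-contrast sinusoid at frequency ``h`` are fitted with an
even power of sine,

    s(t) = A * sin^q(pi*h*t - phi/2) + B,      q = 2n, n in 1..10,

whose phase ``phi`` locates the response peak relative to the stimulus
cycle (phi = -pi/2: peak at the brightest stimulus; +pi/2: at the darkest).
Responses to the amplitude-ramp protocol get the same oscillation under a
sigmoid envelope,

    S(t) = A / (1 + exp(-lam*(t - t0))) * sin^q(pi*h*t - phi/2) + B,

from which contrast sensitivity summaries are derived: the evoked response
at 10% contrast and the midpoint slope |A*lam/4|.  Fit quality is the
explained variance R^2 = 1 - var(data - fit)/var(data); cells pass at
R^2 >= 0.2.  The exponent is chosen by grid search with the continuous
parameters refit for each q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.cluster import KMeans
from statsmodels.stats.proportion import proportions_ztest

from .response_metrics import TrialEnsemble

__all__ = [
    "SineFit",
    "RampFit",
    "PhaseClusters",
    "explained_variance",
    "fit_fixed_frequency_response",
    "frequency_tuning_summary",
    "fit_contrast_ramp_response",
    "cluster_response_phase",
    "FIT_R2_THRESHOLD",
]

FIT_R2_THRESHOLD = 0.2

_N_GRID = range(1, 11)  # exponent q = 2n


def _wrap_phase(phi: float) -> float:
    return float((phi + np.pi) % (2.0 * np.pi) - np.pi)


def explained_variance(data: np.ndarray, fit: np.ndarray) -> float:
    """R^2 = 1 - var(data - fit)/var(data); negative values are kept."""
    v = np.var(data)
    if v == 0.0:
        return 0.0 if np.var(data - fit) == 0.0 else -np.inf
    return float(1.0 - np.var(data - fit) / v)


@dataclass(frozen=True)
class SineFit:
    A: float
    B: float
    q: int
    phi: float
    h: float
    r2: float
    converged: bool = True


@dataclass(frozen=True)
class RampFit(SineFit):
    t0_s: float = float("nan")
    lam: float = float("nan")
    ramp_duration_s: float = float("nan")
    a_ci_low: float = float("nan")
    a_ci_high: float = float("nan")

    @property
    def t0_contrast_pct(self) -> float:
        return 100.0 * self.t0_s / self.ramp_duration_s

    @property
    def evoked_at_10pct(self) -> float:
        t10 = 0.1 * self.ramp_duration_s
        return abs(self.A) / (1.0 + np.exp(-self.lam * (t10 - self.t0_s)))

    @property
    def midpoint_slope_hz_per_s(self) -> float:
        return abs(self.A * self.lam) / 4.0

    @property
    def midpoint_slope_hz_per_pct(self) -> float:
        # the ramp traverses 100% contrast in ramp_duration seconds
        return self.midpoint_slope_hz_per_s * self.ramp_duration_s / 100.0

    @property
    def off_suppressive(self) -> bool:
        """Significantly negative amplitude (95% CI entirely below zero)."""
        return bool(self.a_ci_high < 0.0)


def _sine_model(t, A, B, phi, q, h):
    return A * np.sin(np.pi * h * t - phi / 2.0) ** q + B


def _fit_for_q(t, y, q, h, model, x0_list, bounds):
    best = None
    for x0 in x0_list:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = least_squares(
                    lambda p: model(t, *p, q, h) - y, x0, bounds=bounds, max_nfev=2000
                )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best


def fit_fixed_frequency_response(psth: TrialEnsemble, h: float) -> SineFit:
    """Fit the even-power-of-sine model to a PSTH at stimulus frequency h.

    The exponent grid n = 1..10 is scanned with (A, B, phi) refit per n;
    the returned fit maximizes R^2 on the trial-mean PSTH.  A failed fit at
    every n returns ``converged=False`` with ``r2 = -inf``.
    """
    y = psth.psth()
    t = (np.arange(y.size) + 0.5) * psth.bin_s
    if t[-1] - t[0] < 1.0 / h:
        raise ValueError("PSTH must cover at least one full stimulus period")
    a0 = float(np.ptp(y)) or 1.0
    b0 = float(np.maximum(y.min(), 0.0))
    phis = np.linspace(-np.pi, np.pi, 6, endpoint=False)
    x0_list = [(s * a0, b0, p) for p in phis for s in (1.0, -1.0)]
    bounds = ([-np.inf, 0.0, -2.0 * np.pi], [np.inf, np.inf, 2.0 * np.pi])
    best_fit, best_r2 = None, -np.inf
    for n in _N_GRID:
        res = _fit_for_q(t, y, 2 * n, h, _sine_model, x0_list, bounds)
        if res is None:
            continue
        r2 = explained_variance(y, _sine_model(t, *res.x, 2 * n, h))
        if r2 > best_r2:
            best_r2 = r2
            A, B, phi = res.x
            best_fit = SineFit(float(A), float(B), 2 * n, _wrap_phase(phi), h, r2)
        if best_r2 > 1.0 - 1e-9:
            break
    if best_fit is None:
        return SineFit(np.nan, np.nan, 2, np.nan, h, -np.inf, converged=False)
    return best_fit


def _ramp_model(t, A, B, phi, t0, lam, q, h):
    z = np.clip(-lam * (t - t0), -700.0, 700.0)
    return A / (1.0 + np.exp(z)) * np.sin(np.pi * h * t - phi / 2.0) ** q + B


def fit_contrast_ramp_response(
    psth: TrialEnsemble, h: float, ramp_duration: float
) -> RampFit:
    """Fit the sigmoid-envelope oscillation to a ramp-aligned PSTH.

    Joint nonlinear least squares over (A, B, phi, t0, lam) with the
    exponent on a grid; the 95% CI of the amplitude comes from the
    asymptotic covariance of the best fit.  ``t`` is local to the ramp
    start, so ``t0`` maps to contrast as 100 * t0 / ramp_duration %.
    """
    y = psth.psth()
    t = (np.arange(y.size) + 0.5) * psth.bin_s
    a0 = float(np.ptp(y)) or 1.0
    b0 = float(np.median(y))
    phis = np.linspace(-np.pi, np.pi, 4, endpoint=False)
    x0_list = [
        (s * a0, b0, p, 0.6 * ramp_duration, 0.5) for p in phis for s in (1.0, -1.0)
    ]
    bounds = (
        [-np.inf, 0.0, -2.0 * np.pi, 0.0, 1e-3],
        [np.inf, np.inf, 2.0 * np.pi, 2.0 * ramp_duration, 100.0],
    )
    best_res, best_r2, best_q = None, -np.inf, 2
    for n in _N_GRID:
        res = _fit_for_q(t, y, 2 * n, h, _ramp_model, x0_list, bounds)
        if res is None:
            continue
        r2 = explained_variance(y, _ramp_model(t, *res.x, 2 * n, h))
        if r2 > best_r2:
            best_res, best_r2, best_q = res, r2, 2 * n
        if best_r2 > 1.0 - 1e-9:
            break
    if best_res is None:
        return RampFit(np.nan, np.nan, 2, np.nan, h, -np.inf, converged=False)
    A, B, phi, t0, lam = best_res.x
    # asymptotic covariance of the amplitude
    dof = max(y.size - 5, 1)
    s2 = 2.0 * best_res.cost / dof
    J = best_res.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se_a = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se_a = float("inf")
    return RampFit(
        float(A),
        float(B),
        best_q,
        _wrap_phase(phi),
        h,
        best_r2,
        True,
        t0_s=float(t0),
        lam=float(lam),
        ramp_duration_s=float(ramp_duration),
        a_ci_low=float(A - 1.96 * se_a),
        a_ci_high=float(A + 1.96 * se_a),
    )


def frequency_tuning_summary(
    r2_by_condition: dict[str, dict[float, list[float]]],
    threshold: float = FIT_R2_THRESHOLD,
) -> dict:
    """Responsive fractions per (condition, frequency) + two-proportion z-tests.

    ``r2_by_condition[condition][h]`` is the list of per-cell fit R^2 at
    stimulus frequency ``h``.  Conditions with no cells are dropped with a
    warning; pairwise tests are only run when >= 2 conditions remain.
    """
    fractions: dict[str, dict[float, tuple[float, int]]] = {}
    for cond, by_h in r2_by_condition.items():
        if not by_h or all(len(v) == 0 for v in by_h.values()):
            warnings.warn(f"condition {cond!r} has no cells; excluded")
            continue
        fractions[cond] = {
            h: (float(np.mean(np.asarray(v) >= threshold)), len(v))
            for h, v in by_h.items()
            if len(v)
        }
    tests = {}
    conds = sorted(fractions)
    for i, c1 in enumerate(conds):
        for c2 in conds[i + 1 :]:
            for h in sorted(set(fractions[c1]) & set(fractions[c2])):
                f1, n1 = fractions[c1][h]
                f2, n2 = fractions[c2][h]
                count = np.array([round(f1 * n1), round(f2 * n2)])
                nobs = np.array([n1, n2])
                stat, p = proportions_ztest(count, nobs)
                tests[(c1, c2, h)] = (float(stat), float(p))
    return {"fractions": fractions, "tests": tests}


@dataclass(frozen=True)
class PhaseClusters:
    assignments: np.ndarray  # 0 = ON-like (negative mean phase), 1 = OFF-like
    mean_phase: tuple[float, float]
    degenerate: bool


def cluster_response_phase(phis: np.ndarray, seed: int = 0) -> PhaseClusters:
    """k-means (k=2) on phases embedded on the unit circle.

    The cluster whose circular mean phase is negative is labelled ON-like
    (cluster 0).  Fewer than two distinct phases yields a degenerate result.
    """
    phis = np.asarray(phis, dtype=float)
    if phis.size < 2:
        raise ValueError("need at least 2 cells")
    pts = np.column_stack([np.cos(phis), np.sin(phis)])
    if np.unique(np.round(pts, 12), axis=0).shape[0] < 2:
        mu = float(np.arctan2(np.sin(phis).mean(), np.cos(phis).mean()))
        return PhaseClusters(np.zeros(phis.size, dtype=int), (mu, mu), True)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(pts)
    labels = km.labels_
    means = []
    for c in (0, 1):
        sel = phis[labels == c]
        means.append(float(np.arctan2(np.sin(sel).mean(), np.cos(sel).mean())))
    if means[0] > means[1]:  # order clusters: ON-like (negative phase) first
        labels = 1 - labels
        means = means[::-1]
    return PhaseClusters(labels, (means[0], means[1]), False)
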