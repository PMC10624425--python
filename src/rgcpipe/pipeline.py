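"""End-to-end orchestration: simulate, analyze, classify, compare.

``run_pipeline`` drives one synthetic session per condition through every
analysis stage — response indices on the contrast-inversion epochs, flicker
curve fits, reverse-correlation LN estimation, single-spike information,
rate/latency coding models, and population decoding — and assembles one
row per cell plus session-level decoding summaries.

Cell classification follows the in vivo scheme: cells with SNR below
threshold are 'N/A'; reliable cells are ON / OFF / ON-OFF by the ON-OFF
index (thresholds +-0.25); ON cells whose ramp-fit amplitude is
significantly negative (95% CI) are flagged OFF-suppressive; DS/OS flags
require index > 0.15 with bootstrap p < 0.2.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from . import (
    coding_models,
    flicker_analysis,
    information,
    population_decoding,
    protocols,
    response_metrics,
    reverse_correlation,
    synthdata,
)
from .flicker_analysis import FIT_R2_THRESHOLD
from .response_metrics import (
    DSOS_INDEX_THRESHOLD,
    DSOS_P_THRESHOLD,
    ON_OFF_THRESHOLD,
    SNR_THRESHOLD,
)

__all__ = ["PipelineConfig", "CellReport", "classify_cell", "run_pipeline", "compare_conditions"]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and protocol sizes for one pipeline run."""

    condition: str = "awake"
    n_cells: int = 30
    seed: int = 0
    flicker_duration_s: float = 300.0
    ramp_trials: int = 10
    freq_trials: int = 10
    direction_trials: int = 5
    snr_threshold: float = SNR_THRESHOLD
    on_off_threshold: float = ON_OFF_THRESHOLD
    dsos_index_threshold: float = DSOS_INDEX_THRESHOLD
    dsos_p_threshold: float = DSOS_P_THRESHOLD
    fit_r2_threshold: float = FIT_R2_THRESHOLD
    sta_p_threshold: float = reverse_correlation.STA_P_THRESHOLD
    dog_r2_threshold: float = reverse_correlation.DOG_R2_THRESHOLD
    decode_sizes: tuple[int, ...] = ()  # empty: {1, 2, 4, ... n_cells}
    noise_corr: float = 0.0


@dataclass
class CellReport:
    unit_id: str
    condition: str
    snr: float = np.nan
    on_off_index: float = np.nan
    polarity: str = "N/A"
    off_suppressive: bool = False
    ds_index: float = np.nan
    p_ds: float = np.nan
    os_index: float = np.nan
    p_os: float = np.nan
    is_ds: bool = False
    is_os: bool = False
    freq_r2: dict = field(default_factory=dict)
    ramp_A: float = np.nan
    ramp_B: float = np.nan
    ramp_phi: float = np.nan
    ramp_t0_s: float = np.nan
    ramp_lam: float = np.nan
    ramp_r2: float = np.nan
    sta_ok: bool = False
    latency_ms: float = np.nan
    peak_freq_hz: float = np.nan
    dog_r2: float = np.nan
    neutral_rate_hz: float = np.nan
    gain_midpoint: float = np.nan
    dynamic_range_hz: float = np.nan
    shape_class: str = ""
    mean_rate_hz: float = np.nan
    bits_per_spike: float = np.nan
    bits_per_second: float = np.nan
    rate_code_bits: float = np.nan
    latency_code_bits: float = np.nan


def classify_cell(
    snr: float,
    on_off_index: float | None,
    ramp_fit: flicker_analysis.RampFit | None = None,
    selectivity: response_metrics.SelectivityResult | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Deterministic label assignment from the per-cell metrics."""
    out = {"polarity": "N/A", "off_suppressive": False, "is_ds": False, "is_os": False}
    if not np.isfinite(snr):
        out["reason"] = "missing SNR"
        return out
    if snr >= config.snr_threshold and on_off_index is not None:
        if on_off_index > config.on_off_threshold:
            out["polarity"] = "ON"
        elif on_off_index < -config.on_off_threshold:
            out["polarity"] = "OFF"
        else:
            out["polarity"] = "ON/OFF"
        if (
            out["polarity"] == "ON"
            and ramp_fit is not None
            and ramp_fit.converged
            and ramp_fit.off_suppressive
        ):
            out["off_suppressive"] = True
    if selectivity is not None:
        out["is_ds"] = (
            selectivity.ds_index > config.dsos_index_threshold
            and selectivity.p_ds < config.dsos_p_threshold
        )
        out["is_os"] = (
            selectivity.os_index > config.dsos_index_threshold
            and selectivity.p_os < config.dsos_p_threshold
        )
    return out


def _analyze_cell(
    i: int,
    neuron: synthdata.LNNeuron,
    cfg: PipelineConfig,
    flicker: protocols.StimulusTrace,
    ramp: protocols.StimulusTrace,
    freq: protocols.StimulusTrace,
    dirs: protocols.DirectionProtocol,
    rng: np.random.Generator,
    flicker_train: synthdata.SpikeTrain,
) -> tuple[CellReport, np.ndarray | None]:
    rep = CellReport(unit_id=f"u{i:03d}", condition=cfg.condition)
    rep.mean_rate_hz = flicker_train.mean_rate()

    # --- inversion + ramp protocol ---------------------------------------
    ramp_train = synthdata.simulate_spike_train(
        neuron, ramp, n_trials=cfg.ramp_trials, seed=int(rng.integers(2**31))
    )
    ens_onoff = response_metrics.trial_ensemble_from_train(
        ramp_train, ramp, "on", window=(0.0, 4.0)
    )  # ON + second OFF, contiguous 4 s
    try:
        rep.snr = response_metrics.compute_snr(ens_onoff)
    except ValueError:
        rep.snr = np.nan
    r_on = response_metrics.trial_ensemble_from_train(ramp_train, ramp, "on").psth().mean()
    r_off = response_metrics.trial_ensemble_from_train(ramp_train, ramp, "off2").psth().mean()
    rep.on_off_index = response_metrics.compute_on_off_index(r_on, r_off)
    ens_ramp = response_metrics.trial_ensemble_from_train(ramp_train, ramp, "ramp")
    rfit = flicker_analysis.fit_contrast_ramp_response(ens_ramp, 1.5, 10.0)
    if rfit.converged:
        rep.ramp_A, rep.ramp_B = rfit.A, rfit.B
        rep.ramp_phi, rep.ramp_t0_s = rfit.phi, rfit.t0_s
        rep.ramp_lam, rep.ramp_r2 = rfit.lam, rfit.r2

    # --- frequency series -------------------------------------------------
    freq_train = synthdata.simulate_spike_train(
        neuron, freq, n_trials=cfg.freq_trials, seed=int(rng.integers(2**31))
    )
    for seg in freq.segments:
        if not seg.label.startswith("freq_"):
            continue
        h = float(seg.label.split("_")[1])
        ens = response_metrics.trial_ensemble_from_train(freq_train, freq, seg.label)
        sfit = flicker_analysis.fit_fixed_frequency_response(ens, h)
        rep.freq_r2[h] = sfit.r2

    # --- direction protocol ----------------------------------------------
    dir_rates = synthdata.simulate_direction_trials(
        neuron, dirs, seed=int(rng.integers(2**31))
    )
    sel = None
    if dir_rates.sum() > 0:
        sel = response_metrics.compute_selectivity(
            dir_rates, np.asarray(dirs.directions), seed=int(rng.integers(2**31))
        )
        rep.ds_index, rep.p_ds = sel.ds_index, sel.p_ds
        rep.os_index, rep.p_os = sel.os_index, sel.p_os

    # --- reverse correlation + information + coding models ----------------
    gain_callable = neuron.gain
    filter_taps = neuron.filter
    sta_norm = None
    try:
        filt = reverse_correlation.compute_sta(flicker_train, flicker)
        kin = reverse_correlation.fit_kinetics(filt)
        rep.dog_r2 = kin.r2
        if filt.significant and kin.passes_quality:
            rep.sta_ok = True
            rep.latency_ms = kin.peak_latency_ms
            rep.peak_freq_hz = kin.peak_frequency_hz
            gf = reverse_correlation.estimate_gain_function(flicker_train, flicker, filt)
            rep.neutral_rate_hz = gf.neutral_rate_hz
            rep.gain_midpoint = gf.midpoint
            rep.dynamic_range_hz = gf.dynamic_range_hz
            gain_callable = gf.sigmoid_rate
            filter_taps = filt.sta_norm
            sta_norm = filt.sta_norm
    except ValueError:
        pass
    try:
        est = information.extrapolate_information(flicker_train)
        rep.bits_per_spike = est.bits_per_spike
        rep.bits_per_second = est.bits_per_second
    except ValueError:
        pass
    steps = coding_models.simulate_step_responses(
        filter_taps, gain_callable, frame_rate=flicker.frame_rate
    )
    rep.rate_code_bits = coding_models.rate_code_information(steps).bits
    rep.latency_code_bits = coding_models.latency_code_information(
        steps, seed=int(rng.integers(2**31))
    ).bits

    labels = classify_cell(
        rep.snr,
        rep.on_off_index,
        rfit if rfit.converged else None,
        sel,
        cfg,
    )
    rep.polarity = labels["polarity"]
    rep.off_suppressive = labels["off_suppressive"]
    rep.is_ds, rep.is_os = labels["is_ds"], labels["is_os"]
    return rep, sta_norm


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate one session and run every analysis stage.

    Returns a dict with the per-cell report table (DataFrame), the
    decoding points and saturation fit, and the session itself; optionally
    writes CSV tables plus a JSON run manifest to ``out_dir``.
    """
    rng = np.random.default_rng(cfg.seed)
    preset = synthdata.make_condition_preset(cfg.condition)
    flicker = protocols.make_random_flicker(60.0, cfg.flicker_duration_s, seed=cfg.seed)
    ramp = protocols.make_contrast_ramp_flicker()
    freq = protocols.make_frequency_series()
    dirs = protocols.make_direction_protocol(cfg.direction_trials, seed=cfg.seed)
    session = synthdata.simulate_population_session(
        cfg.n_cells, flicker, preset, noise_corr=cfg.noise_corr, seed=cfg.seed
    )
    reports, stas = [], []
    for i, (neuron, train) in enumerate(zip(session.neurons, session.trains)):
        rep, sta_norm = _analyze_cell(
            i, neuron, cfg, flicker, ramp, freq, dirs, rng, train
        )
        reports.append(rep)
        stas.append(sta_norm)
    # population-level filter-shape classification
    ok = [(r, s) for r, s in zip(reports, stas) if s is not None]
    if len(ok) >= 10:
        shapes = reverse_correlation.classify_filter_shapes(
            np.vstack([s for _, s in ok])
        )
        for (r, _), sh in zip(ok, shapes):
            r.shape_class = sh.label
    # decoding
    sizes = list(cfg.decode_sizes)
    if not sizes:
        sizes = sorted(s for s in {1, 2, 4, 8, 16, cfg.n_cells} if s <= cfg.n_cells)
    points = population_decoding.decoding_vs_population_size(
        session, sizes, reps=2, seed=cfg.seed
    )
    sat = (
        population_decoding.fit_saturation_curve(points)
        if len({n for n, _ in points}) >= 3
        else None
    )
    rows = []
    for r in reports:
        d = dataclasses.asdict(r)
        freq_r2 = d.pop("freq_r2")
        for h, v in freq_r2.items():
            d[f"r2_at_{h:g}hz"] = v
        rows.append(d)
    table = pd.DataFrame(rows)
    result = {
        "cells": table,
        "decoding_points": points,
        "saturation": sat,
        "session": session,
        "config": cfg,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / f"cells_{cfg.condition}.csv", index=False)
        pd.DataFrame(points, columns=["n_cells", "r_cv"]).to_csv(
            out / f"decoding_{cfg.condition}.csv", index=False
        )
        manifest = dataclasses.asdict(cfg)
        manifest["saturation"] = (
            {"a": sat.a, "b": sat.b} if sat is not None and sat.converged else None
        )
        (out / f"manifest_{cfg.condition}.json").write_text(json.dumps(manifest, indent=2))
    return result


def _bonferroni(p: float, m: int) -> float:
    return float(min(p * m, 1.0))


def compare_conditions(reports: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise cross-condition statistics on the per-cell tables.

    Mann-Whitney U for baselines, amplitudes and sigmoid midpoints; t-test
    for phases and latencies; t-test on log rates for mean firing rates
    (zero-rate cells dropped with a count); two-proportion z-test for
    responsive fractions.  Bonferroni correction is applied within each
    quantity family across condition pairs.
    """
    conds = sorted(reports)
    if len(conds) < 2:
        return pd.DataFrame(
            columns=["quantity", "cond_a", "cond_b", "test", "stat", "p", "p_corrected", "note"]
        )
    pairs = [(a, b) for i, a in enumerate(conds) for b in conds[i + 1 :]]
    quantities = [
        ("ramp_B", "utest"),
        ("ramp_A_abs", "utest"),
        ("gain_midpoint", "utest"),
        ("ramp_phi", "ttest"),
        ("latency_ms", "ttest"),
        ("mean_rate_hz", "ttest_log"),
        ("bits_per_spike", "utest"),
        ("sta_ok_fraction", "ztest"),
    ]
    rows = []
    for quantity, test in quantities:
        family = []
        for a, b in pairs:
            ta, tb = reports[a], reports[b]
            note = ""
            try:
                if quantity == "ramp_A_abs":
                    xa, xb = np.abs(ta["ramp_A"].dropna()), np.abs(tb["ramp_A"].dropna())
                elif quantity == "sta_ok_fraction":
                    xa, xb = ta["sta_ok"], tb["sta_ok"]
                else:
                    xa, xb = ta[quantity].dropna(), tb[quantity].dropna()
                if test == "ztest":
                    stat, p = proportions_ztest(
                        np.array([xa.sum(), xb.sum()]), np.array([len(xa), len(xb)])
                    )
                elif len(xa) < 3 or len(xb) < 3:
                    raise ValueError("insufficient n")
                elif test == "utest":
                    stat, p = stats.mannwhitneyu(xa, xb)
                elif test == "ttest_log":
                    n_drop = int((xa <= 0).sum() + (xb <= 0).sum())
                    if n_drop:
                        note = f"{n_drop} zero-rate cells dropped"
                    stat, p = stats.ttest_ind(np.log(xa[xa > 0]), np.log(xb[xb > 0]))
                else:
                    stat, p = stats.ttest_ind(xa, xb)
            except (ValueError, KeyError) as e:
                family.append((quantity, a, b, test, np.nan, np.nan, str(e)))
                continue
            family.append((quantity, a, b, test, float(stat), float(p), note))
        m = sum(1 for f in family if np.isfinite(f[5]))
        for quantity_, a, b, test_, stat, p, note in family:
            rows.append(
                {
                    "quantity": quantity_,
                    "cond_a": a,
                    "cond_b": b,
                    "test": test_,
                    "stat": stat,
                    "p": p,
                    "p_corrected": _bonferroni(p, m) if np.isfinite(p) else np.nan,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)
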