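"""Multi-arm experiment runner and the statistical comparison procedure.

One experiment sweeps a grid of breathing waveforms, repeats each a fixed
number of times (three, mirroring the study's acquisition protocol),
simulates trace + list-mode events per scan, gates with both methods,
scores breathing-regularity metrics (tvar, overlap, R), optionally pushes
every scan through the phantom arms and IQ scoring, and then applies the
comparison procedure: a Kruskal-Wallis omnibus per metric, gatekept
pairwise tests (Wilcoxon signed-rank for ordinal-like metrics, paired t for
liver noise) with Bonferroni correction, an overlap-on-tvar regression, and
a tvar-threshold stratification (default 1.5, boundary to "regular").
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cycles import analyze_trace
from .gating import compute_overlap, compute_r_value, gate_method1_qpg, gate_method2_adaptive
from .iq_metrics import analyze_image_quality, liver_snr
from .listmode import simulate_events
from .phantom_sim import PhantomSpec, ReconArmSpec, build_static_phantom, simulate_arm
from .waveform import IRREGULAR_WAVEFORM, TYPICAL_WAVEFORM, WaveformParams, simulate_trace

logger = logging.getLogger(__name__)

DEFAULT_TVAR_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.05


class HarnessError(ValueError):
    """Experiment configuration or execution failure."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Sweep definition: waveforms x repeats x reconstruction arms."""

    waveforms: tuple[WaveformParams, ...] = (TYPICAL_WAVEFORM, IRREGULAR_WAVEFORM)
    arms: tuple[ReconArmSpec, ...] = ()
    n_repeats: int = 3
    seed: int = 0
    event_rate: float = 1000.0
    duty_fraction: float = 0.5
    offset_fraction: float = 0.3
    tvar_threshold: float = DEFAULT_TVAR_THRESHOLD
    include_iq: bool = True
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    liver_voi_center_mm: tuple[float, float, float] = (0.0, -112.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise HarnessError("n_repeats must be >= 1")
        if self.include_iq and len(self.arms) < 2:
            raise HarnessError("need at least 2 arms for an IQ comparison")
        if not self.waveforms:
            raise HarnessError("need at least one waveform")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


@dataclass(frozen=True)
class StatResult:
    """Omnibus p plus (possibly gatekept-out) adjusted pairwise p-values."""

    omnibus_p: float
    pairwise: dict[tuple[str, str], tuple[float, float]]  # (raw, adjusted)
    family_size: int
    gatekept: bool


@dataclass(frozen=True)
class ComparisonReport:
    """Aggregated experiment output."""

    scans: pd.DataFrame
    metrics: Optional[pd.DataFrame]
    liver: Optional[pd.DataFrame]
    stats: dict
    regression: Optional[RegressionResult]
    stratified: dict
    config: ExperimentConfig


def bonferroni(p: float, family_size: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p x family size)."""
    if family_size < 1:
        raise HarnessError("family_size must be >= 1")
    return min(1.0, p * family_size)


def omnibus_then_pairwise(
    samples: Mapping[str, np.ndarray],
    paired: bool = True,
    family_size: Optional[int] = None,
    alpha: float = DEFAULT_ALPHA,
    gatekeeping: bool = True,
    pairwise_test: str = "wilcoxon",
) -> StatResult:
    """Kruskal-Wallis omnibus followed by gatekept pairwise comparisons.

    Pairwise tests (exact-where-possible Wilcoxon signed-rank, or paired t)
    run only when the omnibus is significant at ``alpha`` — the "where
    indicated" rule; set ``gatekeeping=False`` to force them.  Raw pairwise
    p-values are Bonferroni-adjusted over ``family_size`` (default: the
    number of pairs tested).
    """
    if len(samples) < 2:
        raise HarnessError("need at least 2 arms")
    if pairwise_test not in ("wilcoxon", "ttest"):
        raise HarnessError("pairwise_test must be 'wilcoxon' or 'ttest'")
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if any(len(v) < 2 for v in arrays.values()):
        raise HarnessError("each arm needs at least 2 observations")
    if paired and len({len(v) for v in arrays.values()}) != 1:
        raise HarnessError("paired comparison needs equal-length samples")
    try:
        omnibus_p = float(stats.kruskal(*arrays.values()).pvalue)
    except ValueError:
        # all observations identical across every arm
        omnibus_p = 1.0
    pairs = list(itertools.combinations(arrays.keys(), 2))
    if family_size is None:
        family_size = len(pairs)
    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    gatekept = gatekeeping and omnibus_p >= alpha
    if not gatekept:
        for a, b in pairs:
            x, y = arrays[a], arrays[b]
            if paired:
                diffs = x - y
                if np.all(diffs == 0):
                    raw = 1.0
                elif pairwise_test == "ttest":
                    raw = float(stats.ttest_rel(x, y).pvalue)
                else:
                    method = "exact" if len(diffs) < 25 and not np.any(diffs == 0) else "auto"
                    raw = float(stats.wilcoxon(x, y, method=method).pvalue)
            else:
                raw = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
            pairwise[(a, b)] = (raw, bonferroni(raw, family_size))
    return StatResult(
        omnibus_p=omnibus_p, pairwise=pairwise, family_size=family_size, gatekept=gatekept
    )


def regress_overlap_on_tvar(
    tvar: Sequence[float], overlap: Sequence[float]
) -> RegressionResult:
    """Ordinary least squares of overlap on tvar: slope sign and R^2."""
    x = np.asarray(tvar, dtype=float)
    y = np.asarray(overlap, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise HarnessError("need at least 3 (tvar, overlap) pairs")
    if np.ptp(x) == 0:
        raise HarnessError("tvar is constant: regression undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )


def stratify_by_tvar(
    records: pd.DataFrame, threshold: float = DEFAULT_TVAR_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split scan records into regular (tvar <= threshold) and irregular.

    Irregular is strictly ``tvar > threshold``; boundary values go to the
    regular cohort.
    """
    if "tvar" not in records.columns:
        raise HarnessError("records must carry a 'tvar' column")
    irregular = records["tvar"] > threshold
    return records[~irregular].copy(), records[irregular].copy()


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-condition sub-seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_experiment(config: ExperimentConfig) -> ComparisonReport:
    """Run the full sweep and comparison; reproducible for a fixed config.

    For every waveform x repeat: simulate trace and events, segment cycles,
    gate with both methods, record tvar/overlap/R and retained fractions;
    if ``include_iq``, simulate every arm and score CR/BV/CNR per sphere
    plus liver SNR.  Stage failures propagate with condition context.
    """
    conditions = [
        (wi, rep)
        for wi in range(len(config.waveforms))
        for rep in range(config.n_repeats)
    ]
    seeds = _child_seeds(config.seed, 3 * len(conditions))
    static = build_static_phantom(config.phantom) if config.include_iq else None

    scan_rows, metric_rows, liver_rows = [], [], []
    for ci, (wi, rep) in enumerate(conditions):
        trace_seed, event_seed, noise_seed = seeds[3 * ci : 3 * ci + 3]
        label = f"waveform{wi}"
        try:
            params = replace(config.waveforms[wi], seed=trace_seed)
            trace = simulate_trace(params)
            events = simulate_events(trace, config.event_rate, seed=event_seed)
            cycle_set = analyze_trace(trace)
            m1 = gate_method1_qpg(
                cycle_set, events, config.offset_fraction, config.duty_fraction
            )
            m2 = gate_method2_adaptive(cycle_set, trace, events, config.duty_fraction)
            ov = compute_overlap(m1, m2, events)
            r = compute_r_value(trace)
            scan_rows.append(
                {
                    "waveform": label,
                    "repeat": rep,
                    "tvar": cycle_set.tvar,
                    "overlap": ov.overlap,
                    "r_value": r.r,
                    "r_passes": r.passes_threshold,
                    "m1_retained_fraction": m1.retained_fraction,
                    "m2_retained_fraction": m2.retained_fraction,
                    "n_cycles": cycle_set.n_cycles,
                }
            )
            if config.include_iq:
                masks = {"method1": m1, "method2": m2}
                for ai, arm in enumerate(config.arms):
                    vol = simulate_arm(
                        config.phantom,
                        trace,
                        events,
                        arm,
                        gate_mask=masks.get(arm.gating),
                        seed=noise_seed + ai,
                        static=static,
                    )
                    iq = analyze_image_quality(vol, config.phantom, arm=arm.label)
                    t = iq.table.copy()
                    t["waveform"] = label
                    t["repeat"] = rep
                    metric_rows.append(t)
                    if arm.counts_per_unit is not None:
                        ln = liver_snr(vol, config.liver_voi_center_mm)
                        liver_rows.append(
                            {
                                "arm": arm.label,
                                "waveform": label,
                                "repeat": rep,
                                "voi_mean": ln.voi_mean,
                                "voi_sd": ln.voi_sd,
                                "snr": ln.snr,
                            }
                        )
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise HarnessError(f"condition {label} repeat {rep} failed: {exc}") from exc

    scans = pd.DataFrame(scan_rows)
    metrics = pd.concat(metric_rows, ignore_index=True) if metric_rows else None
    liver = pd.DataFrame(liver_rows) if liver_rows else None

    stat_results: dict = {}
    if metrics is not None:
        n_scans = len(scans)
        for metric in ("CR", "BV", "CNR"):
            for sphere in sorted(metrics["sphere_mm"].unique()):
                sub = metrics[metrics["sphere_mm"] == sphere]
                samples = {
                    arm.label: sub[sub["arm"] == arm.label]
                    .sort_values(["waveform", "repeat"])[metric]
                    .to_numpy(dtype=float)
                    for arm in config.arms
                }
                if n_scans >= 2 and all(len(v) == n_scans for v in samples.values()):
                    stat_results[(metric, sphere)] = omnibus_then_pairwise(
                        samples, paired=True, pairwise_test="wilcoxon"
                    )
    if liver is not None and len(liver):
        samples = {
            a: g.sort_values(["waveform", "repeat"])["snr"].to_numpy(dtype=float)
            for a, g in liver.groupby("arm")
        }
        if len(samples) >= 2 and len({len(v) for v in samples.values()}) == 1:
            stat_results[("liver_snr", None)] = omnibus_then_pairwise(
                samples, paired=True, pairwise_test="ttest"
            )

    regression = None
    if len(scans) >= 3 and np.ptp(scans["tvar"].to_numpy()) > 0:
        regression = regress_overlap_on_tvar(scans["tvar"], scans["overlap"])

    regular, irregular = stratify_by_tvar(scans, config.tvar_threshold)
    stratified = {
        "threshold": config.tvar_threshold,
        "tvar_mode": "sd",
        "n_regular": len(regular),
        "n_irregular": len(irregular),
        "regular_mean_overlap": float(regular["overlap"].mean()) if len(regular) else None,
        "irregular_mean_overlap": float(irregular["overlap"].mean()) if len(irregular) else None,
    }

    return ComparisonReport(
        scans=scans,
        metrics=metrics,
        liver=liver,
        stats=stat_results,
        regression=regression,
        stratified=stratified,
        config=config,
    )
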