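"""Breath-cycle detection, segmentation, and the tvar regularity metric.

Individual breaths are identified as prominent local maxima of the trace
(peak inspiration).  Consecutive peaks delimit one breathing cycle, so cycle
durations are the inter-peak intervals and the end-expiration trough sits in
the cycle interior, where the amplitude-driven gate anchors.  tvar — the
dispersion of cycle durations over a scan — quantifies breathing regularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .waveform import RespiratoryTrace

logger = logging.getLogger(__name__)

#: Literal minimum peak distance (s) used for breath identification.
DEFAULT_MIN_PEAK_DISTANCE = 0.01

#: Conservative preset (s) for very noisy traces.  Never applied silently:
#: pass it explicitly to :func:`detect_breath_peaks` if wanted.
SANITY_MIN_PEAK_DISTANCE = 1.0

#: Default peak prominence as a fraction of the trace dynamic range.
DEFAULT_PROMINENCE_FRACTION = 0.2


class CycleError(ValueError):
    """Cycle detection/segmentation failure."""


@dataclass(frozen=True)
class BreathCycle:
    """One breathing cycle spanning consecutive inspiration peaks.

    ``start_time``/``end_time`` are the bounding peak times (half-open
    ``[start, end)``); ``peak_time`` is the trigger peak opening the cycle;
    ``min_amp_time`` is the interior end-expiration trough.
    """

    start_time: float
    end_time: float
    peak_time: float
    min_amp_time: float
    duration: float

    def __post_init__(self) -> None:
        if not (self.start_time <= self.peak_time < self.end_time):
            raise CycleError("peak_time must lie in [start, end)")
        if self.duration <= 0:
            raise CycleError("cycle duration must be positive")
        if not (self.start_time <= self.min_amp_time < self.end_time):
            raise CycleError("min_amp_time must lie in [start, end)")


@dataclass(frozen=True)
class CycleSet:
    """Ordered, non-overlapping breath cycles plus the tvar attached to them."""

    cycles: tuple[BreathCycle, ...]
    tvar: float | None = None
    tvar_mode: str | None = None

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def durations(self) -> np.ndarray:
        return np.array([c.duration for c in self.cycles])

    @property
    def mean_duration(self) -> float:
        return float(self.durations.mean())

    def __iter__(self):
        return iter(self.cycles)


def detect_breath_peaks(
    trace: RespiratoryTrace,
    min_peak_distance: float = DEFAULT_MIN_PEAK_DISTANCE,
    prominence_threshold: float | None = None,
) -> np.ndarray:
    """Times of inspiration peaks in a trace.

    Local maxima with prominence at least ``prominence_threshold`` (default:
    20% of the trace dynamic range, to exclude noise and artifacts) and
    pairwise spacing at least ``min_peak_distance`` seconds (default 10 ms).
    A flat trace has no respiration to detect and returns an empty array.
    """
    if len(trace) < 3:
        raise CycleError("trace too short for peak detection (< 3 samples)")
    amps = trace.amplitudes
    dyn_range = float(amps.max() - amps.min())
    if dyn_range == 0.0:
        logger.warning("no respiration detected: trace has zero dynamic range")
        return np.array([])
    if prominence_threshold is None:
        prominence_threshold = DEFAULT_PROMINENCE_FRACTION * dyn_range
    if prominence_threshold <= 0:
        raise CycleError("prominence_threshold must be positive")
    distance = max(1, int(round(min_peak_distance * trace.sample_rate)))
    idx, _ = find_peaks(amps, prominence=prominence_threshold, distance=distance)
    return trace.times[idx]


def segment_cycles(trace: RespiratoryTrace, peak_times: Sequence[float]) -> CycleSet:
    """Segment the trace into breath cycles, one per consecutive peak pair.

    Cycle ``i`` spans ``[peak_i, peak_{i+1})``; its duration is the
    inter-peak interval and ``min_amp_time`` is the sample of lowest
    amplitude strictly inside the cycle (ties broken toward the earlier
    sample) — the end-expiration anchor used by amplitude-driven gating.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    if len(peak_times) < 2:
        raise CycleError("cannot segment: need at least 2 peaks")
    cycles = []
    for p0, p1 in zip(peak_times[:-1], peak_times[1:]):
        lo = int(np.searchsorted(trace.times, p0, side="left"))
        hi = int(np.searchsorted(trace.times, p1, side="left"))
        if hi <= lo:
            raise CycleError("peaks closer than one sample")
        seg = trace.amplitudes[lo:hi]
        # argmin returns the first minimum -> earlier-sample tie-break
        min_idx = lo + int(np.argmin(seg))
        cycles.append(
            BreathCycle(
                start_time=float(p0),
                end_time=float(p1),
                peak_time=float(p0),
                min_amp_time=float(trace.times[min_idx]),
                duration=float(p1 - p0),
            )
        )
    return CycleSet(cycles=tuple(cycles))


def compute_tvar(cycle_set: CycleSet, mode: str = "sd") -> CycleSet:
    """Attach tvar, the dispersion of cycle durations, to a cycle set.

    ``mode="sd"`` (default) is the sample standard deviation of the
    durations; ``mode="var"`` the sample variance.  Both are translation-
    and amplitude-scale-invariant since they depend on peak times only.
    Requires at least 2 cycles.
    """
    if mode not in ("sd", "var"):
        raise ValueError("mode must be 'sd' or 'var'")
    if cycle_set.n_cycles < 2:
        raise CycleError("tvar needs at least 2 cycles")
    durations = cycle_set.durations
    var = float(np.var(durations, ddof=1))
    tvar = float(np.sqrt(var)) if mode == "sd" else var
    return CycleSet(cycles=cycle_set.cycles, tvar=tvar, tvar_mode=mode)


def analyze_trace(
    trace: RespiratoryTrace,
    min_peak_distance: float = DEFAULT_MIN_PEAK_DISTANCE,
    prominence_threshold: float | None = None,
    tvar_mode: str = "sd",
) -> CycleSet:
    """Convenience pipeline: detect peaks, segment, and compute tvar."""
    peaks = detect_breath_peaks(trace, min_peak_distance, prominence_threshold)
    cycle_set = segment_cycles(trace, peaks)
    return compute_tvar(cycle_set, mode=tvar_mode)
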