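"""Respiratory gating of list-mode events, plus the overlap and R metrics.

Two quiescent-period gating flavours are implemented:

* **Method 1** — fixed-offset gating: every cycle retains the same phase
  window, ``[offset, offset + duty)`` as a fraction of the cycle, regardless
  of where the end-expiration trough actually falls.  This emulates
  trigger-anchored quiescent-period gating (Q.Static-style), where the
  window is placed at a fixed offset after each inspiration peak.
* **Method 2** — cycle-specific amplitude-driven gating: each gate seeds at
  the cycle's amplitude minimum and greedily grows one trace sample at a
  time toward the lower-amplitude side until it holds the requested
  fraction of that cycle's counts.

With the default offset of 0.3 and duty of 0.5 both methods straddle
end-expiration on a regular breather and select nearly the same counts
(overlap near 1); as breathing becomes irregular the trough drifts in phase
and the two selections diverge, which is what the overlap metric measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import periodogram

from .cycles import CycleSet
from .listmode import EventStream
from .waveform import RespiratoryTrace

logger = logging.getLogger(__name__)

#: Clinical trigger threshold on the R value.
DEFAULT_R_THRESHOLD = 15.0

#: Respiration-like frequency band (Hz) searched by the R metric.
DEFAULT_R_BAND = (0.1, 0.4)


class GatingError(ValueError):
    """Gating could not be applied to the given inputs."""


@dataclass(frozen=True)
class GateWindow:
    """Half-open retained interval ``[t0, t1)`` inside one cycle."""

    cycle_index: int
    t0: float
    t1: float

    def __post_init__(self) -> None:
        if not self.t0 < self.t1:
            raise GatingError("gate window must satisfy t0 < t1")

    @property
    def width(self) -> float:
        return self.t1 - self.t0


@dataclass(frozen=True)
class GateMask:
    """Per-event retention decision produced by one gating method."""

    method: str
    windows: tuple[GateWindow, ...]
    retained: np.ndarray  # bool per event
    retained_fraction: float

    @property
    def retained_counts(self) -> int:
        return int(self.retained.sum())


@dataclass(frozen=True)
class OverlapResult:
    """Fraction of counts selected by both of two gating methods."""

    overlap: float
    intersection_counts: int
    per_method_counts: tuple[int, int]


@dataclass(frozen=True)
class RValueResult:
    """Spectral respiration signal metric and its trigger decision."""

    r: float
    band: tuple[float, float]
    passes_threshold: bool
    threshold: float = DEFAULT_R_THRESHOLD


def _retained_from_windows(
    windows: Sequence[GateWindow], events: EventStream
) -> np.ndarray:
    """Boolean retention per event for sorted, non-overlapping windows."""
    if not windows:
        return np.zeros(events.total_counts, dtype=bool)
    edges = np.ravel([(w.t0, w.t1) for w in windows])
    if np.any(np.diff(edges) < 0):
        raise GatingError("gate windows must be sorted and non-overlapping")
    pos = np.searchsorted(edges, events.event_times, side="right")
    return pos % 2 == 1


def _finalize_mask(
    method: str, windows: list[GateWindow], events: EventStream
) -> GateMask:
    retained = _retained_from_windows(windows, events)
    total = events.total_counts
    frac = float(retained.sum()) / total if total else 0.0
    return GateMask(
        method=method,
        windows=tuple(windows),
        retained=retained,
        retained_fraction=frac,
    )


def gate_method1_qpg(
    cycles: CycleSet,
    events: EventStream,
    offset_fraction: float = 0.3,
    duty_fraction: float = 0.5,
    reference_period: str = "per_cycle",
    include_edges: bool = True,
) -> GateMask:
    """Fixed-offset quiescent-period gating (Method 1).

    Every cycle starting at ``s`` retains the same phase window.  With
    ``reference_period="per_cycle"`` (default) the window is
    ``[s + offset*T_i, s + (offset+duty)*T_i)`` with ``T_i`` the cycle's own
    duration, so the retained fraction of in-cycle time is exactly the duty
    fraction for any breathing pattern.  ``"scan_mean"`` instead places
    ``[s + offset*Tbar, s + (offset+duty)*Tbar)`` with ``Tbar`` the scan-mean
    duration, clipped to the cycle — a stiffer variant that under-retains on
    short cycles.

    ``include_edges`` also gates the partial breaths outside the detected
    cycles: the trigger at the last peak still opens a window (duration
    taken as ``Tbar``), and the unobserved cycle ending at the first peak
    contributes the part of its window that falls inside the scan.  Without
    this, data at the scan edges is systematically discarded and the
    scan-level retained fraction undershoots the duty fraction.
    """
    if cycles.n_cycles < 1:
        raise GatingError("Method 1 needs at least one cycle")
    if not 0 <= offset_fraction < 1:
        raise GatingError("offset_fraction must be in [0, 1)")
    if not 0 < duty_fraction <= 1:
        raise GatingError("duty_fraction must be in (0, 1]")
    if reference_period not in ("per_cycle", "scan_mean"):
        raise GatingError("reference_period must be 'per_cycle' or 'scan_mean'")
    t_bar = cycles.mean_duration
    if t_bar <= 0:
        raise GatingError("degenerate mean cycle duration")
    windows: list[GateWindow] = []
    first = cycles.cycles[0]
    last = cycles.cycles[-1]
    if include_edges:
        # unobserved cycle of duration Tbar ending at the first peak
        t0 = first.start_time + (offset_fraction - 1.0) * t_bar
        t1 = first.start_time + (offset_fraction + duty_fraction - 1.0) * t_bar
        if t1 > t0:
            windows.append(GateWindow(cycle_index=-1, t0=t0, t1=t1))
    for i, cyc in enumerate(cycles):
        ref = cyc.duration if reference_period == "per_cycle" else t_bar
        t0 = cyc.start_time + offset_fraction * ref
        t1 = cyc.start_time + (offset_fraction + duty_fraction) * ref
        t0 = max(t0, cyc.start_time)
        t1 = min(t1, cyc.end_time)
        if t1 > t0:
            windows.append(GateWindow(cycle_index=i, t0=t0, t1=t1))
    if include_edges:
        # trigger at the last peak opens a window in the trailing partial breath
        t0 = last.end_time + offset_fraction * t_bar
        t1 = last.end_time + (offset_fraction + duty_fraction) * t_bar
        windows.append(GateWindow(cycle_index=cycles.n_cycles, t0=t0, t1=t1))
    return _finalize_mask("method1", windows, events)


def _greedy_window(
    amplitudes: np.ndarray, counts: np.ndarray, target: float
) -> tuple[int, int]:
    """Greedy amplitude-driven expansion over one cycle's samples.

    Seeds at the amplitude minimum (earliest on ties) and repeatedly adds
    the neighbouring sample on the side whose adjacent amplitude is lower
    (tie -> earlier side), stopping at the first window holding at least
    ``target`` counts.  Returns the inclusive sample index range ``(l, r)``.
    """
    n = len(amplitudes)
    anchor = int(np.argmin(amplitudes))
    l = r = anchor
    got = float(counts[anchor])
    while got < target and (l > 0 or r < n - 1):
        go_left = False
        if l > 0 and r < n - 1:
            # tie broken toward the earlier (left) side
            go_left = amplitudes[l - 1] <= amplitudes[r + 1]
        elif l > 0:
            go_left = True
        if go_left:
            l -= 1
            got += float(counts[l])
        else:
            r += 1
            got += float(counts[r])
    return l, r


def gate_method2_adaptive(
    cycles: CycleSet,
    trace: RespiratoryTrace,
    events: EventStream,
    duty_fraction: float = 0.5,
    mode: str = "greedy",
    include_edges: bool = True,
) -> GateMask:
    """Cycle-specific amplitude-driven gating (Method 2).

    Per cycle the gate begins at the minimum-amplitude sample and expands
    until it encompasses ``duty_fraction`` of that cycle's counts.  The
    default ``mode="greedy"`` grows a contiguous-in-time window sample by
    sample toward the lower adjacent amplitude; ``mode="threshold"`` instead
    retains the lowest-amplitude samples regardless of contiguity (a rising
    amplitude threshold), which may yield several windows per cycle.  The
    stopping rule may overshoot the duty target by at most one sample's
    counts; the achieved scan-level fraction is reported on the mask.
    A cycle containing no events contributes an empty window.

    ``include_edges`` gates the partial breaths before the first and after
    the last detected peak by the same rule, so scan-edge data is not
    systematically discarded.
    """
    if cycles.n_cycles < 1:
        raise GatingError("Method 2 needs at least one cycle")
    if not 0 < duty_fraction <= 1:
        raise GatingError("duty_fraction must be in (0, 1]")
    if mode not in ("greedy", "threshold"):
        raise GatingError("mode must be 'greedy' or 'threshold'")
    dt = trace.dt
    segments = [
        (i, cyc.start_time, cyc.end_time) for i, cyc in enumerate(cycles)
    ]
    if include_edges:
        first_start = cycles.cycles[0].start_time
        last_end = cycles.cycles[-1].end_time
        if trace.times[0] < first_start:
            segments.insert(0, (-1, float(trace.times[0]), first_start))
        trace_end = float(trace.times[-1]) + dt
        if last_end < trace_end:
            segments.append((cycles.n_cycles, last_end, trace_end))

    windows: list[GateWindow] = []
    for i, seg_start, seg_end in segments:
        lo = int(np.searchsorted(trace.times, seg_start, side="left"))
        hi = int(np.searchsorted(trace.times, seg_end, side="left"))
        if hi - lo < 1:
            continue
        seg_times = trace.times[lo:hi]
        seg_amps = trace.amplitudes[lo:hi]
        # per-sample event counts; the last bin runs to the segment end
        edges = np.append(seg_times, seg_end)
        e_lo = np.searchsorted(events.event_times, seg_start, side="left")
        e_hi = np.searchsorted(events.event_times, seg_end, side="left")
        n_ev = int(e_hi - e_lo)
        if n_ev == 0:
            logger.warning("cycle %d contains no events; empty gate window", i)
            continue
        counts, _ = np.histogram(events.event_times[e_lo:e_hi], bins=edges)
        target = duty_fraction * n_ev
        if mode == "greedy":
            l, r = _greedy_window(seg_amps, counts, target)
            t1 = seg_times[r] + dt if r < len(seg_times) - 1 else seg_end
            windows.append(
                GateWindow(cycle_index=i, t0=float(seg_times[l]), t1=min(float(t1), seg_end))
            )
        else:
            order = np.argsort(seg_amps, kind="stable")
            keep = np.zeros(len(seg_amps), dtype=bool)
            got = 0.0
            for j in order:
                keep[j] = True
                got += float(counts[j])
                if got >= target:
                    break
            # contiguous runs of kept samples -> windows
            padded = np.concatenate([[False], keep, [False]])
            d = np.diff(padded.astype(int))
            run_starts = np.nonzero(d == 1)[0]
            run_ends = np.nonzero(d == -1)[0]
            for a, b in zip(run_starts, run_ends):
                t1 = seg_times[b - 1] + dt if b - 1 < len(seg_times) - 1 else seg_end
                windows.append(
                    GateWindow(cycle_index=i, t0=float(seg_times[a]), t1=min(float(t1), seg_end))
                )
    return _finalize_mask("method2", windows, events)


def compute_overlap(
    mask_a: GateMask, mask_b: GateMask, events: EventStream
) -> OverlapResult:
    """Fraction of counts retained by both methods.

    The denominator is the geometric mean of the two retained counts, so
    the metric stays defined when duty fractions differ and reduces to
    ``intersection/|A|`` for equal-size selections.  Symmetric, in [0, 1],
    and 1 for identical masks.
    """
    for mask in (mask_a, mask_b):
        if len(mask.retained) != events.total_counts:
            raise GatingError("mask does not match the event stream")
    n_a = mask_a.retained_counts
    n_b = mask_b.retained_counts
    if n_a == 0 or n_b == 0:
        raise GatingError("overlap undefined: a mask retains zero events")
    inter = int(np.sum(mask_a.retained & mask_b.retained))
    return OverlapResult(
        overlap=float(inter / np.sqrt(n_a * n_b)),
        intersection_counts=inter,
        per_method_counts=(n_a, n_b),
    )


def compute_r_value(
    trace: RespiratoryTrace,
    band: tuple[float, float] = DEFAULT_R_BAND,
    threshold: float = DEFAULT_R_THRESHOLD,
) -> RValueResult:
    """Spectral signal metric for respiration-like motion.

    R is the percentage of total (DC-excluded) periodogram power carried by
    the single strongest bin inside the respiration band: R = 100 x
    max(P_band) / sum(P).  A coherent breathing signal concentrates power in
    one in-band line and scores high; broadband noise spreads power over
    hundreds of bins and scores near zero.  ``passes_threshold`` applies the
    clinical trigger rule R > 15.
    """
    if trace.duration < 30.0:
        raise GatingError("trace too short for spectral R value (< 30 s)")
    amps = trace.amplitudes - trace.amplitudes.mean()
    if np.allclose(amps, 0.0):
        raise GatingError("zero-variance trace: R value undefined")
    f, p = periodogram(amps, fs=trace.sample_rate)
    nonzero = f > 0
    in_band = nonzero & (f >= band[0]) & (f <= band[1])
    if not in_band.any():
        raise GatingError("no periodogram bins inside the requested band")
    total = float(p[nonzero].sum())
    r = 100.0 * float(p[in_band].max()) / total
    return RValueResult(
        r=r, band=tuple(band), passes_threshold=bool(r > threshold), threshold=threshold
    )
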