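"""List-mode-style event simulation.

PET coincidence events are emulated as a homogeneous Poisson process over
the span of a respiratory trace (phantom activity is effectively constant
over one bed position; decay correction is out of scope).  Each event
carries the axial displacement of the emitting object at its timestamp,
obtained by linear interpolation of the trace — the motion signature that
retrospective gating exploits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .waveform import RespiratoryTrace

logger = logging.getLogger(__name__)


class EventError(ValueError):
    """Invalid event-stream construction or query."""


@dataclass(frozen=True)
class EventStream:
    """Simulated list-mode counts: sorted timestamps plus axial displacement."""

    event_times: np.ndarray
    displacements: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.event_times, dtype=float)
        disp = np.asarray(self.displacements, dtype=float)
        object.__setattr__(self, "event_times", times)
        object.__setattr__(self, "displacements", disp)
        if len(times) != len(disp):
            raise EventError("event_times and displacements must be equal length")
        if len(times) > 1 and np.any(np.diff(times) < 0):
            raise EventError("event_times must be sorted")

    @property
    def total_counts(self) -> int:
        return len(self.event_times)


def simulate_events(trace: RespiratoryTrace, rate: float, seed: int = 0) -> EventStream:
    """Homogeneous Poisson events at ``rate`` counts/s over the trace span.

    Event displacements are linear interpolations of the trace at the event
    times; an event falling exactly on a sample instant carries that sample's
    amplitude.  Seeded and reproducible.
    """
    if rate <= 0:
        raise EventError("rate must be positive")
    if len(trace) < 2:
        raise EventError("trace too short to carry events")
    rng = np.random.default_rng(seed)
    span = trace.duration
    n = rng.poisson(rate * span)
    times = np.sort(rng.uniform(trace.times[0], trace.times[-1], size=n))
    return EventStream(event_times=times, displacements=trace.interpolate(times))


def counts_in_window(stream: EventStream, t0: float, t1: float) -> int:
    """Number of events with ``t0 <= t < t1`` (half-open)."""
    if not t0 < t1:
        raise EventError("window must satisfy t0 < t1")
    lo = np.searchsorted(stream.event_times, t0, side="left")
    hi = np.searchsorted(stream.event_times, t1, side="left")
    return int(hi - lo)


def write_events_csv(stream: EventStream, path: Union[str, Path]) -> None:
    """Write an event table as CSV with columns ``event_time_s, displacement_mm``."""
    pd.DataFrame(
        {"event_time_s": stream.event_times, "displacement_mm": stream.displacements}
    ).to_csv(path, index=False)


def read_events_csv(path: Union[str, Path]) -> EventStream:
    """Read an event table written by :func:`write_events_csv`."""
    df = pd.read_csv(path)
    missing = {"event_time_s", "displacement_mm"} - set(df.columns)
    if missing:
        raise EventError(f"event CSV is missing columns: {sorted(missing)}")
    return EventStream(
        event_times=df["event_time_s"].to_numpy(dtype=float),
        displacements=df["displacement_mm"].to_numpy(dtype=float),
    )
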