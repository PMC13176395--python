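"""Respiratory waveform simulation and trace I/O.

A respiratory trace is the superior–inferior displacement of the abdomen
sampled uniformly in time by an external tracker (or extracted from the PET
list data itself).  The simulator concatenates single-breath raised-cosine
cycles whose period and depth are drawn per cycle, so one parameter set can
emulate both a metronomic ("typical") breather and an erratic ("irregular")
one by widening the jitter terms.

Sign convention: larger amplitude = inspiration (superior displacement);
cycle minima are end-expiration, the quiescent part of the breath.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default tracker sampling rate in Hz.
DEFAULT_SAMPLE_RATE = 25.0

#: Tolerance (s) on sampling uniformity when reading external traces.
UNIFORMITY_TOL = 1e-6

#: Supported single-breath shapes.  The default "raised_cosine" rises over a
#: fixed inspiratory time and falls over the rest of the cycle — real
#: breathing keeps inspiration roughly constant while the expiratory
#: phase/pause absorbs cycle-length variability.  "symmetric_cosine" peaks
#: at mid-cycle; "triangular" is the piecewise-linear analogue of the
#: default.
BREATH_SHAPES = ("raised_cosine", "symmetric_cosine", "triangular")


class TraceError(ValueError):
    """Invalid respiratory-trace construction or file contents."""


@dataclass(frozen=True)
class RespiratoryTrace:
    """Uniformly sampled breathing amplitude versus time.

    Parameters
    ----------
    times : ndarray
        Sample times in seconds, strictly increasing with a uniform step.
    amplitudes : ndarray
        Displacement in mm at each sample; positive = superior (inspiration).
    sample_rate : float
        Sampling rate in Hz; the time step is ``1/sample_rate``.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        amps = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "amplitudes", amps)
        if times.ndim != 1 or amps.ndim != 1 or len(times) != len(amps):
            raise TraceError("times and amplitudes must be 1-D and equal length")
        if len(times) < 2:
            raise TraceError("a trace needs at least 2 samples")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(amps))):
            raise TraceError("trace contains non-finite values")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise TraceError("times must be strictly increasing")
        step = 1.0 / self.sample_rate
        if np.any(np.abs(steps - step) > max(1e-9, UNIFORMITY_TOL)):
            raise TraceError(
                "sampling is not uniform at the declared rate "
                f"({self.sample_rate} Hz)"
            )

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        """Span from first to last sample, in seconds."""
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)

    def interpolate(self, t: np.ndarray) -> np.ndarray:
        """Linearly interpolate the amplitude at arbitrary times within the span."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.amplitudes)


@dataclass(frozen=True)
class WaveformParams:
    """Generative parameters of a simulated breathing pattern.

    ``amplitude`` is the half peak-to-peak excursion in mm (default 15, i.e.
    a ±15 mm motion about the mid-position); per-cycle periods and depths are
    truncated-normal draws so they stay physical.
    """

    mean_period: float = 4.0
    period_jitter_sd: float = 0.0
    amplitude: float = 15.0
    amplitude_jitter_sd: float = 0.0
    baseline_drift_sd: float = 0.0
    noise_sd: float = 0.0
    duration: float = 120.0
    sample_rate: float = DEFAULT_SAMPLE_RATE
    seed: int = 0
    shape: str = "raised_cosine"
    insp_fraction: float = 0.4

    def __post_init__(self) -> None:
        vals = (
            self.mean_period,
            self.period_jitter_sd,
            self.amplitude,
            self.amplitude_jitter_sd,
            self.baseline_drift_sd,
            self.noise_sd,
            self.duration,
            self.sample_rate,
        )
        if not all(math.isfinite(v) for v in vals):
            raise TraceError("waveform parameters must be finite")
        if self.mean_period <= 0:
            raise TraceError("mean_period must be positive")
        if self.duration < 3 * self.mean_period:
            raise TraceError("duration must cover at least 3 mean periods")
        if min(
            self.period_jitter_sd,
            self.amplitude_jitter_sd,
            self.baseline_drift_sd,
            self.noise_sd,
        ) < 0:
            raise TraceError("jitter/noise SDs must be non-negative")
        if self.sample_rate <= 0:
            raise TraceError("sample_rate must be positive")
        if self.shape not in BREATH_SHAPES:
            raise TraceError(f"shape must be one of {BREATH_SHAPES}")
        if not 0 < self.insp_fraction < 0.5:
            raise TraceError("insp_fraction must be in (0, 0.5)")


# Preset parameter sets emulating the two study waveform classes: a typical
# regular breather and an irregular breather with strong cycle-to-cycle
# period and depth variation.
TYPICAL_WAVEFORM = WaveformParams(
    mean_period=4.0,
    period_jitter_sd=0.15,
    amplitude=15.0,
    amplitude_jitter_sd=0.5,
    baseline_drift_sd=0.02,
    noise_sd=0.2,
    duration=360.0,
)
IRREGULAR_WAVEFORM = WaveformParams(
    mean_period=4.0,
    period_jitter_sd=1.0,
    amplitude=15.0,
    amplitude_jitter_sd=3.0,
    baseline_drift_sd=0.05,
    noise_sd=0.3,
    duration=360.0,
)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, n: int
) -> np.ndarray:
    """Normal(mean, sd) draws truncated below at ``lower`` (by resampling)."""
    if sd == 0:
        return np.full(n, max(mean, lower))
    out = rng.normal(mean, sd, size=n)
    bad = out < lower
    # Resampling keeps the draw count deterministic per seed; clip as a
    # last resort for extreme tails.
    for _ in range(100):
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < lower
    return np.clip(out, lower, None)


def _breath_shape(
    t_in_cycle: np.ndarray, period: np.ndarray, rise_time: np.ndarray, shape: str
) -> np.ndarray:
    """Unit-amplitude single breath; 0 at the cycle boundaries.

    Rises from 0 to 1 over ``rise_time`` (inspiration) and falls back over
    the rest of the cycle (expiration).
    """
    rising = t_in_cycle < rise_time
    fall_t = t_in_cycle - rise_time
    fall_dur = period - rise_time
    if shape == "triangular":
        up = t_in_cycle / rise_time
        down = 1.0 - fall_t / fall_dur
    else:  # raised-cosine half-waves on each limb
        up = 0.5 * (1.0 - np.cos(np.pi * t_in_cycle / rise_time))
        down = 0.5 * (1.0 + np.cos(np.pi * fall_t / fall_dur))
    return np.where(rising, up, down)


def simulate_trace(params: WaveformParams) -> RespiratoryTrace:
    """Simulate a respiratory trace by concatenating per-cycle breaths.

    Cycle ``i`` has period ~ Normal(mean_period, period_jitter_sd) truncated
    at ``0.5*mean_period`` and half peak-to-peak depth ~ Normal(amplitude,
    amplitude_jitter_sd) truncated at 0.  Within a cycle the displacement
    rises from 0 (end-expiration, cycle boundary) to ``2*depth`` at the end
    of inspiration and falls back to 0, so the excursion about the
    mid-position is ±depth.  With the default shape the inspiratory time is
    fixed at ``insp_fraction*mean_period`` for every cycle — period jitter
    lives entirely in the expiratory limb, as in real breathing — so the
    inspiration peaks are spaced exactly one cycle period apart.  White
    measurement noise and a random-walk baseline drift are added per
    sample.  Identical parameters and seed give a bit-identical trace.
    """
    rng = np.random.default_rng(params.seed)
    # Draw enough cycles to cover the duration, then trim.
    n_guess = int(np.ceil(params.duration / (0.5 * params.mean_period))) + 2
    periods = _truncated_normal(
        rng, params.mean_period, params.period_jitter_sd, 0.5 * params.mean_period, n_guess
    )
    depths = _truncated_normal(rng, params.amplitude, params.amplitude_jitter_sd, 0.0, n_guess)
    starts = np.concatenate([[0.0], np.cumsum(periods)])

    n_samples = int(np.floor(params.duration * params.sample_rate)) + 1
    times = np.arange(n_samples) / params.sample_rate
    # Which generated cycle each sample belongs to.
    idx = np.searchsorted(starts, times, side="right") - 1
    idx = np.clip(idx, 0, n_guess - 1)
    t_in_cycle = times - starts[idx]
    if params.shape == "symmetric_cosine":
        rise = 0.5 * periods[idx]
        shape = "raised_cosine"
    else:
        # fixed inspiratory time; truncation keeps every period above it
        rise = np.full_like(t_in_cycle, params.insp_fraction * params.mean_period)
        shape = params.shape
    amplitudes = 2.0 * depths[idx] * _breath_shape(t_in_cycle, periods[idx], rise, shape)

    if params.noise_sd > 0:
        amplitudes = amplitudes + rng.normal(0.0, params.noise_sd, size=n_samples)
    if params.baseline_drift_sd > 0:
        drift = np.cumsum(rng.normal(0.0, params.baseline_drift_sd, size=n_samples))
        amplitudes = amplitudes + drift

    return RespiratoryTrace(times=times, amplitudes=amplitudes, sample_rate=params.sample_rate)


def write_trace_csv(trace: RespiratoryTrace, path: Union[str, Path]) -> None:
    """Write a trace as CSV with columns ``time_s, amplitude_mm``."""
    # Default float formatting is the shortest exact repr, so write -> read
    # round-trips bit-exactly.
    pd.DataFrame({"time_s": trace.times, "amplitude_mm": trace.amplitudes}).to_csv(
        path, index=False
    )


def read_trace_csv(path: Union[str, Path]) -> RespiratoryTrace:
    """Read a tracker trace from CSV (columns ``time_s, amplitude_mm``).

    Raises :class:`TraceError` on missing columns, fewer than two rows,
    non-monotonic time, or sampling non-uniform beyond 1 µs.
    """
    df = pd.read_csv(path)
    missing = {"time_s", "amplitude_mm"} - set(df.columns)
    if missing:
        raise TraceError(f"trace CSV is missing columns: {sorted(missing)}")
    times = df["time_s"].to_numpy(dtype=float)
    amps = df["amplitude_mm"].to_numpy(dtype=float)
    if len(times) < 2:
        raise TraceError("trace CSV must contain at least 2 rows")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise TraceError("time_s must be strictly increasing")
    step = np.median(steps)
    if np.any(np.abs(steps - step) > UNIFORMITY_TOL):
        raise TraceError("time_s is not uniformly sampled (tolerance 1e-6 s)")
    return RespiratoryTrace(times=times, amplitudes=amps, sample_rate=1.0 / step)
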