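import numpy as np
import pytest

import respigate as rg


@pytest.fixture(scope="session")
def regular_trace() -> rg.RespiratoryTrace:
    """Metronomic 4 s breathing, 120 s at 25 Hz, no noise."""
    return rg.simulate_trace(rg.WaveformParams(mean_period=4.0, duration=120.0, seed=11))


@pytest.fixture(scope="session")
def irregular_trace() -> rg.RespiratoryTrace:
    """Erratic breathing: 1 s period jitter and variable depth."""
    return rg.simulate_trace(
        rg.WaveformParams(
            mean_period=4.0,
            period_jitter_sd=1.0,
            amplitude_jitter_sd=3.0,
            duration=120.0,
            seed=12,
        )
    )


@pytest.fixture(scope="session")
def regular_events(regular_trace) -> rg.EventStream:
    return rg.simulate_events(regular_trace, rate=1000.0, seed=21)


@pytest.fixture(scope="session")
def irregular_events(irregular_trace) -> rg.EventStream:
    return rg.simulate_events(irregular_trace, rate=1000.0, seed=22)


@pytest.fixture(scope="session")
def phantom_spec() -> rg.PhantomSpec:
    return rg.PhantomSpec()


@pytest.fixture(scope="session")
def static_volume(phantom_spec) -> rg.ImageVolume:
    """Default static phantom, built once per session."""
    return rg.build_static_phantom(phantom_spec)


def make_single_cycle(start: float, end: float, min_amp_time: float) -> rg.CycleSet:
    """One hand-built breath cycle for window-arithmetic tests."""
    cyc = rg.BreathCycle(
        start_time=start,
        end_time=end,
        peak_time=start,
        min_amp_time=min_amp_time,
        duration=end - start,
    )
    return rg.CycleSet(cycles=(cyc,))
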