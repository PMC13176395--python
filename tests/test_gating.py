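import numpy as np
import pytest

import respigate as rg
from respigate.gating import GatingError, _greedy_window
from conftest import make_single_cycle


def brute_force_min_window(amps, counts, target):
    """Exhaustive minimal contiguous window containing the amplitude minimum.

    Among all anchor-containing windows with enough counts, pick the fewest
    samples, then the lowest maximum amplitude, then the earliest start —
    the tie-break order the greedy expansion realises.
    """
    amps = np.asarray(amps, float)
    counts = np.asarray(counts, float)
    anchor = int(np.argmin(amps))
    best_key, best_lr = None, None
    for l in range(anchor + 1):
        for r in range(anchor, len(amps)):
            if counts[l : r + 1].sum() >= target:
                key = (r - l + 1, float(amps[l : r + 1].max()), l)
                if best_key is None or key < best_key:
                    best_key, best_lr = key, (l, r)
    return best_lr


def _uniform_events(t0, t1, n):
    times = np.linspace(t0, t1, n, endpoint=False)
    return rg.EventStream(event_times=times, displacements=np.zeros(n))


class TestMethod1:
    def test_window_arithmetic_single_cycle(self):
        cs = make_single_cycle(0.0, 4.0, 2.0)
        events = _uniform_events(0.0, 4.0, 400)
        mask = rg.gate_method1_qpg(
            cs, events, offset_fraction=0.25, duty_fraction=0.5, include_edges=False
        )
        assert len(mask.windows) == 1
        assert mask.windows[0].t0 == pytest.approx(1.0)
        assert mask.windows[0].t1 == pytest.approx(3.0)
        kept = events.event_times[mask.retained]
        assert kept.min() >= 1.0 and kept.max() < 3.0

    def test_full_duty_retains_everything(self):
        cs = make_single_cycle(0.0, 4.0, 2.0)
        events = _uniform_events(0.0, 4.0, 500)
        mask = rg.gate_method1_qpg(
            cs, events, offset_fraction=0.0, duty_fraction=1.0, include_edges=False
        )
        assert mask.retained_fraction == 1.0

    @pytest.mark.parametrize("trace_fix", ["regular", "irregular"])
    def test_retained_fraction_near_duty(self, trace_fix, request):
        trace = request.getfixturevalue(f"{trace_fix}_trace")
        events = request.getfixturevalue(f"{trace_fix}_events")
        cs = rg.analyze_trace(trace)
        mask = rg.gate_method1_qpg(cs, events, duty_fraction=0.5)
        assert mask.retained_fraction == pytest.approx(0.5, abs=0.02)

    def test_scan_mean_windows_stay_inside_cycles(self, irregular_trace, irregular_events):
        cs = rg.analyze_trace(irregular_trace)
        mask = rg.gate_method1_qpg(
            cs, irregular_events, reference_period="scan_mean", include_edges=False
        )
        for w in mask.windows:
            cyc = cs.cycles[w.cycle_index]
            assert cyc.start_time <= w.t0 < w.t1 <= cyc.end_time

    @pytest.mark.parametrize(
        "kwargs", [{"offset_fraction": 1.2}, {"duty_fraction": 0.0}, {"duty_fraction": 1.5}]
    )
    def test_invalid_fractions_rejected(self, regular_events, kwargs):
        cs = make_single_cycle(0.0, 4.0, 2.0)
        with pytest.raises(GatingError):
            rg.gate_method1_qpg(cs, regular_events, **kwargs)


class TestMethod2:
    def test_toy_cycle_matches_exhaustive_search(self):
        amps = np.array([5.0, 3.0, 1.0, 0.0, 1.0, 2.0, 4.0, 6.0])
        trace = rg.RespiratoryTrace(times=np.arange(8.0), amplitudes=amps, sample_rate=1.0)
        events = rg.EventStream(event_times=np.arange(8.0), displacements=amps)
        cs = make_single_cycle(0.0, 8.0, 3.0)
        mask = rg.gate_method2_adaptive(cs, trace, events, duty_fraction=0.5, include_edges=False)
        l, r = brute_force_min_window(amps, np.ones(8), 4)
        assert len(mask.windows) == 1
        assert mask.windows[0].t0 == pytest.approx(float(l))
        assert mask.windows[0].t1 == pytest.approx(float(r + 1))
        assert mask.retained_counts == 4

    def test_symmetric_cycle_selects_central_window(self):
        # V-shaped cycle, uniform events: the gate is the central half
        n = 41
        amps = np.abs(np.arange(n) - n // 2).astype(float)
        trace = rg.RespiratoryTrace(times=np.arange(float(n)), amplitudes=amps, sample_rate=1.0)
        events = _uniform_events(0.0, float(n), 4 * n)
        cs = make_single_cycle(0.0, float(n), float(n // 2))
        mask = rg.gate_method2_adaptive(cs, trace, events, duty_fraction=0.5, include_edges=False)
        w = mask.windows[0]
        center = 0.5 * (w.t0 + w.t1)
        assert center == pytest.approx(n // 2, abs=1.0)
        assert w.width == pytest.approx(n / 2, abs=1.5)

    def test_greedy_matches_bruteforce_on_random_unimodal_cycles(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(5, 35))
            k = int(rng.integers(1, n - 1))
            left = np.sort(rng.uniform(0.5, 10.0, size=k))[::-1]
            right = np.sort(rng.uniform(0.5, 10.0, size=n - k - 1))
            amps = np.concatenate([left, [rng.uniform(0.0, 0.4)], right])
            counts = np.ones(n)
            target = float(rng.uniform(0.2, 0.95)) * n
            assert _greedy_window(amps, counts, target) == brute_force_min_window(
                amps, counts, target
            )

    @pytest.mark.parametrize("trace_fix", ["regular", "irregular"])
    def test_retained_fraction_near_duty(self, trace_fix, request):
        trace = request.getfixturevalue(f"{trace_fix}_trace")
        events = request.getfixturevalue(f"{trace_fix}_events")
        cs = rg.analyze_trace(trace)
        mask = rg.gate_method2_adaptive(cs, trace, events, duty_fraction=0.5)
        assert mask.retained_fraction == pytest.approx(0.5, abs=0.02)

    def test_threshold_mode_also_hits_duty(self, irregular_trace, irregular_events):
        cs = rg.analyze_trace(irregular_trace)
        mask = rg.gate_method2_adaptive(
            cs, irregular_trace, irregular_events, duty_fraction=0.5, mode="threshold"
        )
        assert mask.retained_fraction == pytest.approx(0.5, abs=0.02)

    def test_cycle_without_events_yields_no_window(self):
        amps = np.array([5.0, 3.0, 1.0, 0.0, 1.0, 2.0, 4.0, 6.0])
        trace = rg.RespiratoryTrace(times=np.arange(8.0), amplitudes=amps, sample_rate=1.0)
        events = rg.EventStream(event_times=np.array([20.0]), displacements=np.array([0.0]))
        cs = make_single_cycle(0.0, 8.0, 3.0)
        mask = rg.gate_method2_adaptive(cs, trace, events, include_edges=False)
        assert len(mask.windows) == 0
        assert mask.retained_fraction == 0.0


class TestOverlap:
    def _mask(self, retained, t_lo, t_hi):
        return rg.GateMask(
            method="method1",
            windows=(rg.GateWindow(0, t_lo, t_hi),),
            retained=retained,
            retained_fraction=float(retained.mean()),
        )

    def test_identical_masks_overlap_one(self, regular_trace, regular_events):
        cs = rg.analyze_trace(regular_trace)
        m = rg.gate_method1_qpg(cs, regular_events)
        assert rg.compute_overlap(m, m, regular_events).overlap == pytest.approx(1.0)

    def test_disjoint_and_half_shifted_masks(self):
        events = _uniform_events(0.0, 150.0, 150)
        idx = np.arange(150)
        a = self._mask(idx < 100, 0.0, 100.0)
        b = self._mask((idx >= 50) & (idx < 150), 50.0, 150.0)
        c = self._mask(idx >= 100, 100.0, 150.0)
        assert rg.compute_overlap(a, b, events).overlap == pytest.approx(0.5)
        assert rg.compute_overlap(a, c, events).overlap == 0.0

    def test_symmetry_and_bounds(self, irregular_trace, irregular_events):
        cs = rg.analyze_trace(irregular_trace)
        m1 = rg.gate_method1_qpg(cs, irregular_events)
        m2 = rg.gate_method2_adaptive(cs, irregular_trace, irregular_events)
        ab = rg.compute_overlap(m1, m2, irregular_events)
        ba = rg.compute_overlap(m2, m1, irregular_events)
        assert ab.overlap == pytest.approx(ba.overlap)
        assert 0.0 <= ab.overlap <= 1.0

    def test_zero_retention_rejected(self):
        events = _uniform_events(0.0, 10.0, 10)
        empty = rg.GateMask("method1", (), np.zeros(10, bool), 0.0)
        full = self._mask(np.ones(10, bool), 0.0, 10.0)
        with pytest.raises(GatingError):
            rg.compute_overlap(empty, full, events)


class TestGatingCohortProperties:
    def _cohort(self, n, rate=600.0):
        rows = []
        for seed in range(n):
            jitter = 1.5 * seed / max(n - 1, 1)
            p = rg.WaveformParams(
                mean_period=4.0, period_jitter_sd=jitter, duration=120.0, seed=300 + seed
            )
            trace = rg.simulate_trace(p)
            events = rg.simulate_events(trace, rate=rate, seed=600 + seed)
            cs = rg.analyze_trace(trace)
            m1 = rg.gate_method1_qpg(cs, events)
            m2 = rg.gate_method2_adaptive(cs, trace, events)
            rows.append(
                (
                    cs.tvar,
                    rg.compute_overlap(m1, m2, events).overlap,
                    float(np.std(events.displacements[m1.retained])),
                    float(np.std(events.displacements[m2.retained])),
                )
            )
        return np.array(rows)

    def test_overlap_decreases_with_breathing_irregularity(self):
        rows = self._cohort(20)
        res = rg.regress_overlap_on_tvar(rows[:, 0], rows[:, 1])
        assert res.slope < 0

    def test_amplitude_gating_leaves_less_residual_motion(self):
        # within-gate displacement SD, paired per scan on erratic breathing
        sds = []
        for seed in range(10):
            p = rg.WaveformParams(
                mean_period=4.0, period_jitter_sd=1.2, duration=120.0, seed=seed
            )
            trace = rg.simulate_trace(p)
            events = rg.simulate_events(trace, rate=600.0, seed=seed + 900)
            cs = rg.analyze_trace(trace)
            m1 = rg.gate_method1_qpg(cs, events)
            m2 = rg.gate_method2_adaptive(cs, trace, events)
            sds.append(
                (
                    np.std(events.displacements[m1.retained]),
                    np.std(events.displacements[m2.retained]),
                )
            )
        sds = np.array(sds)
        assert sds[:, 1].mean() <= sds[:, 0].mean()


class TestRValue:
    def test_in_band_sinusoid_passes_threshold(self):
        t = np.arange(3001) / 25.0
        rng = np.random.default_rng(5)
        amps = 10.0 * np.sin(2 * np.pi * 0.25 * t) + rng.normal(0, 1.0, len(t))
        trace = rg.RespiratoryTrace(times=t, amplitudes=amps, sample_rate=25.0)
        res = rg.compute_r_value(trace)
        assert res.r > 15.0 and res.passes_threshold

    def test_white_noise_stays_below_threshold(self):
        t = np.arange(3001) / 25.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            trace = rg.RespiratoryTrace(
                times=t, amplitudes=rng.normal(0, 1.0, len(t)), sample_rate=25.0
            )
            assert rg.compute_r_value(trace).r < 15.0

    def test_flat_trace_rejected(self):
        t = np.arange(3001) / 25.0
        trace = rg.RespiratoryTrace(times=t, amplitudes=np.zeros(len(t)), sample_rate=25.0)
        with pytest.raises(GatingError, match="variance"):
            rg.compute_r_value(trace)

    def test_short_trace_rejected(self):
        t = np.arange(250) / 25.0
        trace = rg.RespiratoryTrace(times=t, amplitudes=np.sin(t), sample_rate=25.0)
        with pytest.raises(GatingError, match="short"):
            rg.compute_r_value(trace)
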