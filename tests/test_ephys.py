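import numpy as np
import pytest

from striamap.ephys import (
    APEvent,
    CellClass,
    EphysError,
    SweepRecording,
    classify_cell,
    compute_hhw,
    compute_passive,
    compute_train_features,
    detect_aps,
    steady_state_check,
)

DT = 0.05  # ms, 20 kHz


def make_sweep(knots_t, knots_v, total=700.0, current=400.0, window=(100.0, 600.0)):
    """Piecewise-linear sweep through grid-snapped knot times."""
    t = np.arange(int(round(total / DT)) + 1) * DT
    v = np.interp(t, knots_t, knots_v)
    return SweepRecording(time=t, voltage=v, current_step=current, step_window=window)


def triangle_sweep(thr_t, rise, fall, thr_v=0.0, peak_v=40.0, base=-75.0):
    """One triangular AP (threshold at thr_t) with a slow subthreshold approach."""
    knots_t = [0.0, 100.0, thr_t, thr_t + rise, thr_t + rise + fall, 600.0, 700.0]
    knots_v = [base, base, thr_v, peak_v, thr_v, thr_v, base]
    return make_sweep(knots_t, knots_v)


class TestDetectAps:
    def test_flat_trace_no_events(self):
        s = make_sweep([0.0, 700.0], [-75.0, -75.0], current=100.0)
        assert detect_aps(s) == []

    def test_planted_train_threshold_times(self):
        # three triangular APs with thresholds at 200, 210, 225 ms
        knots_t = [0.0, 100.0, 105.0]
        knots_v = [-75.0, -75.0, -45.0]
        for tau in (200.0, 210.0, 225.0):
            knots_t += [tau, tau + 0.5, tau + 1.5, tau + 4.0]
            knots_v += [-45.0, 15.0, -55.0, -45.0]
        knots_t += [600.0, 700.0]
        knots_v += [-45.0, -75.0]
        s = make_sweep(knots_t, knots_v)
        events = detect_aps(s)
        assert [e.threshold[0] for e in events] == pytest.approx([200.0, 210.0, 225.0])
        assert all(e.threshold[0] < e.peak[0] < e.ahp[0] for e in events)

    def test_double_hump_single_event_global_peak(self):
        # two local maxima above threshold within one excursion
        knots_t = [0.0, 100.0, 105.0, 200.0, 200.5, 200.8, 201.2, 202.0, 205.0, 600.0, 700.0]
        knots_v = [-75.0, -75.0, -45.0, -45.0, 10.0, 0.0, 25.0, -55.0, -45.0, -45.0, -75.0]
        s = make_sweep(knots_t, knots_v)
        events = detect_aps(s)
        assert len(events) == 1
        assert events[0].peak[1] == pytest.approx(25.0, abs=0.5)


class TestHHW:
    def test_symmetric_triangle(self):
        s = triangle_sweep(200.0, rise=1.0, fall=1.0)
        (e,) = detect_aps(s)
        # crossings at 0.5 and 1.5 ms after threshold by symmetry
        assert compute_hhw(s, e) == pytest.approx(1.0, abs=2 * 2.0 / 999)

    def test_amplitude_scaling_invariance(self):
        s1 = triangle_sweep(200.0, rise=1.0, fall=1.0, peak_v=40.0)
        s2 = triangle_sweep(200.0, rise=1.0, fall=1.0, peak_v=80.0)
        (e1,), (e2,) = detect_aps(s1), detect_aps(s2)
        assert compute_hhw(s1, e1) == pytest.approx(compute_hhw(s2, e2), abs=1e-9)

    def test_sawtooth_analytic_crossings(self):
        # rise 0→40 over 1.5 ms, fall over 0.5 ms: crossings 0.75 and 1.75
        s = triangle_sweep(200.0, rise=1.5, fall=0.5)
        (e,) = detect_aps(s)
        assert compute_hhw(s, e) == pytest.approx(1.0, abs=2 * 2.0 / 999)

    def test_time_translation_invariance(self):
        a = triangle_sweep(200.0, rise=1.0, fall=0.6)
        b = triangle_sweep(350.0, rise=1.0, fall=0.6)
        (ea,), (eb,) = detect_aps(a), detect_aps(b)
        assert compute_hhw(a, ea) == pytest.approx(compute_hhw(b, eb), abs=1e-9)

    def test_never_recrossing_is_error(self):
        t = np.arange(0, 700.0 + DT / 2, DT)
        v = np.full_like(t, -75.0)
        s = SweepRecording(time=t, voltage=v, current_step=400.0, step_window=(100.0, 600.0))
        e = APEvent(threshold=(200.0, -75.0), peak=(201.0, -74.9), ahp=(202.0, -75.0))
        with pytest.raises(EphysError, match="recross|half"):
            # flat trace never reaches the half level of a fabricated event
            compute_hhw(s, APEvent(threshold=(200.0, 0.0), peak=(201.0, 40.0), ahp=(202.0, 0.0)))


class TestTrainFeatures:
    def _events(self, times):
        return [
            APEvent(threshold=(t, -45.0), peak=(t + 0.3, 10.0), ahp=(t + 1.0, -55.0))
            for t in times
        ]

    def test_hand_computed_train(self):
        fs = compute_train_features(self._events([100.0, 110.0, 125.0]))
        assert fs.isi == pytest.approx([10.0, 15.0])
        assert fs.iff == pytest.approx([100.0, 1000.0 / 15.0])
        assert fs.mff == pytest.approx(100.0)

    def test_uniform_train_mean_iff(self):
        fs = compute_train_features(self._events([0.0, 10.0, 20.0]))
        assert fs.mean_iff == pytest.approx(100.0)

    def test_iff_isi_product_and_mff_bound(self, rng):
        times = np.cumsum(rng.uniform(5, 50, size=20))
        fs = compute_train_features(self._events(times))
        assert np.allclose(fs.iff * fs.isi, 1000.0)
        assert fs.mff >= fs.mean_iff

    def test_single_event_flagged(self):
        fs = compute_train_features(self._events([100.0]))
        assert fs.mff is None
        assert "too_few_events_for_isi" in fs.flags


class TestPassive:
    def _ohmic(self, current, dv, rmp=-75.0):
        knots_t = [0.0, 100.0, 100.0 + DT, 600.0, 600.0 + DT, 700.0]
        knots_v = [rmp, rmp, rmp + dv, rmp + dv, rmp, rmp]
        return make_sweep(knots_t, knots_v, current=current)

    def test_ohms_law(self):
        sweeps = [self._ohmic(-100.0, -10.0), self._ohmic(-200.0, -20.0)]
        rmp, rin = compute_passive(sweeps)
        assert rmp == pytest.approx(-75.0)
        assert rin == pytest.approx(100.0, rel=1e-6)

    def test_single_step_undefined(self):
        with pytest.raises(EphysError, match="distinct"):
            compute_passive([self._ohmic(0.0, 0.0), self._ohmic(0.0, 0.0)])


class TestSteadyStateAndClassification:
    def _events(self, isis):
        times = np.concatenate([[100.0], 100.0 + np.cumsum(isis)])
        return [
            APEvent(threshold=(t, -45.0), peak=(t + 0.2, 10.0), ahp=(t + 0.8, -55.0))
            for t in times
        ]

    def test_uniform_isis_steady(self):
        ok, _ = steady_state_check(self._events([10.0] * 8))
        assert ok

    def test_doubling_isis_not_steady(self):
        ok, _ = steady_state_check(self._events([5.0, 10.0, 20.0, 40.0, 80.0]), cv_cut=0.2)
        assert not ok

    def test_too_few_events(self):
        ok, reason = steady_state_check(self._events([10.0, 10.0]))
        assert not ok and "few" in reason

    @pytest.mark.parametrize(
        "hhw,iff,expected",
        [
            (0.4043, 75.21, CellClass.FSI),
            (1.282, 26.47, CellClass.SPN),
            (0.4, 20.0, CellClass.AMBIGUOUS),
        ],
    )
    def test_classification_from_group_means(self, hhw, iff, expected):
        from striamap.ephys import APFeatureSet

        fs = APFeatureSet(hhw=np.array([hhw]), mean_iff=iff, steady_state=True)
        assert classify_cell(fs) is expected

    def test_not_steady_is_ambiguous(self):
        from striamap.ephys import APFeatureSet

        fs = APFeatureSet(hhw=np.array([0.4]), mean_iff=80.0, steady_state=False)
        assert classify_cell(fs) is CellClass.AMBIGUOUS
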