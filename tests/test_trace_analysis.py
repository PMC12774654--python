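"""Smoothing, step detection, ramp unfolding detection, QC."""
import numpy as np
import pytest

from dnacaliper.errors import ArgumentError, PreconditionError
from dnacaliper.polymer_mechanics import ConstructDesign, PolymerSegment, wlc_extension
from dnacaliper.presets import get_preset
from dnacaliper.simulator import NoiseSpec, simulate_force_jump_trace
from dnacaliper.trace_analysis import (
    Trace,
    classify_cycle_events,
    detect_constant_force_steps,
    detect_ramp_unfolding,
    sliding_window_average,
    validate_tether,
)

FS = 1400.0

NA_BANDS = {"unfold": (2.0, 9.0), "unloop_unfolded": (18.0, 22.0),
            "unloop_folded": (24.0, 28.0)}


def _hold_trace(levels, seg_len, sigma, rng, force=10.0):
    """Constant-force trace whose extension is piecewise constant."""
    x = np.concatenate([np.full(seg_len, lv) for lv in levels])
    if sigma:
        x = x + rng.normal(0, sigma, size=len(x))
    n = len(x)
    return Trace(np.arange(n) / FS, np.full(n, force), x, FS)


class TestSlidingWindowAverage:
    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=100)
        assert np.array_equal(sliding_window_average(x, 1), x)

    def test_constant_series_unchanged(self):
        x = np.full(500, 3.14)
        assert np.allclose(sliding_window_average(x, 200), 3.14)

    def test_noise_reduction_scales_as_sqrt_window(self, rng):
        x = rng.normal(size=100_000)
        w = 200
        sm = sliding_window_average(x, w)[w:-w]
        assert np.std(sm) == pytest.approx(1.0 / np.sqrt(w), rel=0.10)

    def test_length_preserved_and_bad_window_rejected(self, rng):
        x = rng.normal(size=50)
        assert len(sliding_window_average(x, 7)) == 50
        with pytest.raises(ArgumentError):
            sliding_window_average(x, 0)


class TestConstantForceSteps:
    def test_step_free_plateau_yields_no_events(self, rng):
        tr = _hold_trace([100.0], 4000, 2.0, rng)
        assert detect_constant_force_steps(tr) == []

    def test_single_26nm_step_sized_within_half_nm(self, rng):
        tr = _hold_trace([100.0, 126.0], 2000, 2.0, rng)
        events = detect_constant_force_steps(tr)
        assert len(events) == 1
        assert events[0].deltaL == pytest.approx(26.0, abs=0.5)

    def test_sequential_unfold_then_unloop_steps(self, rng):
        # the sodium pattern: 6 nm unfolding then 20 nm unlooping
        tr = _hold_trace([100.0, 106.0, 126.0], 1400, 2.0, rng)
        events = detect_constant_force_steps(tr)
        assert len(events) == 2
        assert events[0].time < events[1].time
        assert events[0].deltaL == pytest.approx(6.0, abs=0.5)
        assert events[1].deltaL == pytest.approx(20.0, abs=0.5)

    def test_reversed_trace_detects_sign_flipped_magnitudes(self, rng):
        tr = _hold_trace([100.0, 126.0], 2000, 2.0, rng)
        rev = Trace(tr.time, tr.force, tr.extension[::-1].copy(), FS)
        fwd = detect_constant_force_steps(tr)
        bwd = detect_constant_force_steps(rev)
        assert len(fwd) == len(bwd) == 1
        assert bwd[0].deltaL == pytest.approx(-fwd[0].deltaL, abs=0.3)

    def test_nonconstant_force_raises_naming_samples(self, rng):
        tr = _hold_trace([100.0], 1000, 2.0, rng)
        tr.force[500:510] = 20.0
        with pytest.raises(PreconditionError, match="500"):
            detect_constant_force_steps(tr)

    def test_subthreshold_steps_ignored(self, rng):
        tr = _hold_trace([100.0, 101.0], 2000, 0.1, rng)
        events = detect_constant_force_steps(tr, min_step=2.0)
        assert events == []

    def test_recall_and_accuracy_on_simulated_holds(self):
        # >= 95% recall and <= 0.5 nm MAE for 27 nm steps at sigma_x = 2 nm
        preset = get_preset("k_endtoend", n_molecules=1, cycles=25)
        found, errors, n_true = 0, [], 0
        for seed in range(4):
            noise = NoiseSpec(sigma_x=2.0, sigma_deltaL=0.0, seed=seed)
            tr, log = simulate_force_jump_trace(
                preset.design, preset.geometry, preset.protocol,
                preset.kinetics, noise,
            )
            truth = {int(round(t * FS)): dl for t, dl in
                     zip(log["time_s"], log["deltaL_true"])}
            n_true += len(truth)
            for seg in tr.segments:
                if seg["phase"] != "high":
                    continue
                for ev in detect_constant_force_steps(
                    tr, (seg["i0"], seg["i1"])
                ):
                    k = int(round(ev.time * FS))
                    match = [dl for kk, dl in truth.items() if abs(kk - k) < 140]
                    if match:
                        found += 1
                        errors.append(abs(ev.deltaL - match[0]))
        assert found / n_true >= 0.95
        assert np.mean(errors) <= 0.5


def _ramp_trace(lc_pre, release, f_event, sigma, rng, fs=FS,
                f0=1.0, f1=45.0, rate=6.0):
    n = int(round((f1 - f0) / rate * fs))
    F = f0 + rate * np.arange(n) / fs
    lp = 50.0
    x = np.empty(n)
    pre = PolymerSegment("double-stranded", lc_pre, lp)
    post = PolymerSegment("double-stranded", lc_pre + release, lp)
    k = int((f_event - f0) / (f1 - f0) * n)
    x[:k] = wlc_extension(F[:k], pre)
    x[k:] = wlc_extension(F[k:], post)
    if sigma:
        x = x + rng.normal(0, sigma, n)
    return Trace(np.arange(n) / fs, F, x, fs,
                 segments=[{"cycle": 0, "phase": "ramp", "i0": 0, "i1": n,
                            "force": None}])


class TestRampUnfolding:
    def test_known_release_recovered_within_tolerances(self, rng):
        tr = _ramp_trace(976.0, 6.0, 21.0, 2.0, rng)
        ev = detect_ramp_unfolding(tr)
        assert ev.event_type == "unfold"
        assert ev.deltaL == pytest.approx(6.0, abs=1.0)
        assert ev.force == pytest.approx(21.0, abs=1.0)

    def test_event_free_ramp_returns_none_type(self, rng):
        tr = _ramp_trace(976.0, 0.0, 21.0, 2.0, rng)
        ev = detect_ramp_unfolding(tr)
        assert ev.event_type == "none"

    def test_release_below_detection_floor_returns_none(self, rng):
        # models the unobservable pulling direction
        tr = _ramp_trace(976.0, 1.0, 21.0, 0.5, rng)
        ev = detect_ramp_unfolding(tr, min_deltaL=2.0)
        assert ev.event_type == "none"


class TestClassifyCycleEvents:
    BANDS = {"unfold": (2, 9), "unloop_folded": (24, 28),
             "unloop_unfolded": (18, 22)}

    def _ev(self, dl, t):
        from dnacaliper.trace_analysis import EventRecord

        return EventRecord("m", 0, "step", dl, 10.0, t)

    def test_single_folded_unloop(self):
        out = classify_cycle_events([self._ev(26.0, 1.0)], self.BANDS)
        assert out[0].label == "unloop_folded"
        assert out[0].event_type == "unloop"

    def test_unfold_then_unloop_sequence(self):
        out = classify_cycle_events(
            [self._ev(6.0, 1.0), self._ev(20.0, 1.5)], self.BANDS
        )
        assert [e.label for e in out] == ["unfold", "unloop_unfolded"]
        assert [e.event_type for e in out] == ["unfold", "unloop"]

    def test_out_of_band_event_marked_ambiguous_not_dropped(self):
        out = classify_cycle_events([self._ev(15.0, 1.0)], self.BANDS)
        assert len(out) == 1
        assert out[0].label == "ambiguous"


class TestValidateTether:
    design = ConstructDesign(2820, 73, 30, {"3p": 9}, ("3p",))

    def _pull_trace(self, scale, rng, fmax=50.0):
        n = 5000
        F = np.linspace(0.5, fmax, n)
        seg = PolymerSegment("double-stranded", 990.0, 50.0)
        x = scale * wlc_extension(F, seg) + rng.normal(0, 2.0, n)
        return Trace(np.arange(n) / FS, F, x, FS)

    def test_single_tether_passes(self, rng):
        report = validate_tether(self._pull_trace(1.0, rng), self.design)
        assert report.status == "pass"
        expected = report.expected_Lc
        assert abs(report.fitted_Lc - expected) <= 0.15 * expected

    def test_doubled_extension_fails(self, rng):
        report = validate_tether(self._pull_trace(2.0, rng), self.design)
        assert report.status == "fail"

    def test_no_high_force_data_indeterminate(self, rng):
        report = validate_tether(self._pull_trace(1.0, rng, fmax=8.0),
                                 self.design)
        assert report.status == "indeterminate"
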