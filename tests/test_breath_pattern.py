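import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from varvent.breath_pattern import (BreathDetectionError, BreathRecord,
                                    PlethysmographRecording, VentilationPattern,
                                    build_pvv_pattern, detect_breaths,
                                    find_artifact_intervals, loop_schedule,
                                    pattern_from_series, pattern_statistics,
                                    remove_artifact_segments, rescale_pattern)
from varvent.synthetic_data import (BreathingSimParams,
                                    generate_spontaneous_breathing)


def _breaths(amps, pers):
    return [BreathRecord(i, a, p, p / 4) for i, (a, p) in
            enumerate(zip(amps, pers))]


class TestDetectBreaths:
    def test_pure_sinusoid_periods_within_one_sample(self):
        fs = 250.0
        t = np.arange(0, 60, 1 / fs)
        rec = PlethysmographRecording(np.sin(2 * np.pi * 0.4 * t), fs)
        breaths = detect_breaths(rec)
        assert len(breaths) == 24
        periods = np.array([b.period for b in breaths])
        assert np.all(np.abs(periods - 2.5) <= 1.0 / fs)

    def test_amplitude_cv_round_trip(self):
        params = BreathingSimParams(seed=3, sampling_rate=250.0,
                                    artifact_rate=0.0)
        rec, truth = generate_spontaneous_breathing(params, 600.0)
        breaths = detect_breaths(rec)
        amps = np.array([b.amplitude for b in breaths])
        cv_est = amps.std(ddof=1) / amps.mean()
        cv_true = truth.amplitude.std(ddof=1) / truth.amplitude.mean()
        assert abs(cv_est - cv_true) < 0.01

    def test_fully_artifactual_recording_errors(self):
        fs = 250.0
        t = np.arange(0, 30, 1 / fs)
        rec = PlethysmographRecording(np.sin(2 * np.pi * 0.4 * t), fs,
                                      artifact_intervals=[(0.0, 30.0)])
        with pytest.raises(BreathDetectionError):
            detect_breaths(rec)


class TestArtifactRemoval:
    def test_no_artifacts_is_identity(self):
        rec = PlethysmographRecording(np.sin(np.arange(1000) / 40.0), 100.0)
        out = remove_artifact_segments(rec)
        assert np.array_equal(out.samples, rec.samples)
        assert out.segment_edges == []

    def test_excision_bookkeeping(self):
        fs = 100.0
        rec = PlethysmographRecording(np.zeros(60000), fs,
                                      artifact_intervals=[(100.0, 105.0)])
        out = remove_artifact_segments(rec)
        assert out.duration == pytest.approx(595.0, abs=1 / fs)
        assert out.segment_edges == [pytest.approx(100.0, abs=1 / fs)]

    def test_detector_removes_annotated_artifact_samples(self):
        params = BreathingSimParams(seed=7, sampling_rate=250.0,
                                    artifact_rate=1.0)
        rec, _ = generate_spontaneous_breathing(params, 600.0)
        assert rec.artifact_intervals, "fixture should contain artifacts"
        fs = rec.sampling_rate
        truth_mask = np.zeros(len(rec.samples), dtype=bool)
        for a, b in rec.artifact_intervals:
            truth_mask[int(a * fs):int(b * fs)] = True
        det_mask = np.zeros_like(truth_mask)
        for a, b in find_artifact_intervals(rec):
            det_mask[int(a * fs):int(b * fs)] = True
        removed = (truth_mask & det_mask).sum() / truth_mask.sum()
        assert removed >= 0.95


class TestPatternAlgebra:
    def test_equal_breaths_give_unit_ratios(self):
        pat = build_pvv_pattern(_breaths([3.0] * 5, [2.0] * 5), n_breaths=5)
        assert np.allclose(pat.pressure_ratios, 1.0)
        assert np.allclose(pat.period_ratios, 1.0)

    def test_direct_arithmetic(self):
        pat = build_pvv_pattern(_breaths([5, 7, 9], [2, 2, 2]), n_breaths=3)
        assert pat.pressure_ratios == pytest.approx([5 / 7, 1.0, 9 / 7])
        assert pat.period_ratios == pytest.approx([1.0, 1.0, 1.0])

    def test_shortfall_names_the_deficit(self):
        with pytest.raises(ValueError, match="short by 380"):
            build_pvv_pattern(_breaths([5, 7], [2, 2]), n_breaths=382)

    @given(hnp.arrays(np.float64, st.integers(2, 50),
                      elements=st.floats(0.1, 50.0)),
           hnp.arrays(np.float64, st.integers(2, 50),
                      elements=st.floats(0.5, 10.0)))
    def test_unit_mean_invariant(self, amps, pers):
        n = min(len(amps), len(pers))
        pat = pattern_from_series(amps[:n], pers[:n])
        assert abs(pat.pressure_ratios.mean() - 1.0) <= 1e-9
        assert abs(pat.period_ratios.mean() - 1.0) <= 1e-9

    def test_rescale_preserves_cv_exactly(self):
        rng = np.random.default_rng(0)
        pat = pattern_from_series(rng.lognormal(0, 0.126, 382),
                                  rng.lognormal(0, 0.129, 382))
        sched = rescale_pattern(pat, target_mean_rr=22.9, target_mean_vt=7.1)
        cv_pat = pat.pressure_ratios.std(ddof=1) / pat.pressure_ratios.mean()
        cv_sched = sched.vt.std(ddof=1) / sched.vt.mean()
        assert cv_sched == pytest.approx(cv_pat, rel=1e-12)
        assert sched.vt.mean() == pytest.approx(7.1, rel=1e-12)

    def test_rescale_composition(self):
        pat = pattern_from_series([5, 7, 9.0], [2, 2.5, 3.0])
        once = rescale_pattern(pat, 30.0, 8.0)
        rebuilt = pattern_from_series(
            rescale_pattern(pat, 15.0, 4.0).vt,
            rescale_pattern(pat, 15.0, 4.0).period)
        twice = rescale_pattern(rebuilt, 30.0, 8.0)
        assert np.allclose(once.vt, twice.vt, rtol=1e-12)
        assert np.allclose(once.period, twice.period, rtol=1e-12)

    def test_rescale_arithmetic(self):
        pat = VentilationPattern([0.5, 1.5], [1.0, 1.0])
        sched = rescale_pattern(pat, target_mean_rr=20.0, target_mean_vt=8.0)
        assert sched.vt == pytest.approx([4.0, 12.0])

    def test_build_rescale_round_trip(self):
        rng = np.random.default_rng(5)
        pat = pattern_from_series(rng.lognormal(2, 0.2, 100),
                                  rng.lognormal(1, 0.1, 100))
        sched = rescale_pattern(pat, 22.9, 7.1)
        back = pattern_from_series(sched.vt, sched.period)
        assert np.allclose(back.pressure_ratios, pat.pressure_ratios,
                           atol=1e-9)
        assert np.allclose(back.period_ratios, pat.period_ratios, atol=1e-9)

    def test_loop_closure(self):
        rng = np.random.default_rng(1)
        pat = pattern_from_series(rng.lognormal(2, 0.13, 382),
                                  rng.lognormal(1, 0.13, 382))
        sched = rescale_pattern(pat, 22.9, 7.1)
        looped = loop_schedule(sched, 3)
        assert looped.n_breaths == 3 * 382
        for k in range(3):
            part = looped.vt[k * 382:(k + 1) * 382]
            assert part.mean() == sched.vt.mean()
            assert part.std(ddof=1) == sched.vt.std(ddof=1)


class TestPatternStatistics:
    def test_constant_series(self):
        stats = pattern_statistics(np.full(10, 7.0), np.full(10, 2.5))
        assert stats.loc["cv_pct", "vt"] == 0.0
        assert stats.loc["min", "vt"] == stats.loc["max", "vt"] == 7.0

    def test_hand_computed_cv(self):
        stats = pattern_statistics(np.array([4.0, 6, 8, 10]), np.full(4, 2.5))
        assert stats.loc["mean", "vt"] == pytest.approx(7.0)
        assert stats.loc["cv_pct", "vt"] == pytest.approx(36.886, abs=0.01)

    def test_single_breath_errors(self):
        with pytest.raises(ValueError):
            pattern_statistics(np.array([7.0]), np.array([2.5]))

    def test_default_schedule_matches_recorded_pattern(self, pvv_pattern):
        """Full-pipeline pattern rescaled to study targets shows the recorded
        VT variability (CV near 12.6%, min/max near 3.7/10.7 mL/kg)."""
        sched = rescale_pattern(pvv_pattern, 22.9, 7.1)
        stats = pattern_statistics(sched.vt, sched.period)
        assert abs(stats.loc["cv_pct", "vt"] - 12.6) < 3.0
        assert 2.5 < stats.loc["min", "vt"] < 5.5
        assert 9.0 < stats.loc["max", "vt"] < 13.5


class TestPatternIO:
    def test_bit_exact_round_trip(self, tmp_path):
        from varvent.io import read_pattern, write_pattern
        rng = np.random.default_rng(9)
        pat = pattern_from_series(rng.lognormal(2, 0.13, 382),
                                  rng.lognormal(1, 0.13, 382))
        path = tmp_path / "pattern.tsv"
        write_pattern(path, pat)
        back = read_pattern(path)
        assert np.array_equal(back.pressure_ratios, pat.pressure_ratios)
        assert np.array_equal(back.period_ratios, pat.period_ratios)

    def test_checksum_detects_tampering(self, tmp_path):
        from varvent.io import read_pattern, write_pattern
        pat = pattern_from_series([5, 7, 9.0], [2, 2, 2.0])
        path = tmp_path / "pattern.tsv"
        write_pattern(path, pat)
        path.write_text(path.read_text().replace("1", "2", 1))
        with pytest.raises(ValueError, match="checksum"):
            read_pattern(path)
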