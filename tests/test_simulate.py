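"""Generator correctness: RR model, event injection, waveform, wall images."""

import numpy as np
import pytest
from scipy.signal import lombscargle

from mousebeat import simulate as sim


class TestGenerateRR:
    def test_degenerate_no_noise_gives_constant_rr(self):
        rr = sim.generate_rr_series(sim.RRSpec(100.0, 0.0, duration_s=10.0, seed=0))
        assert np.allclose(rr.rr, 100.0)

    def test_sample_sd_matches_spec(self):
        # law of large numbers: ~12000 beats pin the sample SD
        rr = sim.generate_rr_series(
            sim.RRSpec(100.0, 2.0, duration_s=1200.0, seed=42))
        assert rr.rr.size > 11000
        assert abs(np.std(rr.rr, ddof=1) - 2.0) < 0.1

    def test_hf_modulation_peaks_at_set_frequency(self):
        rr = sim.generate_rr_series(
            sim.RRSpec(100.0, 0.5, hf_mod=(3.0, 3.0), duration_s=120.0, seed=7))
        t = rr.r_times[1:] / 1000.0
        y = rr.rr - rr.rr.mean()
        f = np.linspace(0.1, 5.0, 2000)
        pgram = lombscargle(t, y, 2 * np.pi * f)
        assert abs(f[np.argmax(pgram)] - 3.0) < 0.05

    def test_cumulative_time_covers_duration(self):
        rr = sim.generate_rr_series(sim.RRSpec(100.0, 2.0, duration_s=60.0, seed=1))
        assert rr.r_times[-1] >= 60_000.0

    def test_determinism(self):
        a = sim.generate_rr_series(sim.RRSpec(100.0, 2.0, duration_s=30.0, seed=9))
        b = sim.generate_rr_series(sim.RRSpec(100.0, 2.0, duration_s=30.0, seed=9))
        np.testing.assert_array_equal(a.r_times, b.r_times)

    @pytest.mark.parametrize("bad", [
        sim.RRSpec(mean_rr_ms=-1.0),
        sim.RRSpec(sd_rr_ms=-0.1),
        sim.RRSpec(hf_mod=(20.0, 1.0)),  # above beat-rate Nyquist (5 Hz)
        sim.RRSpec(duration_s=0.0),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            sim.generate_rr_series(bad)

    def test_infeasible_sd_fails_explicitly(self):
        with pytest.raises(ValueError, match="infeasible"):
            sim.generate_rr_series(
                sim.RRSpec(1.0, 500.0, duration_s=5.0, seed=0), max_resample=5)


def constant_series(n=400, rr_ms=100.0):
    r = np.arange(n, dtype=float) * rr_ms
    return sim.RRSeries(r, beat_flags=np.zeros(n, dtype=int))


class TestInjectEvents:
    def test_empty_specs_identity(self):
        base = constant_series()
        out, truth = sim.inject_events(base, [], seed=0)
        np.testing.assert_array_equal(out.r_times, base.r_times)
        assert truth.event_log == []

    def test_single_extrasystole_compensatory_arithmetic(self):
        # prematurity 0.6 in a 100 ms rhythm: ... 100, 60, 140, 100 ...
        base = constant_series()
        spec = sim.EventSpec("extrasystole_single", 1, prematurity=0.6)
        out, truth = sim.inject_events(base, [spec], seed=0, positions={0: 50})
        rr = out.rr
        j = int(np.argmin(rr))
        assert rr[j] == pytest.approx(60.0)
        assert rr[j + 1] == pytest.approx(140.0)
        assert rr[j - 1] == pytest.approx(100.0) and rr[j + 2] == pytest.approx(100.0)
        # local-cycle conservation, exact
        assert rr[j] + rr[j + 1] == pytest.approx(200.0, abs=1e-9)

    def test_sinus_arrest_unique_pause_without_p(self):
        base = constant_series()
        spec = sim.EventSpec("sinus_arrest", 1, pause_multiple=2.3)
        out, truth = sim.inject_events(base, [spec], seed=0)
        # oracle: scan output intervals for the unique > 2x interval
        long = np.nonzero(out.rr > 200.0)[0]
        assert long.size == 1
        assert out.rr[long[0]] == pytest.approx(230.0)
        t0, t1 = out.r_times[long[0]], out.r_times[long[0] + 1]
        inside = (truth.p_times > t0 + 1) & (truth.p_times < t1 - 50)
        assert not np.any(inside & np.isfinite(truth.p_times))

    def test_blocked_p_keeps_p_on_time(self):
        base = constant_series()
        out, truth = sim.inject_events(
            base, [sim.EventSpec("blocked_p", 1)], seed=0)
        drop = [i for i, lab in enumerate(truth.beat_labels) if lab == "dropped_qrs"]
        assert len(drop) == 1
        i = drop[0]
        assert np.isfinite(truth.p_times[i])
        # conducted series skips the dropped beat: one doubled interval
        assert np.isclose(out.rr, 200.0).sum() == 1

    def test_av_block_pr_escalates_on_preceding_conducted_beats(self):
        base = constant_series()
        out, truth = sim.inject_events(base, [sim.EventSpec("av_block", 1)], seed=0)
        i = [k for k, lab in enumerate(truth.beat_labels) if lab == "dropped_qrs"][0]
        prs = truth.beat_times[i - 3:i] - truth.p_times[i - 3:i]
        assert np.all(np.diff(prs) > 0)
        assert prs[-1] > 1.5 * (truth.beat_times[i - 5] - truth.p_times[i - 5])

    def test_beat_count_bookkeeping(self):
        base = constant_series(800)
        specs = [sim.EventSpec("extrasystole_doublet", 2),
                 sim.EventSpec("blocked_p", 3),
                 sim.EventSpec("sinus_arrest", 1)]
        out, truth = sim.inject_events(base, specs, seed=4)
        # truth retains every cycle; the conducted series drops blocked QRS
        assert truth.beat_times.size == 800
        assert out.n_beats == 800 - 3

    def test_truth_log_maps_to_existing_beats(self):
        base = constant_series(800)
        specs = [sim.EventSpec(t, 2, pause_multiple=2.5) for t in sim.EVENT_TYPES]
        _, truth = sim.inject_events(base, specs, seed=6)
        assert len(truth.event_log) == 12
        for ev in truth.event_log:
            assert 0 <= ev.beat_start <= ev.beat_end < truth.beat_times.size

    def test_overlapping_pinned_positions_rejected(self):
        base = constant_series()
        specs = [sim.EventSpec("sinus_arrest", 2)]
        with pytest.raises(ValueError, match="overlap"):
            sim.inject_events(base, specs, seed=0, positions={0: 100, 1: 105})

    def test_too_few_host_beats_fails(self):
        base = constant_series(40)
        with pytest.raises(ValueError, match="too few host beats"):
            sim.inject_events(base, [sim.EventSpec("sinus_arrest", 30)], seed=0)

    def test_non_sinus_base_rejected(self):
        base = constant_series()
        base.beat_flags[5] = 1
        with pytest.raises(ValueError, match="all-sinus"):
            sim.inject_events(base, [], seed=0)

    def test_determinism(self):
        base = constant_series(800)
        specs = [sim.EventSpec(t, 2) for t in sim.EVENT_TYPES]
        a, ta = sim.inject_events(base, specs, seed=11)
        b, tb = sim.inject_events(base, specs, seed=11)
        np.testing.assert_array_equal(a.r_times, b.r_times)
        assert [e.event_type for e in ta.event_log] == [e.event_type for e in tb.event_log]


class TestSynthesizeECG:
    def test_single_beat_argmax_at_r_time(self):
        truth = sim.BeatTruth(np.array([200.0, 300.0]), ["sinus", "sinus"],
                              np.array([180.0, 280.0]))
        tr = sim.synthesize_ecg(truth, fs=2000.0, noise_sd=0.0)
        t_peak = np.argmax(tr.samples) / tr.fs * 1000.0
        assert abs(t_peak - 300.0) <= 0.5 or abs(t_peak - 200.0) <= 0.5

    def test_trace_length_is_fs_times_duration(self):
        rr = sim.generate_rr_series(sim.RRSpec(100.0, 0.0, duration_s=59.0, seed=0))
        _, truth = sim.inject_events(rr, [], seed=0)
        tr = sim.synthesize_ecg(truth, fs=2000.0, duration_s=60.0)
        assert tr.samples.size == 120_000

    def test_blocked_beat_renders_p_without_r(self):
        base = constant_series()
        _, truth = sim.inject_events(base, [sim.EventSpec("blocked_p", 1)], seed=0)
        tr = sim.synthesize_ecg(truth, noise_sd=0.0)
        i = [k for k, lab in enumerate(truth.beat_labels) if lab == "dropped_qrs"][0]
        t_r = truth.beat_times[i] / 1000.0
        # no R deflection within 15 ms of the expected R time
        w = tr.samples[int((t_r - 0.008) * tr.fs):int((t_r + 0.015) * tr.fs)]
        assert w.max() < 0.5
        # P deflection present at its expected time
        t_p = truth.p_times[i] / 1000.0
        wp = tr.samples[int((t_p - 0.004) * tr.fs):int((t_p + 0.004) * tr.fs)]
        assert wp.max() > 0.08

    def test_low_sample_rate_rejected(self):
        truth = sim.BeatTruth(np.array([100.0, 200.0]), ["sinus", "sinus"],
                              np.array([80.0, 180.0]))
        with pytest.raises(ValueError, match="fs"):
            sim.synthesize_ecg(truth, fs=500.0)


class TestWallImage:
    def test_solid_annulus_fraction_zero(self):
        w = sim.generate_wall_image(
            sim.WallImageSpec(finger_count=0, target_fraction=0.0))
        assert w.achieved_fraction == 0.0

    def test_achieved_fraction_is_exact_pixel_count(self):
        w = sim.generate_wall_image(sim.WallImageSpec(target_fraction=0.2, seed=3))
        oracle = (w.roi_mask & ~w.tissue_mask).sum() / w.roi_mask.sum()
        assert w.achieved_fraction == oracle
        assert abs(w.achieved_fraction - 0.2) < 0.01

    def test_determinism_bitwise(self):
        spec = sim.WallImageSpec(target_fraction=0.15, noise_sd=4.0, seed=12)
        a = sim.generate_wall_image(spec)
        b = sim.generate_wall_image(spec)
        np.testing.assert_array_equal(a.image, b.image)

    def test_unreachable_target_names_range(self):
        with pytest.raises(ValueError, match="achievable range"):
            sim.generate_wall_image(sim.WallImageSpec(target_fraction=0.9))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_wall_image(
                sim.WallImageSpec(outer_radius=100, inner_radius=150))
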