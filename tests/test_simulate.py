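"""Entrainment simulator: phase map, activity emission, bioluminescence."""

import numpy as np
import pytest

from circakit import (
    clock_to_zt,
    cosinor_fit,
    detect_onsets,
    evolve_phase,
    make_dd,
    make_ld,
    make_sjl,
    normalize_to_daily_mean,
    onset_delays,
    organ_profile,
    phase_trajectory,
    preset,
    simulate_activity,
    simulate_bioluminescence,
)
from circakit.errors import InvalidArgumentError
from circakit.simulate import SimConfig, read_activity_csv, write_activity_csv

from _oracles import circular_signed_diff_oracle


def _noise_free(p="ND_NoWheel", **kw):
    return preset(p, onset_jitter_sd=0.0, lambda_rest=0.0, **kw)


class TestEvolvePhase:
    def test_ld_fixed_point_at_dark_onset(self):
        cfg = preset("ND_NoWheel")
        day = make_ld(1).day(1)
        assert evolve_phase(12.0, day, cfg) == pytest.approx(12.0)

    def test_dd_drift_equals_tau_minus_24(self):
        cfg = preset("ND_Wheel")
        day = make_dd(1).day(1)
        assert evolve_phase(12.0, day, cfg) == pytest.approx(11.5)

    def test_delayed_day_shift_capped(self):
        # 6-h delayed dark onset (ZT18): one day moves the phase by
        # min(delta_delay_max, r*gap) = 3.75 h
        cfg = SimConfig(tau=24.0, delta_delay_max=3.75, response_frac=0.625)
        day = make_sjl().day(8)
        assert evolve_phase(12.0, day, cfg) == pytest.approx(15.75)

    def test_correction_follows_shorter_circular_arc(self):
        # for any phase, the pull toward the dark onset must follow the
        # shorter arc (e.g. ZT23 -> ZT12 is -11 h, not +13)
        cfg = SimConfig(tau=24.0, delta_delay_max=10, delta_advance_max=10,
                        response_frac=1.0)
        sched = make_ld(1)
        day = sched.day(1)
        for psi in np.arange(0, 24, 0.5):
            target = day.dark_onset_zt()
            gap = circular_signed_diff_oracle(target, psi)
            expected = (psi + np.clip(gap, -10, 10)) % 24
            assert evolve_phase(psi, day, cfg) == pytest.approx(expected)

    def test_phase_is_circular(self):
        cfg = preset("ND_NoWheel")
        day = make_sjl().day(8)
        a = evolve_phase(3.0, day, cfg)
        b = evolve_phase(3.0 + 24.0, day, cfg)
        assert a == pytest.approx(b)


class TestActivitySimulation:
    def test_noise_free_ld_onsets_lock_to_zt12(self):
        sched = make_ld(7)
        rec = simulate_activity(sched, _noise_free(), rng=np.random.default_rng(0))
        onsets = detect_onsets(rec, sched).onsets
        assert np.allclose(onsets, 12.0, atol=0.11)  # within one 6-min bin

    def test_dd_drift_slope_matches_tau(self):
        sched = make_dd(10)
        rec = simulate_activity(sched, preset("ND_Wheel"),
                                rng=np.random.default_rng(42))
        onsets = detect_onsets(rec, sched).onsets
        days = np.arange(10)
        unwrapped = np.unwrap(onsets, period=24)
        slope = np.polyfit(days, unwrapped, 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)

    def test_sjl_saturday_delay_in_printed_range(self):
        sched = make_sjl()
        delays = []
        for i in range(10):
            rec = simulate_activity(sched, preset("ND_NoWheel"),
                                    rng=np.random.default_rng(100 + i))
            s = onset_delays(detect_onsets(rec, sched), range(1, 8))
            delays.append(s.delays[7])
        assert 3.5 <= np.mean(delays) <= 4.0

    def test_determinism_same_seed_same_counts(self):
        sched = make_sjl()
        cfg = preset("ND_Wheel", seed=7)
        a = simulate_activity(sched, cfg)
        b = simulate_activity(sched, cfg)
        assert np.array_equal(a.counts, b.counts)

    def test_masking_suppresses_active_bins_in_light(self):
        sched = make_ld(3)
        # push the active phase into the light: tau<24 drags onset earlier
        cfg = SimConfig(tau=22.0, delta_advance_max=0.0, delta_delay_max=0.0,
                        onset_jitter_sd=0.0, lambda_rest=0.0, masking=True)
        rec = simulate_activity(sched, cfg, rng=np.random.default_rng(3))
        bins_per_day = rec.bins_per_day
        # all light-phase bins (ZT0-12) must stay silent despite the early phase
        for d in range(3):
            lit = rec.counts[d * bins_per_day:d * bins_per_day + bins_per_day // 2]
            assert lit.sum() == 0

    def test_counts_roundtrip_csv(self, tmp_path):
        sched = make_ld(2)
        rec = simulate_activity(sched, preset("ND_NoWheel"),
                                rng=np.random.default_rng(5))
        path = tmp_path / "act.csv"
        write_activity_csv(rec, path)
        back = read_activity_csv(path)
        assert np.array_equal(back.counts, rec.counts)
        assert back.bin_minutes == rec.bin_minutes
        assert back.modality == rec.modality


class TestPresets:
    def test_no_wheel_tau_24(self):
        assert preset("ND_NoWheel").tau == 24.0

    def test_wheel_tau_23_5_and_larger_advance(self):
        w, nw = preset("ND_Wheel"), preset("ND_NoWheel")
        assert w.tau == 23.5
        assert w.delta_advance_max > nw.delta_advance_max

    def test_hfd_adds_peripheral_delay(self):
        assert preset("HFD_NoWheel").peripheral_delay_h > 0
        assert preset("ND_NoWheel").peripheral_delay_h == 0

    def test_unknown_preset_rejected(self):
        with pytest.raises(InvalidArgumentError):
            preset("X")

    def test_config_validation(self):
        with pytest.raises(InvalidArgumentError):
            SimConfig(tau=19.0)
        with pytest.raises(InvalidArgumentError):
            SimConfig(lambda_active=1.0, lambda_rest=2.0)


class TestBioluminescence:
    def test_sampling_design_six_points_4h_apart(self):
        sched = make_ld(14)
        series = simulate_bioluminescence(
            0.0, organ_profile("kidney", wheel=True, noise_cv=0.0),
            preset("ND_NoWheel"), sched, rng=np.random.default_rng(0),
        )
        zts = [clock_to_zt(c, sched) for c in series.sample_clock_times]
        assert zts[0] == pytest.approx(9.0)  # 17:00 on an 08:00 reference
        gaps = np.diff(zts) % 24
        assert np.allclose(gaps, 4.0)

    def test_noise_free_acrophase_recovered_exactly(self):
        sched = make_ld(14)
        series = simulate_bioluminescence(
            0.0, organ_profile("kidney", wheel=True, noise_cv=0.0),
            preset("ND_NoWheel"), sched, rng=np.random.default_rng(0),
        )
        series = normalize_to_daily_mean(series)
        zts = [clock_to_zt(c, sched) for c in series.sample_clock_times]
        fit = cosinor_fit(zts, series.normalized_pct)
        assert fit.acrophase_zt == pytest.approx(18.8, abs=1e-6)

    def test_zero_coupling_ignores_behavior_shift(self):
        sched = make_ld(14)
        prof = organ_profile("liver", wheel=False, noise_cv=0.0, coupling=0.0)
        cfg = preset("ND_NoWheel")
        a = simulate_bioluminescence(0.0, prof, cfg, sched,
                                     rng=np.random.default_rng(1))
        b = simulate_bioluminescence(-6.0, prof, cfg, sched,
                                     rng=np.random.default_rng(1))
        assert np.allclose(a.photon_rates, b.photon_rates)

    def test_minus_six_shift_recovers_modular_acrophase(self):
        sched = make_ld(14)
        prof = organ_profile("submandibular_gland", wheel=False, noise_cv=0.0,
                             coupling=1.0)
        prof = type(prof)(organ=prof.organ, baseline_acrophase=18.9,
                          coupling=1.0, amplitude_pct=20.0, noise_cv=0.0)
        series = normalize_to_daily_mean(
            simulate_bioluminescence(-6.0, prof, preset("ND_NoWheel"), sched,
                                     rng=np.random.default_rng(2))
        )
        zts = [clock_to_zt(c, sched) for c in series.sample_clock_times]
        fit = cosinor_fit(zts, series.normalized_pct)
        assert fit.acrophase_zt == pytest.approx(12.9, abs=1e-6)

    def test_normalized_series_averages_100(self):
        sched = make_ld(14)
        series = simulate_bioluminescence(
            2.0, organ_profile("kidney", wheel=False),
            preset("HFD_NoWheel"), sched, rng=np.random.default_rng(9),
        )
        norm = normalize_to_daily_mean(series)
        assert norm.normalized_pct.mean() == pytest.approx(100.0, abs=1e-9)
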