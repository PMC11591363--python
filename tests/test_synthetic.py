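import numpy as np
import pytest

from gaitdf.dissimilarity import df_cross_group
from gaitdf.geometry import Homography
from gaitdf.normalize import normalize_step
from gaitdf.pipeline import correct_tracks, normalize_dataset
from gaitdf.synthetic import (
    GaitParams,
    InjuryEffect,
    NULL_EFFECT,
    ScenarioConfig,
    default_paper_scenario,
    gait_waveform,
    simulate_dataset,
    simulate_step,
)


class TestWaveform:
    def test_boundaries(self):
        p = GaitParams()
        x0, y0 = gait_waveform(p, 0.0)
        x1, y1 = gait_waveform(p, 1.0)
        assert (x0, y0) == (0.0, 0.0)
        assert x1 == pytest.approx(p.stride_length_cm)
        assert y1 == pytest.approx(0.0, abs=1e-12)

    def test_peak_at_swing_peak_phase(self):
        p = GaitParams()
        _, y = gait_waveform(p, p.swing_peak_phase)
        assert y == pytest.approx(p.swing_peak_height_cm)

    def test_x_monotone_and_stance_slower(self):
        p = GaitParams()
        phase = np.linspace(0, 1, 201)
        x, _ = gait_waveform(p, phase)
        assert np.all(np.diff(x) > 0)
        stance_slope = x[20] - x[10]
        swing_slope = x[180] - x[170]
        assert stance_slope < swing_slope

    def test_phase_domain_enforced(self):
        with pytest.raises(ValueError):
            gait_waveform(GaitParams(), 1.2)


class TestSimulateStep:
    def test_zero_noise_null_effect_on_template(self, rng):
        p = GaitParams(step_noise_cm=0.0)
        raw = simulate_step(p, NULL_EFFECT, rng)
        phase = raw.t / raw.t[-1]
        x_t, y_t = gait_waveform(p, phase)
        np.testing.assert_allclose(raw.x, x_t, atol=1e-12)
        np.testing.assert_allclose(raw.y, y_t, atol=1e-12)

    def test_attenuation_halves_peak(self, rng):
        p = GaitParams(step_noise_cm=0.0)
        raw = simulate_step(p, InjuryEffect(amplitude_attenuation=0.5), rng)
        assert raw.y.max() == pytest.approx(p.swing_peak_height_cm / 2, rel=1e-6)

    def test_phase_delay_shifts_peak_bin(self, rng):
        p = GaitParams(step_noise_cm=0.0)
        base = normalize_step(simulate_step(p, NULL_EFFECT, rng))
        delayed = normalize_step(
            simulate_step(p, InjuryEffect(phase_delay=0.1), rng)
        )
        assert np.argmax(delayed.y) > np.argmax(base.y)

    def test_window_offset_applied_inside_window(self, rng):
        p = GaitParams(step_noise_cm=0.0)
        eff = InjuryEffect(perturbation_window=(1, 20), perturbation_offset_cm=0.5)
        raw = simulate_step(p, eff, rng)
        clean = simulate_step(p, NULL_EFFECT, rng)
        diff = raw.y - clean.y
        phase = raw.t / raw.t[-1]
        assert np.all(diff[phase <= 19 / 99.0] == pytest.approx(0.5))
        assert np.all(diff[phase > 20 / 99.0] == 0.0)

    def test_noise_sd_recovered_on_normalized_bins(self):
        """Per-bin SD of normalized curves ~ programmed noise away from endpoints."""
        sigma = 0.08
        p = GaitParams(step_noise_cm=sigma)
        curves = []
        for i in range(1000):
            r = np.random.default_rng(10_000 + i)
            curves.append(normalize_step(simulate_step(p, NULL_EFFECT, r)))
        ys = np.stack([c.y for c in curves])
        interior_sd = ys[:, 10:90].std(axis=0, ddof=1)
        assert np.median(interior_sd) == pytest.approx(sigma, rel=0.10)


class TestSimulateDataset:
    def test_default_config_counts(self):
        sc = default_paper_scenario(seed=5, n_animals=2, steps_per_session=2)
        ds, gt = simulate_dataset(sc)
        assert len(ds.tracks) == 5 * 2 * 3 * 2 * 3  # groups*animals*days*sides*joints
        assert len(ds.intervals) == 5 * 2 * 3 * 2 * 2  # one set per session
        assert len(gt.animal_effects) == 10

    def test_same_seed_identical_bytes(self, tmp_path):
        from gaitdf.pipeline import write_dataset

        sc = default_paper_scenario(seed=11, n_animals=2, days=(0,), joints=("ankle",))
        for d in ("a", "b"):
            ds, _ = simulate_dataset(sc)
            write_dataset(ds, tmp_path / d)
        assert (tmp_path / "a/tracks.csv").read_bytes() == (tmp_path / "b/tracks.csv").read_bytes()
        assert (
            tmp_path / "a/intervals.csv"
        ).read_bytes() == (tmp_path / "b/intervals.csv").read_bytes()

    def test_different_seeds_differ(self):
        sc1 = default_paper_scenario(seed=1, n_animals=1, days=(0,), joints=("ankle",))
        sc2 = default_paper_scenario(seed=2, n_animals=1, days=(0,), joints=("ankle",))
        ds1, _ = simulate_dataset(sc1)
        ds2, _ = simulate_dataset(sc2)
        assert not np.array_equal(ds1.tracks[0].xy, ds2.tracks[0].xy)

    def test_pixel_emission_round_trips_through_geometry(self):
        h_true = Homography(
            np.array([[0.05, 0.002, -3.0], [0.001, -0.048, 30.0], [1e-5, -2e-5, 1.0]]),
            src_units="px",
            dst_units="cm",
        )
        sc = ScenarioConfig(
            effects={},
            groups=("control",),
            n_animals=2,
            days=(0,),
            joints=("ankle",),
            seed=4,
            h_true=h_true,
        )
        ds, _ = simulate_dataset(sc)
        assert all(t.units == "px" for t in ds.tracks)
        # ground truth arena coordinates from the same seed without distortion
        sc_cm = ScenarioConfig(
            effects={}, groups=("control",), n_animals=2, days=(0,),
            joints=("ankle",), seed=4,
        )
        ds_cm, _ = simulate_dataset(sc_cm)
        corrected = correct_tracks(ds)
        assert all(t.units == "cm" for t in corrected.tracks)
        for t, t_cm in zip(corrected.tracks, ds_cm.tracks):
            np.testing.assert_allclose(t.xy, t_cm.xy, atol=1e-6)

    def test_laterality_scales_contralateral_side(self):
        eff = InjuryEffect(
            amplitude_attenuation=0.4, laterality="left", contralateral_scale=0.5
        )
        assert eff.for_side("left").amplitude_attenuation == 0.4
        assert eff.for_side("right").amplitude_attenuation == pytest.approx(0.2)


class TestEffectRecovery:
    def test_mean_df_monotone_in_attenuation(self):
        """Cross-group DF strictly increases over attenuations .1/.3/.5."""
        means = []
        for i, att in enumerate((0.1, 0.3, 0.5)):
            sc = ScenarioConfig(
                effects={("ischemia", 3): InjuryEffect(amplitude_attenuation=att)},
                groups=("control", "ischemia"),
                days=(3,),
                sides=("left",),
                joints=("metatarsus",),
                seed=21,
            )
            ds, _ = simulate_dataset(sc)
            curves, _ = normalize_dataset(ds)
            exp = [c for c in curves if c.group == "ischemia"]
            ctrl = [c for c in curves if c.group == "control"]
            means.append(df_cross_group(exp, ctrl).mean)
        assert means[0] < means[1] < means[2]

    def test_perturbation_window_is_modal_flag_location(self):
        from gaitdf.bin_compare import flag_runs, per_bin_ttest

        sc = ScenarioConfig(
            effects={
                ("ischemia", 3): InjuryEffect(
                    perturbation_window=(41, 60), perturbation_offset_cm=1.0
                )
            },
            groups=("control", "ischemia"),
            days=(3,),
            sides=("left",),
            joints=("metatarsus",),
            n_animals=10,
            seed=8,
        )
        ds, _ = simulate_dataset(sc)
        curves, _ = normalize_dataset(ds)
        exp = [c for c in curves if c.group == "ischemia"]
        ctrl = [c for c in curves if c.group == "control"]
        cmp_ = per_bin_ttest(exp, ctrl, component="VD")
        modal = max(flag_runs(cmp_.flags), key=lambda se: se[1] - se[0])
        # spline smoothing blurs the hard window edge by a couple of bins
        assert abs(modal[0] - 41) <= 4 and abs(modal[1] - 60) <= 4
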