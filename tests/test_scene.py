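"""Ground-truth generator and renderer properties."""

import numpy as np
import pytest

from ribbontrack import (BehaviorConfig, ConfigurationError, GeometryError,
                         GroundTruthScene, ScanLine, bead_image,
                         deinterleave, fit_profile, fit_spot_2d, make_scene,
                         make_trajectory, render_line_scan, render_xy_stack)


class TestMakeScene:
    def test_empty_scene_for_background_calibration(self, scene_template):
        scene = make_scene(scene_template, BehaviorConfig(n_vesicles=0),
                           seed=0)
        assert scene.trajectories == []

    def test_determinism_bit_identical(self, scene_template, params_sim):
        beh = BehaviorConfig(n_vesicles=4, p_disappear_proximal=0.3,
                             p_appear_distal=0.3)
        a = make_scene(scene_template, beh, seed=7)
        b = make_scene(scene_template, beh, seed=7)
        for ta, tb in zip(a.trajectories, b.trajectories):
            assert ta.kind == tb.kind
            assert np.array_equal(ta.positions, tb.positions)
        sa, _ = render_xy_stack(a, params_sim, 3, seed=5)
        sb, _ = render_xy_stack(b, params_sim, 3, seed=5)
        assert np.array_equal(sa, sb)

    def test_mean_shift_recovered_over_seeds(self, scene_template):
        # generator truth: mean toward-membrane shift ~33 nm, 70 % positive
        beh = BehaviorConfig(n_vesicles=64, mean_shift_x=33.0,
                             frac_positive_ddx=0.70)
        ddx, pos = [], []
        for seed in range(20):
            scene = make_scene(scene_template, beh, seed=seed,
                               kinds=["displaced"] * 64, paradigm="xy")
            shifts = [tr.shift[0] for tr in scene.trajectories]
            ddx.extend(shifts)
            pos.append(np.mean([s > 0 for s in shifts]))
        assert np.mean(ddx) == pytest.approx(33.0, abs=10.0)
        assert np.mean(pos) == pytest.approx(0.70, abs=0.05)

    def test_invalid_probability_names_field(self, scene_template):
        with pytest.raises(ConfigurationError, match="p_appear_distal"):
            BehaviorConfig(p_appear_distal=1.5)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigurationError, match="ribbon_center"):
            GroundTruthScene(membrane_x0=500.0, ribbon_center=(600.0, 500.0))

    def test_trajectory_time_order_enforced(self, scene_template):
        with pytest.raises(ConfigurationError):
            make_trajectory("stable", (650.0, 1280.0),
                            times=scene_template.times, amplitude=1.0,
                            t_on=2.0, t_off=1.0)

    def test_ground_truth_events_recorded(self, scene_template):
        beh = BehaviorConfig(n_vesicles=2, p_disappear_proximal=1.0)
        scene = make_scene(scene_template, beh, seed=3)
        kinds = [e["kind"] for e in scene.events]
        assert kinds.count("disappearance") == 2


class TestRenderXY:
    def test_zero_scene_renders_zero(self, scene_template):
        from ribbontrack import ImagingParams
        params = ImagingParams(channel_scheme="simultaneous",
                               background_intra=0.0, background_extra=0.0)
        scene = make_scene(scene_template, BehaviorConfig(n_vesicles=0),
                           seed=0)
        scene.ribbon_amplitude = 0.0
        stack, _ = render_xy_stack(scene, params, 2, seed=0)
        assert np.all(stack == 0.0)

    def test_amplitude_linearity(self, scene_template, params_sim):
        # doubling emitter amplitude doubles expected integrated intensity
        from dataclasses import replace
        scenes = []
        for amp in (3.0, 6.0):
            s = make_scene(scene_template, BehaviorConfig(n_vesicles=0),
                           seed=0)
            s.trajectories = [make_trajectory(
                "stable", (650.0, 1280.0), times=s.times, amplitude=amp,
                t_on=-1.0, t_off=100.0)]
            scenes.append(s)
        p = replace(params_sim, background_intra=0.0, background_extra=0.0,
                    emitter_background_scale=0.0)
        lo, _ = render_xy_stack(scenes[0], p, 1, seed=0, noise=False)
        hi, _ = render_xy_stack(scenes[1], p, 1, seed=0, noise=False)
        assert hi[0, 1].sum() == pytest.approx(2.0 * lo[0, 1].sum(), rel=1e-9)

    def test_shot_noise_variance_to_mean(self, scene_template, params_sim):
        # Poisson detection: variance/mean within [0.9, 1.1] over >=1e4 px
        scene = make_scene(scene_template, BehaviorConfig(n_vesicles=0),
                           seed=0)
        scene.ribbon_amplitude = 0.0
        stack, _ = render_xy_stack(scene, params_sim, 8, seed=42,
                                   shape=(64, 64))
        region = stack[:, 0, :, :20]    # intracellular, emitter-free
        assert region.size >= 10_000
        ratio = region.var() / region.mean()
        assert 0.9 <= ratio <= 1.1

    def test_membrane_crossing_at_apex(self, scene_template, params_sim):
        # noiseless sigmoid fit on the apex row recovers membrane_x0
        scene = make_scene(scene_template, BehaviorConfig(n_vesicles=0),
                           seed=0)
        scene.ribbon_amplitude = 0.0
        stack, _ = render_xy_stack(scene, params_sim, 1, seed=0, noise=False)
        row = int(scene.membrane_apex_y / params_sim.pixel_size)
        xs = (np.arange(64) + 0.5) * params_sim.pixel_size
        fit = fit_profile(xs, stack[0, 0, row], model="sigmoid_only")
        assert abs(fit.x_half - scene.membrane_x0) < params_sim.pixel_size / 2

    def test_scene_outside_fov_rejected(self, params_sim):
        scene = GroundTruthScene(membrane_x0=5000.0,
                                 ribbon_center=(4800.0, 1280.0))
        with pytest.raises(GeometryError):
            render_xy_stack(scene, params_sim, 1, seed=0, shape=(64, 64))


class TestRenderLineScan:
    def test_stable_noiseless_lines_identical(self, scene_template,
                                              params_sim):
        scene = make_scene(scene_template, BehaviorConfig(n_vesicles=0),
                           seed=0)
        scene.trajectories = [make_trajectory(
            "stable", (650.0, 1280.0), times=scene.times, amplitude=5.0,
            t_on=-1.0, t_off=100.0)]
        xt = render_line_scan(scene, params_sim, ScanLine(1280.0, 0.0, 48),
                              16, seed=0, noise=False)
        for i in range(1, 16):
            assert np.array_equal(xt.data[i, 1], xt.data[0, 1])

    def test_departure_gives_gaussian_time_course(self, params_alt):
        # line-integrated intensity of a constant-velocity departure equals
        # A exp(-v^2 (t - t0)^2 / (2 sigma^2)) to better than 1e-6 of peak
        from dataclasses import replace
        tpl = GroundTruthScene(duration=4.0, stimulus_time=1.0)
        tpl.trajectories = [make_trajectory(
            "departing", (650.0, 1280.0), times=tpl.times, amplitude=5.0,
            t_on=-1.0, t_off=1.5, departure_speed=1.5)]
        p = replace(params_alt, background_intra=0.0, background_extra=0.0)
        xt = render_line_scan(tpl, p, ScanLine(1280.0, 200.0, 32), 2000,
                              seed=1, noise=False)
        _, em, _, te = deinterleave(xt.data, "alternate_lines", xt.times)
        integ = em.sum(axis=1)
        v, sig = 1.5e3, p.psf_sigma
        pred = np.exp(-v**2 * np.clip(te - 1.5, 0, None) ** 2 / (2 * sig**2))
        assert np.max(np.abs(integ / integ[0] - pred)) < 1e-6

    def test_alternating_deinterleaves_into_halves(self, scene_template,
                                                   params_alt):
        scene = make_scene(scene_template, BehaviorConfig(n_vesicles=1),
                           seed=0)
        xt = render_line_scan(scene, params_alt, ScanLine(1280.0, 0.0, 48),
                              64, seed=0)
        ch0, ch1, t0, t1 = deinterleave(xt.data, "alternate_lines", xt.times)
        assert ch0.shape == (32, 48) and ch1.shape == (32, 48)
        assert np.allclose(t1 - t0, params_alt.line_period_s)

    def test_line_missing_membrane_rejected(self, scene_template, params_sim):
        scene = make_scene(scene_template, BehaviorConfig(n_vesicles=0),
                           seed=0)
        with pytest.raises(GeometryError):
            render_line_scan(scene, params_sim, ScanLine(1280.0, 0.0, 10),
                             4, seed=0)   # ends before the membrane


class TestBeadImage:
    def test_zero_diameter_is_exact_psf(self, params_sim):
        img = bead_image(params_sim, 0.0, seed=0, amplitude=100.0,
                         noise=False)
        fit = fit_spot_2d(img, params_sim.pixel_size)
        sd = 0.5 * (fit.sd_x + fit.sd_y)
        assert sd == pytest.approx(params_sim.psf_sigma, rel=0.01)

    def test_27nm_bead_fits_psf_within_2pct(self, params_sim):
        img = bead_image(params_sim, 27.0, seed=0, amplitude=100.0,
                         noise=False)
        fit = fit_spot_2d(img, params_sim.pixel_size)
        sd = 0.5 * (fit.sd_x + fit.sd_y)
        assert sd == pytest.approx(params_sim.psf_sigma, rel=0.02)

    def test_same_seed_identical(self, params_sim):
        a = bead_image(params_sim, 27.0, seed=9)
        b = bead_image(params_sim, 27.0, seed=9)
        assert np.array_equal(a, b)

    def test_negative_diameter_rejected(self, params_sim):
        with pytest.raises(ConfigurationError):
            bead_image(params_sim, -1.0, seed=0)


class TestJitterModel:
    def test_stable_jitter_bounded(self, scene_template):
        with pytest.raises(ConfigurationError):
            BehaviorConfig(jitter_sd=(20.0, 7.0))

    def test_jitter_stationary_sd(self, scene_template):
        beh = BehaviorConfig(n_vesicles=40, mean_shift_x=0.0,
                             frac_positive_ddx=0.5, jitter_sd=(10.0, 7.0))
        scene = make_scene(scene_template, beh, seed=1,
                           kinds=["stable"] * 40)
        jx = np.concatenate([t.jitter[:, 0] for t in scene.trajectories])
        jy = np.concatenate([t.jitter[:, 1] for t in scene.trajectories])
        assert np.std(jx) == pytest.approx(10.0, rel=0.2)
        assert np.std(jy) == pytest.approx(7.0, rel=0.2)
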