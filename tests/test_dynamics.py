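"""Ribbon-relative dynamics: positions, events, declines, membrane geometry."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribbontrack import (BehaviorConfig, GroundTruthScene, ImagingParams,
                         NoEventError, PropagationError, VesicleEvent,
                         classify_decline, detect_events, displacement,
                         event_position_histogram, make_scene,
                         membrane_bounds, relative_position,
                         render_xy_stack, track_line_positions)
from ribbontrack.dynamics import MembraneBounds, RelativePosition
from ribbontrack.profiles import ProfileFitResults, SpotFit2DResults


def spot(x, y, converged=True):
    return SpotFit2DResults(x_peak=x, y_peak=y, sd_x=110.0, sd_y=110.0,
                            amplitude=10.0, offset=0.0, rms_residual=0.1,
                            converged=converged, nobs=100, bse={})


def profile_fit(x0, x_half=np.nan, a=10.0, converged=True,
                model="gaussian_only"):
    return ProfileFitResults(model=model, a=a, b=1.0, c=np.nan, d=np.nan,
                             w=155.0, x_0=x0, x_half=x_half, rms_residual=0.1,
                             converged=converged, nobs=24, bse={"a": 0.5})


class TestRelativePosition:
    def test_arithmetic(self):
        rel = relative_position(spot(510.0, 305.0), spot(480.0, 330.0))
        assert (rel.dx, rel.dy) == (30.0, -25.0)

    def test_coincident(self):
        rel = relative_position(spot(480.0, 330.0), spot(480.0, 330.0))
        assert (rel.dx, rel.dy) == (0.0, 0.0)

    def test_translation_invariance(self):
        r0 = relative_position(spot(510.0, 305.0), spot(480.0, 330.0))
        r1 = relative_position(spot(610.0, 345.0), spot(580.0, 370.0))
        assert (r0.dx, r0.dy) == (r1.dx, r1.dy)

    def test_unconverged_propagates(self):
        with pytest.raises(PropagationError):
            relative_position(spot(0, 0, converged=False), spot(1, 1))


class TestDisplacement:
    def test_three_four_five(self):
        v = displacement(RelativePosition(10, 20), RelativePosition(40, -20))
        assert (v.ddx, v.ddy) == (30.0, -40.0)
        assert v.amplitude == pytest.approx(50.0)

    def test_identity(self):
        v = displacement(RelativePosition(5, 5), RelativePosition(5, 5))
        assert v.amplitude == 0.0

    @given(st.floats(-500, 500), st.floats(-500, 500),
           st.floats(-500, 500), st.floats(-500, 500))
    @settings(max_examples=50, deadline=None)
    def test_amplitude_invariants(self, x0, y0, x1, y1):
        v = displacement(RelativePosition(x0, y0), RelativePosition(x1, y1))
        assert v.amplitude == pytest.approx(math.hypot(v.ddx, v.ddy))
        assert (v.amplitude == 0) == (v.ddx == 0 and v.ddy == 0)


class TestTrackLinePositions:
    def test_constant_noiseless(self):
        times = np.arange(5) * 0.01
        em = [profile_fit(650.0) for _ in times]
        rib = [profile_fit(600.0, x_half=800.0, model="composite")
               for _ in times]
        track = track_line_positions(em, list(times), rib, list(times))
        assert len(track) == 5
        assert np.allclose(track["dx"], 50.0)
        assert np.allclose(track["membrane_distance"], 150.0)

    def test_empty_emitter_series(self):
        rib = [profile_fit(600.0, x_half=800.0, model="composite")]
        track = track_line_positions([], [], rib, [0.0])
        assert len(track) == 0

    def test_unconverged_ribbon_blocks_skipped(self):
        times = [0.0, 0.01]
        em = [profile_fit(650.0), profile_fit(651.0)]
        rib = [profile_fit(600.0, 800.0, converged=False, model="composite"),
               profile_fit(601.0, 800.0, model="composite")]
        track = track_line_positions(em, times, rib, times)
        # all emitter blocks pair with the single converged ribbon fit
        assert np.allclose(track["dx"], [49.0, 50.0])


def make_track(amps, dx=0.0):
    n = len(amps)
    return pd.DataFrame({"t": np.arange(n) * 0.014,
                         "dx": np.full(n, dx),
                         "membrane_distance": np.full(n, 100.0),
                         "amplitude": np.asarray(amps, dtype=float),
                         "converged": True})


class TestDetectEvents:
    def test_step_appearance_at_block_12(self):
        amps = [0.0] * 12 + [10.0] * 8   # noise_sd = 1, k_on = 4
        events = detect_events(make_track(amps), noise_sd=1.0, k_on=4,
                               m_consec=3)
        assert len(events) == 1
        assert events[0].kind == "appearance"
        assert events[0].block_index == 12

    def test_disappearance_locus_is_last_supra_block(self):
        amps = [10.0] * 10 + [0.0] * 10
        events = detect_events(make_track(amps), noise_sd=1.0)
        assert len(events) == 1
        assert events[0].kind == "disappearance"
        assert events[0].block_index == 9

    def test_constant_trace_no_events(self):
        assert detect_events(make_track([10.0] * 20), noise_sd=1.0) == []
        assert detect_events(make_track([0.0] * 20), noise_sd=1.0) == []

    def test_brief_blip_ignored(self):
        amps = [0.0] * 8 + [10.0] * 2 + [0.0] * 10   # shorter than m_consec
        assert detect_events(make_track(amps), noise_sd=1.0, m_consec=3) == []

    def test_fusion_channel_labels_fusion(self):
        amps = [0.0] * 6 + [10.0] * 6
        events = detect_events(make_track(amps), noise_sd=1.0,
                               channel="fusion")
        assert events[0].kind == "fusion"

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            detect_events(make_track([1.0, 2.0]), noise_sd=1.0, m_consec=3)


class TestClassifyDecline:
    def test_analytic_gaussian_decline(self):
        # constant-velocity departure: A exp(-(t-t0)^2 / width^2)
        t = np.arange(40) * 0.014
        t0, width = 0.2, 0.104    # v = sigma*sqrt(2)/width
        amp = np.where(t <= t0, 10.0,
                       10.0 * np.exp(-((t - t0) ** 2) / width**2))
        fit = classify_decline(t, amp)
        assert fit.model == "gaussian"
        assert fit.width == pytest.approx(width, rel=0.05)

    def test_step_to_baseline(self):
        t = np.arange(30) * 0.014
        amp = np.where(t < 0.2, 10.0, 0.0)
        assert classify_decline(t, amp).model == "step"

    def test_exponential_decay(self):
        t = np.arange(60) * 0.014
        amp = np.where(t <= 0.2, 10.0, 10.0 * np.exp(-(t - 0.2) / 0.15))
        assert classify_decline(t, amp).model == "exponential"

    def test_flat_trace_rejected(self):
        t = np.arange(30) * 0.014
        with pytest.raises(NoEventError):
            classify_decline(t, np.full(30, 10.0))

    def test_scores_reported_for_all_candidates(self):
        t = np.arange(30) * 0.014
        amp = np.where(t < 0.2, 10.0, 0.0)
        fit = classify_decline(t, amp)
        assert set(fit.scores) == {"gaussian", "step", "exponential"}
        assert fit.scores[fit.model] == min(fit.scores.values())


class TestMembraneBounds:
    def test_closed_form_chord_drop(self):
        # R = 1500 nm, T = 600 nm -> drop = 1500 - sqrt(1500^2 - 300^2)
        params = ImagingParams(channel_scheme="simultaneous",
                               optical_section_thickness=600.0)
        scene = GroundTruthScene(membrane_x0=1800.0, membrane_radius=1500.0,
                                 ribbon_center=(1650.0, 1280.0))
        stack, _ = render_xy_stack(scene, params, 1, seed=0, shape=(64, 64),
                                   noise=False)
        mb = membrane_bounds(stack[0, 0], params)
        drop_true = 1500.0 - math.sqrt(1500.0**2 - 300.0**2)
        assert mb.radius == pytest.approx(1500.0, rel=0.10)
        assert mb.x_mid - mb.x_extreme == pytest.approx(drop_true, rel=0.05)

    def test_flat_membrane_exact(self):
        params = ImagingParams(channel_scheme="simultaneous")
        scene = GroundTruthScene(membrane_x0=1800.0,
                                 ribbon_center=(1650.0, 1280.0))
        stack, _ = render_xy_stack(scene, params, 1, seed=0, shape=(64, 64),
                                   noise=False)
        mb = membrane_bounds(stack[0, 0], params)
        assert mb.x_extreme == mb.x_mid
        assert math.isinf(mb.radius)

    def test_bounds_invariant(self):
        with pytest.raises(ValueError):
            MembraneBounds(x_mid=100.0, x_extreme=150.0)


def event_at(dx, kind="fusion"):
    return VesicleEvent(kind=kind, locus=RelativePosition(dx, 0.0),
                        membrane_distance=150.0 - dx, t_event=1.0)


class TestEventHistogram:
    def test_singleton_bins(self):
        h = event_position_histogram([event_at(-100.0), event_at(0.0),
                                      event_at(100.0)], bin_width=100.0)
        assert h.n == 3
        assert np.all(h.counts[h.counts > 0] == 1)

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        events = [event_at(d) for d in rng.normal(0, 120, size=127)]
        h = event_position_histogram(events, bin_width=50.0)
        assert h.n == 127

    def test_empty_event_list(self):
        h = event_position_histogram([], bin_width=50.0)
        assert h.n == 0

    def test_beyond_membrane_counts(self):
        events = [event_at(d) for d in (-100.0, 0.0, 120.0, 160.0)]
        bounds = MembraneBounds(x_mid=150.0, x_extreme=110.0)
        h = event_position_histogram(events, bin_width=50.0, bounds=bounds,
                                     ribbon_x=0.0)
        assert h.n_beyond_mid == 1       # only 160 > 150
        assert h.n_beyond_extreme == 2   # 120 and 160 > 110

    def test_spread_matches_configured(self, scene_template):
        # fusion loci drawn with event_spread sd; histogram SD within 20 %
        beh = BehaviorConfig(n_vesicles=127, p_fusion=1.0, event_spread=120.0)
        scene = make_scene(scene_template, beh, seed=5)
        dx = np.array([e["x"] - scene.ribbon_center[0]
                       for e in scene.events if e["kind"] == "fusion"])
        assert len(dx) == 127
        assert np.std(dx) == pytest.approx(120.0, rel=0.20)

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            event_position_histogram([], bin_width=0.0)
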