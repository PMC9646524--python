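"""Tests for the per-cell quantification statistics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viscocell import quantify as q
from viscocell import synthdata as sd


class TestLamellaGrowth:
    def test_constant_area_gives_zero_growth(self):
        series = q.ContourSeries(np.arange(5.0), np.full(5, 100.0), np.full(5, 35.0))
        assert np.allclose(q.lamella_growth(series), 0.0)

    def test_growing_circle_matches_closed_form(self):
        r = np.array([10.0, 10.1])
        series = q.ContourSeries(np.array([0.0, 5.0]), np.pi * r**2, 2 * np.pi * r)
        expected = np.pi * (10.1**2 - 10.0**2) / (2 * np.pi * 10.0)
        growth = q.lamella_growth(series)
        assert growth[0] == pytest.approx(expected)
        assert growth[0] == pytest.approx(0.1005, abs=1e-4)

    def test_shrinking_area_is_negative(self):
        series = q.ContourSeries(np.arange(3.0), np.array([100.0, 90.0, 80.0]), np.full(3, 35.0))
        assert np.all(q.lamella_growth(series) < 0)

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            q.lamella_growth(q.ContourSeries(np.array([0.0]), np.array([1.0]), np.array([1.0])))


class TestCellVolume:
    def test_empty_stack_warns_and_returns_zero(self):
        stack = q.LabeledStack(np.zeros((3, 8, 8), dtype=bool))
        with pytest.warns(UserWarning):
            assert q.cell_volume(stack) == 0.0

    def test_uniform_cylinder(self):
        masks = np.ones((6, 10, 10), dtype=bool)
        stack = q.LabeledStack(masks, dz=0.5, pixel_size=0.2)
        area = 100 * 0.2**2
        assert q.cell_volume(stack) == pytest.approx(area * 0.5 * 5)

    def test_sphere_within_two_percent(self):
        stack, truth = sd.make_sphere_stack(radius=8.0, dz=0.5, pixel_size=0.1)
        vol = q.cell_volume(stack)
        assert vol == pytest.approx(truth.parameters["true_volume"], rel=0.02)

    def test_scales_with_pixel_size_and_dz(self):
        """Dimensional analysis: volume ∝ pixel_size² · dz for identical masks."""
        masks = np.zeros((4, 10, 10), dtype=bool)
        masks[:, 3:7, 3:7] = True
        v1 = q.cell_volume(q.LabeledStack(masks, dz=0.5, pixel_size=0.1))
        v2 = q.cell_volume(q.LabeledStack(masks, dz=1.0, pixel_size=0.2))
        assert v2 == pytest.approx(v1 * 2.0 * 4.0)


class TestLamellaAreaFraction:
    def test_flat_cell_is_all_lamella(self):
        masks = np.zeros((3, 10, 10), dtype=bool)
        masks[:3, 2:8, 2:8] = True  # top slice at 2·0.5 = 1 µm < 2 µm
        stack = q.LabeledStack(masks, dz=0.5)
        assert q.lamella_area_fraction(stack) == pytest.approx(1.0)

    def test_vertical_cylinder_has_no_lamella(self):
        masks = np.ones((12, 10, 10), dtype=bool)  # up to 5.5 µm, same footprint
        stack = q.LabeledStack(masks, dz=0.5)
        assert q.lamella_area_fraction(stack) == pytest.approx(0.0)

    def test_thin_skirt_around_tall_core(self):
        """A 1-µm skirt of area equal to the core gives fraction 1/2."""
        masks = np.zeros((10, 30, 30), dtype=bool)
        core = np.zeros((30, 30), dtype=bool)
        core[10:20, 10:20] = True  # area A = 100 px
        skirt = np.zeros((30, 30), dtype=bool)
        skirt[5:25, 5:25] = True  # area 2A = 400 px... adjusted below
        skirt[10:20, 10:20] = True
        # make skirt footprint exactly 200 px (2× core)
        skirt = np.zeros((30, 30), dtype=bool)
        skirt[8:18, 4:24] = True  # 10 × 20 = 200 px
        core = np.zeros((30, 30), dtype=bool)
        core[8:18, 9:19] = True  # 10 × 10 = 100 px inside the skirt
        masks[0:2] = skirt  # heights 0, 0.5 µm
        masks[2:10] = core  # heights 1.0 ... 4.5 µm
        stack = q.LabeledStack(masks, dz=0.5)
        assert q.lamella_area_fraction(stack, h_crit=2.0) == pytest.approx(0.5)

    def test_empty_projection_errors(self):
        with pytest.raises(ValueError):
            q.lamella_area_fraction(q.LabeledStack(np.zeros((3, 5, 5), dtype=bool)))


class TestSpeedAndPersistence:
    def test_straight_track_has_unit_persistence(self):
        t = np.arange(10.0)
        track = q.Track(t, 0.5 * t, 0.2 * t)
        speed, pers = q.speed_and_persistence(track)
        assert pers == pytest.approx(1.0)
        assert speed == pytest.approx(np.hypot(0.5, 0.2))

    def test_closed_loop_has_zero_persistence(self):
        theta = np.linspace(0, 2 * np.pi, 20)
        track = q.Track(np.arange(20.0), np.cos(theta), np.sin(theta))
        _, pers = q.speed_and_persistence(track)
        assert pers == pytest.approx(0.0, abs=1e-12)

    def test_short_track_rejected_with_reason(self):
        track = q.Track(np.arange(3.0), np.arange(3.0), np.zeros(3))
        with pytest.raises(q.TrackRejected, match="at least 4"):
            q.speed_and_persistence(track)

    def test_long_track_truncated_to_cap(self):
        t = np.arange(200.0)
        x = np.where(t < 71, t, 71.0 + 50 * np.sin(t))  # junk beyond the cap
        track = q.Track(t, x, np.zeros_like(t))
        speed, _ = q.speed_and_persistence(track, max_frames=71)
        assert speed == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None)
    @given(
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
        angle=st.floats(0, 2 * np.pi),
    )
    def test_rigid_motion_invariance(self, dx, dy, angle):
        track, _ = sd.make_prw_track(n=20, seed=42)
        s0, p0 = q.speed_and_persistence(track)
        c, s = np.cos(angle), np.sin(angle)
        x2 = c * track.x - s * track.y + dx
        y2 = s * track.x + c * track.y + dy
        s1, p1 = q.speed_and_persistence(q.Track(track.t, x2, y2))
        assert s1 == pytest.approx(s0, rel=1e-9)
        assert p1 == pytest.approx(p0, rel=1e-9)


class TestCalciumSpikes:
    def make_trace(self, values):
        values = np.asarray(values, dtype=float)
        return q.IntensityTrace(np.arange(values.size, dtype=float), values)

    def test_flat_trace_has_no_spikes(self):
        assert q.calcium_spike_count(self.make_trace(np.full(30, 10.0))) == 0

    def test_three_disjoint_excursions(self):
        v = np.full(40, 10.0)
        for start in (5, 15, 25):
            v[start : start + 3] = 25.0
        assert q.calcium_spike_count(self.make_trace(v)) == 3

    def test_exactly_twice_baseline_is_not_a_spike(self):
        v = np.full(30, 10.0)
        v[10:13] = 20.0  # exactly 2×: the rule is strictly greater
        trace = q.IntensityTrace(np.arange(30.0), v, baseline=10.0)
        assert q.calcium_spike_count(trace) == 0

    def test_nearby_excursions_merge(self):
        v = np.full(40, 10.0)
        v[10:13] = 25.0
        v[14:17] = 25.0  # 1-sample gap < refractory gap of 2: one event
        trace = q.IntensityTrace(np.arange(40.0), v, baseline=10.0)
        assert q.calcium_spike_count(trace) == 1

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        trace, _ = sd.make_spike_trace(seed=9)
        scaled = q.IntensityTrace(trace.t, trace.value * scale,
                                  baseline=trace.baseline * scale)
        assert q.calcium_spike_count(scaled) == q.calcium_spike_count(trace)

    def test_too_short_for_baseline(self):
        with pytest.raises(ValueError):
            q.calcium_spike_count(self.make_trace(np.full(5, 10.0)))


class TestFrontRearRatio:
    @pytest.mark.parametrize(
        ("front", "rear", "expected"),
        [(100.0, 100.0, 1.0), (167.0, 100.0, 1.67), (284.0, 100.0, 2.84)],
    )
    def test_values(self, front, rear, expected):
        assert q.front_rear_ratio(q.PolarizedCell(front, rear)) == pytest.approx(expected)

    def test_swap_gives_reciprocal(self):
        cell = q.PolarizedCell(123.0, 77.0)
        swapped = q.PolarizedCell(77.0, 123.0)
        assert q.front_rear_ratio(swapped) == pytest.approx(1.0 / q.front_rear_ratio(cell))

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            q.PolarizedCell(100.0, 0.0)


class TestStormEdgeDensity:
    def square(self, npx=200, margin=30):
        return np.array(
            [[margin, margin], [margin, npx - margin],
             [npx - margin, npx - margin], [npx - margin, margin]],
            dtype=float,
        )

    def test_all_on_band(self):
        img = np.ones((200, 200), dtype=bool)
        assert q.storm_edge_density(img, self.square(), pixel_size=0.02) == 100.0

    def test_all_off_band(self):
        img = np.zeros((200, 200), dtype=bool)
        assert q.storm_edge_density(img, self.square(), pixel_size=0.02) == 0.0

    def test_band_restriction(self):
        """High interior occupancy far from the edge must not leak into the band."""
        img, poly, truth = sd.make_edge_pattern(
            occupancy_in_band=0.4, occupancy_out=0.9, seed=3
        )
        pct = q.storm_edge_density(
            img, poly, band=truth.parameters["band"],
            pixel_size=truth.parameters["pixel_size"],
        )
        assert pct == pytest.approx(40.0, abs=1.0)

    def test_polygon_outside_image_rejected(self):
        img = np.zeros((50, 50), dtype=bool)
        with pytest.raises(ValueError, match="bounds"):
            q.storm_edge_density(img, self.square(npx=200), pixel_size=0.02)


class TestPhRecovery:
    def test_exact_line(self):
        t = np.arange(20.0)
        trace = q.IntensityTrace(t, 1.0 - 0.02 * t)
        assert q.ph_recovery_rate(trace) == pytest.approx(0.02)

    def test_constant_ratio(self):
        trace = q.IntensityTrace(np.arange(10.0), np.full(10, 1.1))
        assert q.ph_recovery_rate(trace) == pytest.approx(0.0)

    def test_noisy_line_recovery(self):
        trace, truth = sd.make_ph_trace(slope=-0.015, noise_sd=0.001, n=20, seed=7)
        assert q.ph_recovery_rate(trace) == pytest.approx(0.015, abs=0.002)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            q.ph_recovery_rate(q.IntensityTrace(np.array([0.0, 1.0]), np.array([1.0, 1.0])))


class TestRetrogradeFlow:
    def test_exact_slope(self):
        t, s, _ = sd.make_kymograph_track(flow_speed=0.05)
        assert q.retrograde_flow(t, s) == pytest.approx(0.05)

    def test_stationary_feature(self):
        assert q.retrograde_flow(np.arange(10.0), np.full(10, 3.0)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_linearity_in_flow_speed(self):
        t1, s1, _ = sd.make_kymograph_track(flow_speed=0.05)
        t2, s2, _ = sd.make_kymograph_track(flow_speed=0.025)
        assert q.retrograde_flow(t1, s1) == pytest.approx(2 * q.retrograde_flow(t2, s2))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            q.retrograde_flow(np.array([0.0]), np.array([1.0]))


class TestMediumChemistry:
    def test_methylcellulose_dose(self):
        """0.6% w/v of a 65 kDa polymer is 92 µM at the usual rounding."""
        uM = q.mass_to_molar(0.6, 65_000.0)
        assert uM == pytest.approx(92.3, abs=0.05)
        assert round(uM) == 92

    def test_dextran_dose(self):
        assert q.mass_to_molar(0.0975, 500_000.0) == pytest.approx(1.95)

    def test_zero_dose(self):
        assert q.mass_to_molar(0.0, 65_000.0) == 0.0

    def test_invalid_mass(self):
        with pytest.raises(ValueError):
            q.mass_to_molar(0.6, 0.0)

    def test_osmolarity_contribution_identity_and_bound(self):
        uM = q.mass_to_molar(0.6, 65_000.0)
        uOsm = q.osmolarity_contribution(uM)
        assert uOsm == pytest.approx(uM)
        assert uOsm <= 100.0  # insignificant next to ~300 mOsm basal media
        assert uOsm / 300_000.0 < 1e-3
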