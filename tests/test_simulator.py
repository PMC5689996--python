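"""Projection-occupancy simulator: worked integer examples, conservation,
closed forms, and the continuous occupancy oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbctmotion import (
    ConfigurationError,
    ConstantSpeedMotion,
    OutOfViewError,
    ScanProtocol,
    SinusoidalMotion,
    TargetSpec,
    WindowGrid,
    constant_speed_level,
    mobile_level_ratio,
    occupancy_profile_continuous,
    preset_phantom,
    projection_times,
    simulate_mobile_profile,
    sinusoidal_occupancy_fraction,
    stationary_profile,
)


class TestProjectionTimes:
    @pytest.mark.parametrize(
        "n, duration, expected",
        [
            (10, 10.0, list(range(10))),
            (1, 37.0, [0.0]),
            (4, 2.0, [0.0, 0.5, 1.0, 1.5]),
        ],
    )
    def test_uniform_schedule(self, n, duration, expected):
        times = projection_times(ScanProtocol(n_projections=n, scan_duration=duration))
        assert times.tolist() == pytest.approx(expected)
        assert np.all(np.diff(times) > 0) or n == 1


class TestStationaryProfile:
    def test_single_window_target_reaches_full_level(self):
        grid = WindowGrid(0.0, 2.0, 10)
        target = TargetSpec(length_y=2.0, ct_level=100.0, center_y0=5.0)
        prof = stationary_profile(target, grid, ScanProtocol(n_projections=10, scan_duration=10.0))
        assert prof.values[2] == pytest.approx(100.0)
        assert np.count_nonzero(prof.values) == 1

    def test_aligned_target_is_flat_with_conserved_area(self, grid):
        target = TargetSpec(length_y=20.0, ct_level=100.0, center_y0=0.0)
        prof = stationary_profile(target, grid)
        assert np.count_nonzero(prof.values == 100.0) == 10
        assert prof.integral() == pytest.approx(2000.0)

    def test_half_window_shift_splits_edge_windows(self, grid):
        target = TargetSpec(length_y=20.0, ct_level=100.0, center_y0=1.0)
        prof = stationary_profile(target, grid)
        assert np.count_nonzero(prof.values == 100.0) == 9
        assert np.count_nonzero(prof.values == 50.0) == 2
        assert prof.integral() == pytest.approx(2000.0)

    def test_overlapping_targets_rejected(self, grid):
        targets = [
            TargetSpec(length_y=20.0, ct_level=100.0, center_y0=0.0, label="a"),
            TargetSpec(length_y=10.0, ct_level=100.0, center_y0=5.0, label="b"),
        ]
        with pytest.raises(ConfigurationError):
            stationary_profile(targets, grid)


class TestMobileSimulation:
    def test_single_voxel_half_window_speed(self, single_voxel_scan):
        """One voxel moving 0.5 w per interval spreads its 10 increments over
        5 windows, 2 projections each, at 0.2 of the stationary level."""
        target, motion, protocol, grid = single_voxel_scan
        prof, ledger = simulate_mobile_profile(target, motion, protocol, grid,
                                               deposition="center")
        nonzero = np.nonzero(prof.values)[0]
        assert nonzero.size == 5
        m = ledger.projections_per_window()
        assert m[nonzero].tolist() == [2, 2, 2, 2, 2]
        assert prof.values[nonzero] == pytest.approx([20.0] * 5)
        assert prof.values[nonzero] == pytest.approx(
            [target.ct_level * mobile_level_ratio(2, 10)] * 5)

    def test_ten_voxel_one_window_speed(self, ten_voxel_scan):
        """Ten voxels moving 1 w per interval: support 19 windows, cumulative
        level maximal at the 10th window, zero at the 20th."""
        target, motion, protocol, grid = ten_voxel_scan
        prof, _ = simulate_mobile_profile(target, motion, protocol, grid,
                                          deposition="center")
        v = prof.values
        first = grid.index(target.extent[0])
        assert np.count_nonzero(v) == 19
        assert int(np.argmax(v)) - first + 1 == 10
        assert v[first + 19] == 0.0
        # triangular accumulation: 1,2,...,10,9,...,1 tenths of CT_S
        expected = np.r_[np.arange(1, 11), np.arange(9, 0, -1)] * 10.0
        assert v[first:first + 19] == pytest.approx(expected)

    def test_zero_motion_reproduces_stationary(self, grid, medium_target):
        protocol = ScanProtocol(n_projections=100, scan_duration=30.0)
        stat = stationary_profile(medium_target, grid, protocol)
        for mode in ("center", "overlap"):
            prof, _ = simulate_mobile_profile(
                medium_target, ConstantSpeedMotion(0.0), protocol, grid, mode)
            if mode == "overlap":
                assert prof.allclose(stat, atol=1e-12)
            else:
                assert prof.integral() == pytest.approx(stat.integral())

    def test_out_of_view_names_projection(self, grid, medium_target):
        protocol = ScanProtocol(n_projections=100, scan_duration=100.0)
        with pytest.raises(OutOfViewError) as err:
            simulate_mobile_profile(medium_target, ConstantSpeedMotion(2.0),
                                    protocol, grid, "overlap")
        assert err.value.projection_index is not None
        assert err.value.projection_index > 0

    def test_mobile_max_never_exceeds_stationary_max(self, grid, medium_target):
        protocol = ScanProtocol(n_projections=500, scan_duration=60.0)
        stat = stationary_profile(medium_target, grid, protocol)
        for motion in (SinusoidalMotion(12.0, 0.25), ConstantSpeedMotion(0.5)):
            prof, _ = simulate_mobile_profile(medium_target, motion, protocol, grid)
            assert prof.max_level() <= stat.max_level() + 1e-9

    @settings(deadline=None, max_examples=30)
    @given(
        amplitude=st.floats(0.0, 18.0),
        frequency=st.floats(0.1, 0.5),
        phase=st.floats(0.0, 2 * np.pi),
        mode=st.sampled_from(["center", "overlap"]),
    )
    def test_conservation_under_random_cyclic_motion(self, amplitude, frequency,
                                                     phase, mode):
        """Area under the profile is invariant under any in-view motion."""
        grid = WindowGrid(-60.0, 2.0, 60)
        target = preset_phantom("medium")
        protocol = ScanProtocol(n_projections=200, scan_duration=20.0)
        stat = stationary_profile(target, grid, protocol)
        prof, ledger = simulate_mobile_profile(
            target, SinusoidalMotion(amplitude, frequency, phase), protocol, grid, mode)
        assert prof.integral() == pytest.approx(stat.integral(), rel=1e-9)
        assert ledger.total_deposited() * grid.window_width == pytest.approx(
            stat.integral(), rel=1e-9)


class TestLevelRatioAndClosedForm:
    @pytest.mark.parametrize("m, n, expected", [(2, 10, 0.2), (7, 7, 1.0), (0, 5, 0.0)])
    def test_level_ratio(self, m, n, expected):
        assert mobile_level_ratio(m, n) == pytest.approx(expected)

    def test_level_ratio_rejects_m_above_n(self):
        with pytest.raises(ConfigurationError):
            mobile_level_ratio(11, 10)

    @pytest.mark.parametrize(
        "ct_s, w, vp, t, expected",
        [(100.0, 2.0, 0.0, 10.0, 100.0), (100.0, 2.0, 0.8, 10.0, 20.0)],
    )
    def test_constant_speed_level(self, ct_s, w, vp, t, expected):
        assert constant_speed_level(ct_s, w, vp, t) == pytest.approx(expected)

    @settings(deadline=None)
    @given(ct_s=st.floats(1.0, 2000.0), w=st.floats(0.5, 5.0),
           vp=st.floats(0.0, 3.0), t=st.floats(1.0, 120.0))
    def test_area_identity(self, ct_s, w, vp, t):
        """level * (w + VP*T) = CT_S * w — the conservation statement."""
        level = constant_speed_level(ct_s, w, vp, t)
        assert level * (w + vp * t) == pytest.approx(ct_s * w, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ConfigurationError):
            constant_speed_level(100.0, 0.0, 1.0, 10.0)
        with pytest.raises(ConfigurationError):
            constant_speed_level(100.0, 2.0, 1.0, 0.0)


def _brute_force_occupancy(target, motion, duration, grid, n_steps=200_000):
    """Independent oracle: fraction of time each window is covered by the
    displaced target, overlap-length weighted, by direct time sampling."""
    ts = (np.arange(n_steps) + 0.5) * duration / n_steps
    lo0, hi0 = target.extent
    values = np.zeros(grid.n_windows)
    d = np.asarray(motion.displacement(ts))
    for k in range(grid.n_windows):
        wlo = grid.origin_y + k * grid.window_width
        whi = wlo + grid.window_width
        ov = np.clip(np.minimum(whi, hi0 + d) - np.maximum(wlo, lo0 + d), 0.0, None)
        values[k] = target.ct_level * ov.mean() / grid.window_width
    return values


class TestContinuousOracle:
    def test_zero_motion_equals_stationary(self, grid, medium_target):
        stat = stationary_profile(medium_target, grid)
        cont = occupancy_profile_continuous(
            medium_target, SinusoidalMotion(0.0, 0.25), 60.0, grid)
        assert cont.allclose(stat, atol=1e-12)

    def test_arcsine_residence_fractions(self):
        """Full-excursion case L = 2A = 20 mm: a point at the stationary
        center is covered one third of the time, the best-covered points
        (y = +/- (A - L/2) = +/- 10 mm... here the excursion ends) half of
        the time."""
        assert sinusoidal_occupancy_fraction(0.0, 20.0, 20.0) == pytest.approx(1 / 3, abs=1e-12)
        assert sinusoidal_occupancy_fraction(10.0, 20.0, 20.0) == pytest.approx(0.5, abs=1e-12)
        assert sinusoidal_occupancy_fraction(-10.0, 20.0, 20.0) == pytest.approx(0.5, abs=1e-12)

    def test_window_profile_matches_pointwise_arcsine_on_fine_grid(self):
        grid = WindowGrid(-50.0, 0.1, 1000)
        target = TargetSpec(20.0, 100.0, 0.0)
        prof = occupancy_profile_continuous(target, SinusoidalMotion(20.0, 0.25), 60.0, grid)
        assert prof.metadata["method"] == "arcsine"
        center = grid.index(0.0)
        assert prof.values[center] == pytest.approx(100.0 / 3, rel=1e-3)
        assert prof.max_level() == pytest.approx(50.0, rel=5e-3)

    @pytest.mark.parametrize(
        "motion",
        [SinusoidalMotion(12.0, 0.25, 0.9), ConstantSpeedMotion(0.4)],
        ids=["sinusoidal", "constant_speed"],
    )
    def test_matches_brute_force_time_sampling(self, motion):
        grid = WindowGrid(-60.0, 2.0, 60)
        target = preset_phantom("medium")
        prof = occupancy_profile_continuous(target, motion, 60.0, grid,
                                            n_quadrature=200_000)
        brute = _brute_force_occupancy(target, motion, 60.0, grid)
        assert np.abs(prof.values - brute).max() < 1e-3 * target.ct_level

    def test_arcsine_and_quadrature_paths_agree(self):
        grid = WindowGrid(-60.0, 2.0, 60)
        target = preset_phantom("small")
        motion = SinusoidalMotion(15.0, 0.25, 1.1)
        closed = occupancy_profile_continuous(target, motion, 60.0, grid)
        quad = occupancy_profile_continuous(target, motion, 60.0, grid,
                                            n_quadrature=400_000, method="quadrature")
        assert closed.metadata["method"] == "arcsine"
        assert np.abs(closed.values - quad.values).max() < 1e-3 * target.ct_level

    def test_frequency_invariance_over_integer_cycles(self):
        grid = WindowGrid(-60.0, 2.0, 60)
        target = preset_phantom("medium")
        p1 = occupancy_profile_continuous(target, SinusoidalMotion(10.0, 0.2), 60.0, grid)
        p2 = occupancy_profile_continuous(target, SinusoidalMotion(10.0, 0.4), 60.0, grid)
        assert np.array_equal(p1.values, p2.values)

    def test_discrete_overlap_converges_to_oracle(self):
        grid = WindowGrid(-60.0, 2.0, 60)
        target = preset_phantom("medium")
        motion = SinusoidalMotion(10.0, 0.25)
        cont = occupancy_profile_continuous(target, motion, 60.0, grid)
        errs = []
        for n in (100, 1000, 10_000):
            prof, _ = simulate_mobile_profile(
                target, motion, ScanProtocol(n_projections=n, scan_duration=60.0),
                grid, "overlap")
            errs.append(np.abs(prof.values - cont.values).max())
        assert errs[0] > errs[1] > errs[2]

    def test_out_of_view_raises(self):
        grid = WindowGrid(-15.0, 2.0, 15)
        target = preset_phantom("medium")
        with pytest.raises(OutOfViewError):
            occupancy_profile_continuous(target, SinusoidalMotion(10.0, 0.25), 60.0, grid)
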