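"""Shared fixtures: grids, preset targets, and the worked integer-arithmetic
acquisition configurations (single-voxel and ten-voxel constant-speed scans).
"""

import pytest

from cbctmotion import (
    ConstantSpeedMotion,
    ScanProtocol,
    TargetSpec,
    WindowGrid,
    preset_phantom,
)

SWEEP_AMPLITUDES = [2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0]
SWEEP_SPEEDS = [0.25, 0.5, 1.0]
PRESET_NAMES = ["small", "medium", "large"]


@pytest.fixture
def grid() -> WindowGrid:
    """2 mm slices spanning [-60, 60) mm."""
    return WindowGrid(origin_y=-60.0, window_width=2.0, n_windows=60)


@pytest.fixture
def medium_target() -> TargetSpec:
    return preset_phantom("medium")


@pytest.fixture
def single_voxel_scan():
    """Worked example: one voxel (w = 2 mm) initially at a window boundary,
    N = 10 projections over 10 s, translating half a window width per
    inter-projection interval (1 mm/s)."""
    grid = WindowGrid(origin_y=0.0, window_width=2.0, n_windows=20)
    target = TargetSpec(length_y=2.0, ct_level=100.0, center_y0=4.0, label="voxel")
    protocol = ScanProtocol(n_projections=10, scan_duration=10.0)
    motion = ConstantSpeedMotion(speed=1.0)
    return target, motion, protocol, grid


@pytest.fixture
def ten_voxel_scan():
    """Worked example: ten-voxel target (20 mm) initially tiling windows
    1-10, N = 10 projections over 10 s, translating one window width per
    inter-projection interval (2 mm/s)."""
    grid = WindowGrid(origin_y=0.0, window_width=2.0, n_windows=25)
    target = TargetSpec(length_y=20.0, ct_level=100.0, center_y0=10.0, label="ten")
    protocol = ScanProtocol(n_projections=10, scan_duration=10.0)
    motion = ConstantSpeedMotion(speed=2.0)
    return target, motion, protocol, grid
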