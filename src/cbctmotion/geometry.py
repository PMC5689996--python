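"""Targets and the 1-D imaging-window grid along the superior–inferior axis.

The model is one-dimensional: everything happens along the patient
superior–inferior direction (``y``, increasing toward superior).  The
reconstructed volume is represented by a uniform grid of imaging windows of
width ``w`` (one slice thickness); windows are 0-indexed half-open intervals
``[origin + k*w, origin + (k+1)*w)``.

A target is a homogeneous rectangular insert characterised by its extent along
the motion axis and its CT number above the surrounding background.  Lateral
dimensions are carried only as metadata for coronal rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, FieldOfViewError

# Relative slack used when snapping positions that sit a rounding error below
# a window boundary onto that boundary.
_EDGE_RTOL = 1e-9


@dataclass(frozen=True)
class WindowGrid:
    """Uniform 1-D grid of imaging windows (slices).

    Parameters
    ----------
    origin_y:
        Left edge of window 0, in mm.
    window_width:
        Slice thickness ``w`` in mm; also the voxel thickness used when
        targets are voxelized.
    n_windows:
        Number of windows; the grid spans
        ``[origin_y, origin_y + n_windows * window_width)``.
    """

    origin_y: float
    window_width: float
    n_windows: int

    def __post_init__(self) -> None:
        if not self.window_width > 0:
            raise ConfigurationError(f"window_width must be > 0, got {self.window_width}")
        if self.n_windows < 1:
            raise ConfigurationError(f"n_windows must be >= 1, got {self.n_windows}")

    @property
    def span(self) -> tuple[float, float]:
        """(low, high) edges of the grid in mm."""
        return self.origin_y, self.origin_y + self.n_windows * self.window_width

    @property
    def extent(self) -> float:
        return self.n_windows * self.window_width

    @property
    def edges(self) -> np.ndarray:
        """Window edges, length ``n_windows + 1``."""
        return self.origin_y + self.window_width * np.arange(self.n_windows + 1)

    @property
    def centers(self) -> np.ndarray:
        """Window center positions, length ``n_windows``."""
        return self.origin_y + self.window_width * (np.arange(self.n_windows) + 0.5)

    def index_array(self, positions: np.ndarray) -> np.ndarray:
        """Vectorized window lookup; positions exactly on a boundary belong
        to the window on their right (half-open convention)."""
        x = (np.asarray(positions, dtype=float) - self.origin_y) / self.window_width
        k = np.floor(x)
        # snap positions a rounding error below a boundary up onto it
        k = np.where(x - k > 1.0 - _EDGE_RTOL, k + 1, k).astype(int)
        if np.any((k < 0) | (k >= self.n_windows)):
            bad = np.asarray(positions, dtype=float)[(k < 0) | (k >= self.n_windows)]
            raise FieldOfViewError(
                f"position(s) {bad[:5].tolist()} outside grid span {self.span}"
            )
        return k

    def index(self, position: float) -> int:
        """Ordinal of the window containing ``position``."""
        return int(self.index_array(np.asarray([position]))[0])

    def contains_interval(self, lo: float, hi: float) -> bool:
        g_lo, g_hi = self.span
        slack = _EDGE_RTOL * self.extent
        return lo >= g_lo - slack and hi <= g_hi + slack

    def same_as(self, other: "WindowGrid", rtol: float = 1e-9) -> bool:
        tol = rtol * self.window_width
        return (
            self.n_windows == other.n_windows
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.window_width - other.window_width) <= tol
        )


def window_index(position: float, grid: WindowGrid) -> int:
    """Ordinal ``k`` with ``origin + k*w <= position < origin + (k+1)*w``."""
    return grid.index(position)


@dataclass(frozen=True)
class TargetSpec:
    """Homogeneous rectangular target.

    ``ct_level`` is the CT number of the stationary target *above the
    surrounding background* (HU); profiles produced from this target are on
    the same background-relative scale.
    """

    length_y: float
    ct_level: float
    center_y0: float = 0.0
    lateral_dims: tuple[float, float] = (30.0, 50.0)  # (x, z) mm, metadata only
    label: str = ""

    def __post_init__(self) -> None:
        if not self.length_y > 0:
            raise ConfigurationError(f"target length_y must be > 0, got {self.length_y}")
        if not math.isfinite(self.ct_level):
            raise ConfigurationError("target ct_level must be finite")

    @property
    def extent(self) -> tuple[float, float]:
        """(low, high) edges of the stationary target in mm."""
        half = self.length_y / 2.0
        return self.center_y0 - half, self.center_y0 + half


@dataclass(frozen=True)
class Voxel:
    """One voxel of a voxelized target: center position, thickness and level."""

    center: float
    thickness: float
    level: float
    target_label: str = ""


def voxelize_target(target: TargetSpec, grid: WindowGrid) -> list[Voxel]:
    """Tile the target extent with voxels of thickness ``w``.

    Voxels tile ``[center_y0 - L/2, center_y0 + L/2)`` from the low edge; if
    the target length is not an integer multiple of ``w`` the last voxel is
    shorter, so the union of voxel extents reproduces the target extent
    exactly.  Each voxel carries the full target level; its thickness encodes
    its proportional weight in the deposition arithmetic.
    """
    lo, hi = target.extent
    if not grid.contains_interval(lo, hi):
        raise FieldOfViewError(
            f"target {target.label!r} extent ({lo}, {hi}) outside grid span {grid.span}"
        )
    w = grid.window_width
    voxels: list[Voxel] = []
    edge = lo
    while edge < hi - _EDGE_RTOL * w:
        thickness = min(w, hi - edge)
        voxels.append(
            Voxel(center=edge + thickness / 2.0, thickness=thickness,
                  level=target.ct_level, target_label=target.label)
        )
        edge += thickness
    return voxels


def check_targets_disjoint(targets: list[TargetSpec]) -> None:
    """Raise ConfigurationError if any two targets overlap along y."""
    spans = sorted((t.extent, t.label) for t in targets)
    for (ext_a, lab_a), (ext_b, lab_b) in zip(spans, spans[1:]):
        if ext_b[0] < ext_a[1] - _EDGE_RTOL * (ext_a[1] - ext_a[0]):
            raise ConfigurationError(
                f"targets {lab_a!r} and {lab_b!r} overlap along the motion axis"
            )
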