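"""Exception hierarchy for cbctmotion.

Configuration problems (bad input descriptions) and model-validity violations
(a target leaving the imaging view during the scan) are kept distinct so that
callers — the CLI in particular — can map them to different exit codes.
"""

from __future__ import annotations


class CBCTMotionError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CBCTMotionError, ValueError):
    """Invalid or inconsistent input description (targets, grid, protocol)."""


class FieldOfViewError(CBCTMotionError, ValueError):
    """A static position or target lies outside the window grid."""


class OutOfViewError(CBCTMotionError, RuntimeError):
    """A displaced voxel left the imaging view during the scan.

    The occupancy model's conservation law only holds while every voxel of the
    target stays inside the imaging view for every projection; this error names
    the first offending projection.
    """

    def __init__(self, message: str, projection_index: int | None = None):
        super().__init__(message)
        self.projection_index = projection_index


class GridMismatchError(CBCTMotionError, ValueError):
    """Two profiles that must share a grid do not."""


class TrajectoryRangeError(CBCTMotionError, ValueError):
    """A sampled trajectory was queried outside its time support."""


class ProfileParseError(CBCTMotionError, ValueError):
    """A profile CSV file is malformed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number
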