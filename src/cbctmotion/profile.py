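"""The CT-number profile container.

A :class:`CTProfile` holds one CT number (HU above background) per imaging
window of a :class:`~cbctmotion.geometry.WindowGrid`, plus free-form
provenance metadata (motion and protocol parameters, deposition mode, noise
parameters, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GridMismatchError
from .geometry import WindowGrid


@dataclass(eq=False)
class CTProfile:
    """CT number versus position on a regular window grid."""

    grid: WindowGrid
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != self.grid.n_windows:
            raise ConfigurationError(
                f"profile needs {self.grid.n_windows} values, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("profile values must be finite")

    @property
    def positions(self) -> np.ndarray:
        """Window-center positions in mm."""
        return self.grid.centers

    @property
    def window_width(self) -> float:
        return self.grid.window_width

    def integral(self) -> float:
        """Area under the profile, sum(values) * w, in HU*mm."""
        return float(np.sum(self.values) * self.grid.window_width)

    def max_level(self) -> float:
        return float(np.max(self.values))

    def copy(self, **metadata) -> "CTProfile":
        md = dict(self.metadata)
        md.update(metadata)
        return CTProfile(self.grid, self.values.copy(), md)

    def allclose(self, other: "CTProfile", atol: float = 1e-9) -> bool:
        return self.grid.same_as(other.grid) and np.allclose(
            self.values, other.values, atol=atol, rtol=0.0
        )


def require_same_grid(a: CTProfile, b: CTProfile) -> None:
    if not a.grid.same_as(b.grid):
        raise GridMismatchError(
            f"profiles are on different grids: {a.grid} vs {b.grid}"
        )
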