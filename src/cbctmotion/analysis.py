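"""Quantitative analysis of CT-number profiles.

Metrics: support extent, motion-induced elongation, level drop, profile
splitting, area (conservation check), percentage-normalized RMS difference
between two profiles, and inversion of the elongation law to recover the
motion amplitude from a blurred profile of a marker of known length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigurationError
from .profile import CTProfile, require_same_grid

#: Default support threshold: a window belongs to the support if its value is
#: at least this fraction of the profile maximum.
DEFAULT_SUPPORT_THRESHOLD = 0.05
#: Default split-detection dip: an interior minimum below this fraction of
#: the smaller of the two peaks counts as a split.
DEFAULT_DIP_FRAC = 0.9
#: Default smoothing width (windows) applied before split detection, to
#: suppress single-bin streak spikes in measured profiles.
DEFAULT_SMOOTH_WINDOW = 3


def support_extent(profile: CTProfile, threshold_frac: float = DEFAULT_SUPPORT_THRESHOLD) -> float:
    """Extent (mm) of the support: w times the number of windows whose value
    is at least ``threshold_frac`` of the profile maximum.  0 for a profile
    with no positive values."""
    if not 0.0 < threshold_frac < 1.0:
        raise ConfigurationError("threshold_frac must be in (0, 1)")
    m = profile.max_level()
    if m <= 0.0:
        return 0.0
    count = int(np.sum(profile.values >= threshold_frac * m))
    return count * profile.window_width


def elongation(mobile: CTProfile, stationary: CTProfile,
               threshold_frac: float = DEFAULT_SUPPORT_THRESHOLD) -> float:
    """Motion-induced increase of the support extent (mm).

    May be negative only through quantization, and is clamped at ``-w``.
    """
    require_same_grid(mobile, stationary)
    diff = support_extent(mobile, threshold_frac) - support_extent(stationary, threshold_frac)
    return max(diff, -mobile.window_width)


def estimate_amplitude(mobile: CTProfile, marker_length: float,
                       threshold_frac: float = DEFAULT_SUPPORT_THRESHOLD) -> float:
    """Invert the elongation law to recover the motion amplitude (mm).

    Cyclic 1-D motion broadens a marker of known length ``L`` to a support of
    ``L + 2A``, so ``A = (support - L) / 2``, floored at zero.
    """
    if not marker_length > 0:
        raise ConfigurationError("marker_length must be > 0")
    support = support_extent(mobile, threshold_frac)
    if support < marker_length - mobile.window_width:
        warnings.warn(
            f"profile support ({support} mm) is smaller than the marker "
            f"length ({marker_length} mm) minus one window; returning 0",
            stacklevel=2,
        )
        return 0.0
    return max(0.0, (support - marker_length) / 2.0)


def level_drop(mobile: CTProfile, reference: CTProfile) -> float:
    """Percent drop of the profile maximum relative to a reference profile."""
    require_same_grid(mobile, reference)
    ref_max = reference.max_level()
    if ref_max <= 0.0:
        raise ConfigurationError("reference profile maximum must be > 0")
    return 100.0 * (1.0 - mobile.max_level() / ref_max)


@dataclass(frozen=True)
class SplitResult:
    split: bool
    dip_position: float | None = None
    dip_value: float | None = None
    peak_positions: tuple[float, ...] = ()

    def __bool__(self) -> bool:  # allows `if detect_split(...)`
        return self.split


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values
    kernel = np.ones(width) / width
    padded = np.pad(values, width // 2, mode="edge")
    out = np.convolve(padded, kernel, mode="same")
    h = width // 2
    return out[h:h + values.size]


#: Peaks below this fraction of the global maximum are ignored by split
#: detection — they are baseline ripple, not a second lobe of the target.
MIN_PEAK_FRAC = 0.1


def detect_split(profile: CTProfile, dip_frac: float = DEFAULT_DIP_FRAC,
                 smooth_window: int = DEFAULT_SMOOTH_WINDOW,
                 min_peak_frac: float = MIN_PEAK_FRAC) -> SplitResult:
    """Detect a split profile: two maxima with a sufficiently deep dip.

    Returns a truthy :class:`SplitResult` iff the (optionally smoothed)
    profile has two local maxima — each at least ``min_peak_frac`` of the
    global maximum — with an interior minimum below ``dip_frac`` times the
    smaller of the two.  ``smooth_window=1`` disables the smoothing pass; the
    default 3-window pass suppresses single-bin streak spikes in measured
    profiles.
    """
    if not 0.0 < dip_frac < 1.0:
        raise ConfigurationError("dip_frac must be in (0, 1)")
    v = _smooth(profile.values, smooth_window)
    peaks, _ = find_peaks(v, plateau_size=1)
    peaks = peaks[v[peaks] >= min_peak_frac * np.max(v)] if peaks.size else peaks
    if peaks.size < 2:
        return SplitResult(split=False)
    # the two tallest local maxima, in positional order
    order = peaks[np.argsort(v[peaks])][-2:]
    i, j = int(np.min(order)), int(np.max(order))
    interior = v[i + 1:j]
    if interior.size == 0:
        return SplitResult(split=False)
    k = int(np.argmin(interior)) + i + 1
    centers = profile.positions
    split = v[k] < dip_frac * min(v[i], v[j])
    return SplitResult(
        split=bool(split),
        dip_position=float(centers[k]),
        dip_value=float(v[k]),
        peak_positions=(float(centers[i]), float(centers[j])),
    )


def integral(profile: CTProfile) -> float:
    """Area under the profile, sum(values) * w (HU*mm)."""
    return profile.integral()


def conservation_check(a: CTProfile, b: CTProfile, rel_tol: float = 1e-6) -> bool:
    """True iff the areas under the two profiles agree to ``rel_tol``
    relative to the first — the conserved quantity for in-view motion."""
    require_same_grid(a, b)
    ia, ib = a.integral(), b.integral()
    return abs(ia - ib) <= rel_tol * abs(ia)


@dataclass(frozen=True)
class ComparisonResult:
    """PRMS comparison of a calculated and a measured profile."""

    prms_pct: float
    residuals: np.ndarray
    support_windows: np.ndarray
    normalization: float


def prms(calculated: CTProfile, measured: CTProfile,
         normalization: float | None = None) -> ComparisonResult:
    """Percentage normalized RMS difference over the union support.

    The union support is the set of windows where either profile is nonzero.
    ``normalization`` defaults to the maximum absolute value of the
    calculated profile; pass the stationary target level ``CT_S`` to
    normalize mobile profiles consistently across motion parameters.
    """
    require_same_grid(calculated, measured)
    support = (calculated.values != 0.0) | (measured.values != 0.0)
    if not np.any(support):
        raise ConfigurationError("both profiles are identically zero")
    if normalization is None:
        normalization = float(np.max(np.abs(calculated.values)))
    if not normalization > 0:
        raise ConfigurationError("normalization must be > 0")
    resid = calculated.values[support] - measured.values[support]
    value = 100.0 * float(np.sqrt(np.mean(resid ** 2))) / normalization
    return ComparisonResult(
        prms_pct=value,
        residuals=resid,
        support_windows=np.nonzero(support)[0],
        normalization=float(normalization),
    )


@dataclass
class ProfileMetrics:
    """Bundle of scalar metrics for one profile (optionally vs a reference)."""

    support_extent: float
    max_level: float
    max_positions: list[float]
    integral: float
    split: bool
    elongation: float | None = None
    level_drop_pct: float | None = None
    estimated_amplitude: float | None = None
    threshold_frac: float = DEFAULT_SUPPORT_THRESHOLD

    def as_dict(self) -> dict:
        return {
            "extent_mm": self.support_extent,
            "elongation_mm": self.elongation,
            "max_hu": self.max_level,
            "max_positions_mm": self.max_positions,
            "drop_pct": self.level_drop_pct,
            "split": self.split,
            "integral_hu_mm": self.integral,
            "estimated_amplitude_mm": self.estimated_amplitude,
            "threshold_frac": self.threshold_frac,
        }


def compute_metrics(
    profile: CTProfile,
    reference: CTProfile | None = None,
    threshold_frac: float = DEFAULT_SUPPORT_THRESHOLD,
    dip_frac: float = DEFAULT_DIP_FRAC,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    marker_length: float | None = None,
) -> ProfileMetrics:
    """Compute the standard metric bundle for a profile."""
    m = profile.max_level()
    if m > 0:
        at_max = np.abs(profile.values - m) <= 1e-12 * max(abs(m), 1.0)
        max_positions = [float(p) for p in profile.positions[at_max]]
    else:
        max_positions = []
    metrics = ProfileMetrics(
        support_extent=support_extent(profile, threshold_frac),
        max_level=m,
        max_positions=max_positions,
        integral=profile.integral(),
        split=detect_split(profile, dip_frac, smooth_window).split,
        threshold_frac=threshold_frac,
    )
    if reference is not None:
        metrics.elongation = elongation(profile, reference, threshold_frac)
        metrics.level_drop_pct = level_drop(profile, reference)
    if marker_length is not None:
        metrics.estimated_amplitude = estimate_amplitude(profile, marker_length, threshold_frac)
    return metrics
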