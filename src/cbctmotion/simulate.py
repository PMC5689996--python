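"""Projection-occupancy acquisition model.

The model treats CBCT reconstruction to first order: every projection
contributes a fixed increment to the CT number of the window in which each
target voxel is found at the moment the projection is acquired.  For a
stationary voxel all ``N`` projections land in its own window, giving the
stationary level ``CT_S``; for a mobile voxel the increments are spread over
the windows the voxel visits, so each window accumulates ``M <= N``
projections and a level ``CT_S * M / N``.  The area under the profile is
conserved as long as the target stays in the imaging view for every
projection.

Two deposition rules are provided:

``center``
    The whole increment goes to the window containing the displaced voxel
    center.  This reproduces the integer bookkeeping of the worked
    single-voxel and ten-voxel examples exactly.
``overlap``
    The increment is split between the (at most two) windows the displaced
    voxel overlaps, proportionally to geometric overlap.  This is the smooth
    default and converges to the continuous occupancy limit as ``N`` grows.

A continuous-time occupancy oracle (the ``N -> infinity`` limit) is computed
either from the arcsine residence-time distribution (sinusoidal motion over
an integer number of cycles — exact and phase-free) or by midpoint time
quadrature (any motion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, OutOfViewError
from .geometry import TargetSpec, WindowGrid, check_targets_disjoint, voxelize_target
from .motion import ConstantSpeedMotion, MotionModel, SinusoidalMotion, STATIONARY
from .profile import CTProfile

#: Conventional projection counts for a 60 s gantry rotation when a protocol
#: does not pin N explicitly (offset-detector half-fan scans use a full 360
#: degree arc and collect more projections than the 180-degree full-fan mode).
DEFAULT_PROJECTIONS = {"half": 655, "full": 360}
DEFAULT_ROTATION_S = 60.0


@dataclass(frozen=True)
class ScanProtocol:
    """Scan protocol: projection count, duration and fan-mode metadata.

    ``fan_mode`` and ``fov_span`` are metadata only — the model is
    projection-count based, and the angular range of the acquisition does not
    enter the first-order occupancy arithmetic.  ``fov_span`` (mm), when
    given, must cover the window grid in use.
    """

    n_projections: int | None = None
    scan_duration: float = DEFAULT_ROTATION_S
    fan_mode: str = "half"
    fov_span: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.fan_mode not in DEFAULT_PROJECTIONS:
            raise ConfigurationError(f"fan_mode must be one of {set(DEFAULT_PROJECTIONS)}")
        if self.n_projections is not None and self.n_projections < 1:
            raise ConfigurationError("n_projections must be >= 1")
        if not self.scan_duration > 0:
            raise ConfigurationError("scan_duration must be > 0")

    @property
    def n(self) -> int:
        if self.n_projections is not None:
            return self.n_projections
        return DEFAULT_PROJECTIONS[self.fan_mode]

    def check_grid(self, grid: WindowGrid) -> None:
        if self.fov_span is not None:
            lo, hi = grid.span
            if self.fov_span[0] > lo or self.fov_span[1] < hi:
                raise ConfigurationError(
                    f"fov_span {self.fov_span} does not cover grid span {grid.span}"
                )


def projection_times(protocol: ScanProtocol) -> np.ndarray:
    """Uniform projection times t_n = n * (duration / N), n = 0..N-1 (s)."""
    n = protocol.n
    return np.arange(n) * (protocol.scan_duration / n)


@dataclass
class DepositionLedger:
    """Per-projection, per-voxel increment bookkeeping.

    Each row is one increment: which projection, which voxel, into which
    window, how much (HU added to the window value).  In overlap mode a
    voxel's increment may be split into two rows.
    """

    n_projections: int
    n_windows: int
    projection: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    voxel: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    window: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    amount: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    def increments_per_window(self) -> np.ndarray:
        """Number of increment rows landing in each window."""
        return np.bincount(self.window, minlength=self.n_windows)

    def projections_per_window(self) -> np.ndarray:
        """M per window: the number of distinct projections contributing to
        each window (the quantity relating mobile to stationary levels via
        CT_M = CT_S * M / N)."""
        key = self.window.astype(np.int64) * self.n_projections + self.projection
        uniq = np.unique(key)
        return np.bincount((uniq // self.n_projections).astype(int),
                           minlength=self.n_windows)

    def window_totals(self) -> np.ndarray:
        return np.bincount(self.window, weights=self.amount, minlength=self.n_windows)

    def total_deposited(self) -> float:
        return float(np.sum(self.amount))


def mobile_level_ratio(m: int, n: int) -> float:
    """Level ratio M/N between the mobile and stationary CT number of a voxel."""
    if n < 1:
        raise ConfigurationError("N must be >= 1")
    if not 0 <= m <= n:
        raise ConfigurationError(f"M must satisfy 0 <= M <= N, got M={m}, N={n}")
    return m / n


def constant_speed_level(ct_s: float, w: float, vp: float, t: float) -> float:
    """Mean mobile level for constant-speed motion: CT_S * w / (w + VP*T).

    This is the area-conservation statement CT_S * w = CT_M * (w + L) with the
    elongation L = VP * T travelled during the acquisition time T.
    """
    if not w > 0:
        raise ConfigurationError("window width w must be > 0")
    if not t > 0:
        raise ConfigurationError("acquisition time T must be > 0")
    if vp < 0:
        raise ConfigurationError("speed must be >= 0")
    return ct_s * w / (w + vp * t)


def _gather_voxels(targets: list[TargetSpec], grid: WindowGrid):
    check_targets_disjoint(targets)
    voxels = []
    for t in targets:
        voxels.extend(voxelize_target(t, grid))
    centers = np.array([v.center for v in voxels])
    thickness = np.array([v.thickness for v in voxels])
    levels = np.array([v.level for v in voxels])
    return centers, thickness, levels


def simulate_mobile_profile(
    targets: list[TargetSpec] | TargetSpec,
    motion: MotionModel,
    protocol: ScanProtocol,
    grid: WindowGrid,
    deposition: str = "overlap",
) -> tuple[CTProfile, DepositionLedger]:
    """Accumulate per-projection CT-number increments for moving targets.

    For each projection time ``t_n`` every voxel deposits an increment
    ``level * thickness / (w * N)`` into the window(s) at its displaced
    position.  Returns the window-wise sum as a :class:`CTProfile` together
    with the full :class:`DepositionLedger`.

    Raises :class:`OutOfViewError` (naming the first offending projection) if
    any displaced voxel leaves the grid during the scan — outside that regime
    the conservation law does not hold and the model is invalid.
    """
    if isinstance(targets, TargetSpec):
        targets = [targets]
    if deposition not in ("center", "overlap"):
        raise ConfigurationError("deposition must be 'center' or 'overlap'")
    protocol.check_grid(grid)

    centers, thickness, levels = _gather_voxels(targets, grid)
    n_proj = protocol.n
    w = grid.window_width
    times = projection_times(protocol)
    disp = np.asarray(motion.displacement(times), dtype=float).reshape(n_proj)

    # displaced voxel positions, (N, V)
    pos = centers[None, :] + disp[:, None]
    half = thickness[None, :] / 2.0
    g_lo, g_hi = grid.span
    slack = 1e-9 * grid.extent
    bad = (pos - half < g_lo - slack) | (pos + half > g_hi + slack)
    if np.any(bad):
        first = int(np.argmax(np.any(bad, axis=1)))
        raise OutOfViewError(
            f"target voxel leaves the imaging view at projection {first} "
            f"(t = {times[first]:.6g} s)",
            projection_index=first,
        )

    # per-voxel increment, HU added to a window value per projection
    q = levels * thickness / (w * n_proj)
    v = centers.size

    if deposition == "center":
        wins = grid.index_array(pos)
        proj_idx = np.repeat(np.arange(n_proj), v)
        vox_idx = np.tile(np.arange(v), n_proj)
        win_idx = wins.ravel()
        amounts = np.tile(q, n_proj)
    else:
        lo = pos - half
        x = (lo - grid.origin_y) / w
        k0 = np.floor(x)
        k0 = np.where(x - k0 > 1.0 - 1e-9, k0 + 1, k0).astype(int)
        right_edge = grid.origin_y + (k0 + 1) * w
        ov0 = np.clip(np.minimum(lo + thickness[None, :], right_edge) - lo,
                      0.0, thickness[None, :])
        frac0 = ov0 / thickness[None, :]
        a0 = q[None, :] * frac0
        a1 = q[None, :] - a0

        proj_base = np.repeat(np.arange(n_proj), v)
        vox_base = np.tile(np.arange(v), n_proj)
        k0_flat = np.clip(k0.ravel(), 0, grid.n_windows - 1)
        a0_flat = a0.ravel()
        a1_flat = a1.ravel()
        spill = a1_flat > np.tile(q, n_proj) * 1e-12

        proj_idx = np.concatenate([proj_base, proj_base[spill]])
        vox_idx = np.concatenate([vox_base, vox_base[spill]])
        win_idx = np.concatenate(
            [k0_flat, np.clip(k0.ravel()[spill] + 1, 0, grid.n_windows - 1)]
        )
        amounts = np.concatenate([a0_flat, a1_flat[spill]])

    values = np.bincount(win_idx, weights=amounts, minlength=grid.n_windows)
    ledger = DepositionLedger(
        n_projections=n_proj, n_windows=grid.n_windows,
        projection=proj_idx, voxel=vox_idx, window=win_idx, amount=amounts,
    )
    meta = {
        "kind": "mobile" if _is_moving(motion) else "stationary",
        "motion": motion.kind,
        "deposition": deposition,
        "n_projections": n_proj,
        "scan_duration_s": protocol.scan_duration,
        "fan_mode": protocol.fan_mode,
    }
    return CTProfile(grid, values, meta), ledger


def _is_moving(motion: MotionModel) -> bool:
    if isinstance(motion, ConstantSpeedMotion):
        return motion.speed != 0.0
    if isinstance(motion, SinusoidalMotion):
        return motion.amplitude != 0.0 and motion.frequency != 0.0
    return True


def stationary_profile(
    targets: list[TargetSpec] | TargetSpec,
    grid: WindowGrid,
    protocol: ScanProtocol | None = None,
) -> CTProfile:
    """Profile of stationary targets: CT_S inside, overlap-weighted edges.

    Computed through the same deposition path as the mobile case (all N
    projections land geometrically), so stationary and mobile profiles are
    exactly comparable.
    """
    if protocol is None:
        protocol = ScanProtocol(n_projections=1, scan_duration=1.0)
    profile, _ = simulate_mobile_profile(targets, STATIONARY, protocol, grid,
                                         deposition="overlap")
    profile.metadata["kind"] = "stationary"
    return profile


# ---------------------------------------------------------------------------
# Continuous-time occupancy oracle
# ---------------------------------------------------------------------------

def _arcsin_antiderivative(u: np.ndarray) -> np.ndarray:
    """Antiderivative of arcsin(clip(u, -1, 1)); continuous and C1."""
    u = np.asarray(u, dtype=float)
    uc = np.clip(u, -1.0, 1.0)
    inner = uc * np.arcsin(uc) + np.sqrt(np.clip(1.0 - uc * uc, 0.0, None))
    return np.where(np.abs(u) >= 1.0, 0.5 * np.pi * np.abs(u), inner)


def sinusoidal_occupancy_fraction(y, length: float, amplitude: float,
                                  center: float = 0.0):
    """Fraction of time a point ``y`` is covered by a target of the given
    length whose center executes sinusoidal motion of the given amplitude
    about ``center``, over an integer number of cycles.

    This is the arcsine residence-time law: the displacement of a sinusoid
    sampled uniformly in time follows the arcsine distribution on
    ``[-A, A]``, so the coverage fraction is
    ``(arcsin(b) - arcsin(a)) / pi`` with ``a, b`` the clipped normalized
    bounds of the displacement interval that covers ``y``.
    """
    y = np.asarray(y, dtype=float)
    half = length / 2.0
    if amplitude <= 0:
        out = ((y >= center - half) & (y < center + half)).astype(float)
        return out if out.ndim else float(out)
    a = np.clip((y - center - half) / amplitude, -1.0, 1.0)
    b = np.clip((y - center + half) / amplitude, -1.0, 1.0)
    out = (np.arcsin(b) - np.arcsin(a)) / np.pi
    return out if out.ndim else float(out)


def _arcsine_window_values(edges: np.ndarray, w: float, target: TargetSpec,
                           amplitude: float) -> np.ndarray:
    """Window-averaged sinusoidal occupancy times target level (exact)."""
    c0 = target.center_y0
    half = target.length_y / 2.0
    if amplitude <= 0:
        lo = np.maximum(edges[:-1], c0 - half)
        hi = np.minimum(edges[1:], c0 + half)
        return target.ct_level * np.clip(hi - lo, 0.0, None) / w
    s_lo = c0 - half  # occupancy(y) uses arcsin((y - s_lo)/A) - arcsin((y - s_hi)/A)
    s_hi = c0 + half
    g_b = _arcsin_antiderivative((edges - s_lo) / amplitude)
    g_a = _arcsin_antiderivative((edges - s_hi) / amplitude)
    per_window = (np.diff(g_b) - np.diff(g_a)) * amplitude / (np.pi * w)
    # windows entirely outside the reachable span hold only rounding dust
    reachable = (edges[1:] > s_lo - amplitude) & (edges[:-1] < s_hi + amplitude)
    per_window = np.where(reachable, per_window, 0.0)
    return target.ct_level * per_window


def occupancy_profile_continuous(
    targets: list[TargetSpec] | TargetSpec,
    motion: MotionModel,
    duration: float,
    grid: WindowGrid,
    n_quadrature: int = 100_000,
    method: str = "auto",
) -> CTProfile:
    """N -> infinity limit of the discrete simulator (overlap deposition).

    The value at window ``k`` is ``CT_S`` times the overlap-length-weighted
    fraction of ``[0, duration]`` during which the displaced target covers
    window ``k``.

    ``method='arcsine'`` (or ``'auto'`` with sinusoidal motion spanning an
    integer number of cycles) evaluates the closed-form arcsine occupancy —
    exact and independent of the motion phase.  Otherwise a midpoint time
    quadrature with ``n_quadrature`` samples is used.
    """
    if isinstance(targets, TargetSpec):
        targets = [targets]
    if method not in ("auto", "arcsine", "quadrature"):
        raise ConfigurationError("method must be 'auto', 'arcsine' or 'quadrature'")
    if not duration > 0:
        raise ConfigurationError("duration must be > 0")
    check_targets_disjoint(targets)

    d_min, d_max = motion.bounds(duration)
    g_lo, g_hi = grid.span
    slack = 1e-9 * grid.extent
    for t in targets:
        lo, hi = t.extent
        if lo + d_min < g_lo - slack or hi + d_max > g_hi + slack:
            raise OutOfViewError(
                f"target {t.label!r} leaves the imaging view "
                f"(displaced extent ({lo + d_min:.6g}, {hi + d_max:.6g}) mm "
                f"vs grid span {grid.span})"
            )

    use_arcsine = method == "arcsine"
    if method == "auto" and isinstance(motion, SinusoidalMotion):
        cycles = motion.cycles(duration)
        if motion.amplitude == 0.0 or (
            cycles >= 1.0 - 1e-9 and abs(cycles - round(cycles)) < 1e-9
        ):
            use_arcsine = True
    if use_arcsine and not isinstance(motion, SinusoidalMotion):
        raise ConfigurationError("arcsine method requires sinusoidal motion")

    edges = grid.edges
    w = grid.window_width
    values = np.zeros(grid.n_windows)

    if use_arcsine:
        for t in targets:
            values += _arcsine_window_values(edges, w, t, motion.amplitude)
        method_used = "arcsine"
    else:
        if n_quadrature < 1000:
            raise ConfigurationError("n_quadrature must be >= 1000")
        ts = (np.arange(n_quadrature) + 0.5) * (duration / n_quadrature)
        disp = np.asarray(motion.displacement(ts), dtype=float)
        chunk = max(1, 4_000_000 // max(grid.n_windows, 1))
        for t in targets:
            lo0, hi0 = t.extent
            acc = np.zeros(grid.n_windows)
            for start in range(0, n_quadrature, chunk):
                d = disp[start:start + chunk, None]
                ov = np.clip(
                    np.minimum(edges[None, 1:], hi0 + d)
                    - np.maximum(edges[None, :-1], lo0 + d),
                    0.0, None,
                )
                acc += ov.sum(axis=0)
            values += t.ct_level * acc / (n_quadrature * w)
        method_used = "quadrature"

    meta = {
        "kind": "continuous_occupancy",
        "motion": motion.kind,
        "duration_s": duration,
        "method": method_used,
    }
    return CTProfile(grid, values, meta)
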