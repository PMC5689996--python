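"""Experiment runners: single simulations, parameter sweeps, coronal renders.

These are the batch entry points behind the CLI: run one configured
acquisition (stationary + mobile + optional pseudo-measurement, with metrics
and conservation logging), sweep one motion parameter and tabulate metrics,
or extrude profiles into a coronal-view grayscale image.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import analysis
from .config import RunConfig
from .errors import CBCTMotionError, ConfigurationError
from .io import _jsonable, write_profile_csv
from .motion import ConstantSpeedMotion, SinusoidalMotion
from .profile import CTProfile
from .simulate import (
    occupancy_profile_continuous,
    simulate_mobile_profile,
    stationary_profile,
)
from .synthetic import generate_measured_profile

logger = logging.getLogger("cbctmotion")


@dataclass
class SimulationRun:
    """Everything a single configured acquisition produced."""

    stationary: CTProfile
    mobile: CTProfile
    measured: CTProfile | None
    metrics: analysis.ProfileMetrics
    conservation_ok: bool
    m_per_window: np.ndarray
    paths: dict[str, Path]


def run_simulate(config: RunConfig, output_dir: str | Path | None = None) -> SimulationRun:
    """Run one acquisition and write profiles, ledger summary and metrics."""
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    targets = config.build_targets()
    motion = config.motion.build()
    protocol = config.protocol.build()
    grid = config.grid.build()

    stat = stationary_profile(targets, grid, protocol)
    mobile, ledger = simulate_mobile_profile(targets, motion, protocol, grid,
                                             deposition=config.deposition)

    conserved = analysis.conservation_check(stat, mobile, rel_tol=1e-6)
    logger.info(
        "conservation check: stationary integral %.6g, mobile %.6g HU*mm -> %s",
        stat.integral(), mobile.integral(), "ok" if conserved else "FAILED",
    )
    if not conserved:
        # in-view motion conserves the area by construction; a failure here
        # is an internal arithmetic error, not a data problem
        raise CBCTMotionError("conservation check failed for in-view motion")

    marker = config.analysis.marker_length_mm
    if marker is None and len(targets) == 1:
        marker = targets[0].length_y
    metrics = analysis.compute_metrics(
        mobile, reference=stat,
        threshold_frac=config.analysis.support_threshold,
        dip_frac=config.analysis.split_dip_frac,
        smooth_window=config.analysis.smooth_window,
        marker_length=marker,
    )

    measured = None
    if config.noise is not None:
        measured = generate_measured_profile(mobile, config.noise.build(config.seed))

    paths = {
        "stationary": write_profile_csv(stat, out / "stationary.csv"),
        "mobile": write_profile_csv(mobile, out / "mobile.csv"),
    }
    if measured is not None:
        paths["measured"] = write_profile_csv(measured, out / "measured.csv")

    m_per_window = ledger.projections_per_window()
    ledger_summary = {
        "n_projections": ledger.n_projections,
        "projections_per_window": m_per_window.tolist(),
        "total_deposited_hu": ledger.total_deposited(),
    }
    paths["ledger"] = out / "ledger.json"
    paths["ledger"].write_text(json.dumps(ledger_summary, indent=2) + "\n")

    record = metrics.as_dict()
    record["conservation_ok"] = conserved
    paths["metrics"] = out / "metrics.json"
    paths["metrics"].write_text(json.dumps(_jsonable(record), indent=2, sort_keys=True) + "\n")

    return SimulationRun(
        stationary=stat, mobile=mobile, measured=measured, metrics=metrics,
        conservation_ok=conserved, m_per_window=m_per_window, paths=paths,
    )


SWEEP_AXES = ("amplitude", "frequency", "speed")


def run_sweep(
    config: RunConfig,
    axis: str,
    values: list[float],
    engine: str = "discrete",
    output_path: str | Path | None = None,
) -> pd.DataFrame:
    """Sweep one motion parameter and tabulate profile metrics.

    ``engine='discrete'`` runs the projection simulator with the configured
    protocol; ``engine='continuous'`` uses the continuous occupancy oracle
    over the protocol duration.  The returned frame carries one row per sweep
    value; a fitted slope of elongation vs amplitude (or extent vs speed) is
    attached as ``df.attrs['slope_mm_per_unit']``.
    """
    if axis not in SWEEP_AXES:
        raise ConfigurationError(f"sweep axis must be one of {SWEEP_AXES}")
    if not values:
        raise ConfigurationError("sweep values list is empty")
    if engine not in ("discrete", "continuous"):
        raise ConfigurationError("engine must be 'discrete' or 'continuous'")

    targets = config.build_targets()
    base_motion = config.motion.build()
    protocol = config.protocol.build()
    grid = config.grid.build()
    stat = stationary_profile(targets, grid, protocol)
    thr = config.analysis.support_threshold

    rows = []
    for value in values:
        motion = _motion_for(base_motion, axis, value)
        if engine == "discrete":
            profile, _ = simulate_mobile_profile(targets, motion, protocol, grid,
                                                 deposition=config.deposition)
        else:
            profile = occupancy_profile_continuous(targets, motion,
                                                   protocol.scan_duration, grid)
        marker = targets[0].length_y if len(targets) == 1 else None
        metrics = analysis.compute_metrics(
            profile, reference=stat, threshold_frac=thr,
            dip_frac=config.analysis.split_dip_frac,
            smooth_window=config.analysis.smooth_window,
            marker_length=config.analysis.marker_length_mm or marker,
        )
        rows.append({
            "target": ",".join(t.label or "target" for t in targets),
            "A_mm": getattr(motion, "amplitude", np.nan),
            "f_hz": getattr(motion, "frequency", np.nan),
            "vp_mm_s": getattr(motion, "speed", np.nan),
            axis: value,
            "extent_mm": metrics.support_extent,
            "elongation_mm": metrics.elongation,
            "max_hu": metrics.max_level,
            "drop_pct": metrics.level_drop_pct,
            "split": metrics.split,
            "integral_hu_mm": metrics.integral,
            "estimated_amplitude_mm": metrics.estimated_amplitude,
        })
    df = pd.DataFrame(rows)

    if len(values) >= 2:
        if axis == "amplitude":
            df.attrs["slope_mm_per_unit"] = float(
                np.polyfit(df[axis], df["elongation_mm"], 1)[0])
        elif axis == "speed":
            df.attrs["slope_mm_per_unit"] = float(
                np.polyfit(df[axis], df["extent_mm"], 1)[0])

    if output_path is not None:
        df.to_csv(output_path, index=False)
    return df


def _motion_for(base, axis: str, value: float):
    if axis == "amplitude":
        if not isinstance(base, SinusoidalMotion):
            raise ConfigurationError("amplitude sweep needs sinusoidal motion")
        return replace(base, amplitude=value)
    if axis == "frequency":
        if not isinstance(base, SinusoidalMotion):
            raise ConfigurationError("frequency sweep needs sinusoidal motion")
        return replace(base, frequency=value)
    if not isinstance(base, ConstantSpeedMotion):
        raise ConfigurationError("speed sweep needs constant-speed motion")
    return replace(base, speed=value)


def render_coronal(
    profiles: list[CTProfile],
    lateral_widths: list[float],
    path: str | Path,
    px_per_mm: float = 1.0,
    gap_mm: float = 10.0,
    background_level: float = 0.0,
) -> Path:
    """Extrude profiles across their lateral widths into a coronal PNG.

    Each profile becomes a horizontal strip whose gray level follows the
    profile along y; strips are separated by background.  Rendering is
    deterministic: identical inputs give byte-identical files.
    """
    path = Path(path)
    if len(profiles) != len(lateral_widths):
        raise ConfigurationError("need one lateral width per profile")
    if profiles:
        grid = profiles[0].grid
        for p in profiles[1:]:
            if not grid.same_as(p.grid):
                raise ConfigurationError("coronal rendering needs a common grid")
        n_cols = max(2, int(round(grid.extent * px_per_mm)))
        peak = max([background_level] + [p.max_level() for p in profiles])
    else:
        n_cols, peak = 64, 1.0
    gap_px = max(1, int(round(gap_mm * px_per_mm)))

    strips = [np.full((gap_px, n_cols), background_level)]
    for prof, width in zip(profiles, lateral_widths):
        h = max(1, int(round(width * px_per_mm)))
        cols = np.interp(
            np.linspace(prof.grid.span[0], prof.grid.span[1], n_cols, endpoint=False),
            prof.positions, prof.values, left=background_level, right=background_level,
        )
        strips.append(np.tile(cols, (h, 1)))
        strips.append(np.full((gap_px, n_cols), background_level))
    image = np.vstack(strips)
    scale = 255.0 / peak if peak > 0 else 1.0
    img8 = np.clip(image * scale, 0, 255).astype(np.uint8)
    Image.fromarray(img8, mode="L").save(path, format="PNG")
    return path
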