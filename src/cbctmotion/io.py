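"""Profile CSV and sidecar-JSON input/output.

Profile files are two-column CSV with header ``position_mm,hu`` and one row
per window center.  Positions must be strictly increasing and uniformly
spaced; the window grid is reconstructed from the spacing, taking each
position as a window center.  A sidecar JSON next to the CSV carries the
profile metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ProfileParseError
from .geometry import WindowGrid
from .profile import CTProfile

HEADER = "position_mm,hu"
_SPACING_RTOL = 1e-6


def write_profile_csv(profile: CTProfile, path: str | Path,
                      sidecar: bool = True) -> Path:
    """Write a profile as CSV (and its metadata as ``<path>.json``)."""
    path = Path(path)
    lines = [HEADER]
    for pos, hu in zip(profile.positions, profile.values):
        lines.append(f"{float(pos)!r},{float(hu)!r}")
    path.write_text("\n".join(lines) + "\n")
    if sidecar:
        sidecar_path(path).write_text(
            json.dumps(_jsonable(profile.metadata), indent=2, sort_keys=True) + "\n"
        )
    return path


def sidecar_path(csv_path: str | Path) -> Path:
    return Path(str(csv_path) + ".json")


def read_profile_csv(path: str | Path) -> CTProfile:
    """Read a profile CSV; round-trips :func:`write_profile_csv` exactly.

    Raises :class:`ProfileParseError` (with the offending line number) on a
    malformed header, non-numeric cells, or non-uniform spacing.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != HEADER:
        got = lines[0].strip() if lines else "<empty file>"
        raise ProfileParseError(f"expected header {HEADER!r}, got {got!r}", line_number=1)
    positions: list[float] = []
    values: list[float] = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != 2:
            raise ProfileParseError(f"expected 2 cells, got {len(cells)}", line_number=i)
        try:
            positions.append(float(cells[0]))
            values.append(float(cells[1]))
        except ValueError:
            raise ProfileParseError(f"non-numeric cell in {line!r}", line_number=i) from None
    if len(positions) < 2:
        raise ProfileParseError("need at least 2 data rows to infer the window grid")
    pos = np.asarray(positions)
    spacing = np.diff(pos)
    if np.any(spacing <= 0):
        bad = int(np.argmax(spacing <= 0)) + 3  # +2 header/1-based, +1 second row of pair
        raise ProfileParseError("positions must be strictly increasing", line_number=bad)
    w = float(np.mean(spacing))
    if np.any(np.abs(spacing - w) > _SPACING_RTOL * w):
        bad = int(np.argmax(np.abs(spacing - w) > _SPACING_RTOL * w)) + 3
        raise ProfileParseError("positions must be uniformly spaced", line_number=bad)
    grid = WindowGrid(origin_y=float(pos[0]) - w / 2.0, window_width=w,
                      n_windows=len(positions))
    metadata = {}
    sc = sidecar_path(path)
    if sc.exists():
        metadata = json.loads(sc.read_text())
    return CTProfile(grid, np.asarray(values), metadata)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
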