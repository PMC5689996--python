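"""Synthetic "measured" profiles and preset phantom targets.

Measured CBCT profiles differ from the first-order model by per-window noise,
occasional single-window spikes from streaking artifacts (dense couch or
phantom components crossing the view), and a small level offset between
half-fan and full-fan acquisitions of the same object.  This module generates
such pseudo-measurements from a model profile so the comparison pipeline can
be exercised without phantom data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .geometry import TargetSpec
from .profile import CTProfile

#: Motion-axis lengths (mm) of the thorax-phantom gel inserts, and their
#: lateral (x, z) dimensions in mm.
PHANTOM_PRESETS = {
    "small": {"length_y": 10.0, "lateral": (30.0, 50.0)},
    "medium": {"length_y": 20.0, "lateral": (30.0, 50.0)},
    "large": {"length_y": 40.0, "lateral": (30.0, 50.0)},
}

#: Default absolute HU of the water-equivalent gel targets and the
#: lung-equivalent foam background; profiles carry the difference.
DEFAULT_TARGET_HU = 0.0
DEFAULT_BACKGROUND_HU = -700.0


def preset_phantom(
    name: str,
    background: float = DEFAULT_BACKGROUND_HU,
    target_hu: float = DEFAULT_TARGET_HU,
    center_y0: float = 0.0,
) -> TargetSpec:
    """One of the three thorax-phantom inserts: small / medium / large.

    The returned target's ``ct_level`` is the water-equivalent level above
    the lung-equivalent background (``target_hu - background``; 700 HU with
    the defaults).
    """
    try:
        preset = PHANTOM_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown phantom preset {name!r}; choose from {sorted(PHANTOM_PRESETS)}"
        ) from None
    return TargetSpec(
        length_y=preset["length_y"],
        ct_level=target_hu - background,
        center_y0=center_y0,
        lateral_dims=preset["lateral"],
        label=name,
    )


@dataclass(frozen=True)
class NoiseSpec:
    """Noise/artifact recipe for a pseudo-measured profile.

    gaussian_sd:
        Per-window i.i.d. Gaussian noise standard deviation (HU).
    n_spikes / spike_amplitude / spike_sign:
        Single-window impulses emulating streaking artifacts; positions are
        drawn without replacement.
    baseline_offset:
        Constant HU shift, emulating the inter-mode (half-fan vs full-fan)
        level offset of the same object.
    seed:
        Seeds every random draw; equal seeds give bit-identical output.
    """

    gaussian_sd: float = 0.0
    n_spikes: int = 0
    spike_amplitude: float = 0.0
    spike_sign: str = "both"
    baseline_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ConfigurationError("gaussian_sd must be >= 0")
        if self.n_spikes < 0:
            raise ConfigurationError("n_spikes must be >= 0")
        if self.spike_sign not in ("positive", "negative", "both"):
            raise ConfigurationError("spike_sign must be 'positive', 'negative' or 'both'")


def generate_measured_profile(model: CTProfile, noise: NoiseSpec) -> CTProfile:
    """Model profile + baseline offset + Gaussian noise + streak spikes.

    Deterministic given ``noise.seed``.  Spikes land on distinct windows.
    """
    rng = np.random.default_rng(noise.seed)
    values = model.values + noise.baseline_offset
    if noise.gaussian_sd > 0:
        values = values + rng.normal(0.0, noise.gaussian_sd, size=values.size)
    if noise.n_spikes > 0:
        if noise.n_spikes > values.size:
            raise ConfigurationError("n_spikes exceeds the number of windows")
        where = rng.choice(values.size, size=noise.n_spikes, replace=False)
        if noise.spike_sign == "positive":
            signs = np.ones(noise.n_spikes)
        elif noise.spike_sign == "negative":
            signs = -np.ones(noise.n_spikes)
        else:
            signs = rng.choice([-1.0, 1.0], size=noise.n_spikes)
        values = values.copy()
        values[where] += signs * noise.spike_amplitude
    meta = dict(model.metadata)
    meta.update(
        kind="measured_synthetic",
        noise={
            "gaussian_sd": noise.gaussian_sd,
            "n_spikes": noise.n_spikes,
            "spike_amplitude": noise.spike_amplitude,
            "spike_sign": noise.spike_sign,
            "baseline_offset": noise.baseline_offset,
            "seed": noise.seed,
        },
    )
    return CTProfile(model.grid, values, meta)
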