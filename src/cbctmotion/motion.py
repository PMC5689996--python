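"""One-dimensional motion trajectories.

Three trajectory families cover the experiments the model targets: sinusoidal
cyclic motion (respiratory surrogate), unidirectional constant speed, and a
sampled trajectory interpolated piecewise-linearly (for irregular waveforms
supplied as data).  All displacements are in mm relative to the stationary
position, evaluated at scan time ``t`` in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, TrajectoryRangeError


class MotionModel:
    """Base class: a displacement d(t) evaluable at any scan time."""

    kind: str = "abstract"

    def displacement(self, t):
        """Displacement in mm at time(s) ``t`` (seconds); vectorized."""
        raise NotImplementedError

    def bounds(self, duration: float) -> tuple[float, float]:
        """(min, max) displacement over ``[0, duration]``.

        The default implementation samples densely; analytic subclasses
        override it.
        """
        ts = np.linspace(0.0, duration, 10001)
        d = self.displacement(ts)
        return float(np.min(d)), float(np.max(d))


@dataclass(frozen=True)
class SinusoidalMotion(MotionModel):
    """d(t) = A sin(2 pi f t + phi): cyclic motion of amplitude A (mm),
    frequency f (Hz) and phase phi (rad).  Range of motion (ROM) = 2 A."""

    amplitude: float
    frequency: float
    phase: float = 0.0
    kind = "sinusoidal"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be >= 0")
        if self.frequency < 0:
            raise ConfigurationError("frequency must be >= 0")

    @classmethod
    def from_cycles_per_min(cls, amplitude: float, cycles_per_min: float,
                            phase: float = 0.0) -> "SinusoidalMotion":
        return cls(amplitude=amplitude, frequency=cycles_per_min / 60.0, phase=phase)

    def displacement(self, t):
        t = np.asarray(t, dtype=float)
        out = self.amplitude * np.sin(2.0 * np.pi * self.frequency * t + self.phase)
        return out if out.ndim else float(out)

    def bounds(self, duration: float) -> tuple[float, float]:
        # exact when at least a quarter cycle fits; otherwise fall back
        if self.frequency > 0 and duration * self.frequency >= 1.0:
            return -self.amplitude, self.amplitude
        return super().bounds(duration)

    def cycles(self, duration: float) -> float:
        return self.frequency * duration


@dataclass(frozen=True)
class ConstantSpeedMotion(MotionModel):
    """d(t) = VP t: unidirectional motion at speed VP (mm/s)."""

    speed: float
    kind = "constant_speed"

    def displacement(self, t):
        t = np.asarray(t, dtype=float)
        out = self.speed * t
        return out if out.ndim else float(out)

    def bounds(self, duration: float) -> tuple[float, float]:
        d_end = self.speed * duration
        return (min(0.0, d_end), max(0.0, d_end))


@dataclass(frozen=True)
class SampledMotion(MotionModel):
    """Trajectory given as (time, displacement) samples, interpolated
    piecewise-linearly.  Queries outside the sampled time support raise."""

    times: tuple[float, ...]
    displacements: tuple[float, ...]
    kind = "sampled"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.displacements, dtype=float)
        if t.size < 2 or t.size != d.size:
            raise ConfigurationError("sampled trajectory needs >= 2 (time, displacement) pairs")
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError("sampled trajectory times must be strictly increasing")

    @classmethod
    def from_pairs(cls, pairs) -> "SampledMotion":
        t, d = zip(*pairs)
        return cls(times=tuple(float(x) for x in t),
                   displacements=tuple(float(x) for x in d))

    def displacement(self, t):
        t_arr = np.asarray(t, dtype=float)
        lo, hi = self.times[0], self.times[-1]
        if np.any(t_arr < lo) or np.any(t_arr > hi):
            raise TrajectoryRangeError(
                f"time(s) outside sampled trajectory support [{lo}, {hi}] s"
            )
        out = np.interp(t_arr, self.times, self.displacements)
        return out if out.ndim else float(out)

    def bounds(self, duration: float) -> tuple[float, float]:
        if duration > self.times[-1]:
            raise TrajectoryRangeError(
                f"scan duration {duration} s exceeds trajectory support "
                f"[{self.times[0]}, {self.times[-1]}] s"
            )
        return super().bounds(duration)


#: No-motion sentinel used for stationary acquisitions.
STATIONARY = ConstantSpeedMotion(speed=0.0)


def displacement(motion: MotionModel, t):
    """Displacement of ``motion`` at time(s) ``t`` in seconds (mm)."""
    return motion.displacement(t)
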