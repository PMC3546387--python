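"""Time-varying covariate paths z(t).

Four path types cover the treatments the simulator supports:

* ``TimeInvariantTrajectory`` -- z(t) = z constant (degenerate case; makes the
  reduction to the time-invariant generator explicit).
* ``SingleSwitchTrajectory`` -- binary exposure switching once from 0 to 1 at
  t0 (e.g. organ transplant).  t0 = 0 means treated from baseline.
* ``PiecewiseBinaryTrajectory`` -- binary exposure alternating 0 -> 1 -> 0 ...
  at a strictly increasing list of switch times; all subjects start untreated
  (e.g. on/off medication compliance).  Any number of switches is allowed.
* ``LinearDoseTrajectory`` -- continuous cumulative dose z(t) = k*t at a
  constant dose rate k (e.g. fixed daily exposure).

Switches are left-closed: the switch instant belongs to the post-switch state,
z(t) = new value for t >= switch time.  This keeps the subject-specific
cumulative hazard continuous and its piecewise inverse well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

__all__ = [
    "Trajectory",
    "TimeInvariantTrajectory",
    "SingleSwitchTrajectory",
    "PiecewiseBinaryTrajectory",
    "LinearDoseTrajectory",
    "UnsupportedTrajectoryError",
]


class UnsupportedTrajectoryError(TypeError):
    """Raised when an operation needs a piecewise-constant path but got a continuous one."""


@dataclass(frozen=True)
class TimeInvariantTrajectory:
    """z(t) = z for all t."""

    z: float = 0.0

    piecewise_constant = True

    def value_at(self, t: float) -> float:
        if t < 0:
            raise ValueError(f"t >= 0 required, got {t}")
        return self.z

    def segments(self) -> list[tuple[float, float]]:
        """[(segment start, z on segment), ...]; the last segment is unbounded."""
        return [(0.0, self.z)]

    def exposure_intervals(self, horizon: float) -> list[tuple[float, float, float]]:
        return _intervals_from_segments(self.segments(), horizon)


@dataclass(frozen=True)
class SingleSwitchTrajectory:
    """Binary exposure: z = 0 before t0, z = 1 from t0 on (left-closed)."""

    t0: float

    piecewise_constant = True

    def __post_init__(self) -> None:
        if not self.t0 >= 0:
            raise ValueError(f"switch time t0 >= 0 required, got {self.t0}")

    def value_at(self, t: float) -> float:
        if t < 0:
            raise ValueError(f"t >= 0 required, got {t}")
        return 1.0 if t >= self.t0 else 0.0

    def segments(self) -> list[tuple[float, float]]:
        if self.t0 == 0:
            return [(0.0, 1.0)]
        return [(0.0, 0.0), (self.t0, 1.0)]

    def exposure_intervals(self, horizon: float) -> list[tuple[float, float, float]]:
        return _intervals_from_segments(self.segments(), horizon)


@dataclass(frozen=True)
class PiecewiseBinaryTrajectory:
    """Binary exposure alternating at each switch time; untreated at t = 0."""

    switch_times: tuple[float, ...]

    piecewise_constant = True

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.switch_times)
        object.__setattr__(self, "switch_times", times)
        if len(times) < 1:
            raise ValueError("at least one switch time required")
        if times[0] <= 0:
            raise ValueError(f"switch times must be > 0, got {times[0]}")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"switch times must be strictly increasing, got {times}")

    def value_at(self, t: float) -> float:
        if t < 0:
            raise ValueError(f"t >= 0 required, got {t}")
        n_past = sum(1 for s in self.switch_times if t >= s)
        return float(n_past % 2)

    def segments(self) -> list[tuple[float, float]]:
        segs = [(0.0, 0.0)]
        for i, s in enumerate(self.switch_times):
            segs.append((s, float((i + 1) % 2)))
        return segs

    def exposure_intervals(self, horizon: float) -> list[tuple[float, float, float]]:
        return _intervals_from_segments(self.segments(), horizon)


@dataclass(frozen=True)
class LinearDoseTrajectory:
    """Cumulative dose at constant rate: z(t) = k*t, k > 0."""

    k: float

    piecewise_constant = False

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"dose rate k > 0 required, got {self.k}")

    def value_at(self, t: float) -> float:
        if t < 0:
            raise ValueError(f"t >= 0 required, got {t}")
        return self.k * t

    def exposure_intervals(self, horizon: float) -> list[tuple[float, float, float]]:
        raise UnsupportedTrajectoryError(
            "a continuous linear-dose path has no finite piecewise-constant "
            "decomposition; discretize it on an explicit grid instead"
        )


Trajectory = Union[
    TimeInvariantTrajectory,
    SingleSwitchTrajectory,
    PiecewiseBinaryTrajectory,
    LinearDoseTrajectory,
]


def _intervals_from_segments(
    segments: list[tuple[float, float]], horizon: float
) -> list[tuple[float, float, float]]:
    """Clip [(start, z), ...] segments to half-open intervals partitioning [0, horizon)."""
    if not horizon > 0:
        raise ValueError(f"horizon > 0 required, got {horizon}")
    out: list[tuple[float, float, float]] = []
    for i, (start, z) in enumerate(segments):
        if start >= horizon:
            break
        stop = segments[i + 1][0] if i + 1 < len(segments) else horizon
        stop = min(stop, horizon)
        if stop > start:
            out.append((start, stop, z))
    return out
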