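"""Piecewise frame schedules for time-varying scalar parameters.

Used for the edge-swap budget per frame and for the cue sharpness exponent
n(t).  A schedule is given either as a constant, or as a list of
``(frame, value)`` breakpoints interpreted stepwise (value holds from its
frame until the next breakpoint) or with linear interpolation ("ramp").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Schedule"]


@dataclass(frozen=True)
class Schedule:
    frames: tuple  # increasing breakpoint frames
    values: tuple
    mode: str = "step"  # "step" or "linear"

    def __post_init__(self):
        if len(self.frames) != len(self.values) or not self.frames:
            raise ValueError("schedule needs matching, non-empty frames/values")
        if list(self.frames) != sorted(self.frames):
            raise ValueError("schedule frames must be increasing")
        if self.mode not in ("step", "linear"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")

    @classmethod
    def constant(cls, value: float) -> "Schedule":
        return cls((0,), (float(value),))

    @classmethod
    def from_spec(cls, spec) -> "Schedule":
        """Accept a number, a Schedule, or a mapping
        ``{"mode": ..., "points": [[frame, value], ...]}``."""
        if isinstance(spec, Schedule):
            return spec
        if isinstance(spec, (int, float)):
            return cls.constant(spec)
        if isinstance(spec, dict):
            pts = spec["points"]
            return cls(
                tuple(int(f) for f, _ in pts),
                tuple(float(v) for _, v in pts),
                spec.get("mode", "step"),
            )
        raise ValueError(f"cannot build schedule from {spec!r}")

    def to_spec(self):
        if len(self.frames) == 1:
            return self.values[0]
        return {"mode": self.mode, "points": [[f, v] for f, v in zip(self.frames, self.values)]}

    def __call__(self, frame: int) -> float:
        f = np.asarray(self.frames)
        v = np.asarray(self.values)
        if frame <= f[0]:
            return float(v[0])
        if frame >= f[-1]:
            return float(v[-1])
        if self.mode == "step":
            return float(v[np.searchsorted(f, frame, side="right") - 1])
        return float(np.interp(frame, f, v))
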