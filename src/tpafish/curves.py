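"""In-memory container for a double-compression force-time trace."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .protocol import ProbeProtocol


class CurveValidationError(ValueError):
    """A trace violates the structural requirements of a TPA curve."""


@dataclass
class ForceTimeCurve:
    """One two-cycle compression trace.

    Attributes
    ----------
    time_s:
        Sample times, strictly increasing, seconds.
    force_n:
        Probe force, newtons (positive in compression; the adhesion
        region on withdrawal is negative).
    distance_mm:
        Probe travel from the start of the approach, mm, increasing
        toward the base plate.  Zero is the approach start position,
        not sample contact: contact is located by the force trigger.
    protocol:
        Acquisition settings used for the test.
    meta:
        Free-form metadata (fish id, treatment, fillet side, point
        index 1-8, ...).
    """

    time_s: np.ndarray
    force_n: np.ndarray
    distance_mm: np.ndarray
    protocol: ProbeProtocol = field(default_factory=ProbeProtocol)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)

    def __len__(self) -> int:
        return self.time_s.size

    def validate(self) -> "ForceTimeCurve":
        """Check structural invariants; raise :class:`CurveValidationError`.

        Returns the curve itself so calls can be chained.
        """
        n = self.time_s.size
        if not (self.force_n.size == n and self.distance_mm.size == n):
            raise CurveValidationError("time, force and distance differ in length")
        if n < 100:
            raise CurveValidationError(f"trace too short: {n} samples (need >= 100)")
        for name, arr in (("time", self.time_s), ("force", self.force_n),
                          ("distance", self.distance_mm)):
            if not np.all(np.isfinite(arr)):
                idx = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise CurveValidationError(f"non-finite {name} at row {idx}")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            idx = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise CurveValidationError(f"time not strictly increasing at row {idx}")
        return self
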