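"""Anchor detection, work integration and TPA attribute computation.

A texture-profile-analysis trace carries two compression cycles.  Eight
anchor points structure the trace:

========  =====================================================
anchor    meaning
========  =====================================================
a1        cycle-1 contact: upward trigger-force crossing
a2        cycle-1 peak force
a3        first return of force to <= 0 after the cycle-1 peak
a4, a5    bounds of the negative adhesion region on withdrawal
a6        cycle-2 contact (trigger crossing)
a7        cycle-2 peak force
a8        end of trace
========  =====================================================

From the anchors come four work areas (trapezoidal integration of force
over time, N*s) and two probe-travel distances (mm), and from those the
twelve attributes:

* hardness-1 / hardness-2 — peak force of each compression (N)
* hardness-1b — work under the first compression limb, Area 1 (N*s)
* cohesiveness — Area 4 / Area 1
* resilience — 100 * Area 2 / Area 1 (%)
* springiness — 100 * Distance 2 / Distance 1 (%)
* adhesiveness — Area 3 (negative work, N*s)
* chewiness-1 / -1b / -2 — hardness variant * cohesiveness * springiness/100
* thickness-1 / thickness-2 — 2 * Distance 1 / 2 * Distance 2 (mm)

Thickness follows from the 50% strain geometry: the probe travels half
the local sample height, so twice the travel is the height itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Any, Iterator

import numpy as np
from scipy.ndimage import median_filter

from .curves import ForceTimeCurve
from .protocol import ProbeProtocol

logger = logging.getLogger(__name__)

#: canonical attribute order used in tables and files
ATTRIBUTE_NAMES: tuple[str, ...] = (
    "adhesiveness", "chewiness_1", "chewiness_1b", "chewiness_2",
    "cohesiveness", "hardness_1", "hardness_1b", "hardness_2",
    "resilience", "springiness", "thickness_1", "thickness_2",
)


class AnchorError(ValueError):
    """Anchor detection failed or produced an inconsistent set."""


@dataclass(frozen=True)
class AnchorSet:
    """Interpolated anchor times (s) for one two-cycle trace."""

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    a6: float
    a7: float
    a8: float

    def __post_init__(self) -> None:
        seq = [self.a1, self.a2, self.a3, self.a4, self.a5, self.a6, self.a7, self.a8]
        strict = [(0, 1), (4, 5), (5, 6)]  # a1<a2, a5<a6, a6<a7
        for i in range(7):
            lo, hi = seq[i], seq[i + 1]
            if (i, i + 1) in strict:
                ok = lo < hi
            else:
                ok = lo <= hi
            if not ok:
                raise AnchorError(
                    f"anchors out of order: a{i+1}={lo:.4f} !< a{i+2}={hi:.4f}")

    def __iter__(self) -> Iterator[float]:
        return iter((self.a1, self.a2, self.a3, self.a4,
                     self.a5, self.a6, self.a7, self.a8))


@dataclass(frozen=True)
class CurveMeasures:
    """Areas (N*s) and distances (mm) between anchors."""

    area1: float      # cycle-1 compression work, a1 -> a2
    area2: float      # cycle-1 decompression (positive limb) work, a2 -> a3
    area3: float      # adhesion work, a4 -> a5, <= 0
    area4: float      # cycle-2 compression work, a6 -> a7
    distance1: float  # probe travel a1 -> a2
    distance2: float  # probe travel a6 -> a7
    hardness1: float  # peak force at a2, N
    hardness2: float  # peak force at a7, N

    def __post_init__(self) -> None:
        if self.area1 <= 0 or self.area4 <= 0:
            raise ValueError("compression areas must be positive")
        if self.area2 < 0:
            raise ValueError("decompression area must be non-negative")
        if self.area3 > 0:
            raise ValueError("adhesion area must be non-positive")
        if self.distance1 <= 0 or self.distance2 <= 0:
            raise ValueError("distances must be positive")
        if self.distance2 > self.distance1:
            logger.warning("distance2 (%.3f) exceeds distance1 (%.3f)",
                           self.distance2, self.distance1)


@dataclass(frozen=True)
class TPAProfile:
    """The twelve TPA attributes for one test point (or one fish mean)."""

    adhesiveness: float
    chewiness_1: float
    chewiness_1b: float
    chewiness_2: float
    cohesiveness: float
    hardness_1: float
    hardness_1b: float
    hardness_2: float
    resilience: float
    springiness: float
    thickness_1: float
    thickness_2: float

    def __post_init__(self) -> None:
        if self.cohesiveness > 1.5 or self.cohesiveness < 0:
            logger.warning("cohesiveness %.3f outside [0, 1.5]", self.cohesiveness)
        if not (self.thickness_1 >= self.thickness_2 > 0):
            logger.warning("thickness ordering violated: t1=%.3f t2=%.3f",
                           self.thickness_1, self.thickness_2)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __getitem__(self, key: str) -> float:
        return getattr(self, key)


# ---------------------------------------------------------------------------
# anchor detection


def _interp_crossing(t: np.ndarray, f: np.ndarray, i: int, level: float) -> float:
    """Time of the crossing of ``level`` between samples i-1 and i."""
    if i == 0 or f[i] == f[i - 1]:
        return float(t[i])
    frac = (level - f[i - 1]) / (f[i] - f[i - 1])
    frac = min(max(frac, 0.0), 1.0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _above_runs(above: np.ndarray, debounce: int) -> list[tuple[int, int]]:
    """Contiguous True runs of at least ``debounce`` samples, as [start, stop)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    runs = [(int(s), int(e)) for s, e in zip(idx[::2], idx[1::2])]
    return [(s, e) for s, e in runs if e - s >= debounce]


def detect_anchors(curve: ForceTimeCurve,
                   protocol: ProbeProtocol | None = None) -> AnchorSet:
    """Locate the eight anchor points of a two-cycle trace.

    Anchor *location* uses a 5-sample median-filtered force so isolated
    noise spikes cannot spawn spurious cycles; the reported crossing
    times are interpolated on the raw force between bracketing samples.

    Raises
    ------
    AnchorError
        ``"no contact detected"`` when the force never crosses the
        trigger threshold; ``"second compression missing"`` when only
        one compression cycle is present.
    """
    curve.validate()
    proto = protocol or curve.protocol
    t, f = curve.time_s, curve.force_n
    trigger = proto.trigger_force_n

    smooth = median_filter(f, size=5, mode="nearest")
    runs = _above_runs(smooth > trigger, debounce=3)
    # a compression cycle must rise well clear of the trigger level
    runs = [r for r in runs if smooth[r[0]:r[1]].max() > 10 * trigger]
    if not runs:
        raise AnchorError("no contact detected")
    if len(runs) == 1:
        raise AnchorError("second compression missing")
    if len(runs) > 2:
        # keep the two tallest runs, in time order
        runs = sorted(sorted(runs, key=lambda r: -smooth[r[0]:r[1]].max())[:2])
    (s1, e1), (s2, e2) = runs

    # contact anchors, interpolated on raw force
    a1 = _interp_crossing(t, f, s1, trigger)
    a6 = _interp_crossing(t, f, s2, trigger)

    # peak anchors (earliest index on ties)
    i2 = s1 + int(np.argmax(f[s1:e1]))
    i7 = s2 + int(np.argmax(f[s2:e2]))
    a2, a7 = float(t[i2]), float(t[i7])

    # a3: first return of raw force to <= 0 after the cycle-1 peak
    seg = np.flatnonzero(f[i2:s2] <= 0.0)
    if seg.size:
        i3 = i2 + int(seg[0])
        a3 = _interp_crossing(t, f, i3, 0.0)
    else:
        # force never reaches zero before cycle 2 (strong baseline offset);
        # fall back to the end of the above-trigger run
        i3 = e1
        a3 = float(t[min(i3, t.size - 1)])
    a4 = a3

    # adhesion region: a dip below -trigger between a4 and cycle-2 contact
    window = smooth[i3:s2]
    dip = np.flatnonzero(window < -trigger)
    if dip.size:
        i_min = i3 + int(dip[0] + np.argmin(window[dip[0]:]))
        after = np.flatnonzero(f[i_min:s2] >= 0.0)
        if after.size:
            i5 = i_min + int(after[0])
            a5 = _interp_crossing(t, f, i5, 0.0)
        else:
            a5 = float(t[s2 - 1])
    else:
        a5 = a4  # degenerate: no adhesion

    a8 = float(t[-1])
    return AnchorSet(a1, a2, a3, a4, a5, a6, a7, a8)


# ---------------------------------------------------------------------------
# integration


def _trapz_between(t: np.ndarray, y: np.ndarray, ta: float, tb: float) -> float:
    """Trapezoidal integral of y(t) over [ta, tb] with interpolated endpoints."""
    if tb <= ta:
        return 0.0
    inside = (t > ta) & (t < tb)
    tt = np.concatenate(([ta], t[inside], [tb]))
    yy = np.concatenate(([np.interp(ta, t, y)], y[inside], [np.interp(tb, t, y)]))
    return float(np.trapezoid(yy, tt))


def integrate_measures(curve: ForceTimeCurve, anchors: AnchorSet) -> CurveMeasures:
    """Integrate areas between anchor times and read off travel distances.

    Areas are trapezoidal integrals of the *raw* force over time (N*s);
    at the constant 1 mm/s test speed these equal work over distance
    numerically.  Distances come from the displacement channel
    interpolated at the anchor times.
    """
    t, f, d = curve.time_s, curve.force_n, curve.distance_mm
    area1 = _trapz_between(t, f, anchors.a1, anchors.a2)
    area2 = _trapz_between(t, f, anchors.a2, anchors.a3)
    area3 = _trapz_between(t, f, anchors.a4, anchors.a5)
    area4 = _trapz_between(t, f, anchors.a6, anchors.a7)
    area3 = min(area3, 0.0)

    dist = lambda ta, tb: float(np.interp(tb, t, d) - np.interp(ta, t, d))
    return CurveMeasures(
        area1=area1, area2=max(area2, 0.0), area3=area3, area4=area4,
        distance1=dist(anchors.a1, anchors.a2),
        distance2=dist(anchors.a6, anchors.a7),
        hardness1=float(np.interp(anchors.a2, t, f)),
        hardness2=float(np.interp(anchors.a7, t, f)),
    )


# ---------------------------------------------------------------------------
# attributes


def compute_attributes(measures: CurveMeasures) -> TPAProfile:
    """Apply the attribute formulas to one set of curve measures.

    Springiness and resilience are reported in percent; the chewiness
    products use springiness as a fraction so chewiness stays on the
    hardness scale.
    """
    m = measures
    if m.area1 == 0:
        raise ZeroDivisionError("Area 1 is zero: no first-compression work "
                                "(check trigger detection)")
    cohesiveness = m.area4 / m.area1
    springiness = 100.0 * m.distance2 / m.distance1
    resilience = 100.0 * m.area2 / m.area1
    spring_frac = springiness / 100.0
    return TPAProfile(
        adhesiveness=m.area3,
        chewiness_1=m.hardness1 * cohesiveness * spring_frac,
        chewiness_1b=m.area1 * cohesiveness * spring_frac,
        chewiness_2=m.hardness2 * cohesiveness * spring_frac,
        cohesiveness=cohesiveness,
        hardness_1=m.hardness1,
        hardness_1b=m.area1,
        hardness_2=m.hardness2,
        resilience=resilience,
        springiness=springiness,
        thickness_1=2.0 * m.distance1,
        thickness_2=2.0 * m.distance2,
    )


def extract_profile(curve: ForceTimeCurve,
                    protocol: ProbeProtocol | None = None,
                    ) -> tuple[TPAProfile, AnchorSet, CurveMeasures]:
    """Full pipeline for one trace: anchors -> measures -> attributes."""
    anchors = detect_anchors(curve, protocol)
    measures = integrate_measures(curve, anchors)
    return compute_attributes(measures), anchors, measures


def extract_many(curves: "list[ForceTimeCurve]") -> "tuple[list[dict[str, Any]], int]":
    """Extract attributes from many curves, tolerating per-curve failures.

    Returns (rows, n_failed); each row is curve.meta plus the twelve
    attributes.  Failures are logged and skipped so a batch run
    continues.
    """
    rows: list[dict[str, Any]] = []
    failed = 0
    for curve in curves:
        try:
            profile, _, _ = extract_profile(curve)
        except (AnchorError, ValueError, ZeroDivisionError) as exc:
            failed += 1
            logger.error("extraction failed for %s: %s", curve.meta, exc)
            continue
        rows.append({**curve.meta, **profile.as_dict()})
    return rows, failed
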