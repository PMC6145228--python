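"""Synthetic double-compression curves and whole cohorts.

No raw traces from instrumented fillet tests are publicly available, so
this module generates them.  The generator is calibrated at the
*attribute* level: its defaults are chosen so that extracted TPA
attributes land on the published cohort summary (``tpafish.reference``)
for the two processing treatments, not to reproduce any particular
constitutive law of cooked muscle.

Force model
-----------
During a compression limb the force at normalized depth ``x = d/d_max``
is::

    F(x) = S * (x**m + c*x) / (1 + c)

where ``S`` is the peak force (hardness), ``m`` a steepness exponent
and ``c`` a small linear "toe" weight.  The toe makes the 5 g trigger
fire within a few hundredths of a millimetre of contact, as a real
load cell does; without it a steep power law would bury contact deep in
the stroke.  The exponent default (``m = 12``) makes the ratio of
compression work to peak force match the published cohorts (work ~
0.75 N*s per N of peak at ~7.5 mm of travel).

Geometry
--------
The first compression travels ``d1 = strain * thickness`` from contact.
The second compression returns to the same absolute probe position, but
contacts the sample at its partially recovered height, giving a second
travel ``d2 = recovery_fraction * d1``.  Springiness is therefore
``recovery_fraction`` (up to the tiny trigger offset) and
``thickness_2 = springiness/100 * thickness_1`` exactly.

Withdrawal force decays to zero over ``decompression_fraction * d1`` of
upward travel (so resilience equals that fraction), followed by an
optional half-sine adhesion dip of amplitude ``adhesion_force_n`` and
duration ``adhesion_duration_s`` whose area is the adhesiveness.

Every quantity above has a closed form, so :func:`simulate_curve`
returns the exact ground-truth attribute profile alongside the sampled
trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import reference
from .curves import ForceTimeCurve
from .extract import ATTRIBUTE_NAMES, CurveMeasures, TPAProfile, compute_attributes
from .protocol import ProbeProtocol

logger = logging.getLogger(__name__)

SENSORY_NAMES: tuple[str, ...] = (
    "cohesiveness_of_mass", "fibrous", "firmness", "flaky",
    "moisture_release", "moisture_retention", "springiness",
)

#: ceiling of the descriptive-panel intensity scale
SENSORY_SCALE_MAX = 15.0

_STANDOFF_MM = 2.0  # probe start height above the sample surface


# ---------------------------------------------------------------------------
# force-law helpers (normalized depth x in [0, 1])


def _load(x, m: float, c: float):
    """Normalized loading force at normalized depth x."""
    x = np.clip(x, 0.0, None)
    return (x ** m + c * x) / (1.0 + c)


def _load_integral(x: float, m: float, c: float) -> float:
    """Integral of :func:`_load` from 0 to x (closed form)."""
    return (x ** (m + 1.0) / (m + 1.0) + c * x * x / 2.0) / (1.0 + c)


def mean_load(m: float, c: float) -> float:
    """Mean normalized force over a full limb: work / (peak * travel)."""
    return _load_integral(1.0, m, c)


def shape_for_mean_load(g: float, c: float) -> float:
    """Invert :func:`mean_load` for the exponent m.

    Raises ``ValueError`` when no exponent >= 1 can produce the
    requested mean load ``g`` (feasible range is
    ``(c/2/(1+c), (0.5 + c/2)/(1+c)]``).
    """
    lo = c / 2.0 / (1.0 + c)   # limit of an infinitely steep law
    hi = mean_load(1.0, c)     # linear law
    if not (lo < g <= hi):
        raise ValueError(
            f"mean load {g:.4f} outside feasible range ({lo:.4f}, {hi:.4f}]")
    return 1.0 / (g * (1.0 + c) - c / 2.0) - 1.0


def _trigger_depth(m: float, c: float, ratio: float) -> float:
    """Normalized depth where the load first equals ``ratio`` of peak."""
    if ratio >= 1.0:
        raise ValueError("trigger force is not below the peak force")
    return float(brentq(lambda x: _load(x, m, c) - ratio, 0.0, 1.0))


# ---------------------------------------------------------------------------
# fillet parameters


@dataclass(frozen=True)
class FilletParams:
    """Local mechanical parameters of one fillet test point.

    ``stiffness_scale`` is the first-compression peak force (N);
    ``recovery_fraction`` the recovered fraction of the compressed
    depth (equals springiness/100); ``decompression_fraction`` the
    fraction of the compression travel over which withdrawal force
    decays (equals resilience/100); ``second_peak_fraction`` the ratio
    of second to first peak force; ``stiffness_shape2`` the exponent of
    the second compression (steeper exponent -> lower cohesiveness).
    """

    thickness_mm: float = 15.0
    stiffness_scale: float = 200.0
    stiffness_shape: float = 12.0
    toe_fraction: float = 0.05
    recovery_fraction: float = 0.72
    decompression_fraction: float = 0.22
    second_peak_fraction: float = 0.885
    stiffness_shape2: float = 18.0
    adhesion_force_n: float = 0.9
    adhesion_duration_s: float = 2.0
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive")
        if not (0.0 < self.recovery_fraction <= 1.0):
            raise ValueError("recovery_fraction must be in (0, 1]")
        if self.stiffness_shape < 1 or self.stiffness_shape2 < 1:
            raise ValueError("stiffness shapes must be >= 1")
        if self.stiffness_scale <= 0:
            raise ValueError("stiffness_scale must be positive")
        if not (0.0 < self.decompression_fraction < 1.0):
            raise ValueError("decompression_fraction must be in (0, 1)")
        if self.second_peak_fraction <= 0:
            raise ValueError("second_peak_fraction must be positive")
        if self.toe_fraction < 0:
            raise ValueError("toe_fraction must be non-negative")
        if self.adhesion_force_n < 0 or self.adhesion_duration_s <= 0:
            raise ValueError("adhesion dip parameters invalid")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def ground_truth_measures(protocol: ProbeProtocol,
                          fillet: FilletParams) -> CurveMeasures:
    """Closed-form anchor measures for the continuum (noise-free) curve.

    These are exact for the idealized curve; the extractor applied to a
    sampled trace should agree up to discretization.
    """
    p, f = protocol, fillet
    d1 = p.strain * f.thickness_mm
    d2 = f.recovery_fraction * d1
    s1 = f.stiffness_scale
    s2 = f.second_peak_fraction * s1
    m1, m2, c = f.stiffness_shape, f.stiffness_shape2, f.toe_fraction

    x1 = _trigger_depth(m1, c, p.trigger_force_n / s1)
    x2 = _trigger_depth(m2, c, p.trigger_force_n / s2)
    dist1 = d1 * (1.0 - x1)
    dist2 = d2 * (1.0 - x2)
    if dist2 <= 0:
        raise ValueError(
            "recovery_fraction/strain give a nonpositive second-compression "
            "distance")

    area1 = s1 * d1 * (_load_integral(1.0, m1, c) - _load_integral(x1, m1, c)) \
        / p.test_speed
    area2 = s1 * f.decompression_fraction * d1 * _load_integral(1.0, m1, c) \
        / p.posttest_speed
    area3 = -2.0 * f.adhesion_force_n * f.adhesion_duration_s / np.pi
    area4 = s2 * d2 * (_load_integral(1.0, m2, c) - _load_integral(x2, m2, c)) \
        / p.test_speed
    return CurveMeasures(area1=area1, area2=area2, area3=area3, area4=area4,
                         distance1=dist1, distance2=dist2,
                         hardness1=s1, hardness2=s2)


def ground_truth_profile(protocol: ProbeProtocol,
                         fillet: FilletParams) -> TPAProfile:
    """Exact attribute profile implied by the generator parameters."""
    return compute_attributes(ground_truth_measures(protocol, fillet))


def simulate_curve(protocol: ProbeProtocol, fillet: FilletParams,
                   seed: int | np.random.Generator | None = 0,
                   meta: Mapping[str, Any] | None = None,
                   ) -> tuple[ForceTimeCurve, TPAProfile]:
    """Synthesize one sampled two-cycle trace plus its ground truth.

    The trace covers: approach at pretest speed, first compression to
    ``strain`` of the initial height, withdrawal (positive
    decompression limb, then the negative adhesion dip), full retract,
    pause, second compression to the same absolute depth starting at
    the recovered surface, and a final retract.  Gaussian noise of
    ``fillet.noise_sd`` N is added to the force channel only; the
    displacement channel is crosshead-driven and exact.
    """
    p, f = protocol, fillet
    truth = ground_truth_profile(p, f)  # validates geometry up front
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    d1 = p.strain * f.thickness_mm
    d2 = f.recovery_fraction * d1
    s1 = f.stiffness_scale
    s2 = f.second_peak_fraction * s1
    m1, m2, c = f.stiffness_shape, f.stiffness_shape2, f.toe_fraction
    z0 = _STANDOFF_MM
    q1 = f.decompression_fraction

    # segment durations
    t_app = z0 / p.pretest_speed
    t_c1 = d1 / p.test_speed
    t_wd = (z0 + d1) / p.posttest_speed
    t_pause = p.pause_s
    t_c2 = (z0 + d1) / p.test_speed
    t_end = (z0 + d1) / p.posttest_speed
    bounds = np.cumsum([0.0, t_app, t_c1, t_wd, t_pause, t_c2, t_end])

    # sample each motion segment on a grid that lands exactly on its
    # boundaries, so the true peak/zero instants are present in the data
    t_parts = []
    seg_parts = []
    for i in range(6):
        dur = bounds[i + 1] - bounds[i]
        n = max(int(np.ceil(dur * p.sample_rate)), 1)
        t_parts.append(np.linspace(bounds[i], bounds[i + 1], n + 1)[:-1])
        seg_parts.append(np.full(n, i))
    t = np.concatenate(t_parts + [bounds[-1:]])
    seg = np.concatenate(seg_parts + [[5]])
    disp = np.empty_like(t)
    force = np.zeros_like(t)
    tau = t - bounds[seg]  # time within segment

    # displacement (probe travel from approach start, toward the plate)
    disp[seg == 0] = p.pretest_speed * tau[seg == 0]
    disp[seg == 1] = z0 + p.test_speed * tau[seg == 1]
    disp[seg == 2] = (z0 + d1) - p.posttest_speed * tau[seg == 2]
    disp[seg == 3] = 0.0
    disp[seg == 4] = p.test_speed * tau[seg == 4]
    disp[seg == 5] = (z0 + d1) - p.posttest_speed * tau[seg == 5]

    # force
    k = seg == 1  # first compression
    force[k] = s1 * _load((disp[k] - z0) / d1, m1, c)
    k = seg == 2  # withdrawal: decompression limb then adhesion dip
    w = p.posttest_speed * tau[k]
    fw = np.zeros_like(w)
    rel = w < q1 * d1
    fw[rel] = s1 * _load(1.0 - w[rel] / (q1 * d1), m1, c)
    dip_len = f.adhesion_duration_s * p.posttest_speed
    in_dip = ~rel & (w < q1 * d1 + dip_len)
    fw[in_dip] = -f.adhesion_force_n * np.sin(
        np.pi * (w[in_dip] - q1 * d1) / dip_len)
    force[k] = fw
    k = seg == 4  # second compression: contact at the recovered surface
    depth2 = disp[k] - (z0 + d1 - d2)
    force[k] = np.where(depth2 > 0, s2 * _load(depth2 / d2, m2, c), 0.0)
    k = seg == 5  # final retract
    w = p.posttest_speed * tau[k]
    force[k] = np.where(w < q1 * d2,
                        s2 * _load(1.0 - w / np.maximum(q1 * d2, 1e-12), m2, c),
                        0.0)

    if f.noise_sd > 0:
        force = force + rng.normal(0.0, f.noise_sd, size=force.size)

    curve = ForceTimeCurve(time_s=t, force_n=force, distance_mm=disp,
                           protocol=p, meta=dict(meta or {}))
    return curve, truth


# ---------------------------------------------------------------------------
# sensory link


@dataclass(frozen=True)
class SensoryLink:
    """Linear map from TPA attributes to one sensory intensity score."""

    intercept: float
    coefs: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.7

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def sensory_link(tpa: Mapping[str, float], link: SensoryLink,
                 seed: int | np.random.Generator | None = 0) -> float:
    """Score = intercept + sum(coef * attribute) + noise, clipped to [0, 15].

    Raises ``KeyError`` naming any link attribute absent from ``tpa``.
    """
    missing = [k for k in link.coefs if k not in tpa]
    if missing:
        raise KeyError(f"unknown TPA attribute(s) in sensory link: {missing}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    score = link.intercept + sum(co * tpa[k] for k, co in link.coefs.items())
    if link.noise_sd > 0:
        score += rng.normal(0.0, link.noise_sd)
    return float(np.clip(score, 0.0, SENSORY_SCALE_MAX))


# ---------------------------------------------------------------------------
# cohort specification


@dataclass(frozen=True)
class GroupSpec:
    """Target moments (over fish means) for one treatment group.

    ``(mean, sd)`` pairs are the per-fish-mean moments the generated
    cohort should converge to; ``hardness_1b_mean`` and
    ``hardness_2_mean`` calibrate the force-law exponent and the
    second-peak ratio (their SDs are emergent).
    """

    name: str
    n_fish: int
    points_per_fillet: int = 8
    thickness_1: tuple[float, float] = (15.73, 1.53)
    hardness_1: tuple[float, float] = (200.34, 42.19)
    cohesiveness: tuple[float, float] = (0.48, 0.02)
    springiness: tuple[float, float] = (69.77, 2.51)
    resilience: tuple[float, float] = (21.73, 2.84)
    adhesiveness: tuple[float, float] = (-1.13, 0.35)
    hardness_1b_mean: float = 151.22
    hardness_2_mean: float = 178.06
    #: between-fish correlation of peak force with thickness; thicker
    #: fillets read harder, which is what residualization removes
    thickness_hardness_corr: float = 0.5
    sensory_links: Mapping[str, SensoryLink] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_fish < 2:
            raise ValueError("n_fish must be at least 2")
        if self.points_per_fillet < 1:
            raise ValueError("points_per_fillet must be at least 1")
        for nm in ("thickness_1", "hardness_1", "cohesiveness",
                   "springiness", "resilience", "adhesiveness"):
            mean, sd = getattr(self, nm)
            if sd < 0:
                raise ValueError(f"{nm} SD must be non-negative")
        if not (0.0 < self.cohesiveness[0] < 1.0):
            raise ValueError("cohesiveness target mean must be in (0, 1)")
        if not (0.0 < self.springiness[0] <= 100.0):
            raise ValueError("springiness target mean must be in (0, 100]")
        if self.thickness_1[0] <= 0 or self.hardness_1[0] <= 0:
            raise ValueError("thickness/hardness target means must be positive")
        if self.adhesiveness[0] > 0:
            raise ValueError("adhesiveness target mean must be <= 0")
        if not (-1.0 <= self.thickness_hardness_corr <= 1.0):
            raise ValueError("thickness_hardness_corr must be in [-1, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Two (or more) treatment groups plus the master seed."""

    groups: tuple[GroupSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")


def _default_links(group: str) -> dict[str, SensoryLink]:
    """Links calibrated so implied sensory means match the published table."""
    tpa = reference.tpa_summary()
    sens = reference.sensory_summary()
    coefs = {
        "cohesiveness_of_mass": {"cohesiveness": 5.0},
        "fibrous": {"resilience": -0.10},
        "firmness": {"hardness_1": 0.01},
        "flaky": {"hardness_1": -0.0124},
        "moisture_release": {"hardness_2": -0.005},
        "moisture_retention": {"thickness_2": 0.20},
        "springiness": {"springiness": 0.05},
    }
    links = {}
    for name, co in coefs.items():
        target = reference.group_mean(sens, name, group)
        implied = sum(v * reference.group_mean(tpa, k, group)
                      for k, v in co.items())
        links[name] = SensoryLink(intercept=target - implied, coefs=co,
                                  noise_sd=0.7)
    return links


def iqf_group(n_fish: int = 60, **overrides: Any) -> GroupSpec:
    """Group spec calibrated to the published IQF cohort (default n=60)."""
    base = GroupSpec(name="iqf", n_fish=n_fish,
                     sensory_links=_default_links("iqf"))
    return replace(base, **overrides) if overrides else base


def fresh_frozen_group(n_fish: int = 34, **overrides: Any) -> GroupSpec:
    """Group spec calibrated to the published fresh-frozen cohort (n=34)."""
    base = GroupSpec(
        name="fresh_frozen", n_fish=n_fish,
        thickness_1=(14.47, 1.09), hardness_1=(220.51, 34.81),
        cohesiveness=(0.47, 0.03), springiness=(73.84, 2.65),
        resilience=(23.50, 1.79), adhesiveness=(-1.17, 0.28),
        hardness_1b_mean=158.15, hardness_2_mean=194.68,
        sensory_links=_default_links("fresh_frozen"))
    return replace(base, **overrides) if overrides else base


def default_cohort_spec(seed: int = 0, n_iqf: int = 60,
                        n_ff: int = 34) -> CohortSpec:
    """The study-design cohort: 60 IQF + 34 fresh-frozen fish, 8 points."""
    return CohortSpec(groups=(iqf_group(n_iqf), fresh_frozen_group(n_ff)),
                      seed=seed)


# ---------------------------------------------------------------------------
# cohort simulation

#: within-fish point-to-point SDs (fillets taper and tissue is heterogeneous)
_WITHIN_SD = {
    "thickness_1": 0.8,     # mm
    "hardness_1_rel": 0.06,  # relative to the fish mean
    "cohesiveness": 0.015,
    "springiness": 1.5,      # percentage points
    "resilience": 1.5,       # percentage points
    "adhesiveness": 0.15,    # N*s
}


@dataclass
class SimulatedCohort:
    """Generated cohort: per-point TPA rows, per-fish sensory rows."""

    tpa: pd.DataFrame
    sensory: pd.DataFrame
    fish: pd.DataFrame
    curves: list[ForceTimeCurve] | None = None


def _between_sd(target_sd: float, within_sd: float, k: int) -> float:
    """Deflate a fish-mean SD target by the averaged-out within-fish part."""
    return float(np.sqrt(max(target_sd ** 2 - within_sd ** 2 / k, 0.0)))


def _fillet_for_point(protocol: ProbeProtocol, group: GroupSpec,
                      fish_vals: dict[str, float], m1: float, f2: float,
                      rng: np.random.Generator) -> FilletParams:
    """Draw one test point's parameters around the fish-level values."""
    w = _WITHIN_SD
    thick = max(2.0, rng.normal(fish_vals["thickness_1"], w["thickness_1"]))
    s1 = max(5.0, rng.normal(fish_vals["hardness_1"],
                             w["hardness_1_rel"] * fish_vals["hardness_1"]))
    spring = np.clip(rng.normal(fish_vals["springiness"], w["springiness"]),
                     5.0, 99.9)
    resil = np.clip(rng.normal(fish_vals["resilience"], w["resilience"]),
                    1.0, 60.0)
    adh = min(0.0, rng.normal(fish_vals["adhesiveness"], w["adhesiveness"]))
    coh = rng.normal(fish_vals["cohesiveness"], w["cohesiveness"])
    # peak ratio wobbles a little point to point: the two peaks are very
    # highly, but not perfectly, correlated
    f2 = f2 * float(np.clip(rng.normal(1.0, 0.02), 0.7, 1.3))

    c = 0.05
    rf = spring / 100.0
    # invert cohesiveness -> second-compression exponent, clipping the draw
    # into the feasible band for this point's springiness
    g1 = mean_load(m1, c)
    lo = f2 * rf * (c / 2.0 / (1.0 + c)) / g1
    hi = f2 * rf * mean_load(1.0, c) / g1
    coh = float(np.clip(coh, lo * 1.05, hi * 0.95))
    m2 = shape_for_mean_load(coh * g1 / (f2 * rf), c)

    # compensate the trigger offset so *measured* thickness and
    # springiness land on the drawn values, not a hair below them
    x1 = _trigger_depth(m1, c, protocol.trigger_force_n / s1)
    x2 = _trigger_depth(m2, c, protocol.trigger_force_n / (f2 * s1))
    thick_param = thick / (2.0 * protocol.strain * (1.0 - x1))
    rf = min(rf * (1.0 - x1) / (1.0 - x2), 1.0)

    tau = 2.0
    a_force = -adh * np.pi / (2.0 * tau)
    return FilletParams(
        thickness_mm=thick_param, stiffness_scale=s1, stiffness_shape=m1,
        toe_fraction=c, recovery_fraction=rf,
        decompression_fraction=resil / 100.0, second_peak_fraction=f2,
        stiffness_shape2=m2, adhesion_force_n=a_force,
        adhesion_duration_s=tau, noise_sd=0.02)


def simulate_cohort(spec: CohortSpec,
                    protocol: ProbeProtocol | None = None,
                    return_curves: bool = False) -> SimulatedCohort:
    """Generate a full cohort with linked sensory scores.

    Per fish, latent attribute values are drawn around the group
    targets (between-fish SD deflated so the SD *of fish means*
    converges to the target); per point, within-fish jitter is added
    and the TPA profile is computed from the generator's closed-form
    ground truth.  With ``return_curves=True`` sampled traces are also
    synthesized (one per test point) — intended for small cohorts.

    Sensory scores are generated per fish from the fish-mean TPA
    profile through the group's :class:`SensoryLink` map and clipped to
    the 0-15 intensity scale.  Everything derives from ``spec.seed``.
    """
    proto = protocol or ProbeProtocol()
    root = np.random.SeedSequence(spec.seed)
    tpa_rows: list[dict[str, Any]] = []
    sens_rows: list[dict[str, Any]] = []
    fish_rows: list[dict[str, Any]] = []
    curves: list[ForceTimeCurve] = []

    for group, gseq in zip(spec.groups, root.spawn(len(spec.groups))):
        # group-level calibration of the force-law exponent and peak ratio
        c = 0.05
        d1_mean = proto.strain * group.thickness_1[0]
        g_target = group.hardness_1b_mean * proto.test_speed \
            / (group.hardness_1[0] * d1_mean)
        m1 = shape_for_mean_load(g_target, c)
        f2 = group.hardness_2_mean / group.hardness_1[0]

        k = group.points_per_fillet
        w = _WITHIN_SD
        between = {
            "thickness_1": _between_sd(group.thickness_1[1], w["thickness_1"], k),
            "hardness_1": _between_sd(
                group.hardness_1[1],
                w["hardness_1_rel"] * group.hardness_1[0], k),
            "cohesiveness": _between_sd(group.cohesiveness[1],
                                        w["cohesiveness"], k),
            "springiness": _between_sd(group.springiness[1],
                                       w["springiness"], k),
            "resilience": _between_sd(group.resilience[1], w["resilience"], k),
            "adhesiveness": _between_sd(group.adhesiveness[1],
                                        w["adhesiveness"], k),
        }

        for i, fseq in enumerate(gseq.spawn(group.n_fish)):
            rng = np.random.default_rng(fseq)
            fish_id = f"{group.name}_{i + 1:03d}"
            rho = group.thickness_hardness_corr
            z_t, z_h = rng.standard_normal(2)
            z_h = rho * z_t + np.sqrt(1.0 - rho ** 2) * z_h
            fish_vals = {
                "thickness_1": max(2.0, group.thickness_1[0]
                                   + between["thickness_1"] * z_t),
                "hardness_1": max(5.0, group.hardness_1[0]
                                  + between["hardness_1"] * z_h),
                "cohesiveness": float(np.clip(
                    rng.normal(group.cohesiveness[0], between["cohesiveness"]),
                    0.05, 0.95)),
                "springiness": float(np.clip(
                    rng.normal(group.springiness[0], between["springiness"]),
                    5.0, 99.9)),
                "resilience": float(np.clip(
                    rng.normal(group.resilience[0], between["resilience"]),
                    1.0, 60.0)),
                "adhesiveness": min(0.0, rng.normal(group.adhesiveness[0],
                                                    between["adhesiveness"])),
            }
            fish_rows.append({"fish_id": fish_id, "treatment": group.name,
                              **fish_vals})

            point_profiles = []
            for point in range(1, k + 1):
                fillet = _fillet_for_point(proto, group, fish_vals, m1, f2, rng)
                meta = {"fish_id": fish_id, "treatment": group.name,
                        "side": "left", "point": point}
                if return_curves:
                    curve, truth = simulate_curve(proto, fillet, rng, meta)
                    curves.append(curve)
                else:
                    truth = ground_truth_profile(proto, fillet)
                point_profiles.append(truth.as_dict())
                tpa_rows.append({**meta, **point_profiles[-1]})

            fish_mean = {nm: float(np.mean([pp[nm] for pp in point_profiles]))
                         for nm in ATTRIBUTE_NAMES}
            srow: dict[str, Any] = {"fish_id": fish_id,
                                    "treatment": group.name}
            for sname in SENSORY_NAMES:
                link = group.sensory_links.get(sname)
                if link is None:
                    continue
                srow[sname] = sensory_link(fish_mean, link, rng)
            sens_rows.append(srow)

    return SimulatedCohort(
        tpa=pd.DataFrame(tpa_rows),
        sensory=pd.DataFrame(sens_rows),
        fish=pd.DataFrame(fish_rows),
        curves=curves if return_curves else None,
    )
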