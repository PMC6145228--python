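"""Thickness residualization of instrumental and sensory attributes.

Many attributes scale with local fillet thickness, which varies along
the fillet and between fish.  The thickness contribution is removed by
taking the residual from a straight-line regression of the attribute on
thickness-2 (the post-first-compression thickness)::

    residual = value - (slope * thickness_2 + intercept)

Two sources of lines are supported: the fixed published constants
(:func:`builtin_lines`, eight attributes) and cohort-fitted ordinary
least squares lines (:func:`fit_thickness_line`).  Residual hardness-1
has no published line and is only available by fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: attributes with a published residual line, TPA first then sensory
FIXED_LINE_CONSTANTS: dict[str, tuple[float, float]] = {
    "chewiness_1": (8.215, -17.386),
    "chewiness_1b": (9.807, -54.626),
    "cohesiveness": (0.005, 0.421),
    "hardness_1b": (26.845, -138.455),
    "springiness": (1.008, 60.275),
    "cohesiveness_of_mass": (0.147, 4.332),
    "firmness": (0.151, 2.531),
    "flaky": (-0.159, 6.546),
}


@dataclass(frozen=True)
class ResidualLine:
    """attribute = slope * thickness_2 + intercept (+ residual)."""

    attribute: str
    slope: float
    intercept: float
    source: str = "fixed"          # "fixed" or "fitted"
    n: int | None = None           # fit diagnostics when fitted
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("slope and intercept must be finite")


def builtin_lines() -> dict[str, ResidualLine]:
    """The eight published thickness-2 regression lines.

    Five instrumental (chewiness-1, chewiness-1b, cohesiveness,
    hardness-1b, springiness) and three sensory (cohesiveness of mass,
    firmness, flaky).  There is no published line for hardness-1; use
    :func:`fit_thickness_line` for it.
    """
    return {name: ResidualLine(name, slope, intercept, source="fixed")
            for name, (slope, intercept) in FIXED_LINE_CONSTANTS.items()}


def residualize(value, thickness2, line: ResidualLine):
    """Residual of ``value`` about the line at ``thickness2`` (vectorized)."""
    return value - (line.slope * np.asarray(thickness2) + line.intercept)


def fit_thickness_line(values, thickness2, attribute: str = "") -> ResidualLine:
    """OLS fit of an attribute on thickness-2 over (per-fish) observations.

    Requires at least 3 finite pairs and non-constant thickness;
    residuals about the returned line average zero on the fitting
    sample to machine precision.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(thickness2, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if y.size < 3:
        raise ValueError(f"need at least 3 observations to fit, got {y.size}")
    if np.ptp(x) == 0:
        raise ValueError("thickness-2 is constant: singular fit")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 1.0
    return ResidualLine(attribute, float(slope), float(intercept),
                        source="fitted", n=int(y.size), r_squared=r2)


def residualize_table(df: pd.DataFrame, mode: str = "fixed",
                      attributes: "list[str] | None" = None,
                      thickness_col: str = "thickness_2") -> pd.DataFrame:
    """Add ``residual_<attr>`` columns to a (fish-level) table.

    mode="fixed" uses the published lines for whichever of their eight
    attributes are present (all requested ones must be published);
    mode="fit" fits a line per attribute on this table.  Fitting is
    meant for per-fish means; pass per-point data deliberately if that
    granularity is wanted.
    """
    if thickness_col not in df.columns:
        raise KeyError(f"table lacks '{thickness_col}'")
    out = df.copy()
    lines = builtin_lines()
    if attributes is None:
        attributes = [a for a in lines if a in df.columns] if mode == "fixed" \
            else [a for a in df.columns
                  if a not in ("fish_id", "treatment", "side", "point")
                  and pd.api.types.is_numeric_dtype(df[a])
                  and a != thickness_col]
    for attr in attributes:
        if attr not in df.columns:
            raise KeyError(f"attribute '{attr}' not in table")
        if mode == "fixed":
            if attr not in lines:
                raise KeyError(f"no published residual line for '{attr}'")
            line = lines[attr]
        elif mode == "fit":
            if attr == "hardness_1":
                logger.info("residual hardness-1 has no published line; "
                            "using a cohort-fitted line")
            line = fit_thickness_line(df[attr], df[thickness_col], attr)
        else:
            raise ValueError(f"unknown mode '{mode}' (use 'fixed' or 'fit')")
        out[f"residual_{attr}"] = residualize(df[attr], df[thickness_col], line)
    return out
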