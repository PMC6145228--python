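"""Text-format readers and writers for traces and cohort tables.

Canonical curve format: CSV with header ``time_s,force_N,distance_mm``
preceded by ``# key: value`` comment lines carrying metadata and the
acquisition protocol.  Other instrument exports are accommodated by a
:class:`CurveDialect` that names the columns and declares units; units
are normalized on read (seconds / newtons / millimetres).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .curves import CurveValidationError, ForceTimeCurve
from .extract import ATTRIBUTE_NAMES
from .protocol import GRAMS_PER_NEWTON, ProbeProtocol

logger = logging.getLogger(__name__)

_META_KEYS = ("fish_id", "treatment", "side", "point")
_PROTO_FIELDS = [f.name for f in dataclasses.fields(ProbeProtocol)]


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


@dataclass(frozen=True)
class CurveDialect:
    """Column names and units of a curve file."""

    time_col: str = "time_s"
    force_col: str = "force_N"
    distance_col: str = "distance_mm"
    force_unit: str = "N"      # "N" or "g" (grams-force)
    distance_unit: str = "mm"  # "mm" or "cm"
    time_unit: str = "s"       # "s" or "ms"


def _read_comment_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_curve(path: str | Path,
               dialect: CurveDialect | None = None) -> ForceTimeCurve:
    """Read and validate one force-time trace.

    Units are normalized to s/N/mm according to the dialect (grams-force
    divided by 101.97, cm multiplied by 10, ms divided by 1000).
    Raises :class:`FormatError` on missing columns and
    :class:`~tpafish.curves.CurveValidationError` on structural
    problems such as non-monotone time.
    """
    path = Path(path)
    dia = dialect or CurveDialect()
    raw_meta = _read_comment_meta(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in (dia.time_col, dia.force_col, dia.distance_col)
               if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}; "
                          f"found {list(df.columns)}")
    bad = df[[dia.time_col, dia.force_col, dia.distance_col]].isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        raise FormatError(f"{path.name}: malformed/missing value at row {row}")

    time = df[dia.time_col].to_numpy(float)
    force = df[dia.force_col].to_numpy(float)
    dist = df[dia.distance_col].to_numpy(float)
    if dia.time_unit == "ms":
        time = time / 1000.0
    if dia.force_unit == "g":
        force = force / GRAMS_PER_NEWTON
    if dia.distance_unit == "cm":
        dist = dist * 10.0

    proto_kwargs = {k: float(raw_meta[k]) for k in _PROTO_FIELDS
                    if k in raw_meta}
    protocol = ProbeProtocol(**proto_kwargs) if proto_kwargs else ProbeProtocol()
    meta = {k: v for k, v in raw_meta.items() if k not in _PROTO_FIELDS}
    if "point" in meta:
        meta["point"] = int(meta["point"])
    curve = ForceTimeCurve(time_s=time, force_n=force, distance_mm=dist,
                           protocol=protocol, meta=meta)
    try:
        curve.validate()
    except CurveValidationError as exc:
        raise CurveValidationError(f"{path.name}: {exc}") from exc
    return curve


def write_curve(curve: ForceTimeCurve, path: str | Path) -> None:
    """Write a trace in the canonical commented-CSV format."""
    path = Path(path)
    lines = [f"# {k}: {v}" for k, v in curve.meta.items()]
    lines += [f"# {k}: {getattr(curve.protocol, k)}" for k in _PROTO_FIELDS]
    body = pd.DataFrame({"time_s": curve.time_s, "force_N": curve.force_n,
                         "distance_mm": curve.distance_mm})
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        body.to_csv(fh, index=False, float_format="%.10g")


def write_attributes(profiles: "list[dict[str, Any]]",
                     path: str | Path) -> None:
    """Write one row per test point: metadata plus the twelve attributes.

    Each profile is a mapping holding every attribute name (a
    ``TPAProfile.as_dict()`` merged with metadata).  Raises
    ``KeyError`` naming the first missing attribute.  An empty list
    still writes the header, with a warning.
    """
    for i, prof in enumerate(profiles):
        for name in ATTRIBUTE_NAMES:
            if name not in prof:
                raise KeyError(f"profile {i} missing attribute '{name}'")
    if not profiles:
        logger.warning("writing empty attribute table to %s", path)
    meta_cols = [k for k in _META_KEYS
                 if any(k in p for p in profiles)] if profiles else list(_META_KEYS)
    cols = meta_cols + list(ATTRIBUTE_NAMES)
    df = pd.DataFrame(profiles, columns=cols)
    df.to_csv(path, index=False, float_format="%.8g")


def read_attributes(path: str | Path) -> pd.DataFrame:
    """Read an attribute table written by :func:`write_attributes`."""
    df = pd.read_csv(path)
    missing = [c for c in ATTRIBUTE_NAMES if c not in df.columns]
    if missing:
        raise FormatError(f"attribute table missing column(s) {missing}")
    return df


@dataclass
class CohortData:
    """Joined instrumental and sensory tables, keyed by fish."""

    tpa: pd.DataFrame          # per test point, inner-joined fish only
    sensory: pd.DataFrame      # per fish
    tpa_only: list[str]        # fish with TPA rows but no sensory row
    sensory_only: list[str]    # fish with sensory row but no TPA rows

    @property
    def fish_ids(self) -> list[str]:
        return sorted(self.tpa["fish_id"].unique())


def read_cohort(tpa: str | Path | pd.DataFrame,
                sensory: str | Path | pd.DataFrame) -> CohortData:
    """Inner-join the per-point TPA table with the per-fish sensory table.

    Repeated measures are preserved (aggregation happens later); fish
    present in only one table are reported, not silently dropped rows.
    Raises on duplicate (fish, point) keys and on empty overlap.
    """
    tpa_df = pd.read_csv(tpa) if not isinstance(tpa, pd.DataFrame) else tpa.copy()
    sens_df = pd.read_csv(sensory) if not isinstance(sensory, pd.DataFrame) \
        else sensory.copy()
    for name, df, key in (("tpa", tpa_df, "fish_id"),
                          ("sensory", sens_df, "fish_id")):
        if key not in df.columns:
            raise FormatError(f"{name} table lacks a 'fish_id' column")
    if "point" in tpa_df.columns:
        dup = tpa_df.duplicated(subset=["fish_id", "point"])
        if dup.any():
            row = tpa_df[dup.to_numpy()].iloc[0]
            raise FormatError("duplicate (fish, point) key: "
                              f"({row['fish_id']}, {row['point']})")
    if sens_df["fish_id"].duplicated().any():
        raise FormatError("duplicate fish_id in sensory table")

    tpa_ids = set(tpa_df["fish_id"])
    sens_ids = set(sens_df["fish_id"])
    common = tpa_ids & sens_ids
    if not common:
        raise FormatError("no overlapping fish between TPA and sensory tables")
    tpa_only = sorted(tpa_ids - sens_ids)
    sens_only = sorted(sens_ids - tpa_ids)
    if tpa_only or sens_only:
        logger.warning("unmatched fish: %d TPA-only, %d sensory-only",
                       len(tpa_only), len(sens_only))
    return CohortData(
        tpa=tpa_df[tpa_df["fish_id"].isin(common)].reset_index(drop=True),
        sensory=sens_df[sens_df["fish_id"].isin(common)].reset_index(drop=True),
        tpa_only=tpa_only, sensory_only=sens_only)
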