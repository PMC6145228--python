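"""Per-fish aggregation and two-group cohort comparison.

Repeated measures (eight test points per fillet) are averaged per fish
first; the treatment comparison is then a one-way fixed-effects ANOVA
on the fish means.  With one aggregated observation per fish and two
groups this is exactly the pooled-variance two-sample t test
(F = t^2), which is also what a mixed model collapses to once the
within-fish replicates have been averaged out.  Unbalanced data (fish
with missing points, missing attributes) are tolerated throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupComparison:
    """One attribute's two-group summary: moments, F, p."""

    attribute: str
    groups: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    f_stat: float
    p_value: float

    @property
    def significant(self) -> bool:
        """True when p < 0.05."""
        return self.p_value < 0.05


def aggregate_fish(tpa: pd.DataFrame,
                   sensory: pd.DataFrame | None = None) -> pd.DataFrame:
    """Average repeated measures per fish (unweighted arithmetic mean).

    Missing points are simply omitted; a fish with no valid value for
    an attribute gets NaN there.  Fish whose rows are all-NaN across
    every attribute are dropped with a warning.  If a per-fish sensory
    table is given it is merged on fish_id.
    """
    if "fish_id" not in tpa.columns:
        raise KeyError("table lacks 'fish_id'")
    keys = ["fish_id"] + (["treatment"] if "treatment" in tpa.columns else [])
    value_cols = [c for c in tpa.columns
                  if c not in keys + ["side", "point"]
                  and pd.api.types.is_numeric_dtype(tpa[c])]
    agg = tpa.groupby(keys, as_index=False, sort=True)[value_cols].mean()

    empty = agg[value_cols].isna().all(axis=1)
    if empty.any():
        dropped = agg.loc[empty, "fish_id"].tolist()
        logger.warning("dropping fish with no valid measurements: %s", dropped)
        agg = agg[~empty].reset_index(drop=True)

    if sensory is not None:
        sens_cols = [c for c in sensory.columns if c not in ("treatment",)]
        agg = agg.merge(sensory[sens_cols], on="fish_id", how="left",
                        suffixes=("", "_sensory"))
    return agg


def compare_groups(aggregated: pd.DataFrame, attribute: str,
                   group_col: str = "treatment") -> GroupComparison:
    """One-way fixed-effects ANOVA between two groups of fish means.

    For two groups F equals the square of the pooled two-sample t
    statistic; the p value is the upper tail of F(1, n1+n2-2).
    """
    if attribute not in aggregated.columns:
        raise KeyError(f"attribute '{attribute}' not in table")
    names = sorted(aggregated[group_col].dropna().unique())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, found {names}")
    samples = []
    for g in names:
        vals = aggregated.loc[aggregated[group_col] == g, attribute] \
            .dropna().to_numpy(float)
        if vals.size < 2:
            raise ValueError(f"group '{g}' has fewer than 2 fish "
                             f"with '{attribute}'")
        samples.append(vals)
    a, b = samples
    n1, n2 = a.size, b.size
    grand = np.concatenate([a, b]).mean()
    ss_between = n1 * (a.mean() - grand) ** 2 + n2 * (b.mean() - grand) ** 2
    ss_within = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    df_within = n1 + n2 - 2
    if ss_within == 0:
        f_stat = 0.0 if ss_between == 0 else np.inf
    else:
        f_stat = float(ss_between / (ss_within / df_within))
    p = float(sps.f.sf(f_stat, 1, df_within))
    return GroupComparison(
        attribute=attribute, groups=(str(names[0]), str(names[1])),
        n=(n1, n2), means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        f_stat=f_stat, p_value=p)


def summarize_cohort(aggregated: pd.DataFrame,
                     attributes: "list[str] | None" = None,
                     group_col: str = "treatment") -> pd.DataFrame:
    """Group mean/SD and p value per attribute, one row per attribute.

    Attributes whose comparison is impossible (all missing, too few
    fish) are emitted with NaN markers rather than dropped.
    """
    if attributes is None:
        attributes = [c for c in aggregated.columns
                      if c not in ("fish_id", group_col)
                      and pd.api.types.is_numeric_dtype(aggregated[c])]
    names = sorted(aggregated[group_col].dropna().unique())
    rows = []
    for attr in attributes:
        try:
            cmp_ = compare_groups(aggregated, attr, group_col)
            rows.append({"attribute": attr,
                         f"{cmp_.groups[0]}_mean": cmp_.means[0],
                         f"{cmp_.groups[0]}_sd": cmp_.sds[0],
                         f"{cmp_.groups[1]}_mean": cmp_.means[1],
                         f"{cmp_.groups[1]}_sd": cmp_.sds[1],
                         "f_stat": cmp_.f_stat, "p_value": cmp_.p_value})
        except (ValueError, KeyError) as exc:
            logger.warning("summary row for '%s' unavailable: %s", attr, exc)
            rows.append({"attribute": attr,
                         **{f"{g}_{s}": np.nan for g in names
                            for s in ("mean", "sd")},
                         "f_stat": np.nan, "p_value": np.nan})
    return pd.DataFrame(rows)
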