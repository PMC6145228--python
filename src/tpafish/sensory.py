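"""Sensory-prediction equations and forward stepwise regression.

Two routes from instrumental (TPA) attributes to descriptive sensory
intensities are provided:

* :func:`builtin_equations` returns the published per-treatment
  equations verbatim (intercept + linear, squared and cross-product
  terms over TPA attributes and their thickness residuals), evaluated
  without refitting by :func:`predict`.
* :func:`stepwise_fit` re-derives equations of the same family:
  phase 1 is forward selection over main effects with a partial-F
  entry p-value below ``alpha`` (0.05); phase 2 re-runs forward
  selection over the squares and pairwise cross products of the
  phase-1 survivors only.  Fit quality is reported as RMSE (regression
  convention, denominator n-p-1), R^2, adjusted R^2 and R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

GROUP_ALIASES = {
    "iqf": "iqf", "IQF": "iqf",
    "ff": "fresh_frozen", "FF": "fresh_frozen",
    "fresh_frozen": "fresh_frozen", "fresh-frozen": "fresh_frozen",
}

#: published shorthand -> canonical attribute names
ABBREVIATIONS = {
    "A": "adhesiveness",
    "C1": "chewiness_1",
    "C1b": "chewiness_1b",
    "C1r": "residual_chewiness_1",
    "C2": "chewiness_2",
    "Co": "cohesiveness",
    "Cor": "residual_cohesiveness",
    "H1": "hardness_1",
    "H1b": "hardness_1b",
    "H1br": "residual_hardness_1b",
    "H1r": "residual_hardness_1",
    "H2": "hardness_2",
    "R": "resilience",
    "Sr": "residual_springiness",
    "T1": "thickness_1",
    "T2": "thickness_2",
}


@dataclass(frozen=True)
class Term:
    """One equation term: coef * attr, coef * attr^2, or coef * a_i*a_j."""

    kind: str                 # "linear" | "square" | "cross"
    attributes: tuple[str, ...]
    coef: float

    def __post_init__(self) -> None:
        n_expected = {"linear": 1, "square": 1, "cross": 2}.get(self.kind)
        if n_expected is None:
            raise ValueError(f"unknown term kind '{self.kind}'")
        if len(self.attributes) != n_expected:
            raise ValueError(f"{self.kind} term needs {n_expected} attribute(s)")

    @property
    def name(self) -> str:
        if self.kind == "linear":
            return self.attributes[0]
        if self.kind == "square":
            return f"{self.attributes[0]}^2"
        return f"{self.attributes[0]}*{self.attributes[1]}"

    def value(self, data: Mapping[str, float] | pd.DataFrame):
        for a in self.attributes:
            if a not in data:
                raise KeyError(f"missing attribute '{a}' for term {self.name}")
        if self.kind == "linear":
            return data[self.attributes[0]]
        if self.kind == "square":
            return data[self.attributes[0]] ** 2
        return data[self.attributes[0]] * data[self.attributes[1]]


@dataclass(frozen=True)
class FitReport:
    """Fit statistics of a prediction equation."""

    rmse: float
    r_squared: float
    adj_r_squared: float
    r: float
    n: int | None = None
    entry_p: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class PredictionEquation:
    """intercept + sum of terms mapping TPA attributes to one sensory score."""

    target: str
    group: str
    intercept: float
    terms: tuple[Term, ...]
    provenance: str = "fitted"       # "builtin-table" | "fitted"
    report: FitReport | None = None

    def __post_init__(self) -> None:
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate terms in equation: {names}")

    @property
    def predictors(self) -> tuple[str, ...]:
        """All attributes referenced anywhere in the equation."""
        seen: list[str] = []
        for t in self.terms:
            for a in t.attributes:
                if a not in seen:
                    seen.append(a)
        return tuple(seen)


def predict(eq: PredictionEquation,
            data: Mapping[str, float] | pd.DataFrame):
    """Evaluate an equation on one profile (mapping) or a DataFrame.

    Raises ``KeyError`` naming the first missing attribute.
    """
    total = eq.intercept
    for term in eq.terms:
        total = total + term.coef * term.value(data)
    return total


# ---------------------------------------------------------------------------
# published equations

def _lin(abbr: str, coef: float) -> Term:
    return Term("linear", (ABBREVIATIONS[abbr],), coef)


def _sq(abbr: str, coef: float) -> Term:
    return Term("square", (ABBREVIATIONS[abbr],), coef)


def _x(a: str, b: str, coef: float) -> Term:
    return Term("cross", (ABBREVIATIONS[a], ABBREVIATIONS[b]), coef)


def _eq(group, target, intercept, terms, rmse, r2, r):
    return PredictionEquation(
        target=target, group=group, intercept=intercept, terms=tuple(terms),
        provenance="builtin-table",
        report=FitReport(rmse=rmse, r_squared=r2,
                         adj_r_squared=float("nan"), r=r))


_FF = "fresh_frozen"
_IQ = "iqf"

_BUILTIN: dict[str, dict[str, PredictionEquation | None]] = {
    _FF: {
        "cohesiveness_of_mass": _eq(_FF, "cohesiveness_of_mass", 1.758,
            [_lin("C1b", -0.0073), _lin("T2", 0.426),
             _x("C1b", "T2", 0.0274), _sq("T2", -0.349)],
            0.646, 0.240, 0.490),
        "fibrous": _eq(_FF, "fibrous", 6.955,
            [_lin("A", -0.725), _lin("R", -0.118)], 0.694, 0.136, 0.369),
        "firmness": _eq(_FF, "firmness", -0.305,
            [_lin("T1", 0.322), _lin("H1", -0.001), _sq("H1", 0.0003)],
            0.814, 0.280, 0.530),
        "flaky": _eq(_FF, "flaky", 7.533, [_lin("H1", -0.0124)],
            0.680, 0.270, 0.520),
        "moisture_release": _eq(_FF, "moisture_release", 5.126,
            [_lin("H1r", -0.0334), _sq("H1", 0.001)], 1.014, 0.210, 0.400),
        "moisture_retention": _eq(_FF, "moisture_retention", 1.301,
            [_lin("T2", 0.354), _lin("H1br", -0.0247),
             _x("T2", "H1br", 0.014), _sq("H1br", -0.0004), _sq("T2", -0.0723)],
            0.648, 0.302, 0.549),
        "springiness": _eq(_FF, "springiness", 3.437,
            [_lin("Sr", -0.094), _sq("Sr", -0.0309)], 0.615, 0.190, 0.430),
        "residual_cohesiveness_of_mass": _eq(
            _FF, "residual_cohesiveness_of_mass", -10.05,
            [_lin("Co", 12.69), _lin("C1b", -0.048), _lin("T2", 0.62),
             _x("Co", "T2", -14.73), _x("C1b", "T2", 0.073), _sq("T2", -0.736)],
            0.590, 0.270, 0.520),
        "residual_firmness": _eq(_FF, "residual_firmness", -3.723,
            [_lin("T1", 0.303), _lin("C1b", -0.0114),
             _sq("C1b", 0.0018), _sq("T1", -0.062)], 0.870, 0.097, 0.310),
        "residual_flaky": _eq(_FF, "residual_flaky", 1.938,
            [_lin("H2", -0.0102)], 0.708, 0.174, 0.417),
    },
    _IQ: {
        "cohesiveness_of_mass": _eq(_IQ, "cohesiveness_of_mass", 1.909,
            [_lin("H1", 0.0043), _lin("Co", 6.512),
             _sq("H1", -0.00004), _sq("Co", 315.4)], 0.698, 0.094, 0.307),
        "fibrous": _eq(_IQ, "fibrous", 4.188,
            [_lin("H1", 0.0162), _lin("C1", -0.0279),
             _sq("H1", -0.0003), _sq("C1", 0.0015)], 0.708, 0.160, 0.400),
        "firmness": _eq(_IQ, "firmness", 2.566,
            [_lin("H2", 0.0138), _lin("C2", -0.0128),
             _sq("H2", -0.0006), _x("H2", "C2", 0.0013)], 0.866, 0.102, 0.319),
        "flaky": _eq(_IQ, "flaky", 6.239,
            [_lin("H1b", -0.0192), _lin("C1b", 0.0272), _sq("H1b", 0.00006)],
            0.862, 0.124, 0.352),
        "moisture_release": _eq(_IQ, "moisture_release", 5.577,
            [_lin("Cor", 23.32), _sq("Cor", 274.3)], 1.050, 0.141, 0.375),
        # no TPA attribute correlated with IQF moisture retention
        "moisture_retention": None,
        "springiness": _eq(_IQ, "springiness", 1.284, [_lin("H1br", 0.0122)],
            0.800, 0.117, 0.342),
        "residual_cohesiveness_of_mass": _eq(
            _IQ, "residual_cohesiveness_of_mass", 0.0936,
            [_lin("C1r", 0.0160)], 0.704, 0.069, 0.263),
        "residual_firmness": _eq(_IQ, "residual_firmness", 1.589,
            [_lin("R", -0.0761), _lin("C1r", 0.0761), _x("R", "C1r", 0.0047)],
            0.863, 0.100, 0.316),
        "residual_flaky": _eq(_IQ, "residual_flaky", -1.065,
            [_lin("H1br", -0.0093), _lin("R", 0.1168), _sq("R", -0.0075)],
            0.842, 0.141, 0.375),
    },
}


def builtin_equations(group: str) -> dict[str, PredictionEquation | None]:
    """Published prediction equations for one treatment group.

    Ten targets per group; the IQF moisture-retention entry is ``None``
    (no TPA attribute qualified — an explicitly absent model).
    """
    key = GROUP_ALIASES.get(group)
    if key is None:
        raise ValueError(f"unknown group '{group}' "
                         f"(use 'iqf' or 'fresh_frozen')")
    return dict(_BUILTIN[key])


def builtin_equation(group: str, target: str) -> PredictionEquation | None:
    """One published equation (or None for an absent model)."""
    eqs = builtin_equations(group)
    if target not in eqs:
        raise KeyError(f"no published equation target '{target}'")
    return eqs[target]


# ---------------------------------------------------------------------------
# evaluation and stepwise fitting


def _design(columns: Sequence[np.ndarray], n: int) -> np.ndarray:
    return np.column_stack([np.ones(n)] + list(columns))


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares coefficients and SSE."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def evaluate(eq: PredictionEquation, data: pd.DataFrame,
             target: str | None = None) -> FitReport:
    """Fit statistics of an equation's predictions on a dataset.

    RMSE uses the regression convention sqrt(SSE/(n-p-1)) with p the
    number of terms; R^2 = 1 - SSE/SST (can be negative for an
    equation evaluated off its fitting sample, in which case R is NaN).
    """
    target = target or eq.target
    if target not in data.columns:
        raise KeyError(f"data lack target column '{target}'")
    sub = data.dropna(subset=[target, *eq.predictors])
    y = sub[target].to_numpy(float)
    n, p = y.size, len(eq.terms)
    if n <= p + 1:
        raise ValueError(f"need n > p+1 observations (n={n}, p={p})")
    yhat = np.asarray(predict(eq, sub), dtype=float)
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return FitReport(
        rmse=float(np.sqrt(sse / (n - p - 1))),
        r_squared=r2, adj_r_squared=adj,
        r=float(np.sqrt(r2)) if r2 >= 0 else float("nan"), n=n)


def _forward_pass(y: np.ndarray, current: "list[Term]",
                  candidates: "list[Term]", values: dict[str, np.ndarray],
                  alpha: float, entry_p: dict[str, float]) -> "list[Term]":
    """Forward selection: repeatedly add the best candidate with p < alpha."""
    n = y.size
    current = list(current)
    candidates = list(candidates)
    _, sse_cur = _ols(_design([values[t.name] for t in current], n), y)
    while candidates:
        best = None  # (p, -gain, name, term, sse_new)
        for term in candidates:
            cols = [values[t.name] for t in current] + [values[term.name]]
            X = _design(cols, n)
            p_new = len(current) + 1
            if n - p_new - 1 <= 0 or np.linalg.matrix_rank(X) < X.shape[1]:
                continue  # rank-deficient or saturated: skip candidate
            _, sse_new = _ols(X, y)
            df2 = n - p_new - 1
            if sse_new <= 0:
                p_val, gain = 0.0, sse_cur - sse_new
            else:
                f_part = (sse_cur - sse_new) / (sse_new / df2)
                p_val = float(sps.f.sf(max(f_part, 0.0), 1, df2))
                gain = sse_cur - sse_new
            key = (p_val, -gain, term.name)
            if best is None or key < best[0]:
                best = (key, term, sse_new)
        if best is None or best[0][0] >= alpha:
            break
        _, term, sse_cur = best
        entry_p[term.name] = best[0][0]
        current.append(term)
        candidates = [t for t in candidates if t.name != term.name]
    return current


def stepwise_fit(data: pd.DataFrame, target: str,
                 candidates: Sequence[str], group: str = "",
                 alpha: float = 0.05,
                 interactions: bool = True) -> tuple[PredictionEquation, FitReport]:
    """Two-phase forward stepwise regression of a sensory attribute.

    Phase 1 screens the main-effect ``candidates``; at each step the
    candidate with the smallest partial-F entry p-value joins the model
    if that p-value is below ``alpha``.  Phase 2 (``interactions=True``)
    offers only the squares and pairwise cross products of the phase-1
    survivors, under the same entry rule, with the phase-1 terms kept.
    Constant candidate columns are rejected; candidates whose entry
    would make the design rank-deficient are skipped with a warning.

    Returns the fitted equation (coefficients re-estimated jointly at
    the end) and its :class:`FitReport` on the fitting sample.
    """
    cols = [target, *candidates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"data lack column(s) {missing}")
    sub = data.dropna(subset=cols)
    y = sub[target].to_numpy(float)
    n = y.size
    if n < 5:
        raise ValueError(f"too few complete observations (n={n})")
    for c in candidates:
        if np.ptp(sub[c].to_numpy(float)) == 0:
            raise ValueError(f"candidate '{c}' is constant")

    main_terms = [Term("linear", (c,), 0.0) for c in candidates]
    values: dict[str, np.ndarray] = {
        t.name: sub[t.attributes[0]].to_numpy(float) for t in main_terms}

    entry_p: dict[str, float] = {}
    selected = _forward_pass(y, [], main_terms, values, alpha, entry_p)

    if interactions and selected:
        survivors = [t.attributes[0] for t in selected]
        aug: list[Term] = [Term("square", (a,), 0.0) for a in survivors]
        aug += [Term("cross", (a, b), 0.0)
                for i, a in enumerate(survivors) for b in survivors[i + 1:]]
        for t in aug:
            values[t.name] = np.asarray(t.value(sub), dtype=float)
        selected = _forward_pass(y, selected, aug, values, alpha, entry_p)

    X = _design([values[t.name] for t in selected], n)
    beta, sse = _ols(X, y)
    terms = tuple(Term(t.kind, t.attributes, float(b))
                  for t, b in zip(selected, beta[1:]))
    p = len(terms)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else np.nan
    report = FitReport(
        rmse=float(np.sqrt(sse / (n - p - 1))) if n - p - 1 > 0 else np.nan,
        r_squared=r2, adj_r_squared=float(adj),
        r=float(np.sqrt(max(r2, 0.0))), n=n, entry_p=dict(entry_p))
    eq = PredictionEquation(target=target, group=group,
                            intercept=float(beta[0]), terms=terms,
                            provenance="fitted", report=report)
    return eq, report


def equation_to_dict(eq: PredictionEquation) -> dict:
    """JSON-serializable form of an equation (with report if present)."""
    d = {
        "target": eq.target, "group": eq.group, "intercept": eq.intercept,
        "provenance": eq.provenance,
        "terms": [{"kind": t.kind, "attributes": list(t.attributes),
                   "coef": t.coef} for t in eq.terms],
    }
    if eq.report is not None:
        d["report"] = {
            "rmse": eq.report.rmse, "r_squared": eq.report.r_squared,
            "adj_r_squared": eq.report.adj_r_squared, "r": eq.report.r,
            "n": eq.report.n, "entry_p": dict(eq.report.entry_p)}
    return d
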