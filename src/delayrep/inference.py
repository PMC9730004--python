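"""Condition-level inference for delayed-reproduction datasets.

Three model families:

* a linear mixed model of log reproduction on log sample interval with
  an interval x retention-condition interaction and a participant random
  intercept — its interval coefficient is the reproduction *slope*, and
  the interaction terms carry the per-condition slope differences;
* scalar mixed models (indifference point, VE, CV as outcomes) with a
  condition fixed effect and participant random intercept;
* an ordinary-least-squares comparison of linear versus logarithmic
  growth of an error measure with the retention period, scored by AIC.

All mixed models are fit by maximum likelihood (so AICs are comparable)
and tested with large-sample Wald statistics.  Pairwise contrasts are
Holm-adjusted within each family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "ReproductionModelFit",
    "ScalarModelFit",
    "AICComparison",
    "fit_reproduction_model",
    "condition_slopes",
    "holm_adjust",
    "pairwise_slope_contrasts",
    "fit_scalar_model",
    "retention_curve_comparison",
]


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment, returned in the original order.

    ``adj_(j) = max_{i<=j} min(1, (m-i+1) * p_(i))`` over the ascending
    order statistics.  Controls familywise error without independence
    assumptions.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj


def _prepare(df: pd.DataFrame) -> tuple[pd.DataFrame, list[float]]:
    d = df.copy()
    if "log10_sample" not in d.columns or "log10_reproduced" not in d.columns:
        from .stats import log_transform

        d = log_transform(d)
    conditions = sorted(d["retention_s"].unique())
    d["condition"] = pd.Categorical(
        d["retention_s"].map(lambda r: f"{r:g}"), categories=[f"{c:g}" for c in conditions]
    )
    return d, conditions


@dataclass
class ReproductionModelFit:
    """Fitted slope model with its condition structure.

    ``converged`` is False (never silent) when the optimizer reported a
    singular or non-converged fit; ``messages`` carries the warnings.
    """

    result: object
    conditions: list[float]
    converged: bool
    messages: list[str] = field(default_factory=list)

    def _interaction_name(self, cond: float) -> str | None:
        label = f"{cond:g}"
        if label == f"{self.conditions[0]:g}":
            return None  # reference level
        name = f"log10_sample:C(condition)[T.{label}]"
        if name not in self.result.fe_params.index:
            raise KeyError(f"condition {cond!r} not in model")
        return name

    def fe_cov(self) -> pd.DataFrame:
        names = list(self.result.fe_params.index)
        return self.result.cov_params().loc[names, names]

    def wald_tests(self) -> dict[str, tuple[float, float]]:
        """Overall Wald chi2 tests (statistic, p) for interval, condition, interaction."""
        names = list(self.result.fe_params.index)
        out = {}
        for term, selector in (
            ("interval", lambda n: n == "log10_sample"),
            ("condition", lambda n: n.startswith("C(condition)")),
            ("interaction", lambda n: n.startswith("log10_sample:C(condition)")),
        ):
            sel = [n for n in names if selector(n)]
            constraint = ", ".join(f"{n} = 0" for n in sel)
            w = self.result.wald_test(constraint, scalar=True)
            out[term] = (float(w.statistic), float(w.pvalue))
        return out

    def summary_text(self) -> str:
        return str(self.result.summary())


def fit_reproduction_model(df: pd.DataFrame, random_slope: bool = False) -> ReproductionModelFit:
    """Fit log10(reproduced) ~ log10(sample) x condition, participant random intercept.

    Maximum-likelihood estimation.  ``random_slope=True`` adds a random
    slope on log10(sample) (off by default).  Requires >= 2 retention
    conditions and >= 2 participants.
    """
    d, conditions = _prepare(df)
    if len(conditions) < 2:
        raise ValueError("need >= 2 retention conditions")
    if d["participant"].nunique() < 2:
        raise ValueError("need >= 2 participants")
    re_formula = "1 + log10_sample" if random_slope else "1"
    messages: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(
            "log10_reproduced ~ log10_sample * C(condition)",
            d,
            groups=d["participant"],
            re_formula=re_formula,
        )
        # Powell is markedly more reliable than gradient methods for the
        # profiled variance components here
        result = model.fit(reml=False, method="powell")
        messages = [str(w.message) for w in caught]
    converged = bool(getattr(result, "converged", True)) and not any(
        "singular" in m.lower() or "converge" in m.lower() for m in messages
    )
    return ReproductionModelFit(result, conditions, converged, messages)


def condition_slopes(fit: ReproductionModelFit) -> pd.Series:
    """Reproduction slope per retention condition.

    Reference condition: the interval coefficient itself; others add the
    matching interaction coefficient.
    """
    base = float(fit.result.fe_params["log10_sample"])
    out = {}
    for c in fit.conditions:
        name = fit._interaction_name(c)
        out[c] = base if name is None else base + float(fit.result.fe_params[name])
    return pd.Series(out, name="slope")


def _contrast_rows(fit_params: pd.Series, cov: pd.DataFrame, vectors: dict) -> pd.DataFrame:
    rows = []
    for pair, L in vectors.items():
        L = np.asarray(L, dtype=float)
        est = float(L @ fit_params.to_numpy())
        se = float(np.sqrt(L @ cov.to_numpy() @ L))
        z = est / se if se > 0 else np.nan
        p = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append(
            {"condition_1": pair[0], "condition_2": pair[1], "estimate": est,
             "se": se, "statistic": z, "p_raw": p}
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


def pairwise_slope_contrasts(fit: ReproductionModelFit) -> pd.DataFrame:
    """Wald contrasts on slope differences for every condition pair, Holm-adjusted."""
    names = list(fit.result.fe_params.index)
    vectors = {}
    for c1, c2 in combinations(fit.conditions, 2):
        L = np.zeros(len(names))
        for cond, sign in ((c1, 1.0), (c2, -1.0)):
            name = fit._interaction_name(cond)
            if name is not None:
                L[names.index(name)] += sign
        vectors[(c1, c2)] = L
    return _contrast_rows(fit.result.fe_params, fit.fe_cov(), vectors)


@dataclass
class ScalarModelFit:
    """Condition-effect test for a scalar per-participant outcome."""

    outcome: str
    result: object
    conditions: list[float]
    wald_statistic: float
    wald_p: float
    contrasts: pd.DataFrame
    n_dropped: int
    converged: bool
    messages: list[str] = field(default_factory=list)


def fit_scalar_model(stats_df: pd.DataFrame, outcome: str) -> ScalarModelFit:
    """Mixed model of a scalar outcome on retention condition.

    ``outcome`` names a column (e.g. ``indifference_ms``, ``ve``,
    ``cv``); expects one row per participant x condition (indifference
    points) or per participant x condition x interval (VE, CV).  Rows
    with undefined (NaN) outcome are dropped with a logged count.
    Returns the overall Wald condition test plus pairwise Holm-adjusted
    contrasts of condition means.
    """
    if outcome not in stats_df.columns:
        raise KeyError(f"outcome column {outcome!r} not found")
    d = stats_df[stats_df[outcome].notna()].copy()
    n_dropped = len(stats_df) - len(d)
    if d[outcome].nunique() < 2:
        raise ValueError(f"outcome {outcome!r} is constant: degenerate model")
    d, conditions = _prepare_scalar(d)
    messages: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(f"{outcome} ~ C(condition)", d, groups=d["participant"])
        result = model.fit(reml=False, method="powell")
        messages = [str(w.message) for w in caught]
    converged = bool(getattr(result, "converged", True))

    names = list(result.fe_params.index)
    cond_terms = [n for n in names if n.startswith("C(condition)")]
    w = result.wald_test(", ".join(f"{n} = 0" for n in cond_terms), scalar=True)

    cov = result.cov_params().loc[names, names]
    vectors = {}
    for c1, c2 in combinations(conditions, 2):
        L = np.zeros(len(names))
        for cond, sign in ((c1, 1.0), (c2, -1.0)):
            term = f"C(condition)[T.{cond:g}]"
            if term in names:
                L[names.index(term)] += sign
        vectors[(c1, c2)] = L
    contrasts = _contrast_rows(result.fe_params, cov, vectors)
    return ScalarModelFit(
        outcome, result, conditions, float(w.statistic), float(w.pvalue),
        contrasts, n_dropped, converged, messages,
    )


def _prepare_scalar(d: pd.DataFrame) -> tuple[pd.DataFrame, list[float]]:
    conditions = sorted(d["retention_s"].unique())
    d = d.copy()
    d["condition"] = pd.Categorical(
        d["retention_s"].map(lambda r: f"{r:g}"), categories=[f"{c:g}" for c in conditions]
    )
    return d, conditions


@dataclass(frozen=True)
class AICComparison:
    """Linear vs logarithmic retention-curve fits for one error measure."""

    outcome: str
    aic_linear: float
    aic_log: float
    n_points: int
    k_linear: int = 2
    k_log: int = 2

    @property
    def delta_aic(self) -> float:
        """aic_log - aic_linear; positive favors the linear model."""
        return self.aic_log - self.aic_linear


def _gaussian_aic(rss: float, n: int, k: int) -> float:
    # k regression parameters + 1 for the error variance; floor keeps a
    # perfectly interpolating fit finite (both models then tie at the floor)
    rss = max(rss, 1e-300)
    return n * math.log(2.0 * math.pi * rss / n) + n + 2.0 * (k + 1)


def _ols_rss(x: np.ndarray, y: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def retention_curve_comparison(stats_df: pd.DataFrame, outcome: str) -> AICComparison:
    """Does an error measure grow linearly or logarithmically with retention?

    Fits ``outcome ~ retention_s`` and ``outcome ~ ln(retention_s)`` by
    OLS on the provided rows (participant x condition x interval) and
    compares Gaussian maximum-likelihood AICs.  Positive ``delta_aic``
    (= aic_log - aic_linear) favors the linear growth law.
    """
    if outcome not in stats_df.columns:
        raise KeyError(f"outcome column {outcome!r} not found")
    d = stats_df[stats_df[outcome].notna()]
    x = d["retention_s"].to_numpy(float)
    y = d[outcome].to_numpy(float)
    if len(np.unique(x)) < 2:
        raise ValueError("retention-curve comparison needs >= 2 distinct retention periods")
    aic_lin = _gaussian_aic(_ols_rss(x, y), len(y), 2)
    aic_log = _gaussian_aic(_ols_rss(np.log(x), y), len(y), 2)
    return AICComparison(outcome, aic_lin, aic_log, len(y))
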