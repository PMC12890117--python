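"""Assay statistics: ANOVA window optimization and method comparison.

Two statistical questions surround the flow assay.  First, which early
time window (frame count) best separates the concentration groups: a
one-way ANOVA of replicate velocities across concentrations is run per
candidate window and the window with the smallest p-value is chosen (ties
broken by the smaller mean standard error).  Second, how well do
flow-derived concentrations agree with the ELISA reference: an ordinary
least-squares regression of flow on ELISA concentration per subject, with
outliers flagged by externally studentized residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidInputError, UndefinedFError

__all__ = [
    "AnovaResult",
    "WindowChoice",
    "CorrelationResult",
    "one_way_anova",
    "optimize_window",
    "standard_error",
    "method_correlation",
]


@dataclass(frozen=True)
class AnovaResult:
    """Classical fixed-effects one-way ANOVA outcome."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class WindowChoice:
    """Per-window ANOVA diagnostics and the selected window (frame count)."""

    candidates: tuple[int, ...]
    p_values: tuple[float, ...]
    mean_ses: tuple[float, ...]
    selected: int


@dataclass(frozen=True)
class CorrelationResult:
    """Flow-vs-reference regression: slope/intercept/R² and flagged outliers.

    ``slope``/``intercept`` are the free-intercept OLS fit (the headline);
    ``slope_through_origin`` is the no-intercept fit reported alongside.
    """

    slope: float
    intercept: float
    r_squared: float
    slope_through_origin: float
    outlier_ids: tuple

    @property
    def n_outliers(self) -> int:
        return len(self.outlier_ids)


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across ``k`` groups.

    F = MS_between / MS_within with (k−1, N−k) degrees of freedom; the
    p-value is the upper tail of the central F distribution.  Groups with
    identical values throughout (zero between- and within-group variance)
    leave F undefined.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InsufficientDataError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise InsufficientDataError("each group needs at least 2 observations")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = sum(float(a.sum()) for a in arrays) / n_total
    ss_between = sum(a.size * (float(a.mean()) - grand) ** 2 for a in arrays)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0.0 and ss_between == 0.0:
        raise UndefinedFError("no variance within or between groups: F is 0/0")
    if ss_within == 0.0:
        return AnovaResult(math.inf, df_between, df_within, 0.0)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), df_between, df_within, p)


def standard_error(values) -> float:
    """Standard error of the mean: sample sd (n−1 denominator) over √n."""
    a = np.asarray(values, dtype=float)
    if a.size < 2:
        raise InsufficientDataError("need at least 2 values")
    return float(a.std(ddof=1) / math.sqrt(a.size))


def optimize_window(velocities_by_window) -> WindowChoice:
    """Pick the time window whose ANOVA best separates concentration groups.

    ``velocities_by_window`` maps a candidate window (frame count) to its
    list of per-concentration velocity groups; all windows must share the
    group structure.  The window with the minimal ANOVA p-value is selected;
    ties are broken by the smaller mean per-group standard error.  All
    per-window diagnostics are reported.
    """
    if len(velocities_by_window) < 2:
        raise InsufficientDataError("need at least 2 candidate windows")
    structures = {
        w: tuple(len(g) for g in groups) for w, groups in velocities_by_window.items()
    }
    if len(set(structures.values())) != 1:
        raise InvalidInputError(
            f"group structure differs across windows: {structures}"
        )
    candidates = tuple(sorted(velocities_by_window))
    p_values = []
    mean_ses = []
    for w in candidates:
        groups = velocities_by_window[w]
        p_values.append(one_way_anova(groups).p_value)
        mean_ses.append(float(np.mean([standard_error(g) for g in groups])))
    order = sorted(range(len(candidates)), key=lambda i: (p_values[i], mean_ses[i]))
    return WindowChoice(
        candidates=candidates,
        p_values=tuple(p_values),
        mean_ses=tuple(mean_ses),
        selected=candidates[order[0]],
    )


def method_correlation(
    flow_conc,
    elisa_conc,
    ids=None,
    outlier_threshold: float = 2.0,
) -> CorrelationResult:
    """Regress flow-derived on reference (ELISA) concentrations per subject.

    Free-intercept OLS of flow on ELISA (slope near 1 and high R² indicate
    method agreement); a through-origin slope is reported as a secondary
    summary.  Subjects whose externally studentized residual exceeds
    ``outlier_threshold`` in magnitude are flagged as outliers (flagging is
    skipped when the leave-one-out residual degrees of freedom vanish).
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    x = np.asarray(elisa_conc, dtype=float)
    y = np.asarray(flow_conc, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("flow and elisa vectors must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 paired subjects")
    if ids is None:
        ids = tuple(range(x.size))
    ids = tuple(ids)
    if len(ids) != x.size:
        raise InvalidInputError("ids length must match the data")

    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = (float(v) for v in model.params)
    r2 = float(model.rsquared)

    origin = float(np.dot(x, y) / np.dot(x, x)) if np.any(x != 0) else math.nan

    outliers: tuple = ()
    exact_fit = bool(np.allclose(model.resid, 0.0, atol=1e-10 * max(1.0, float(np.abs(y).max()))))
    if x.size >= 4 and model.df_resid > 1 and not exact_fit:
        resid = OLSInfluence(model).resid_studentized_external
        outliers = tuple(
            ids[j]
            for j in range(x.size)
            if np.isfinite(resid[j]) and abs(resid[j]) > outlier_threshold
        )
    return CorrelationResult(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        slope_through_origin=origin,
        outlier_ids=outliers,
    )
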