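"""Standard curves, inverse concentration prediction, and precipitin zones.

The flow assay's calibration is semi-logarithmic: response (flow velocity,
px/frame) is linear in log10 of analyte concentration within the
antibody-excess zone, ``y = m·log10(c) + b``.  Fitting that line, inverting
it (with dilution/spiking arithmetic and an optional correction factor for
the elevated-particle-load protocol), and classifying concentrations into
Heidelberger-Kendall zones (antibody excess / equivalence / antigen excess)
are the operations here.  A plain linear curve (response vs concentration)
is included for ELISA optical-density tables.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateCurveError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "StandardCurve",
    "ZoneClassification",
    "DilutionSpec",
    "ExtrapolationWarning",
    "fit_semilog",
    "predict_concentration",
    "dilute",
    "spiked_concentration",
    "classify_zones",
    "fit_standard_linear",
]

#: ng/mL per unit of each supported stock unit
_UNIT_TO_NG_PER_ML = {
    "mg/dL": 1e4,
    "mg/mL": 1e6,
    "µg/mL": 1e3,
    "ug/mL": 1e3,
    "ng/mL": 1.0,
}


class ExtrapolationWarning(UserWarning):
    """A predicted concentration falls outside the curve's fitted range."""


@dataclass(frozen=True)
class StandardCurve:
    """A fitted calibration line.

    For the semi-log flow curve, ``response = slope_m·log10(c) + intercept_b``
    with c in ng/mL; for the linear ELISA curve, ``response = slope_m·c +
    intercept_b``.  ``kind`` records which.
    """

    slope_m: float
    intercept_b: float
    r_squared: float
    n_points: int
    conc_range: tuple[float, float]
    zero_excluded: bool = True
    kind: str = "semilog"

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise InsufficientDataError("a curve needs at least 2 points")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise InvalidInputError(f"r_squared out of [0, 1]: {self.r_squared}")

    def response_at(self, c: float) -> float:
        """Evaluate the fitted curve at concentration ``c`` (ng/mL)."""
        if self.kind == "semilog":
            if c <= 0:
                raise InvalidInputError("semilog curve undefined at c ≤ 0")
            return self.slope_m * math.log10(c) + self.intercept_b
        return self.slope_m * c + self.intercept_b

    def to_json(self, path: "str | Path | None" = None) -> str:
        payload = {
            "slope_m": self.slope_m,
            "intercept_b": self.intercept_b,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "conc_range": list(self.conc_range),
            "zero_excluded": self.zero_excluded,
            "kind": self.kind,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: "str | Path") -> "StandardCurve":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        d = json.loads(text)
        d["conc_range"] = tuple(d["conc_range"])
        return cls(**d)


@dataclass(frozen=True)
class ZoneClassification:
    """Per-concentration precipitin-zone labels plus the equivalence estimate."""

    zones: tuple[str, ...]
    c_eq_estimate: float
    tolerance_eps: float


@dataclass(frozen=True)
class DilutionSpec:
    """A stock concentration and the dilution fraction applied to it."""

    stock_value: float
    stock_unit: str
    fraction: float

    def __post_init__(self) -> None:
        if self.stock_unit not in _UNIT_TO_NG_PER_ML:
            raise ConfigurationError(
                f"unknown unit {self.stock_unit!r}; supported: "
                f"{sorted(_UNIT_TO_NG_PER_ML)}"
            )
        if not (0.0 < self.fraction <= 1.0):
            raise InvalidInputError("fraction must be in (0, 1]")
        if self.stock_value < 0:
            raise InvalidInputError("stock_value must be ≥ 0")


def _prepare_xy(
    concs, responses
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse replicate responses to per-concentration means."""
    df = pd.DataFrame({"conc": np.asarray(concs, dtype=float),
                       "resp": np.asarray(responses, dtype=float)})
    g = df.groupby("conc", sort=True)["resp"].mean()
    return g.index.to_numpy(), g.to_numpy()


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        raise InsufficientDataError("all abscissa values identical")
    m = float(np.sum((x - xm) * (y - ym)) / sxx)
    b = float(ym - m * xm)
    ss_res = float(np.sum((y - (m * x + b)) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return m, b, r2


def fit_semilog(
    concs,
    responses,
    exclude_zero: bool = True,
    on_means: bool = True,
) -> StandardCurve:
    """Fit ``response = m·log10(c) + b`` by ordinary least squares.

    Zero-concentration points cannot enter a logarithmic plot; with
    ``exclude_zero`` (default) they are dropped, otherwise any
    non-positive concentration is an error.  When replicates are present the
    fit is on per-concentration mean responses (``on_means=True``, the
    default, matching how averaged velocities are calibrated); set it False
    to fit all replicates individually.
    """
    concs = np.asarray(concs, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if concs.shape != responses.shape:
        raise InvalidInputError("concs and responses must have equal length")
    if exclude_zero:
        keep = concs > 0
        concs, responses = concs[keep], responses[keep]
    elif np.any(concs <= 0):
        raise InvalidInputError(
            "non-positive concentration in a semilog fit with exclude_zero=False"
        )
    if np.unique(concs).size < 2:
        raise InsufficientDataError(
            "need at least 2 distinct positive concentrations"
        )
    if on_means:
        x_conc, y = _prepare_xy(concs, responses)
    else:
        x_conc, y = concs, responses
    m, b, r2 = _ols_line(np.log10(x_conc), y)
    return StandardCurve(
        slope_m=m,
        intercept_b=b,
        r_squared=max(0.0, min(1.0, r2)),
        n_points=int(np.unique(x_conc).size),
        conc_range=(float(concs.min()), float(concs.max())),
        zero_excluded=exclude_zero,
        kind="semilog",
    )


def fit_standard_linear(concs, optical_densities) -> StandardCurve:
    """Fit a plain linear standard curve ``OD = m·c + b`` (ELISA tables).

    Inverse prediction is ``c = (OD − b) / m`` via
    :func:`predict_concentration`.
    """
    concs = np.asarray(concs, dtype=float)
    od = np.asarray(optical_densities, dtype=float)
    if concs.shape != od.shape:
        raise InvalidInputError("concs and optical_densities must have equal length")
    if np.unique(concs).size < 2:
        raise InsufficientDataError("need at least 2 distinct standards")
    x, y = _prepare_xy(concs, od)
    m, b, r2 = _ols_line(x, y)
    return StandardCurve(
        slope_m=m,
        intercept_b=b,
        r_squared=max(0.0, min(1.0, r2)),
        n_points=int(x.size),
        conc_range=(float(concs.min()), float(concs.max())),
        zero_excluded=False,
        kind="linear",
    )


def predict_concentration(
    curve: StandardCurve,
    response: float,
    correction_factor: float = 1.0,
) -> float:
    """Invert a standard curve: concentration (ng/mL) producing ``response``.

    For the semilog curve this is ``10^((response − b)/m)`` divided by the
    correction factor (1.5 for the elevated particle-load protocol, 1
    otherwise); for the linear curve, ``(response − b)/m`` over the factor.
    Predictions outside the fitted concentration range are flagged with an
    :class:`ExtrapolationWarning`, not an error.
    """
    if correction_factor <= 0:
        raise InvalidInputError("correction_factor must be positive")
    if curve.slope_m == 0:
        raise DegenerateCurveError("cannot invert a zero-slope curve")
    if curve.kind == "semilog":
        conc = 10.0 ** ((response - curve.intercept_b) / curve.slope_m)
    else:
        conc = (response - curve.intercept_b) / curve.slope_m
    conc /= correction_factor
    lo, hi = curve.conc_range
    raw = conc * correction_factor
    if not (lo * (1 - 1e-9) <= raw <= hi * (1 + 1e-9)):
        warnings.warn(
            f"predicted {conc:.4g} ng/mL lies outside the fitted range "
            f"[{lo:g}, {hi:g}] ng/mL (extrapolated)",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return conc


def dilute(spec: DilutionSpec) -> float:
    """Concentration (ng/mL) after diluting the stock by ``fraction``.

    E.g. normal plasma antithrombin of 15 mg/dL at a 10⁻⁵ dilution (0.001%
    plasma) is 1.5 ng/mL.
    """
    return spec.stock_value * _UNIT_TO_NG_PER_ML[spec.stock_unit] * spec.fraction


def spiked_concentration(endogenous: float, spike: float) -> float:
    """Total concentration after spiking: endogenous + added (both ng/mL)."""
    if endogenous < 0 or spike < 0:
        raise InvalidInputError("concentrations must be ≥ 0")
    return endogenous + spike


def classify_zones(
    concs,
    mean_responses,
    eps: float | None = None,
    sems=None,
) -> ZoneClassification:
    """Label each concentration with its Heidelberger-Kendall zone.

    Along increasing concentration the precipitin response rises (antibody
    excess), plateaus (equivalence) and falls (antigen excess).  The
    equivalence zone is the contiguous run of points whose mean response is
    within ``eps`` of the maximum; everything before it is antibody excess,
    everything after is antigen excess, and the equivalence-concentration
    estimate is the concentration of the maximum mean.  ``eps`` defaults to
    the pooled standard error of the group means (``sems``); one of
    ``eps``/``sems`` must be given.

    A strictly monotone series shows no plateau: if the would-be equivalence
    run is the single last (first) point and the step into it exceeds eps,
    the whole series is classified antibody excess (antigen excess), with
    the extreme concentration as the equivalence bound.
    """
    concs = np.asarray(concs, dtype=float)
    y = np.asarray(mean_responses, dtype=float)
    if concs.shape != y.shape:
        raise InvalidInputError("concs and mean_responses must have equal length")
    if concs.size < 3:
        raise InsufficientDataError("need at least 3 concentrations")
    if np.any(np.diff(concs) <= 0):
        raise InvalidInputError("concs must be sorted strictly ascending")
    if eps is None:
        if sems is None:
            raise InvalidInputError("provide eps or per-group sems")
        sems = np.asarray(sems, dtype=float)
        eps = float(np.sqrt(np.mean(sems**2)))  # pooled SE of the means
    if eps < 0:
        raise InvalidInputError("eps must be ≥ 0")

    n = concs.size
    i_max = int(np.argmax(y))
    near_max = y >= y[i_max] - eps
    # maximal contiguous equivalence run containing the peak
    start = i_max
    while start > 0 and near_max[start - 1]:
        start -= 1
    end = i_max
    while end < n - 1 and near_max[end + 1]:
        end += 1

    if start == end == n - 1 and y[n - 1] - y[n - 2] > eps:
        zones = ("antibody_excess",) * n
    elif start == end == 0 and y[0] - y[1] > eps:
        zones = ("antigen_excess",) * n
    else:
        zones = tuple(
            "antibody_excess" if i < start
            else "antigen_excess" if i > end
            else "equivalence"
            for i in range(n)
        )
    return ZoneClassification(
        zones=zones,
        c_eq_estimate=float(concs[i_max]),
        tolerance_eps=float(eps),
    )
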