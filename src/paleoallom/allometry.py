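"""Power-law (allometric) fitting on log10-log10 axes.

A reproductive trait Y (egg mass, clutch mass or annual clutch mass, kg
or kg/yr) scales with body mass BM (kg) as

    Y = c * BM**b,

which is a straight line ``log10 Y = log10 c + b * log10 BM``.  Fits are
ordinary least squares on the log10-transformed pairs; prediction
intervals are for a single new observation, computed in log10 space and
back-transformed with a plain ``10**`` (no smearing correction).

Base-10 logarithms are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.stats as st
import statsmodels.api as sm

from .records import InsufficientDataError, TraitDataset

__all__ = [
    "AllometricFit",
    "PredictionBand",
    "DegenerateDesignError",
    "fit_loglog_ols",
    "fit_loglog_xy",
    "refit_fixed_slope",
    "fit_along_line",
    "predict_trait",
    "prediction_interval",
    "power_law_through_points",
    "fit_from_power_law",
]


class DegenerateDesignError(ValueError):
    """The predictor has zero variance (all body masses equal)."""


@dataclass(frozen=True)
class AllometricFit:
    """A fitted log10-log10 line with everything needed for intervals.

    ``intercept_log10`` is log10 of the normalization constant c (c in kg
    when BM is in kg); ``slope`` is the dimensionless exponent b.  The
    leverage statistics (``n``, ``x_bar``, ``Sxx``, ``s2``, ``df_resid``)
    are kept so prediction intervals can be evaluated without the data.
    A fit constructed from bare power-law coefficients carries no
    interval statistics and only supports point prediction.
    """

    trait: str
    group_label: str
    slope: float
    intercept_log10: float
    n: int = 0
    x_bar: float | None = None
    Sxx: float | None = None
    s2: float | None = None  # residual variance in log10 space
    df_resid: int | None = None
    ci_slope: tuple[float, float] | None = None
    ci_intercept: tuple[float, float] | None = None
    r: float | None = None
    p_slope: float | None = None
    slope_fixed: bool = False

    @property
    def c(self) -> float:
        """Normalization constant on the natural scale."""
        return 10.0 ** self.intercept_log10

    @property
    def has_interval_stats(self) -> bool:
        return None not in (self.x_bar, self.Sxx, self.s2, self.df_resid) and self.n > 0

    def predict(self, BM):
        return predict_trait(self, BM)

    def to_dict(self) -> dict:
        d = {
            "trait": self.trait,
            "group_label": self.group_label,
            "slope": self.slope,
            "intercept_log10": self.intercept_log10,
            "n": self.n,
            "x_bar": self.x_bar,
            "Sxx": self.Sxx,
            "s2": self.s2,
            "df_resid": self.df_resid,
            "slope_fixed": self.slope_fixed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AllometricFit":
        return cls(
            trait=d["trait"],
            group_label=d["group_label"],
            slope=float(d["slope"]),
            intercept_log10=float(d["intercept_log10"]),
            n=int(d.get("n", 0) or 0),
            x_bar=d.get("x_bar"),
            Sxx=d.get("Sxx"),
            s2=d.get("s2"),
            df_resid=d.get("df_resid"),
            slope_fixed=bool(d.get("slope_fixed", False)),
        )


@dataclass(frozen=True)
class PredictionBand:
    """A 95% (by default) prediction interval on the natural scale."""

    BM: float
    y_hat: float
    lo: float
    hi: float
    level: float = 0.95


def _group_xy(dataset: TraitDataset, group: str, trait: str):
    x, y = dataset.xy(group, trait)
    if len(x) < 3:
        raise InsufficientDataError(
            f"group {group!r} has {len(x)} records; at least 3 are required to fit"
        )
    if np.ptp(x) == 0:
        raise DegenerateDesignError(f"group {group!r}: log10 body mass has zero variance")
    return x, y


def fit_loglog_xy(x, y, trait: str, label: str) -> AllometricFit:
    """Free-slope OLS on pre-transformed (log10 BM, log10 Y) arrays.

    Residual variance uses n - 2 degrees of freedom; the slope confidence
    interval, correlation coefficient and two-sided slope p-value come
    from the standard OLS theory.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"{label!r}: {n} points; at least 3 required")
    if np.ptp(x) == 0:
        raise DegenerateDesignError(f"{label!r}: log10 body mass has zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    ci = res.conf_int(alpha=0.05)
    r = math.copysign(math.sqrt(res.rsquared), slope)
    return AllometricFit(
        trait=trait,
        group_label=label,
        slope=float(slope),
        intercept_log10=float(intercept),
        n=n,
        x_bar=float(np.mean(x)),
        Sxx=float(np.sum((x - np.mean(x)) ** 2)),
        s2=float(res.mse_resid),
        df_resid=n - 2,
        ci_slope=(float(ci[1, 0]), float(ci[1, 1])),
        ci_intercept=(float(ci[0, 0]), float(ci[0, 1])),
        r=float(r),
        p_slope=float(res.pvalues[1]),
    )


def fit_loglog_ols(dataset: TraitDataset, group: str, trait: str) -> AllometricFit:
    """Free-slope OLS fit of log10(trait) on log10(BM) for one group."""
    x, y = _group_xy(dataset, group, trait)
    return fit_loglog_xy(x, y, trait, group)


def refit_fixed_slope(
    dataset: TraitDataset, group: str, trait: str, b_common: float
) -> AllometricFit:
    """Refit one group with the slope held at ``b_common``.

    Only the normalization constant is estimated: the log10 intercept is
    the mean of ``log10 Y - b_common * log10 BM``, and the residual
    variance uses n - 1 degrees of freedom (one estimated parameter).
    """
    if not math.isfinite(b_common):
        raise ValueError(f"b_common must be finite, got {b_common!r}")
    x, y = _group_xy(dataset, group, trait)
    n = len(x)
    intercept = float(np.mean(y - b_common * x))
    resid = y - b_common * x - intercept
    s2 = float(np.sum(resid**2) / (n - 1))
    half = st.t.ppf(0.975, n - 1) * math.sqrt(s2 / n)
    return AllometricFit(
        trait=trait,
        group_label=group,
        slope=float(b_common),
        intercept_log10=intercept,
        n=n,
        x_bar=float(np.mean(x)),
        Sxx=float(np.sum((x - np.mean(x)) ** 2)),
        s2=s2,
        df_resid=n - 1,
        ci_intercept=(intercept - half, intercept + half),
        slope_fixed=True,
    )


def fit_along_line(
    dataset: TraitDataset,
    groups: Sequence[str],
    trait: str,
    slope: float,
    intercept_log10: float,
    label: str,
) -> AllometricFit:
    """Package a given line with residual statistics of the pooled data.

    Used for merged-group models whose slope and intercept are averages
    of the member groups: the line is taken as given and the pooled
    records supply n, the leverage statistics and the residual variance
    (n - 2 degrees of freedom, two line parameters).
    """
    xs, ys = [], []
    for g in groups:
        x, y = _group_xy(dataset, g, trait)
        xs.append(x)
        ys.append(y)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    n = len(x)
    resid = y - slope * x - intercept_log10
    return AllometricFit(
        trait=trait,
        group_label=label,
        slope=float(slope),
        intercept_log10=float(intercept_log10),
        n=n,
        x_bar=float(np.mean(x)),
        Sxx=float(np.sum((x - np.mean(x)) ** 2)),
        s2=float(np.sum(resid**2) / (n - 2)),
        df_resid=n - 2,
    )


def predict_trait(fit: AllometricFit, BM):
    """Evaluate the power law at body mass ``BM`` (kg), natural scale."""
    BM = np.asarray(BM, dtype=float)
    if np.any(BM <= 0):
        raise ValueError("body mass must be > 0")
    out = 10.0 ** (fit.intercept_log10 + fit.slope * np.log10(BM))
    return float(out) if out.ndim == 0 else out


def prediction_interval(fit: AllometricFit, BM: float, level: float = 0.95) -> PredictionBand:
    """Prediction interval for a single new observation at ``BM``.

    Computed in log10 space as ``y_hat +/- t * sqrt(s2 * (1 + 1/n +
    (x0 - x_bar)^2 / Sxx))`` and back-transformed; the band is narrowest
    at the mean log10 body mass of the calibration data.
    """
    if not fit.has_interval_stats:
        raise DegenerateDesignError(
            f"fit {fit.group_label!r} carries no residual statistics for intervals"
        )
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if BM <= 0:
        raise ValueError("body mass must be > 0")
    x0 = math.log10(BM)
    y_hat = fit.intercept_log10 + fit.slope * x0
    se = math.sqrt(fit.s2 * (1.0 + 1.0 / fit.n + (x0 - fit.x_bar) ** 2 / fit.Sxx))
    tcrit = st.t.ppf(0.5 + level / 2.0, fit.df_resid)
    return PredictionBand(
        BM=BM,
        y_hat=10.0**y_hat,
        lo=10.0 ** (y_hat - tcrit * se),
        hi=10.0 ** (y_hat + tcrit * se),
        level=level,
    )


def power_law_through_points(
    BM1: float, Y1: float, BM2: float, Y2: float
) -> tuple[float, float]:
    """Exact power law (c, b) through two points on log-log axes.

    Two positive points determine the line uniquely; used to recover
    published model coefficients from pairs of reported predictions.
    """
    if min(BM1, Y1, BM2, Y2) <= 0:
        raise ValueError("all coordinates must be > 0")
    if BM1 == BM2:
        raise ValueError("body masses must differ")
    b = math.log10(Y2 / Y1) / math.log10(BM2 / BM1)
    c = Y1 / BM1**b
    return c, b


def fit_from_power_law(c: float, b: float, trait: str, label: str) -> AllometricFit:
    """Wrap bare power-law coefficients as a point-prediction-only fit."""
    if c <= 0:
        raise ValueError("normalization constant must be > 0")
    return AllometricFit(
        trait=trait, group_label=label, slope=b, intercept_log10=math.log10(c)
    )
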