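"""Burrow surveys and cross-method comparison statistics.

Burrow occupancy (burrows containing an adult, egg, or chick) is the
ground-truth abundance measure every remote index is compared against.
This module computes occupancy/density summaries from survey records
(quadrat or whole-plot census mode), and provides the comparison-layer
statistics: simple OLS regression with the F test, the 2x2 chi-square for
saturation frequency, the Wilcoxon rank-sum island test, and the logistic
call-saturation model linking a bounded aerial call rate (ceiling 30/min)
to an unbounded abundance covariate such as nightly acoustic energy.

The saturation model is

    rate = asymptote / (1 + exp((xmidpt - x) / scale))

with asymptote fixed at 30 calls/min and xmidpt at 15 calls/min by
default; only ``scale`` is estimated. A variant with free xmidpt (and
optionally free asymptote) is available for covariates on arbitrary
scales. Model comparison uses Gaussian AIC with the error variance
profiled out, so logistic and linear AICs are commensurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "PlotGeometry",
    "BurrowStatus",
    "BurrowRecord",
    "OccupancySummary",
    "RegressionResult",
    "SaturationModel",
    "SaturationFit",
    "occupancy_summary",
    "ols_regress",
    "fit_saturation",
    "saturation_contingency",
    "rank_test",
]


@dataclass(frozen=True)
class PlotGeometry:
    """Survey plot: 10 m x 25 m rectangle or radius-7 m circle."""

    shape: str  # "rectangle" | "circle"
    area_m2: float

    @classmethod
    def rectangle(cls) -> "PlotGeometry":
        return cls("rectangle", 250.0)

    @classmethod
    def circle(cls, radius_m: float = 7.0) -> "PlotGeometry":
        return cls("circle", math.pi * radius_m**2)


class BurrowStatus(str, Enum):
    OCCUPIED = "occupied"
    UNOCCUPIED = "unoccupied"
    UNKNOWN = "unknown"
    NOT_CHECKED = "not_checked"


# Data S1-style status code vocabulary
STATUS_CODES = {"O": BurrowStatus.OCCUPIED, "U": BurrowStatus.UNOCCUPIED,
                "X": BurrowStatus.UNKNOWN, "NA": BurrowStatus.NOT_CHECKED}


@dataclass(frozen=True)
class BurrowRecord:
    plot_id: str
    status: BurrowStatus
    quadrat_id: str | None = None  # set in quadrat mode
    contents_code: str | None = None


@dataclass(frozen=True)
class OccupancySummary:
    mode: str
    n_burrows: int
    n_occupied: int
    searched_area_m2: float
    total_density: float      # burrows / m^2
    occupied_density: float   # occupied burrows / m^2
    total_density_se: float | None = None
    occupied_density_se: float | None = None


def occupancy_summary(
    records: Sequence[BurrowRecord],
    geometry: PlotGeometry | Sequence[PlotGeometry],
    mode: str = "census",
    quadrat_area_m2: float = 1.0,
    n_quadrats: int | None = None,
) -> OccupancySummary:
    """Total and occupied burrow densities from one plot-survey.

    Unknown-status burrows are excluded from both numerator and denominator
    counts. Census mode divides counts by the summed plot area; quadrat mode
    averages per-quadrat densities (1 m^2 quadrats) and reports the SE across
    quadrats. ``n_quadrats`` covers quadrats searched but empty of burrows.
    """
    known = [r for r in records if r.status in (BurrowStatus.OCCUPIED, BurrowStatus.UNOCCUPIED)]
    n_burrows = len(known)
    n_occ = sum(1 for r in known if r.status == BurrowStatus.OCCUPIED)
    if mode == "census":
        geoms = [geometry] if isinstance(geometry, PlotGeometry) else list(geometry)
        area = sum(g.area_m2 for g in geoms)
        if area <= 0:
            raise ValueError("zero searched area")
        return OccupancySummary(
            mode="census",
            n_burrows=n_burrows,
            n_occupied=n_occ,
            searched_area_m2=area,
            total_density=n_burrows / area,
            occupied_density=n_occ / area,
        )
    if mode != "quadrat":
        raise ValueError(f"unknown mode {mode!r}")
    qids = sorted({r.quadrat_id for r in known if r.quadrat_id is not None})
    if n_quadrats is None:
        n_quadrats = len(qids)
    if n_quadrats == 0 or quadrat_area_m2 <= 0:
        raise ValueError("zero searched area")
    tot = np.zeros(n_quadrats)
    occ = np.zeros(n_quadrats)
    index = {q: i for i, q in enumerate(qids)}
    for r in known:
        i = index[r.quadrat_id]
        tot[i] += 1
        if r.status == BurrowStatus.OCCUPIED:
            occ[i] += 1
    tot_d = tot / quadrat_area_m2
    occ_d = occ / quadrat_area_m2
    se = lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else None
    return OccupancySummary(
        mode="quadrat",
        n_burrows=n_burrows,
        n_occupied=n_occ,
        searched_area_m2=n_quadrats * quadrat_area_m2,
        total_density=float(tot_d.mean()),
        occupied_density=float(occ_d.mean()),
        total_density_se=se(tot_d),
        occupied_density_se=se(occ_d),
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    f_stat: float
    p_value: float
    df_resid: int
    n: int


def ols_regress(x: Iterable[float], y: Iterable[float]) -> RegressionResult:
    """Simple OLS of y on x with R^2 and the F(1, n-2) test."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need n >= 3 paired finite observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        adj_r_squared=float(model.rsquared_adj),
        f_stat=float(model.fvalue),
        p_value=float(model.f_pvalue),
        df_resid=int(model.df_resid),
        n=len(x),
    )


@dataclass(frozen=True)
class SaturationModel:
    asymptote: float = 30.0  # calls/min at saturation
    xmidpt: float = 15.0     # covariate value at half saturation
    scale: float = 1.0       # covariate change for half -> 3/4 saturation

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = np.clip((self.xmidpt - x) / self.scale, -500, 500)
        return self.asymptote / (1.0 + np.exp(z))


@dataclass(frozen=True)
class SaturationFit:
    model: SaturationModel
    aic: float
    linear: RegressionResult
    linear_aic: float
    converged: bool
    message: str = ""

    @property
    def delta_aic(self) -> float:
        """AIC(logistic) - AIC(linear); negative favors the logistic."""
        return self.aic - self.linear_aic


def _gaussian_aic(rss: float, n: int, k_mean_params: int) -> float:
    """AIC under iid Gaussian errors with sigma^2 profiled out.

    k counts the mean-function parameters plus one for sigma, so linear
    (2 + 1) and one-parameter logistic (1 + 1) fits are comparable.
    """
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * (k_mean_params + 1)


def fit_saturation(
    response: Iterable[float],
    rates: Iterable[float],
    asymptote: float = 30.0,
    xmidpt: float | None = 15.0,
    free_asymptote: bool = False,
) -> SaturationFit:
    """Fit the logistic saturation model rate ~ f(response) and compare to OLS.

    By default asymptote (30) and xmidpt (15) are fixed and only ``scale``
    is estimated by nonlinear least squares. Pass ``xmidpt=None`` to
    estimate the midpoint too (needed when the covariate is on an arbitrary
    scale), and ``free_asymptote=True`` for the fully free 3-parameter fit.
    Non-convergence is flagged in the result, never silently replaced.
    """
    x = np.asarray(list(response), dtype=float)
    y = np.asarray(list(rates), dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 nights")
    if y.min() < 0 or y.max() > asymptote + 1e-9:
        raise ValueError(f"rates must lie in [0, {asymptote}]")

    free_mid = xmidpt is None
    mid0 = float(np.median(x)) if free_mid else float(xmidpt)
    span = float(np.ptp(x)) or 1.0
    s0 = span / 10.0

    if free_asymptote:
        f = lambda x_, a, m, s: SaturationModel(a, m, s).predict(x_)
        p0, k = [asymptote, mid0, s0], 3
    elif free_mid:
        f = lambda x_, m, s: SaturationModel(asymptote, m, s).predict(x_)
        p0, k = [mid0, s0], 2
    else:
        f = lambda x_, s: SaturationModel(asymptote, mid0, s).predict(x_)
        p0, k = [s0], 1

    converged, message = True, ""
    try:
        popt, _ = optimize.curve_fit(f, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        converged, message, popt = False, str(exc), np.asarray(p0)
    if free_asymptote:
        model = SaturationModel(float(popt[0]), float(popt[1]), float(popt[2]))
    elif free_mid:
        model = SaturationModel(asymptote, float(popt[0]), float(popt[1]))
    else:
        model = SaturationModel(asymptote, mid0, float(popt[0]))

    rss = float(((y - model.predict(x)) ** 2).sum())
    aic = _gaussian_aic(rss, len(x), k)
    lin = ols_regress(x, y)
    lin_rss = float(((y - (lin.intercept + lin.slope * x)) ** 2).sum())
    lin_aic = _gaussian_aic(lin_rss, len(x), 2)
    return SaturationFit(model=model, aic=aic, linear=lin, linear_aic=lin_aic,
                         converged=converged, message=message)


def saturation_contingency(
    group_a_rates: Iterable[float],
    group_b_rates: Iterable[float],
    cutoff: float = 20.0,
) -> tuple[float, float]:
    """2x2 chi-square of saturated (rate >= cutoff) vs not, by group.

    Pearson chi-square without continuity correction (sum (O-E)^2/E).
    """
    a = np.asarray(list(group_a_rates), dtype=float)
    b = np.asarray(list(group_b_rates), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    table = np.array([
        [(a >= cutoff).sum(), (a < cutoff).sum()],
        [(b >= cutoff).sum(), (b < cutoff).sum()],
    ])
    if (table.sum(axis=0) == 0).any():
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq < 1).any():
        import warnings

        warnings.warn("chi-square expected cell count < 1")
    return float(res.statistic), float(res.pvalue)


def rank_test(
    group_a: Iterable[float],
    group_b: Iterable[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U): exact for small tie-free samples,
    normal approximation with tie correction otherwise."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(a) <= 10 and len(b) <= 10
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def comparison_table(rows: list[dict], path=None) -> pd.DataFrame:
    """Tidy comparison-results table (comparison, R2, adj R2, F, p, df)."""
    df = pd.DataFrame(rows, columns=["comparison", "r_squared", "adj_r_squared",
                                     "f_stat", "p_value", "df_resid"])
    if path is not None:
        df.to_csv(path, index=False)
    return df
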