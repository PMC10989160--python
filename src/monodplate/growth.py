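"""Growth-rate extraction and the zero-growth gate.

A well's specific growth rate over each consecutive pair of time points is
the log-ratio rate

    r_i = ln(F_{i+1} / F_i) / (t_{i+1} - t_i)        [day^-1]

The maximum realized growth rate of a well is estimated as the mean of its
five largest interval rates ("top-five" statistic), with a standard error
SD/sqrt(k).  A treatment is classified as truly growing only when its pooled
log-fluorescence slope exceeds the media-control slope significantly
(interaction t-test in a pooled linear model ln F ~ time x side): this gate
separates real exponential increase from spurious fluorescence spikes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, SingularFitError
from .plate import PlateSet, WellSeries

__all__ = [
    "RateSeries",
    "GateResult",
    "pointwise_rates",
    "top_k_rate",
    "classify_growth",
    "estimate_growth",
    "min_growth_concentration",
]

#: Floor applied to fluorescence after optional control-baseline subtraction.
BASELINE_FLOOR_RFU = 1e-3


@dataclass
class RateSeries:
    """Per-interval log-ratio growth rates for one well."""

    well_id: str
    interval_midpoints: np.ndarray  # days
    rates: np.ndarray  # day^-1; negative values allowed


@dataclass
class GateResult:
    """Outcome of the zero-growth gate for one treatment."""

    growth_flag: bool
    p_slope: float
    slope_treatment: float
    slope_control: float
    t_stat: float
    df: int


def pointwise_rates(series: WellSeries) -> RateSeries:
    """Log-ratio growth rate over every consecutive time-point pair."""
    if series.n_points < 2:
        raise InsufficientDataError(
            f"well {series.well_id}: need >= 2 points for interval rates"
        )
    t = series.times
    f = series.fluorescence
    rates = np.diff(np.log(f)) / np.diff(t)
    mid = (t[:-1] + t[1:]) / 2.0
    return RateSeries(series.well_id, mid, rates)


def top_k_rate(rates: RateSeries | np.ndarray, k: int = 5) -> tuple[float, float, int]:
    """Mean and SE of the ``k`` largest interval rates.

    Returns ``(mu_hat, se, k_used)``.  If fewer than ``k`` rates are
    available all of them are used and ``k_used`` records the count.  The SE
    is the sample standard deviation of the selected rates divided by
    sqrt(k_used) (0 when only one rate is available).  Ties at the k-th
    largest rate are broken by interval order (stable descending sort).
    """
    r = rates.rates if isinstance(rates, RateSeries) else np.asarray(rates, float)
    if r.size == 0:
        raise InsufficientDataError("empty rate series")
    k_used = min(int(k), r.size)
    # stable sort on -r keeps earlier intervals first among ties
    top = r[np.argsort(-r, kind="stable")[:k_used]]
    mu_hat = float(np.mean(top))
    se = float(np.std(top, ddof=1) / np.sqrt(k_used)) if k_used > 1 else 0.0
    return mu_hat, se, k_used


def _pool_log_points(wells: Iterable[WellSeries]) -> tuple[np.ndarray, np.ndarray]:
    ts, ys = [], []
    for w in wells:
        ts.append(w.times)
        ys.append(np.log(w.fluorescence))
    if not ts:
        raise InsufficientDataError("no wells supplied to the gate")
    return np.concatenate(ts), np.concatenate(ys)


def _ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int]:
    """Return (slope, intercept, residual SS, n) of y ~ t."""
    n = t.size
    sxx = float(np.sum((t - t.mean()) ** 2))
    if sxx <= 0:
        raise SingularFitError("all time points identical; slope is undefined")
    slope = float(np.sum((t - t.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * t.mean())
    resid = y - (intercept + slope * t)
    return slope, intercept, float(np.sum(resid**2)), n


def classify_growth(
    treatment_wells: Sequence[WellSeries],
    control_wells: Sequence[WellSeries],
    alpha: float = 0.05,
) -> GateResult:
    """Zero-growth gate: does the treatment's ln(F) slope exceed the control's?

    Points are pooled across wells within each side, ln-transformed, and fit
    to straight lines in time.  The slope difference is tested with the
    pooled-error t statistic (equivalent to the interaction coefficient of
    ln F ~ time * side), df = n1 + n2 - 4, two-sided p.  The treatment is
    flagged as growing only when the difference is significant *and* the
    treatment slope is the larger one — a significantly declining signal is
    not growth.
    """
    t1, y1 = _pool_log_points(treatment_wells)
    t0, y0 = _pool_log_points(control_wells)
    b1, _, rss1, n1 = _ols_slope(t1, y1)
    b0, _, rss0, n0 = _ols_slope(t0, y0)
    df = n1 + n0 - 4
    if df <= 0:
        raise InsufficientDataError("gate needs more than 4 pooled points")
    s2 = (rss1 + rss0) / df
    sxx1 = float(np.sum((t1 - t1.mean()) ** 2))
    sxx0 = float(np.sum((t0 - t0.mean()) ** 2))
    se_diff = np.sqrt(s2 * (1.0 / sxx1 + 1.0 / sxx0))
    if se_diff == 0:
        # noiseless degenerate case: identical slopes -> p = 1, else p = 0
        tstat = 0.0 if b1 == b0 else np.inf * np.sign(b1 - b0)
        p = 1.0 if b1 == b0 else 0.0
    else:
        tstat = (b1 - b0) / se_diff
        p = 2.0 * float(stats.t.sf(abs(tstat), df))
    flag = bool(p < alpha and b1 > b0)
    return GateResult(flag, float(p), b1, b0, float(tstat), df)


def _subtract_baseline(
    wells: Sequence[WellSeries], controls: Sequence[WellSeries]
) -> list[WellSeries]:
    """Subtract the time-matched mean control signal, flooring at a small
    positive epsilon so log-rates stay defined."""
    if not controls:
        return list(wells)
    # mean control value per time point (times assumed shared across wells)
    ctrl_t = controls[0].times
    ctrl_mean = np.mean([c.fluorescence for c in controls], axis=0)
    out = []
    for w in wells:
        base = np.interp(w.times, ctrl_t, ctrl_mean)
        f = np.maximum(w.fluorescence - base, BASELINE_FLOOR_RFU)
        out.append(
            WellSeries(
                w.well_id, w.strain, w.state, w.nutrient, w.concentration,
                w.replicate, w.is_control, w.times, f,
            )
        )
    return out


def estimate_growth(
    plate: PlateSet,
    k: int = 5,
    alpha: float = 0.05,
    subtract_control_baseline: bool = False,
    aggregate: str = "per_well",
) -> pd.DataFrame:
    """Growth estimates for every treatment on a plate.

    The top-k statistic is computed per well (per replicate) by default, or
    from the pooled interval rates of all replicates when
    ``aggregate="per_treatment"``.  The zero-growth gate always pools the
    replicate wells of a treatment against the plate's media controls, and
    its verdict is attached to every replicate row of that treatment.

    Returns a table with columns strain, state, nutrient, concentration,
    replicate, mu_hat, se, k_used, p_slope, growth_flag.
    """
    if aggregate not in ("per_well", "per_treatment"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    controls = plate.control_wells
    treatments = plate.treatment_wells
    if subtract_control_baseline:
        treatments = _subtract_baseline(treatments, controls)

    groups: dict[tuple[str, str, float], list[WellSeries]] = {}
    for w in treatments:
        groups.setdefault((w.strain, w.state, float(w.concentration)), []).append(w)

    rows = []
    for (strain, state, conc), wells in sorted(groups.items()):
        if controls:
            gate = classify_growth(wells, controls, alpha=alpha)
            p_slope, flag = gate.p_slope, gate.growth_flag
        else:
            warnings.warn(
                "no control wells on plate; zero-growth gate skipped",
                stacklevel=2,
            )
            p_slope, flag = np.nan, True
        if aggregate == "per_well":
            for w in sorted(wells, key=lambda w: w.replicate):
                mu, se, k_used = top_k_rate(pointwise_rates(w), k=k)
                rows.append(
                    dict(
                        strain=strain, state=state, nutrient=plate.nutrient_assayed,
                        concentration=conc, replicate=w.replicate, mu_hat=mu,
                        se=se, k_used=k_used, p_slope=p_slope, growth_flag=flag,
                    )
                )
        else:
            pooled = np.concatenate([pointwise_rates(w).rates for w in wells])
            mu, se, k_used = top_k_rate(pooled, k=k)
            rows.append(
                dict(
                    strain=strain, state=state, nutrient=plate.nutrient_assayed,
                    concentration=conc, replicate=0, mu_hat=mu, se=se,
                    k_used=k_used, p_slope=p_slope, growth_flag=flag,
                )
            )
    return pd.DataFrame(rows)


def min_growth_concentration(estimates: pd.DataFrame) -> float | None:
    """Lowest tested concentration whose treatment passed the growth gate.

    ``estimates`` holds one strain x state x nutrient group (replicate rows
    share the pooled gate verdict).  Returns ``None`` when no concentration
    supports growth.
    """
    if estimates.empty:
        return None
    flags = estimates.groupby("concentration")["growth_flag"].all()
    growing = flags[flags].index
    return float(growing.min()) if len(growing) else None
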