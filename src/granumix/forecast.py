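"""ARIMA time-to-endpoint forecasting of the segregation index.

Fits ARIMA(p, d, q) models by maximum likelihood (statsmodels), selects the
order by AIC over a (p, d, q) grid — by default a stepwise expansion in p
with an early stop, optionally exhaustive — validates by a half-split
(train on the first half of the series, forecast the second), and forecasts
the time of first crossing of the uniform-mixing cutoff (psi = 1.1 by
default), with 95% prediction-interval crossing bounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from statsmodels.tsa.arima.model import ARIMA

logger = logging.getLogger(__name__)

__all__ = ["ArimaOrder", "FittedArima", "EndpointEstimate", "HalfSplitReport",
           "SeriesTooShortError", "NoConvergedModelError", "fit_arima",
           "select_order_aic", "validate_half_split", "forecast_to_cutoff",
           "rank_key"]


class SeriesTooShortError(ValueError):
    """Series too short for the requested order."""


class NoConvergedModelError(RuntimeError):
    """No candidate order produced a converged fit."""

    def __init__(self, attempted: list):
        super().__init__(
            f"no ARIMA order converged; attempted {len(attempted)} orders: "
            f"{attempted}")
        self.attempted = attempted


@dataclass(frozen=True)
class ArimaOrder:
    p: int
    d: int
    q: int

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 100):
            raise ValueError("p must lie in [0, 100]")
        if not (0 <= self.d <= 2):
            raise ValueError("d must lie in [0, 2]")
        if not (0 <= self.q <= 2):
            raise ValueError("q must lie in [0, 2]")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)


@dataclass
class FittedArima:
    """One MLE fit; ``aic`` always satisfies aic = 2 k - 2 loglik."""

    order: ArimaOrder
    coefficients: np.ndarray
    log_likelihood: float
    aic: float
    converged: bool
    n_params: int
    n_obs: int
    degenerate: bool = False
    trend: str = "n"
    result: Any = field(default=None, repr=False, compare=False)


def fit_arima(series: Sequence[float], order: ArimaOrder | tuple[int, int, int],
              trend: str | None = None) -> FittedArima:
    """MLE fit of ARIMA(p, d, q).

    ``trend`` defaults to the Box-Jenkins convention: a constant level for
    d = 0 and no deterministic term once the series is differenced (pass
    ``trend="t"`` explicitly for a drift model).  Non-convergence and
    numerical failure are flagged on the returned object
    (``converged=False``, aic = inf), never silently hidden.
    """
    if not isinstance(order, ArimaOrder):
        order = ArimaOrder(*order)
    y = np.asarray(series, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    if len(y) <= order.p + order.d + order.q + 1:
        raise SeriesTooShortError(
            f"series length {len(y)} insufficient for order "
            f"{order.as_tuple()}")
    if trend is None:
        trend = "c" if order.d == 0 else "n"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ARIMA(y, order=order.as_tuple(), trend=trend)
            res = model.fit()
        converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
        llf = float(res.llf)
        k = len(res.params)
        sigma2 = float(res.params[-1]) if k else 0.0
        degenerate = sigma2 <= 1e-10 * max(float(np.var(y)), 1e-12)
        if not np.isfinite(llf):
            converged = False
        return FittedArima(order=order, coefficients=np.asarray(res.params),
                           log_likelihood=llf,
                           aic=2.0 * k - 2.0 * llf if np.isfinite(llf) else np.inf,
                           converged=converged, n_params=k, n_obs=len(y),
                           degenerate=degenerate, trend=trend, result=res)
    except (np.linalg.LinAlgError, ValueError, IndexError) as err:
        logger.debug("ARIMA%s failed: %s", order.as_tuple(), err)
        return FittedArima(order=order, coefficients=np.empty(0),
                           log_likelihood=-np.inf, aic=np.inf,
                           converged=False, n_params=0, n_obs=len(y),
                           trend=trend)


def rank_key(fit: FittedArima) -> tuple[float, int, int]:
    """AIC, then parsimony tie-breaks: lower p + q, then lower p."""
    return (fit.aic, fit.order.p + fit.order.q, fit.order.p)


def select_order_aic(series: Sequence[float], p_max: int = 100,
                     d_max: int = 2, q_max: int = 2, *,
                     stepwise: bool = True, patience: int = 10,
                     ) -> FittedArima:
    """Best converged fit by AIC over the (p, d, q) grid.

    In stepwise mode (the default) each (d, q) line expands p from 0 and
    stops after ``patience`` consecutive fits without an AIC improvement;
    ``stepwise=False`` restores the exhaustive grid.  For d = 1 both the
    no-constant and the drift model are candidates, compared by AIC like
    any other pair of models.  Ties break toward parsimony (lower p + q,
    then lower p).
    """
    y = np.asarray(series, float)
    fits: list[FittedArima] = []
    attempted: list[tuple[int, int, int]] = []
    for d in range(d_max + 1):
        trends = ("n", "t") if d == 1 else (None,)
        for q in range(q_max + 1):
            for trend in trends:
                best_line = np.inf
                stale = 0
                for p in range(p_max + 1):
                    try:
                        f = fit_arima(y, ArimaOrder(p, d, q), trend=trend)
                    except SeriesTooShortError:
                        break
                    attempted.append((p, d, q))
                    fits.append(f)
                    if stepwise:
                        if f.converged and f.aic < best_line - 1e-9:
                            best_line = f.aic
                            stale = 0
                        else:
                            stale += 1
                            if stale >= patience:
                                break
    converged = [f for f in fits if f.converged]
    if not converged:
        raise NoConvergedModelError(attempted)
    best = min(converged, key=rank_key)
    logger.info("AIC selection over %d orders -> ARIMA%s (aic=%.3f)",
                len(attempted), best.order.as_tuple(), best.aic)
    best.search_log = [(f.order.as_tuple(), f.aic, f.converged) for f in fits]
    return best


def forecast_path(fit: FittedArima, steps: int) -> np.ndarray:
    """Mean forecast of ``steps`` future points; 0 steps is an empty path
    and leaves the fitted state untouched."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if steps == 0:
        return np.empty(0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(fit.result.forecast(steps=steps))


@dataclass
class HalfSplitReport:
    mape: float       # mean absolute percentage error, %
    max_ape: float    # maximum absolute percentage error, %
    fit: FittedArima
    n_train: int
    n_test: int


def validate_half_split(series: Sequence[float], **select_kwargs,
                        ) -> HalfSplitReport:
    """Train on the first half, forecast the second, report MAPE (%).

    This is the standard check that the model family can extrapolate the
    transient: order selection and fitting see only the first half.
    """
    y = np.asarray(series, float)
    if len(y) < 20:
        raise SeriesTooShortError("half-split validation needs >= 20 points")
    n_train = len(y) // 2
    train, test = y[:n_train], y[n_train:]
    fit = select_order_aic(train, **select_kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = np.asarray(fit.result.forecast(steps=len(test)))
    ape = 100.0 * np.abs(pred - test) / np.abs(test)
    return HalfSplitReport(mape=float(np.mean(ape)), max_ape=float(np.max(ape)),
                           fit=fit, n_train=n_train, n_test=len(test))


@dataclass
class EndpointEstimate:
    """First crossing of the mixing cutoff, observed or forecast."""

    cutoff_psi: float
    t_end: float | None
    crossed_in_observed: bool
    no_crossing: bool
    t_early: float | None = None     # 95% PI lower-bound crossing
    t_late: float | None = None      # 95% PI upper-bound crossing
    forecast_times: np.ndarray | None = None
    forecast_mean: np.ndarray | None = None
    order: tuple[int, int, int] | None = None
    aic: float | None = None
    horizon_cap: int | None = None

    def as_dict(self) -> dict:
        return {"cutoff_psi": self.cutoff_psi, "t_end": self.t_end,
                "crossed_in_observed": self.crossed_in_observed,
                "no_crossing": self.no_crossing,
                "t_early": self.t_early, "t_late": self.t_late,
                "order": list(self.order) if self.order else None,
                "aic": self.aic, "horizon_cap": self.horizon_cap}


def _first_crossing(times: np.ndarray, values: np.ndarray, cutoff: float,
                    ) -> float | None:
    """Linearly interpolated time of first descent to <= cutoff."""
    below = np.nonzero(values <= cutoff)[0]
    if len(below) == 0:
        return None
    i = int(below[0])
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    if v0 == v1:
        return float(t1)
    return float(t0 + (t1 - t0) * (v0 - cutoff) / (v0 - v1))


def forecast_to_cutoff(times: Sequence[float], psi: Sequence[float],
                       cutoff: float = 1.1, horizon_cap: int | None = None,
                       alpha: float = 0.05, **select_kwargs,
                       ) -> EndpointEstimate:
    """Forecast the first time psi reaches the uniform-mixing cutoff.

    If the observed series already crosses, the observed (interpolated)
    crossing is returned with ``crossed_in_observed`` set and no model is
    fit.  Otherwise the AIC-selected ARIMA is extrapolated up to
    ``horizon_cap`` steps (default 100x the training length); absence of a
    crossing within the cap is reported explicitly, never fabricated.
    """
    t = np.asarray(times, float)
    y = np.asarray(psi, float)
    if cutoff <= 1.0:
        raise ValueError("cutoff must exceed 1 (the random-mixing asymptote)")
    if len(t) != len(y):
        raise ValueError("times and psi must have equal length")
    observed = _first_crossing(t, y, cutoff)
    if observed is not None:
        return EndpointEstimate(cutoff_psi=cutoff, t_end=observed,
                                crossed_in_observed=True, no_crossing=False)
    if horizon_cap is None:
        horizon_cap = 100 * len(y)
    dt = float(np.median(np.diff(t)))
    fit = select_order_aic(y, **select_kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fc = fit.result.get_forecast(steps=horizon_cap)
        mean = np.asarray(fc.predicted_mean)
        ci = np.asarray(fc.conf_int(alpha=alpha))
    ft = t[-1] + dt * np.arange(1, horizon_cap + 1)
    t_end = _first_crossing(ft, mean, cutoff)
    t_early = _first_crossing(ft, ci[:, 0], cutoff)
    t_late = _first_crossing(ft, ci[:, 1], cutoff)
    return EndpointEstimate(
        cutoff_psi=cutoff, t_end=t_end, crossed_in_observed=False,
        no_crossing=t_end is None, t_early=t_early, t_late=t_late,
        forecast_times=ft, forecast_mean=mean,
        order=fit.order.as_tuple(), aic=fit.aic, horizon_cap=horizon_cap)
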