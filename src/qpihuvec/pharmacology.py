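"""Concentration–response fitting and normalisation.

The model is the three-parameter logistic with unit Hill slope,

    Y = Bottom + (Top - Bottom) / (10**(LogEC50 - X) + 1),

where X is the log10 molar concentration and Top/Bottom the response
plateaus. Potency is reported as pEC50 = -LogEC50 and efficacy as the span
Top - Bottom. Fitting is unweighted nonlinear least squares on well-level
replicates; condition summaries aggregate per-experiment fits as
mean ± SEM, so the experiment is the statistical unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .phantoms import logistic3

_RESTART_JITTERS = (0.0, 1.0, -1.0, 0.5, -0.5)  # log-units on the LogEC50 start


@dataclass
class LogisticFit:
    """A fitted three-parameter logistic.

    ``se`` holds per-parameter standard errors from the Jacobian at the
    optimum (keys ``top``, ``bottom``, ``log_ec50``, ``span``); they are
    infinite when a parameter is unidentifiable (e.g. flat data).
    """

    top: float
    bottom: float
    log_ec50: float
    se: dict
    converged: bool
    rss: float
    n_points: int

    @property
    def span(self) -> float:
        return self.top - self.bottom

    @property
    def pec50(self) -> float:
        return -self.log_ec50

    def predict(self, x):
        return logistic3(x, self.top, self.bottom, self.log_ec50)


def _as_xy(table) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(table, pd.DataFrame):
        x = table["x"].to_numpy(dtype=float)
        y = table["y"].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in table)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("concentration-response data must be finite")
    return x, y


def fit_3pl(table) -> LogisticFit:
    """Fit the three-parameter logistic to a dose-response table.

    ``table`` is a DataFrame with columns ``x`` (log10 molar) and ``y``
    (response), or an ``(x, y)`` pair of arrays; replicates appear as repeated
    x values. Requires at least 3 distinct concentrations. The fit is
    parameterised as (bottom, span, log_ec50) with span ≥ 0, so Top ≥ Bottom
    by construction; up to five restarts jitter the initial LogEC50 by ±1
    log-unit before the fit is declared non-converged.
    """
    x, y = _as_xy(table)
    if len(np.unique(x)) < 3:
        raise ValueError(
            f"need at least 3 distinct concentrations, got {len(np.unique(x))}")

    b0 = float(y.min())
    s0 = max(float(y.max() - y.min()), 1e-12)
    half = b0 + 0.5 * s0
    lec0 = float(x[np.argmin(np.abs(y - half))])

    def residuals(p):
        bottom, span, lec = p
        return logistic3(x, bottom + span, bottom, lec) - y

    best = None
    for jit in _RESTART_JITTERS:
        try:
            res = least_squares(residuals, x0=[b0, s0, lec0 + jit],
                                bounds=([-np.inf, 0.0, -np.inf],
                                        [np.inf, np.inf, np.inf]),
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost - 1e-15):
            best = res
        if best is not None and jit == 0.0 and best.success:
            # accept the default start unless it failed
            break

    if best is None:
        return LogisticFit(top=float("nan"), bottom=float("nan"),
                           log_ec50=float("nan"),
                           se={k: float("inf") for k in ("top", "bottom", "log_ec50", "span")},
                           converged=False, rss=float("nan"), n_points=len(x))

    bottom, span, lec = best.x
    rss = float(2.0 * best.cost)
    dof = max(len(x) - 3, 1)
    J = best.jac
    JTJ = J.T @ J
    se = {}
    converged = bool(best.success)
    try:
        cov = np.linalg.inv(JTJ) * (rss / dof)
        var_b, var_s = cov[0, 0], cov[1, 1]
        se = {
            "bottom": math.sqrt(max(var_b, 0.0)),
            "span": math.sqrt(max(var_s, 0.0)),
            "top": math.sqrt(max(var_b + var_s + 2.0 * cov[0, 1], 0.0)),
            "log_ec50": math.sqrt(max(cov[2, 2], 0.0)),
        }
    except np.linalg.LinAlgError:
        se = {k: float("inf") for k in ("top", "bottom", "log_ec50", "span")}
        converged = False
    if span <= 1e-10:
        # flat response: the midpoint is unidentifiable
        se["log_ec50"] = float("inf")
        converged = False
    return LogisticFit(top=float(bottom + span), bottom=float(bottom),
                       log_ec50=float(lec), se=se, converged=converged,
                       rss=rss, n_points=len(x))


def fit_by_experiment(table: pd.DataFrame) -> list[LogisticFit]:
    """Fit each experiment in a tidy table separately.

    ``table`` needs columns ``x``, ``y`` and ``experiment_id``; replicate
    wells within an experiment are pooled into one unweighted fit.
    """
    return [fit_3pl(sub) for _, sub in table.groupby("experiment_id", sort=True)]


def derive_potency_table(fits: Mapping[str, Sequence[LogisticFit]]) -> pd.DataFrame:
    """Summarise per-experiment fits into a potency/efficacy table.

    One row per condition: mean ± SEM of pEC50 and span over experiment-level
    fits, and the experiment count n. With a single experiment the SEMs are
    NaN (undefined, flagged by ``single_experiment``).
    """
    rows = []
    for condition, cond_fits in fits.items():
        cond_fits = list(cond_fits)
        if not cond_fits:
            raise ValueError(f"condition {condition!r} has no fits")
        pec = np.array([f.pec50 for f in cond_fits], dtype=float)
        spans = np.array([f.span for f in cond_fits], dtype=float)
        n = len(cond_fits)

        def sem(v):
            return float(v.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")

        rows.append({
            "condition": condition,
            "pec50": float(pec.mean()),
            "pec50_sem": sem(pec),
            "n": n,
            "span": float(spans.mean()),
            "span_sem": sem(spans),
            "n_converged": sum(f.converged for f in cond_fits),
            "single_experiment": n == 1,
        })
    return pd.DataFrame(rows)


def normalize_to_vehicle(values, vehicle_values) -> np.ndarray:
    """Express responses as a percentage of the mean vehicle response.

    Vehicle wells average to 100% by construction. A non-positive vehicle
    mean is rejected (the normalisation would be meaningless).
    """
    values = np.asarray(values, dtype=float)
    ref = float(np.mean(np.asarray(vehicle_values, dtype=float)))
    if ref <= 0:
        raise ValueError(f"vehicle mean must be positive, got {ref}")
    return 100.0 * values / ref


def percent_of_baseline(series: pd.DataFrame, baseline_time_h: float = 0.0,
                        time_col: str = "time_h",
                        value_col: str = "value") -> pd.DataFrame:
    """Express a metric time series as a percentage of its baseline value.

    Returns the input with an added ``percent`` column; the baseline row is
    100%. A zero baseline yields NaN percentages (undefined, not infinite).
    """
    if baseline_time_h not in set(series[time_col]):
        raise ValueError(f"no entry at baseline time {baseline_time_h} h")
    base = float(series.loc[series[time_col] == baseline_time_h, value_col].mean())
    out = series.copy()
    out["percent"] = 100.0 * out[value_col] / base if base != 0 else float("nan")
    return out
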