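"""Hermia's four dead-end blocking laws: closed forms, linearization, fitting.

Under constant pressure the dead-end blocking family is
``-dJ/dt = K J^(3-n)`` with blocking index ``n`` (2 complete, 1.5 standard,
1 intermediate, 0 cake).  The integrated forms and their linearizations are

==============  ==========================  =====================  ==========
mechanism       J(t)                        linear form            K = f(slope)
==============  ==========================  =====================  ==========
complete        Jo·e^(−Kb·t)                ln J  = −Kb·t + ln Jo  −slope
intermediate    Jo/(1+Ki·Jo·t)              1/J   =  Ki·t + 1/Jo    slope
standard        Jo/(1+(Ks·Jo/2)·t)²         t/v   = (Ks/2)·t + 1/Jo 2·slope
cake            Jo/√(1+2·Kc·Jo²·t)          t/v   = (Kc/2)·v + 1/Jo 2·slope
==============  ==========================  =====================  ==========

Mechanism attribution compares the coefficient of determination R² of these
ordinary least-squares fits; the slope sign is a validity diagnostic (a flux
series that is not declining produces a slope with the wrong sign, which
contradicts the physical model even when R² is high).
"""

from __future__ import annotations

import logging

import numpy as np

from .exceptions import FittingError, ValidationError
from .flux import FluxSeries, Mechanism
from .results import FitResult, ols_line

logger = logging.getLogger("foulfit")

__all__ = [
    "deadend_flux",
    "deadend_volume",
    "linearize_deadend",
    "fit_deadend",
    "predict_deadend",
]


def deadend_flux(mechanism: Mechanism, t, jo: float, k: float) -> np.ndarray:
    """Closed-form J(t) (L·m⁻²·h⁻¹) for a dead-end blocking law."""
    t = np.asarray(t, dtype=float)
    m = Mechanism.from_name(mechanism)
    if m is Mechanism.COMPLETE:
        return jo * np.exp(-k * t)
    if m is Mechanism.INTERMEDIATE:
        return jo / (1.0 + k * jo * t)
    if m is Mechanism.STANDARD:
        return jo / (1.0 + 0.5 * k * jo * t) ** 2
    return jo / np.sqrt(1.0 + 2.0 * k * jo**2 * t)


def deadend_volume(mechanism: Mechanism, t, jo: float, k: float) -> np.ndarray:
    """Exact cumulative per-area volume v(t) = ∫₀ᵗ J for a dead-end law."""
    t = np.asarray(t, dtype=float)
    m = Mechanism.from_name(mechanism)
    if m is Mechanism.COMPLETE:
        return jo * -np.expm1(-k * t) / k
    if m is Mechanism.INTERMEDIATE:
        return np.log1p(k * jo * t) / k
    if m is Mechanism.STANDARD:
        return jo * t / (1.0 + 0.5 * k * jo * t)
    return (np.sqrt(1.0 + 2.0 * k * jo**2 * t) - 1.0) / (k * jo)


def linearize_deadend(series: FluxSeries, mechanism) -> tuple[np.ndarray, np.ndarray]:
    """Transformed (x, y) points for the linearized dead-end form.

    complete: (t, ln J); intermediate: (t, 1/J); standard: (t, t/v);
    cake: (v, t/v).  Points with t ≤ 0 (and v ≤ 0 for the volume-based
    transforms) are excluded.
    """
    m = Mechanism.from_name(mechanism)
    t, j, v = series.times, series.flux, series.v
    usable = t > 0
    if m in (Mechanism.STANDARD, Mechanism.CAKE):
        usable &= v > 0
    dropped = int((~usable).sum())
    if dropped:
        logger.info(
            "%s/%s: excluded %d point(s) with t<=0 or v<=0 from linearization",
            series.stage_label or "series", m.value, dropped,
        )
    t, j, v = t[usable], j[usable], v[usable]
    if t.size < 3:
        raise FittingError(
            f"need >=3 usable points for {m.value} linearization, have {t.size}"
        )
    if m is Mechanism.COMPLETE:
        return t, np.log(j)
    if m is Mechanism.INTERMEDIATE:
        return t, 1.0 / j
    if m is Mechanism.STANDARD:
        return t, t / v
    return v, t / v


_SLOPE_SIGN = {  # sign the model form requires of the fitted slope
    Mechanism.COMPLETE: -1.0,
    Mechanism.INTERMEDIATE: +1.0,
    Mechanism.STANDARD: +1.0,
    Mechanism.CAKE: +1.0,
}

_K_FROM_SLOPE = {
    Mechanism.COMPLETE: lambda s: -s,
    Mechanism.INTERMEDIATE: lambda s: s,
    Mechanism.STANDARD: lambda s: 2.0 * s,
    Mechanism.CAKE: lambda s: 2.0 * s,
}


def _jo_from_intercept(mechanism: Mechanism, intercept: float) -> float:
    if mechanism is Mechanism.COMPLETE:
        return float(np.exp(intercept))
    return 1.0 / intercept if intercept > 0 else float("nan")


def fit_deadend(series: FluxSeries, mechanism) -> FitResult:
    """Ordinary least squares on the linearized dead-end form.

    Returns a :class:`FitResult` with the blocking constant extracted from
    the slope, the intercept-implied initial flux, the linearized R², the
    slope-sign validity flag and the flux-space reconstruction RMSE.
    """
    m = Mechanism.from_name(mechanism)
    x, y = linearize_deadend(series, m)
    slope, intercept, r2 = ols_line(x, y)
    k = _K_FROM_SLOPE[m](slope)
    jo_fit = _jo_from_intercept(m, intercept)
    valid = bool(_SLOPE_SIGN[m] * slope > 0)
    if not valid:
        logger.info(
            "%s/%s dead-end fit: slope %.3g contradicts the model's required sign",
            series.stage_label or "series", m.value, slope,
        )
    fit = FitResult(
        mechanism=m,
        family="dead_end",
        K=float(k),
        Jo_fit=float(jo_fit),
        JR_fit=0.0,
        r2=float(r2),
        slope_sign_valid=valid,
        slope=float(slope),
        intercept=float(intercept),
        n_points=int(x.size),
        stage_label=series.stage_label,
        t_end=float(series.times[-1]),
    )
    fit.rmse_flux = _rmse(fit, series)
    return fit


def _rmse(fit: FitResult, series: FluxSeries) -> float:
    try:
        pred = deadend_flux(fit.mechanism, series.times, fit.Jo_fit, fit.K)
    except (FloatingPointError, ZeroDivisionError):
        return float("inf")
    if not np.all(np.isfinite(pred)):
        return float("inf")
    return float(np.sqrt(np.mean((pred - series.flux) ** 2)))


def predict_deadend(fit: FitResult, time_grid) -> FluxSeries:
    """Reconstruct the fitted flux-decline curve on ``time_grid`` (h)."""
    if fit.family != "dead_end":
        raise ValidationError("predict_deadend requires a dead-end fit")
    t = np.asarray(time_grid, dtype=float)
    j = deadend_flux(fit.mechanism, t, fit.Jo_fit, fit.K)
    v = deadend_volume(fit.mechanism, t, fit.Jo_fit, fit.K)
    return FluxSeries(times=t, flux=j, v=v, stage_label=fit.stage_label)
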