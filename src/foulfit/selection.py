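"""Mechanism attribution: rank blocking-law fits per stage and family.

All four mechanisms of a family are fitted to the stage's flux series and
ranked by the linearized R² (ties broken by lower flux-space RMSE) — the
order in which published blocking-law tables are read.  Fits whose slope
sign contradicts the model form, or whose implied removal flux had to be
clamped, are excluded from the "best valid" verdict — the regression then
rules the mechanism out rather than supporting it.

The verdict itself (``best_valid``) is decided by the flux-reconstruction
error, not by the linearized R².  The four linearizations propagate
measurement noise very differently (the cumulative t/v transforms average
noise away, the point-wise ln J and 1/J transforms do not), so R² values are
only comparable across mechanisms on noise-free data; on measured data a
mechanism can post R² ≈ 0.999 while its reconstructed flux curve is far from
the observations.  Among the physically admissible fits, the mechanism whose
re-integrated flux curve tracks the data best (lowest RMSE) is selected.

For crossflow fits with JR > 0, a dominance window [0, t*] estimates over
which initial period the mechanism actively shapes the flux decline: t* is
the first time the predicted flux comes within a threshold fraction (default
5%) of the steady-state flux JR, after which the decline is spent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .crossflow import fit_crossflow, ode_rate
from .deadend import fit_deadend
from .exceptions import FittingError, SolverError, ValidationError
from .flux import FluxSeries, Mechanism, _validate_family
from .results import FitResult

logger = logging.getLogger("foulfit")

__all__ = ["DominanceWindow", "MechanismReport", "rank_mechanisms",
           "dominance_window"]


@dataclass(frozen=True)
class DominanceWindow:
    """Time interval [start, end] (h) over which a mechanism dominates."""

    start: float
    end: float
    reached: bool       # predicted flux actually reached (1+threshold)·JR
    full_series: bool   # JR≈0: no steady state, window spans the whole series
    threshold: float


def dominance_window(
    fit: FitResult, threshold_fraction: float = 0.05, t_max: float | None = None
) -> DominanceWindow:
    """First time the predicted flux decays to within ``threshold`` of JR.

    Returns [0, t*] with t* the first time J(t) ≤ (1+threshold)·JR under the
    fitted crossflow law.  If the target is never reached before ``t_max``
    (default: the fitted series' last sample time), the window runs to
    ``t_max``; a fit with JR≈0 has no steady state and is flagged as spanning
    the full series.
    """
    if fit.family != "crossflow":
        raise ValidationError("dominance_window requires a crossflow fit")
    if threshold_fraction < 0:
        raise ValidationError("threshold_fraction must be >= 0")
    if t_max is None:
        t_max = fit.t_end
    if not np.isfinite(t_max):
        raise ValidationError("t_max is required when the fit carries no series end")
    jr, jo, k = fit.JR_fit, fit.Jo_fit, fit.K
    # a fitted JR at numerical-zero scale means no steady state is attained
    if jr <= 1e-6 * jo:
        return DominanceWindow(0.0, float(t_max), reached=False, full_series=True,
                               threshold=threshold_fraction)
    target = (1.0 + threshold_fraction) * jr
    if target >= jo:
        return DominanceWindow(0.0, fit.t_ref, reached=True, full_series=False,
                               threshold=threshold_fraction)
    m = fit.mechanism
    if m is Mechanism.COMPLETE:
        t_star = fit.t_ref + math.log((jo - jr) / (threshold_fraction * jr)) / k
    elif m is Mechanism.INTERMEDIATE:
        c = (jo - jr) / jo
        t_star = fit.t_ref + math.log(
            c * (1.0 + threshold_fraction) / threshold_fraction
        ) / (k * jr)
    else:
        t_star = _crossing_time_ode(m, jo, k, jr, target, fit.t_ref, float(t_max))
    if t_star is None or t_star > t_max:
        return DominanceWindow(0.0, float(t_max), reached=False, full_series=False,
                               threshold=threshold_fraction)
    return DominanceWindow(0.0, float(t_star), reached=True, full_series=False,
                           threshold=threshold_fraction)


def _crossing_time_ode(
    m: Mechanism, jo: float, k: float, jr: float, target: float,
    t0: float, t_max: float,
) -> float | None:
    rate = ode_rate(m, k)
    n = m.n

    def rhs(_t, y):
        return [-rate * (y[0] - jr) * y[0] ** (2.0 - n)]

    def hit(_t, y):
        return y[0] - target

    hit.terminal = True
    hit.direction = -1
    sol = solve_ivp(rhs, (t0, t_max), [jo], method="DOP853",
                    rtol=1e-10, atol=1e-10 * jo, events=hit)
    if not sol.success:
        raise SolverError(f"dominance-window integration failed for {m.value}")
    if sol.t_events[0].size:
        return float(sol.t_events[0][0])
    return None


@dataclass
class MechanismReport:
    """Ranked blocking-law fits for one stage and model family."""

    stage_label: str
    family: str
    ranking: list[tuple[Mechanism, FitResult]]
    failures: dict[Mechanism, str] = field(default_factory=dict)
    best_valid: Mechanism | None = None
    dominance_windows: dict[Mechanism, DominanceWindow] = field(default_factory=dict)

    @property
    def identifiable(self) -> bool:
        return self.best_valid is not None

    @property
    def best_fit(self) -> FitResult | None:
        if self.best_valid is None:
            return None
        return dict(self.ranking)[self.best_valid]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([fit.to_dict() for _, fit in self.ranking])

    def to_dict(self) -> dict:
        return {
            "stage": self.stage_label,
            "family": self.family,
            "identifiable": self.identifiable,
            "best_valid": self.best_valid.value if self.best_valid else None,
            "fits": [fit.to_dict() for _, fit in self.ranking],
            "failures": {m.value: msg for m, msg in self.failures.items()},
            "dominance_windows": {
                m.value: {
                    "start_h": w.start, "end_h": w.end, "reached": w.reached,
                    "full_series": w.full_series, "threshold": w.threshold,
                }
                for m, w in self.dominance_windows.items()
            },
        }

    def summary(self) -> str:
        lines = [
            f"Mechanism ranking — stage {self.stage_label or '-'} "
            f"({self.family.replace('_', '-')})",
        ]
        lines.append("=" * len(lines[0]))
        for mech, fit in self.ranking:
            mark = "*" if mech == self.best_valid else " "
            note = "" if fit.valid else "  [invalid]"
            lines.append(
                f"{mark} {mech.value:<12} R2={fit.r2:8.5f}  "
                f"K={fit.K:.4g} {fit.k_units}  "
                f"JR={fit.JR_fit:.4g}  rmse={fit.rmse_flux:.4g}{note}"
            )
        for mech, msg in self.failures.items():
            lines.append(f"  {mech.value:<12} fit rejected: {msg}")
        if self.best_valid is None:
            lines.append("no mechanism identifiable")
        return "\n".join(lines)


def rank_mechanisms(
    series: FluxSeries,
    family: str = "crossflow",
    jo: float | None = None,
    threshold: float = 0.05,
    compute_windows: bool = True,
) -> MechanismReport:
    """Fit all four blocking mechanisms of a family and rank them.

    Ranking is by linearized R² (descending), ties broken by lower
    flux-reconstruction RMSE.  ``best_valid`` is the mechanism whose slope
    sign matches the model form, whose JR did not need clamping, and whose
    reconstructed flux curve has the lowest RMSE against the observations;
    when no fit qualifies the report is explicitly non-identifiable.
    """
    family = _validate_family(family)
    fits: list[tuple[Mechanism, FitResult]] = []
    failures: dict[Mechanism, str] = {}
    for mech in Mechanism:
        try:
            if family == "dead_end":
                fit = fit_deadend(series, mech)
            else:
                fit = fit_crossflow(series, mech, jo=jo)
        except (FittingError, SolverError) as exc:
            failures[mech] = str(exc)
            logger.info("%s/%s %s fit rejected: %s",
                        series.stage_label or "series", family, mech.value, exc)
            continue
        fits.append((mech, fit))

    def sort_key(item):
        _, fit = item
        rmse = fit.rmse_flux if np.isfinite(fit.rmse_flux) else np.inf
        return (-fit.r2, rmse)

    fits.sort(key=sort_key)
    admissible = [
        (mech, fit) for mech, fit in fits
        if fit.valid and np.isfinite(fit.rmse_flux)
    ]
    best = (
        min(admissible, key=lambda mf: mf[1].rmse_flux)[0] if admissible else None
    )
    report = MechanismReport(
        stage_label=series.stage_label,
        family=family,
        ranking=fits,
        failures=failures,
        best_valid=best,
    )
    if compute_windows and family == "crossflow":
        t_end = float(series.times[-1])
        for mech, fit in fits:
            if fit.valid and fit.K > 0:
                report.dominance_windows[mech] = dominance_window(
                    fit, threshold_fraction=threshold, t_max=t_end
                )
    return report
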