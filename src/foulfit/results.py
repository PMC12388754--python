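"""Fit results container shared by the dead-end and crossflow fitters."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import FittingError
from .flux import FluxSeries, Mechanism
from .units import K_UNITS, K_UNITS_SI, constant_to_si

logger = logging.getLogger("foulfit")

__all__ = ["FitResult", "ols_line"]


def ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R² of an ordinary least-squares line.

    R² is 1 − SSres/SStot of the linearized regression; a y-series with zero
    variance yields slope 0 and R² defined as 0 (degenerate, to be caught by
    the slope-sign diagnostics).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise FittingError(f"need >=3 points for a regression, have {x.size}")
    if np.ptp(x) == 0:
        raise FittingError("degenerate regression: x has zero variance")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    ssr = float(np.sum((y - (res.slope * x + res.intercept)) ** 2))
    return float(res.slope), float(res.intercept), 1.0 - ssr / sst


@dataclass
class FitResult:
    """Estimates and diagnostics from one linearized blocking-law regression.

    Attributes
    ----------
    K : float
        Blocking constant in the canonical units implied by the fitting form
        (see :mod:`foulfit.units`).
    Jo_fit : float
        Intercept-implied initial flux (dead-end) or the initial flux used to
        anchor the transform (crossflow), L·m⁻²·h⁻¹.
    JR_fit : float
        Steady-state (removal) flux, L·m⁻²·h⁻¹; 0 for the dead-end family.
    r2 : float
        Coefficient of determination of the linearized regression.
    slope_sign_valid : bool
        False when the fitted slope contradicts the sign the model form
        requires — the series then contradicts the mechanism regardless of R².
    rmse_flux : float
        Root-mean-square error between reconstructed and observed flux,
        L·m⁻²·h⁻¹.  Complements R²: a high linearized R² can coexist with a
        poor flux reconstruction.
    jr_clamped : bool
        True when the intercept-implied JR fell outside [0, Jo) and was
        clamped (crossflow only).
    t_ref, v_ref : float
        Anchor used by the crossflow transform when Jo was taken from the
        first sample at t > 0 (both 0 when Jo refers to t = 0).
    """

    mechanism: Mechanism
    family: str
    K: float
    Jo_fit: float
    JR_fit: float
    r2: float
    slope_sign_valid: bool
    slope: float
    intercept: float
    n_points: int
    stage_label: str = ""
    rmse_flux: float = field(default=float("nan"))
    jr_clamped: bool = False
    t_ref: float = 0.0
    v_ref: float = 0.0
    #: last sample time of the fitted series (h); used as the default horizon
    #: for dominance windows
    t_end: float = float("nan")

    @property
    def k_units(self) -> str:
        return K_UNITS[(self.mechanism, self.family)]

    @property
    def K_si(self) -> float:
        """The blocking constant in SI-style (s, m³·m⁻²) units."""
        return constant_to_si(self.K, self.mechanism, self.family)

    @property
    def k_units_si(self) -> str:
        return K_UNITS_SI[(self.mechanism, self.family)]

    @property
    def valid(self) -> bool:
        """Physically admissible fit: correct slope sign and no JR clamping."""
        return self.slope_sign_valid and not self.jr_clamped

    def predict(self, time_grid) -> FluxSeries:
        """Reconstructed flux-decline curve on ``time_grid`` (h)."""
        if self.family == "dead_end":
            from .deadend import predict_deadend

            return predict_deadend(self, time_grid)
        from .crossflow import predict_crossflow

        return predict_crossflow(self, time_grid)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage_label,
            "family": self.family,
            "mechanism": self.mechanism.value,
            "K": self.K,
            "K_units": self.k_units,
            "K_si": self.K_si,
            "K_si_units": self.k_units_si,
            "Jo_fit": self.Jo_fit,
            "JR_fit": self.JR_fit,
            "r2": self.r2,
            "rmse_flux": self.rmse_flux,
            "slope_sign_valid": self.slope_sign_valid,
            "jr_clamped": self.jr_clamped,
            "n_points": self.n_points,
        }

    def summary(self) -> str:
        """Human-readable fit summary table."""
        rows = [
            ("stage", self.stage_label or "-"),
            ("family", self.family),
            ("mechanism", f"{self.mechanism.value} (n={self.mechanism.n:g})"),
            ("n points", str(self.n_points)),
            ("K", f"{self.K:.6g} {self.k_units}"),
            ("K (SI)", f"{self.K_si:.6g} {self.k_units_si}"),
            ("Jo", f"{self.Jo_fit:.6g} L/m2 h"),
        ]
        if self.family == "crossflow":
            rows.append(("JR", f"{self.JR_fit:.6g} L/m2 h"
                         + ("  [clamped]" if self.jr_clamped else "")))
        rows += [
            ("R2 (linearized)", f"{self.r2:.6f}"),
            ("RMSE flux", f"{self.rmse_flux:.6g} L/m2 h"),
            ("slope sign valid", str(self.slope_sign_valid)),
        ]
        width = max(len(k) for k, _ in rows)
        title = "Blocking-law fit"
        lines = [title, "=" * max(len(title), width + 22)]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def plot(self, series: FluxSeries | None = None, ax=None):
        """Plot the reconstructed flux curve (and observations, if given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if series is not None:
            ax.plot(series.times, series.flux, "o", ms=4, label="observed")
            grid = np.linspace(max(series.times[0], self.t_ref), series.times[-1], 200)
        else:
            grid = np.linspace(self.t_ref, self.t_ref + 1.0, 200)
        pred = self.predict(grid)
        ax.plot(pred.times, pred.flux, "-",
                label=f"{self.mechanism.value} ({self.family})")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("flux (L m$^{-2}$ h$^{-1}$)")
        ax.legend()
        return ax
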