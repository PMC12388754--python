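"""Forward simulation of flux-decline curves (the synthetic-data generator).

The generator evaluates the dead-end blocking laws in closed form and
integrates the crossflow law −dJ/dt = K(J−JR)J^(2−n) (closed forms for n=2
and n=1, adaptive ODE otherwise), then optionally applies multiplicative
Gaussian measurement noise to the flux.  Noisy series have v recomputed from
the noisy flux by trapezoid, as a real experiment would, so v and J stay
mutually consistent.

The default sampling grid is 1-minute spacing over a 60-minute window —
representative of bench-scale crossflow stages, which typically run 30–120
minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .crossflow import (
    _CLOSED_FORM,
    crossflow_flux_closed,
    crossflow_volume_closed,
    integrate_crossflow,
)
from .deadend import deadend_flux, deadend_volume
from .exceptions import ValidationError
from .flux import FluxSeries, Mechanism, _trapz_volume, _validate_family, write_flux_csv

logger = logging.getLogger("foulfit")

__all__ = [
    "BlockingParams",
    "NoiseSpec",
    "default_time_grid",
    "simulate_deadend",
    "simulate_crossflow",
    "simulate",
    "add_noise",
    "calibrate_k",
    "SimulationConfig",
]


@dataclass(frozen=True)
class BlockingParams:
    """Parameters of one blocking law.

    ``K`` is the fitted-form (Table) constant in canonical units: complete
    h⁻¹; intermediate m²·L⁻¹; standard-crossflow h⁻⁰·⁵·(L·m⁻²)⁻⁰·⁵ (the
    fitted slope; the ODE rate is 2K); cake h·m⁴·L⁻².  ``JR`` is the
    steady-state removal flux, 0 for the dead-end family.
    """

    mechanism: Mechanism
    Jo: float
    K: float
    JR: float = 0.0
    family: str = "dead_end"

    def __post_init__(self):
        object.__setattr__(self, "mechanism", Mechanism.from_name(self.mechanism))
        object.__setattr__(self, "family", _validate_family(self.family))
        if self.Jo <= 0:
            raise ValidationError("Jo must be > 0")
        if self.K <= 0:
            raise ValidationError("K must be > 0")
        if not 0 <= self.JR < self.Jo:
            raise ValidationError("JR must satisfy 0 <= JR < Jo")
        if self.family == "dead_end" and self.JR != 0:
            raise ValidationError("dead-end family requires JR = 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative flux measurement noise: J' = J·(1+ε), ε ~ N(0, cv²)."""

    cv: float
    seed: int

    def __post_init__(self):
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")


def default_time_grid(t_end_min: float = 60.0, dt_min: float = 1.0) -> np.ndarray:
    """Sampling grid in hours: ``dt``-minute spacing from dt to ``t_end``."""
    n = int(round(t_end_min / dt_min))
    return np.arange(1, n + 1) * (dt_min / 60.0)


def _check_grid(time_grid) -> np.ndarray:
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValidationError("time grid must be a non-empty 1-D array")
    if t[0] <= 0 or np.any(np.diff(t) <= 0):
        raise ValidationError("time grid must be strictly increasing and > 0")
    return t


def simulate_deadend(params: BlockingParams, time_grid) -> FluxSeries:
    """Noiseless dead-end flux-decline curve with exact closed-form J and v."""
    if params.family != "dead_end":
        raise ValidationError("simulate_deadend requires family='dead_end'")
    t = _check_grid(time_grid)
    j = deadend_flux(params.mechanism, t, params.Jo, params.K)
    v = deadend_volume(params.mechanism, t, params.Jo, params.K)
    return FluxSeries(times=t, flux=j, v=v,
                      stage_label=f"sim {params.mechanism.value} dead_end")


def simulate_crossflow(
    params: BlockingParams, time_grid, method: str = "auto"
) -> FluxSeries:
    """Noiseless crossflow flux-decline curve.

    ``method="auto"`` uses the closed forms for n=2 and n=1 and the adaptive
    integrator otherwise; ``method="ode"`` forces numerical integration (used
    to cross-check the integrator against the closed forms).
    """
    if params.family != "crossflow":
        raise ValidationError("simulate_crossflow requires family='crossflow'")
    t = _check_grid(time_grid)
    m = params.mechanism
    if method == "auto" and m in _CLOSED_FORM:
        j = crossflow_flux_closed(m, t, params.Jo, params.K, params.JR)
        v = crossflow_volume_closed(m, t, params.Jo, params.K, params.JR)
    elif method in ("auto", "ode"):
        j, v = integrate_crossflow(m, t, params.Jo, params.K, params.JR)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return FluxSeries(times=t, flux=j, v=v,
                      stage_label=f"sim {m.value} crossflow")


def simulate(params: BlockingParams, time_grid, **kw) -> FluxSeries:
    """Dispatch to the dead-end or crossflow simulator by params.family."""
    if params.family == "dead_end":
        return simulate_deadend(params, time_grid)
    return simulate_crossflow(params, time_grid, **kw)


def add_noise(series: FluxSeries, noise: NoiseSpec) -> FluxSeries:
    """Apply multiplicative Gaussian flux noise; recompute v from noisy flux.

    Draws with J' ≤ 0 are redrawn (truncation), which is immaterial at the
    few-percent noise levels typical of flux measurements.  The same seed
    always produces the identical series.
    """
    if noise.cv == 0:
        return series
    rng = np.random.default_rng(noise.seed)
    j = series.flux * (1.0 + rng.normal(0.0, noise.cv, series.flux.size))
    bad = j <= 0
    while np.any(bad):
        j[bad] = series.flux[bad] * (1.0 + rng.normal(0.0, noise.cv, int(bad.sum())))
        bad = j <= 0
    v = _trapz_volume(series.times, j)
    return FluxSeries(times=series.times, flux=j, v=v, area=series.area,
                      stage_label=series.stage_label)


def calibrate_k(
    mechanism,
    jo: float,
    j_end: float,
    t_end: float,
    jr: float = 0.0,
    family: str = "dead_end",
) -> float:
    """Blocking constant K such that J(t_end) = j_end.

    A convenient way to state generator conditions by decline depth ("the
    flux falls to j_end within the sampling window") instead of by raw rate
    constant; J(t_end) is strictly decreasing in K, so the root is unique.
    """
    from scipy.optimize import brentq

    m = Mechanism.from_name(mechanism)
    family = _validate_family(family)
    if not (jr < j_end < jo):
        raise ValidationError("need JR < j_end < Jo")

    def j_at_end(k: float) -> float:
        if family == "dead_end":
            return float(deadend_flux(m, t_end, jo, k))
        if m in _CLOSED_FORM:
            return float(crossflow_flux_closed(m, t_end, jo, k, jr))
        j, _ = integrate_crossflow(m, [t_end], jo, k, jr, rtol=1e-9)
        return float(j[0])

    lo, hi = 1e-12, 1.0
    while j_at_end(hi) > j_end:
        hi *= 10.0
        if hi > 1e12:
            raise ValidationError("calibration failed: target depth unreachable")
    return float(brentq(lambda k: j_at_end(k) - j_end, lo, hi, xtol=1e-14, rtol=1e-12))


class _NoiseModel(BaseModel):
    cv: float = Field(0.0, ge=0)
    seed: int = 0


class SimulationConfig(BaseModel):
    """YAML/JSON simulation config: mechanism, family, Jo, K, JR, grid, noise."""

    mechanism: str
    family: str = "dead_end"
    Jo: float = Field(..., gt=0)
    K: float = Field(..., gt=0)
    JR: float = Field(0.0, ge=0)
    t_end: float = Field(60.0, gt=0, description="window length, minutes")
    dt: float = Field(1.0, gt=0, description="sampling interval, minutes")
    noise: _NoiseModel = _NoiseModel()

    @model_validator(mode="after")
    def _admissible(self):
        # delegate the cross-field checks to BlockingParams
        self.to_params()
        return self

    def to_params(self) -> BlockingParams:
        return BlockingParams(
            mechanism=Mechanism.from_name(self.mechanism),
            Jo=self.Jo, K=self.K, JR=self.JR, family=self.family,
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def run(self) -> FluxSeries:
        series = simulate(self.to_params(), default_time_grid(self.t_end, self.dt))
        if self.noise.cv > 0:
            series = add_noise(series, NoiseSpec(cv=self.noise.cv, seed=self.noise.seed))
        return series

    def run_to_csv(self, path) -> FluxSeries:
        series = self.run()
        write_flux_csv(series, path)
        return series
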