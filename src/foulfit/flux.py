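"""Flux time series: the canonical container and elementary conversions.

A :class:`FluxSeries` holds sampled permeate flux ``J(t)`` (L·m⁻²·h⁻¹) and the
cumulative permeate volume per unit membrane area ``v(t)`` (L·m⁻²) for one
filtration stage operated at constant transmembrane pressure.  Flux can be
built from raw cumulative permeate volumes via :func:`flux_from_volumes`
(``J = Vp / (A·t)``), and ``v`` recovered from flux via
:func:`cumulative_volume`.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger("foulfit")

__all__ = [
    "Mechanism",
    "FluxSeries",
    "flux_from_volumes",
    "cumulative_volume",
    "read_flux_csv",
    "write_flux_csv",
]


class Mechanism(enum.Enum):
    """Pore-blocking mechanism and its blocking index ``n``.

    ``n`` is the exponent of the unified constant-pressure blocking law
    ``-dJ/dt = K (J - JR) J^(2-n)``: 2 = complete pore blocking, 1.5 =
    standard blocking (pore filling), 1 = intermediate blocking, 0 = cake
    formation.
    """

    COMPLETE = "complete"
    STANDARD = "standard"
    INTERMEDIATE = "intermediate"
    CAKE = "cake"

    @property
    def n(self) -> float:
        return _BLOCKING_INDEX[self]

    @classmethod
    def from_name(cls, name: "str | Mechanism") -> "Mechanism":
        if isinstance(name, Mechanism):
            return name
        try:
            return cls(str(name).lower())
        except ValueError:
            raise ValidationError(
                f"unknown mechanism {name!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


_BLOCKING_INDEX = {
    Mechanism.COMPLETE: 2.0,
    Mechanism.STANDARD: 1.5,
    Mechanism.INTERMEDIATE: 1.0,
    Mechanism.CAKE: 0.0,
}

FAMILIES = ("dead_end", "crossflow")


def _validate_family(family: str) -> str:
    family = str(family).lower()
    if family not in FAMILIES:
        raise ValidationError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return family


@dataclass(frozen=True)
class FluxSeries:
    """Sampled permeate flux and cumulative per-area volume for one stage.

    Parameters
    ----------
    times : array-like
        Elapsed filtration time in h, strictly increasing, ≥ 0 (a t=0 point
        is allowed and carries v=0).
    flux : array-like
        Permeate flux J in L·m⁻²·h⁻¹, strictly positive.
    v : array-like
        Cumulative permeate volume per membrane area in L·m⁻², non-decreasing.
    area : float, optional
        Membrane area in m² (kept for volume reconstruction; may be None).
    stage_label : str
        Free-text stage name, e.g. ``"MF"`` or ``"UF 100"``.
    """

    times: np.ndarray
    flux: np.ndarray
    v: np.ndarray
    area: float | None = None
    stage_label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        j = np.asarray(self.flux, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if t.ndim != 1 or j.shape != t.shape or v.shape != t.shape:
            raise ValidationError(
                "times, flux and v must be 1-D arrays of equal length "
                f"(got {t.shape}, {j.shape}, {v.shape})"
            )
        if t.size < 1:
            raise ValidationError("empty series")
        if t[0] < 0:
            raise ValidationError("times must be >= 0")
        dt = np.diff(t)
        if np.any(dt <= 0):
            k = int(np.argmax(dt <= 0)) + 1
            raise ValidationError(f"times must be strictly increasing (index {k})")
        if np.any(~np.isfinite(j)) or np.any(j <= 0):
            k = int(np.argmax(~np.isfinite(j) | (j <= 0)))
            raise ValidationError(f"flux must be finite and > 0 (index {k})")
        dv = np.diff(v)
        if np.any(dv < 0):
            k = int(np.argmax(dv < 0)) + 1
            raise ValidationError(f"v must be non-decreasing (index {k})")
        if self.area is not None and self.area <= 0:
            raise ValidationError("area must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "flux", j)
        object.__setattr__(self, "v", v)

    def __len__(self) -> int:
        return self.times.size

    @property
    def jo(self) -> float:
        """Flux at the earliest sample (the default initial-flux estimator)."""
        return float(self.flux[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "flux": self.flux, "v": self.v})

    def with_label(self, label: str) -> "FluxSeries":
        return replace(self, stage_label=label)

    def interval_volumes(self, area: float | None = None) -> np.ndarray:
        """Cumulative permeate volumes (L) under the interval-flux convention.

        Inverse of :func:`flux_from_volumes` in ``mode="interval"``: each
        sampling interval (anchored at t=0) contributes ``J·A·Δt``.
        """
        a = self.area if area is None else area
        if a is None or a <= 0:
            raise ValidationError("a positive membrane area is required")
        if self.times[0] > 0:
            dt = np.diff(np.concatenate([[0.0], self.times]))
            return np.cumsum(self.flux * dt) * a
        # series includes t=0: the first sample contributes no volume
        dt = np.diff(self.times)
        return np.concatenate([[0.0], np.cumsum(self.flux[1:] * dt)]) * a


def flux_from_volumes(
    sample_times,
    permeate_volumes,
    area: float,
    mode: str = "interval",
    stage_label: str = "",
) -> FluxSeries:
    """Build a :class:`FluxSeries` from cumulative permeate volumes.

    ``J = Vp/(A·t)``: permeate volume divided by membrane area and sampling
    time.  Two readings of the sampling time are supported:

    * ``mode="interval"`` (default): ``J[k] = (V[k]-V[k-1]) / (A·(t[k]-t[k-1]))``
      with ``J[0] = V[0]/(A·t[0])`` — flux over each sampling interval.
    * ``mode="cumulative"``: ``J[k] = V[k]/(A·t[k])`` — the cumulative-average
      flux since the start of filtration.

    Parameters
    ----------
    sample_times : array-like
        Sampling times in h, strictly increasing, all > 0.
    permeate_volumes : array-like
        Cumulative permeate volume in L at each sampling time, non-decreasing.
    area : float
        Membrane area in m².
    """
    t = np.asarray(sample_times, dtype=float)
    vol = np.asarray(permeate_volumes, dtype=float)
    if t.ndim != 1 or vol.shape != t.shape:
        raise ValidationError("sample_times and permeate_volumes must match in shape")
    if t.size < 1:
        raise ValidationError("at least one sample required")
    if t[0] <= 0:
        raise ValidationError("sampling times must be > 0 (index 0)")
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValidationError(f"sampling times must be strictly increasing (index {bad[0] + 1})")
    bad = np.nonzero(np.diff(vol) < 0)[0]
    if bad.size:
        raise ValidationError(f"cumulative volumes must be non-decreasing (index {bad[0] + 1})")
    if area <= 0:
        raise ValidationError("area must be > 0")
    if mode not in ("interval", "cumulative"):
        raise ValidationError(f"unknown mode {mode!r}")

    v = vol / area
    if mode == "interval":
        dvol = np.diff(np.concatenate([[0.0], vol]))
        dt = np.diff(np.concatenate([[0.0], t]))
        j = dvol / (area * dt)
        stalled = np.nonzero(j <= 0)[0]
        if stalled.size:
            raise ValidationError(
                f"interval flux must be > 0; stalled interval at index {stalled[0]}"
            )
    else:
        j = vol / (area * t)
        if np.any(j <= 0):
            k = int(np.argmax(j <= 0))
            raise ValidationError(f"flux must be > 0 (index {k})")
    return FluxSeries(times=t, flux=j, v=v, area=area, stage_label=stage_label)


def cumulative_volume(series: FluxSeries) -> np.ndarray:
    """Per-area cumulative volume (L·m⁻²) by trapezoidal integration of flux.

    Anchored at v=0 for t=0.  If the first sample is at t>0, flux over the
    unobserved initial interval is taken constant at the first sample's value.
    """
    return _trapz_volume(series.times, series.flux)


def _trapz_volume(times: np.ndarray, flux: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    j = np.asarray(flux, dtype=float)
    v = np.empty_like(t)
    v[0] = j[0] * t[0]  # rectangle over [0, t0]; zero when t0 == 0
    if t.size > 1:
        v[1:] = v[0] + np.cumsum(0.5 * (j[1:] + j[:-1]) * np.diff(t))
    return v


def series_from_flux(
    times, flux, area: float | None = None, stage_label: str = ""
) -> FluxSeries:
    """Build a :class:`FluxSeries` from flux samples, deriving v by trapezoid."""
    t = np.asarray(times, dtype=float)
    j = np.asarray(flux, dtype=float)
    return FluxSeries(
        times=t, flux=j, v=_trapz_volume(t, j), area=area, stage_label=stage_label
    )


def read_flux_csv(
    path, area: float | None = None, mode: str = "interval", stage_label: str = ""
) -> FluxSeries:
    """Read a stage CSV with columns ``time,volume`` (h, L) or ``time,flux``.

    A header row is required; lines starting with ``#`` are ignored.  A
    ``time,volume`` file additionally requires ``area`` (m²).
    """
    df = pd.read_csv(path, comment="#")
    cols = {c.strip().lower() for c in df.columns}
    df.columns = [c.strip().lower() for c in df.columns]
    if {"time", "volume"} <= cols:
        if area is None:
            raise ValidationError("area (m²) is required for a time,volume CSV")
        return flux_from_volumes(
            df["time"].to_numpy(), df["volume"].to_numpy(), area,
            mode=mode, stage_label=stage_label,
        )
    if {"time", "flux"} <= cols:
        return series_from_flux(
            df["time"].to_numpy(), df["flux"].to_numpy(), area=area,
            stage_label=stage_label,
        )
    raise ValidationError(
        f"CSV must have columns time,volume or time,flux (found {sorted(cols)})"
    )


def write_flux_csv(series: FluxSeries, path) -> None:
    """Write the standard ``time,flux`` CSV for a series."""
    pd.DataFrame({"time": series.times, "flux": series.flux}).to_csv(path, index=False)
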