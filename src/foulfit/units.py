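"""Unit conventions and converters.

Canonical internal units:

* flux ``J``: L·m⁻²·h⁻¹
* time ``t``: h
* per-area permeate volume ``v``: L·m⁻²
* membrane area: m²

Blocking constants carry the units implied by the linearized fitting forms
(see :mod:`foulfit.deadend` and :mod:`foulfit.crossflow`):

===============  =======================  ==========================
mechanism        canonical (h, L·m⁻²)     SI-style (s, m³·m⁻²)
===============  =======================  ==========================
complete         h⁻¹                      s⁻¹
intermediate     m²·L⁻¹                   m⁻¹
standard (dead)  m²·L⁻¹                   m⁻¹
standard (cross) h⁻⁰·⁵·(L·m⁻²)⁻⁰·⁵        s⁻⁰·⁵·m⁻⁰·⁵
cake             h·m⁴·L⁻²                 s·m⁻²
===============  =======================  ==========================

Published tables in this field frequently print the SI-style column (per-area
volume expressed in m = m³·m⁻²), so both directions are provided.
"""

from __future__ import annotations

from .flux import Mechanism

SECONDS_PER_HOUR = 3600.0
#: 1 m³·m⁻² expressed in L·m⁻²
L_PER_M2_PER_M = 1000.0

# multiply a canonical-unit constant by this factor to get the SI-style value
_TO_SI = {
    # h⁻¹ -> s⁻¹
    (Mechanism.COMPLETE, "dead_end"): 1.0 / SECONDS_PER_HOUR,
    (Mechanism.COMPLETE, "crossflow"): 1.0 / SECONDS_PER_HOUR,
    # m²·L⁻¹ -> m⁻¹   (1 m²·L⁻¹ · 1000 L·m⁻² per m = 1000 m⁻¹)
    (Mechanism.INTERMEDIATE, "dead_end"): L_PER_M2_PER_M,
    (Mechanism.INTERMEDIATE, "crossflow"): L_PER_M2_PER_M,
    (Mechanism.STANDARD, "dead_end"): L_PER_M2_PER_M,
    # h⁻⁰·⁵(L·m⁻²)⁻⁰·⁵ -> s⁻⁰·⁵m⁻⁰·⁵ : (1/60)·√1000
    (Mechanism.STANDARD, "crossflow"): L_PER_M2_PER_M**0.5 / 60.0,
    # h·m⁴·L⁻² -> s·m⁻² : 3600 · (1e-3 m per L·m⁻²)⁻² ... i.e. ·3600·1e-6
    (Mechanism.CAKE, "dead_end"): SECONDS_PER_HOUR / L_PER_M2_PER_M**2,
    (Mechanism.CAKE, "crossflow"): SECONDS_PER_HOUR / L_PER_M2_PER_M**2,
}

K_UNITS = {
    (Mechanism.COMPLETE, "dead_end"): "1/h",
    (Mechanism.COMPLETE, "crossflow"): "1/h",
    (Mechanism.INTERMEDIATE, "dead_end"): "m2/L",
    (Mechanism.INTERMEDIATE, "crossflow"): "m2/L",
    (Mechanism.STANDARD, "dead_end"): "m2/L",
    (Mechanism.STANDARD, "crossflow"): "1/(h^0.5 (L/m2)^0.5)",
    (Mechanism.CAKE, "dead_end"): "h m4/L2",
    (Mechanism.CAKE, "crossflow"): "h m4/L2",
}

K_UNITS_SI = {
    (Mechanism.COMPLETE, "dead_end"): "1/s",
    (Mechanism.COMPLETE, "crossflow"): "1/s",
    (Mechanism.INTERMEDIATE, "dead_end"): "1/m",
    (Mechanism.INTERMEDIATE, "crossflow"): "1/m",
    (Mechanism.STANDARD, "dead_end"): "1/m",
    (Mechanism.STANDARD, "crossflow"): "1/(s^0.5 m^0.5)",
    (Mechanism.CAKE, "dead_end"): "s/m2",
    (Mechanism.CAKE, "crossflow"): "s/m2",
}


def constant_to_si(k: float, mechanism: Mechanism, family: str = "dead_end") -> float:
    """Convert a blocking constant from canonical (h, L·m⁻²) to SI-style (s, m) units."""
    return k * _TO_SI[(mechanism, family)]


def constant_from_si(k: float, mechanism: Mechanism, family: str = "dead_end") -> float:
    """Convert a blocking constant from SI-style (s, m) to canonical (h, L·m⁻²) units."""
    return k / _TO_SI[(mechanism, family)]


def hours_to_seconds(t: float) -> float:
    return t * SECONDS_PER_HOUR


def seconds_to_hours(t: float) -> float:
    return t / SECONDS_PER_HOUR
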