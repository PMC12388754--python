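"""Filtration-train performance metrics and degree-of-fouling quantities.

Per stage, from the feed (subscript 0) and retentate (subscript r) assays:

* specific activity        SA  = Lac / Pro                (U·mg⁻¹)
* volumetric conc. factor  VCF = V0 / Vr
* activity conc. factor    ACF = Lacr / Lac0
* recovery efficiency      R   = (Lacr·Vr)/(Lac0·V0) = ACF/VCF
* purification factor      PF  = SAr/SA0 = ACF·(Pro0/Pror)

All derived metrics are computed from unrounded intermediates; rounding is
applied only for display.  R and PF are computed through the ACF/VCF
identities so that the algebraic invariants hold exactly in floating point.

When the intermediate blocking mechanism dominates and no cake forms, the
flux decays with collected volume as J = Jo·e^(−Ki·v), so the per-area
permeate volume at which flux has fallen to a residual fraction f of Jo is
Vmax = |ln f| / Ki.  Collecting much more than Vmax signals exhaustive
(irreversibility-prone) membrane use; the degree-of-fouling verdict compares
the collected volume against this critical value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .exceptions import ValidationError
from .flux import FluxSeries
from .stages import FiltrationStage, StageAssay

__all__ = [
    "PerformanceSummary",
    "specific_activity",
    "stage_performance",
    "performance_table",
    "vmax",
    "FoulingDegree",
    "fouling_degree",
]


def specific_activity(assay: StageAssay) -> float:
    """Enzyme activity per unit protein, U·mg⁻¹ (full precision)."""
    if assay.pro <= 0:
        raise ValidationError("protein concentration must be > 0")
    return assay.lac / assay.pro


@dataclass(frozen=True)
class PerformanceSummary:
    """VCF, ACF, recovery, PF and specific activities for one stage."""

    vcf: float
    acf: float
    recovery: float  # fraction; report as % for display
    pf: float
    sa_feed: float
    sa_retentate: float
    stage_label: str = ""
    diluted: bool = False  # retentate volume >= feed volume (VCF < 1)

    def as_row(self) -> dict:
        return {
            "stage": self.stage_label,
            "VCF": self.vcf,
            "ACF": self.acf,
            "R_pct": 100.0 * self.recovery,
            "PF": self.pf,
            "SA_feed": self.sa_feed,
            "SA_retentate": self.sa_retentate,
        }


def stage_performance(
    feed: StageAssay, retentate: StageAssay, stage_label: str = ""
) -> PerformanceSummary:
    """Concentration/purification metrics for one feed→retentate step."""
    if feed.lac <= 0:
        raise ValidationError("feed activity must be > 0")
    vcf = feed.volume / retentate.volume
    acf = retentate.lac / feed.lac
    recovery = acf / vcf
    pf = acf * (feed.pro / retentate.pro)
    return PerformanceSummary(
        vcf=vcf,
        acf=acf,
        recovery=recovery,
        pf=pf,
        sa_feed=specific_activity(feed),
        sa_retentate=specific_activity(retentate),
        stage_label=stage_label,
        diluted=retentate.volume >= feed.volume,
    )


def performance_table(stages: list[FiltrationStage]) -> pd.DataFrame:
    """Per-stage performance summary frame for a filtration train."""
    rows = [
        stage_performance(s.feed, s.retentate, stage_label=s.label).as_row()
        for s in stages
    ]
    return pd.DataFrame(rows)


def vmax(ki: float, residual_fraction: float = 0.4) -> float:
    """Critical cumulative per-area volume |ln f|/Ki of the intermediate law.

    ``ki`` is the intermediate blocking constant in inverse per-area-volume
    units (m²·L⁻¹ canonically, or m⁻¹ when v is expressed in m³·m⁻²); the
    result carries the corresponding volume units.  ``residual_fraction`` is
    the flux fraction J/Jo defining "spent" (default 0.4: flux reduced to
    40% of its initial value).
    """
    if ki <= 0:
        raise ValidationError("Ki must be > 0")
    if not 0 < residual_fraction < 1:
        raise ValidationError("residual_fraction must be in (0, 1)")
    return abs(math.log(residual_fraction)) / ki


@dataclass(frozen=True)
class FoulingDegree:
    """Collected vs critical permeate volume for one stage."""

    v_collected: float
    v_critical: float
    ratio: float
    non_exhaustive: bool
    at_ceiling: bool
    ceiling: float


def fouling_degree(
    series: FluxSeries,
    ki: float,
    residual_fraction: float = 0.4,
    ceiling: float = 1.10,
) -> FoulingDegree:
    """Compare the collected per-area volume with the critical value Vmax.

    The verdict is "non-exhaustive use" when collected/critical ≤ ``ceiling``
    (default 1.10: up to ~10% beyond the critical volume is still considered
    reversible by backwashing).  ``ki`` must be in m²·L⁻¹ so its units match
    the series' v (L·m⁻²).
    """
    v_collected = float(series.v[-1])
    v_critical = vmax(ki, residual_fraction)
    ratio = v_collected / v_critical
    return FoulingDegree(
        v_collected=v_collected,
        v_critical=v_critical,
        ratio=ratio,
        non_exhaustive=ratio <= ceiling,
        at_ceiling=math.isclose(ratio, ceiling, rel_tol=1e-9),
        ceiling=ceiling,
    )
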