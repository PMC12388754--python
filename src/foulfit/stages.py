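"""Stage assay streams, the packaged laccase filtration table, train simulation.

A sequential filtration train passes the permeate of each stage to the next
as feed, while the retentate concentrates the target enzyme.  Each stream is
characterised by its volume, enzyme (laccase) activity and total protein
concentration.  :func:`laccase_train_table` packages the measured assay table
of a seven-stage crossflow train (one 0.45 µm microfiltration stage followed
by 1000/500/300/100/50/10 kDa ultrafiltration stages) concentrating a
*Pleurotus ostreatus* laccase extract; :func:`simulate_train` generates
synthetic analogues with prescribed rejection behaviour and exact mass
balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["StageAssay", "StageSpec", "FiltrationStage", "laccase_train_table",
           "laccase_blocking_constants", "simulate_train"]


@dataclass(frozen=True)
class StageAssay:
    """One stream: volume (mL), laccase activity (U/mL), protein (mg/mL)."""

    volume: float
    lac: float
    pro: float
    label: str = ""

    def __post_init__(self):
        if self.volume <= 0:
            raise ValidationError(f"{self.label or 'stream'}: volume must be > 0")
        if self.lac < 0:
            raise ValidationError(f"{self.label or 'stream'}: activity must be >= 0")
        if self.pro <= 0:
            raise ValidationError(f"{self.label or 'stream'}: protein must be > 0")

    @property
    def total_activity(self) -> float:
        """Total enzyme activity in the stream, U."""
        return self.volume * self.lac

    @property
    def total_protein(self) -> float:
        """Total protein in the stream, mg."""
        return self.volume * self.pro


@dataclass(frozen=True)
class FiltrationStage:
    """Feed/retentate pair (and optionally permeate) for one membrane stage."""

    label: str
    feed: StageAssay
    retentate: StageAssay
    permeate: StageAssay | None = None


def laccase_train_table() -> list[FiltrationStage]:
    """The packaged measured assay table for the seven-stage laccase train.

    Values are the printed feed/retentate volumes (mL), laccase activities
    (U/mL) and protein concentrations (mg/mL) for the MF stage and the six
    ultrafiltration stages; each stage's feed is the previous stage's
    permeate.
    """
    rows = [
        # label,   feed (V, lac, pro, name),                retentate (V, lac, pro)
        ("MF", (500, 0.217, 0.08, "Initial extract"), (30, 1.038, 0.28)),
        ("UF 1000", (470, 0.166, 0.08, "MF permeate"), (45, 0.339, 0.11)),
        ("UF 500", (425, 0.122, 0.09, "UF 1000 permeate"), (15, 0.097, 0.04)),
        ("UF 300", (400, 0.114, 0.07, "UF 500 permeate"), (15, 0.101, 0.07)),
        ("UF 100", (365, 0.095, 0.07, "UF 300 permeate"), (15, 0.473, 0.05)),
        ("UF 50", (345, 0.071, 0.06, "UF 100 permeate"), (15, 0.379, 0.10)),
        ("UF 10", (320, 0.046, 0.05, "UF 50 permeate"), (15, 0.260, 0.07)),
    ]
    out = []
    for label, (fv, fl, fp, fname), (rv, rl, rp) in rows:
        out.append(
            FiltrationStage(
                label=label,
                feed=StageAssay(volume=fv, lac=fl, pro=fp, label=fname),
                retentate=StageAssay(volume=rv, lac=rl, pro=rp,
                                     label=f"{label} retentate"),
            )
        )
    return out


def laccase_blocking_constants() -> pd.DataFrame:
    """Reference fitted blocking constants for the laccase train stages.

    Tidy frame of the reported per-stage fits for the complete, intermediate
    and standard mechanisms, both model families.  ``K_si`` is in SI-style
    units (complete: s⁻¹; intermediate/standard dead-end: m⁻¹; standard
    crossflow: s⁻⁰·⁵·m⁻⁰·⁵ — see :mod:`foulfit.units`); ``JR`` is in
    L·m⁻²·h⁻¹ and is NaN for the dead-end family.  Several crossflow rows
    carry a fitted JR far above any plausible initial flux; they are
    physically implausible (useful only for ruling the mechanism out) and
    are inadmissible as forward-simulation inputs.
    """
    stages = ["MF", "UF 1000", "UF 500", "UF 300", "UF 100", "UF 50", "UF 10"]
    nan = float("nan")
    rows = []

    def block(mechanism, dead, cross):
        for st, (r2d, kd), (r2c, kc, jr) in zip(
            [s for s in stages if s != "UF 300"], dead, cross
        ):
            rows.append((st, mechanism, "dead_end", r2d, kd, nan))
            rows.append((st, mechanism, "crossflow", r2c, kc, jr))

    block(
        "complete",
        [(0.922, 2.58e-4), (0.864, 1.38e-4), (0.965, 14.60e-4),
         (0.947, 12.07e-4), (0.973, 10.70e-4), (0.932, 9.47e-4)],
        [(0.939, 4.64e-4, 59.39), (0.954, 7.31e-4, 20.76),
         (0.948, 8.51e-4, 506.45), (0.933, 10.51e-4, 283.20),
         (0.503, 1.70e-4, 1248.08), (0.932, 12.60e-4, 157.19)],
    )
    block(
        "intermediate",
        [(0.998, 0.181), (0.999, 0.196), (0.999, 0.204),
         (0.999, 0.238), (0.999, 0.254), (0.999, 0.271)],
        [(0.996, 30.60, 32.35), (0.989, 36.50, 18.74), (0.979, 13.50, 452.00),
         (0.972, 16.70, 325.87), (0.989, 22.40, 197.95), (0.962, 20.30, 230.84)],
    )
    block(
        "standard",
        [(0.998, 21.72), (0.999, 23.56), (0.999, 24.46),
         (0.999, 28.54), (0.999, 30.42), (0.999, 32.48)],
        [(0.998, 29.83e-2, 0.0049), (0.996, 31.17e-2, 0.0034),
         (0.993, 21.21e-2, 0.0507), (0.991, 23.61e-2, 0.0362),
         (0.997, 28.18e-2, 0.0212), (0.988, 26.09e-2, 0.0253)],
    )
    return pd.DataFrame(
        rows, columns=["stage", "mechanism", "family", "r2", "K_si", "JR"]
    )


@dataclass(frozen=True)
class StageSpec:
    """Synthetic stage behaviour.

    ``retentate_fraction`` is the volume fraction kept as retentate;
    ``rejection_lac``/``rejection_pro`` ∈ [0, 1] set the permeate
    concentration to ``(1-σ)`` times the feed concentration; ``loss`` is the
    fraction of total activity and protein lost to adsorption/inactivation.
    """

    label: str
    retentate_fraction: float
    rejection_lac: float
    rejection_pro: float
    loss: float = 0.0

    def __post_init__(self):
        if not 0 < self.retentate_fraction < 1:
            raise ValidationError("retentate_fraction must be in (0, 1)")
        for name in ("rejection_lac", "rejection_pro"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not 0 <= self.loss < 1:
            raise ValidationError("loss must be in [0, 1)")


def _split(feed: StageAssay, spec: StageSpec) -> tuple[StageAssay, StageAssay]:
    vr = feed.volume * spec.retentate_fraction
    vp = feed.volume - vr
    keep = 1.0 - spec.loss

    def concentrations(cf: float, sigma: float) -> tuple[float, float]:
        cp = (1.0 - sigma) * cf
        total = feed.volume * cf * keep
        retained = total - cp * vp
        if retained < 0:
            raise ValidationError(
                f"{spec.label}: infeasible balance (loss {spec.loss} too large "
                f"for rejection {sigma})"
            )
        return retained / vr, cp

    lac_r, lac_p = concentrations(feed.lac, spec.rejection_lac)
    pro_r, pro_p = concentrations(feed.pro, spec.rejection_pro)
    retentate = StageAssay(vr, lac_r, max(pro_r, np.finfo(float).tiny),
                           label=f"{spec.label} retentate")
    permeate = StageAssay(vp, lac_p, max(pro_p, np.finfo(float).tiny),
                          label=f"{spec.label} permeate")
    return retentate, permeate


def simulate_train(
    feed: StageAssay,
    specs: list[StageSpec],
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> list[FiltrationStage]:
    """Simulate a sequential filtration train: each permeate feeds the next.

    Volume is conserved exactly per stage (feed = retentate + permeate), and
    total activity/protein are conserved up to the stage's stated loss
    factor.  ``noise_cv`` optionally applies multiplicative measurement noise
    to the reported concentrations (the underlying balance stays exact).
    """
    rng = np.random.default_rng(seed)
    stages: list[FiltrationStage] = []
    current = feed
    for spec in specs:
        retentate, permeate = _split(current, spec)
        rep_r, rep_p = retentate, permeate
        if noise_cv > 0:
            def jitter(a: StageAssay) -> StageAssay:
                f = 1.0 + rng.normal(0.0, noise_cv, 2)
                return StageAssay(a.volume, max(a.lac * f[0], 0.0),
                                  max(a.pro * f[1], np.finfo(float).tiny), a.label)
            rep_r, rep_p = jitter(retentate), jitter(permeate)
        stages.append(FiltrationStage(label=spec.label, feed=current,
                                      retentate=rep_r, permeate=rep_p))
        current = permeate
    return stages
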