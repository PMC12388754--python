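"""Statsmodels-style front end: a model object built from data, fit() → results.

:class:`BlockingLawModel` wraps one flux series together with a mechanism
and model family; ``fit()`` runs the linearized regression and returns the
:class:`~foulfit.results.FitResult` results object (estimates, R²,
diagnostics, ``summary()``, ``predict()``, ``plot()``).

Example
-------
>>> from foulfit import BlockingLawModel, BlockingParams, simulate, default_time_grid
>>> params = BlockingParams("complete", Jo=400, K=2.0, JR=60, family="crossflow")
>>> series = simulate(params, default_time_grid(60))
>>> res = BlockingLawModel(series, "complete", family="crossflow", jo=400).fit()
>>> round(res.K, 6), round(res.JR_fit, 4)
(2.0, 60.0)
"""

from __future__ import annotations

from .crossflow import fit_crossflow
from .deadend import fit_deadend
from .exceptions import ValidationError
from .flux import FluxSeries, Mechanism, _validate_family, read_flux_csv
from .results import FitResult

__all__ = ["BlockingLawModel"]


class BlockingLawModel:
    """One blocking law (mechanism × family) to be fitted to a flux series.

    Parameters
    ----------
    series : FluxSeries
        Observed flux-decline data for one filtration stage.
    mechanism : str or Mechanism
        ``complete``, ``intermediate``, ``standard`` or ``cake``.
    family : str
        ``dead_end`` (no removal term) or ``crossflow`` (steady-state flux
        JR fitted from the intercept).
    jo : float, optional
        Initial flux anchoring the crossflow transforms; defaults to the
        flux at the earliest sample (``jo_mode="first"``).
    jo_mode : str
        For reporting/prediction of dead-end fits: ``"intercept"`` (default)
        uses the intercept-implied initial flux, ``"first"`` the earliest
        observed flux.
    """

    def __init__(
        self,
        series: FluxSeries,
        mechanism,
        family: str = "dead_end",
        jo: float | None = None,
        jo_mode: str = "intercept",
    ):
        self.series = series
        self.mechanism = Mechanism.from_name(mechanism)
        self.family = _validate_family(family)
        if jo_mode not in ("intercept", "first"):
            raise ValidationError("jo_mode must be 'intercept' or 'first'")
        self.jo = jo
        self.jo_mode = jo_mode

    @classmethod
    def from_csv(
        cls,
        path,
        mechanism,
        family: str = "dead_end",
        area: float | None = None,
        flux_mode: str = "interval",
        **kw,
    ) -> "BlockingLawModel":
        """Build the model from a ``time,flux`` or ``time,volume`` CSV."""
        series = read_flux_csv(path, area=area, mode=flux_mode)
        return cls(series, mechanism, family=family, **kw)

    def fit(self) -> FitResult:
        """Run the linearized OLS fit and return the results object."""
        if self.family == "dead_end":
            res = fit_deadend(self.series, self.mechanism)
            if self.jo_mode == "first":
                res.Jo_fit = self.series.jo
            return res
        return fit_crossflow(self.series, self.mechanism, jo=self.jo)
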