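"""Report serialization: parameter tables and JSON reports.

The parameter table mirrors the usual published layout for blocking-law
analyses: one row per stage × family × mechanism with R², the blocking
constant (canonical and SI-style units) and, for crossflow fits, the
steady-state flux JR.
"""

from __future__ import annotations

import json

import pandas as pd

from .results import FitResult
from .selection import MechanismReport

__all__ = ["fits_frame", "write_fits_csv", "write_report_json"]


def fits_frame(fits: "list[FitResult] | list[MechanismReport]") -> pd.DataFrame:
    """Parameter table from FitResults or MechanismReports."""
    rows: list[dict] = []
    for item in fits:
        if isinstance(item, MechanismReport):
            rows.extend(fit.to_dict() for _, fit in item.ranking)
        else:
            rows.append(item.to_dict())
    return pd.DataFrame(rows)


def write_fits_csv(fits, path) -> None:
    fits_frame(fits).to_csv(path, index=False)


def write_report_json(report: "MechanismReport | dict", path) -> None:
    """Deterministic (sorted-key) JSON serialization of a report."""
    payload = report.to_dict() if isinstance(report, MechanismReport) else report
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
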