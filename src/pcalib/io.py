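"""Readers, writers and run records for batch use.

CSV input carries one header column ``p_value``; calibration output adds
``min_bayes_factor``, ``calibrated_lower_bound`` and ``informative`` at full
precision, plus a ``rounded_3dp`` presentation column in CSV.  Every CLI
invocation emits one self-describing RunRecord (command, parameters, seed,
timestamp, version, results) so any run can be reproduced from its own
output.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import pandas as pd

from .calibration import CalibrationResult, round_half_up

__all__ = ["RunRecord", "read_pvalues", "write_calibration", "calibration_frame"]


class FormatError(ValueError):
    """A structurally invalid input file (missing column, bad value)."""


@dataclass
class RunRecord:
    """One CLI invocation: parameters in, results out, fully re-runnable."""

    command: str
    params: dict[str, Any]
    results: Any
    seed: Optional[int] = None
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )
    version: str = field(default_factory=lambda: _package_version())

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "command": self.command,
                "params": self.params,
                "seed": self.seed,
                "timestamp": self.timestamp,
                "version": self.version,
                "results": self.results,
            },
            indent=indent,
        )


def _package_version() -> str:
    from . import __version__

    return __version__


def read_pvalues(path: str | Path) -> list[float]:
    """Read the ``p_value`` column of a CSV file into a list of probabilities.

    Blank lines are skipped.  A missing column names the headers found; an
    unparseable or out-of-range value names its row (1-based data rows).
    """
    try:
        df = pd.read_csv(path, skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty (expected a p_value header)") from exc
    if "p_value" not in df.columns:
        raise FormatError(
            f"{path}: no 'p_value' column; found columns {list(df.columns)}"
        )
    values: list[float] = []
    for row, raw in enumerate(df["p_value"], start=1):
        try:
            p = float(raw)
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path}: row {row}: cannot parse {raw!r} as a probability"
            ) from exc
        if not (0.0 < p < 1.0):
            raise FormatError(
                f"{path}: row {row}: p_value {p!r} outside (0, 1)"
            )
        values.append(p)
    return values


def calibration_frame(results: Sequence[CalibrationResult]) -> pd.DataFrame:
    """Tabulate calibration results with full precision plus a rounded column."""
    return pd.DataFrame(
        {
            "p_value": [r.p for r in results],
            "min_bayes_factor": [r.bf_bound for r in results],
            "calibrated_lower_bound": [r.alpha_lower for r in results],
            "informative": [r.informative for r in results],
            "rounded_3dp": [round_half_up(r.alpha_lower, 3) for r in results],
        }
    )


def write_calibration(
    results: Sequence[CalibrationResult], path: str | Path, format: str = "csv"
) -> None:
    """Write calibration results to CSV (with rounded column) or JSON.

    JSON carries full precision only; round-tripping it reproduces the
    values exactly.
    """
    df = calibration_frame(results)
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        records = df.drop(columns=["rounded_3dp"]).to_dict(orient="records")
        path.write_text(json.dumps(records, indent=2) + "\n")
    else:
        raise ValueError(f"format must be 'csv' or 'json'; got {format!r}")
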