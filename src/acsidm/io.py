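"""File formats: ACS count tables, trajectories, and estimation reports.

The ACS table format is a plain CSV with header ``t,S,C,D0,D1`` and one
row per monitoring age: machine-friendly, diff-friendly, and bit-exact
under a write/read round trip.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .design import ACSTable, STATE_LABELS
from .estimation import EstimationResult
from .ode import StateProbabilities
from .rates import ParameterVector

__all__ = [
    "read_acs_table",
    "write_acs_table",
    "load_reference_table",
    "write_trajectory",
    "report_frame",
    "write_report",
]

_HEADER = "t,S,C,D0,D1"


class ACSParseError(ValueError):
    """Malformed ACS table file, with the offending line number."""


def _format_time(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else repr(float(t))


def read_acs_table(path: Union[str, Path]) -> ACSTable:
    """Parse an ACS count table from CSV (header ``t,S,C,D0,D1``)."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != _HEADER:
        raise ACSParseError(
            f"line 1: expected header {_HEADER!r}, "
            f"got {lines[0].strip()!r}" if lines else "empty file"
        )
    times: list[float] = []
    counts: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 5:
            raise ACSParseError(f"line {lineno}: expected 5 fields, got {len(parts)}")
        try:
            t = float(parts[0])
        except ValueError:
            raise ACSParseError(f"line {lineno}: bad time {parts[0]!r}") from None
        row = []
        for label, cell in zip(STATE_LABELS, parts[1:]):
            try:
                row.append(int(cell))
            except ValueError:
                raise ACSParseError(
                    f"line {lineno}: count {label}={cell!r} is not an integer"
                ) from None
        if times and t <= times[-1]:
            raise ACSParseError(
                f"line {lineno}: time {t:g} not strictly increasing "
                f"(previous {times[-1]:g})"
            )
        times.append(t)
        counts.append(row)
    return ACSTable(
        times=np.asarray(times, dtype=float),
        counts=np.asarray(counts, dtype=np.int64).reshape(len(times), 4),
    )


def write_acs_table(acs: ACSTable, path: Union[str, Path]) -> None:
    """Write a count table; inverse of :func:`read_acs_table`."""
    lines = [_HEADER]
    for t, row in zip(acs.times, acs.counts):
        lines.append(",".join([_format_time(t)] + [str(int(c)) for c in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_reference_table() -> ACSTable:
    """The packaged reference ACS realization (N=10,000, eleven
    cross-sections at ages 0, 10, ..., 100) from the diabetes-motivated
    feasibility experiment."""
    source = resources.files("acsidm.data") / "acs_reference.csv"
    with resources.as_file(source) as path:
        return read_acs_table(path)


def write_trajectory(solution: StateProbabilities, path: Union[str, Path]) -> None:
    """Write a solved trajectory as CSV with columns t,p1,p2,p3,p4."""
    frame = pd.DataFrame(
        solution.values, columns=["p1", "p2", "p3", "p4"]
    )
    frame.insert(0, "t", solution.times)
    frame.to_csv(path, index=False)


def report_frame(
    results: dict[str, EstimationResult],
    theta_true: Optional[ParameterVector] = None,
) -> pd.DataFrame:
    """Long-format estimation report, one row per (method, parameter).

    ``theta2`` is additionally reported per 10,000 (the conventional
    scale for a slope of order 1e-4).
    """
    rows = []
    names = ["theta1", "theta2", "theta3", "theta4", "theta5", "theta6"]
    for method, result in results.items():
        hat = result.theta_hat.as_array()
        for i, name in enumerate(names):
            row = {
                "method": method,
                "parameter": name,
                "estimate": hat[i],
                "converged": result.converged,
            }
            if name == "theta2":
                row["estimate_per_10000"] = hat[i] * 1e4
            if theta_true is not None:
                ref = theta_true.as_array()[i]
                row["true_value"] = ref
                row["rel_error_pct"] = abs(hat[i] - ref) / abs(ref) * 100.0
            rows.append(row)
    return pd.DataFrame(rows)


def write_report(
    results: dict[str, EstimationResult],
    path: Union[str, Path],
    theta_true: Optional[ParameterVector] = None,
) -> None:
    report_frame(results, theta_true).to_csv(path, index=False)
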