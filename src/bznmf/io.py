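"""Reading and writing signal matrices, reports, and summary tables.

The on-disk matrix layout is delimited text (TSV by default, CSV accepted):
first column the measurement times, remaining columns one signal sequence
each, with an optional header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import SignalMatrix, TimeGrid

REPORT_SCHEMA_VERSION = 1


def read_signal_matrix(
    path, delimiter: str | None = None, allow_negative: bool = False
) -> SignalMatrix:
    """Read a times + sequences table into a :class:`SignalMatrix`.

    The delimiter is sniffed (tab or comma) unless given; a header row is
    detected by attempting numeric conversion of the first row.  Structural
    problems (non-numeric cells, non-increasing times, negative intensities)
    raise ``ValueError`` naming the offending location.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: file is empty")
    if delimiter is None:
        first_line = text.splitlines()[0]
        delimiter = "\t" if "\t" in first_line else ","
    try:
        df = pd.read_csv(path, sep=delimiter, header=None, comment="#")
    except Exception as exc:
        raise ValueError(f"{path}: could not parse delimited text: {exc}") from exc

    # header detection: first row not fully numeric -> treat as column names
    try:
        df.iloc[0].astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
    try:
        data = df.astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric cell: {exc}") from exc
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus at least one sequence")

    times, values = data[:, 0], data[:, 1:]
    if np.any(np.diff(times) <= 0):
        j = int(np.argmax(np.diff(times) <= 0))
        raise ValueError(f"{path}: times not strictly increasing at row {j + 1}")
    if not allow_negative and np.any(values < 0):
        j, i = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative intensity at row {j}, sequence column {i}"
        )
    return SignalMatrix(values, TimeGrid(times), allow_negative=allow_negative)


def write_signal_matrix(I: SignalMatrix, path, delimiter: str = "\t") -> None:
    """Write a matrix in the times + sequences layout with a header row."""
    path = Path(path)
    header = ["time"] + [f"seq{i + 1}" for i in range(I.n_sequences)]
    df = pd.DataFrame(
        np.column_stack([I.grid.times, I.values]), columns=header
    )
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def write_json_report(report: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report = {"schema_version": REPORT_SCHEMA_VERSION, **report}
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_json_report(path) -> dict:
    return json.loads(Path(path).read_text())


def write_summary_table(rows: list[dict], path, delimiter: str = "\t") -> None:
    """Flat TSV summary (one row per component / per cell)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False,
                              float_format="%.6g")
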