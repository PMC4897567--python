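"""Reading and writing survival tables and estimate tables.

Input is delimited text with a header row and one record per subject:
a time column (non-negative reals) and a status column coded 0/1.  By
default status 1 marks an observed event; ``censored_convention=True``
flips the coding for files where 1 marks censoring.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .distribution import SurvivalSample
from .mle import EstimateResult

__all__ = ["read_survival_table", "estimates_frame", "write_estimates"]


def read_survival_table(
    path,
    time_column: str = "time",
    status_column: str = "status",
    censored_convention: bool = False,
    sep: str | None = None,
) -> SurvivalSample:
    """Parse a delimited survival table into a :class:`SurvivalSample`."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    for col in (time_column, status_column):
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing column {col!r}; found {list(df.columns)}"
            )
    times = pd.to_numeric(df[time_column], errors="coerce")
    if times.isna().any():
        row = int(times.index[times.isna()][0])
        raise ValueError(f"{path}: non-numeric time in row {row}")
    if (times < 0).any():
        row = int(times.index[times < 0][0])
        raise ValueError(f"{path}: negative time in row {row}")
    status = pd.to_numeric(df[status_column], errors="coerce")
    if status.isna().any() or not status.isin((0, 1)).all():
        bad = status.isna() | ~status.isin((0, 1))
        row = int(status.index[bad][0])
        raise ValueError(f"{path}: status outside {{0,1}} in row {row}")
    events = status.to_numpy(dtype=int)
    if censored_convention:
        events = 1 - events
    return SurvivalSample(times.to_numpy(dtype=float), events)


def estimates_frame(results: list[EstimateResult]) -> pd.DataFrame:
    """Tidy table of estimates: one row per method x parameter."""
    rows = []
    for res in results:
        for name, point, sd, ci in zip(
            ("theta", "p"),
            res.params.as_array(),
            res.sd,
            res.intervals or ((np.nan, np.nan), (np.nan, np.nan)),
        ):
            rows.append(
                {
                    "method": res.method,
                    "loss_k": res.loss.k if res.loss and res.loss.kind == "LINEX" else np.nan,
                    "parameter": name,
                    "estimate": point,
                    "sd": sd,
                    "ci_lower": ci[0],
                    "ci_upper": ci[1],
                    "level": res.interval_level,
                    "converged": res.converged,
                }
            )
    return pd.DataFrame(rows)


def write_estimates(results: list[EstimateResult], path, float_format: str = "%.6f") -> None:
    estimates_frame(results).to_csv(path, index=False, float_format=float_format)
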