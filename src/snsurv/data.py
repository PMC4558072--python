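"""Survival-data containers and delimited-text I/O.

A subject is a row (entry, time, event, covariates):

* ``entry`` -- age/time of delayed entry (left-truncation point). ``-inf``
  (or, for positive-time models, 0) means the subject is observed from the
  time origin and contributes no truncation term.
* ``time`` -- exit age/time: age at death if ``event == 1``, censoring age
  otherwise.
* ``event`` -- 1 if the death was observed, 0 if censored.

The on-disk format is a delimited text table with header columns
``entry_age, exit_age, event`` followed by covariate columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["check_survival_y", "make_survival_y", "read_survival_table", "write_survival_table"]

_Y_COLUMNS = ("entry", "time", "event")


def make_survival_y(time, event=None, entry=None) -> np.ndarray:
    """Assemble an (n, 3) survival target [entry, time, event].

    ``event`` defaults to all-observed; ``entry`` defaults to ``-inf``
    (no truncation).
    """
    time = np.asarray(time, dtype=float)
    n = time.shape[0]
    if event is None:
        event = np.ones(n)
    if entry is None:
        entry = np.full(n, -np.inf)
    return np.column_stack([np.asarray(entry, float), time, np.asarray(event, float)])


def check_survival_y(y):
    """Validate a survival target; returns (entry, time, event) float arrays.

    Accepts an (n, 3) array in column order (entry, time, event), a DataFrame
    with those columns, or a tuple of the three arrays.
    """
    if isinstance(y, pd.DataFrame):
        missing = [c for c in _Y_COLUMNS if c not in y.columns]
        if missing:
            raise ValueError(f"survival target is missing columns {missing}")
        entry = y["entry"].to_numpy(float)
        time = y["time"].to_numpy(float)
        event = y["event"].to_numpy(float)
    elif isinstance(y, tuple) and len(y) == 3:
        entry, time, event = (np.asarray(a, dtype=float) for a in y)
    else:
        arr = np.asarray(y, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(
                "survival target must be (n, 3) [entry, time, event], a "
                "DataFrame with those columns, or a 3-tuple of arrays"
            )
        entry, time, event = arr[:, 0], arr[:, 1], arr[:, 2]
    if entry.shape != time.shape or time.shape != event.shape:
        raise ValueError("entry, time and event must have equal length")
    if time.shape[0] == 0:
        raise ValueError("empty survival target")
    if np.any(np.isnan(time)) or np.any(np.isnan(entry)) or np.any(np.isnan(event)):
        raise ValueError("missing values in survival target are rejected")
    if not np.all(np.isin(event, (0.0, 1.0))):
        raise ValueError("event indicator must be 0 or 1")
    if np.any(time < entry):
        bad = int(np.nonzero(time < entry)[0][0])
        raise ValueError(f"record {bad}: exit time {time[bad]} precedes entry {entry[bad]}")
    return entry, time, event


def read_survival_table(path, sep=None):
    """Read a survival table; returns (X: DataFrame or None, y: (n,3) array).

    Expects header ``entry_age, exit_age, event`` then covariate columns;
    rows with missing values are rejected.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    required = ["entry_age", "exit_age", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.isna().any().any():
        bad = int(np.nonzero(df.isna().any(axis=1).to_numpy())[0][0]) + 2  # header line
        raise ValueError(f"{path}: missing value at line {bad}")
    y = make_survival_y(
        time=df["exit_age"], event=df["event"], entry=df["entry_age"]
    )
    covs = [c for c in df.columns if c not in required]
    X = df[covs] if covs else None
    check_survival_y(y)
    return X, y


def write_survival_table(path, y, X=None, sep=","):
    """Write a survival table in the package's delimited format."""
    entry, time, event = check_survival_y(y)
    out = pd.DataFrame(
        {"entry_age": entry, "exit_age": time, "event": event.astype(int)}
    )
    if X is not None:
        X = pd.DataFrame(X)
        X.index = out.index
        out = pd.concat([out, X], axis=1)
    out.to_csv(path, sep=sep, index=False)
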