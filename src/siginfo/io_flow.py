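"""Reading, normalising and transforming single-cell flow-cytometry event tables.

The unit of all downstream computation is the *event table*: a
:class:`pandas.DataFrame` with one row per cell and the columns

``cell_index, stat3, pstat3, genotype, dose_ng_ml, time_min, replicate``

where ``stat3`` is total STAT3 fluorescence and ``pstat3`` is the
STAT3-Y705-phospho channel, both on a linear intensity scale (arbitrary
units).  A *condition* is a ``(genotype, dose_ng_ml, time_min, replicate)``
tuple.  CSV is the canonical interchange format.

Display and analysis conventions implemented here:

* ``log_transform`` — channels are log10-transformed after flooring at a
  small positive intensity (methanol-fixed flow data can contain near-zero
  events).
* ``normalize_to_max_mean`` — across a set of conditions, the condition with
  the largest channel mean is rescaled to a mean of 100%.
* ``display_subsample`` — uniform random subset for plotting (the study
  convention is ~1000 events per concentration).
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, EmptyInputError, SchemaError

#: Exact CSV column names of an event table.
REQUIRED_COLUMNS = (
    "cell_index",
    "stat3",
    "pstat3",
    "genotype",
    "dose_ng_ml",
    "time_min",
    "replicate",
)

#: Recognised genotype labels: wildtype, SHP2 ΔEx3 mutant, mutant
#: reconstituted with wildtype SHP2, and wildtype under MEK inhibition.
GENOTYPES = ("wt", "dEx3", "dEx3_SHP2", "wt_U0126")

#: Columns holding fluorescence intensities.
CHANNELS = ("stat3", "pstat3")

#: Columns that jointly identify a condition.
CONDITION_COLUMNS = ("genotype", "dose_ng_ml", "time_min", "replicate")

_NUMERIC_COLUMNS = ("stat3", "pstat3", "dose_ng_ml", "time_min")


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate an event table in place and return it.

    Raises
    ------
    SchemaError
        If a required column is missing or not numeric where it must be.
    EmptyInputError
        If the table has no rows.
    ValueError
        If channel values are non-finite or doses are negative.
    """
    for col in REQUIRED_COLUMNS:
        if col not in events.columns:
            raise SchemaError(f"event table is missing required column {col!r}")
    if len(events) == 0:
        raise EmptyInputError("event table contains no events")
    for col in _NUMERIC_COLUMNS:
        if not np.issubdtype(events[col].dtype, np.number):
            raise SchemaError(f"column {col!r} must be numeric, got {events[col].dtype}")
        if not np.isfinite(events[col].to_numpy()).all():
            raise ValueError(f"column {col!r} contains non-finite values")
    if (events["dose_ng_ml"].to_numpy() < 0).any():
        raise ValueError("doses must be >= 0 ng/ml")
    return events


def read_event_table(path, format: str = "csv") -> pd.DataFrame:
    """Read and validate an event table from ``path``.

    Parameters
    ----------
    path
        File to read.
    format
        Only ``"csv"`` is supported; CSV is the canonical interchange format.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}; only 'csv' is supported")
    try:
        events = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: file contains no data") from exc
    return validate_events(events)


def write_event_table(events: pd.DataFrame, path) -> None:
    """Write a validated event table to CSV (round-trip safe with repr precision)."""
    validate_events(events)
    events.to_csv(path, index=False)


class LogTransformResult(NamedTuple):
    events: pd.DataFrame
    n_floored: int


def log_transform(
    events: pd.DataFrame,
    floor: float = 1.0,
    channels: Sequence[str] = CHANNELS,
) -> LogTransformResult:
    """Replace channel intensities by ``log10(max(value, floor))``.

    Returns the transformed copy together with the number of values that hit
    the floor.  ``floor`` must be > 0.
    """
    if not floor > 0:
        raise ValueError(f"floor must be > 0, got {floor}")
    out = events.copy()
    n_floored = 0
    for ch in channels:
        values = out[ch].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError(f"channel {ch!r} contains non-finite values")
        n_floored += int((values < floor).sum())
        out[ch] = np.log10(np.maximum(values, floor))
    return LogTransformResult(out, n_floored)


def normalize_to_max_mean(
    tables: Iterable[pd.DataFrame], channel: str = "pstat3"
) -> list[pd.DataFrame]:
    """Rescale ``channel`` across conditions so the largest condition mean is 100.

    Every table is multiplied by the same factor ``100 / max(condition means)``,
    so relative differences between conditions are preserved and the operation
    is invariant to a common positive rescaling of the raw data.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one condition table")
    means = [float(t[channel].mean()) for t in tables]
    top = max(means)
    if top == 0:
        raise DegenerateDataError(
            f"all condition means of channel {channel!r} are zero; cannot normalise"
        )
    factor = 100.0 / top
    out = []
    for t in tables:
        u = t.copy()
        u[channel] = u[channel] * factor
        out.append(u)
    return out


def display_subsample(events: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Uniform random subset of ``min(n, len(events))`` rows, reproducible per seed."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if n >= len(events):
        return events.copy()
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(events), size=n, replace=False))
    return events.iloc[idx].copy()
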