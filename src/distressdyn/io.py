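"""File-format plumbing: validated readers for the pipeline's CSV inputs."""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .dynamics import STREAMS
from .observation import ObservationSet

__all__ = ["read_observations"]


def read_observations(path) -> ObservationSet:
    """Read an observation CSV (header ``stream,year,value``) with validation.

    Errors name the offending line; unknown stream names list the allowed
    set; duplicate (stream, year) pairs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"observation file not found: {path}")
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if [c.strip() for c in header] != ["stream", "year", "value"]:
            raise ValueError(
                f"{path}: expected header 'stream,year,value', got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            stream, year, value = (c.strip() for c in row)
            if stream not in STREAMS:
                raise ValueError(
                    f"{path}:{lineno}: unknown stream {stream!r}; "
                    f"allowed names are {', '.join(STREAMS)}"
                )
            try:
                year_i = int(year)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: year {year!r} is not an integer") from None
            try:
                value_i = int(value)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: value {value!r} is not an integer count"
                ) from None
            if value_i < 0:
                raise ValueError(f"{path}:{lineno}: value {value_i} is negative")
            rows.append((stream, year_i, value_i))
    df = pd.DataFrame(rows, columns=["stream", "year", "value"])
    dup = df.duplicated(subset=["stream", "year"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate record for ({first['stream']}, {first['year']})"
        )
    return ObservationSet.from_dataframe(df)
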