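"""Text-based readers/writers for the toolkit's tabular artifacts.

Feature tables are tab-delimited with a mandatory header row whose first
column is ``time_ns``; decimals use '.'. Current traces are two-column
delimited text with a YAML protocol sidecar. Gridded/tabular analysis
outputs carry '#'-prefixed metadata header lines.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

TIME_COLUMN = "time_ns"


class FeatureTableError(ValueError):
    """Raised for malformed feature tables."""


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the feature-table contract; returns the table unchanged.

    Contract: first column is ``time_ns``, all columns numeric and equal
    length (guaranteed by the DataFrame), time strictly increasing.
    """
    if table.shape[1] < 1 or table.columns[0] != TIME_COLUMN:
        raise FeatureTableError(
            f"first column must be {TIME_COLUMN!r}, got {list(table.columns[:1])!r}"
        )
    t = table[TIME_COLUMN].to_numpy(dtype=float)
    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        raise FeatureTableError("time_ns must be strictly increasing")
    if not np.isfinite(table.to_numpy(dtype=float)).all():
        raise FeatureTableError("feature table contains non-finite values")
    return table


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_feature_table(table)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return validate_feature_table(table)


def frame_spacing_ns(table: pd.DataFrame) -> float:
    """Uniform frame spacing of a feature table (ns); checks uniformity."""
    t = table[TIME_COLUMN].to_numpy(dtype=float)
    if len(t) < 2:
        raise FeatureTableError("need >= 2 frames to define a spacing")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
        raise FeatureTableError("frame spacing is not uniform")
    return float(dt[0])


def write_trace(time_s, current, protocol: Mapping, path: str | os.PathLike) -> None:
    """Write a current trace (two columns) plus a YAML protocol sidecar."""
    df = pd.DataFrame({"time_s": np.asarray(time_s), "current": np.asarray(current)})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    with open(f"{path}.protocol.yaml", "w") as fh:
        yaml.safe_dump(dict(protocol), fh, sort_keys=False)


def read_trace(path: str | os.PathLike):
    """Read a current trace and its YAML protocol sidecar (if present)."""
    df = pd.read_csv(path, sep="\t")
    protocol = {}
    sidecar = f"{path}.protocol.yaml"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            protocol = yaml.safe_load(fh) or {}
    return df["time_s"].to_numpy(), df["current"].to_numpy(), protocol


def write_grid(path: str | os.PathLike, metadata: Mapping, **arrays) -> None:
    """Write named 1-D/2-D arrays as delimited text with '#' metadata lines."""
    with open(path, "w") as fh:
        for key, value in metadata.items():
            fh.write(f"# {key}: {value}\n")
        for name, arr in arrays.items():
            arr = np.asarray(arr)
            fh.write(f"# array: {name} shape: {'x'.join(map(str, arr.shape))}\n")
            np.savetxt(fh, np.atleast_2d(arr), delimiter="\t", fmt="%.10g")
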