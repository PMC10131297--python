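"""File I/O: series tables, results tables, run manifests, census input.

Everything is plain text: long-format CSV for series and results, YAML for
manifests.  A census file is a two-column CSV with header ``year,N``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .projection import BatchResult

__all__ = [
    "series_to_frame",
    "write_series_csv",
    "read_series_csv",
    "write_manifest",
    "read_census_csv",
]


def series_to_frame(batches: list[BatchResult]) -> pd.DataFrame:
    """Long-format table (species, scenario, replicate, year, N) of batches."""
    frames = []
    for b in batches:
        n_reps, T = b.N.shape
        frames.append(
            pd.DataFrame(
                {
                    "species": np.repeat(b.abbr, n_reps * T),
                    "scenario": np.repeat(b.scenario_id, n_reps * T),
                    "replicate": np.repeat(np.arange(n_reps), T),
                    "year": np.tile(np.arange(T), n_reps),
                    "N": b.N.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_series_csv(batches: list[BatchResult], path: str | Path) -> None:
    series_to_frame(batches).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"species", "scenario", "replicate", "year", "N"}
    if not expected.issubset(df.columns):
        raise ValueError(f"series file {path} missing columns {expected - set(df.columns)}")
    return df


def write_manifest(path: str | Path, **entries) -> None:
    """Structured-text sidecar recording seeds, calibrations and event order."""
    payload = {
        "event_order": [
            "resample_rates", "density_feedback", "catastrophe",
            "matrix_transition", "harvest_or_pulse", "census",
        ],
    }
    payload.update(entries)
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(payload, default=float)), fh,
                       sort_keys=True)


def read_census_csv(path: str | Path) -> np.ndarray:
    """Yearly abundances from a user census CSV with header ``year,N``.

    Years must be unique; gaps are allowed but the series is fitted on the
    recorded transitions as if consecutive (a warning is left to the caller).
    """
    df = pd.read_csv(path)
    if not {"year", "N"}.issubset(df.columns):
        raise ValueError("census file needs columns year,N")
    df = df.sort_values("year")
    if df["year"].duplicated().any():
        raise ValueError("census file has duplicate years")
    return df["N"].to_numpy(dtype=float)
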