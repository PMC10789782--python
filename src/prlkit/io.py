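"""CSV/JSON file formats binding the pipeline stages.

The interchange format is a long-format trial CSV, one row per choice:

======================  =========================================------
column                  meaning
======================  =================================================
``subject_id``          subject identifier (string)
``condition``           condition label (string)
``session``             0-based session index (int)
``trial``               0-based trial index within session (int)
``choice``              option token ("A"/"B" stimuli or "left"/"right")
``outcome``             +1 reward / -1 punishment (int)
``chose_correct``       0/1, optional — synthetic data only
``correct_option``      latent correct option, optional — synthetic only
======================  =================================================

Reading validates the schema (header present, no missing required values,
outcomes in {+1, -1}, unique (subject, condition, session, trial) keys) and
sorts rows canonically; schema errors name the offending row and column.
Write -> read round-trips the record stream exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Dataset

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "read_trials",
    "write_trials",
    "read_truth",
    "write_truth",
    "write_dataset",
    "read_dataset",
    "write_manifest",
    "write_draws",
    "read_draws",
]

REQUIRED_COLUMNS = ("subject_id", "condition", "session", "trial",
                    "choice", "outcome")
OPTIONAL_COLUMNS = ("chose_correct", "correct_option")
KEY = ["subject_id", "condition", "session", "trial"]


class SchemaError(ValueError):
    """A trial table violates the interchange schema."""


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    for col in REQUIRED_COLUMNS:
        na = df[col].isna()
        if na.any():
            raise SchemaError(f"missing value in column {col!r} at row "
                              f"{int(np.flatnonzero(na)[0])}")
    bad = ~df["outcome"].isin((1, -1))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(f"outcome must be +1 or -1: column 'outcome' at row {row} "
                          f"has value {df['outcome'].iloc[row]!r}")
    dup = df.duplicated(subset=KEY)
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise SchemaError(f"duplicate (subject_id, condition, session, trial) key "
                          f"at row {row}")
    return df.sort_values(KEY, kind="mergesort").reset_index(drop=True)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV; rows come back canonically sorted."""
    df = pd.read_csv(path, dtype={"subject_id": str, "condition": str,
                                  "choice": str})
    return _validate(df)


def write_trials(records, path) -> None:
    """Write a trial table (a DataFrame or a :class:`Dataset`) as CSV."""
    df = records.records if isinstance(records, Dataset) else records
    _validate(df.reset_index(drop=True))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_truth(truth: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    truth.to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str, "condition": str,
                                    "parameter": str})


def write_dataset(ds: Dataset, out_dir) -> dict[str, Path]:
    """Write trials CSV + truth CSV + provenance JSON under one directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"trials": out / "trials.csv", "truth": out / "truth.csv",
             "provenance": out / "provenance.json"}
    write_trials(ds.records, paths["trials"])
    write_truth(ds.truth, paths["truth"])
    paths["provenance"].write_text(json.dumps(ds.provenance, indent=2, default=str))
    return paths


def read_dataset(in_dir) -> Dataset:
    p = Path(in_dir)
    prov = json.loads((p / "provenance.json").read_text()) \
        if (p / "provenance.json").exists() else {}
    return Dataset(records=read_trials(p / "trials.csv"),
                   truth=read_truth(p / "truth.csv"), provenance=prov)


def write_draws(samples, path) -> None:
    """Posterior draws as long-format CSV (chain, draw, parameter, value)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    samples.to_long_frame().to_csv(path, index=False)


def read_draws(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"parameter": str})


def write_manifest(path, *, config: dict, seed: int | None, extra: dict | None = None):
    """Run manifest: config hash, seed, package version; full provenance."""
    from . import __version__
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {"config": config,
                "config_sha256": hashlib.sha256(blob).hexdigest(),
                "seed": seed, "prlkit_version": __version__}
    if extra:
        manifest.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
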