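"""Readers and writers for the pipeline's on-disk formats.

Trial, covariate and QC tables are TSV/CSV; voxel pattern matrices are HDF5
(one group per ROI/phase with ``values``, ``run_labels`` and ``trial_ids``
datasets) with a delimited-text fallback for inspection; configuration is a
single TOML or YAML file.
"""
from __future__ import annotations

import pathlib
import tomllib
from typing import Iterable

import h5py
import numpy as np
import pandas as pd
import yaml

from ._util import log
from .datatypes import (
    TRIAL_COLUMNS,
    Category,
    PatternMatrix,
    Phase,
    QCSeries,
    Response,
)


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an unparseable value."""


class AlignmentError(ValueError):
    """Pattern rows cannot be aligned with the trial table."""


_RESPONSE_ALIASES = {r.value.lower(): r.value for r in Response}
_CATEGORY_ALIASES = {c.value.lower(): c.value for c in Category}
_PHASE_ALIASES = {p.value.lower(): p.value for p in Phase}


def _normalize_enum(series: pd.Series, aliases: dict, what: str) -> pd.Series:
    out = []
    for i, raw in enumerate(series):
        if pd.isna(raw) or raw == "":
            out.append(aliases.get("none", "none"))
            continue
        key = str(raw).strip().lower()
        if key not in aliases:
            raise SchemaError(f"row {i}: unknown {what} token {raw!r}")
        out.append(aliases[key])
    return pd.Series(out, index=series.index)


def make_trial_ids(trials: pd.DataFrame) -> pd.Series:
    """Canonical trial identifier: participant:phase:run:trial_index."""
    return (
        trials["participant_id"].astype(str)
        + ":"
        + trials["phase"].astype(str)
        + ":"
        + trials["run"].astype(str)
        + ":"
        + trials["trial_index"].astype(str)
    )


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial table from TSV/CSV, normalising enum tokens.

    The ``condition`` column is left as-is if present and set to
    ``unclassified`` otherwise; classification is the behaviour module's
    job.  Row order is preserved.
    """
    path = pathlib.Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"participant_id": str, "word": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table {path} missing column(s): {missing}")
    df["phase"] = _normalize_enum(df["phase"], _PHASE_ALIASES, "phase")
    df["category"] = _normalize_enum(df["category"], _CATEGORY_ALIASES, "category")
    df["response"] = _normalize_enum(df["response"], _RESPONSE_ALIASES, "response")
    df["is_foil"] = df["is_foil"].astype(bool)
    df["run"] = df["run"].astype(int)
    df["trial_index"] = df["trial_index"].astype(int)
    if "condition" not in df.columns:
        df["condition"] = "unclassified"
    if "artifact" not in df.columns:
        df["artifact"] = False
    df["artifact"] = df["artifact"].astype(bool)
    if "trial_id" not in df.columns:
        df["trial_id"] = make_trial_ids(df)
    return df


def write_trial_table(trials: pd.DataFrame, path) -> None:
    path = pathlib.Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    trials.to_csv(path, sep=sep, index=False)


def read_covariates(path) -> pd.DataFrame:
    """Per-participant covariate table (age, sex, education, mean FD, ...)."""
    path = pathlib.Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise SchemaError(f"covariate table {path} missing 'participant_id'")
    return df


def _align_to_trials(
    values: np.ndarray,
    run_labels: np.ndarray,
    trial_ids: np.ndarray,
    trial_table: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reorder pattern rows to trial-table order, rejecting mismatches."""
    want = list(trial_table["trial_id"])
    if len(want) != len(trial_ids):
        raise AlignmentError(
            f"pattern has {len(trial_ids)} rows but trial table has {len(want)}"
        )
    pos = {tid: i for i, tid in enumerate(trial_ids)}
    unknown = [tid for tid in trial_ids if tid not in set(want)]
    if unknown:
        raise AlignmentError(f"pattern trial ids absent from trial table: {unknown[:5]}")
    try:
        order = [pos[tid] for tid in want]
    except KeyError as exc:  # pragma: no cover - symmetric to `unknown`
        raise AlignmentError(f"trial id {exc} has no pattern row") from exc
    values = values[order]
    bad_rows = np.where(~np.isfinite(values).all(axis=1))[0]
    if bad_rows.size:
        raise SchemaError(f"non-finite pattern values in rows {bad_rows.tolist()[:10]}")
    return values, run_labels[order], trial_ids[order]


def read_pattern_matrix(path, trial_table: pd.DataFrame, roi: str, phase) -> PatternMatrix:
    """Read one ROI/phase pattern matrix and align its rows to the trial table.

    ``trial_table`` must already be restricted to the matching participant
    and phase (and carry a ``trial_id`` column).
    """
    phase = Phase(phase)
    path = pathlib.Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            grp = f[f"{roi}/{phase.value}"]
            values = np.asarray(grp["values"], dtype=float)
            run_labels = np.asarray(grp["run_labels"])
            trial_ids = np.asarray(grp["trial_ids"].asstr(), dtype=object)
    else:
        df = pd.read_csv(path, sep="\t")
        trial_ids = df["trial_id"].to_numpy(dtype=object)
        run_labels = df["run"].to_numpy()
        values = df.drop(columns=["trial_id", "run"]).to_numpy(dtype=float)
    values, run_labels, trial_ids = _align_to_trials(
        values, run_labels, trial_ids, trial_table
    )
    return PatternMatrix(
        roi=roi, phase=phase, values=values, run_labels=run_labels, trial_ids=trial_ids
    )


def write_pattern_matrix(pm: PatternMatrix, path) -> None:
    """Write a pattern matrix to HDF5 (.h5) or TSV (anything else)."""
    path = pathlib.Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "a") as f:
            grp = f.require_group(f"{pm.roi}/{pm.phase.value}")
            for name in ("values", "run_labels", "trial_ids"):
                if name in grp:
                    del grp[name]
            grp.create_dataset("values", data=pm.values)
            grp.create_dataset("run_labels", data=np.asarray(pm.run_labels, dtype=int))
            grp.create_dataset(
                "trial_ids",
                data=np.asarray([str(t) for t in pm.trial_ids], dtype=object),
                dtype=h5py.string_dtype(),
            )
    else:
        df = pd.DataFrame(pm.values)
        df.insert(0, "run", pm.run_labels)
        df.insert(0, "trial_id", pm.trial_ids)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_qc_table(path) -> list[QCSeries]:
    """Read per-volume QC series (columns: run, framewise_displacement,
    global_intensity), one QCSeries per run in ascending run order."""
    df = pd.read_csv(pathlib.Path(path), sep="\t")
    needed = {"run", "framewise_displacement", "global_intensity"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"QC table missing column(s): {sorted(missing)}")
    keys = [c for c in ("participant_id", "phase", "run") if c in df.columns]
    out = []
    for key, sub in df.groupby(keys, sort=True):
        run = key[-1] if isinstance(key, tuple) else key
        out.append(
            QCSeries(
                run=int(run),
                framewise_displacement=sub["framewise_displacement"].to_numpy(),
                global_intensity=sub["global_intensity"].to_numpy(),
            )
        )
    return out


def write_qc_table(series: Iterable[QCSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "run": s.run,
                "volume": np.arange(s.n_volumes),
                "framewise_displacement": s.framewise_displacement,
                "global_intensity": s.global_intensity,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        pathlib.Path(path), sep="\t", index=False, float_format="%.17g"
    )


def read_config(path) -> dict:
    """Read a TOML or YAML configuration file into a dict."""
    path = pathlib.Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as f:
            cfg = tomllib.load(f)
    else:
        with open(path) as f:
            cfg = yaml.safe_load(f)
    log.info("resolved config from %s: %s", path, cfg)
    return cfg
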