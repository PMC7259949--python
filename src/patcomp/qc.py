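"""Volume-, run- and trial-level artifact screening.

A volume is flagged when framewise displacement exceeds 0.5 mm relative to
the previous frame, or when whole-brain mean intensity deviates from the
run mean by more than five run standard deviations.  A run is dropped when
more than 25% of its volumes are flagged or its maximum FD exceeds 2 mm
(strict inequalities: a run at exactly 25% is retained).  A trial is
excluded when any of its constituent volumes is flagged or its run is
dropped; excluded trials leave all analyses.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import log
from .datatypes import QCSeries


def flag_artifact_volumes(
    qc: QCSeries,
    fd_threshold: float = 0.5,
    intensity_sd_threshold: float = 5.0,
) -> np.ndarray:
    """Boolean artifact flag per volume of one run."""
    if qc.n_volumes == 0:
        raise ValueError("QC series is empty")
    fd_flags = qc.framewise_displacement > fd_threshold
    intensity = qc.global_intensity
    sd = float(np.std(intensity))
    if sd == 0.0:
        if not np.all(intensity == intensity[0]):  # pragma: no cover
            sd = np.finfo(float).tiny
        warnings.warn(
            f"run {qc.run}: zero-variance intensity series; "
            "intensity criterion skipped",
            stacklevel=2,
        )
        int_flags = np.zeros(qc.n_volumes, dtype=bool)
    else:
        int_flags = np.abs(intensity - intensity.mean()) > intensity_sd_threshold * sd
    return fd_flags | int_flags


def apply_run_exclusion(
    flags: np.ndarray,
    qc: QCSeries,
    artifact_fraction: float = 0.25,
    fd_run_max: float = 2.0,
) -> bool:
    """True iff the run is kept.

    Dropped iff the flagged fraction strictly exceeds ``artifact_fraction``
    or the maximum FD strictly exceeds ``fd_run_max``.
    """
    flags = np.asarray(flags, dtype=bool)
    frac = flags.mean() if flags.size else 0.0
    return not (frac > artifact_fraction or qc.framewise_displacement.max() > fd_run_max)


def exclude_artifact_trials(
    trials: pd.DataFrame,
    flags_per_run: Mapping[int, np.ndarray],
    trial_volume_map: Mapping[str, Sequence[int]],
    kept_runs: Mapping[int, bool] | None = None,
) -> pd.DataFrame:
    """Return the trial table with an ``artifact`` column set and excluded
    trials dropped.

    ``trial_volume_map`` maps trial_id -> volume indices within the trial's
    run; ``kept_runs`` maps run -> keep decision (all kept if omitted).
    """
    kept_runs = dict(kept_runs or {})
    artifact = np.zeros(len(trials), dtype=bool)
    for i, (_, row) in enumerate(trials.iterrows()):
        run = int(row["run"])
        if not kept_runs.get(run, True):
            artifact[i] = True
            continue
        tid = row["trial_id"]
        if tid not in trial_volume_map:
            raise ValueError(f"trial {tid} is mapped to no volumes")
        vols = np.asarray(trial_volume_map[tid], dtype=int)
        if vols.size == 0:
            raise ValueError(f"trial {tid} is mapped to no volumes")
        run_flags = np.asarray(flags_per_run[run], dtype=bool)
        artifact[i] = bool(run_flags[vols].any())
    out = trials.copy()
    out["artifact"] = artifact
    n_drop = int(artifact.sum())
    if n_drop:
        log.info("excluding %d of %d trials for artifacts", n_drop, len(trials))
    return out.loc[~out["artifact"]].reset_index(drop=True)
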