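"""Reading, validating and preprocessing experience-sampling (ESM) tables.

The long-format ESM table has one row per survey prompt: participant id,
timestamp, an optional burst label, a 0/1 regulation flag, one 0/1 column
per tactic id in the active codebook, and pre-/post-regulation affect on a
1-7 Likert scale (present only when the prompt branched into the
regulation items).

Bursts — contiguous 7-day measurement periods separated by roughly four
weeks — can be taken from the file or recomputed from inter-response gaps:
a gap of ``gap_days`` or more starts a new burst.  Participants are kept
for analysis when at least one of their bursts has ``min_instances``
completed prompts.  A *regulation instance* is a prompt with regulated = 1
and at least one tactic endorsed; prompts where the respondent reported
regulating but endorsed no tactic do not count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .codebook import Codebook

log = logging.getLogger(__name__)

DEFAULT_GAP_DAYS = 14.0
DEFAULT_MIN_INSTANCES = 13

#: Fixed (non-tactic) columns of the long-format ESM schema.
BASE_COLUMNS = ("participant_id", "timestamp", "regulated", "pre_affect", "post_affect")


class SchemaError(ValueError):
    """ESM or participant table does not match the documented schema."""


@dataclass
class StudyDataset:
    """An ESM study: one prompt per row plus a participant table.

    ``observations`` columns: participant_id, timestamp, burst (may be NA
    until assigned), regulated, one 0/1 column per tactic id, pre_affect,
    post_affect.  ``participants`` columns: participant_id, age_years and
    pass-through covariates.
    """

    observations: pd.DataFrame
    participants: pd.DataFrame
    codebook: Codebook

    @property
    def tactic_columns(self) -> list[str]:
        return [t for t in self.codebook.ids if t in self.observations.columns]

    def copy(self) -> "StudyDataset":
        return StudyDataset(
            self.observations.copy(), self.participants.copy(), self.codebook
        )

    def validate(self) -> "StudyDataset":
        obs, part = self.observations, self.participants
        for col in ("participant_id", "timestamp", "regulated"):
            if col not in obs.columns:
                raise SchemaError(f"ESM table missing required column {col!r}")
        if "participant_id" not in part.columns or "age_years" not in part.columns:
            raise SchemaError("participant table needs participant_id and age_years")
        unknown = set(obs["participant_id"]) - set(part["participant_id"])
        if unknown:
            raise SchemaError(
                f"observations reference participants absent from the participant "
                f"table: {sorted(unknown)[:5]}"
            )
        missing_tactics = [t for t in self.codebook.ids if t not in obs.columns]
        if missing_tactics:
            raise SchemaError(f"ESM table missing tactic columns: {missing_tactics}")
        for col in ("pre_affect", "post_affect"):
            if col in obs.columns:
                vals = obs[col].dropna()
                bad = vals[(vals < 1) | (vals > 7)]
                if len(bad):
                    raise SchemaError(
                        f"{col} outside the 1-7 Likert range at rows "
                        f"{bad.index.tolist()[:5]}"
                    )
        for t in self.codebook.ids:
            vals = obs[t].fillna(0)
            if not vals.isin((0, 1)).all():
                raise SchemaError(f"tactic column {t!r} has values outside {{0,1}}")
        return self


def read_esm_csv(
    esm_path: Union[str, Path],
    participants_path: Union[str, Path],
    codebook: Codebook,
) -> StudyDataset:
    """Read and validate long-format ESM and participant CSVs."""
    obs = pd.read_csv(esm_path, dtype={"participant_id": str})
    part = pd.read_csv(participants_path, dtype={"participant_id": str})
    if "timestamp" not in obs.columns:
        raise SchemaError("ESM table missing required column 'timestamp'")
    obs["timestamp"] = pd.to_datetime(obs["timestamp"], errors="raise")
    known = set(BASE_COLUMNS) | {"burst"} | set(codebook.ids)
    extra = [c for c in obs.columns if c not in known]
    if extra:
        raise SchemaError(
            f"unknown ESM columns {extra}; tactic columns must match codebook ids"
        )
    if "burst" not in obs.columns:
        obs["burst"] = pd.NA
    ds = StudyDataset(obs, part, codebook)
    ds.validate()
    return ds


def assign_bursts(
    dataset: StudyDataset,
    gap_days: float = DEFAULT_GAP_DAYS,
    recompute: bool = True,
) -> StudyDataset:
    """Segment each participant's prompts into bursts by inter-response gaps.

    Rows are sorted by timestamp within participant; a new burst starts
    whenever the gap to the previous response is >= ``gap_days``.  Burst
    indices are 1-based and consecutive.  If the table already carries a
    complete burst column and ``recompute`` is False, it is honored.
    """
    ds = dataset.copy()
    obs = ds.observations
    if not recompute and obs["burst"].notna().all():
        obs["burst"] = obs["burst"].astype(int)
        return ds
    obs = obs.sort_values(["participant_id", "timestamp"], kind="mergesort")
    gap = pd.Timedelta(days=gap_days)
    deltas = obs.groupby("participant_id")["timestamp"].diff()
    new_burst = (deltas >= gap) | deltas.isna()
    obs["burst"] = new_burst.groupby(obs["participant_id"]).cumsum().astype(int)
    ds.observations = obs.reset_index(drop=True)
    return ds


def filter_eligible(
    dataset: StudyDataset, min_instances: int = DEFAULT_MIN_INSTANCES
) -> StudyDataset:
    """Keep participants with >=1 burst containing >= ``min_instances`` prompts.

    Idempotent; removals are logged with per-participant burst sizes.
    """
    obs = dataset.observations
    if len(obs) == 0:
        return dataset.copy()
    if obs["burst"].isna().any():
        raise ValueError("bursts must be assigned before eligibility filtering")
    sizes = obs.groupby(["participant_id", "burst"]).size()
    best = sizes.groupby("participant_id").max()
    keep = set(best[best >= min_instances].index)
    dropped = sorted(set(obs["participant_id"]) - keep)
    if dropped:
        log.info(
            "eligibility filter removed %d participant(s): %s",
            len(dropped),
            dropped[:10],
        )
    ds = dataset.copy()
    ds.observations = obs[obs["participant_id"].isin(keep)].reset_index(drop=True)
    ds.participants = dataset.participants[
        dataset.participants["participant_id"].isin(keep)
    ].reset_index(drop=True)
    return ds


def regulation_instances(dataset: StudyDataset) -> tuple[pd.DataFrame, float]:
    """Return the regulation instances and their proportion of all prompts.

    An instance must have regulated = 1 and endorse at least one codebook
    tactic; "yes, I regulated" rows with no tactic are excluded.
    """
    obs = dataset.observations
    tcols = dataset.tactic_columns
    if len(obs) == 0:
        return obs.copy(), float("nan")
    used_any = obs[tcols].fillna(0).sum(axis=1) > 0
    mask = (obs["regulated"] == 1) & used_any
    instances = obs[mask].copy()
    proportion = float(mask.mean())
    log.info(
        "%d of %d prompts are regulation instances (%.1f%%)",
        len(instances),
        len(obs),
        100 * proportion,
    )
    return instances, proportion


def write_esm_csv(dataset: StudyDataset, esm_path, participants_path) -> None:
    """Write a StudyDataset back to the documented CSV pair."""
    cols = ["participant_id", "timestamp", "burst", "regulated"]
    cols += list(dataset.tactic_columns) + ["pre_affect", "post_affect"]
    out = dataset.observations[[c for c in cols if c in dataset.observations.columns]]
    out.to_csv(esm_path, index=False)
    dataset.participants.to_csv(participants_path, index=False)
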