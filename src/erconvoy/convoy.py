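"""Emotion-regulation convoys: person-specific tertile banding of tactic use.

A convoy summarizes one participant's regulation behavior in a burst as
three frequency bands, by analogy to social convoys: an *inner circle* of
the most-used tactics ("top tactics"), a *middle circle*, and an *outer
circle* of seldom-used tactics.

Construction, per participant:

1.  Within each burst, count how often each tactic was endorsed across the
    participant's regulation instances and convert to a percentage of
    instances (instances may endorse several tactics, so percentages need
    not sum to 100).  Tactics with zero uses are excluded from the convoy.
2.  Sort the used-tactic percentages of the *anchor burst* (the first
    burst with any instances) ascending and take the values at the
    nearest-rank 67th and 33rd percentile positions — ceil(0.67*n) and
    ceil(0.33*n) — as that participant's fixed upper and lower cut-points.
3.  In every burst, place each used tactic by comparing its percentage p
    against the fixed cut-points: inner if p >= upper; otherwise outer if
    p <= lower (default ``outer_wins`` precedence; under ``middle_wins``
    the outer rule is strict p < lower); otherwise middle.

Because the cut-points are person-specific, two participants with the same
absolute frequency of a tactic can band it differently — the convoy
captures *relative* reliance.  Instance-level "top tactic" codings flag,
for each regulation instance, whether it used any inner-circle tactic and
whether it used an inner-circle tactic of each valence category.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .codebook import Codebook
from .esm_io import StudyDataset, regulation_instances

log = logging.getLogger(__name__)

CIRCLES = ("inner", "middle", "outer")
BoundaryRule = Literal["outer_wins", "middle_wins"]
PercentileConvention = Literal["nearest_rank", "interpolated"]


@dataclass(frozen=True)
class TacticProfile:
    """Per participant x burst tactic counts and use percentages.

    ``percentages`` maps each *used* tactic to 100 * count / n_instances;
    zero-count tactics have no entry.
    """

    participant_id: str
    burst: int
    n_instances: int
    counts: dict[str, int]
    percentages: dict[str, float]


@dataclass(frozen=True)
class ConvoyCutoffs:
    """A participant's fixed tertile cut-points, anchored to one burst."""

    participant_id: str
    upper: float
    lower: float
    anchor_burst: int


@dataclass(frozen=True)
class Convoy:
    """Circle membership of every used tactic for one participant x burst."""

    participant_id: str
    burst: int
    circle_of: dict[str, str]
    cutoffs: ConvoyCutoffs

    def tactics_in(self, circle: str) -> tuple[str, ...]:
        return tuple(t for t, c in self.circle_of.items() if c == circle)


def tactic_profile(
    instances: pd.DataFrame, codebook: Codebook
) -> Optional[TacticProfile]:
    """Counts and percentages for one participant x burst's instances.

    Returns None (and logs) for an empty instance set.
    """
    if len(instances) == 0:
        log.info("empty instance set; no profile")
        return None
    pids = instances["participant_id"].unique()
    bursts = instances["burst"].unique()
    if len(pids) != 1 or len(bursts) != 1:
        raise ValueError("instances must belong to a single participant and burst")
    n = len(instances)
    tcols = [t for t in codebook.ids if t in instances.columns]
    counts = instances[tcols].fillna(0).astype(int).sum()
    used = counts[counts > 0]
    return TacticProfile(
        participant_id=str(pids[0]),
        burst=int(bursts[0]),
        n_instances=n,
        counts={t: int(c) for t, c in counts.items()},
        percentages={t: 100.0 * c / n for t, c in used.items()},
    )


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    """Value at the nearest-rank position ceil(q*n) of an ascending array."""
    n = len(sorted_vals)
    pos = max(1, math.ceil(q * n))
    return float(sorted_vals[min(pos, n) - 1])


def derive_cutoffs(
    profile: TacticProfile,
    convention: PercentileConvention = "nearest_rank",
) -> ConvoyCutoffs:
    """Upper/lower tertile cut-points from a profile's used-tactic percentages.

    Default convention: nearest-rank positions ceil(0.67*n), ceil(0.33*n)
    on the ascending-sorted percentages.  ``interpolated`` uses linear
    quantile interpolation instead.
    """
    vals = np.sort(np.asarray(list(profile.percentages.values()), dtype=float))
    if len(vals) == 0:
        raise ValueError(
            f"participant {profile.participant_id}: no used tactics to derive "
            "cut-points from"
        )
    if convention == "nearest_rank":
        upper = _nearest_rank(vals, 0.67)
        lower = _nearest_rank(vals, 0.33)
    elif convention == "interpolated":
        upper = float(np.quantile(vals, 0.67))
        lower = float(np.quantile(vals, 0.33))
    else:
        raise ValueError(f"unknown percentile convention {convention!r}")
    return ConvoyCutoffs(profile.participant_id, upper, lower, profile.burst)


def assign_circles(
    profile: TacticProfile,
    cutoffs: ConvoyCutoffs,
    boundary_rule: BoundaryRule = "outer_wins",
) -> Convoy:
    """Band each used tactic against the participant's fixed cut-points.

    The cut-points come from the anchor burst even when ``profile`` is a
    later burst; tactics unused in the anchor burst are banded by the same
    numeric comparison.  Equal percentages always share a circle.
    """
    if boundary_rule not in ("outer_wins", "middle_wins"):
        raise ValueError(f"unknown boundary_rule {boundary_rule!r}")
    circle_of: dict[str, str] = {}
    for t, p in profile.percentages.items():
        if p >= cutoffs.upper:
            circle_of[t] = "inner"
        elif (p <= cutoffs.lower) if boundary_rule == "outer_wins" else (p < cutoffs.lower):
            circle_of[t] = "outer"
        else:
            circle_of[t] = "middle"
    return Convoy(profile.participant_id, profile.burst, circle_of, cutoffs)


def circle_category_shares(convoy: Convoy, codebook: Codebook) -> pd.DataFrame:
    """Per-circle proportions of tactics in each valence category.

    For each non-empty circle, share(category) = (# circle tactics in the
    category) / (# circle tactics); shares over categories sum to 1.
    Returns a long table (participant_id, burst, circle, category, share)
    with rows for every category present in the codebook; empty circles
    yield no rows.
    """
    rows = []
    cats = codebook.categories_present
    for circle in CIRCLES:
        tactics = convoy.tactics_in(circle)
        if not tactics:
            log.debug(
                "participant %s burst %d: empty %s circle",
                convoy.participant_id,
                convoy.burst,
                circle,
            )
            continue
        n = len(tactics)
        for cat in cats:
            k = sum(1 for t in tactics if codebook.category_of(t) == cat)
            rows.append(
                {
                    "participant_id": convoy.participant_id,
                    "burst": convoy.burst,
                    "circle": circle,
                    "category": cat,
                    "share": k / n,
                }
            )
    return pd.DataFrame(rows, columns=["participant_id", "burst", "circle", "category", "share"])


#: Categories carried as instance-level top-tactic flags, in output order.
_FLAG_CATEGORIES = ("POS_UP", "NEG_DOWN", "NEG_UP", "ACCEPTANCE")


def code_top_tactics(
    instances: pd.DataFrame,
    convoys: dict[tuple[str, int], Convoy],
    codebook: Codebook,
) -> pd.DataFrame:
    """Instance-level 0/1 top-tactic codings.

    For each regulation instance: ``top_any`` = 1 iff the instance endorsed
    at least one tactic in the participant's inner circle for that burst;
    ``top_<category>`` = 1 iff it endorsed an inner-circle tactic of that
    category.  Flags are independent ORs over the endorsed inner tactics,
    so an instance can raise several category flags at once.  Instances
    whose participant x burst has no convoy are coded missing.
    """
    flag_cols = ["top_any"] + [f"top_{c.lower()}" for c in _FLAG_CATEGORIES]
    out = instances.copy()
    for col in flag_cols:
        out[col] = pd.NA
    tcols = [t for t in codebook.ids if t in instances.columns]
    n_missing = 0
    for idx, row in instances.iterrows():
        key = (str(row["participant_id"]), int(row["burst"]))
        convoy = convoys.get(key)
        if convoy is None:
            n_missing += 1
            continue
        inner = set(convoy.tactics_in("inner"))
        used = [t for t in tcols if row[t] == 1]
        used_inner = [t for t in used if t in inner]
        out.loc[idx, "top_any"] = int(bool(used_inner))
        for cat in _FLAG_CATEGORIES:
            out.loc[idx, f"top_{cat.lower()}"] = int(
                any(codebook.category_of(t) == cat for t in used_inner)
            )
    if n_missing:
        log.info("%d instance(s) had no convoy and were coded missing", n_missing)
    return out


def code_category_use(instances: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    """Instance-level 0/1 raw category-use indicators.

    ``used_<category>`` = 1 iff the instance endorsed any tactic of that
    category, regardless of convoy circle; ``used_any`` = 1 iff any
    tactic at all was endorsed (identically 1 on regulation instances).
    Useful as ground-truth predictors in simulation studies.
    """
    out = instances.copy()
    tcols = [t for t in codebook.ids if t in instances.columns]
    vals = out[tcols].fillna(0).astype(int)
    out["used_any"] = (vals.sum(axis=1) > 0).astype(int)
    for cat in _FLAG_CATEGORIES:
        cat_cols = [t.id for t in codebook.by_category(cat) if t.id in tcols]
        if cat_cols:
            out[f"used_{cat.lower()}"] = (vals[cat_cols].sum(axis=1) > 0).astype(int)
        else:
            out[f"used_{cat.lower()}"] = 0
    return out


@dataclass
class ConvoyResults:
    """End-to-end convoy pipeline outputs for a study."""

    profiles: dict[tuple[str, int], TacticProfile]
    cutoffs: dict[str, ConvoyCutoffs]
    convoys: dict[tuple[str, int], Convoy]
    shares: pd.DataFrame
    codings: pd.DataFrame
    instance_proportion: float
    options: dict = field(default_factory=dict)

    def convoys_frame(self) -> pd.DataFrame:
        """Long table: participant_id, burst, tactic_id, count, percentage, circle."""
        rows = []
        for (pid, burst), convoy in sorted(self.convoys.items()):
            prof = self.profiles[(pid, burst)]
            for t in sorted(convoy.circle_of):
                rows.append(
                    {
                        "participant_id": pid,
                        "burst": burst,
                        "tactic_id": t,
                        "count": prof.counts[t],
                        "percentage": prof.percentages[t],
                        "circle": convoy.circle_of[t],
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["participant_id", "burst", "tactic_id", "count", "percentage", "circle"],
        )

    def cutoffs_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": c.participant_id,
                "upper": c.upper,
                "lower": c.lower,
                "anchor_burst": c.anchor_burst,
            }
            for c in sorted(self.cutoffs.values(), key=lambda c: c.participant_id)
        ]
        return pd.DataFrame(rows, columns=["participant_id", "upper", "lower", "anchor_burst"])


def build_convoys(
    dataset: StudyDataset,
    codebook: Optional[Codebook] = None,
    boundary_rule: BoundaryRule = "outer_wins",
    convention: PercentileConvention = "nearest_rank",
) -> ConvoyResults:
    """Run the full convoy pipeline on a burst-assigned, filtered dataset.

    Deterministic given inputs and options; participants are processed
    independently.  Participants with no anchor-burst instances at all are
    skipped; participants whose first burst has no instances anchor to
    their first burst that has any (flagged in the log).
    """
    codebook = codebook or dataset.codebook
    instances, proportion = regulation_instances(dataset)
    profiles: dict[tuple[str, int], TacticProfile] = {}
    for (pid, burst), group in instances.groupby(["participant_id", "burst"]):
        prof = tactic_profile(group, codebook)
        if prof is not None:
            profiles[(str(pid), int(burst))] = prof

    cutoffs: dict[str, ConvoyCutoffs] = {}
    for pid in sorted({k[0] for k in profiles}):
        bursts = sorted(b for (p, b) in profiles if p == pid)
        anchor = bursts[0]
        if anchor != 1:
            log.info(
                "participant %s has no burst-1 instances; anchoring cut-points "
                "to burst %d",
                pid,
                anchor,
            )
        cutoffs[pid] = derive_cutoffs(profiles[(pid, anchor)], convention)

    convoys = {
        key: assign_circles(prof, cutoffs[key[0]], boundary_rule)
        for key, prof in profiles.items()
    }
    shares = pd.concat(
        [circle_category_shares(c, codebook) for _, c in sorted(convoys.items())],
        ignore_index=True,
    ) if convoys else pd.DataFrame(
        columns=["participant_id", "burst", "circle", "category", "share"]
    )
    codings = code_top_tactics(instances, convoys, codebook)
    return ConvoyResults(
        profiles=profiles,
        cutoffs=cutoffs,
        convoys=convoys,
        shares=shares,
        codings=codings,
        instance_proportion=proportion,
        options={
            "boundary_rule": boundary_rule,
            "percentile_convention": convention,
            "codebook_digest": codebook.digest(),
        },
    )
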