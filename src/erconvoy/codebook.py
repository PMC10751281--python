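"""Tactic codebook: the taxonomy of emotion-regulation tactics.

An emotion-regulation *strategy* is a family from the process model
(situation selection, situation modification, attentional deployment,
cognitive change, response modulation), plus acceptance.  A *tactic* is a
concrete, valence-specific implementation of a strategy ("enter or seek out
positive situations").  Tactics are grouped across strategies into
valence-based *categories*: positivity-upregulating (POS_UP),
negativity-downregulating (NEG_DOWN), negativity-upregulating (NEG_UP) and
ACCEPTANCE.  An OTHER category is available for user-defined tactics that
fall outside that scheme.

The default codebook ships 17 tactics: one POS_UP, NEG_DOWN and NEG_UP
tactic per process-model strategy (5 each) plus emotional and situational
acceptance (2).  Users may supply their own codebook as YAML or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

import yaml

STRATEGIES = frozenset(
    {
        "situation_selection",
        "situation_modification",
        "attentional_deployment",
        "cognitive_change",
        "response_modulation",
        "acceptance",
    }
)

CATEGORIES = ("POS_UP", "NEG_DOWN", "NEG_UP", "ACCEPTANCE", "OTHER")


class CodebookError(ValueError):
    """Invalid codebook definition (duplicate id, unknown vocabulary token...)."""


@dataclass(frozen=True)
class TacticCode:
    """One tactic: a short unique id, a label, its strategy and category."""

    id: str
    label: str
    strategy: str
    category: str

    def __post_init__(self) -> None:
        if not self.id or not isinstance(self.id, str):
            raise CodebookError(f"tactic id must be a non-empty string, got {self.id!r}")
        if self.strategy not in STRATEGIES:
            raise CodebookError(
                f"tactic {self.id!r}: unknown strategy {self.strategy!r}; "
                f"expected one of {sorted(STRATEGIES)}"
            )
        if self.category not in CATEGORIES:
            raise CodebookError(
                f"tactic {self.id!r}: unknown category {self.category!r}; "
                f"expected one of {list(CATEGORIES)}"
            )


@dataclass(frozen=True)
class Codebook:
    """Ordered collection of tactics with unique ids."""

    tactics: tuple[TacticCode, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.tactics:
            if t.id in seen:
                raise CodebookError(f"duplicate tactic id {t.id!r}")
            seen.add(t.id)

    def __len__(self) -> int:
        return len(self.tactics)

    def __iter__(self) -> Iterator[TacticCode]:
        return iter(self.tactics)

    def __getitem__(self, tactic_id: str) -> TacticCode:
        for t in self.tactics:
            if t.id == tactic_id:
                return t
        raise KeyError(tactic_id)

    def __contains__(self, tactic_id: str) -> bool:
        return any(t.id == tactic_id for t in self.tactics)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(t.id for t in self.tactics)

    def category_of(self, tactic_id: str) -> str:
        return self[tactic_id].category

    def by_category(self, category: str) -> tuple[TacticCode, ...]:
        if category not in CATEGORIES:
            raise CodebookError(f"unknown category {category!r}")
        return tuple(t for t in self.tactics if t.category == category)

    @property
    def categories_present(self) -> tuple[str, ...]:
        """Categories with at least one tactic, in canonical order."""
        present = {t.category for t in self.tactics}
        return tuple(c for c in CATEGORIES if c in present)

    def to_records(self) -> list[dict]:
        return [
            {"id": t.id, "label": t.label, "strategy": t.strategy, "category": t.category}
            for t in self.tactics
        ]

    def digest(self) -> str:
        """Stable content hash, recorded in run metadata for provenance."""
        import hashlib

        payload = json.dumps(self.to_records(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class AgeGroup:
    """A labelled inclusive age band in years."""

    label: str
    min_age: int
    max_age: int

    def __contains__(self, age_years: int) -> bool:
        return self.min_age <= age_years <= self.max_age


#: Default study age bands: young (YA), middle-aged (MA) and older (OA) adults.
DEFAULT_AGE_GROUPS: tuple[AgeGroup, ...] = (
    AgeGroup("YA", 18, 39),
    AgeGroup("MA", 40, 59),
    AgeGroup("OA", 60, 87),
)


def age_group_of(
    age_years: int, groups: Iterable[AgeGroup] = DEFAULT_AGE_GROUPS
) -> str:
    """Return the label of the unique age group containing ``age_years``."""
    for g in groups:
        if age_years in g:
            return g.label
    bounds = ", ".join(f"{g.label}: {g.min_age}-{g.max_age}" for g in groups)
    raise ValueError(f"age {age_years} outside all age-group ranges ({bounds})")


_DEFAULT_ROWS: tuple[tuple[str, str, str, str], ...] = (
    # (id, label, strategy, category)
    ("ss_seek_pos", "Enter or seek out positive situations", "situation_selection", "POS_UP"),
    ("sm_make_pos", "Change a situation to make it more positive", "situation_modification", "POS_UP"),
    ("ad_attend_pos", "Pay attention to positive aspects of a situation", "attentional_deployment", "POS_UP"),
    ("cc_think_pos", "Think about the positive aspects or consequences of the situation", "cognitive_change", "POS_UP"),
    ("rm_smile", "Put on a smile even if you felt negative", "response_modulation", "POS_UP"),
    ("ss_avoid_neg", "Avoid or leave negative situations", "situation_selection", "NEG_DOWN"),
    ("sm_make_less_neg", "Change a situation to make it less negative", "situation_modification", "NEG_DOWN"),
    ("ad_distract_neg", "Ignore or distract yourself from negative aspects of a situation", "attentional_deployment", "NEG_DOWN"),
    ("cc_distance", "Distance yourself or analyze the situation objectively", "cognitive_change", "NEG_DOWN"),
    ("rm_hide", "Hide the expression of emotion you were feeling", "response_modulation", "NEG_DOWN"),
    ("ss_seek_neg", "Enter or seek out negative situations", "situation_selection", "NEG_UP"),
    ("sm_make_neg", "Change a situation to make it more negative", "situation_modification", "NEG_UP"),
    ("ad_attend_neg", "Pay attention to the negative aspects of a situation", "attentional_deployment", "NEG_UP"),
    ("cc_think_neg", "Think about the negative aspects or consequences of the situation", "cognitive_change", "NEG_UP"),
    ("rm_express", "Intentionally express or exaggerate expressions", "response_modulation", "NEG_UP"),
    ("acc_emotion", "Accept current emotions at any point", "acceptance", "ACCEPTANCE"),
    ("acc_situation", "Accept the current situation at any point", "acceptance", "ACCEPTANCE"),
)


def default_codebook() -> Codebook:
    """The default 17-tactic codebook (5 POS_UP, 5 NEG_DOWN, 5 NEG_UP, 2 ACCEPTANCE)."""
    return Codebook(tuple(TacticCode(*row) for row in _DEFAULT_ROWS))


def load_codebook(path: Union[str, Path]) -> Codebook:
    """Load and validate a codebook from a YAML or JSON file.

    The file holds a list of entries with keys ``id``, ``label``,
    ``strategy``, ``category`` (optionally nested under a ``tactics`` key).
    """
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise CodebookError(f"cannot parse codebook file {path}: {exc}") from exc
    if isinstance(data, dict) and "tactics" in data:
        data = data["tactics"]
    if not isinstance(data, list):
        raise CodebookError(f"{path}: expected a list of tactic entries")
    tactics = []
    for i, entry in enumerate(data):
        if not isinstance(entry, dict):
            raise CodebookError(f"{path}: entry {i} is not a mapping")
        missing = {"id", "label", "strategy", "category"} - entry.keys()
        if missing:
            raise CodebookError(f"{path}: entry {i} missing fields {sorted(missing)}")
        tactics.append(
            TacticCode(entry["id"], entry["label"], entry["strategy"], entry["category"])
        )
    return Codebook(tuple(tactics))


def write_codebook(codebook: Codebook, path: Union[str, Path]) -> None:
    """Serialize a codebook to YAML or JSON (by file extension)."""
    path = Path(path)
    records = codebook.to_records()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(records, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(records, sort_keys=False))
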