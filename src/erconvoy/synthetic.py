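"""Seeded generator of synthetic ESM studies.

The generator emulates the study design the analysis pipeline assumes:
three 7-day measurement bursts of five prompts per day separated by
four-week gaps, a branching survey in which roughly 27% of prompts become
regulation instances, multi-tactic instances drawn from age-group-tilted
tactic propensities, and pre/post affect on a 1-7 Likert scale produced
by rounding and clamping a latent Gaussian two-level model:

    post* = gamma00 + u0 + b_pre_w * (pre* - person pre mean)
            + b_pre_b * (person pre deviation)
            + sum_c beta_c * used_c + eps,
    u0 ~ N(0, tau00),  eps ~ N(0, sigma2),

where ``used_c`` indicates that the instance endorsed at least one tactic
of category c.  Per-person random slopes on the category indicators are
optional.  The realized random effects and every configured parameter are
returned as ground truth, so parameter-recovery studies can compare
estimates against the generating values.

All randomness flows from the single ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .codebook import Codebook, DEFAULT_AGE_GROUPS, default_codebook
from .esm_io import StudyDataset

_CATEGORY_EFFECT_KEYS = ("POS_UP", "NEG_DOWN", "NEG_UP", "ACCEPTANCE", "OTHER")


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic ESM study."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"YA": 82, "MA": 77, "OA": 77}
    )
    bursts: int = 3
    days_per_burst: int = 7
    prompts_per_day: int = 5
    burst_gap_days: int = 28
    p_regulation: float = 0.27
    #: per age group, tactic id -> per-instance endorsement probability
    propensities: dict[str, dict[str, float]] = field(default_factory=dict)
    gamma00: float = 5.2
    b_pre_within: float = 0.45
    b_pre_between: float = 0.08
    #: category -> fixed effect of using that category on post affect
    category_effects: dict[str, float] = field(default_factory=dict)
    tau00: float = 0.72
    sigma2: float = 1.08
    #: category -> variance of per-person random slopes (0 = homogeneous)
    slope_variances: dict[str, float] = field(default_factory=dict)
    pre_mean: float = 4.2
    pre_between_var: float = 0.55
    pre_within_var: float = 1.2
    #: extra residual variance multiplier per age group (1.0 = homogeneous)
    residual_scale_by_group: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.13
    seed: int = 0

    def validate(self, codebook: Codebook) -> None:
        if not (0.0 <= self.p_regulation <= 1.0):
            raise ValueError("p_regulation must be in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        for v in (self.tau00, self.sigma2, self.pre_between_var, self.pre_within_var):
            if v < 0:
                raise ValueError("variances must be non-negative")
        for g, props in self.propensities.items():
            for t, p in props.items():
                if t not in codebook:
                    raise ValueError(f"propensity for unknown tactic {t!r}")
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"propensity out of [0,1] for {g}/{t}")
            if self.p_regulation > 0 and all(p == 0.0 for p in props.values()):
                raise ValueError(
                    f"group {g}: all tactic propensities are 0 while regulation "
                    "can occur; instances would be impossible"
                )

    def to_dict(self) -> dict:
        return asdict(self)


def _default_propensities(codebook: Codebook) -> dict[str, dict[str, float]]:
    """Age-group-tilted per-tactic endorsement probabilities.

    Positivity-upregulating tactics are the most endorsed for everyone;
    older adults lean further toward them and away from
    negativity-downregulating tactics, younger adults the opposite.
    Negativity-upregulation is rare throughout.
    """
    base = {"POS_UP": 0.26, "NEG_DOWN": 0.20, "NEG_UP": 0.04, "ACCEPTANCE": 0.30, "OTHER": 0.10}
    tilt = {
        "YA": {"POS_UP": -0.04, "NEG_DOWN": +0.05},
        "MA": {},
        "OA": {"POS_UP": +0.05, "NEG_DOWN": -0.05},
    }
    out: dict[str, dict[str, float]] = {}
    for g in ("YA", "MA", "OA"):
        out[g] = {
            t.id: float(np.clip(base[t.category] + tilt[g].get(t.category, 0.0), 0.01, 0.99))
            for t in codebook
        }
    return out


def preset_paper_like(seed: int = 0) -> SyntheticConfig:
    """A study-scale configuration: 82/77/77 participants across the YA/MA/OA
    age bands, 3 bursts x 7 days x 5 prompts, 27% regulation prompts,
    positivity-upregulating tactics most prevalent, latent two-level affect
    model with between-person share of variance 0.40 and a positive
    within-person positivity-upregulation effect."""
    cfg = SyntheticConfig(seed=seed)
    cfg.propensities = _default_propensities(default_codebook())
    cfg.category_effects = {"POS_UP": 0.36, "NEG_DOWN": -0.10, "NEG_UP": 0.0, "ACCEPTANCE": 0.0}
    return cfg


def preset_parameter_recovery(
    seed: int = 0,
    n_per_group: int = 67,
    icc: float = 0.40,
    pos_up_effect: float = 0.4,
    total_variance: float = 1.8,
) -> SyntheticConfig:
    """A recovery-study configuration: planted latent ICC and a single
    within-person positivity-upregulation effect, all other affect effects
    zero, no missingness.  n_per_group=67 gives ~200 participants."""
    cfg = SyntheticConfig(
        n_per_group={"YA": n_per_group, "MA": n_per_group, "OA": n_per_group},
        gamma00=4.0,
        b_pre_within=0.0,
        b_pre_between=0.0,
        tau00=icc * total_variance,
        sigma2=(1 - icc) * total_variance,
        missing_rate=0.0,
        seed=seed,
    )
    cfg.propensities = _default_propensities(default_codebook())
    cfg.category_effects = {"POS_UP": pos_up_effect, "NEG_DOWN": 0.0, "NEG_UP": 0.0, "ACCEPTANCE": 0.0}
    return cfg


def _likert(x: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(x), 1, 7).astype(int)


def generate_dataset(
    config: SyntheticConfig, codebook: Optional[Codebook] = None
) -> tuple[StudyDataset, dict]:
    """Generate a synthetic StudyDataset and its ground truth.

    Deterministic for a given (config, codebook): identical inputs yield
    bit-identical outputs.
    """
    codebook = codebook or default_codebook()
    if not config.propensities:
        config = SyntheticConfig(**{**config.to_dict(), "propensities": _default_propensities(codebook)})
    config.validate(codebook)
    rng = np.random.default_rng(config.seed)
    groups = {g.label: g for g in DEFAULT_AGE_GROUPS}
    tactic_ids = list(codebook.ids)
    cat_of = {t.id: t.category for t in codebook}

    obs_rows: list[dict] = []
    part_rows: list[dict] = []
    truth_persons: dict[str, dict] = {}
    base = pd.Timestamp("2024-01-06 00:00:00")
    slope_cats = sorted(config.slope_variances)

    pid_counter = 0
    for glabel in sorted(config.n_per_group):
        band = groups[glabel]
        props = config.propensities[glabel]
        prop_vec = np.array([props.get(t, 0.0) for t in tactic_ids])
        resid_scale = config.residual_scale_by_group.get(glabel, 1.0)
        for _ in range(config.n_per_group[glabel]):
            pid_counter += 1
            pid = f"p{pid_counter:04d}"
            age = int(rng.integers(band.min_age, band.max_age + 1))
            u0 = rng.normal(0.0, np.sqrt(config.tau00))
            v0 = rng.normal(0.0, np.sqrt(config.pre_between_var))
            person_slopes = {
                c: rng.normal(0.0, np.sqrt(config.slope_variances[c]))
                for c in slope_cats
            }
            truth_persons[pid] = {
                "age_years": age,
                "age_group": glabel,
                "u0": float(u0),
                "pre_person_dev": float(v0),
                "random_slopes": {k: float(v) for k, v in person_slopes.items()},
            }
            part_rows.append({"participant_id": pid, "age_years": age})

            for b in range(config.bursts):
                burst_start = base + pd.Timedelta(
                    days=b * (config.days_per_burst + config.burst_gap_days)
                )
                for d in range(config.days_per_burst):
                    for j in range(config.prompts_per_day):
                        # draw the whole prompt even when thinned, so the
                        # random stream does not depend on missingness
                        missing = rng.random() < config.missing_rate
                        ts = (
                            burst_start
                            + pd.Timedelta(days=d)
                            + pd.Timedelta(minutes=int(9 * 60 + j * 150 + rng.integers(0, 80)))
                        )
                        regulated = int(rng.random() < config.p_regulation)
                        row: dict = {
                            "participant_id": pid,
                            "timestamp": ts,
                            "regulated": regulated,
                            "pre_affect": pd.NA,
                            "post_affect": pd.NA,
                        }
                        for t in tactic_ids:
                            row[t] = 0
                        if regulated:
                            while True:
                                draws = (rng.random(len(tactic_ids)) < prop_vec).astype(int)
                                if draws.sum() >= 1:
                                    break
                            for t, val in zip(tactic_ids, draws):
                                row[t] = int(val)
                            used_cats = {cat_of[t] for t, v in zip(tactic_ids, draws) if v}
                            pre_lat = config.pre_mean + v0 + rng.normal(
                                0.0, np.sqrt(config.pre_within_var)
                            )
                            eps = rng.normal(0.0, np.sqrt(config.sigma2 * resid_scale))
                            post_lat = (
                                config.gamma00
                                + u0
                                + config.b_pre_within * (pre_lat - (config.pre_mean + v0))
                                + config.b_pre_between * v0
                                + sum(
                                    config.category_effects.get(c, 0.0)
                                    + person_slopes.get(c, 0.0)
                                    for c in used_cats
                                )
                                + eps
                            )
                            row["pre_affect"] = int(_likert(np.array([pre_lat]))[0])
                            row["post_affect"] = int(_likert(np.array([post_lat]))[0])
                        if not missing:
                            obs_rows.append(row)

    columns = ["participant_id", "timestamp", "regulated"] + tactic_ids + [
        "pre_affect",
        "post_affect",
    ]
    obs = pd.DataFrame(obs_rows, columns=columns)
    obs["burst"] = pd.NA
    participants = pd.DataFrame(part_rows, columns=["participant_id", "age_years"])
    dataset = StudyDataset(obs, participants, codebook)
    truth = {
        "config": config.to_dict(),
        "persons": truth_persons,
        "codebook_digest": codebook.digest(),
    }
    return dataset, truth


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
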