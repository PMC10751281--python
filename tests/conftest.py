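import numpy as np
import pandas as pd
import pytest

import erconvoy as ec


@pytest.fixture(scope="session")
def codebook():
    return ec.default_codebook()


def make_dataset(rows, participants, codebook):
    """Build a StudyDataset from sparse row dicts.

    Each row: participant_id, timestamp, regulated, optional burst,
    optional pre/post affect, and a ``tactics`` list of endorsed ids.
    """
    records = []
    for r in rows:
        rec = {
            "participant_id": r["participant_id"],
            "timestamp": pd.Timestamp(r["timestamp"]),
            "burst": r.get("burst", pd.NA),
            "regulated": r.get("regulated", 0),
            "pre_affect": r.get("pre_affect", pd.NA),
            "post_affect": r.get("post_affect", pd.NA),
        }
        for t in codebook.ids:
            rec[t] = 0
        for t in r.get("tactics", ()):
            rec[t] = 1
        records.append(rec)
    obs = pd.DataFrame(records)
    part = pd.DataFrame(participants)
    return ec.StudyDataset(obs, part, codebook)


@pytest.fixture
def worked_example(codebook):
    """One participant, burst 1: 20 regulation instances, 14 endorsing
    ss_seek_pos (so its convoy percentage is 70%), plus acceptance and
    distancing uses to populate the other circles."""
    rows = []
    for i in range(20):
        tactics = []
        if i < 14:
            tactics.append("ss_seek_pos")
        if i < 10:
            tactics.append("acc_emotion")
        if 14 <= i < 18:
            tactics.append("cc_distance")
        if i >= 18:
            tactics.append("acc_situation")
        rows.append(
            {
                "participant_id": "t1",
                "timestamp": f"2024-01-{i + 1:02d} 10:00",
                "burst": 1,
                "regulated": 1,
                "pre_affect": 3,
                "post_affect": 5,
                "tactics": tactics,
            }
        )
    # a few non-regulation prompts
    for i in range(5):
        rows.append(
            {
                "participant_id": "t1",
                "timestamp": f"2024-01-{i + 1:02d} 15:00",
                "burst": 1,
                "regulated": 0,
            }
        )
    return make_dataset(rows, [{"participant_id": "t1", "age_years": 30}], codebook)


@pytest.fixture(scope="session")
def small_study():
    """A small multi-participant synthetic study with bursts assigned and
    eligibility filtered (shared across tests; treat as read-only)."""
    cfg = ec.preset_paper_like(seed=11)
    cfg.n_per_group = {"YA": 5, "MA": 5, "OA": 5}
    ds, _ = ec.generate_dataset(cfg)
    ds = ec.assign_bursts(ds)
    return ec.filter_eligible(ds)


def two_level_frame(
    n_groups=40,
    n_per=12,
    tau00=0.5,
    sigma2=1.0,
    beta_x=0.0,
    slope_var=0.0,
    seed=0,
    sigma2_by_group=None,
):
    """Directly construct a continuous two-level model frame (no Likert
    discretization) for focused mixed-model tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_groups):
        pid = f"g{i:03d}"
        u0 = rng.normal(0, np.sqrt(tau00))
        ui = rng.normal(0, np.sqrt(slope_var)) if slope_var > 0 else 0.0
        s2 = sigma2
        age_group = ["YA", "MA", "OA"][i % 3]
        if sigma2_by_group:
            s2 = sigma2_by_group[age_group]
        for j in range(n_per):
            x = rng.normal(0, 1)
            y = 3.0 + u0 + (beta_x + ui) * x + rng.normal(0, np.sqrt(s2))
            rows.append(
                {
                    "participant_id": pid,
                    "post_affect": y,
                    "x_w": x,
                    "age_group": age_group,
                    "burst_c": j % 3,
                }
            )
    frame = pd.DataFrame(rows)
    frame["x_w"] = frame["x_w"] - frame.groupby("participant_id")["x_w"].transform("mean")
    return frame
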