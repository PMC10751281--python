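import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import erconvoy as ec
from erconvoy.convoy import TacticProfile, ConvoyCutoffs

from conftest import make_dataset


def make_profile(percentages, pid="p1", burst=1, n_instances=100):
    counts = {t: max(1, round(p * n_instances / 100)) for t, p in percentages.items()}
    return TacticProfile(pid, burst, n_instances, counts, dict(percentages))


def oracle_circles(percentages, boundary_rule="outer_wins"):
    """Independent brute-force banding: sort values, read the nearest-rank
    cut positions by explicit indexing, then band by scalar comparison."""
    vals = sorted(percentages.values())
    n = len(vals)
    upper = vals[max(1, math.ceil(0.67 * n)) - 1]
    lower = vals[max(1, math.ceil(0.33 * n)) - 1]
    out = {}
    for t, p in percentages.items():
        if p >= upper:
            out[t] = "inner"
        elif (p <= lower) if boundary_rule == "outer_wins" else (p < lower):
            out[t] = "outer"
        else:
            out[t] = "middle"
    return out


class TestTacticProfile:
    def test_worked_example_70_percent(self, worked_example):
        results = ec.build_convoys(worked_example)
        prof = results.profiles[("t1", 1)]
        assert prof.n_instances == 20
        assert prof.counts["ss_seek_pos"] == 14
        assert prof.percentages["ss_seek_pos"] == pytest.approx(70.0)
        assert "ss_seek_pos" in results.convoys[("t1", 1)].circle_of

    def test_zero_count_tactic_has_no_percentage(self, worked_example):
        results = ec.build_convoys(worked_example)
        prof = results.profiles[("t1", 1)]
        assert "rm_smile" not in prof.percentages
        assert prof.counts["rm_smile"] == 0

    def test_saturated_tactic_is_100(self, codebook):
        rows = [
            {"participant_id": "p1", "timestamp": f"2024-01-{i + 1:02d}", "burst": 1,
             "regulated": 1, "tactics": ["acc_emotion"], "pre_affect": 4, "post_affect": 5}
            for i in range(20)
        ]
        ds = make_dataset(rows, [{"participant_id": "p1", "age_years": 44}], codebook)
        instances, _ = ec.regulation_instances(ds)
        prof = ec.tactic_profile(instances, codebook)
        assert prof.percentages["acc_emotion"] == pytest.approx(100.0)

    def test_empty_instances_yield_none(self, codebook):
        instances = pd.DataFrame(columns=["participant_id", "burst"] + list(codebook.ids))
        assert ec.tactic_profile(instances, codebook) is None

    def test_counts_cover_instances(self, worked_example):
        # every instance uses >= 1 tactic, so counts sum >= n_instances
        results = ec.build_convoys(worked_example)
        prof = results.profiles[("t1", 1)]
        assert sum(prof.counts.values()) >= prof.n_instances


class TestDeriveCutoffs:
    def test_three_distinct_values_partition_one_each(self):
        prof = make_profile({"a": 60.0, "b": 30.0, "c": 10.0})
        cut = ec.derive_cutoffs(prof)
        assert (cut.upper, cut.lower) == (60.0, 10.0)
        convoy = ec.assign_circles(prof, cut)
        assert convoy.circle_of == {"a": "inner", "b": "middle", "c": "outer"}

    def test_single_tactic_lands_inner(self):
        prof = make_profile({"a": 100.0})
        cut = ec.derive_cutoffs(prof)
        assert cut.upper == cut.lower == 100.0
        assert ec.assign_circles(prof, cut).circle_of == {"a": "inner"}

    def test_two_tactics_split_inner_outer(self):
        prof = make_profile({"a": 80.0, "b": 20.0})
        convoy = ec.assign_circles(prof, ec.derive_cutoffs(prof))
        assert convoy.circle_of == {"a": "inner", "b": "outer"}

    def test_six_distinct_top_two_inner(self):
        pcts = {f"t{i}": 10.0 * (i + 1) for i in range(6)}
        convoy = ec.assign_circles(make_profile(pcts), ec.derive_cutoffs(make_profile(pcts)))
        inner = {t for t, c in convoy.circle_of.items() if c == "inner"}
        assert inner == {"t4", "t5"}

    def test_empty_profile_errors(self):
        prof = TacticProfile("p1", 1, 5, {}, {})
        with pytest.raises(ValueError, match="no used tactics"):
            ec.derive_cutoffs(prof)

    def test_interpolated_convention_available(self):
        prof = make_profile({"a": 60.0, "b": 30.0, "c": 10.0})
        cut = ec.derive_cutoffs(prof, convention="interpolated")
        assert cut.lower <= cut.upper
        assert cut.lower != 10.0  # interpolation moves off the order statistic


class TestBoundaryRules:
    def test_value_at_upper_is_inner(self):
        prof = make_profile({"a": 50.0, "b": 30.0, "c": 10.0})
        cut = ConvoyCutoffs("p1", upper=50.0, lower=10.0, anchor_burst=1)
        assert ec.assign_circles(prof, cut).circle_of["a"] == "inner"

    def test_value_at_lower_outer_wins(self):
        prof = make_profile({"a": 50.0, "b": 30.0, "c": 10.0})
        cut = ConvoyCutoffs("p1", upper=50.0, lower=30.0, anchor_burst=1)
        assert ec.assign_circles(prof, cut, "outer_wins").circle_of["b"] == "outer"

    def test_value_at_lower_middle_wins(self):
        prof = make_profile({"a": 50.0, "b": 30.0, "c": 10.0})
        cut = ConvoyCutoffs("p1", upper=50.0, lower=30.0, anchor_burst=1)
        assert ec.assign_circles(prof, cut, "middle_wins").circle_of["b"] == "middle"

    def test_new_tactic_in_later_burst_banded_by_fixed_cutpoints(self):
        cut = ConvoyCutoffs("p1", upper=40.0, lower=15.0, anchor_burst=1)
        prof2 = make_profile({"never_before": 55.0, "old": 20.0}, burst=2)
        convoy = ec.assign_circles(prof2, cut)
        assert convoy.circle_of["never_before"] == "inner"
        assert convoy.circle_of["old"] == "middle"


class TestOracleEquivalence:
    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        pcts=st.lists(
            st.floats(min_value=1.0, max_value=100.0, allow_nan=False),
            min_size=1,
            max_size=8,
        ),
        rule=st.sampled_from(["outer_wins", "middle_wins"]),
    )
    def test_matches_bruteforce_oracle(self, pcts, rule):
        percentages = {f"t{i}": p for i, p in enumerate(pcts)}
        prof = make_profile(percentages)
        convoy = ec.assign_circles(prof, ec.derive_cutoffs(prof), rule)
        assert convoy.circle_of == oracle_circles(percentages, rule)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(pcts=st.lists(st.floats(min_value=1.0, max_value=100.0), min_size=1, max_size=8))
    def test_partition_and_order(self, pcts):
        percentages = {f"t{i}": p for i, p in enumerate(pcts)}
        prof = make_profile(percentages)
        convoy = ec.assign_circles(prof, ec.derive_cutoffs(prof))
        assert set(convoy.circle_of) == set(percentages)  # circles partition used tactics
        rank = {"inner": 0, "middle": 1, "outer": 2}
        for a in percentages:
            for b in percentages:
                if percentages[a] > percentages[b]:
                    assert rank[convoy.circle_of[a]] <= rank[convoy.circle_of[b]]
                if percentages[a] == percentages[b]:
                    assert convoy.circle_of[a] == convoy.circle_of[b]

    def test_monotonicity_under_count_increment(self):
        rng = np.random.default_rng(5)
        rank = {"inner": 0, "middle": 1, "outer": 2}
        for _ in range(200):
            n = int(rng.integers(2, 9))
            n_inst = 20
            counts = {f"t{i}": int(rng.integers(1, n_inst + 1)) for i in range(n)}
            pcts = {t: 100.0 * c / n_inst for t, c in counts.items()}
            prof = make_profile(pcts, n_instances=n_inst)
            before = ec.assign_circles(prof, ec.derive_cutoffs(prof))
            target = f"t{int(rng.integers(0, n))}"
            if counts[target] >= n_inst:
                continue
            bumped = dict(pcts)
            bumped[target] = 100.0 * (counts[target] + 1) / n_inst
            prof2 = make_profile(bumped, n_instances=n_inst)
            after = ec.assign_circles(prof2, ec.derive_cutoffs(prof2))
            assert rank[after.circle_of[target]] <= rank[before.circle_of[target]]

    def test_relabeling_invariance(self):
        pcts = {"a": 70.0, "b": 40.0, "c": 40.0, "d": 5.0}
        prof = make_profile(pcts)
        cut = ec.derive_cutoffs(prof)
        convoy = ec.assign_circles(prof, cut)
        mapping = {"a": "z", "b": "y", "c": "x", "d": "w"}
        prof2 = make_profile({mapping[t]: p for t, p in pcts.items()})
        cut2 = ec.derive_cutoffs(prof2)
        assert (cut2.upper, cut2.lower) == (cut.upper, cut.lower)
        convoy2 = ec.assign_circles(prof2, cut2)
        assert convoy2.circle_of == {mapping[t]: c for t, c in convoy.circle_of.items()}


@pytest.fixture(scope="module")
def study_results():
    cfg = ec.preset_paper_like(seed=23)
    cfg.n_per_group = {"YA": 6, "MA": 6, "OA": 6}
    ds, _ = ec.generate_dataset(cfg)
    ds = ec.assign_bursts(ds)
    return ec.build_convoys(ec.filter_eligible(ds))


class TestAnchoring:
    def test_cutoffs_identical_across_bursts(self, study_results):
        for (pid, burst), convoy in study_results.convoys.items():
            anchor = study_results.cutoffs[pid]
            assert convoy.cutoffs.upper == anchor.upper
            assert convoy.cutoffs.lower == anchor.lower
            assert convoy.cutoffs.anchor_burst == anchor.anchor_burst

    def test_anchor_is_first_burst_with_instances(self, study_results):
        for pid, cut in study_results.cutoffs.items():
            bursts = sorted(b for (p, b) in study_results.profiles if p == pid)
            assert cut.anchor_burst == bursts[0]

    def test_determinism_and_participant_independence(self):
        cfg = ec.preset_paper_like(seed=29)
        cfg.n_per_group = {"YA": 3, "MA": 3, "OA": 3}
        ds, _ = ec.generate_dataset(cfg)
        ds = ec.filter_eligible(ec.assign_bursts(ds))
        r1 = ec.build_convoys(ds)
        r2 = ec.build_convoys(ds)
        assert r1.convoys_frame().equals(r2.convoys_frame())
        # permuting participant row-blocks leaves per-participant output unchanged
        shuffled = ds.copy()
        order = shuffled.observations["participant_id"].unique()[::-1]
        shuffled.observations = pd.concat(
            [shuffled.observations[shuffled.observations["participant_id"] == p] for p in order]
        ).reset_index(drop=True)
        r3 = ec.build_convoys(shuffled)
        f1 = r1.convoys_frame().sort_values(["participant_id", "burst", "tactic_id"]).reset_index(drop=True)
        f3 = r3.convoys_frame().sort_values(["participant_id", "burst", "tactic_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(f1, f3)


class TestCategoryShares:
    def _convoy(self, circle_of, codebook):
        pcts = {t: 50.0 for t in circle_of}
        prof = make_profile(pcts)
        cut = ConvoyCutoffs("p1", 50.0, 10.0, 1)
        return ec.Convoy("p1", 1, dict(circle_of), cut)

    def test_one_pos_up_of_five_is_point_two(self, codebook):
        circle_of = {
            "ss_seek_pos": "inner", "ss_avoid_neg": "inner", "cc_distance": "inner",
            "acc_emotion": "inner", "acc_situation": "inner",
        }
        shares = ec.circle_category_shares(self._convoy(circle_of, codebook), codebook)
        row = shares[(shares["circle"] == "inner") & (shares["category"] == "POS_UP")]
        assert row["share"].iloc[0] == pytest.approx(0.20)

    def test_pure_acceptance_circle(self, codebook):
        circle_of = {"acc_emotion": "inner", "acc_situation": "inner"}
        shares = ec.circle_category_shares(self._convoy(circle_of, codebook), codebook)
        inner = shares[shares["circle"] == "inner"].set_index("category")["share"]
        assert inner["ACCEPTANCE"] == pytest.approx(1.0)
        assert inner.drop("ACCEPTANCE").eq(0).all()

    def test_shares_sum_to_one_per_nonempty_circle(self, small_study):
        results = ec.build_convoys(small_study)
        sums = results.shares.groupby(["participant_id", "burst", "circle"])["share"].sum()
        assert np.allclose(sums, 1.0)

    def test_empty_circle_has_no_rows(self, codebook):
        circle_of = {"acc_emotion": "inner"}  # middle and outer empty
        shares = ec.circle_category_shares(self._convoy(circle_of, codebook), codebook)
        assert set(shares["circle"]) == {"inner"}


class TestTopTacticCoding:
    def _setup(self, codebook, tactics_per_instance):
        rows = [
            {"participant_id": "p1", "timestamp": f"2024-01-{i + 1:02d}", "burst": 1,
             "regulated": 1, "tactics": ts, "pre_affect": 4, "post_affect": 5}
            for i, ts in enumerate(tactics_per_instance)
        ]
        ds = make_dataset(rows, [{"participant_id": "p1", "age_years": 30}], codebook)
        instances, _ = ec.regulation_instances(ds)
        cut = ConvoyCutoffs("p1", 50.0, 10.0, 1)
        convoy = ec.Convoy(
            "p1", 1,
            {"ss_seek_pos": "inner", "cc_distance": "inner", "acc_emotion": "middle",
             "rm_hide": "outer"},
            cut,
        )
        return ec.code_top_tactics(instances, {("p1", 1): convoy}, codebook)

    def test_inner_pos_up_only(self, codebook):
        coded = self._setup(codebook, [["ss_seek_pos"]])
        row = coded.iloc[0]
        assert (row["top_any"], row["top_pos_up"]) == (1, 1)
        assert row["top_neg_down"] == 0 and row["top_acceptance"] == 0 and row["top_neg_up"] == 0

    def test_only_middle_outer_gives_zero(self, codebook):
        coded = self._setup(codebook, [["acc_emotion", "rm_hide"]])
        row = coded.iloc[0]
        assert row["top_any"] == 0
        assert row[["top_pos_up", "top_neg_down", "top_acceptance", "top_neg_up"]].eq(0).all()

    def test_two_inner_categories_raise_both_flags(self, codebook):
        # flags are independent ORs over the endorsed inner tactics:
        # enumerate all 2-subsets of the inner circle
        coded = self._setup(codebook, [["ss_seek_pos", "cc_distance"]])
        row = coded.iloc[0]
        assert (row["top_any"], row["top_pos_up"], row["top_neg_down"]) == (1, 1, 1)

    def test_category_flags_never_exceed_top_any(self, small_study):
        results = ec.build_convoys(small_study)
        coded = results.codings.dropna(subset=["top_any"])
        for c in ("top_pos_up", "top_neg_down", "top_neg_up", "top_acceptance"):
            assert (coded[c].astype(int) <= coded["top_any"].astype(int)).all()

    def test_instance_without_convoy_coded_missing(self, codebook):
        rows = [{"participant_id": "p1", "timestamp": "2024-01-01", "burst": 2,
                 "regulated": 1, "tactics": ["ss_seek_pos"], "pre_affect": 4,
                 "post_affect": 5}]
        ds = make_dataset(rows, [{"participant_id": "p1", "age_years": 30}], codebook)
        instances, _ = ec.regulation_instances(ds)
        coded = ec.code_top_tactics(instances, {}, codebook)
        assert coded["top_any"].isna().all()
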