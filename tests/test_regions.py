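"""Region merging, coverage, overlap and replication statistics."""

import numpy as np
import pandas as pd
import pytest

from acghcnv import (
    Genome, combine_states, coverage_summary, false_negative_rate,
    merge_regions, overlap_statistic, region_presence_from_calls,
    replication_matrix,
)
from conftest import bitarray_union_length


def calls_frame(rows, state="loss"):
    return pd.DataFrame(rows, columns=["strain", "chrom", "start", "end"]) \
        .assign(state=state)


def union_find_clusters(rows):
    """Independent oracle: transitive closure of >=1 bp overlap."""
    parent = list(range(len(rows)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, (_, ci, si, ei) in enumerate(rows):
        for j, (_, cj, sj, ej) in enumerate(rows):
            if i < j and ci == cj and si < ej and sj < ei:
                parent[find(i)] = find(j)
    return {i: find(i) for i in range(len(rows))}


class TestMergeRegions:
    def test_single_call(self):
        calls = calls_frame([("a", "c1", 0, 10)])
        out = merge_regions(calls, "loss", ["ref", "a"])
        assert out[["start", "end", "sdp", "n_strains"]].values.tolist() == \
            [[0, 10, "01", 1]]

    def test_two_strains_union_span(self):
        calls = calls_frame([("a", "c1", 0, 10), ("b", "c1", 5, 15)])
        out = merge_regions(calls, "loss", ["ref", "a", "b"])
        assert out[["start", "end", "sdp"]].values.tolist() == [[0, 15, "011"]]

    def test_bookended_calls_do_not_merge(self):
        calls = calls_frame([("a", "c1", 0, 10), ("b", "c1", 10, 20)])
        assert len(merge_regions(calls, "loss")) == 2

    def test_transitive_chain_becomes_one_region(self):
        calls = calls_frame([("a", "c1", 0, 10), ("b", "c1", 8, 20), ("c", "c1", 18, 30)])
        out = merge_regions(calls, "loss")
        assert out[["start", "end", "n_strains"]].values.tolist() == [[0, 30, 3]]

    def test_mixed_state_rejected(self):
        calls = calls_frame([("a", "c1", 0, 10)])
        calls.loc[0, "state"] = "gain"
        with pytest.raises(ValueError):
            merge_regions(calls, "loss")

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(1)
        rows = [(f"s{rng.integers(4)}", f"c{rng.integers(2)}",
                 int(s), int(s + rng.integers(1000, 20_000)))
                for s in rng.integers(0, 300_000, 80)]
        out = merge_regions(calls_frame(rows), "loss")
        oracle = union_find_clusters(rows)
        assert len(out) == len(set(oracle.values()))
        assert out["n_members"].sum() == len(rows)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        rows = [("a", "c1", int(s), int(s + rng.integers(500, 5000)))
                for s in rng.integers(0, 100_000, 40)]
        once = merge_regions(calls_frame(rows), "loss")
        again = merge_regions(
            once.rename(columns={"strains": "strain"})[
                ["strain", "chrom", "start", "end", "state"]],
            "loss")
        assert once[["chrom", "start", "end"]].equals(again[["chrom", "start", "end"]])


class TestCombineStates:
    def test_disjoint_inputs_concatenate(self):
        loss = merge_regions(calls_frame([("a", "c1", 0, 10)]), "loss")
        gain = merge_regions(calls_frame([("a", "c1", 100, 110)], "gain"), "gain")
        out = combine_states(loss, gain)
        assert len(out) == 2 and not out["mixed"].any()

    def test_nested_loss_in_gain_is_mixed(self):
        loss = merge_regions(calls_frame([("a", "c1", 5, 8)]), "loss")
        gain = merge_regions(calls_frame([("a", "c1", 0, 10)], "gain"), "gain")
        out = combine_states(loss, gain)
        assert out[["start", "end"]].values.tolist() == [[0, 10]]
        assert out["mixed"].all()

    def test_total_length_bounded_by_parts(self):
        rng = np.random.default_rng(3)
        loss = merge_regions(calls_frame(
            [("a", "c1", int(s), int(s + 2000)) for s in rng.integers(0, 500_000, 30)]), "loss")
        gain = merge_regions(calls_frame(
            [("a", "c1", int(s), int(s + 2000)) for s in rng.integers(0, 500_000, 30)],
            "gain"), "gain")
        out = combine_states(loss, gain)
        assert len(np.unique(out["start"])) == len(out)
        combined_len = (out["end"] - out["start"]).sum()
        parts_len = (loss["end"] - loss["start"]).sum() + (gain["end"] - gain["start"]).sum()
        assert combined_len <= parts_len


class TestCoverage:
    def test_one_call_percentages(self):
        genome = Genome([("c1", 100_000_000)])
        calls = calls_frame([("a", "c1", 0, 1_000_000)])
        out = coverage_summary(calls, genome, by="strain")
        assert out.loc[0, "mb"] == pytest.approx(1.0)
        assert out.loc[0, "pct_genome"] == pytest.approx(1.0)
        assert out.loc[0, "median_length"] == 1_000_000

    def test_matches_bitarray_oracle(self):
        genome = Genome([("c1", 400_000)])
        rng = np.random.default_rng(4)
        intervals = [(int(s), int(s + rng.integers(100, 30_000)))
                     for s in rng.integers(0, 350_000, 40)]
        calls = calls_frame([("a", "c1", s, e) for s, e in intervals])
        out = coverage_summary(calls, genome, by="strain")
        expected = bitarray_union_length(intervals, 400_000)
        assert out.loc[0, "mb"] * 1e6 == pytest.approx(expected)


class TestOverlapStatistic:
    def test_identical_sets(self):
        a = calls_frame([("s", "c1", i * 100, i * 100 + 50) for i in range(5)])
        assert overlap_statistic(a, a.copy()) == 1.0

    def test_disjoint_sets(self):
        a = calls_frame([("s", "c1", 0, 10), ("s", "c1", 100, 110)])
        b = calls_frame([("s", "c1", 50, 60), ("s", "c1", 200, 210), ("s", "c1", 300, 310)])
        assert overlap_statistic(a, b) == 0.0

    def test_hand_enumerated_example(self):
        """3 calls each side, one overlapping pair -> 5 regions, statistic 0.2."""
        a = calls_frame([("s", "c1", 0, 10), ("s", "c1", 100, 110), ("s", "c1", 200, 210)])
        b = calls_frame([("s", "c1", 5, 15), ("s", "c1", 400, 410), ("s", "c1", 500, 510)])
        assert overlap_statistic(a, b) == pytest.approx(0.2)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = calls_frame([("s", "c1", int(s), int(s + 1000)) for s in rng.integers(0, 50_000, 10)])
        b = calls_frame([("s", "c1", int(s), int(s + 1000)) for s in rng.integers(0, 50_000, 10)])
        assert overlap_statistic(a, b) == pytest.approx(overlap_statistic(b, a))
        shuffled = a.sample(frac=1, random_state=0).reset_index(drop=True)
        assert overlap_statistic(shuffled, b) == pytest.approx(overlap_statistic(a, b))

    def test_same_strain_required_for_grouping(self):
        a = calls_frame([("s1", "c1", 0, 10)])
        b = calls_frame([("s2", "c1", 5, 15)])
        assert overlap_statistic(a, b) == 0.0


def study(rows):
    return pd.DataFrame(rows, columns=["strain", "chrom", "start", "end", "state"])


class TestReplicationMatrix:
    def test_self_replication_is_100(self):
        s = study([("a", "c1", 0, 10, "loss"), ("a", "c1", 50, 60, "loss")])
        mat = replication_matrix({"A": s, "B": s.copy()}, "loss")
        assert (mat.values == 100.0).all()

    def test_two_single_call_studies(self):
        s1 = study([("a", "c1", 0, 10, "loss")])
        s2 = study([("a", "c1", 5, 15, "loss")])
        mat = replication_matrix({"A": s1, "B": s2}, "loss")
        assert mat.loc["A", "B"] == 100.0 and mat.loc["B", "A"] == 100.0

    def test_abnormal_counts_as_either_state(self):
        s1 = study([("a", "c1", 0, 10, "loss"), ("a", "c1", 100, 110, "gain")])
        s2 = study([("a", "c1", 5, 15, "abnormal"), ("a", "c1", 105, 115, "abnormal")])
        for state in ("loss", "gain"):
            mat = replication_matrix({"A": s1, "B": s2}, state)
            assert mat.loc["A", "B"] == 100.0

    def test_strain_restriction(self):
        """Only strains common to both studies enter the comparison."""
        s1 = study([("a", "c1", 0, 10, "loss"), ("b", "c1", 0, 10, "loss")])
        s2 = study([("a", "c1", 5, 15, "loss")])  # strain b absent
        mat = replication_matrix({"A": s1, "B": s2}, "loss")
        assert mat.loc["A", "B"] == 100.0  # the b call is excluded, not a miss

    def test_no_common_strains_is_nan(self):
        s1 = study([("a", "c1", 0, 10, "loss")])
        s2 = study([("b", "c1", 0, 10, "loss")])
        mat = replication_matrix({"A": s1, "B": s2}, "loss")
        assert np.isnan(mat.loc["A", "B"])

    def test_counting_oracle(self):
        rng = np.random.default_rng(6)
        mk = lambda seed: study([
            ("a", "c1", int(s), int(s + 800), "loss")
            for s in np.random.default_rng(seed).integers(0, 30_000, 12)])
        s1, s2 = mk(7), mk(8)
        mat = replication_matrix({"A": s1, "B": s2}, "loss")
        hits = sum(
            any(r.start < t.end and t.start < r.end for t in s2.itertuples())
            for r in s1.itertuples())
        assert mat.loc["A", "B"] == pytest.approx(round(100 * hits / len(s1), 1), abs=0.05)


class TestFalseNegativeRate:
    def presence(self, rows):
        return pd.DataFrame(rows, columns=["region_id", "strain", "variant"])

    def test_identical_presence_gives_zero(self):
        t = self.presence([("r1", "a", True), ("r2", "a", True)])
        rates = false_negative_rate(t, t.copy())
        assert rates["a"] == 0.0 and rates["mean"] == 0.0

    def test_empty_array_calls_give_one(self):
        t = self.presence([("r1", "a", True), ("r2", "a", True)])
        arr = self.presence([("r1", "a", False), ("r2", "a", False)])
        assert false_negative_rate(t, arr)["a"] == 1.0

    def test_no_targeted_variation_is_nan(self):
        t = self.presence([("r1", "a", False)])
        arr = self.presence([("r1", "a", False)])
        assert np.isnan(false_negative_rate(t, arr)["a"])

    def test_matches_set_difference_oracle(self):
        rng = np.random.default_rng(9)
        regions = [f"r{i}" for i in range(30)]
        t = self.presence([(r, "a", bool(rng.random() < 0.7)) for r in regions])
        arr = self.presence([(r, "a", bool(rng.random() < 0.5)) for r in regions])
        rates = false_negative_rate(t, arr)
        tv = {r for r, _, v in t.itertuples(index=False) if v}
        av = {r for r, _, v in arr.itertuples(index=False) if v}
        assert rates["a"] == pytest.approx(len(tv - av) / len(tv))

    def test_presence_from_calls_uses_overlap(self):
        regions = pd.DataFrame({"region_id": ["r1", "r2"], "chrom": ["c1", "c1"],
                                "start": [0, 1000], "end": [100, 1100]})
        calls = calls_frame([("a", "c1", 50, 80)])
        pres = region_presence_from_calls(regions, calls)
        assert pres.set_index("region_id")["variant"].to_dict() == {"r1": True, "r2": False}
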