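"""CBS segmentation, control-based segment testing, architecture labels."""

import numpy as np
import pandas as pd
import pytest

from acghcnv import (
    CbsParams, ControlStats, call_region, cbs_segment, classify_architecture,
    classify_region, fpr_threshold_sweep,
)
from acghcnv.targeted import test_segment as mw_segment_test

FAST = CbsParams(n_perm=200, seed=0)


@pytest.fixture(scope="module")
def controls():
    rng = np.random.default_rng(100)
    return ControlStats.from_regions([rng.normal(0, 0.25, 230) for _ in range(10)])


def seg_frame(rows):
    return pd.DataFrame(rows, columns=["start", "end", "median_ratio", "mw_p", "state"])


class TestControlStats:
    def test_requires_two_regions(self):
        with pytest.raises(ValueError):
            ControlStats.from_regions([np.zeros(10)])

    def test_sample_sd_of_medians(self):
        cs = ControlStats.from_regions([np.array([0.0, 0.0]), np.array([1.0, 1.0])])
        assert cs.sd_of_medians == pytest.approx(np.std([0, 1], ddof=1))
        assert cs.pooled_values.size == 4


class TestCbs:
    def test_flat_noise_free_profile_is_one_segment(self):
        assert cbs_segment(np.zeros(80), FAST) == [(0, 80)]

    def test_too_few_probes_single_segment(self, caplog):
        with caplog.at_level("WARNING", logger="acghcnv.targeted"):
            assert cbs_segment(np.zeros(5), FAST) == [(0, 5)]
        assert any("single segment" in r.message for r in caplog.records)

    def test_step_profile_breakpoint_recovered(self):
        """0 then -1.5 (50 probes each, noise 0.2): breakpoint within +-3."""
        hits = 0
        for rep in range(25):
            rng = np.random.default_rng(200 + rep)
            x = np.concatenate([rng.normal(0, 0.2, 50), rng.normal(-1.5, 0.2, 50)])
            segs = cbs_segment(x, CbsParams(n_perm=200, seed=rep))
            bounds = sorted({b for s in segs for b in s} - {0, 100})
            hits += any(abs(b - 50) <= 3 for b in bounds)
        assert hits >= 24  # >= 95% of replicates

    def test_two_plants_with_normal_gap_give_three_plus_segments(self):
        """Two deletions separated by normal copy number resolve separately."""
        rng = np.random.default_rng(7)
        x = np.concatenate([
            rng.normal(0, 0.2, 30), rng.normal(-2, 0.2, 25),
            rng.normal(0, 0.2, 30), rng.normal(-2, 0.2, 25),
            rng.normal(0, 0.2, 30),
        ])
        segs = cbs_segment(x, FAST)
        assert len(segs) >= 4
        means = [float(np.mean(x[a:b])) for a, b in segs]
        assert sum(m < -1 for m in means) == 2

    def test_agrees_with_exhaustive_single_split(self):
        """On short single-change-point profiles CBS finds the best split."""
        for rep in range(10):
            rng = np.random.default_rng(300 + rep)
            k = int(rng.integers(10, 40))
            x = np.concatenate([rng.normal(0, 0.1, k), rng.normal(2, 0.1, 50 - k)])
            # exhaustive: best single breakpoint by two-sample statistic
            n = len(x)
            best_k, best_t = None, -np.inf
            for c in range(1, n):
                m1, m2 = x[:c].mean(), x[c:].mean()
                t = abs(m1 - m2) / np.sqrt(1 / c + 1 / (n - c))
                if t > best_t:
                    best_k, best_t = c, t
            segs = cbs_segment(x, CbsParams(n_perm=200, seed=rep))
            assert segs == [(0, best_k), (best_k, n)]

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 0.3, 40), rng.normal(-1, 0.3, 40)])
        assert cbs_segment(x, CbsParams(n_perm=200, seed=5)) == \
            cbs_segment(x, CbsParams(n_perm=200, seed=5))


class TestSegmentTest:
    def test_null_segments_mostly_normal(self, controls):
        """Calibration: segments drawn from the control distribution are
        declared non-normal at roughly the nominal rate or below."""
        rng = np.random.default_rng(9)
        nonnormal = sum(
            mw_segment_test(rng.normal(0, 0.25, 20), controls)[1] != "normal"
            for _ in range(1000)
        )
        assert nonnormal <= 80  # ~5% nominal + amplitude-rule slack

    def test_clear_loss(self, controls):
        rng = np.random.default_rng(10)
        p, state = mw_segment_test(rng.normal(-1.0, 0.1, 30), controls)
        assert p < 0.05 and state == "loss"

    def test_significance_required(self, controls):
        """A big median with a non-significant rank test stays normal."""
        seg = np.array([-1.0, 0.4, 0.3])
        p, state = mw_segment_test(seg, controls)
        if p >= 0.05:
            assert state == "normal"

    def test_amplitude_rule_required(self, controls):
        """Significant but tiny-amplitude shifts stay normal."""
        rng = np.random.default_rng(11)
        shift = 1.5 * controls.sd_of_medians
        p, state = mw_segment_test(rng.normal(-shift, 0.01, 500), controls)
        assert p < 0.05 and state == "normal"

    def test_missing_controls_raise(self):
        with pytest.raises(ValueError):
            mw_segment_test(np.zeros(10), None)


class TestArchitecture:
    def test_all_normal_region(self):
        segs = seg_frame([(0, 10, 0.0, 0.5, "normal")])
        assert call_region(segs) == "non-variant"
        assert classify_architecture(segs) == "non-variant"

    def test_single_loss_is_simple_and_variant(self):
        segs = seg_frame([(0, 10, -1.0, 0.001, "loss"), (10, 20, 0.0, 0.9, "normal")])
        assert call_region(segs) == "variant"
        assert classify_architecture(segs) == "simple"

    def test_loss_normal_loss_is_complex(self):
        segs = seg_frame([(0, 10, -1, 0.001, "loss"), (10, 20, 0, 0.9, "normal"),
                          (20, 30, -1, 0.001, "loss")])
        assert classify_architecture(segs) == "complex"

    def test_adjacent_loss_gain_is_complex(self):
        segs = seg_frame([(0, 10, -1, 0.001, "loss"), (10, 20, 1, 0.001, "gain")])
        assert classify_architecture(segs) == "complex"

    def test_invariant_to_splitting_equal_state_segments(self):
        whole = seg_frame([(0, 20, -1, 0.001, "loss"), (20, 30, 0, 0.9, "normal")])
        split = seg_frame([(0, 10, -1, 0.001, "loss"), (10, 20, -1, 0.001, "loss"),
                           (20, 30, 0, 0.9, "normal")])
        assert classify_architecture(whole) == classify_architecture(split) == "simple"

    def test_adding_nonnormal_segment_keeps_variant(self):
        base = [(0, 10, -1, 0.001, "loss")]
        assert call_region(seg_frame(base)) == "variant"
        assert call_region(seg_frame(base + [(10, 20, 1, 0.001, "gain")])) == "variant"


class TestClassifyRegion:
    def test_loss_normal_loss_plant(self, controls):
        rng = np.random.default_rng(12)
        x = np.concatenate([
            rng.normal(0, 0.25, 30), rng.normal(-3, 0.25, 25),
            rng.normal(0, 0.25, 30), rng.normal(-3, 0.25, 25),
            rng.normal(0, 0.25, 30),
        ])
        cls = classify_region("r", "s", x, controls, FAST)
        assert cls.region_call == "variant"
        assert cls.architecture == "complex"
        assert (cls.segments["state"] == "loss").sum() == 2

    def test_tiny_segments_are_merged(self, controls):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 0.25, 60)
        cls = classify_region("r", "s", x, controls, FAST)
        assert (cls.segments["end"] - cls.segments["start"] >= 3).all()
        # segments tile the region
        assert cls.segments["start"].iat[0] == 0
        assert cls.segments["end"].iat[-1] == 60
        assert (cls.segments["start"].to_numpy()[1:] ==
                cls.segments["end"].to_numpy()[:-1]).all()


class TestFprSweep:
    def test_separable_case_has_zero_fpr_zero_rejection(self):
        calls = pd.DataFrame({
            "mean_std_ratio": [-10.0, -9.0, -8.0, -2.0, -1.5],
            "label": ["simple", "complex", "simple", "false_positive", "false_positive"],
        })
        curve, zero = fpr_threshold_sweep(calls)
        assert zero is not None
        at = curve[curve["threshold"] == zero].iloc[0]
        assert at["fpr"] == 0.0 and at["pct_verified_rejected"] == 0.0

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(14)
        labels = rng.choice(["simple", "complex", "false_positive"], size=40)
        means = np.round(rng.uniform(-13, -1.2, size=40), 3)
        calls = pd.DataFrame({"mean_std_ratio": means, "label": labels})
        curve, _ = fpr_threshold_sweep(calls)
        verified = labels != "false_positive"
        for _, row in curve.sample(10, random_state=0).iterrows():
            t = row["threshold"]
            acc = means <= t
            if acc.sum():
                assert row["fpr"] == pytest.approx(
                    100.0 * (acc & ~verified).sum() / acc.sum())
            else:
                assert np.isnan(row["fpr"])
            assert row["pct_verified_rejected"] == pytest.approx(
                100.0 * (verified & ~acc).sum() / verified.sum())

    def test_unknown_labels_rejected(self):
        calls = pd.DataFrame({"mean_std_ratio": [-2.0], "label": ["weird"]})
        with pytest.raises(ValueError, match="weird"):
            fpr_threshold_sweep(calls)
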