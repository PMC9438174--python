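import numpy as np
import pytest

import mircascade as mc
from mircascade.filters import fit_exp2

from conftest import make_profile


def _single_rep_ds(values, days):
    samples = [mc.SampleMeta(f"s{i}", day=float(d), replicate=1) for i, d in enumerate(days)]
    ids = [f"t{i}" for i in range(len(values))]
    return mc.ExpressionDataset("gene", ids, np.asarray(values, float), samples)


class TestDetectionFilter:
    def test_counts_per_row_oracle(self):
        # detection counts per transcript over 13 days: {6, 5, 13, 0} -> 2 survive at min=6
        days = np.arange(13.0)
        rows = np.zeros((4, 13))
        rows[0, :6] = 10.0
        rows[1, :5] = 10.0
        rows[2, :] = 10.0
        ds = _single_rep_ds(rows, days)
        kept = mc.detection_filter(ds, min_timepoints=6, detect_thr=5.0)
        assert kept.transcript_ids == ["t0", "t2"]

    def test_identity_when_all_detected(self, toy_ds):
        kept = mc.detection_filter(toy_ds, min_timepoints=3, detect_thr=0.0)
        assert kept.transcript_ids == toy_ds.transcript_ids

    def test_boundary_below_min(self):
        days = np.arange(13.0)
        row = np.zeros((1, 13))
        row[0, :5] = 10.0  # 5 of 13 days above threshold
        ds = _single_rep_ds(row, days)
        assert mc.detection_filter(ds, 6, 5.0).n_transcripts == 0

    def test_min_timepoints_exceeding_days_errors(self, toy_ds):
        with pytest.raises(ValueError, match="distinct sampled days"):
            mc.detection_filter(toy_ds, min_timepoints=4, detect_thr=0.0)

    def test_monotone_in_min_timepoints(self):
        rng = np.random.default_rng(3)
        ds = _single_rep_ds(rng.normal(5, 2, (30, 7)), [0, 2, 4, 6, 8, 15, 30])
        prev = None
        for m in range(1, 8):
            kept = set(mc.detection_filter(ds, m, detect_thr=5.0).transcript_ids)
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestSegmentalFoldChange:
    def test_flat_profile_is_uninformative(self, scheme030, days7):
        calls = mc.segmental_fold_change([make_profile("t", days7, np.full(7, 5.0))], scheme030)
        assert all(c.fold_change == 1.0 and not c.informative for c in calls)

    def test_one_doubling_is_up_informative(self, scheme030, days7):
        vals = np.array([2.0, 2.5, 3.0, 5.0, 5.0, 5.0, 5.0])  # early: 2.0 -> 3.0
        calls = mc.segmental_fold_change([make_profile("t", days7, vals)], scheme030)
        early = next(c for c in calls if c.segment_name == "early")
        assert early.fold_change == pytest.approx(2.0)
        assert early.informative and early.direction == "up"

    def test_threshold_exactly_inclusive(self, scheme030, days7):
        vals = np.zeros(7)
        vals[2] = np.log2(1.2)  # early segment ends at day 4
        calls = mc.segmental_fold_change([make_profile("t", days7, vals)], scheme030)
        early = next(c for c in calls if c.segment_name == "early")
        assert early.fold_change == pytest.approx(1.2)
        assert early.informative

    def test_intermediate_fold_change(self, scheme030, days7):
        vals = np.full(7, 1.0)
        vals[2:] = 1.585
        calls = mc.segmental_fold_change([make_profile("t", days7, vals)], scheme030)
        early = next(c for c in calls if c.segment_name == "early")
        assert early.fold_change == pytest.approx(1.500, abs=1e-3)
        assert early.informative

    def test_invariant_to_constant_log2_shift(self, scheme030, days7):
        rng = np.random.default_rng(5)
        vals = rng.normal(6, 1, 7)
        base = mc.segmental_fold_change([make_profile("t", days7, vals)], scheme030)
        shifted = mc.segmental_fold_change([make_profile("t", days7, vals + 3.7)], scheme030)
        for a, b in zip(base, shifted):
            assert a.fold_change == pytest.approx(b.fold_change)

    def test_widening_window_never_shrinks_informative_set(self, scheme030, days7):
        rng = np.random.default_rng(6)
        profiles = [make_profile(f"t{i}", days7, rng.normal(6, 0.5, 7)) for i in range(50)]
        def informative(lo, hi):
            calls = mc.segmental_fold_change(profiles, scheme030, lo, hi)
            return {c.transcript_id for c in calls if c.informative}
        assert informative(0.9, 1.1) >= informative(0.8, 1.2) >= informative(0.6, 1.4)

    def test_segment_with_one_day_errors(self, days7):
        scheme = mc.SegmentScheme((("lonely", 9, 11),))  # contains no two sampled days
        with pytest.raises(ValueError, match="lonely"):
            mc.segmental_fold_change([make_profile("t", days7, np.zeros(7))], scheme)

    def test_strategy_segment_mean_vs_day0(self, scheme030, days7):
        vals = np.array([1.0, 1.0, 1.0, 3.0, 3.0, 1.0, 1.0])
        calls = mc.segmental_fold_change(
            [make_profile("t", days7, vals)], scheme030, strategy="segment-mean-vs-day0"
        )
        mid = next(c for c in calls if c.segment_name == "mid")
        assert mid.fold_change == pytest.approx(2.0 ** 2.0)


class TestSegmentOverlap:
    def _call(self, tid, seg, informative):
        return mc.SegmentalCall(tid, seg, 2.0 if informative else 1.0, "up", informative)

    def test_planted_memberships_exact_venn(self):
        calls = [
            self._call("all3", s, True) for s in ("a", "b", "c")
        ] + [
            self._call("ab", "a", True), self._call("ab", "b", True), self._call("ab", "c", False),
            self._call("onlyc", "c", True), self._call("onlyc", "a", False),
            self._call("never", "a", False), self._call("never", "b", False),
        ]
        table = mc.segment_overlap(calls)
        assert table[frozenset({"a", "b", "c"})] == ["all3"]
        assert table[frozenset({"a", "b"})] == ["ab"]
        assert table[frozenset({"c"})] == ["onlyc"]
        assert table[frozenset({"a"})] == []

    def test_cells_partition_informative_union(self):
        rng = np.random.default_rng(8)
        calls = []
        for i in range(40):
            for seg in ("a", "b", "c"):
                calls.append(self._call(f"t{i}", seg, bool(rng.integers(2))))
        table = mc.segment_overlap(calls)
        seen: set[str] = set()
        for cell in table.values():
            assert not (seen & set(cell))  # no transcript in two cells
            seen |= set(cell)
        union = {c.transcript_id for c in calls if c.informative}
        assert seen == union

    def test_single_segment_errors(self):
        with pytest.raises(ValueError, match=">= 2 segments"):
            mc.segment_overlap([self._call("t", "a", True)])


class TestFitExp2:
    def test_noiseless_two_term_recovery(self, days7):
        t = (days7 - days7[0]) / (days7[-1] - days7[0])
        prof = make_profile("x", days7, 2.0 * np.exp(1.5 * t))
        fit = fit_exp2(prof)
        assert fit.converged and fit.passed
        assert fit.r_goodness == pytest.approx(1.0, abs=1e-6)
        assert fit.sse < 1e-8

    def test_underdetermined_profile_errors(self):
        with pytest.raises(ValueError, match="5 time points"):
            fit_exp2(make_profile("x", [0, 1, 2, 3], [1, 2, 3, 4]))

    def test_goodness_invariant_under_day_axis_rescaling(self, days7):
        rng = np.random.default_rng(9)
        vals = 6 + np.cumsum(rng.normal(0.3, 0.2, 7))
        r1 = fit_exp2(make_profile("x", days7, vals)).r_goodness
        r2 = fit_exp2(make_profile("x", 10 + 4 * days7, vals)).r_goodness
        assert r1 == pytest.approx(r2, abs=1e-6)

    def test_sqrt_r2_goodness_close_to_r_for_good_fits(self, days7):
        t = (days7 - days7[0]) / (days7[-1] - days7[0])
        prof = make_profile("x", days7, 3 * (1 - np.exp(-3 * t)) + 8)
        r = fit_exp2(prof, goodness="r").r_goodness
        r2 = fit_exp2(prof, goodness="sqrt_r2").r_goodness
        assert r == pytest.approx(1.0, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-6)

    def test_saturating_and_decaying_shapes_pass(self, days7):
        t = (days7 - days7[0]) / (days7[-1] - days7[0])
        sat = make_profile("sat", days7, 8 + 3 * (1 - np.exp(-3 * t)))
        dec = make_profile("dec", days7, 9 - 3 * (1 - np.exp(-3 * t)))
        assert fit_exp2(sat).passed
        assert fit_exp2(dec).passed


class TestExponentialFilter:
    def test_noiseless_planted_all_retained(self, days7):
        t = (days7 - days7[0]) / (days7[-1] - days7[0])
        profiles = [
            make_profile(f"p{i}", days7, 8 + (1 + i) * (1 - np.exp(-(1 + i) * t)))
            for i in range(5)
        ]
        assert mc.exponential_filter(profiles) == [p.transcript_id for p in profiles]

    def test_empty_input(self):
        assert mc.exponential_filter([]) == []

    def test_planted_recovery_with_noise(self, days7):
        # 20 planted saturating trajectories + 200 noise transcripts at sigma=0.2
        rng = np.random.default_rng(20220902)
        t = (days7 - days7[0]) / (days7[-1] - days7[0])
        planted = [
            make_profile(
                f"p{i}",
                days7,
                8 + 3 * (1 - np.exp(-3 * t)) + rng.normal(0, 0.2, 7),
            )
            for i in range(20)
        ]
        noise = [make_profile(f"n{i}", days7, rng.normal(8, 0.2, 7)) for i in range(200)]
        kept = set(mc.exponential_filter(planted + noise))
        assert len(kept & {p.transcript_id for p in planted}) >= 18
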