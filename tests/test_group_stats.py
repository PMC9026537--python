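import math

import numpy as np
import pytest

from ccflow import mann_whitney_u, summarize_groups, wilcoxon_signed_rank
from ccflow.fd_metrics import CORNERS, EyeAverages, EyeRecord, FDMetrics, ROISpec

from oracles import enumerate_mann_whitney_p, enumerate_signed_rank_p


class TestWilcoxonSignedRank:
    def test_constant_shift_of_three_pairs(self):
        res = wilcoxon_signed_rank([1, 2, 3], [2, 3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.25)

    def test_identical_samples_are_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert math.isnan(res.p_value)
        assert "zero" in res.note

    def test_unequal_lengths_point_to_rank_sum(self):
        with pytest.raises(ValueError, match="mann_whitney_u"):
            wilcoxon_signed_rank([1, 2, 3], [1, 2])

    @pytest.mark.parametrize("n", [3, 5, 8, 10])
    def test_exact_path_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = wilcoxon_signed_rank(x, y)
            assert res.p_value == pytest.approx(enumerate_signed_rank_p(x, y), abs=1e-12)

    def test_exact_path_handles_tied_ranks(self):
        # integer data with many tied |differences|
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 4, size=8).astype(float)
            y = rng.integers(0, 4, size=8).astype(float)
            if np.all(x == y):
                continue
            res = wilcoxon_signed_rank(x, y)
            assert res.p_value == pytest.approx(enumerate_signed_rank_p(x, y), abs=1e-12)

    def test_large_sample_approximation_is_close_to_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.4, 1, 40)
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "normal_approx"
        ref = stats.wilcoxon(x - y, zero_method="wilcox", correction=True, method="approx")
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=0.02)


class TestMannWhitney:
    def test_fully_separated_pairs(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)

    def test_tied_singletons_give_p_one(self):
        res = mann_whitney_u([5.0], [5.0])
        assert res.statistic == 0.5
        assert res.p_value == 1.0

    def test_label_swap_leaves_p_unchanged(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6), rng.normal(0.5, 1, size=9)
        assert mann_whitney_u(x, y).p_value == pytest.approx(mann_whitney_u(y, x).p_value)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("sizes", [(3, 3), (4, 6), (5, 7), (6, 6)])
    def test_exact_path_matches_enumeration_oracle(self, sizes):
        m, n = sizes
        rng = np.random.default_rng(m * 10 + n)
        for _ in range(10):
            x = rng.normal(size=m)
            y = rng.normal(size=n)
            res = mann_whitney_u(x, y)
            assert res.p_value == pytest.approx(enumerate_mann_whitney_p(x, y), abs=1e-12)


def _fake_record(eye_id, group, fd_percent, rng, mnv="not_applicable"):
    spec = {
        c: ROISpec(corner=c, size_mm=1.0, side_px=100, pixel_pitch_um=10.0) for c in CORNERS
    }
    corner = {}
    for radius in (4, 8):
        corner[radius] = {
            c: FDMetrics(
                fd_percent=fd_percent + rng.normal(0, 0.5),
                n_fd=10,
                mean_fd_size_um2=1000.0,
                total_fd_area_mm2=fd_percent / 100.0,
                roi=spec[c],
            )
            for c in CORNERS
        }
    averages = {
        r: EyeAverages(
            fd_percent=float(np.mean([m.fd_percent for m in corner[r].values()])),
            n_fd=10.0,
            mean_fd_size_um2=1000.0,
            total_fd_area_mm2=fd_percent / 100.0,
        )
        for r in (4, 8)
    }
    return EyeRecord(eye_id, group, mnv, corner, averages)


class TestSummarizeGroups:
    def _records(self, rng, a_fd=47.0, b_fd=39.0, n=8):
        return [
            *(_fake_record(f"A{i}", "angioid_streaks", a_fd, rng) for i in range(n)),
            *(_fake_record(f"B{i}", "control", b_fd, rng) for i in range(n)),
        ]

    def test_disjoint_fd_ranges_are_significant(self, rng):
        with pytest.warns(UserWarning, match="paired"):
            rows = summarize_groups(self._records(rng, 60.0, 30.0, n=12), radius_px=4)
        fd_row = next(r for r in rows if r.metric == "mean FD%")
        assert fd_row.p_value < 0.001
        assert fd_row.mean_a > fd_row.mean_b
        # one row per averaged metric plus one per corner quadrant
        assert len(rows) == 4 + 4

    def test_identical_groups_are_null_or_degenerate(self, rng):
        records = self._records(rng, 40.0, 40.0)
        rows = summarize_groups(records, radius_px=4, test="mann_whitney_u")
        for row in rows:
            assert row.result.degenerate or row.p_value > 0.05
            assert row.mean_a == pytest.approx(row.mean_b, abs=1.0)

    def test_small_group_rejected(self, rng):
        records = self._records(rng)[:9]  # one control eye only
        with pytest.raises(ValueError, match="need >= 2"):
            summarize_groups(records, radius_px=4, test="mann_whitney_u")

    def test_sample_sd_uses_n_minus_one(self):
        from ccflow.group_stats import _compare

        row = _compare("m", 4, "a", "b", [1.0, 2.0, 3.0], [4.0, 5.0, 6.0], "mann_whitney_u")
        assert row.sd_a == pytest.approx(1.0)

    def test_formatted_row_uses_two_decimals(self, rng):
        rows = summarize_groups(self._records(rng), radius_px=8, test="mann_whitney_u")
        cell = rows[0].formatted()["angioid_streaks"]
        assert "±" in cell and len(cell.split("±")[0].strip().split(".")[-1]) == 2
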