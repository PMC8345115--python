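import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import chromatex as cx
from chromatex.exceptions import EmptyInputError, ParameterError

from _oracles import permutation_pvalue


def disk_field(centers, radius=6, shape=(96, 96), mir_value=0.0,
               cyto_width=4):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    nuclear = np.full(shape, 5.0)
    mir = np.zeros(shape)
    for cy, cx_ in centers:
        d2 = (yy - cy) ** 2 + (xx - cx_) ** 2
        nuclear[d2 <= radius ** 2] = 200.0
        mir[(d2 <= (radius + cyto_width) ** 2) & (d2 > radius ** 2)] = mir_value
    return cx.TissueField(nuclear, mir, pixel_size_um=0.5)


class TestDetectCells:
    def test_planted_disjoint_nuclei_counted(self):
        centers = [(r, c) for r in (16, 48, 80) for c in (16, 48, 80)]
        centers.append((16, 64))
        field = disk_field(centers[:10], shape=(112, 112))
        cells = cx.detect_cells(field, 2.0, cytoplasm_width_px=4)
        assert len(cells) == 10

    def test_blank_field_yields_no_cells(self):
        field = cx.TissueField(np.zeros((64, 64)), np.zeros((64, 64)), 0.5)
        assert cx.detect_cells(field, 2.0) == []

    def test_touching_pair_split_and_regions_disjoint(self):
        field = disk_field([(32, 25), (32, 38)], shape=(64, 64))
        cells, nuclei, cyto = cx.detect_cells(field, 2.0, cytoplasm_width_px=4,
                                              return_labels=True)
        assert len(cells) == 2
        # cytoplasm never overlaps any nucleus and regions are disjoint labels
        assert not np.any((cyto > 0) & (nuclei > 0))
        sizes = [c.cytoplasm_area_px for c in cells]
        assert abs(sizes[0] - sizes[1]) / max(sizes) < 0.35

    def test_channel_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            cx.TissueField(np.zeros((10, 10)), np.zeros((12, 10)), 0.5)


class TestClassifyAndSummarise:
    @staticmethod
    def record(intensity):
        return cx.CellRecord(1, (0.0, 0.0), 10, 20, intensity, False)

    @pytest.mark.parametrize("intensity,positive", [
        (5.0, True), (4.99, False), (0.0, False), (255.0, True)])
    def test_inclusive_threshold_boundary(self, intensity, positive):
        cell, = cx.classify_mir_positive([self.record(intensity)])
        assert cell.is_mir_positive is positive

    def test_raising_threshold_is_monotone(self, rng):
        cells = [self.record(v) for v in rng.uniform(0, 20, 100)]
        n_prev = None
        for thr in (0, 2, 5, 10, 20, 30):
            n = sum(c.is_mir_positive
                    for c in cx.classify_mir_positive(cells, thr))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_field_summary_percentages(self):
        cells = cx.classify_mir_positive(
            [self.record(v) for v in [10, 30] + [0] * 8])
        s = cx.field_summary(cells)
        assert (s.n_cells, s.n_positive, s.percent_positive) == (10, 2, 20.0)
        all_pos = cx.classify_mir_positive([self.record(9)] * 4)
        assert cx.field_summary(all_pos).percent_positive == 100.0

    def test_background_subtraction_clips_and_shifts_classification(self):
        field = disk_field([(32, 32)], shape=(64, 64), mir_value=7.0)
        corrected = cx.subtract_background(field, mir_background=3.0)
        assert corrected.mir_channel.min() == 0.0  # clipped, not negative
        before = cx.field_summary(cx.detect_cells(field, 2.0, 4))
        after = cx.field_summary(cx.detect_cells(corrected, 2.0, 4))
        assert before.n_positive == 1 and after.n_positive == 0

    def test_zero_cells_undefined(self):
        with pytest.raises(EmptyInputError):
            cx.field_summary([])

    def test_planted_fraction_recovered(self):
        field, truth = cx.simulate_tissue_field(
            cx.TissueFieldSpec(n_cells=200, positive_fraction=0.3, seed=4))
        cells = cx.detect_cells(field, 2.0, cytoplasm_width_px=4)
        s = cx.field_summary(cells)
        planted = 100 * truth["n_positive"] / 200
        assert s.percent_positive == pytest.approx(planted, abs=3.0)


class TestRankSum:
    def test_fully_separated_small_samples_exact(self):
        res = cx.rank_sum_one_sided([4, 5, 6], [1, 2, 3], "greater")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 20)
        assert res.u_statistic == 9.0

    def test_no_separation_is_insignificant(self):
        res = cx.rank_sum_one_sided([1.0, 2.0, 3.1], [1.1, 2.1, 3.0], "greater")
        assert res.p_value > 0.4

    def test_exact_agrees_with_scipy(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.5, 1, 6)
            ours = cx.rank_sum_one_sided(x, y, "greater")
            ref = mannwhitneyu(x, y, alternative="greater", method="exact")
            assert ours.method == "exact"
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)
            assert ours.u_statistic == pytest.approx(ref.statistic)

    def test_matches_permutation_oracle(self, rng):
        x = rng.normal(1.0, 1, 5)
        y = rng.normal(0.0, 1, 5)
        ours = cx.rank_sum_one_sided(x, y, "greater")
        perm = permutation_pvalue(x, y, "greater", n_draws=10_000, rng=rng)
        assert ours.p_value == pytest.approx(perm, abs=0.01)

    def test_sidedness_identity_for_tie_free_data(self, rng):
        x = rng.normal(0, 1, 4)
        y = rng.normal(0, 1, 5)
        p_fwd = cx.rank_sum_one_sided(x, y, "greater")
        p_rev = cx.rank_sum_one_sided(y, x, "greater")
        # P(U >= u) + P(U' >= nm - u) = 1 + P(U = u)
        ref = mannwhitneyu(x, y, alternative="greater", method="exact")
        p_eq = cx.rank_sum_one_sided(x, y, "less").p_value + ref.pvalue - 1
        assert p_fwd.p_value + p_rev.p_value == pytest.approx(1 + p_eq)

    def test_ties_use_corrected_normal_approximation(self):
        x = [5, 5, 5, 7, 8, 9, 9, 10, 11, 12]
        y = [1, 2, 2, 3, 5, 5, 6, 6, 7, 7]
        ours = cx.rank_sum_one_sided(x, y, "greater")
        ref = mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert ours.method == "normal_approx"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_rejects_empty_or_bad_alternative(self):
        with pytest.raises(ParameterError):
            cx.rank_sum_one_sided([], [1], "greater")
        with pytest.raises(ParameterError):
            cx.rank_sum_one_sided([1], [2], "two-sided")

    def test_group_comparison_report(self):
        rep = cx.compare_groups([50, 60, 45, 55, 52], [5, 4, 6, 3, 7],
                                alternative="greater")
        assert rep["significant"] and rep["method"] == "exact"
        assert rep["p_value"] == pytest.approx(1 / 252)
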