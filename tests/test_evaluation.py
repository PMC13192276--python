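"""Experiment grids, scoring, thresholds, similarity and statistics."""

import numpy as np
import pytest

from cuedgain.evaluation import (EXP4_SNRS, GridParams, PsychometricCurve,
                                 ThresholdTable, TrialRecord,
                                 build_experiment_grid, estimate_threshold,
                                 mutual_information, permutation_interaction,
                                 score_trial, sign_test, similarity,
                                 spatial_release)


class TestGrids:
    @pytest.mark.parametrize("eid,count", [
        ("1", 44896), ("1b", 5856), ("2", 23424), ("3", 16168),
        ("4", 43920), ("5", 23424), ("6", 58560), ("7", 15616)])
    def test_paper_scale_counts(self, eid, count):
        assert len(build_experiment_grid(eid)) == count

    def test_exp4_snr_axis(self):
        assert EXP4_SNRS == (-18.0, -15.0, -12.0, -9.0, -6.0, -3.0,
                             0.0, 3.0, 6.0)

    def test_grids_are_pure_functions(self):
        assert build_experiment_grid("7") == build_experiment_grid("7")

    def test_desk_scale_structure_preserved(self):
        p = GridParams(n_targets=10)
        g = build_experiment_grid("1", p)
        assert len(g) == 10 + 10 * 9 * 5
        assert len(build_experiment_grid("7", p)) == 20 * 2 * 4

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError):
            build_experiment_grid("99")


class TestScoring:
    def rec(self, resp, tgt=(3, 4, 5), dis=(6, 7, 8)):
        return TrialRecord(condition={}, response=resp,
                           target_words=list(tgt), distractor_words=list(dis))

    def test_target_word_is_correct(self):
        assert score_trial(self.rec(4)) == {"correct": True,
                                            "confusion": False}

    def test_distractor_word_is_confusion(self):
        assert score_trial(self.rec(7)) == {"correct": False,
                                            "confusion": True}

    def test_word_in_neither_transcript(self):
        assert score_trial(self.rec(0)) == {"correct": False,
                                            "confusion": False}

    def test_correct_takes_precedence_over_confusion(self):
        out = score_trial(self.rec(4, tgt=(4,), dis=(4,)))
        assert out == {"correct": True, "confusion": False}

    def test_empty_response_scored_incorrect(self):
        assert score_trial(self.rec("")) == {"correct": False,
                                             "confusion": False}


class TestThresholds:
    def test_exact_quadratic_recovered(self):
        x = np.array([-12, -9, -6, -3, 0, 3], float)
        y = np.clip(0.5 + 0.05 * (x + 6) - 0.001 * (x + 6) ** 2, 0, 1)
        thr = estimate_threshold(PsychometricCurve(x, y), "fixed_50")
        assert thr == pytest.approx(-6.0, abs=1e-6)

    def test_shift_equivariance(self):
        x = np.array([-12, -9, -6, -3, 0, 3], float)
        y = np.clip(0.5 + 0.04 * (x + 5), 0, 1)
        t0 = estimate_threshold(PsychometricCurve(x, y), "fixed_50")
        t3 = estimate_threshold(PsychometricCurve(x + 3, y), "fixed_50")
        assert t3 - t0 == pytest.approx(3.0, abs=1e-6)

    def test_recovery_from_binomial_noise_within_1db(self):
        # known 50% point at -4 dB, n = 200 per SNR point
        rng = np.random.default_rng(0)
        x = np.arange(-12.0, 6.1, 3.0)
        true = 1.0 / (1.0 + np.exp(-(x - (-4.0)) / 2.0))
        errs = []
        for _ in range(20):
            y = rng.binomial(200, true) / 200
            thr = estimate_threshold(PsychometricCurve(x, y), "fixed_50")
            errs.append(thr - (-4.0))
        assert abs(np.mean(errs)) < 1.0

    def test_unattained_criterion_gives_nan(self):
        x = np.array([-9, -6, -3, 0, 3], float)
        y = np.full(5, 0.9)
        thr = estimate_threshold(PsychometricCurve(x, y), "fixed_50")
        assert np.isnan(thr)

    def test_spatial_release_arithmetic(self):
        srm = spatial_release({0.0: -2.0, 40.0: -8.0})
        assert srm[40.0] == pytest.approx(6.0)
        assert srm[0.0] == 0.0
        shifted = spatial_release({0.0: 3.0, 40.0: -3.0})
        assert shifted[40.0] == pytest.approx(6.0)

    def test_missing_colocated_cell_rejected(self):
        with pytest.raises(ValueError):
            spatial_release({10.0: -5.0})


class TestSimilarity:
    def test_identical_vectors(self, rng):
        v = rng.random(30)
        rep = similarity(v, v, n_boot=50, rng=rng)
        assert rep.rmse == 0.0
        assert rep.pearson_r2 == pytest.approx(1.0)

    def test_constant_offset_dissociates_rmse_from_r2(self, rng):
        v = rng.random(30)
        rep = similarity(v, v + 0.25, n_boot=50, rng=rng)
        assert rep.rmse == pytest.approx(0.25)
        assert rep.pearson_r2 == pytest.approx(1.0)

    def test_mi_nonnegative_and_symmetric(self, rng):
        a, b = rng.random(100), rng.random(100)
        for bins in (5, 10, 15, 20):
            m1 = mutual_information(a, b, bins)
            assert m1 >= 0
            assert m1 == pytest.approx(mutual_information(b, a, bins))

    def test_mi_of_independent_vectors_below_permutation_null(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(200), rng.random(200)
        mi = mutual_information(a, b, 10)
        null = [mutual_information(a, rng.permutation(b), 10)
                for _ in range(200)]
        assert mi < np.percentile(null, 95)

    def test_zero_variance_flags_r_undefined(self, rng):
        rep = similarity(np.ones(10), rng.random(10), n_boot=10, rng=rng)
        assert rep.r_undefined and np.isnan(rep.pearson_r2)
        assert rep.rmse >= 0 and rep.mutual_information[5] >= 0


class TestSignTest:
    def test_ten_of_ten_matches_paper_value(self):
        p, pos, neg, ties = sign_test(np.zeros(10), np.ones(10))
        assert neg == 10 and pos == 0
        assert p == pytest.approx(2 * 0.5 ** 10)
        assert round(p, 3) == 0.002

    def test_even_split_gives_p_one(self):
        a = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0.0])
        b = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1.0])
        p, *_ = sign_test(a, b)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("k", range(13))
    def test_matches_exact_binomial_enumeration(self, k):
        from math import comb
        n = 12
        a = np.arange(n, dtype=float)
        b = a.copy()
        b[:k] -= 1          # k positive differences
        b[k:] += 1
        p, pos, neg, _ = sign_test(a, b)
        assert pos == k
        tail = sum(comb(n, i) for i in range(0, min(k, n - k) + 1)) * 0.5 ** n
        expected = min(1.0, 2 * tail)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_all_ties_rejected(self):
        with pytest.raises(ValueError):
            sign_test(np.ones(5), np.ones(5))


class TestPermutationInteraction:
    def test_additive_table_has_zero_statistic_and_large_p(self, rng):
        cells = np.zeros((12, 2, 3))
        cells += np.array([1.0, 3.0])[None, :, None]
        cells += np.array([0.0, 2.0, 4.0])[None, None, :]
        res = permutation_interaction(ThresholdTable(cells), n_perm=200,
                                      rng=rng)
        assert res["observed"] == pytest.approx(0.0, abs=1e-20)
        assert res["p_value"] > 0.5

    def test_two_by_two_hand_oracle(self, rng):
        # single participant, thresholds [[1, 2], [3, 6]]:
        # interactions are +/-0.5 in each cell -> sum of squares = 1
        cells = np.array([[[1.0, 2.0], [3.0, 6.0]]])
        tab = ThresholdTable(cells, directions=("a", "b"),
                             offsets=(0.0, 1.0))
        res = permutation_interaction(tab, n_perm=10, rng=rng)
        assert res["observed"] == pytest.approx(1.0)

    def test_planted_interaction_detected(self, rng):
        cells = rng.normal(0, 0.5, (33, 2, 3))
        cells[:, 0, 2] += 4.0        # strong non-additive cell
        res = permutation_interaction(ThresholdTable(cells), n_perm=500,
                                      rng=rng)
        assert res["p_value"] < 0.01

    def test_incomplete_cells_rejected(self):
        cells = np.zeros((5, 2, 3))
        cells[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            ThresholdTable(cells)
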