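"""Rule-based classification, cohort summaries and the classical tests."""

import math

import numpy as np
import pytest
from scipy.special import comb

from epimark.pathology import (
    AdiposityControlStats,
    AnimalRecord,
    ObserverScore,
    OvaryControlStats,
    OvaryMeasurements,
    adipocyte_mean_area,
    bmi,
    classify_adiposity,
    classify_ovary,
    classify_tissue,
    fisher_exact_2x2,
    load_f3_vinclozolin_males,
    observer_threshold,
    summarize_cohort,
    t_statistic,
    t_test_two_tailed,
)


def scores(counts, tissue="testis", animal="a1"):
    return [ObserverScore(animal, tissue, i + 1, c) for i, c in enumerate(counts)]


class TestObserverThreshold:
    def test_mean_plus_two_sd(self):
        # four control animals scored by the same observer
        ctrl = [ObserverScore(f"c{i}", "testis", 1, c) for i, c in enumerate([0, 0, 1, 1])]
        cut = observer_threshold(ctrl)[("testis", 1)]
        assert cut == pytest.approx(0.5 + 2 * np.std([0, 0, 1, 1], ddof=1), abs=1e-9)
        assert cut == pytest.approx(1.6547, abs=1e-4)

    def test_all_zero_controls_cutoff_zero(self):
        ctrl = [ObserverScore(f"c{i}", "testis", 1, 0) for i in range(5)]
        cut = observer_threshold(ctrl)[("testis", 1)]
        assert cut == 0.0
        assert classify_tissue(scores([1, 1, 0]), {("testis", i): 0.0 for i in (1, 2, 3)})

    def test_single_control_errors(self):
        with pytest.raises(ValueError):
            observer_threshold([ObserverScore("c1", "testis", 1, 0)])


class TestClassifyTissue:
    cutoffs = {("testis", i): 1.6547 for i in (1, 2, 3)}

    @pytest.mark.parametrize(
        "counts,expected",
        [((3, 3, 0), True), ((3, 0, 0), False), ((0, 0, 0), False), ((2, 2, 2), True)],
    )
    def test_two_of_three_consensus(self, counts, expected):
        assert classify_tissue(scores(counts), self.cutoffs) is expected

    def test_monotone_in_counts(self):
        # raising any observer's count never flips diseased -> healthy
        rng = np.random.default_rng(0)
        for _ in range(200):
            base = rng.integers(0, 5, size=3)
            before = classify_tissue(scores(tuple(base)), self.cutoffs)
            j = rng.integers(3)
            bumped = base.copy()
            bumped[j] += rng.integers(1, 4)
            after = classify_tissue(scores(tuple(bumped)), self.cutoffs)
            assert after or not before

    def test_more_than_three_observers_errors(self):
        bad = [ObserverScore("a1", "testis", i, 0) for i in (1, 2, 3, 4)]
        with pytest.raises(ValueError):
            classify_tissue(bad, self.cutoffs)

    def test_two_observers_require_unanimity(self):
        two = scores((3, 3))
        assert classify_tissue(two, self.cutoffs)
        assert not classify_tissue(scores((3, 0)), self.cutoffs)


class TestOvary:
    stats = OvaryControlStats(30, 5, 1, 0.5, 1, 0.5)

    def test_follicle_loss_below_mean_minus_2sd(self):
        m = OvaryMeasurements("a", (18, 18, 18), (0, 0, 0), (0, 0, 0))
        assert classify_ovary(m, self.stats)["follicle_loss"]

    def test_boundary_is_healthy(self):
        m = OvaryMeasurements("a", (20, 20, 20), (2, 2, 2), (2, 2, 2))
        out = classify_ovary(m, self.stats)
        assert not out["follicle_loss"] and not out["polycystic"]

    def test_polycystic_above_mean_plus_2sd(self):
        m = OvaryMeasurements("a", (30, 30, 30), (3, 3, 3), (0, 0, 0))
        assert classify_ovary(m, self.stats)["polycystic"]

    def test_three_sections_enforced(self):
        with pytest.raises(ValueError):
            OvaryMeasurements("a", (1, 2), (0, 0, 0), (0, 0, 0))


class TestAdiposity:
    stats = AdiposityControlStats(adipocyte_mean=5000, adipocyte_sd=500, bmi_mean=0.7, bmi_sd=0.05)

    def test_bmi_formula(self):
        assert bmi(600, 25) == pytest.approx(0.96)

    def test_control_mean_is_normal(self):
        r = AnimalRecord("a", body_weight_g=437.5, body_length_cm=25, adipocyte_mean_area_um2=5000)
        assert classify_adiposity(r, self.stats) == "normal"

    def test_both_criteria_high_is_obese(self):
        r = AnimalRecord("a", body_weight_g=625, body_length_cm=25, adipocyte_mean_area_um2=6000)
        assert classify_adiposity(r, self.stats) == "obese"

    def test_either_mode(self):
        r = AnimalRecord("a", body_weight_g=437.5, body_length_cm=25, adipocyte_mean_area_um2=6000)
        assert classify_adiposity(r, self.stats) == "normal"
        assert classify_adiposity(r, self.stats, require_both=False) == "obese"

    def test_missing_length_errors(self):
        r = AnimalRecord("a", body_weight_g=600, adipocyte_mean_area_um2=6000)
        with pytest.raises(ValueError):
            classify_adiposity(r, self.stats)

    def test_adipocyte_mean_top20_per_image(self):
        images = [list(range(100)) for _ in range(5)]  # top 20 of 0..99 -> 80..99
        assert adipocyte_mean_area(images) == pytest.approx(np.mean(range(80, 100)))


class TestCohortSummary:
    def test_f3_vinclozolin_males_match_printed_table(self):
        s = summarize_cohort(load_f3_vinclozolin_males())
        assert (s.affected["testis"], s.evaluated["testis"]) == (13, 27)
        assert (s.affected["prostate"], s.evaluated["prostate"]) == (13, 27)
        assert (s.affected["kidney"], s.evaluated["kidney"]) == (13, 26)
        assert (s.affected["tumor"], s.evaluated["tumor"]) == (1, 46)
        assert (s.affected["lean"], s.evaluated["lean"]) == (3, 27)
        assert (s.affected["obese"], s.evaluated["obese"]) == (7, 27)
        assert (s.affected["late_puberty"], s.evaluated["late_puberty"]) == (1, 44)
        assert (s.affected["early_puberty"], s.evaluated["early_puberty"]) == (0, 44)
        assert s.multiple_disease_affected == 20
        assert s.multiple_disease_evaluated == 46

    def test_empty_cohort_all_zero(self):
        s = summarize_cohort([])
        assert all(v == 0 for v in s.affected.values())
        assert s.multiple_disease_affected == 0

    def test_duplicate_animal_errors(self):
        recs = [AnimalRecord("a1"), AnimalRecord("a1")]
        with pytest.raises(ValueError):
            summarize_cohort(recs)

    def test_missing_flags_excluded_from_denominator(self):
        recs = [
            AnimalRecord("a1", {"testis": True, "kidney": None}),
            AnimalRecord("a2", {"testis": False, "kidney": True}),
        ]
        s = summarize_cohort(recs, diseases=("testis", "kidney"))
        assert s.evaluated == {"testis": 2, "kidney": 1}
        assert s.affected == {"testis": 1, "kidney": 1}


def fisher_enumeration(a, b, c, d):
    """Independent oracle: enumerate all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):  # hypergeometric mass for top-left cell x
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / comb(n, c1, exact=True)

    p_obs = prob(a)
    return sum(p for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-12))


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == 1.0

    def test_extreme_table_closed_form(self):
        assert fisher_exact_2x2(10, 0, 0, 10) == pytest.approx(2 / comb(20, 10, exact=True), rel=1e-9)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, size=4)
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_enumeration(int(a), int(b), int(c), int(d)), rel=1e-8
            )

    def test_transpose_and_swap_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = map(int, rng.integers(0, 10, size=4))
            p = fisher_exact_2x2(a, b, c, d)
            assert p == pytest.approx(fisher_exact_2x2(a, c, b, d), rel=1e-9)  # transpose
            assert p == pytest.approx(fisher_exact_2x2(c, d, a, b), rel=1e-9)  # row swap
            assert p == pytest.approx(fisher_exact_2x2(b, a, d, c), rel=1e-9)  # col swap

    def test_negative_entry_errors(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestTTest:
    def test_identical_groups_p_one(self):
        assert t_test_two_tailed([1, 2, 3], [1, 2, 3]) == 1.0

    def test_shifted_groups_hand_t(self):
        t, df = t_statistic([1, 2, 3], [11, 12, 13])
        assert t == pytest.approx(-12.247, abs=1e-3)
        assert df == 4

    def test_df_two_for_2v2(self):
        _, df = t_statistic([1.0, 2.0], [3.0, 5.0])
        assert df == 2

    def test_zero_variance_conventions(self):
        assert t_test_two_tailed([2, 2], [2, 2]) == 1.0
        assert t_test_two_tailed([2, 2], [3, 3]) == 0.0

    def test_too_small_group_errors(self):
        with pytest.raises(ValueError):
            t_test_two_tailed([1], [1, 2])
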