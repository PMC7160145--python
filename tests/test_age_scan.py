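import numpy as np
import pytest
from oracles import fisher_two_sided_enumeration, pearson_chi2_p

from nbsca import age_scan as asc

T = asc.ContingencyTable2x2


class TestBuildContingency:
    def test_hand_count(self):
        table = asc.build_contingency([2, 5, 7, 9], [0, 0, 1, 1], cutoff_years=6)
        assert (table.a, table.b, table.c, table.d) == (2, 0, 0, 2)
        assert not table.degenerate

    def test_empty_older_group_is_degenerate(self):
        table = asc.build_contingency([2, 5, 7, 9], [0, 0, 1, 1], cutoff_years=10)
        assert (table.a, table.b, table.c, table.d) == (0, 0, 2, 2)
        assert table.degenerate

    def test_under_eighteen_month_samples_excluded(self):
        table = asc.build_contingency([1.0, 2, 7], [1, 0, 1], cutoff_years=6)
        assert table.total == 2
        assert (table.a, table.c) == (1, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            T(a=-1, b=1, c=1, d=1)


class TestAssociationTest:
    def test_balanced_table(self):
        result = asc.association_test(T(5, 5, 5, 5))
        assert result.p == 1.0
        assert result.direction == 0

    def test_fisher_branch_matches_enumeration(self):
        # min expected count 4.58 < 5 -> Fisher path
        result = asc.association_test(T(1, 9, 10, 4))
        assert result.method == asc.FISHER_EXACT
        assert result.p == pytest.approx(
            fisher_two_sided_enumeration(1, 9, 10, 4), rel=1e-7
        )
        assert result.direction == -1

    def test_expected_exactly_five_takes_chi_square(self):
        # (1,9,11,3): min expected count is exactly 5.0, not below it
        assert asc.association_test(T(1, 9, 11, 3)).method == asc.CHI_SQUARE

    def test_chi_square_branch_matches_closed_form(self):
        result = asc.association_test(T(40, 60, 20, 80))
        assert result.method == asc.CHI_SQUARE
        assert result.p == pytest.approx(pearson_chi2_p(40, 60, 20, 80), rel=1e-12)
        assert result.direction == 1

    def test_degenerate_table_returns_unit_p(self):
        result = asc.association_test(T(0, 0, 2, 2))
        assert (result.p, result.direction) == (1.0, 0)
        assert result.method == asc.FISHER_EXACT

    @pytest.mark.parametrize("seed", range(3))
    def test_fisher_agrees_with_enumeration_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            table = T(int(a), int(b), int(c), int(d))
            if table.degenerate:
                continue
            assert asc.fisher_exact_two_sided(table) == pytest.approx(
                fisher_two_sided_enumeration(a, b, c, d), rel=1e-7, abs=1e-12
            )


class TestStouffer:
    def test_single_study_identity(self):
        assert asc.stouffer_combine([(0.2, 1)]) == pytest.approx(0.2, rel=1e-12)

    def test_two_concordant_studies_closed_form(self):
        # z = Phi^-1(0.975) = 1.9599640, Z = 2 z / sqrt(2) = 2.7718076
        assert asc.stouffer_combine([(0.05, 1), (0.05, 1)]) == pytest.approx(
            0.005574596680784402, abs=1e-12
        )

    def test_discordant_studies_cancel(self):
        assert asc.stouffer_combine([(0.05, 1), (0.05, -1)]) == 1.0

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_evidence_accumulates_as_sqrt_k(self, k):
        from scipy.stats import norm
        z1 = norm.isf(0.05 / 2)
        expected = 2 * norm.sf(np.sqrt(k) * z1)
        assert asc.stouffer_combine([(0.05, 1)] * k) == pytest.approx(expected, rel=1e-10)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            asc.stouffer_combine([(0.0, 1)])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            asc.stouffer_combine([])

    def test_weighted_combination(self):
        unweighted = asc.stouffer_combine([(0.05, 1), (0.5, 1)])
        upweighted = asc.stouffer_combine([(0.05, 1), (0.5, 1)], weights=[4, 1])
        assert upweighted < unweighted  # weight on the stronger study


class TestBonferroni:
    @pytest.mark.parametrize("p, m, expected", [
        (0.03, 10, 0.30),
        (0.5, 3, 1.0),
        (0.0005, 9, 0.0045),
    ])
    def test_examples(self, p, m, expected):
        assert asc.bonferroni_correct(p, m) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            asc.bonferroni_correct(1.5, 3)
        with pytest.raises(ValueError):
            asc.bonferroni_correct(0.5, 0)


def make_cohort(name, rng, n, p_young, p_old, threshold=6.0):
    ages = rng.uniform(1.6, 12.0, size=n)
    prevalence = np.where(ages > threshold, p_old, p_young)
    return asc.AgeScaCohort(name, ages, rng.random(n) < prevalence)


class TestRunAgeScan:
    def test_single_cohort_single_cutoff_identity(self):
        rng = np.random.default_rng(0)
        cohort = make_cohort("only", rng, 300, 0.1, 0.4)
        scan = asc.run_age_scan([cohort], cutoffs=[6])
        (result,) = scan.results
        assert scan.m == 1
        assert result.corrected_p == result.combined_p == result.cohort_p[0]

    def test_corrected_never_below_combined(self):
        rng = np.random.default_rng(1)
        cohorts = [make_cohort(f"c{i}", rng, 250, 0.1, 0.35) for i in range(2)]
        scan = asc.run_age_scan(cohorts)
        for result in scan.results:
            assert 0 <= result.combined_p <= result.corrected_p <= 1

    def test_sample_order_and_cohort_swap_invariance(self):
        rng = np.random.default_rng(2)
        cohorts = [make_cohort(f"c{i}", rng, 200, 0.1, 0.35) for i in range(2)]
        reference = asc.run_age_scan(cohorts)
        perm = np.random.default_rng(3).permutation(200)
        shuffled = [
            asc.AgeScaCohort(c.name, c.ages[perm], c.sca_flags[perm]) for c in cohorts
        ]
        swapped = asc.run_age_scan(shuffled[::-1])
        for res_a, res_b in zip(reference.results, swapped.results):
            assert res_a.combined_p == pytest.approx(res_b.combined_p, rel=1e-12)
        assert reference.lowest_significant_cutoff == swapped.lowest_significant_cutoff

    def test_planted_threshold_is_flagged_significant(self):
        # at this n the cut-off matching the planted threshold must reach
        # corrected significance with an older-group enrichment direction
        rng = np.random.default_rng(4)
        cohorts = [
            make_cohort("a", rng, 2000, 0.1, 0.35),
            make_cohort("b", rng, 800, 0.1, 0.35),
        ]
        scan = asc.run_age_scan(cohorts)
        at_six = next(r for r in scan.results if r.cutoff_years == 6)
        assert at_six.corrected_p < scan.alpha
        assert all(d == 1 for d in at_six.directions)
        assert scan.lowest_significant_cutoff is not None
        assert scan.lowest_significant_cutoff <= 6

    def test_no_eligible_samples_rejected(self):
        babies = asc.AgeScaCohort("infants", np.array([0.5, 1.0]), np.array([0, 1]))
        with pytest.raises(ValueError, match="older than"):
            asc.run_age_scan([babies])

    def test_cutoffs_must_increase(self):
        rng = np.random.default_rng(5)
        cohort = make_cohort("c", rng, 100, 0.1, 0.35)
        with pytest.raises(ValueError):
            asc.run_age_scan([cohort], cutoffs=[6, 5])

    def test_report_frame_and_summary(self, tmp_path):
        rng = np.random.default_rng(6)
        scan = asc.run_age_scan([make_cohort("c", rng, 300, 0.1, 0.4)])
        frame = scan.to_frame()
        assert len(frame) == len(asc.DEFAULT_CUTOFFS)
        assert {"combined_p", "corrected_p"} <= set(frame.columns)
        scan.write(tmp_path / "scan.tsv", tmp_path / "scan.json")
        assert (tmp_path / "scan.tsv").exists()
        assert (tmp_path / "scan.json").exists()
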