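"""Odds ratios, trend tests, combined tables, interaction LRT."""

import numpy as np
import pandas as pd
import pytest

from dietmicrobe import (
    SyntheticTruth,
    adjusted_or,
    combined_or_table,
    crude_or_ci,
    gen_cohort,
    interaction_lrt,
    trend_test,
)
from dietmicrobe.errors import DegenerateDistributionError, UndefinedOrError
from dietmicrobe.published import PUBLISHED_CRUDE_ORS, recompute_row


class TestCrudeOr:
    def test_balanced_table_is_one(self):
        assert crude_or_ci(10, 10, 10, 10).or_point == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "counts, published",
        [
            ((52, 97, 129, 95), (0.40, 0.26, 0.61)),  # fruit T3, total
            ((17, 36, 34, 36), (0.50, 0.24, 1.05)),  # snacks T3, females
            ((40, 47, 54, 44), (0.69, 0.39, 1.24)),  # veg/seafood highP lowM, males
            ((8, 31, 25, 23), (0.24, 0.10, 0.62)),  # dairy highP lowM, females
        ],
    )
    def test_reproduces_published_examples(self, counts, published):
        est = crude_or_ci(*counts)
        for got, want in zip((est.or_point, est.ci_low, est.ci_high), published):
            assert got == pytest.approx(want, abs=0.0105)

    def test_all_published_rows_within_print_rounding(self):
        """All 56 transcribed table rows: recomputation from integer counts
        agrees with the published (unrounded-fit) estimates to about two
        units in the last printed digit."""
        for row in PUBLISHED_CRUDE_ORS:
            est = recompute_row(row)
            assert est.or_point == pytest.approx(row.published_or, abs=0.021), row
            assert est.ci_low == pytest.approx(row.published_lo, abs=0.021), row
            assert est.ci_high == pytest.approx(row.published_hi, abs=0.021), row

    def test_reciprocal_symmetry_exact(self):
        a = crude_or_ci(13, 27, 41, 19).or_point
        b = crude_or_ci(41, 19, 13, 27).or_point
        assert a * b == pytest.approx(1.0, abs=1e-12)

    def test_ci_contains_point_and_shrinks_with_scale(self):
        est1 = crude_or_ci(20, 30, 25, 25)
        est4 = crude_or_ci(80, 120, 100, 100)
        assert est1.ci_low <= est1.or_point <= est1.ci_high
        assert (est4.ci_high - est4.ci_low) < (est1.ci_high - est1.ci_low)

    def test_haldane_correction_on_zero_cell(self):
        est = crude_or_ci(0, 10, 10, 10)
        expected = (0.5 * 10.5) / (10.5 * 10.5)
        assert est.or_point == pytest.approx(expected)

    def test_undefined_when_no_exposed(self):
        with pytest.raises(UndefinedOrError):
            crude_or_ci(0, 0, 10, 10)


class TestAdjustedOr:
    def test_no_covariates_matches_crude(self):
        truth = SyntheticTruth(
            precision_matrix=np.eye(2),
            fold_changes=np.ones(2),
            effect_log_ors=np.array([np.log(2.0), 0.0]),
            seed=2,
        )
        coh = gen_cohort(4000, truth)
        ests = adjusted_or(coh, coh["x1"], covariates=[])
        a = int(((coh.case == 1) & (coh.x1 == 1)).sum())
        b = int(((coh.case == 0) & (coh.x1 == 1)).sum())
        c = int(((coh.case == 1) & (coh.x1 == 0)).sum())
        d = int(((coh.case == 0) & (coh.x1 == 0)).sum())
        crude = crude_or_ci(a, b, c, d)
        assert ests[1].or_point == pytest.approx(crude.or_point, abs=1e-6)

    def test_confounded_effect_recovered_with_adjustment(self):
        truth = SyntheticTruth(
            precision_matrix=np.eye(2),
            fold_changes=np.ones(2),
            effect_log_ors=np.array([np.log(2.0), 0.0]),
            seed=0,
        )
        coh = gen_cohort(20000, truth, confounding=0.5, conf_log_or=np.log(1.5))
        est = adjusted_or(coh, coh["x1"], covariates=["conf"])[1]
        assert abs(est.or_point - 2.0) / 2.0 < 0.05

    def test_reference_level_is_exactly_one(self):
        truth = SyntheticTruth(
            precision_matrix=np.eye(2), fold_changes=np.ones(2), effect_log_ors=np.zeros(2), seed=5
        )
        coh = gen_cohort(500, truth)
        ests = adjusted_or(coh, coh["x1"])
        assert ests[0].or_point == 1.0

    def test_constant_covariate_dropped_without_changing_fit(self):
        truth = SyntheticTruth(
            precision_matrix=np.eye(2), fold_changes=np.ones(2), effect_log_ors=np.zeros(2), seed=6
        )
        coh = gen_cohort(800, truth).assign(flat=1.0)
        base = adjusted_or(coh, coh["x1"], covariates=[])
        with_flat = adjusted_or(coh, coh["x1"], covariates=["flat"])
        assert with_flat[1].or_point == pytest.approx(base[1].or_point, abs=1e-8)


class TestTrend:
    @staticmethod
    def _cohort_with_tertiles(beta, n=5000, seed=0):
        rng = np.random.default_rng(seed)
        score = rng.normal(size=n)
        eta = -0.5 + beta * score
        case = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame({"case": case, "score": score})
        cuts = np.quantile(score, [1 / 3, 2 / 3])
        tert = 1 + (score > cuts[0]).astype(int) + (score > cuts[1]).astype(int)
        return df, pd.Series(tert, index=df.index), pd.Series(score, index=df.index)

    def test_strong_monotone_effect_detected(self):
        df, tert, score = self._cohort_with_tertiles(beta=0.8)
        assert trend_test(df, tert, score) < 0.001

    def test_two_empty_tertiles_rejected(self):
        df, tert, score = self._cohort_with_tertiles(beta=0.0, n=300)
        tert[:] = 1
        with pytest.raises(DegenerateDistributionError):
            trend_test(df, tert, score)

    def test_identical_medians_rejected(self):
        df, tert, score = self._cohort_with_tertiles(beta=0.0, n=300)
        with pytest.raises(DegenerateDistributionError):
            trend_test(df, tert, pd.Series(1.0, index=df.index))

    def test_null_p_values_approximately_uniform(self):
        """Under no trend, p-values over 500 replicates stay within
        Kolmogorov distance 0.1 of uniform."""
        ps = []
        for seed in range(500):
            df, tert, score = self._cohort_with_tertiles(beta=0.0, n=400, seed=seed)
            ps.append(trend_test(df, tert, score))
        ps = np.sort(ps)
        ks = np.max(np.abs(ps - (np.arange(1, 501) - 0.5) / 500))
        assert ks < 0.1


class TestCombined:
    @staticmethod
    def _df_from_counts(counts):
        """counts: {(p,m): (n_cases, n_controls)}"""
        rows = []
        for (p, m), (ca, co) in counts.items():
            rows += [{"case": 1, "p": p, "m": m}] * ca + [{"case": 0, "p": p, "m": m}] * co
        df = pd.DataFrame(rows)
        return df, df["p"], df["m"]

    def test_reference_cell_exactly_one(self):
        df, p, m = self._df_from_counts(
            {(0, 0): (5, 5), (1, 0): (5, 5), (0, 1): (5, 5), (1, 1): (5, 5)}
        )
        cells = combined_or_table(df, p, m)
        assert cells[0].or_point == 1.0

    def test_published_male_vegetable_cell(self):
        # males, vegetables/seafood: ref cell 54 cases/44 controls,
        # high-pattern low-MDI cell 40 cases/47 controls -> crude OR 0.69
        df, p, m = self._df_from_counts(
            {(0, 0): (54, 44), (1, 0): (40, 47), (0, 1): (39, 46), (1, 1): (39, 44)}
        )
        cells = combined_or_table(df, p, m)
        high_low = cells[1]
        assert high_low.or_point == pytest.approx(0.69, abs=0.0105)
        assert (high_low.ci_low, high_low.ci_high) == pytest.approx((0.39, 1.24), abs=0.0105)

    def test_published_female_dairy_cell(self):
        df, p, m = self._df_from_counts(
            {(0, 0): (25, 23), (1, 0): (8, 31), (0, 1): (37, 31), (1, 1): (26, 22)}
        )
        cells = combined_or_table(df, p, m)
        assert cells[1].or_point == pytest.approx(0.24, abs=0.0105)

    def test_empty_stratum_raises(self):
        df, p, m = self._df_from_counts(
            {(0, 0): (5, 5), (1, 0): (0, 0), (0, 1): (5, 5), (1, 1): (5, 5)}
        )
        with pytest.raises(UndefinedOrError):
            combined_or_table(df, p, m)


class TestInteraction:
    def test_deviance_nonnegative_so_p_at_most_one(self):
        truth = SyntheticTruth(
            precision_matrix=np.eye(2), fold_changes=np.ones(2), effect_log_ors=np.zeros(2), seed=9
        )
        coh = gen_cohort(2000, truth)
        p = interaction_lrt(coh, coh["x1"], coh["x2"])
        assert 0.0 < p <= 1.0

    def test_planted_interaction_detected(self):
        truth = SyntheticTruth(
            precision_matrix=np.eye(2),
            fold_changes=np.ones(2),
            effect_log_ors=np.array([np.log(1.5), np.log(1.5)]),
            interaction_log_or=np.log(3.0),
            seed=6,
        )
        coh = gen_cohort(20000, truth)
        assert interaction_lrt(coh, coh["x1"], coh["x2"]) < 0.001

    def test_null_rejection_rate_near_nominal(self):
        """No planted product term: LRT rejects at 5% within 2 Monte-Carlo
        standard errors over 500 replicates."""
        rejections = 0
        n_rep = 500
        for seed in range(n_rep):
            truth = SyntheticTruth(
                precision_matrix=np.eye(2),
                fold_changes=np.ones(2),
                effect_log_ors=np.array([np.log(1.5), np.log(1.5)]),
                seed=20000 + seed,
            )
            coh = gen_cohort(1500, truth)
            if interaction_lrt(coh, coh["x1"], coh["x2"]) < 0.05:
                rejections += 1
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 2 * se
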