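"""Toxicity indices, HWE screen, SNP association and minP correction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hbcgm.cohort_association import (
    binomial_enrichment,
    classify_toxicity,
    combined_indicator,
    cumulative_auc,
    hwe_test,
    incidence_curve,
    minp_permutation,
    patient_auc_table,
    run_cohort_association,
    snp_association,
)


class TestToxicityIndices:
    @pytest.mark.parametrize("score,toxic", [(0, False), (1, False),
                                             (2, True), (3, True)])
    def test_classification_threshold(self, score, toxic):
        assert classify_toxicity(score) is toxic

    def test_na_propagates(self):
        assert classify_toxicity(None) is None
        assert classify_toxicity(float("nan")) is None

    @pytest.mark.parametrize("scores,expected", [
        ((0, 3, 1), 1),
        ((1, 1, 0), 0),
        ((None, 1, 1), None),     # cannot certify all <= 1
        ((None, 3, 0), 1),        # a severe score decides despite the NA
        ((2, 2, 2), 1),
    ])
    def test_combined_indicator(self, scores, expected):
        assert combined_indicator(scores) == expected

    @pytest.mark.parametrize("inds,auc", [
        ((1, 1, 1, 1), 4), ((0, 0, 0, 0), 0), ((1, 0, 1, 0), 2),
    ])
    def test_cumulative_auc_counts(self, inds, auc):
        assert cumulative_auc(inds) == auc

    def test_auc_na_on_missing_day(self):
        assert cumulative_auc((1, None, 1, 1)) is None

    @given(st.permutations([1, 0, 1, 0]))
    @settings(derandomize=True)
    def test_auc_order_invariant(self, inds):
        assert cumulative_auc(inds) == 2


class TestHwe:
    def test_exact_proportions_give_zero(self):
        chi2, p = hwe_test(25, 50, 25)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        # (30, 40, 30): q = 0.5 -> expected (25, 50, 25)
        chi2, p = hwe_test(30, 40, 30)
        assert chi2 == pytest.approx(25 / 25 + 100 / 50 + 25 / 25)
        assert p == pytest.approx(stats.chi2.sf(4.0, 1))

    def test_monomorphic_flagged(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_test(85, 0, 0)


class TestSnpAssociation:
    def test_three_genotypes_matches_regression_oracle(self, rng):
        d = rng.integers(0, 3, size=60).astype(float)
        a = rng.integers(0, 5, size=60).astype(float)
        res = snp_association(a, d)
        assert res.test == "additive-ANOVA"
        lm = stats.linregress(d, a)
        assert res.p == pytest.approx(lm.pvalue, rel=1e-12)

    def test_two_genotypes_uses_t_test(self, rng):
        d = rng.integers(0, 2, size=40).astype(float)
        a = rng.normal(size=40)
        res = snp_association(a, d)
        assert res.test == "t-test"
        tt = stats.ttest_ind(a[d == 0], a[d == 1], equal_var=True)
        assert res.p == pytest.approx(tt.pvalue, rel=1e-12)

    def test_perfect_association_floors_p(self):
        d = np.array([0.0, 1.0, 2.0] * 10)
        res = snp_association(d.copy(), d)
        assert res.p < 1e-50

    def test_single_genotype_rejected(self):
        with pytest.raises(ValueError, match="single"):
            snp_association(np.arange(5.0), np.ones(5))

    def test_na_patients_dropped(self):
        d = np.array([0, 0, 1, 1, 2, 2, np.nan])
        a = np.array([1, 2, 3, 4, 5, 6, 100.0])
        assert snp_association(a, d).n == 6


class TestMinP:
    def test_raw_p_one_gives_adjusted_one(self, rng):
        d = np.column_stack([rng.integers(0, 3, 40), np.repeat([0.0, 1.0], 20)])
        a = np.concatenate([rng.normal(size=20), rng.normal(size=20)])
        a[:20] = a[20:]  # make SNP2 grouping exactly balanced -> p near 1
        out = minp_permutation(a, d, n_perm=100, seed=0)
        assert (out["adjusted_p"] <= 1.0).all()
        assert (out["adjusted_p"] >= out["raw_p"].min()).all()

    def test_single_snp_collapses_to_marginal_permutation(self, rng):
        """With one SNP, minP equals the plain permutation p of that SNP."""
        n = 50
        d = rng.integers(0, 3, size=(n, 1)).astype(float)
        a = 0.3 * d[:, 0] + rng.normal(size=n)
        out = minp_permutation(a, d, n_perm=4000, seed=1)
        # marginal permutation p computed independently
        obs = stats.linregress(d[:, 0], a).pvalue
        rng2 = np.random.default_rng(99)
        hits = 0
        n_perm = 4000
        for _ in range(n_perm):
            p = stats.linregress(d[:, 0], a[rng2.permutation(n)]).pvalue
            hits += p <= obs
        marginal = max(hits, 1) / n_perm
        assert out["adjusted_p"].iloc[0] == pytest.approx(marginal, abs=0.03)

    def test_adjusted_monotone_in_raw(self, rng):
        d = rng.integers(0, 3, size=(60, 8)).astype(float)
        a = rng.normal(size=60)
        out = minp_permutation(a, d, n_perm=200, seed=2)
        df = out.sort_values("raw_p")
        assert df["adjusted_p"].is_monotonic_increasing

    def test_nperm_validation(self, rng):
        d = rng.integers(0, 3, size=(20, 2)).astype(float)
        a = rng.normal(size=20)
        with pytest.raises(ValueError):
            minp_permutation(a, d, n_perm=0)
        with pytest.warns(UserWarning):
            minp_permutation(a, d, n_perm=50, seed=3)


class TestBinomialEnrichment:
    def test_closed_forms(self):
        point, tail = binomial_enrichment(0, 7, 0.1)
        assert point == pytest.approx(0.9 ** 7)
        point, _ = binomial_enrichment(1, 1, 0.05)
        assert point == pytest.approx(0.05)

    def test_exact_arithmetic(self):
        point, tail = binomial_enrichment(10, 29, 0.05)
        expected = math.comb(29, 10) * 0.05 ** 10 * 0.95 ** 19
        assert point == pytest.approx(expected, rel=1e-12)
        assert tail >= point

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            binomial_enrichment(5, 3, 0.05)
        with pytest.raises(ValueError):
            binomial_enrichment(1, 3, 1.5)


class TestCohortTable:
    def test_auc_from_toy_cohort(self):
        rows = []
        # patient toxic on days 0 and 3 only; patient 2 never; patient 3 NA day 1
        scores = {
            "P0": {0: (2, 0, 0), 1: (1, 1, 1), 3: (0, 3, 0), 7: (0, 0, 0)},
            "P1": {0: (0, 0, 0), 1: (0, 0, 0), 3: (1, 1, 1), 7: (0, 0, 0)},
            "P2": {0: (0, 0, 0), 1: (None, 1, 1), 3: (0, 0, 0), 7: (0, 0, 0)},
        }
        for pid, days in scores.items():
            row = {"patient_id": pid}
            for day in (0, 1, 3, 7, 14, 21):
                for t_i, tox in enumerate(("parkinsonoid", "dyskinesia", "akathisia")):
                    val = days.get(day, (0, 0, 0))[t_i] if day in days else 0
                    row[f"tox_{tox}_{day}"] = np.nan if val is None else val
            rows.append(row)
        auc = patient_auc_table(pd.DataFrame(rows))
        assert auc["P0"] == 2.0
        assert auc["P1"] == 0.0
        assert math.isnan(auc["P2"])

    def test_incidence_curve_hand_check(self):
        df = pd.DataFrame({
            "patient_id": ["P0", "P1", "P2"],
            "tox_parkinsonoid_0": [0.0, 1.0, 2.0],
            "tox_dyskinesia_0": [0.0, 0.0, np.nan],
            "tox_akathisia_0": [0.0, 0.0, 0.0],
        })
        out = incidence_curve(df)
        park = out[(out["toxicity"] == "parkinsonoid") & (out["day"] == 0)].iloc[0]
        assert park["mean"] == pytest.approx(1.0)
        assert park["sem"] == pytest.approx(np.std([0, 1, 2], ddof=1) / np.sqrt(3))
        dys = out[(out["toxicity"] == "dyskinesia") & (out["day"] == 0)].iloc[0]
        assert dys["n"] == 2

    def test_full_cohort_run_excludes_monomorphic(self, null_cohort):
        cohort, _ = null_cohort
        cohort = cohort.copy()
        cohort["snp_00"] = 0.0   # force one monomorphic SNP
        out = run_cohort_association(cohort, n_perm=100, seed=4)
        row = out[out["snp"] == "snp_00"].iloc[0]
        assert row["excluded"] == "non-polymorphic"
        tested = out[out["excluded"] == ""]
        assert (tested["adjusted_p"] >= tested["raw_p"]).all()
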