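"""Generators: reproducibility, configured structure, truth labels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hbcgm.cohort_association import patient_auc_table
from hbcgm.synthetic_data import (
    CausalBlockSpec,
    CohortSimConfig,
    LdBlock,
    PanelSimConfig,
    default_latency_block,
    simulate_cohort,
    simulate_strain_panel,
    simulate_variant_calls,
)
from hbcgm.variant_filter import ALT_CODE, N_CODE


class TestPanelGenerator:
    def test_three_phenotype_clusters(self, latency_panel):
        """Group means 20/158/234 s with SD 15 give three separated clusters
        of sizes 14/2/1."""
        _, phenotype, _, truth = latency_panel
        pheno = dict(zip(phenotype["strain"], phenotype["mean"]))
        groups = {}
        for strain, g in truth.group_of_strain.items():
            groups.setdefault(g, []).append(pheno[strain])
        assert sorted(len(v) for v in groups.values()) == [1, 2, 14]
        means = sorted(np.mean(v) for v in groups.values())
        assert means[0] < 80 < means[1] < 220 < means[2]

    def test_matrix_invariants(self, latency_panel):
        matrix = latency_panel[0]
        assert (matrix.alleles == ALT_CODE).any(axis=0).all()
        pos = matrix.sites["pos"].to_numpy()
        assert (np.diff(pos) > 0).all()

    def test_zero_missing_rate_gives_no_n(self):
        config = PanelSimConfig(seed=3, n_sites=300, missing_rate=0.0)
        matrix, *_ = simulate_strain_panel(config)
        assert not (matrix.alleles == N_CODE).any()

    def test_seed_reproducibility(self):
        config = PanelSimConfig(seed=17, n_sites=200,
                                causal_block=default_latency_block(17))
        m1, p1, a1, _ = simulate_strain_panel(config)
        m2, p2, a2, _ = simulate_strain_panel(config)
        assert np.array_equal(m1.alleles, m2.alleles)
        assert p1.equals(p2) and a1.equals(a2)

    def test_noise_free_phenotype_equals_group_mean(self):
        cb = CausalBlockSpec(start=105, width=10,
                             group_of_strain=tuple([0] * 14 + [1, 1, 2]),
                             group_means=(20.0, 158.0, 234.0), group_sd=0.0)
        _, phenotype, _, truth = simulate_strain_panel(
            PanelSimConfig(seed=5, causal_block=cb))
        pheno = dict(zip(phenotype["strain"], phenotype["mean"]))
        for strain, g in truth.group_of_strain.items():
            assert pheno[strain] == cb.group_means[g]

    def test_causal_block_crossing_segment_rejected(self):
        cb = CausalBlockSpec(start=45, width=10,
                             group_of_strain=tuple([0] * 15 + [1, 2]),
                             group_means=(20.0, 158.0, 234.0))
        with pytest.raises(ValueError, match="segment"):
            PanelSimConfig(seed=0, region_length=50, causal_block=cb)

    def test_annotation_marks_single_causal_gene(self, latency_panel):
        _, _, annotation, truth = latency_panel
        causal = annotation[annotation["gene"] == truth.causal_gene]
        assert len(causal) == 1
        assert causal.iloc[0]["snp_consequences"] == "missense"
        assert "brain" in causal.iloc[0]["organ_flags"]

    @pytest.mark.parametrize("bad_kwargs", [
        {"n_strains": 3},
        {"missing_rate": 0.7},
    ])
    def test_config_validation(self, bad_kwargs):
        with pytest.raises(ValueError):
            PanelSimConfig(**bad_kwargs)


class TestVariantCallGenerator:
    def test_every_branch_covered(self):
        _, truth = simulate_variant_calls()
        reasons = {r for _, _, r in truth.filter_verdicts}
        assert {"pass", "qual", "gt", "pl-gap", "multi-allelic", "indel"} <= reasons

    def test_one_truth_label_per_record(self):
        records, truth = simulate_variant_calls(n_per_category=2)
        assert len(records) == len(truth.filter_verdicts)
        assert len({rid for rid, *_ in truth.filter_verdicts}) == len(records)


class TestCohortGenerator:
    def test_dropout_counts_match_config(self, null_cohort):
        cohort, _ = null_cohort
        for day, expected in zip((0, 1, 3, 7, 14, 21), (85, 85, 85, 85, 81, 54)):
            for tox in ("parkinsonoid", "dyskinesia", "akathisia"):
                assert cohort[f"tox_{tox}_{day}"].notna().sum() == expected

    def test_hwe_genotype_frequencies(self):
        """Pooled genotype counts match HWE expectation within sampling error."""
        mafs = (0.3,) * 4
        counts = np.zeros(3)
        n_cohorts, n_patients = 30, 85
        for i in range(n_cohorts):
            cohort, _ = simulate_cohort(CohortSimConfig(
                n_patients=n_patients, n_snps=4, ld_blocks=(),
                minor_allele_freqs=mafs, dropout=(85,) * 6, seed=100 + i))
            for j in range(4):
                d = cohort[f"snp_{j:02d}"]
                counts += [np.sum(d == g) for g in (0, 1, 2)]
        total = counts.sum()
        expected = np.array([0.49, 0.42, 0.09]) * total
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=2) > 1e-3

    def test_ld_blocks_induce_genotype_correlation(self):
        cfg = CohortSimConfig(n_patients=400, n_snps=4,
                              ld_blocks=(LdBlock(0, 2, 0.9),),
                              minor_allele_freqs=(0.4,) * 4,
                              dropout=(400,) * 6, seed=8)
        cohort, _ = simulate_cohort(cfg)
        d = cohort[[f"snp_{j:02d}" for j in range(4)]].to_numpy(float)
        corr = np.corrcoef(d.T)
        assert corr[0, 1] > 0.5          # inside the LD block
        assert abs(corr[2, 3]) < 0.2     # outside

    def test_zero_maf_snp_monomorphic(self):
        cfg = CohortSimConfig(n_patients=50, n_snps=3, ld_blocks=(),
                              minor_allele_freqs=(0.0, 0.3, 0.3),
                              dropout=(50,) * 6, seed=9)
        cohort, _ = simulate_cohort(cfg)
        assert (cohort["snp_00"] == 0).all()

    def test_null_pvalues_uniform_over_cohorts(self):
        """With no causal effect, per-SNP association p over replicate
        cohorts is approximately uniform (Kolmogorov-Smirnov)."""
        ps = []
        for i in range(220):
            cfg = CohortSimConfig(n_patients=85, n_snps=2, ld_blocks=(),
                                  minor_allele_freqs=(0.4, 0.3),
                                  dropout=(85,) * 6, seed=3000 + i)
            cohort, _ = simulate_cohort(cfg)
            auc = patient_auc_table(cohort).to_numpy()
            d = cohort["snp_00"].to_numpy(float)
            if np.unique(d).size < 2 or np.var(auc) == 0:
                continue
            ps.append(stats.linregress(d, auc).pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_causal_dosage_shifts_toxicity(self):
        """A strong causal log-odds raises AUC with minor-allele dosage."""
        cfg = CohortSimConfig(causal_snp=5, causal_log_odds=1.5, seed=12)
        cohort, truth = simulate_cohort(cfg)
        auc = patient_auc_table(cohort)
        d = cohort.set_index("patient_id")["snp_05"]
        assert truth.causal_snp == 5
        assert auc[d == 2].mean() > auc[d == 0].mean()

    def test_dropout_validation(self):
        with pytest.raises(ValueError, match="non-increasing"):
            CohortSimConfig(dropout=(85, 85, 86, 85, 81, 54))

    def test_seed_reproducibility(self):
        c1, _ = simulate_cohort(CohortSimConfig(seed=77))
        c2, _ = simulate_cohort(CohortSimConfig(seed=77))
        assert c1.equals(c2)
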