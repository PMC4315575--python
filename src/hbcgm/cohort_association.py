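"""Human pharmacogenetic arm: toxicity indices and SNP association.

Patients are scored 0 (absent) to 3 (severe) for three drug-induced
toxicity types (parkinsonoid, dyskinesia, akathisia) at assessment days
0, 1, 3, 7, 14 and 21.  A patient exhibits toxicity on a day if any of
the three scores is >= 2, and is non-toxic if all three are <= 1.  The
cumulative toxicity index (called AUC) counts the days among {0, 1, 3,
7} on which the combined indicator is 1, so it takes values 0-4.

Each SNP on the panel is screened for Hardy-Weinberg equilibrium, then
tested for association between minor-allele dosage and the AUC: an
additive linear model (1-df slope F test) when all three genotypes are
observed, a two-sample t-test when only two are.  Family-wise multiple
testing is corrected by a minP permutation scheme: toxicity values are
permuted across patients while genotypes stay fixed — preserving the
linkage disequilibrium among SNPs — and each observed p is compared to
the permutation distribution of the minimum p across the panel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TOXICITY_TYPES",
    "ASSESSMENT_DAYS",
    "AUC_DAYS",
    "classify_toxicity",
    "combined_indicator",
    "cumulative_auc",
    "hwe_test",
    "snp_association",
    "minp_permutation",
    "binomial_enrichment",
    "incidence_curve",
    "patient_auc_table",
    "run_cohort_association",
]

TOXICITY_TYPES = ("parkinsonoid", "dyskinesia", "akathisia")
ASSESSMENT_DAYS = (0, 1, 3, 7, 14, 21)
AUC_DAYS = (0, 1, 3, 7)
TOXIC_THRESHOLD = 2


def classify_toxicity(score: float | None) -> bool | None:
    """Toxic iff the ordinal score is >= 2; NA propagates."""
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return None
    if score not in (0, 1, 2, 3):
        raise ValueError(f"score must be ordinal 0-3, got {score!r}")
    return score >= TOXIC_THRESHOLD


def combined_indicator(scores: Sequence[float | None]) -> int | None:
    """Combined toxicity for one day from the three per-type scores.

    1 if any score is >= 2; 0 if all three are present and <= 1; NA when
    undecidable (some score missing and none reaches 2).
    """
    if len(scores) != len(TOXICITY_TYPES):
        raise ValueError("expected one score per toxicity type")
    verdicts = [classify_toxicity(s) for s in scores]
    if any(v is True for v in verdicts):
        return 1
    if all(v is False for v in verdicts):
        return 0
    return None


def cumulative_auc(indicators: Sequence[int | None]) -> int | None:
    """Count of toxic days over the four early assessment days (0-4 scale).

    Any missing indicator makes the cumulative index NA (the patient is
    then excluded from association).  Order of days does not matter.
    """
    if len(indicators) != len(AUC_DAYS):
        raise ValueError(f"expected {len(AUC_DAYS)} day indicators")
    vals = []
    for ind in indicators:
        if ind is None or (isinstance(ind, float) and math.isnan(ind)):
            return None
        if ind not in (0, 1):
            raise ValueError(f"indicator must be 0/1/NA, got {ind!r}")
        vals.append(int(ind))
    return sum(vals)


def hwe_test(n0: int, n1: int, n2: int) -> tuple[float, float]:
    """1-df chi-squared goodness-of-fit of genotype counts against HWE.

    (n0, n1, n2) are counts of major-homozygote, heterozygote and
    minor-homozygote genotypes.  Expected counts come from the sample
    allele frequency.  Monomorphic SNPs (allele frequency 0 or 1) have no
    defined test and raise; callers flag them non-polymorphic.
    """
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("no genotypes observed")
    q = (2 * n2 + n1) / (2 * n)  # minor allele frequency
    if q == 0.0 or q == 1.0:
        raise ValueError("monomorphic SNP: HWE test undefined")
    p = 1.0 - q
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass(frozen=True)
class SnpAssociation:
    test: str            # "additive-ANOVA" | "t-test"
    p: float
    n: int


def snp_association(auc: np.ndarray, dosage: np.ndarray) -> SnpAssociation:
    """Raw association p for one SNP; test chosen by observed genotypes.

    Patients with NA in either variable are dropped.  Three observed
    genotypes: linear regression of AUC on dosage (0/1/2), p from the
    1-df slope F test.  Two genotypes: two-sample t-test.  One genotype:
    raises (the SNP is excluded and flagged upstream).
    """
    auc = np.asarray(auc, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    ok = ~(np.isnan(auc) | np.isnan(dosage))
    a, d = auc[ok], dosage[ok]
    geno = np.unique(d)
    if geno.size < 2:
        raise ValueError("SNP has a single observed genotype; excluded")
    if geno.size >= 3:
        res = stats.linregress(d, a)
        return SnpAssociation("additive-ANOVA", float(res.pvalue), int(a.size))
    g0, g1 = a[d == geno[0]], a[d == geno[1]]
    res = stats.ttest_ind(g0, g1, equal_var=True)
    p = float(res.pvalue)
    if math.isnan(p):  # zero variance in both groups -> no evidence
        p = 1.0
    return SnpAssociation("t-test", p, int(a.size))


def _raw_pvalues(auc_matrix: np.ndarray, dosage: np.ndarray) -> np.ndarray:
    """Vectorised raw p for every SNP against every response column.

    ``auc_matrix`` is (n_patients, n_responses) — the observed AUC and/or
    its permutations; ``dosage`` is (n_patients, n_snps), complete cases
    only.  Additive 1-df slope test expressed through the squared
    correlation; SNPs with two observed genotypes reduce to the pooled
    t-test, which is the same F when dosage is binary-valued, so one
    formula serves both (dosage enters only through its values).
    """
    n = auc_matrix.shape[0]
    x = dosage - dosage.mean(axis=0)
    y = auc_matrix - auc_matrix.mean(axis=0)
    sx = (x ** 2).sum(axis=0)                      # (n_snps,)
    sy = (y ** 2).sum(axis=0)                      # (n_resp,)
    sxy = x.T @ y                                  # (n_snps, n_resp)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sxy ** 2 / np.outer(sx, sy)
        r2 = np.clip(r2, 0.0, 1.0)
        f_stat = (n - 2) * r2 / (1.0 - r2)
    p = stats.f.sf(f_stat, 1, n - 2)
    p = np.where(np.isnan(f_stat) | (sy[None, :] == 0), 1.0, p)
    return p


def minp_permutation(
    auc: np.ndarray,
    dosage_matrix: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    add_one: bool = False,
) -> pd.DataFrame:
    """Westfall-Young-style minP adjusted p-values for a SNP panel.

    AUC values are permuted across patients while genotypes stay fixed,
    raw p is recomputed for every SNP, and the minimum over the panel is
    recorded per permutation.  The adjusted p for SNP j is the proportion
    of permutation minima <= the observed raw p_j (floored at 1/n_perm);
    with ``add_one`` the (k+1)/(n_perm+1) estimator is used instead.
    Patients with NA AUC or any NA genotype are excluded listwise.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse resolution", stacklevel=2)
    auc = np.asarray(auc, dtype=float)
    dosage_matrix = np.asarray(dosage_matrix, dtype=float)
    ok = ~np.isnan(auc) & ~np.isnan(dosage_matrix).any(axis=1)
    a, d = auc[ok], dosage_matrix[ok]
    n = a.size
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for t in range(n_perm):
        perms[:, t] = a[rng.permutation(n)]
    observed = _raw_pvalues(a[:, None], d)[:, 0]
    perm_p = _raw_pvalues(perms, d)          # (n_snps, n_perm)
    min_p = perm_p.min(axis=0)               # (n_perm,)
    counts = (min_p[None, :] <= observed[:, None]).sum(axis=1)
    if add_one:
        adjusted = (counts + 1) / (n_perm + 1)
    else:
        adjusted = np.maximum(counts, 1) / n_perm
    return pd.DataFrame({"raw_p": observed, "adjusted_p": adjusted, "n": n})


def binomial_enrichment(k: int, m: int, alpha: float) -> tuple[float, float]:
    """Probability that k of m independent tests fall below alpha by chance.

    Returns (point probability C(m,k) alpha^k (1-alpha)^(m-k),
    upper-tail P(X >= k)) for X ~ Binomial(m, alpha).
    """
    if not 0 <= k <= m:
        raise ValueError("need 0 <= k <= m")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    point = float(stats.binom.pmf(k, m, alpha))
    tail = float(stats.binom.sf(k - 1, m, alpha))
    return point, tail


# ---------------------------------------------------------------------------
# Cohort-table plumbing
# ---------------------------------------------------------------------------

def _score_column(tox_type: str, day: int) -> str:
    return f"tox_{tox_type}_{day}"


def patient_auc_table(cohort: pd.DataFrame) -> pd.Series:
    """Per-patient cumulative toxicity index (AUC) from the cohort table.

    Expects columns tox_{type}_{day} for the three types and at least the
    four early days; returns a float Series indexed by patient_id with NaN
    where the index is undefined.
    """
    out = {}
    for row in cohort.itertuples(index=False):
        indicators = []
        for day in AUC_DAYS:
            scores = [getattr(row, _score_column(t, day)) for t in TOXICITY_TYPES]
            scores = [None if pd.isna(s) else int(s) for s in scores]
            indicators.append(combined_indicator(scores))
        if any(ind is None for ind in indicators):
            out[row.patient_id] = float("nan")
        else:
            out[row.patient_id] = float(cumulative_auc(indicators))
    return pd.Series(out, name="auc")


def incidence_curve(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-day mean +/- SEM of each toxicity score, with available counts."""
    rows = []
    for tox in TOXICITY_TYPES:
        for day in ASSESSMENT_DAYS:
            col = _score_column(tox, day)
            if col not in cohort.columns:
                continue
            vals = cohort[col].dropna().to_numpy(dtype=float)
            n = vals.size
            mean = float(vals.mean()) if n else float("nan")
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append({"toxicity": tox, "day": day, "mean": mean,
                         "sem": sem, "n": n})
    return pd.DataFrame(rows)


def run_cohort_association(
    cohort: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    hwe_alpha: float = 0.05,
) -> pd.DataFrame:
    """Full cohort analysis mirroring the association-table layout.

    Computes per-patient AUC, flags non-polymorphic SNPs, runs the HWE
    screen, per-SNP association and the minP permutation correction.
    Returns one row per SNP with columns (snp, maf, n, test, hwe_p,
    raw_p, adjusted_p, excluded).
    """
    snp_cols = [c for c in cohort.columns if c.startswith("snp_")]
    auc = patient_auc_table(cohort).to_numpy()
    dosage = cohort[snp_cols].to_numpy(dtype=float)

    rows = []
    testable: list[int] = []
    for j, col in enumerate(snp_cols):
        d = dosage[:, j]
        d_ok = d[~np.isnan(d)]
        n_obs = d_ok.size
        counts = [(d_ok == g).sum() for g in (0, 1, 2)]
        maf = (2 * counts[2] + counts[1]) / (2 * n_obs) if n_obs else float("nan")
        row = {"snp": col, "maf": float(maf), "n": int(n_obs),
               "test": None, "hwe_p": float("nan"),
               "raw_p": float("nan"), "adjusted_p": float("nan"),
               "excluded": ""}
        if maf == 0.0 or maf == 1.0 or n_obs == 0:
            row["excluded"] = "non-polymorphic"
            rows.append(row)
            continue
        chi2, hp = hwe_test(*counts)
        row["hwe_p"] = hp
        if hp < hwe_alpha:
            row["excluded"] = "hwe-violation"
            rows.append(row)
            continue
        assoc = snp_association(auc, d)
        row["test"] = assoc.test
        row["raw_p"] = assoc.p
        testable.append(j)
        rows.append(row)

    out = pd.DataFrame(rows)
    if testable:
        adj = minp_permutation(auc, dosage[:, testable], n_perm=n_perm, seed=seed)
        for r, j in enumerate(testable):
            out.loc[out.index[out["snp"] == snp_cols[j]], "adjusted_p"] = (
                adj["adjusted_p"].iloc[r]
            )
    return out
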