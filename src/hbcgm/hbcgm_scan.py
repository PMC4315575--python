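"""Genome-wide haplotype-phenotype association scan.

Every haplotype block is scored against the strain phenotype by one-way
ANOVA, with strains as observations grouped by haplotype.  The strain
phenotype is the published strain mean (one observation per strain, as in
Mouse Phenome Database tables).  Alongside the F statistic and p-value an
ANOVA-derived genetic effect size is reported:

    effect = (SSB - (k - 1) * MSE) / (SStot + MSE),   MSE = SSW / (n - k)

where SSB/SSW/SStot are the between-, within- and total sums of squares,
k the number of haplotype groups and n the number of strains used.  The
statistic is bounded above by 1, attained exactly when SSW = 0.

Block scores are aggregated to genes by interval overlap (a gene keeps
the smallest p — or largest F for categorical traits — over all blocks it
overlaps), then candidates are filtered to genes that both carry a
missense SNP and are expressed in the designated target organ, and
ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .haplotype_map import EXCLUDED, HaplotypeBlock, build_blocks, eligible_snps
from .variant_filter import StrainGenotypeMatrix

__all__ = [
    "BlockAssociation",
    "GeneResult",
    "SingletonGroupsError",
    "block_anova",
    "effect_size",
    "scan_blocks",
    "aggregate_genes",
    "filter_and_rank",
    "run_scan",
]

logger = logging.getLogger(__name__)

TraitType = Literal["numeric", "categorical"]


class SingletonGroupsError(ValueError):
    """Every group has one strain (n == k): within-group variance undefined."""


@dataclass(frozen=True)
class BlockAssociation:
    block: HaplotypeBlock
    F: float
    p: float
    effect_size: float
    n: int
    k: int


@dataclass(frozen=True)
class GeneResult:
    gene: str
    chrom: str
    start: int
    end: int
    p: float
    F: float
    effect_size: float
    k: int
    block_start: int
    block_end: int
    has_missense: bool
    expressed_in_target_organ: bool


def _group_sums_of_squares(values: np.ndarray,
                           labels: np.ndarray) -> tuple[float, float, int, int]:
    """(SSB, SStot, k, n) for one-way grouped data, via group sums."""
    groups = np.unique(labels)
    k = groups.size
    n = values.size
    grand = values.mean()
    ssb = 0.0
    for g in groups:
        v = values[labels == g]
        ssb += v.size * (v.mean() - grand) ** 2
    sstot = float(((values - grand) ** 2).sum())
    return float(ssb), sstot, k, n


def effect_size(ssb: float, sstot: float, k: int, n: int) -> float:
    """Genetic effect size (SSB - (k-1)*MSE)/(SStot + MSE), MSE = SSW/(n-k)."""
    if n <= k:
        raise SingletonGroupsError(f"n={n} must exceed k={k}")
    mse = (sstot - ssb) / (n - k)
    denom = sstot + mse
    if denom == 0.0:  # constant phenotype: nothing to explain
        return 0.0
    return (ssb - (k - 1) * mse) / denom


def block_anova(
    phenotype: dict[str, float],
    block: HaplotypeBlock,
    categorical: bool = False,
) -> BlockAssociation:
    """One-way ANOVA of the strain phenotype against a block's haplotype groups.

    EXCLUDED strains and strains without phenotype are dropped; groups left
    empty after dropping do not count towards k.  For categorical traits
    the response must already be integer-coded (see ``encode_categorical``).
    Degenerate inputs: identical phenotype values give F=0, p=1; a perfect
    group separation (SSW=0 with SSB>0) gives F=inf, p=0.
    """
    vals, labs = [], []
    for strain, g in block.assignment.items():
        if g == EXCLUDED or strain not in phenotype:
            continue
        vals.append(phenotype[strain])
        labs.append(g)
    values = np.asarray(vals, dtype=float)
    labels = np.asarray(labs)
    k = np.unique(labels).size
    n = values.size
    if k < 2:
        raise ValueError("need >= 2 non-empty groups")
    if n == k:
        raise SingletonGroupsError("all groups singleton (n == k)")
    ssb, sstot, k, n = _group_sums_of_squares(values, labels)
    ssw = sstot - ssb
    if ssb <= 0.0:
        f_stat, p = 0.0, 1.0
    elif ssw <= 0.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ssb / (k - 1)) / (ssw / (n - k))
        p = float(stats.f.sf(f_stat, k - 1, n - k))
    eff = effect_size(ssb, sstot, k, n)
    return BlockAssociation(block, float(f_stat), p, eff, n, k)


def encode_categorical(phenotype: dict[str, object]) -> dict[str, float]:
    """Integer-code a categorical strain trait (stable order of first appearance)."""
    codes: dict[object, int] = {}
    out = {}
    for strain, v in phenotype.items():
        out[strain] = float(codes.setdefault(v, len(codes)))
    return out


def scan_blocks(
    phenotype: dict[str, float],
    blocks: Sequence[HaplotypeBlock],
    categorical: bool = False,
) -> list[BlockAssociation]:
    """Score every block; blocks with undefined ANOVA are skipped and logged."""
    out = []
    for block in blocks:
        try:
            out.append(block_anova(phenotype, block, categorical=categorical))
        except (SingletonGroupsError, ValueError) as exc:
            logger.debug("skipping block %s[%d,%d): %s",
                         block.chrom, block.start, block.end, exc)
    return out


def aggregate_genes(
    associations: Sequence[BlockAssociation],
    annotation: pd.DataFrame,
    matrix: StrainGenotypeMatrix,
    categorical: bool = False,
) -> list[GeneResult]:
    """Attribute blocks to genes by coordinate overlap and keep each gene's best.

    ``annotation`` columns: gene, chrom, start, end, organ_flags,
    snp_consequences (see synthetic_data for the TSV layout).  Best means
    smallest p for numeric traits, largest F for categorical ones.  Genes
    overlapping no scored block are omitted.
    """
    if not associations:
        return []
    pos = matrix.sites["pos"].to_numpy()
    b_chrom = np.array([a.block.chrom for a in associations])
    b_start = np.array([int(pos[a.block.start]) for a in associations])
    b_end = np.array([int(pos[a.block.end - 1]) for a in associations])
    b_p = np.array([a.p for a in associations])
    b_f = np.array([a.F for a in associations])
    results: list[GeneResult] = []
    for row in annotation.itertuples(index=False):
        hit = (
            (b_chrom == str(row.chrom))
            & (b_end >= int(row.start))
            & (b_start <= int(row.end))
        )
        idx = np.flatnonzero(hit)
        if idx.size == 0:
            continue
        if categorical:
            best = associations[idx[np.argmax(b_f[idx])]]
        else:
            # smallest p, largest F on ties (lexsort keys are last-major)
            order = np.lexsort((-b_f[idx], b_p[idx]))
            best = associations[idx[order[0]]]
        consequences = str(getattr(row, "snp_consequences", "") or "")
        organs = str(getattr(row, "organ_flags", "") or "")
        results.append(
            GeneResult(
                gene=str(row.gene),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                p=best.p,
                F=best.F,
                effect_size=best.effect_size,
                k=best.k,
                block_start=best.block.start,
                block_end=best.block.end,
                has_missense="missense" in consequences.split(";"),
                expressed_in_target_organ=organs,  # resolved in filter step
            )
        )
    return results


def filter_and_rank(
    gene_results: Sequence[GeneResult],
    target_organ: str,
    categorical: bool = False,
) -> list[GeneResult]:
    """Keep genes expressed in the target organ that carry a missense SNP.

    Sorted by p ascending (numeric) or F descending (categorical); ties
    broken by gene symbol for determinism.
    """
    available: set[str] = set()
    resolved: list[GeneResult] = []
    for r in gene_results:
        organs = [o for o in str(r.expressed_in_target_organ).split(";") if o]
        available.update(organs)
        expressed = target_organ in organs
        resolved.append(
            GeneResult(**{**r.__dict__, "expressed_in_target_organ": expressed})
        )
    if available and target_organ not in available:
        raise ValueError(
            f"unknown organ {target_organ!r}; available: {sorted(available)}"
        )
    kept = [r for r in resolved if r.expressed_in_target_organ and r.has_missense]
    if categorical:
        kept.sort(key=lambda r: (-r.F, r.gene))
    else:
        kept.sort(key=lambda r: (r.p, -r.F, r.gene))
    return kept


def run_scan(
    matrix: StrainGenotypeMatrix,
    phenotype: dict[str, float],
    annotation: pd.DataFrame,
    target_organ: str,
    max_haplotypes: int = 5,
    categorical: bool = False,
    min_unambiguous: int | None = None,
) -> list[GeneResult]:
    """Full pipeline: eligibility -> blocks -> ANOVA -> genes -> filter/rank."""
    pheno_strains = [s for s in matrix.strains if s in phenotype]
    sub = matrix.subset_strains(pheno_strains)
    if categorical:
        phenotype = encode_categorical(phenotype)
    mask = eligible_snps(sub, pheno_strains, min_unambiguous=min_unambiguous)
    blocks = build_blocks(sub, mask, max_haplotypes=max_haplotypes)
    assoc = scan_blocks(phenotype, blocks, categorical=categorical)
    genes = aggregate_genes(assoc, annotation, sub, categorical=categorical)
    return filter_and_rank(genes, target_organ, categorical=categorical)


def results_to_frame(results: Sequence[GeneResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in results])
    if not df.empty:
        df = df.drop(columns=["block_start", "block_end"])
        df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
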