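"""Synthetic inputs with ground-truth labels for the whole pipeline.

Three generators produce everything the analysis consumes:

* ``simulate_strain_panel`` — an inbred-strain SNP matrix built as a
  mosaic of ancestral haplotypes (the genome is cut into fixed-length
  segments and each strain draws one ancestral haplotype per segment),
  with one causal block whose haplotypes split the panel into 2-5 groups
  with distinct latency-like phenotype means; plus the matching MPD-style
  phenotype table and a gene annotation table.
* ``simulate_variant_calls`` — a VCF exercising every branch of the
  variant-quality filter (QUAL, GT, PL-gap, multi-allelic, indel), each
  record labelled with its expected verdict.
* ``simulate_cohort`` — a patient cohort with LD-blocked genotypes drawn
  under Hardy-Weinberg equilibrium via a latent Gaussian copula, per-day
  ordinal toxicity scores from a latent-logistic model with day effects
  and an optional additive causal-SNP dosage term, and per-day dropout.

Every generator returns a ``SimTruth`` carrying the causal identities
and labels the tests use as oracles.  All randomness flows from the seed
in the config; per-stage streams are derived from it, so outputs are
bit-for-bit reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .variant_filter import (
    ALT_CODE,
    N_CODE,
    REF_CODE,
    StrainGenotypeMatrix,
)
from .cohort_association import ASSESSMENT_DAYS, TOXICITY_TYPES

__all__ = [
    "PanelSimConfig",
    "CohortSimConfig",
    "SimTruth",
    "simulate_strain_panel",
    "simulate_variant_calls",
    "simulate_cohort",
    "FILTER_CATEGORIES",
    "write_vcf",
]

_BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# Configs and truth record
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CausalBlockSpec:
    """Causal block: site interval, strain->group map and phenotype model.

    ``group_of_strain[i]`` is the group (0..G-1) of strain i; group means
    are in seconds (latency), with a shared per-group SD.
    """

    start: int
    width: int
    group_of_strain: tuple[int, ...]
    group_means: tuple[float, ...]
    group_sd: float = 15.0

    @property
    def n_groups(self) -> int:
        return len(self.group_means)


@dataclass(frozen=True)
class PanelSimConfig:
    n_strains: int = 17
    n_sites: int = 2000
    n_ancestral_haplotypes: int = 4
    region_length: int = 50
    causal_block: CausalBlockSpec | None = None
    n_genes: int = 50
    missing_rate: float = 0.02
    alt_freq: float = 0.5          # ancestral allele frequency at each site
    target_organ: str = "brain"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 4:
            raise ValueError("n_strains >= 4 required")
        if not 0.0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        cb = self.causal_block
        if cb is not None:
            if len(cb.group_of_strain) != self.n_strains:
                raise ValueError("group assignment must cover every strain")
            if len(set(cb.group_of_strain)) != cb.n_groups:
                raise ValueError("every group needs >= 1 strain")
            if len(set(cb.group_means)) != cb.n_groups:
                raise ValueError("causal group means must be distinct")
            if not 2 <= cb.n_groups <= 5:
                raise ValueError("causal block needs 2-5 groups")
            if cb.start < 0 or cb.start + cb.width > self.n_sites:
                raise ValueError("causal block out of bounds")
            if cb.width < 2:
                raise ValueError("causal block needs width >= 2")
            seg = cb.start // self.region_length
            if (cb.start + cb.width - 1) // self.region_length != seg:
                raise ValueError(
                    "causal block wider than a mosaic segment: recombination "
                    "would break it"
                )


def default_latency_block(n_strains: int = 17) -> CausalBlockSpec:
    """Three-group latency structure: 14 low strains (~20 s), two
    intermediate (~158 s), one extreme (234 s)."""
    if n_strains < 4:
        raise ValueError("need >= 4 strains")
    groups = [0] * (n_strains - 3) + [1, 1, 2]
    return CausalBlockSpec(
        start=105, width=10, group_of_strain=tuple(groups),
        group_means=(20.0, 158.0, 234.0), group_sd=15.0,
    )


@dataclass(frozen=True)
class LdBlock:
    start: int       # SNP panel index, inclusive
    end: int         # exclusive
    correlation: float = 0.8


@dataclass(frozen=True)
class CohortSimConfig:
    n_patients: int = 85
    n_snps: int = 29
    ld_blocks: tuple[LdBlock, ...] = (
        LdBlock(3, 14, 0.8), LdBlock(14, 21, 0.8), LdBlock(24, 29, 0.8),
    )
    minor_allele_freqs: tuple[float, ...] | None = None
    causal_snp: int | None = None
    causal_log_odds: float = 0.0
    days: tuple[int, ...] = ASSESSMENT_DAYS
    dropout: tuple[int, ...] = (85, 85, 85, 85, 81, 54)
    seed: int = 0

    def __post_init__(self) -> None:
        mafs = self.minor_allele_freqs
        if mafs is not None:
            if len(mafs) != self.n_snps:
                raise ValueError("need one MAF per SNP")
            if any(not 0.0 <= f <= 0.5 for f in mafs):
                raise ValueError("MAFs must lie in [0, 0.5]")
        if len(self.dropout) != len(self.days):
            raise ValueError("dropout needs one count per day")
        if any(b > a for a, b in zip(self.dropout, self.dropout[1:])):
            raise ValueError("dropout counts must be non-increasing over days")
        if any(c > self.n_patients or c < 0 for c in self.dropout):
            raise ValueError("dropout counts must be within 0..n_patients")
        if self.causal_snp is not None and not 0 <= self.causal_snp < self.n_snps:
            raise ValueError("causal SNP index out of panel")
        for blk in self.ld_blocks:
            if not 0 <= blk.start < blk.end <= self.n_snps:
                raise ValueError("LD block out of panel bounds")


@dataclass
class SimTruth:
    """Generator-side ground truth used as the test oracle."""

    causal_block: CausalBlockSpec | None = None
    causal_gene: str | None = None
    group_of_strain: dict[str, int] = field(default_factory=dict)
    filter_verdicts: list[tuple[str, str, str]] = field(default_factory=list)
    # ^ (record id, expected code "ALT"/"N", reason branch)
    causal_snp: int | None = None
    patient_propensity: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Strain panel
# ---------------------------------------------------------------------------

def _strain_names(n: int) -> list[str]:
    return [f"STRAIN_{i:02d}" for i in range(n)]


def _causal_haplotype(group: int, width: int, n_groups: int) -> np.ndarray:
    """Distinct per-group allele strings with every column polymorphic.

    Column j carries the alternative allele in groups with index greater
    than j mod (n_groups - 1); group 0 is all-reference, the top group
    all-alternative.
    """
    j = np.arange(width)
    return (group > (j % (n_groups - 1))).astype(np.int8)


def simulate_strain_panel(
    config: PanelSimConfig,
) -> tuple[StrainGenotypeMatrix, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Mosaic strain matrix + phenotype table + gene annotation + truth.

    Returns (matrix, phenotype_table, annotation, truth).  Sites with no
    alternative call across strains are dropped, so the matrix keeps the
    invariant of >= 1 alt per site; the truth's group labels refer to the
    configured causal partition.
    """
    rng = np.random.default_rng(config.seed)
    hap_rng, pheno_rng, miss_rng, annot_rng = rng.spawn(4)
    n, m = config.n_strains, config.n_sites
    strains = _strain_names(n)

    n_segments = math.ceil(m / config.region_length)
    alleles = np.empty((n, m), dtype=np.int8)
    for seg in range(n_segments):
        lo = seg * config.region_length
        hi = min(m, lo + config.region_length)
        ancestors = (
            hap_rng.random((config.n_ancestral_haplotypes, hi - lo))
            < config.alt_freq
        ).astype(np.int8)
        choice = hap_rng.integers(0, config.n_ancestral_haplotypes, size=n)
        alleles[:, lo:hi] = ancestors[choice]

    truth = SimTruth()
    cb = config.causal_block
    if cb is not None:
        for i, g in enumerate(cb.group_of_strain):
            alleles[i, cb.start:cb.start + cb.width] = _causal_haplotype(
                g, cb.width, cb.n_groups
            )
        truth.causal_block = cb
        truth.group_of_strain = dict(zip(strains, cb.group_of_strain))

    if config.missing_rate > 0:
        mask = miss_rng.random(alleles.shape) < config.missing_rate
        alleles[mask] = N_CODE

    # retained-site invariant: >= 1 definitive alt call per site
    keep = (alleles == ALT_CODE).any(axis=0)
    alleles = alleles[:, keep]
    kept_idx = np.flatnonzero(keep)
    positions = (kept_idx + 1) * 100  # bp coordinates, 100 bp spacing
    refs = annot_rng.integers(0, 4, size=kept_idx.size)
    alts = (refs + 1 + annot_rng.integers(0, 3, size=kept_idx.size)) % 4
    sites = pd.DataFrame({
        "chrom": "chr1",
        "pos": positions,
        "ref": [_BASES[b] for b in refs],
        "alt": [_BASES[b] for b in alts],
    })
    matrix = StrainGenotypeMatrix(strains, sites, alleles)

    # phenotype: one strain mean per strain (MPD layout), truncated at 0
    if cb is not None:
        means = np.array([cb.group_means[g] for g in cb.group_of_strain])
        values = means + pheno_rng.normal(0.0, cb.group_sd, size=n)
    else:
        values = pheno_rng.normal(100.0, 30.0, size=n)
    values = np.maximum(values, 0.0)
    phenotype = pd.DataFrame({
        "strain": strains,
        "mean": values,
        "sd": (cb.group_sd if cb is not None else 30.0),
        "n": 8,
    })

    annotation = _make_annotation(config, kept_idx, positions, truth, annot_rng)
    return matrix, phenotype, annotation, truth


def _make_annotation(config: PanelSimConfig, kept_idx: np.ndarray,
                     positions: np.ndarray, truth: SimTruth,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Tile genes over the original site range; flag exactly one causal gene.

    Gene intervals partition the pre-drop site index range so that the
    causal block (if any) is contained in a single gene, which is marked
    missense + expressed in the target organ.  Other genes draw their
    flags at random so the result filter has both kinds of competitors.
    """
    m = config.n_sites
    n_genes = config.n_genes
    bounds = np.linspace(0, m, n_genes + 1).astype(int)
    cb = config.causal_block
    causal_gene_idx = None
    if cb is not None:
        lo, hi = cb.start, cb.start + cb.width
        causal_gene_idx = int(np.searchsorted(bounds, lo, side="right") - 1)
        # stretch the containing gene over the whole block; clip neighbours
        bounds[causal_gene_idx + 1] = max(bounds[causal_gene_idx + 1], hi)
        for t in range(causal_gene_idx + 2, n_genes + 1):
            bounds[t] = max(bounds[t], bounds[t - 1])
    rows = []
    for g in range(n_genes):
        lo, hi = bounds[g], bounds[g + 1]
        if hi <= lo:
            continue
        name = f"Gene{g:03d}"
        is_causal = causal_gene_idx is not None and g == causal_gene_idx
        if is_causal:
            organs, consequences = config.target_organ, "missense"
            truth.causal_gene = name
        else:
            organs = config.target_organ if rng.random() < 0.5 else "liver"
            consequences = "missense" if rng.random() < 0.3 else "synonymous"
        rows.append({
            "gene": name,
            "chrom": "chr1",
            "start": int((lo + 1) * 100),
            "end": int(hi * 100),
            "organ_flags": organs,
            "snp_consequences": consequences,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Variant calls exercising every filter branch
# ---------------------------------------------------------------------------

# (category, qual, gt, pl, ref, alt, expected code, reason)
FILTER_CATEGORIES: tuple[tuple, ...] = (
    ("hom-alt-clear", 80.0, (1, 1), (60, 40, 0), "A", "G", "ALT", "pass"),
    ("qual-at-threshold", 50.0, (1, 1), (60, 40, 0), "A", "G", "ALT", "pass"),
    ("qual-just-below", 49.0, (1, 1), (60, 40, 0), "A", "G", "N", "qual"),
    ("qual-far-below", 10.0, (1, 1), (90, 45, 0), "A", "G", "N", "qual"),
    ("het-call", 80.0, (0, 1), (40, 0, 40), "A", "G", "N", "gt"),
    ("hom-ref-call", 80.0, (0, 0), (0, 40, 80), "A", "G", "N", "gt"),
    ("pl-gap-at-threshold", 80.0, (1, 1), (60, 20, 0), "A", "G", "ALT", "pass"),
    ("pl-gap-just-below", 80.0, (1, 1), (60, 19, 0), "A", "G", "N", "pl-gap"),
    ("pl-gap-zero", 80.0, (1, 1), (60, 0, 0), "A", "G", "N", "pl-gap"),
    ("multi-allelic", 80.0, (1, 1), (60, 40, 0, 50, 45, 55), "A", "G,T", "EXCLUDE", "multi-allelic"),
    ("indel", 80.0, (1, 1), (60, 40, 0), "A", "AGG", "EXCLUDE", "indel"),
)


def simulate_variant_calls(
    n_per_category: int = 1,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[list[dict], SimTruth]:
    """Variant records covering every filter-rule branch, with truth labels.

    Returns (records, truth): each record is a dict ready for VCF writing;
    truth.filter_verdicts holds (record id, expected allele code, reason).
    Expected code EXCLUDE marks records the matrix assembly must drop
    before classification (multi-allelic, indel).
    """
    truth = SimTruth()
    records = []
    pos = 1000
    for rep in range(n_per_category):
        for cat, qual, gt, pl, ref, alt, code, reason in FILTER_CATEGORIES:
            rec_id = f"{cat}_{rep}"
            records.append({
                "id": rec_id, "chrom": chrom, "pos": pos,
                "ref": ref, "alt": alt, "qual": qual,
                "gt": gt, "pl": pl,
            })
            truth.filter_verdicts.append((rec_id, code, reason))
            pos += 10
    return records, truth


def write_vcf(records: Sequence[dict], path: str | Path,
              sample: str = "STRAIN_00", chrom_length: int = 10_000_000) -> None:
    """Write simulated call records as an uncompressed VCF v4.2."""
    header = pysam.VariantHeader()
    chroms = {r["chrom"] for r in records}
    for c in sorted(chroms):
        header.contigs.add(c, length=chrom_length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda r: (r["chrom"], r["pos"])):
            rec = out.new_record(
                contig=r["chrom"], start=r["pos"] - 1,
                stop=r["pos"] - 1 + len(r["ref"]),
                alleles=(r["ref"], *r["alt"].split(",")),
                id=r["id"], qual=r["qual"],
            )
            rec.samples[sample]["GT"] = r["gt"]
            rec.samples[sample]["PL"] = list(r["pl"])
            out.write(rec)


# ---------------------------------------------------------------------------
# Patient cohort
# ---------------------------------------------------------------------------

def _copula_haplotypes(rng: np.random.Generator, n: int,
                       mafs: np.ndarray, ld_blocks: Sequence[LdBlock]
                       ) -> np.ndarray:
    """One set of n haplotypes (0/1 minor-allele indicators) per SNP.

    Latent Gaussians are independent across SNPs except within declared
    LD blocks, where they share a block factor giving pairwise
    correlation ``correlation``; thresholding at the MAF quantile makes
    each marginal Bernoulli(MAF), hence HWE after summing two draws.
    """
    m = mafs.size
    z = rng.standard_normal((n, m))
    for blk in ld_blocks:
        shared = rng.standard_normal(n)
        rho = blk.correlation
        z[:, blk.start:blk.end] = (
            math.sqrt(rho) * shared[:, None]
            + math.sqrt(1.0 - rho) * z[:, blk.start:blk.end]
        )
    thresh = stats.norm.ppf(mafs)
    return (z < thresh[None, :]).astype(np.int8)


# ordinal-score thresholds on the latent logistic scale: P(score >= s)
# = logistic(eta - _SCORE_CUTS[s]); spacing keeps severe scores rare.
_SCORE_CUTS = (1.0, 2.5, 4.0)   # for scores >=1, >=2, >=3
_DAY_EFFECTS = {0: -1.5, 1: -0.5, 3: 0.0, 7: 0.2, 14: 0.4, 21: 0.4}


def simulate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Patient table with LD-blocked HWE genotypes and ordinal toxicity scores.

    Scores per (type, day) are drawn from a cumulative-logistic model on a
    latent per-patient propensity plus a day effect and, when configured,
    an additive causal-SNP dosage term.  Patients with row index >= the
    day's dropout count have missing scores for that day.
    """
    rng = np.random.default_rng(config.seed)
    geno_rng, tox_rng = rng.spawn(2)
    n, m = config.n_patients, config.n_snps
    if config.minor_allele_freqs is None:
        mafs = geno_rng.uniform(0.1, 0.45, size=m)
    else:
        mafs = np.asarray(config.minor_allele_freqs, dtype=float)
    h1 = _copula_haplotypes(geno_rng, n, np.where(mafs > 0, mafs, 1e-12),
                            config.ld_blocks)
    h2 = _copula_haplotypes(geno_rng, n, np.where(mafs > 0, mafs, 1e-12),
                            config.ld_blocks)
    dosage = (h1 + h2).astype(np.int8)
    dosage[:, mafs == 0.0] = 0

    propensity = tox_rng.logistic(loc=-1.0, scale=1.0, size=n)
    eta_base = propensity.copy()
    if config.causal_snp is not None and config.causal_log_odds != 0.0:
        eta_base = eta_base + config.causal_log_odds * dosage[:, config.causal_snp]

    data: dict[str, object] = {
        "patient_id": [f"P{i:03d}" for i in range(n)],
    }
    for j in range(m):
        data[f"snp_{j:02d}"] = dosage[:, j].astype(float)
    for tox_i, tox in enumerate(TOXICITY_TYPES):
        tox_shift = 0.3 * (tox_i - 1)       # mild heterogeneity across types
        for day, avail in zip(config.days, config.dropout):
            eta = eta_base + _DAY_EFFECTS.get(day, 0.0) + tox_shift
            u = tox_rng.logistic(size=n)
            scores = np.zeros(n)
            for cut in _SCORE_CUTS:
                scores += (eta - cut + u > 0).astype(float)
            col = scores.astype(float)
            col[avail:] = np.nan
            data[f"tox_{tox}_{day}"] = col

    cohort = pd.DataFrame(data)
    truth = SimTruth(causal_snp=config.causal_snp,
                     patient_propensity=propensity)
    return cohort, truth
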