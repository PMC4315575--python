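"""Post-calling quality filters for per-strain variant calls.

Inbred strains are homozygous, so a single diploid call per strain
represents the whole line.  A variant call is accepted as a definitive
alternative allele only when three conditions hold simultaneously:

* the site QUAL score (Phred-scaled confidence that a variant exists at
  all) is at least 50;
* the genotype call is homozygous alternative;
* the Phred-scaled genotype likelihood (PL) of the homozygous-alternative
  genotype beats every other listed genotype by at least 20 units.

Calls failing any rule are converted to ``N`` (undetermined) rather than
discarded, so that a low-confidence variant is never silently treated as
the reference allele.  Sites with no record in a strain's VCF are treated
as reference during matrix assembly — the filter only ever demotes an
explicit variant call.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "QUAL_MIN",
    "PL_GAP_MIN",
    "AlleleCode",
    "FilterReason",
    "VariantCallRecord",
    "FilteredAllele",
    "StrainGenotypeMatrix",
    "NotASnpError",
    "classify_call",
    "read_strain_vcf",
    "build_strain_matrix",
]

QUAL_MIN = 50.0
PL_GAP_MIN = 20


class AlleleCode(enum.Enum):
    REF = 0
    ALT = 1
    N = -1


class FilterReason(enum.Enum):
    """First rule that demoted a call to N, or PASS."""

    PASS = "pass"
    LOW_QUAL = "qual"
    NOT_HOM_ALT = "gt"
    PL_GAP = "pl-gap"


class NotASnpError(ValueError):
    """Record is an indel or multi-allelic site; exclude before classifying."""


@dataclass(frozen=True)
class VariantCallRecord:
    """One bi-allelic SNP call for one strain.

    ``pl`` is ordered (hom-ref, het, hom-alt) as in VCF for a bi-allelic
    site; ``genotype`` is the diploid GT tuple, e.g. ``(1, 1)``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    genotype: tuple[int, int]
    pl: tuple[int, ...]

    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class FilteredAllele:
    code: AlleleCode
    reason: FilterReason

    def __post_init__(self) -> None:
        failed = self.reason is not FilterReason.PASS
        if failed != (self.code is AlleleCode.N):
            raise ValueError("code N iff a fail reason is recorded")


def classify_call(record: VariantCallRecord) -> FilteredAllele:
    """Apply the QUAL / GT / PL-gap rules to a single variant call.

    Returns ALT only when every rule passes; otherwise N with the first
    failing rule recorded.  Rules are checked in order QUAL, GT, PL gap.
    Both thresholds are inclusive: QUAL 50 passes, PL gap 20 passes.
    """
    if not record.is_snp():
        raise NotASnpError(
            f"{record.chrom}:{record.pos} ref={record.ref} alt={record.alt} "
            "is not a bi-allelic SNP; exclude indels/multi-allelics upstream"
        )
    if record.qual < QUAL_MIN:
        return FilteredAllele(AlleleCode.N, FilterReason.LOW_QUAL)
    if record.genotype != (1, 1):
        return FilteredAllele(AlleleCode.N, FilterReason.NOT_HOM_ALT)
    pl = record.pl
    hom_alt_pl = pl[2]
    if any(other - hom_alt_pl < PL_GAP_MIN for other in (pl[0], pl[1])):
        return FilteredAllele(AlleleCode.N, FilterReason.PL_GAP)
    return FilteredAllele(AlleleCode.ALT, FilterReason.PASS)


# ---------------------------------------------------------------------------
# Cross-strain matrix assembly
# ---------------------------------------------------------------------------

# Internal allele coding for the strains x sites matrix.
REF_CODE = 0
ALT_CODE = 1
N_CODE = -1
_TSV_CODES = {REF_CODE: "0", ALT_CODE: "1", N_CODE: "N"}
_TSV_DECODE = {"0": REF_CODE, "1": ALT_CODE, "N": N_CODE}


class StrainGenotypeMatrix:
    """Strains x SNP-sites allele matrix with codes {0 (ref), 1 (alt), N}.

    ``sites`` is a DataFrame with columns (chrom, pos, ref, alt) sorted by
    coordinate; ``alleles`` is an int8 array of shape (n_strains, n_sites)
    with N stored as -1.
    """

    def __init__(self, strains: Sequence[str], sites: pd.DataFrame,
                 alleles: np.ndarray):
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.shape != (len(strains), len(sites)):
            raise ValueError("allele array shape mismatch")
        self.strains = list(strains)
        self.sites = sites.reset_index(drop=True)
        self.alleles = alleles

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def strain_index(self, strains: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.strains)}
        return np.array([lookup[s] for s in strains], dtype=int)

    def subset_strains(self, strains: Sequence[str]) -> "StrainGenotypeMatrix":
        idx = self.strain_index(strains)
        return StrainGenotypeMatrix(list(strains), self.sites, self.alleles[idx])

    def to_tsv(self, path: str | Path) -> None:
        out = self.sites.copy()
        for i, strain in enumerate(self.strains):
            out[strain] = [_TSV_CODES[int(c)] for c in self.alleles[i]]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StrainGenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        site_cols = ["chrom", "pos", "ref", "alt"]
        strains = [c for c in df.columns if c not in site_cols]
        alleles = np.array(
            [[_TSV_DECODE[str(v)] for v in df[s]] for s in strains],
            dtype=np.int8,
        )
        return cls(strains, df[site_cols], alleles)


def read_strain_vcf(path: str | Path) -> list[VariantCallRecord]:
    """Read one strain's VCF into call records.

    Multi-allelic records and indels are kept here (as records with their
    true REF/ALT) so that assembly can drop the whole site; classification
    itself refuses them.
    """
    records: list[VariantCallRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = vcf.header.samples[0] if len(vcf.header.samples) else None
        for rec in vcf:
            alts = rec.alts or ()
            alt = alts[0] if alts else "."
            if sample is not None:
                call = rec.samples[sample]
                gt = tuple(a if a is not None else -1 for a in (call["GT"] or (-1, -1)))
                pl = tuple(call["PL"]) if call.get("PL") is not None else ()
            else:  # pragma: no cover - sites-only VCF
                gt, pl = (-1, -1), ()
            records.append(
                VariantCallRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=",".join(alts) if len(alts) > 1 else alt,
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    genotype=gt,  # type: ignore[arg-type]
                    pl=pl,
                )
            )
    return records


def build_strain_matrix(
    calls: Mapping[str, Sequence[VariantCallRecord]],
    strains: Sequence[str] | None = None,
) -> StrainGenotypeMatrix:
    """Assemble the cross-strain bi-allelic SNP matrix from filtered calls.

    The site set is the union over strains.  A strain with no record at a
    site is coded REF.  Sites are dropped when they are indels, carry more
    than one distinct alternative allele across strains, or retain no
    definitive homozygous-alternative (ALT) call in any strain.
    """
    if strains is None:
        strains = list(calls)
    site_alt: dict[tuple[str, int], set[str]] = {}
    site_ref: dict[tuple[str, int], str] = {}
    site_bad: set[tuple[str, int]] = set()
    per_strain: dict[str, dict[tuple[str, int], int]] = {}

    for strain in strains:
        seen: dict[tuple[str, int], int] = {}
        for rec in calls.get(strain, ()):
            key = (rec.chrom, rec.pos)
            if key in seen:
                raise ValueError(
                    f"duplicate record at {rec.chrom}:{rec.pos} for strain {strain}"
                )
            site_ref.setdefault(key, rec.ref)
            site_alt.setdefault(key, set()).update(rec.alt.split(","))
            if len(rec.ref) != 1 or any(len(a) != 1 for a in rec.alt.split(",")):
                site_bad.add(key)  # indel
                seen[key] = N_CODE
                continue
            try:
                verdict = classify_call(rec)
            except NotASnpError:
                site_bad.add(key)  # multi-allelic within one record
                seen[key] = N_CODE
                continue
            seen[key] = ALT_CODE if verdict.code is AlleleCode.ALT else N_CODE
        per_strain[strain] = seen

    keep: list[tuple[str, int]] = []
    for key in site_alt:
        if key in site_bad or len(site_alt[key]) > 1:
            continue
        if any(per_strain[s].get(key) == ALT_CODE for s in strains):
            keep.append(key)
    keep.sort()

    alleles = np.full((len(strains), len(keep)), REF_CODE, dtype=np.int8)
    for i, strain in enumerate(strains):
        seen = per_strain[strain]
        for j, key in enumerate(keep):
            if key in seen:
                alleles[i, j] = seen[key]
    sites = pd.DataFrame(
        {
            "chrom": [k[0] for k in keep],
            "pos": [k[1] for k in keep],
            "ref": [site_ref[k] for k in keep],
            "alt": [next(iter(site_alt[k])) for k in keep],
        }
    )
    return StrainGenotypeMatrix(strains, sites, alleles)
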