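"""SNP eligibility and dynamic haplotype-block construction.

A haplotype block is a run of consecutive eligible SNPs over which the
strain panel splits into a small number k (2..5 by default) of distinct
allele strings.  Blocks are emitted for every k separately: for each k,
every maximal run of consecutive eligible sites on one chromosome whose
fully-called strains show exactly k distinct haplotype strings becomes a
block.  Maximal means that extending the run by one eligible site on
either side changes the number of distinct strings (or leaves the
eligible run).

Strains carrying an undetermined (N) call inside the interval do not
participate in defining the haplotypes; they are assigned to a group
afterwards iff their non-N alleles are compatible with exactly one of the
k haplotype strings, and are EXCLUDED from the block otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_filter import ALT_CODE, N_CODE, REF_CODE, StrainGenotypeMatrix

__all__ = [
    "EXCLUDED",
    "HaplotypeBlock",
    "eligible_snps",
    "build_blocks",
    "blocks_to_frame",
]

EXCLUDED = -1  # group label for strains not assignable within a block


@dataclass(frozen=True)
class HaplotypeBlock:
    """Contiguous SNP interval plus the strain -> haplotype-group partition.

    ``start``/``end`` are half-open indices into the matrix site table;
    ``assignment`` maps every panel strain to a group in 0..k-1 or
    EXCLUDED.  ``haplotypes`` holds the k distinct allele strings (tuples
    over {0,1}) indexed by group label.
    """

    chrom: str
    start: int
    end: int
    k: int
    assignment: dict[str, int]
    haplotypes: tuple[tuple[int, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("interval non-empty required")
        groups = {g for g in self.assignment.values() if g != EXCLUDED}
        if groups and groups != set(range(self.k)):
            raise ValueError("assigned groups must number exactly k")


def eligible_snps(
    matrix: StrainGenotypeMatrix,
    phenotyped_strains: Sequence[str],
    min_unambiguous: int | None = None,
) -> np.ndarray:
    """Boolean mask of sites usable for block construction.

    A site is eligible iff, restricted to the phenotyped strains, (i) both
    alleles occur among the non-N calls and (ii) the number of non-N calls
    is at least ``min_unambiguous``, which defaults to min(8, ceil(n/2))
    for n phenotyped strains.
    """
    if len(phenotyped_strains) == 0:
        raise ValueError("phenotyped strain list is empty")
    idx = matrix.strain_index(phenotyped_strains)
    sub = matrix.alleles[idx]  # (n_pheno, n_sites)
    n = len(idx)
    if min_unambiguous is None:
        min_unambiguous = min(8, math.ceil(n / 2))
    called = sub != N_CODE
    n_called = called.sum(axis=0)
    has_ref = ((sub == REF_CODE) & called).any(axis=0)
    has_alt = (sub == ALT_CODE).any(axis=0)
    return has_ref & has_alt & (n_called >= min_unambiguous)


def _assign_partial(strain_alleles: np.ndarray,
                    haplotypes: Sequence[tuple[int, ...]]) -> int:
    """Group for an N-bearing strain: unique compatible haplotype or EXCLUDED."""
    called = strain_alleles != N_CODE
    matches = [
        g for g, hap in enumerate(haplotypes)
        if np.array_equal(strain_alleles[called], np.asarray(hap)[called])
    ]
    return matches[0] if len(matches) == 1 else EXCLUDED


def build_blocks(
    matrix: StrainGenotypeMatrix,
    mask: np.ndarray,
    max_haplotypes: int = 5,
) -> list[HaplotypeBlock]:
    """Emit all maximal blocks with 2..max_haplotypes haplotypes.

    Runs of consecutive eligible sites are scanned per chromosome; an
    ineligible site breaks contiguity.  Within a run, for every left
    endpoint the interval is grown site by site while the fully-called
    strains show at most ``max_haplotypes`` distinct strings; each
    interval that shows exactly k strings and cannot be extended in either
    direction without changing that count is emitted as a k-block.
    Intervals whose fully-called strains drop below two are not scanned
    further.
    """
    if not 2 <= max_haplotypes <= 5:
        raise ValueError("max_haplotypes must be in 2..5")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (matrix.n_sites,):
        raise ValueError("mask length must equal the number of sites")
    blocks: list[HaplotypeBlock] = []
    chroms = matrix.sites["chrom"].to_numpy()
    eligible_idx = np.flatnonzero(mask)
    if eligible_idx.size == 0:
        return blocks

    # split eligible indices into runs of consecutive sites on one chromosome
    runs: list[np.ndarray] = []
    run_start = 0
    for t in range(1, eligible_idx.size + 1):
        if (
            t == eligible_idx.size
            or eligible_idx[t] != eligible_idx[t - 1] + 1
            or chroms[eligible_idx[t]] != chroms[eligible_idx[t - 1]]
        ):
            runs.append(eligible_idx[run_start:t])
            run_start = t
    for run in runs:
        blocks.extend(_scan_run(matrix, run, max_haplotypes))
    return blocks


def _distinct_profile(alleles: np.ndarray, run: np.ndarray, start: int,
                      max_k: int) -> list[int]:
    """Distinct-haplotype counts for intervals [start, start+w) of a run.

    Returns counts for w = 1, 2, ... stopping once the count exceeds
    ``max_k`` or fewer than two strains remain fully called.  Counts are
    over strains with no N in the interval.
    """
    n_strains = alleles.shape[0]
    labels = [0] * n_strains
    called = [True] * n_strains
    out: list[int] = []
    for t in range(start, run.size):
        col = alleles[:, run[t]]
        relabel: dict[tuple[int, int], int] = {}
        n_called = 0
        for s in range(n_strains):
            if not called[s]:
                continue
            a = int(col[s])
            if a == N_CODE:
                called[s] = False
                continue
            key = (labels[s], a)
            labels[s] = relabel.setdefault(key, len(relabel))
            n_called += 1
        if n_called < 2:
            break
        distinct = len(relabel)
        out.append(distinct)
        if distinct > max_k:
            break
    return out


def _scan_run(matrix: StrainGenotypeMatrix, run: np.ndarray,
              max_k: int) -> list[HaplotypeBlock]:
    alleles = matrix.alleles
    chrom = str(matrix.sites["chrom"].iloc[run[0]])
    blocks: list[HaplotypeBlock] = []
    prev_profile: list[int] = []
    for start in range(run.size):
        profile = _distinct_profile(alleles, run, start, max_k)
        for w, distinct in enumerate(profile, start=1):
            if distinct > max_k or distinct < 2:
                continue
            right_max = w == len(profile) or profile[w] != distinct
            # left extension covers [start-1, start-1+w+1): width w+1 in prev
            if start == 0:
                left_max = True
            elif len(prev_profile) >= w + 1:
                left_max = prev_profile[w] != distinct
            else:
                left_max = True  # previous scan stopped before reaching here
            if right_max and left_max:
                blocks.append(
                    _make_block(matrix, chrom, int(run[start]),
                                int(run[start + w - 1]) + 1, distinct)
                )
        prev_profile = profile
    return blocks


def _make_block(matrix: StrainGenotypeMatrix, chrom: str, start: int,
                end: int, k: int) -> HaplotypeBlock:
    window = matrix.alleles[:, start:end]
    fully = ~(window == N_CODE).any(axis=1)
    haplotypes: list[tuple[int, ...]] = []
    hap_index: dict[tuple[int, ...], int] = {}
    assignment: dict[str, int] = {}
    for i, strain in enumerate(matrix.strains):
        if not fully[i]:
            continue
        hap = tuple(int(a) for a in window[i])
        g = hap_index.setdefault(hap, len(haplotypes))
        if g == len(haplotypes):
            haplotypes.append(hap)
        assignment[strain] = g
    for i, strain in enumerate(matrix.strains):
        if fully[i]:
            continue
        assignment[strain] = _assign_partial(window[i], haplotypes)
    assert len(haplotypes) == k
    return HaplotypeBlock(chrom, start, end, k, assignment, tuple(haplotypes))


def blocks_to_frame(blocks: Sequence[HaplotypeBlock],
                    matrix: StrainGenotypeMatrix) -> pd.DataFrame:
    """Tabular view of blocks (one row per block, strain labels as columns)."""
    pos = matrix.sites["pos"].to_numpy()
    rows = []
    for b in blocks:
        row = {
            "chrom": b.chrom,
            "start_pos": int(pos[b.start]),
            "end_pos": int(pos[b.end - 1]),
            "start_idx": b.start,
            "end_idx": b.end,
            "k": b.k,
        }
        for strain in matrix.strains:
            g = b.assignment.get(strain, EXCLUDED)
            row[strain] = "X" if g == EXCLUDED else str(g)
        rows.append(row)
    return pd.DataFrame(rows)
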