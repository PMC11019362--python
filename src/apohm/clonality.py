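"""Variant copy number, clonality, and cancer cell fraction (CCF).

The variant copy number of an SNV corrects the variant allele frequency f_m
for tumor purity p and local copy number:

    n_snv = (f_m / p) * [p * C_t + (1 - p) * C_h]

where C_t is the tumor copy number at the variant and C_h the healthy copy
number (2 for autosomes, 1 for allosomes).  A mutation is clonal when
n_snv > 0.75.  The CCF divides n_snv by the maximum-likelihood number of
allelic copies n_chr carrying the variant, chosen by comparing the binomial
likelihood of the observed read counts at the expected VAF of each candidate
n_chr in 1..round(C_t); the CCF is capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

CLONAL_THRESHOLD = 0.75


@dataclass(frozen=True)
class ClonalityResult:
    n_snv: float
    n_chr: int
    ccf: float
    clonal: bool


def variant_copy_number(
    f_m: float, purity: float, tumor_cn: float, normal_cn: float = 2.0
) -> float:
    """Variant copy number n_snv; clonal iff the result exceeds 0.75."""
    if not 0 <= f_m <= 1:
        raise ValueError(f"f_m must be in [0,1], got {f_m}")
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0,1], got {purity}")
    if tumor_cn <= 0 or normal_cn <= 0:
        raise ValueError("copy numbers must be positive")
    return (f_m / purity) * (purity * tumor_cn + (1 - purity) * normal_cn)


def expected_vaf(n_chr: int, purity: float, tumor_cn: float, normal_cn: float) -> float:
    """Expected VAF when the variant sits on ``n_chr`` tumor allelic copies."""
    return n_chr * purity / (purity * tumor_cn + (1 - purity) * normal_cn)


def cancer_cell_fraction(
    alt_reads: int,
    depth: int,
    purity: float,
    tumor_cn: float,
    normal_cn: float = 2.0,
) -> ClonalityResult:
    """Maximum-likelihood allelic multiplicity and CCF for one SNV.

    Candidate multiplicities run over 1..max(1, round(C_t)); candidates whose
    expected VAF exceeds 1 are infeasible.  Likelihood ties go to the smaller
    n_chr.  CCF = min(1, n_snv / n_chr).
    """
    if depth <= 0 or not 0 <= alt_reads <= depth:
        raise ValueError(f"invalid read counts alt={alt_reads} depth={depth}")
    n_snv = variant_copy_number(alt_reads / depth, purity, tumor_cn, normal_cn)
    n_max = max(1, int(round(tumor_cn)))
    best_n, best_ll = None, -float("inf")
    for n in range(1, n_max + 1):
        vaf = expected_vaf(n, purity, tumor_cn, normal_cn)
        if vaf > 1:
            continue
        ll = stats.binom.logpmf(alt_reads, depth, vaf)
        if best_n is None or ll > best_ll:
            best_n, best_ll = n, ll
    if best_n is None:
        raise ValueError("all candidate multiplicities have expected VAF > 1")
    ccf = min(1.0, n_snv / best_n)
    return ClonalityResult(
        n_snv=n_snv, n_chr=best_n, ccf=ccf, clonal=n_snv > CLONAL_THRESHOLD
    )
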