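"""Per-sample APOBEC enrichment scoring and classification.

The fold enrichment E compares the fraction of C>T/C>G mutations falling in
the TCW motif (W = A or T; mutated C central, pyrimidine-normalized) with the
fraction of TCW motifs among all cytosines in the +/-``flank`` nt sequence
context around those mutations, counted on both strands:

    E = (n_mut_tcw * ctx_c) / (n_mut_c * ctx_tcw)

Significance is a one-sided Fisher exact test on the corresponding 2x2 table,
Benjamini-Hochberg corrected across the samples of a cohort.  Samples are
classified as APOBEC high (E >= 3), medium (2 <= E < 3) or low (1 < E < 2),
all requiring adjusted p < 0.01; otherwise non-APOBEC.  The same ratio with
the tetranucleotide motifs YTCA / RTCA (mutated C third) attributes activity
to APOBEC3A vs APOBEC3B.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Mutation, extract_context, revcomp

TCW_MOTIFS = ("TCA", "TCT")
YTCA_MOTIFS = ("TTCA", "CTCA")
RTCA_MOTIFS = ("ATCA", "GTCA")


class UndefinedEnrichmentError(ValueError):
    """Raised when the enrichment ratio is undefined (no mutations or motifs)."""


@dataclass
class EnrichmentResult:
    sample_id: str
    E: float
    p: float
    adj_p: float
    apobec_class: str
    n_mut_tcw: int
    n_mut_c: int
    ctx_tcw: int
    ctx_c: int
    E_ytca: Optional[float] = None
    E_rtca: Optional[float] = None


def _count_motifs_both_strands(seq: str, motifs: Sequence[str]) -> int:
    """Occurrences of any motif on the given sequence or its reverse complement."""
    rc = revcomp(seq)
    total = 0
    for motif in motifs:
        for s in (seq, rc):
            start = 0
            while True:
                i = s.find(motif, start)
                if i < 0:
                    break
                total += 1
                start = i + 1
    return total


def _count_c_both_strands(seq: str) -> int:
    return seq.count("C") + seq.count("G")


def _mutation_motif_counts(
    mutations: Sequence[Mutation], reference, flank: int, motifs: Sequence[str], motif_len: int
) -> tuple[int, int, int, int]:
    """Counts (n_mut_motif, n_mut_c, ctx_motif, ctx_c) over C>T/C>G mutations."""
    n_mut_motif = n_mut_c = ctx_motif = ctx_c = 0
    for m in mutations:
        ctx = extract_context(reference, m.chrom, m.pos, m.ref, m.alt)
        if ctx.alt not in "TG":  # normalized substitution must be C>T or C>G
            continue
        if ctx.trinucleotide[1] != "C":
            continue
        n_mut_c += 1
        if motif_len == 3:
            hit = ctx.trinucleotide in motifs
        else:
            hit = ctx.tetranucleotide is not None and ctx.tetranucleotide in motifs
        if hit:
            n_mut_motif += 1
        contig_len = len(reference[m.chrom])
        lo = max(1, m.pos - flank)
        hi = min(contig_len, m.pos + flank)
        window = str(reference[m.chrom][lo - 1 : hi]).upper()
        ctx_motif += _count_motifs_both_strands(window, motifs)
        ctx_c += _count_c_both_strands(window)
    return n_mut_motif, n_mut_c, ctx_motif, ctx_c


def _fold_enrichment(n_mut_motif, n_mut_c, ctx_motif, ctx_c) -> tuple[float, float]:
    if n_mut_c == 0 or ctx_motif == 0:
        raise UndefinedEnrichmentError(
            f"enrichment undefined: n_mut_c={n_mut_c}, ctx_motif={ctx_motif}"
        )
    e = (n_mut_motif * ctx_c) / (n_mut_c * ctx_motif)
    table = [
        [n_mut_motif, n_mut_c - n_mut_motif],
        [ctx_motif, ctx_c - ctx_motif],
    ]
    p = stats.fisher_exact(table, alternative="greater").pvalue
    return e, float(p)


def tcw_fold_enrichment(
    sample_mutations: Sequence[Mutation],
    reference,
    flank: int = 20,
    sample_id: str = "",
) -> EnrichmentResult:
    """TCW fold enrichment for one sample (adj_p filled in by the cohort caller)."""
    counts = _mutation_motif_counts(sample_mutations, reference, flank, TCW_MOTIFS, 3)
    e, p = _fold_enrichment(*counts)
    return EnrichmentResult(
        sample_id=sample_id or (sample_mutations[0].sample_id if sample_mutations else ""),
        E=e, p=p, adj_p=float("nan"), apobec_class="none",
        n_mut_tcw=counts[0], n_mut_c=counts[1], ctx_tcw=counts[2], ctx_c=counts[3],
    )


def tetra_enrichment(
    sample_mutations: Sequence[Mutation], reference, flank: int = 20
) -> tuple[float, float]:
    """(E_ytca, E_rtca): tetranucleotide enrichment attributing A3A vs A3B."""
    ny, nc, cy, cc = _mutation_motif_counts(sample_mutations, reference, flank, YTCA_MOTIFS, 4)
    e_ytca, _ = _fold_enrichment(ny, nc, cy, cc)
    nr, nc2, cr, cc2 = _mutation_motif_counts(sample_mutations, reference, flank, RTCA_MOTIFS, 4)
    e_rtca, _ = _fold_enrichment(nr, nc2, cr, cc2)
    return e_ytca, e_rtca


def classify_apobec(E: float, adj_p: float) -> str:
    """Map (E, adjusted p) to the APOBEC class: high / medium / low / none."""
    if not (E >= 0) or not (0 <= adj_p <= 1 or np.isnan(adj_p)):
        raise ValueError(f"invalid inputs E={E}, adj_p={adj_p}")
    if np.isnan(adj_p) or adj_p >= 0.01 or E <= 1:
        return "none"
    if E >= 3:
        return "high"
    if E >= 2:
        return "medium"
    return "low"


def cohort_enrichment(
    cohort: Mapping[str, Sequence[Mutation]],
    reference,
    flank: int = 20,
    with_tetra: bool = False,
) -> pd.DataFrame:
    """Per-sample enrichment with BH-adjusted p values and APOBEC classes."""
    from .drivers import bh_adjust

    results = []
    for sample_id, muts in cohort.items():
        res = tcw_fold_enrichment(muts, reference, flank=flank, sample_id=sample_id)
        if with_tetra:
            res.E_ytca, res.E_rtca = tetra_enrichment(muts, reference, flank=flank)
        results.append(res)
    adj = bh_adjust(np.array([r.p for r in results]))
    rows = []
    for r, a in zip(results, adj):
        r = replace(r, adj_p=float(a))
        r.apobec_class = classify_apobec(r.E, r.adj_p)
        rows.append(r.__dict__)
    return pd.DataFrame(rows)


def hotspot_apobec_association(
    hotspot_present: np.ndarray, E: np.ndarray
) -> tuple[float, float]:
    """Logistic regression of hotspot presence on APOBEC fold enrichment.

    Fits intercept + slope by IRLS and returns (slope, two-sided Wald p).
    Complete separation or a degenerate outcome yields (nan, nan) as a flagged
    non-convergence result; the caller applies BH across hotspots.
    """
    import statsmodels.api as sm

    y = np.asarray(hotspot_present, float)
    x = np.asarray(E, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(x)
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if not fit.mle_retvals.get("converged", True):
            return float("nan"), float("nan")
        return float(fit.params[1]), float(fit.pvalues[1])
    except Exception:
        return float("nan"), float("nan")
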