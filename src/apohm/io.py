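"""Reading somatic SNVs, reference context windows, and ChIP-seq peak files.

The internal data model is deliberately small: a :class:`Mutation` is one
somatic single-nucleotide variant with the read support and local copy number
needed downstream for clonality, and a :class:`MutationContext` is its
pyrimidine-normalized trinucleotide/tetranucleotide frame.  Coordinates are
1-based throughout (VCF convention); narrowPeak intervals are converted from
0-based half-open on ingest.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_BASES = frozenset("ACGT")


class ContextUnavailableError(ValueError):
    """Raised when a mutation sits too close to a contig end for its context."""


class ReferenceMismatchError(ValueError):
    """Raised when the VCF REF allele disagrees with the reference genome."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class Mutation:
    """One somatic SNV with read support and local copy number.

    ``tumor_cn`` is the total copy number of the segment containing the
    variant (C_t); ``normal_cn`` is the healthy copy number C_h, 2 for
    autosomes and 1 for allosomes.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_reads: int = 0
    depth: int = 1
    tumor_cn: Optional[float] = None
    normal_cn: float = 2.0

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt_reads < 0 or self.depth <= 0 or self.alt_reads > self.depth:
            raise ValueError(
                f"invalid read support alt_reads={self.alt_reads} depth={self.depth} "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def vaf(self) -> float:
        """Relative frequency of mutant reads (f_m)."""
        return self.alt_reads / self.depth


@dataclass(frozen=True)
class MutationContext:
    """Pyrimidine-normalized local sequence context of a mutation.

    ``trinucleotide`` is the 3-mer centered on the mutated base after strand
    normalization (center is always C or T).  ``tetranucleotide`` is the 4-mer
    whose third base is the mutated C, i.e. the NNCA-style frame used for
    YTCA/RTCA matching; it is ``None`` when the window is truncated.
    """

    trinucleotide: str
    tetranucleotide: Optional[str]
    is_tpc: bool
    strand_flipped: bool
    alt: str  # pyrimidine-normalized alternate allele

    def __post_init__(self) -> None:
        if self.trinucleotide[1] not in "CT":
            raise ValueError(
                f"normalized center base must be a pyrimidine: {self.trinucleotide}"
            )


@dataclass
class PeakSet:
    """Filtered ENCODE narrowPeak records (1-based inclusive internally)."""

    records: pd.DataFrame  # columns: chrom, start, end, signal_value, neg_log10_q
    n_dropped_q: int = 0
    n_dropped_missing_q: int = 0


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """Fetch reference [start, end] (1-based inclusive) as upper-case string."""
    seq = reference[chrom][start - 1 : end]
    return str(seq).upper()


def extract_context(reference, chrom: str, pos: int, ref: str, alt: str) -> MutationContext:
    """Extract the pyrimidine-normalized tri-/tetranucleotide context.

    When the reference base is a purine (G or A) the window is reverse
    complemented so the mutated base reads as a pyrimidine; ``is_tpc`` is true
    iff the base 5' of the normalized mutated C is T.

    Parameters
    ----------
    reference : pyfaidx.Fasta or mapping of str to sequence
    pos : int
        1-based position of the mutated base.
    """
    ref, alt = ref.upper(), alt.upper()
    contig_len = len(reference[chrom])
    if pos < 2 or pos > contig_len - 1:
        raise ContextUnavailableError(
            f"{chrom}:{pos} within 1 base of contig end (len {contig_len})"
        )
    base = _fetch(reference, chrom, pos, pos)
    if base != ref:
        raise ReferenceMismatchError(
            f"reference base {base} != {ref} at {chrom}:{pos}"
        )
    flipped = ref in "GA"
    tri = _fetch(reference, chrom, pos - 1, pos + 1)
    if flipped:
        tri = revcomp(tri)
        alt = COMPLEMENT[alt]
    # Tetranucleotide: 4-mer ending one base 3' of the normalized mutated base,
    # i.e. positions [pos-2, pos+1] on the normalized strand.
    tetra: Optional[str] = None
    if not flipped and pos >= 3:
        tetra = _fetch(reference, chrom, pos - 2, pos + 1)
    elif flipped and pos + 2 <= contig_len:
        tetra = revcomp(_fetch(reference, chrom, pos - 1, pos + 2))
    return MutationContext(
        trinucleotide=tri,
        tetranucleotide=tetra,
        is_tpc=tri[0] == "T" and tri[1] == "C",
        strand_flipped=flipped,
        alt=alt,
    )


class CopyNumberTable:
    """Interval lookup of per-segment tumor copy number.

    Built from a TSV with columns ``chrom, start, end, cn`` (1-based inclusive
    coordinates).  Mutations outside any segment fall back to ``ploidy`` when
    given, else lookup returns ``None``.
    """

    def __init__(self, segments: pd.DataFrame, ploidy: Optional[float] = None):
        self.ploidy = ploidy
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in segments.groupby("chrom"):
            sub = sub.sort_values("start")
            self._by_chrom[str(chrom)] = (
                sub["start"].to_numpy(int),
                sub["end"].to_numpy(int),
                sub["cn"].to_numpy(float),
            )

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, ploidy: Optional[float] = None) -> "CopyNumberTable":
        return cls(pd.read_csv(path, sep="\t"), ploidy=ploidy)

    def lookup(self, chrom: str, pos: int) -> Optional[float]:
        entry = self._by_chrom.get(chrom)
        if entry is not None:
            starts, ends, cns = entry
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and pos <= ends[i]:
                return float(cns[i])
        return self.ploidy


def read_somatic_vcf(
    path: str | os.PathLike,
    sample_id: str,
    cn_table: Optional[CopyNumberTable] = None,
    ad_field: str = "AD",
    dp_field: str = "DP",
    contigs: Optional[Iterable[str]] = None,
    normal_cn_map: Optional[Mapping[str, float]] = None,
) -> list[Mutation]:
    """Read biallelic somatic SNVs from a VCF 4.x file.

    Non-SNV and multi-allelic records are skipped (counted in the log); records
    on contigs absent from ``contigs`` (e.g. the reference index) are dropped
    with a logged count.  ``alt_reads``/``depth`` come from the FORMAT fields
    named by ``ad_field``/``dp_field`` (AD is alt-last per VCF convention);
    records lacking them get ``alt_reads=0, depth=1`` so that context-only
    analyses still work, but clonality operations will reject them upstream.
    ``normal_cn_map`` maps contig name to healthy copy number (default 2; use 1
    for allosomes).
    """
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    contig_set = set(contigs) if contigs is not None else None
    muts: list[Mutation] = []
    n_skipped = n_off_contig = 0
    vcf = VCF(str(path))
    sample_idx = vcf.samples.index(sample_id) if sample_id in vcf.samples else 0
    has_samples = len(vcf.samples) > 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        if rec.REF not in _BASES or rec.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        if contig_set is not None and rec.CHROM not in contig_set:
            n_off_contig += 1
            continue
        alt_reads, depth = 0, 1
        if has_samples:
            try:
                ad = rec.format(ad_field)
                if ad is not None:
                    alt_reads = int(ad[sample_idx][-1])
            except (KeyError, TypeError):
                pass
            try:
                dp = rec.format(dp_field)
                if dp is not None:
                    depth = int(np.atleast_1d(dp[sample_idx])[0])
                elif alt_reads:
                    depth = int(ad[sample_idx].sum())
            except (KeyError, TypeError):
                depth = max(depth, alt_reads)
        depth = max(depth, alt_reads, 1)
        tumor_cn = cn_table.lookup(rec.CHROM, rec.POS) if cn_table is not None else None
        normal_cn = 2.0
        if normal_cn_map is not None:
            normal_cn = float(normal_cn_map.get(rec.CHROM, 2.0))
        muts.append(
            Mutation(
                sample_id=sample_id,
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                alt_reads=alt_reads,
                depth=depth,
                tumor_cn=tumor_cn,
                normal_cn=normal_cn,
            )
        )
    if n_skipped:
        logger.info("%s: skipped %d non-SNV/multiallelic records", path, n_skipped)
    if n_off_contig:
        logger.info("%s: dropped %d records on unknown contigs", path, n_off_contig)
    return muts


MUTATION_TSV_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt",
    "alt_reads", "depth", "tumor_cn", "normal_cn",
]


def write_mutation_tsv(mutations: Sequence[Mutation], path: str | os.PathLike) -> None:
    """Write mutations in the internal TSV dialect (documented header)."""
    df = pd.DataFrame(
        [
            (m.sample_id, m.chrom, m.pos, m.ref, m.alt, m.alt_reads, m.depth,
             "" if m.tumor_cn is None else repr(m.tumor_cn), repr(m.normal_cn))
            for m in mutations
        ],
        columns=MUTATION_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_mutation_tsv(path: str | os.PathLike) -> list[Mutation]:
    """Read the internal mutation TSV dialect written by :func:`write_mutation_tsv`."""
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "chrom": str, "tumor_cn": object}
    )
    out = []
    for row in df.itertuples(index=False):
        cn = row.tumor_cn
        tumor_cn = None if (cn is None or (isinstance(cn, float) and np.isnan(cn)) or cn == "") else float(cn)
        out.append(
            Mutation(
                sample_id=str(row.sample_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                alt_reads=int(row.alt_reads),
                depth=int(row.depth),
                tumor_cn=tumor_cn,
                normal_cn=float(row.normal_cn),
            )
        )
    return out


def read_narrowpeak(path: str | os.PathLike, q_threshold: float = 0.05) -> PeakSet:
    """Read an ENCODE narrowPeak (BED6+4) file, keeping peaks with q < threshold.

    Column 9 holds -log10(q); records with the -1 "unavailable" flag are
    dropped and counted separately.  Coordinates are converted to 1-based
    inclusive on ingest.
    """
    names = [
        "chrom", "start", "end", "name", "score", "strand",
        "signal_value", "neg_log10_p", "neg_log10_q", "peak",
    ]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 10:
                raise ValueError(
                    f"{path}:{lineno}: expected 10 narrowPeak columns, got {len(parts)}"
                )
            rows.append(parts)
    df = pd.DataFrame(rows, columns=names)
    for col in ("start", "end"):
        df[col] = df[col].astype(int)
    for col in ("signal_value", "neg_log10_q"):
        df[col] = df[col].astype(float)
    missing = df["neg_log10_q"] < 0
    n_missing = int(missing.sum())
    df = df[~missing]
    cutoff = -np.log10(q_threshold)
    kept = df["neg_log10_q"] > cutoff
    n_dropped = int((~kept).sum())
    df = df[kept].copy()
    df["start"] = df["start"] + 1  # to 1-based inclusive
    out = df[["chrom", "start", "end", "signal_value", "neg_log10_q"]].reset_index(drop=True)
    return PeakSet(records=out, n_dropped_q=n_dropped, n_dropped_missing_q=n_missing)
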