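"""Genome-wide 1-Mbp tracks: accessibility, expression, and mutational load.

A track is a tiling of each contig into fixed-size bins (the last bin of a
contig may be short) with one value per bin.  DNA accessibility is the sum of
four per-chromosome z-scored histone-mark signals (H3K4me1, H3K4me3, H3K36me3,
H3K27ac); open chromatin is defined as bins strictly above the genome-wide
median, and bins are additionally ranked into genome-wide deciles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import Mutation, PeakSet

DEFAULT_BIN_SIZE = 1_000_000


@dataclass
class BinTrack:
    """Per-bin values on a fixed binning of the genome.

    ``df`` columns: chrom, bin_index (per-chromosome, 0-based), start, end
    (1-based inclusive), value.
    """

    df: pd.DataFrame
    bin_size: int = DEFAULT_BIN_SIZE

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "value"].to_numpy(float)


@dataclass
class AccessibilityTrack:
    """Combined accessibility with high/low label and genome-wide decile."""

    df: pd.DataFrame  # columns: chrom, bin_index, start, end, value, label, decile
    bin_size: int = DEFAULT_BIN_SIZE

    def decile_at(self, chrom: str, pos: int) -> int:
        """Decile of the bin containing a 1-based genomic position."""
        sub = self.df[self.df["chrom"] == chrom]
        idx = (pos - 1) // self.bin_size
        row = sub[sub["bin_index"] == idx]
        if row.empty:
            raise KeyError(f"no bin for {chrom}:{pos}")
        return int(row["decile"].iloc[0])


def make_bins(chrom_sizes: Mapping[str, int], bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Tile contigs into bins of ``bin_size`` bp (last bin may be short)."""
    rows = []
    for chrom, size in chrom_sizes.items():
        n = max(1, int(np.ceil(size / bin_size)))
        for i in range(n):
            rows.append((chrom, i, i * bin_size + 1, min((i + 1) * bin_size, size)))
    return pd.DataFrame(rows, columns=["chrom", "bin_index", "start", "end"])


def moving_average(values: np.ndarray, k: int = 3) -> np.ndarray:
    """Centered moving average with windows truncated at the ends.

    ``k`` must be odd; ``k=1`` is the identity.
    """
    if k % 2 == 0 or k < 1:
        raise ValueError(f"k must be a positive odd integer, got {k}")
    if k == 1:
        return np.asarray(values, float).copy()
    values = np.asarray(values, float)
    half = k // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = len(values)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def bin_and_smooth(
    signal: PeakSet | pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    k: int = 3,
) -> BinTrack:
    """Aggregate a peak set (or precomputed per-bin counts) into a smoothed track.

    Peak signalValue mass is apportioned to bins by overlap length, then a
    centered moving average of window ``k`` (odd) is applied per chromosome.
    ``signal`` may alternatively be a DataFrame with columns
    ``chrom, bin_index, value`` (e.g. an expression read-count table), in which
    case values are placed directly on the binning before smoothing.
    """
    bins = make_bins(chrom_sizes, bin_size)
    values = np.zeros(len(bins))
    offsets = {}
    start = 0
    nbins_by_chrom = {}
    for chrom, sub in bins.groupby("chrom", sort=False):
        offsets[chrom] = start
        nbins_by_chrom[chrom] = len(sub)
        start += len(sub)

    if isinstance(signal, PeakSet):
        recs = signal.records
        for chrom, pstart, pend, sval in zip(
            recs["chrom"], recs["start"], recs["end"], recs["signal_value"]
        ):
            if chrom not in offsets:
                continue
            plen = pend - pstart + 1
            first = (pstart - 1) // bin_size
            last = (pend - 1) // bin_size
            for b in range(first, min(last, nbins_by_chrom[chrom] - 1) + 1):
                b_lo, b_hi = b * bin_size + 1, (b + 1) * bin_size
                overlap = min(pend, b_hi) - max(pstart, b_lo) + 1
                values[offsets[chrom] + b] += sval * overlap / plen
    else:
        for chrom, bidx, val in zip(signal["chrom"], signal["bin_index"], signal["value"]):
            if chrom in offsets and 0 <= bidx < nbins_by_chrom[chrom]:
                values[offsets[chrom] + int(bidx)] += float(val)

    bins = bins.copy()
    bins["value"] = values
    out = []
    for _, sub in bins.groupby("chrom", sort=False):
        sub = sub.copy()
        sub["value"] = moving_average(sub["value"].to_numpy(), k)
        out.append(sub)
    return BinTrack(df=pd.concat(out, ignore_index=True), bin_size=bin_size)


def normalize_chromosome(track: BinTrack) -> BinTrack:
    """Z-score values per chromosome (population sd; constant chromosomes -> 0)."""
    out = []
    for _, sub in track.df.groupby("chrom", sort=False):
        sub = sub.copy()
        v = sub["value"].to_numpy(float)
        sd = v.std()
        sub["value"] = np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd
        out.append(sub)
    return BinTrack(df=pd.concat(out, ignore_index=True), bin_size=track.bin_size)


def assign_deciles(values: np.ndarray) -> np.ndarray:
    """Genome-wide decile (1-10) per value; ties at a boundary go to the lower decile."""
    values = np.asarray(values, float)
    boundaries = np.percentile(values, np.arange(10, 100, 10))
    return np.searchsorted(boundaries, values, side="left") + 1


def build_accessibility(marks: Sequence[BinTrack]) -> AccessibilityTrack:
    """Sum four normalized ChIP-seq tracks into an accessibility track.

    The combined value per bin is the sum of the (per-chromosome z-scored)
    mark signals; ``label`` is ``high`` iff the value is strictly above the
    genome-wide median, and ``decile`` is the genome-wide 10-percentile rank.
    """
    if len(marks) == 0:
        raise ValueError("need at least one mark track")
    base = marks[0].df[["chrom", "bin_index", "start", "end"]].reset_index(drop=True)
    total = np.zeros(len(base))
    for mark in marks:
        if len(mark.df) != len(base) or not (
            mark.df["chrom"].reset_index(drop=True).equals(base["chrom"])
            and mark.df["bin_index"].reset_index(drop=True).equals(base["bin_index"])
        ):
            raise ValueError("mark tracks are not on an identical binning")
        total += mark.df["value"].to_numpy(float)
    df = base.copy()
    df["value"] = total
    median = np.median(total)
    df["label"] = np.where(total > median, "high", "low")
    df["decile"] = assign_deciles(total)
    return AccessibilityTrack(df=df, bin_size=marks[0].bin_size)


def mutational_load(
    cohort: Mapping[str, Sequence[Mutation]],
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    k: int = 3,
    stratify: str = "all",
    contexts: Optional[Mapping[tuple, object]] = None,
) -> BinTrack:
    """Mean SNVs per bin across a cohort, smoothed with a moving average.

    ``stratify`` is one of ``all``, ``TpC`` or ``non-TpC``; the latter two
    require ``contexts``, a mapping from ``(chrom, pos)`` to an object with an
    ``is_tpc`` attribute (e.g. :class:`~apohm.io.MutationContext`).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if stratify not in ("all", "TpC", "non-TpC"):
        raise ValueError(f"unknown stratum {stratify!r}")
    if stratify != "all" and contexts is None:
        raise ValueError("contexts required for TpC stratification")
    bins = make_bins(chrom_sizes, bin_size)
    key = {(c, i): j for j, (c, i) in enumerate(zip(bins["chrom"], bins["bin_index"]))}
    counts = np.zeros(len(bins))
    for muts in cohort.values():
        for m in muts:
            if stratify != "all":
                ctx = contexts.get((m.chrom, m.pos))
                if ctx is None:
                    continue
                if (stratify == "TpC") != bool(ctx.is_tpc):
                    continue
            j = key.get((m.chrom, (m.pos - 1) // bin_size))
            if j is not None:
                counts[j] += 1
    counts /= len(cohort)
    bins = bins.copy()
    bins["value"] = counts
    out = []
    for _, sub in bins.groupby("chrom", sort=False):
        sub = sub.copy()
        sub["value"] = moving_average(sub["value"].to_numpy(), k)
        out.append(sub)
    return BinTrack(df=pd.concat(out, ignore_index=True), bin_size=bin_size)


def read_bin_counts_tsv(path) -> pd.DataFrame:
    """Read a precomputed per-bin read-count table (chrom, bin_index, value)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "bin_index", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"bin-count table must have columns {sorted(required)}")
    return df


def expression_track(
    counts: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    k: int = 3,
) -> pd.DataFrame:
    """Per-bin expression with a high/low label (above genome-wide median).

    Counts are smoothed (k-bin moving average), z-scored per chromosome, and
    labeled high when above the genome-wide median of the normalized values.
    """
    track = normalize_chromosome(bin_and_smooth(counts, chrom_sizes, bin_size, k))
    df = track.df.copy()
    median = np.median(df["value"])
    df["label"] = np.where(df["value"] > median, "high", "low")
    return df
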