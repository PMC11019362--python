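"""Cohort hotspot catalog, twin mutations, and didymi classification.

A hotspot is a genomic position carrying somatic mutations in two or more
tumors of a cohort, pooling all substitution alleles; serial biopsies of one
patient count once.  Each hotspot is annotated with its pyrimidine-normalized
trinucleotide context, 5'-neighbor context group (TpC/ApC/CpC/GpC), best
hairpin (a site is *in loop* when its best hairpin is thermodynamically
stable, delta-G < 0), accessibility decile, and the didymi loop-motif flag.

Twin mutations are two hotspots falling inside the loop of a shared hairpin;
didymi are twins where both dominant substitutions are C>T, the twins are
separated by one or two A/T bases, and at least one twin sits in TpC context.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import pandas as pd

from .hairpin import HairpinStructure, find_best_hairpin, loop_pattern_flag
from .io import COMPLEMENT, Mutation, extract_context
from .tracks import AccessibilityTrack

logger = logging.getLogger(__name__)

STABILITY_THRESHOLD = 0.0  # kcal/mol; best hairpin must be below this to count as in-loop

CATALOG_COLUMNS = [
    "chrom", "pos", "n_mut", "trinucleotide", "context_group", "dominant_alt",
    "in_loop", "delta_g", "loop_pattern", "accessibility_decile",
]


@dataclass
class TwinPair:
    chrom: str
    pos_a: int
    pos_b: int
    separation: int  # bases strictly between the two sites
    separator_seq: str
    loop_gstart: int
    loop_gend: int
    is_didymi: bool = False


def _context_group(trinucleotide: str) -> str:
    if trinucleotide[1] != "C":
        return "other"
    five = trinucleotide[0]
    return {"T": "TpC", "A": "ApC", "C": "CpC", "G": "GpC"}.get(five, "other")


def _dominant_alt(alts: Counter) -> str:
    """Most frequent pyrimidine-normalized alt; ties involving T resolve to T."""
    top = max(alts.values())
    leaders = sorted(a for a, c in alts.items() if c == top)
    return "T" if "T" in leaders else leaders[0]


def build_catalog(
    mutations: Sequence[Mutation],
    reference,
    accessibility: Optional[AccessibilityTrack] = None,
    hairpins: Optional[Mapping[tuple[str, int], Optional[HairpinStructure]]] = None,
    min_recurrence: int = 2,
    stability_threshold: float = STABILITY_THRESHOLD,
    hairpin_flank: int = 50,
) -> tuple[pd.DataFrame, dict[tuple[str, int], HairpinStructure]]:
    """Build the hotspot catalog for a cohort.

    Returns ``(catalog, hairpins)`` where ``catalog`` is a DataFrame with one
    row per position mutated in >= ``min_recurrence`` tumors and ``hairpins``
    maps ``(chrom, pos)`` to the best hairpin at retained sites that have one.
    If ``hairpins`` is passed in, it is used instead of recomputing.
    """
    seen: set[tuple[str, str, int]] = set()
    per_site: dict[tuple[str, int], list[Mutation]] = defaultdict(list)
    n_dup = 0
    for m in mutations:
        key = (m.sample_id, m.chrom, m.pos)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        per_site[(m.chrom, m.pos)].append(m)
    if n_dup:
        logger.warning("de-duplicated %d repeated (sample, position) records", n_dup)

    hp_out: dict[tuple[str, int], HairpinStructure] = {}
    rows = []
    for (chrom, pos), muts in sorted(per_site.items()):
        n_mut = len(muts)
        if n_mut < min_recurrence:
            continue
        ctx = extract_context(reference, chrom, pos, muts[0].ref, muts[0].alt)
        alts = Counter()
        for m in muts:
            alt = m.alt if not ctx.strand_flipped else COMPLEMENT[m.alt]
            alts[alt] += 1
        if hairpins is not None:
            hp = hairpins.get((chrom, pos))
        else:
            hp = find_best_hairpin(reference, chrom, pos, flank=hairpin_flank)
        in_loop = hp is not None and hp.delta_g < stability_threshold
        if hp is not None:
            hp_out[(chrom, pos)] = hp
        pattern = bool(
            in_loop and loop_pattern_flag(hp.loop_seq, {hp.mut_loop_index})
        )
        decile = (
            accessibility.decile_at(chrom, pos) if accessibility is not None else 0
        )
        rows.append(
            (
                chrom, pos, n_mut, ctx.trinucleotide, _context_group(ctx.trinucleotide),
                _dominant_alt(alts), in_loop,
                hp.delta_g if hp is not None else float("nan"),
                pattern, decile,
            )
        )
    catalog = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    return catalog, hp_out


def find_twins(
    catalog: pd.DataFrame,
    hairpins: Mapping[tuple[str, int], HairpinStructure],
    reference=None,
    stability_threshold: float = STABILITY_THRESHOLD,
) -> list[TwinPair]:
    """Pairs of hotspots inside the loop of a shared stable hairpin.

    A pair is accepted when either site's best hairpin contains both positions
    in its loop (the two centered windows can disagree; either is evidence of
    a shared loop).  All unordered combinations within a loop are returned.
    """
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for chrom, pos in zip(catalog["chrom"], catalog["pos"]):
        by_chrom[str(chrom)].append(int(pos))
    pairs: dict[tuple[str, int, int], TwinPair] = {}
    for chrom, positions in by_chrom.items():
        positions = sorted(set(positions))
        for pos in positions:
            hp = hairpins.get((chrom, pos))
            if hp is None or hp.delta_g >= stability_threshold:
                continue
            if hp.loop_gstart is None:
                continue
            inside = [
                q for q in positions if hp.loop_gstart <= q <= hp.loop_gend
            ]
            for a, b in combinations(inside, 2):
                key = (chrom, a, b)
                if key in pairs:
                    continue
                sep = b - a - 1
                sep_seq = ""
                if reference is not None and sep > 0:
                    sep_seq = str(reference[chrom][a : b - 1]).upper()
                pairs[key] = TwinPair(
                    chrom=chrom, pos_a=a, pos_b=b, separation=sep,
                    separator_seq=sep_seq,
                    loop_gstart=hp.loop_gstart, loop_gend=hp.loop_gend,
                )
    return sorted(pairs.values(), key=lambda t: (t.chrom, t.pos_a, t.pos_b))


def classify_didymi(pair: TwinPair, catalog: pd.DataFrame) -> bool:
    """Didymi: twin C>T hotspots separated by 1-2 A/T bases, >= one in TpC.

    Condition (a): both sites' dominant pyrimidine-normalized substitution is
    C>T (center base C, dominant alt T).  Condition (b): separation is 1 or 2
    and every separator base is A or T.  Condition (c): at least one site is
    in TpC context.
    """
    rows = {}
    for pos in (pair.pos_a, pair.pos_b):
        sub = catalog[(catalog["chrom"] == pair.chrom) & (catalog["pos"] == pos)]
        if sub.empty:
            return False
        rows[pos] = sub.iloc[0]
    for row in rows.values():
        if row["trinucleotide"][1] != "C" or row["dominant_alt"] != "T":
            return False
    if pair.separation not in (1, 2):
        return False
    if pair.separator_seq and any(b not in "AT" for b in pair.separator_seq):
        return False
    if not any(rows[p]["context_group"] == "TpC" for p in rows):
        return False
    return True


def annotate_didymi(
    pairs: Sequence[TwinPair], catalog: pd.DataFrame
) -> list[TwinPair]:
    """Set ``is_didymi`` on each twin pair; returns the same list."""
    for pair in pairs:
        pair.is_didymi = classify_didymi(pair, catalog)
    return list(pairs)


def twins_to_frame(pairs: Sequence[TwinPair]) -> pd.DataFrame:
    """Twin/didymi table mirroring the catalog export (one row per pair)."""
    return pd.DataFrame(
        [
            (p.chrom, p.pos_a, p.pos_b, p.separation, p.separator_seq,
             p.loop_gstart, p.loop_gend, p.is_didymi)
            for p in pairs
        ],
        columns=[
            "chrom", "pos_a", "pos_b", "separation", "separator_seq",
            "loop_gstart", "loop_gend", "is_didymi",
        ],
    )
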