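"""DNA hairpin-loop detection and nearest-neighbor Gibbs free energy.

APOBEC3A prefers cytosines exposed in the single-stranded loop of DNA
stem-loop (hairpin) structures.  For a mutated genomic site this module
enumerates every stem-loop configuration within a window centered on the site
whose loop contains the site, with

* loop size 3-10 nt (the closing base pair is not part of the loop),
* a stem of at least 2 contiguous Watson-Crick pairs growing outward from the
  closing pair, and
* at most one defect - a single internal non-WC ("mismatched") pair or a
  single-nucleotide bulge - never at the closing pair and never as the
  outermost pair,

scores each configuration with a nearest-neighbor stability model (stack
terms over adjacent stem pairs, a loop-size initiation penalty, sequence
increments for tri-/tetraloops, and defect increments from the shipped
parameter table) and returns the most stable (minimum delta-G) structure.
Ties are broken toward the longer stem, then the smaller loop, then the
smallest loop start, so the result is unique.

When the reference base at the site is a purine the window is reverse
complemented first, so the mutated base always reads as a pyrimidine.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

from .io import revcomp

logger = logging.getLogger(__name__)

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_R = 1.987e-3  # kcal / (mol K)
_T37 = 310.15

MIN_LOOP = 3
MAX_LOOP = 10
MIN_STEM = 2


def _is_wc(a: str, b: str) -> bool:
    return (a, b) in _WC


class ThermoParams:
    """Nearest-neighbor parameter table loaded from a versioned TSV.

    The TSV carries stack frames (5'-XY-3'/3'-ZW-5'), hairpin-loop initiation
    penalties by loop size, tri-/tetraloop sequence increments keyed by
    closing-base + loop + closing-base, and generic mismatch/bulge increments.
    Loop sizes absent from the table are extrapolated logarithmically
    (Jacobson-Stockmayer) from the nearest tabulated size.
    """

    def __init__(self, path=None):
        if path is None:
            path = resources.files("apohm.data") / "nn_thermo.tsv"
        stacks: dict[str, float] = {}
        self.loop_table: dict[int, float] = {}
        self.special_loops: dict[str, float] = {}
        self.mismatch_penalty = 1.0
        self.bulge_penalty = 4.0
        with open(str(path)) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                category, key, value = line.split("\t")
                dg = float(value)
                if category == "stack":
                    stacks[key] = dg
                elif category == "hairpin_loop":
                    self.loop_table[int(key)] = dg
                elif category in ("triloop", "tetraloop"):
                    self.special_loops[key.upper()] = dg
                elif category == "mismatch":
                    self.mismatch_penalty = dg
                elif category == "bulge":
                    self.bulge_penalty = dg
                else:
                    raise ValueError(f"unknown parameter category {category!r}")
        # expand to all 16 WC stack frames via duplex rotational symmetry:
        # 5'-XY-3'/3'-ZW-5' == 5'-WZ-3'/3'-YX-5'
        self.stacks = {}
        for key, dg in stacks.items():
            top, bottom = key.split("/")
            self.stacks[key] = dg
            self.stacks[f"{bottom[::-1]}/{top[::-1]}"] = dg

    def stack_dg(self, outer: tuple[str, str], inner: tuple[str, str]) -> float:
        """Stack term for the outer pair over the inner pair (toward the loop)."""
        key = f"{outer[0]}{inner[0]}/{outer[1]}{inner[1]}"
        try:
            return self.stacks[key]
        except KeyError:
            raise KeyError(f"no stack parameters for frame {key}") from None

    def loop_dg(self, size: int, closing_frame: str = "") -> float:
        """Loop initiation penalty plus any sequence-specific increment."""
        if size in self.loop_table:
            dg = self.loop_table[size]
        else:
            ref = min(self.loop_table, key=lambda s: abs(s - size))
            dg = self.loop_table[ref] + 1.75 * _R * _T37 * math.log(size / ref)
        if size <= 4 and closing_frame:
            dg += self.special_loops.get(closing_frame.upper(), 0.0)
        return dg


_DEFAULT_PARAMS: Optional[ThermoParams] = None


def default_params() -> ThermoParams:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = ThermoParams()
    return _DEFAULT_PARAMS


@dataclass(frozen=True)
class HairpinStructure:
    """Best stem-loop at a site; indices refer to ``window``.

    ``events`` lists the stem from the closing pair outward; each element is
    ``("pair", i, j)``, ``("mismatch", i, j)``, or ``("bulge", side, k)`` with
    ``side`` in {"left", "right"} and ``k`` the bulged window index.
    ``stem_len`` counts matched pairs only.  Lower ``delta_g`` = more stable.
    """

    window: str
    loop_start: int
    loop_end: int  # half-open
    stem_len: int
    events: tuple
    defect: Optional[tuple]
    delta_g: float
    mut_loop_index: int
    strand_flipped: bool = False
    loop_gstart: Optional[int] = None  # genomic 1-based inclusive
    loop_gend: Optional[int] = None

    @property
    def loop_seq(self) -> str:
        return self.window[self.loop_start : self.loop_end]

    @property
    def loop_size(self) -> int:
        return self.loop_end - self.loop_start


def hairpin_delta_g(structure: HairpinStructure, params: Optional[ThermoParams] = None) -> float:
    """Gibbs free energy (kcal/mol) of a hairpin structure.

    Sums nearest-neighbor stack terms over adjacent matched stem pairs, the
    loop-size initiation penalty (plus tri/tetraloop sequence increments for
    loops of size <= 4), and defect increments.  Stacks flanking a mismatched
    pair are not counted; the stack across a single-nucleotide bulge is.
    """
    params = params or default_params()
    return _score_events(
        structure.window, structure.loop_start, structure.loop_end,
        structure.events, params,
    )


def _score_events(w: str, ls: int, le: int, events: Sequence[tuple], params: ThermoParams) -> float:
    closing_frame = w[ls - 1] + w[ls:le] + w[le]
    for b in closing_frame:
        if b not in "ACGT":
            raise ValueError(f"non-ACGT base in hairpin window: {closing_frame}")
    dg = params.loop_dg(le - ls, closing_frame)
    prev_pair: Optional[tuple[str, str]] = None  # last matched pair (inner side)
    gap = 0  # 0 = adjacent, "bulge" = 1-nt bulge between, None = mismatch break
    pending_bulge = False
    broken = False
    for ev in events:
        kind = ev[0]
        if kind == "pair":
            _, i, j = ev
            pair = (w[i], w[j])
            if not _is_wc(*pair):
                raise ValueError(f"event claims pair but {pair} is not Watson-Crick")
            if prev_pair is not None and not broken:
                dg += params.stack_dg(pair, prev_pair)
            if pending_bulge:
                dg += params.bulge_penalty
                pending_bulge = False
            prev_pair, broken = pair, False
        elif kind == "mismatch":
            dg += params.mismatch_penalty
            prev_pair, broken = None, True
        elif kind == "bulge":
            pending_bulge = True  # stack across the bulge is kept
        else:
            raise ValueError(f"unknown stem event {ev!r}")
    return dg


def _enumerate_structures(
    w: str, center: int, params: ThermoParams,
    min_loop: int = MIN_LOOP, max_loop: int = MAX_LOOP, min_stem: int = MIN_STEM,
) -> Iterable[tuple]:
    """Yield (delta_g, -stem_len, loop_size, loop_start, events) candidates."""
    n = len(w)
    for loop_size in range(min_loop, max_loop + 1):
        for ls in range(max(1, center - loop_size + 1), center + 1):
            le = ls + loop_size
            if le > n - 1 or not (ls <= center < le):
                continue
            if not _is_wc(w[ls - 1], w[le]):
                continue
            closing = ("pair", ls - 1, le)
            stack: list[tuple] = [(ls - 2, le + 1, (closing,), False, 1)]
            while stack:
                i, j, events, used, matched = stack.pop()
                # matched extension
                if i >= 0 and j < n and _is_wc(w[i], w[j]):
                    ev2 = events + (("pair", i, j),)
                    m2 = matched + 1
                    if m2 >= min_stem:
                        try:
                            dg = _score_events(w, ls, le, ev2, params)
                        except ValueError:
                            dg = None
                        if dg is not None:
                            yield (dg, -m2, loop_size, ls, ev2)
                    stack.append((i - 1, j + 1, ev2, used, m2))
                if not used:
                    if i >= 0 and j < n and not _is_wc(w[i], w[j]) and w[i] in "ACGT" and w[j] in "ACGT":
                        stack.append((i - 1, j + 1, events + (("mismatch", i, j),), True, matched))
                    if i >= 0:
                        stack.append((i - 1, j, events + (("bulge", "left", i),), True, matched))
                    if j < n:
                        stack.append((i, j + 1, events + (("bulge", "right", j),), True, matched))


def best_hairpin_in_window(
    window: str,
    center: int,
    params: Optional[ThermoParams] = None,
    min_loop: int = MIN_LOOP,
    max_loop: int = MAX_LOOP,
    min_stem: int = MIN_STEM,
) -> Optional[HairpinStructure]:
    """Most stable hairpin whose loop contains ``center`` (or None).

    The returned structure minimizes delta-G; exact ties resolve to the longer
    stem, then the smaller loop, then the smallest loop start, making repeated
    runs deterministic.
    """
    params = params or default_params()
    w = window.upper()
    best = None
    for cand in _enumerate_structures(w, center, params, min_loop, max_loop, min_stem):
        if best is None or cand[:4] < best[:4]:
            best = cand
    if best is None:
        return None
    dg, neg_stem, loop_size, ls, events = best
    defect = next(
        (
            (ev[0], k) if ev[0] == "mismatch" else (ev[0], k, ev[1])
            for k, ev in enumerate(events)
            if ev[0] != "pair"
        ),
        None,
    )
    return HairpinStructure(
        window=w,
        loop_start=ls,
        loop_end=ls + loop_size,
        stem_len=-neg_stem,
        events=events,
        defect=defect,
        delta_g=dg,
        mut_loop_index=center - ls,
    )


def find_best_hairpin(
    reference,
    chrom: str,
    pos: int,
    ref_base: Optional[str] = None,
    flank: int = 50,
    params: Optional[ThermoParams] = None,
    min_loop: int = MIN_LOOP,
    max_loop: int = MAX_LOOP,
) -> Optional[HairpinStructure]:
    """Best hairpin containing a genomic site, pyrimidine-normalized.

    Considers ``flank`` bases (default 50) on each side of the site.  Returns
    None with a warning when the window is truncated by a contig end, and None
    when no valid stem-loop exists.
    """
    contig_len = len(reference[chrom])
    if pos - flank < 1 or pos + flank > contig_len:
        logger.warning("window truncated by contig end at %s:%d; skipping", chrom, pos)
        return None
    window = str(reference[chrom][pos - flank - 1 : pos + flank]).upper()
    base = window[flank]
    if ref_base is not None and base != ref_base.upper():
        raise ValueError(f"reference base {base} != {ref_base} at {chrom}:{pos}")
    flipped = base in "GA"
    if flipped:
        window = revcomp(window)
    hp = best_hairpin_in_window(window, flank, params, min_loop, max_loop)
    if hp is None:
        return None
    if flipped:
        gstart = pos + flank - (hp.loop_end - 1)
        gend = pos + flank - hp.loop_start
    else:
        gstart = pos - flank + hp.loop_start
        gend = pos - flank + hp.loop_end - 1
    return HairpinStructure(
        window=hp.window, loop_start=hp.loop_start, loop_end=hp.loop_end,
        stem_len=hp.stem_len, events=hp.events, defect=hp.defect,
        delta_g=hp.delta_g, mut_loop_index=hp.mut_loop_index,
        strand_flipped=flipped, loop_gstart=gstart, loop_gend=gend,
    )


def loop_pattern_flag(loop_seq: str, mutated_positions: Iterable[int]) -> bool:
    """True iff the loop matches the didymi motif 101 or 1001 at a mutated end.

    Bases map to 1 for G/C and 0 for A/T; the motif requires G/C bases
    separated by one or two A/T bases, with a mutated loop position at one of
    the terminal "1" positions.
    """
    mutated = set(mutated_positions)
    bits = [1 if b in "GC" else 0 for b in loop_seq.upper()]
    n = len(bits)
    for width in (3, 4):  # 101 and 1001
        for s in range(0, n - width + 1):
            e = s + width - 1
            if bits[s] == 1 and bits[e] == 1 and all(b == 0 for b in bits[s + 1 : e]):
                if s in mutated or e in mutated:
                    return True
    return False
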