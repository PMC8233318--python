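"""Structural-variant and sequence-level analyses around an LTR insertion.

An LTR retrotransposon inserts with two identical long terminal repeats
flanking its internal sequence; mismatches accumulated between the copies
date the insertion, and a solo LTR (the product of inter-LTR recombination)
can be assigned to the copy it derives from by mismatch distance.  This
module finds such direct-repeat pairs by self-comparison, counts mismatches
and tandem-repeat copies, predicts the longest open reading frame in six
frames, merges a per-base conservation score track into peaks, and performs
the peak-to-TSS distance arithmetic across haplotypes that differ by the
insertion.

All intervals are 0-based half-open; reported kb and percent values round
half-up, matching how such figures are conventionally printed.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ConfigError

logger = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class RepeatPair:
    """A pair of same-strand direct repeats (e.g. the two LTRs of an element)."""

    left: tuple[int, int]   # 0-based half-open
    right: tuple[int, int]
    length: int
    mismatches: int
    identity_pct: float
    internal_length: int    # bp between the copies


@dataclass
class HaplotypeCoordModel:
    """Offsets along a haplotype from a regulatory peak to a gene TSS, with an
    optional insertion in between."""

    gap_peak_to_insertion: int
    insertion_present: bool
    insertion_length: int
    gap_insertion_to_tss: int

    def __post_init__(self) -> None:
        for name in ("gap_peak_to_insertion", "gap_insertion_to_tss", "insertion_length"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass
class ScoreTrack:
    """Per-base score track (e.g. conservation probabilities) with sorted
    positions and scores in [0, 1]."""

    positions: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.positions.shape != self.scores.shape:
            raise ConfigError("positions and scores must have equal length")
        if np.any(np.diff(self.positions) < 0):
            raise ConfigError("positions must be sorted")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ConfigError("scores must lie in [0, 1]")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def hamming_divergence(a: str, b: str) -> tuple[int, float]:
    """Mismatch count and percent divergence of two equal-length sequences
    (case-insensitive).  Unequal lengths require alignment first."""
    if len(a) != len(b):
        raise ConfigError(
            f"sequences differ in length ({len(a)} vs {len(b)}); align first "
            "(see align_and_count)")
    a, b = a.upper(), b.upper()
    mism = sum(x != y for x, y in zip(a, b))
    pct = 100.0 * mism / len(a) if a else 0.0
    return mism, pct


def percent_label(pct: float) -> str:
    """Half-up integer-percent label, e.g. 0.851 -> '1%'."""
    return f"{int(Decimal(repr(pct)).quantize(Decimal('1'), rounding=ROUND_HALF_UP))}%"


def align_and_count(a: str, b: str) -> tuple[int, float]:
    """Global-alignment mismatch count for unequal-length sequences
    (match 1, mismatch -1, gap -2); gap columns count as mismatches.
    Used as a logged fallback when simple Hamming comparison is impossible."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(a.upper(), b.upper())[0]
    sa, sb = str(aln[0]), str(aln[1])
    mism = sum(x != y for x, y in zip(sa, sb))
    logger.info("unequal lengths: counted mismatches on a global alignment")
    return mism, 100.0 * mism / len(sa)


# ---------------------------------------------------------------------------
# direct-repeat (LTR) detection
# ---------------------------------------------------------------------------

def word_matches(seq: str, word: int = 15) -> list[tuple[int, int]]:
    """Off-diagonal exact word self-matches (i, j) with i < j; the dot-plot
    primitive behind :func:`find_direct_repeats`, exported for plotting."""
    s = seq.upper()
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(s) - word + 1):
        w = s[i:i + word]
        if "N" not in w:
            index[w].append(i)
    out = []
    for positions in index.values():
        if len(positions) > 50:  # heavily repetitive word; skip to stay bounded
            continue
        for ii in range(len(positions)):
            for jj in range(ii + 1, len(positions)):
                out.append((positions[ii], positions[jj]))
    return out


_XWIN = 10   # look-ahead window for crossing a mismatch during extension
_XNEED = 8   # matches required within the look-ahead window


def _extend_right(s: str, a1: int, diag: int) -> int:
    n = len(s)
    while True:
        while a1 + diag < n and s[a1] == s[a1 + diag]:
            a1 += 1
        j0 = a1 + 1  # first position past the mismatch
        if a1 + diag >= n or j0 + _XWIN + diag > n:
            return a1
        matches = sum(s[j] == s[j + diag] for j in range(j0, j0 + _XWIN))
        if matches < _XNEED:
            return a1
        a1 += 1  # cross the isolated mismatch


def _extend_left(s: str, a0: int, diag: int) -> int:
    while True:
        while a0 > 0 and s[a0 - 1] == s[a0 - 1 + diag]:
            a0 -= 1
        j1 = a0 - 1  # the mismatch position
        if a0 == 0 or j1 - _XWIN < 0:
            return a0
        matches = sum(s[j] == s[j + diag] for j in range(j1 - _XWIN, j1))
        if matches < _XNEED:
            return a0
        a0 -= 1


def find_direct_repeats(seq: str, min_len: int = 300, min_identity: float = 95.0,
                        word: int = 15, min_separation: int = 100) -> list[RepeatPair]:
    """Find long same-strand direct-repeat pairs by seeded self-comparison.

    Exact ``word``-mers shared between two positions define diagonals
    (offset = j - i); word hits on one diagonal are chained into runs across
    gaps <= ``word``, and run ends are extended base-by-base while the copies
    agree, crossing an isolated mismatch whenever at least 8 of the next 10
    aligned positions match (so interior substitutions do not truncate the
    repeat, while extension stops at the boundary against unrelated
    sequence).  Pairs shorter than ``min_len``, below ``min_identity`` or
    with copies separated by less than ``min_separation`` bp are dropped;
    overlapping reports are deduplicated to maximal pairs.
    """
    s = seq.upper()
    if len(s) - s.count("N") < 2 * min_len:
        logger.warning("sequence shorter than two minimum-length copies (or mostly N)")
        return []

    by_diag: dict[int, list[int]] = defaultdict(list)
    for i, j in word_matches(s, word):
        by_diag[j - i].append(i)

    candidates: list[RepeatPair] = []
    for diag, starts in by_diag.items():
        starts = sorted(set(starts))
        # chain word hits into runs across gaps <= word
        runs: list[list[int]] = []  # [start, end) on the left copy
        for st in starts:
            if runs and st - runs[-1][1] <= word:
                runs[-1][1] = max(runs[-1][1], st + word)
            else:
                runs.append([st, st + word])
        for a0, a1 in runs:
            a0 = _extend_left(s, a0, diag)
            a1 = _extend_right(s, a1, diag)
            length = a1 - a0
            internal = diag - length
            if length < min_len or internal < min_separation or a1 + diag > len(s):
                continue
            mism, div = hamming_divergence(s[a0:a1], s[a0 + diag:a1 + diag])
            identity = 100.0 - div
            if identity < min_identity:
                continue
            candidates.append(RepeatPair(
                left=(a0, a1), right=(a0 + diag, a1 + diag), length=length,
                mismatches=mism, identity_pct=identity, internal_length=internal))

    # deduplicate overlapping reports, keeping maximal pairs
    candidates.sort(key=lambda rp: -rp.length)
    kept: list[RepeatPair] = []
    for cand in candidates:
        dup = any(_overlaps(cand.left, k.left) and _overlaps(cand.right, k.right)
                  for k in kept)
        if not dup:
            kept.append(cand)
    kept.sort(key=lambda rp: rp.left)
    return kept


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_solo_origin(solo: str, left: str, right: str
                         ) -> tuple[str, int, int]:
    """Assign a solo LTR to the flanking copy it most resembles.

    Returns ``(origin, d_left, d_right)`` where origin is ``"left"``,
    ``"right"`` or ``"ambiguous"`` (tie) by Hamming distance.
    """
    d_left, _ = hamming_divergence(solo, left)
    d_right, _ = hamming_divergence(solo, right)
    if d_left < d_right:
        origin = "left"
    elif d_right < d_left:
        origin = "right"
    else:
        origin = "ambiguous"
    return origin, d_left, d_right


# ---------------------------------------------------------------------------
# ORF prediction
# ---------------------------------------------------------------------------

class Orf(NamedTuple):
    """An open reading frame: ATG..stop inclusive.  ``start`` is 0-based on
    the scanned strand (for '-' the reverse complement's coordinates);
    ``aa_length`` excludes the stop codon."""

    frame: int
    strand: str
    start: int
    nt_length: int
    aa_length: int


def _orfs_in_strand(seq: str, strand: str) -> list[Orf]:
    out = []
    n = len(seq)
    for frame in range(3):
        open_start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if codon in _STOPS:
                if open_start is not None:
                    nt = i + 3 - open_start
                    out.append(Orf(frame, strand, open_start, nt, nt // 3 - 1))
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = i
    return out


def longest_orf(seq: str) -> Orf | None:
    """Longest ORF over all six reading frames.

    An ORF runs from an ATG to the first in-frame stop codon, stop included;
    ``aa_length = nt_length/3 - 1``.  Ties prefer the '+' strand, then the
    lowest start.  Returns None when no ORF exists.
    """
    s = seq.upper()
    orfs = _orfs_in_strand(s, "+") + _orfs_in_strand(reverse_complement(s), "-")
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o.nt_length, o.strand == "+", -o.start))


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------

def count_tandem_repeats(seq: str, unit: str, max_unit_mismatch: int = 6
                         ) -> tuple[int, tuple[int, int] | None]:
    """Count tandem copies of ``unit`` around its best match in ``seq``.

    The best-scoring occurrence of the unit (Hamming distance <=
    ``max_unit_mismatch``) anchors the array; the array is extended left and
    right in unit-length steps while each additional copy stays within the
    per-copy mismatch tolerance.  Returns ``(copies, (start, end))`` or
    ``(0, None)`` when no acceptable anchor exists.
    """
    if not unit:
        raise ConfigError("unit must be non-empty")
    s, u = seq.upper(), unit.upper()
    k = len(u)
    if k > len(s):
        raise ConfigError("unit longer than sequence")
    # vectorised Hamming profile of the unit against every offset
    sb = np.frombuffer(s.encode(), dtype=np.uint8)
    ub = np.frombuffer(u.encode(), dtype=np.uint8)
    n_off = len(s) - k + 1
    mism = np.zeros(n_off, dtype=np.int64)
    for t in range(k):
        mism += sb[t:t + n_off] != ub[t]
    best = int(mism.argmin())
    if mism[best] > max_unit_mismatch:
        return 0, None
    start = end = best
    copies = 1
    end = best + k
    while start - k >= 0 and int(mism[start - k]) <= max_unit_mismatch:
        start -= k
        copies += 1
    while end + k <= len(s) and int(mism[end]) <= max_unit_mismatch:
        end += k
        copies += 1
    return copies, (start, end)


# ---------------------------------------------------------------------------
# score-track peaks and coordinate arithmetic
# ---------------------------------------------------------------------------

def call_score_peaks(track: ScoreTrack, min_score: float = 0.2,
                     group_window: int = 500, mode: str = "merge"
                     ) -> list[tuple[int, int, float]]:
    """Group qualifying score positions into peaks.

    Positions with score >= ``min_score`` are seeds.  In the default
    ``"merge"`` mode consecutive seeds are joined into one peak whenever the
    gap between them is <= ``group_window`` bp; in ``"bins"`` mode the track
    is cut into fixed ``group_window``-bp bins, qualifying bins are merged
    when adjacent, and the seed span within each merged block is reported.
    Peaks are returned as (start, end, max_score) with half-open intervals.
    """
    if mode not in ("merge", "bins"):
        raise ConfigError(f"unknown peak-grouping mode {mode!r}")
    seeds = track.positions[track.scores >= min_score]
    seed_scores = track.scores[track.scores >= min_score]
    if seeds.size == 0:
        return []
    if mode == "merge":
        breaks = np.where(np.diff(seeds) > group_window)[0]
        bounds = np.concatenate([[0], breaks + 1, [seeds.size]])
    else:
        bin_of = seeds // group_window
        breaks = np.where(np.diff(bin_of) > 1)[0]
        bounds = np.concatenate([[0], breaks + 1, [seeds.size]])
    peaks = []
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        if i1 > i0:
            peaks.append((int(seeds[i0]), int(seeds[i1 - 1]) + 1,
                          float(seed_scores[i0:i1].max())))
    return peaks


def regulatory_distance(model: HaplotypeCoordModel) -> float:
    """Peak-to-TSS distance along a haplotype, in kb (one decimal, half-up).

    The distance is the peak-to-insertion gap, plus the insertion length when
    the haplotype carries it, plus the insertion-to-TSS gap.
    """
    total_bp = model.gap_peak_to_insertion + model.gap_insertion_to_tss
    if model.insertion_present:
        total_bp += model.insertion_length
    kb = Decimal(total_bp) / Decimal(1000)
    return float(kb.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def write_repeat_tsv(pairs: Sequence[RepeatPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("left_start\tleft_end\tright_start\tright_end\tlength\t"
                 "mismatches\tidentity_pct\tinternal_length\n")
        for rp in pairs:
            fh.write(f"{rp.left[0]}\t{rp.left[1]}\t{rp.right[0]}\t{rp.right[1]}\t"
                     f"{rp.length}\t{rp.mismatches}\t{rp.identity_pct:.3f}\t"
                     f"{rp.internal_length}\n")
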