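"""Pool-seq pileup I/O, site filters and coverage subsampling.

A pool is a sequencing library of many diploid individuals; the atom of all
downstream diversity and scan computation is the per-site vector of read
counts by nucleotide (:class:`PooledSiteCounts`).  This module parses
samtools-style mpileup text into such counts, applies the standard site
filters (base quality, indel neighbourhoods, coverage percentiles) and
subsamples each site to a uniform coverage without replacement, which the
truncated-spectrum corrections in :mod:`poolscan.diversity` assume.

Coordinates: pileup positions are 1-based; all interval outputs elsewhere in
the package are 0-based half-open (BED convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import ConfigError, ParseError

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PooledSiteCounts:
    """Read counts by nucleotide at one site of one pool, after quality filtering.

    ``depth_used`` (the retained coverage M) always equals the sum of
    ``counts``; reads dropped by quality, deletion placeholders and Ns are
    excluded from both.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    counts: dict[str, int] = field(default_factory=lambda: {b: 0 for b in BASES})
    indel_flag: bool = False

    @property
    def depth_used(self) -> int:
        return sum(self.counts.values())

    def count_vector(self) -> np.ndarray:
        return np.array([self.counts.get(b, 0) for b in BASES], dtype=np.int64)


@dataclass(frozen=True)
class PoolSpec:
    """Identity and sampling depth of one pool.

    ``n_diploids`` is the number of diploid individuals pooled; the
    chromosome count entering the estimators is ``n_chrom = 2 * n_diploids``.
    """

    pool_id: str
    group: str
    n_diploids: int

    def __post_init__(self) -> None:
        if self.n_diploids < 1:
            raise ConfigError(f"n_diploids must be >= 1, got {self.n_diploids}")

    @property
    def n_chrom(self) -> int:
        return 2 * self.n_diploids


@dataclass(frozen=True)
class FilterConfig:
    """Site-filter settings mirroring a conventional Pool-seq pipeline.

    min_map_qual is a pileup-generation contract (samtools ``-q``): plain
    mpileup text carries no per-read mapping quality, so the parser enforces
    base quality only.
    """

    min_base_qual: int = 20
    min_map_qual: int = 20
    min_minor_count: int = 2
    indel_mask_radius: int = 5
    subsample_percentile: float = 5.0
    max_cov_percentile: float = 99.0

    def __post_init__(self) -> None:
        for name in ("min_base_qual", "min_map_qual", "min_minor_count", "indel_mask_radius"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("subsample_percentile", "max_cov_percentile"):
            p = getattr(self, name)
            if not 0.0 < p < 100.0:
                raise ConfigError(f"{name} must lie in (0, 100), got {p}")


class SiteArray:
    """Column-oriented sequence of :class:`PooledSiteCounts` for one chromosome.

    Behaves as a read-only sequence of sites but stores positions, the
    4-column count matrix (A,C,G,T) and flags as numpy arrays so that the
    window statistics and the simulators can stay vectorised.
    """

    def __init__(self, chrom: str, pos, counts, ref_idx, indel=None):
        self.chrom = chrom
        self.pos = np.asarray(pos, dtype=np.int64)
        self.counts = np.asarray(counts, dtype=np.int64)
        self.ref_idx = np.asarray(ref_idx, dtype=np.int8)
        if indel is None:
            indel = np.zeros(len(self.pos), dtype=bool)
        self.indel = np.asarray(indel, dtype=bool)
        if self.counts.shape != (len(self.pos), 4):
            raise ValueError("counts must have shape (n_sites, 4)")

    # -- sequence protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.pos)

    def __getitem__(self, i: int) -> PooledSiteCounts:
        row = self.counts[i]
        return PooledSiteCounts(
            chrom=self.chrom,
            pos=int(self.pos[i]),
            ref=BASES[self.ref_idx[i]],
            counts={b: int(row[j]) for j, b in enumerate(BASES)},
            indel_flag=bool(self.indel[i]),
        )

    def __iter__(self) -> Iterator[PooledSiteCounts]:
        for i in range(len(self)):
            yield self[i]

    # -- helpers -----------------------------------------------------------
    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def subset(self, mask) -> "SiteArray":
        return SiteArray(self.chrom, self.pos[mask], self.counts[mask],
                         self.ref_idx[mask], self.indel[mask])

    @classmethod
    def from_sites(cls, sites: Iterable[PooledSiteCounts]) -> "SiteArray":
        sites = list(sites)
        if not sites:
            return cls("", [], np.zeros((0, 4)), [])
        chrom = sites[0].chrom
        if any(s.chrom != chrom for s in sites):
            raise ValueError("SiteArray holds a single chromosome")
        pos = [s.pos for s in sites]
        counts = [[s.counts.get(b, 0) for b in BASES] for s in sites]
        ref_idx = [_BASE_INDEX.get(s.ref.upper(), 0) for s in sites]
        indel = [s.indel_flag for s in sites]
        return cls(chrom, pos, counts, ref_idx, indel)

    @classmethod
    def coerce(cls, sites) -> "SiteArray":
        return sites if isinstance(sites, cls) else cls.from_sites(sites)


# ---------------------------------------------------------------------------
# mpileup parsing
# ---------------------------------------------------------------------------

def parse_mpileup_line(line: str, min_base_qual: int = 20, line_number: int | None = None
                       ) -> PooledSiteCounts:
    """Parse one mpileup row into filtered per-base counts.

    Handles the mpileup grammar: ``.``/``,`` count as the reference base,
    ``ACGTacgt`` as alternatives, ``^X`` read-start markers (the mapping
    quality character is skipped), ``$`` read ends, ``+n<seq>``/``-n<seq>``
    indel strings (consumed; they raise ``indel_flag``), ``*`` deletion
    placeholders and ``N`` are dropped.  Bases with quality below
    ``min_base_qual`` (Phred+33) are dropped.  The base and quality strings
    are consumed in lockstep so filtering stays index-aligned.
    """
    where = f" at line {line_number}" if line_number is not None else ""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise ParseError(f"expected >= 6 tab-separated mpileup fields{where}")
    chrom, pos_s, ref, depth_s, bases, quals = fields[:6]
    try:
        pos = int(pos_s)
        declared_depth = int(depth_s)
    except ValueError as exc:
        raise ParseError(f"non-integer pos/depth field{where}") from exc
    ref = ref.upper()

    counts = {b: 0 for b in BASES}
    indel_flag = False
    i = 0  # index into bases
    q = 0  # index into quals
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # skip marker and the mapping-quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ParseError(f"malformed indel length in pileup string{where}")
            length = int(bases[i + 1:j])
            if j + length > n:
                raise ParseError(f"indel sequence overruns pileup string{where}")
            i = j + length
            indel_flag = True
            continue
        # every remaining symbol consumes one quality character
        if q >= len(quals):
            raise ParseError(f"base/quality strings are misaligned{where}")
        qual = ord(quals[q]) - 33
        q += 1
        i += 1
        if c in ".,":
            base = ref
        elif c.upper() in _BASE_INDEX:
            base = c.upper()
        else:
            continue  # '*', 'N'/'n', '<', '>' — dropped
        if base in counts and qual >= min_base_qual:
            counts[base] += 1
    if q != len(quals):
        raise ParseError(f"base/quality strings are misaligned{where}")

    site = PooledSiteCounts(chrom=chrom, pos=pos, ref=ref, counts=counts,
                            indel_flag=indel_flag)
    if site.depth_used > declared_depth:
        raise ParseError(f"retained reads exceed declared depth{where}")
    return site


def read_mpileup(path, min_base_qual: int = 20) -> list[PooledSiteCounts]:
    """Read a whole mpileup file (one pool) into a list of sites."""
    sites = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.strip():
                sites.append(parse_mpileup_line(line, min_base_qual, line_number=ln))
    return sites


def write_mpileup(sites, path, qual_char: str = "I") -> None:
    """Write sites as mpileup text (ref reads as '.', alternatives uppercase)."""
    arr = SiteArray.coerce(sites)
    with open(path, "w") as fh:
        for i in range(len(arr)):
            row = arr.counts[i]
            ref_i = int(arr.ref_idx[i])
            parts = ["." * int(row[ref_i])]
            for j, b in enumerate(BASES):
                if j != ref_i and row[j]:
                    parts.append(b * int(row[j]))
            bases = "".join(parts)
            depth = int(row.sum())
            fh.write(f"{arr.chrom}\t{int(arr.pos[i])}\t{BASES[ref_i]}\t{depth}\t"
                     f"{bases}\t{qual_char * depth}\n")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def mask_indel_neighborhood(sites, radius: int = 5):
    """Drop indel-flagged sites and everything within ``radius`` bp of them.

    Input must be sorted by (chrom, pos); spurious SNPs cluster around
    misaligned indels, hence the symmetric exclusion zone.
    """
    arr = SiteArray.coerce(sites)
    if len(arr) == 0:
        return arr if isinstance(sites, SiteArray) else []
    if np.any(np.diff(arr.pos) < 0):
        raise ValueError("sites must be sorted by position")
    indel_pos = arr.pos[arr.indel]
    keep = np.ones(len(arr), dtype=bool)
    if len(indel_pos):
        # nearest indel distance via searchsorted on sorted indel positions
        idx = np.searchsorted(indel_pos, arr.pos)
        left = np.where(idx > 0, arr.pos - indel_pos[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
        right = np.where(idx < len(indel_pos),
                         indel_pos[np.minimum(idx, len(indel_pos) - 1)] - arr.pos,
                         np.iinfo(np.int64).max)
        keep = np.minimum(left, right) > radius
    out = arr.subset(keep)
    return out if isinstance(sites, SiteArray) else list(out)


def coverage_percentiles(depths: Sequence[int], p_low: float = 5.0, p_high: float = 99.0
                         ) -> tuple[int, int]:
    """Nearest-rank percentiles of a coverage distribution.

    Returns ``(target_cov, max_cov)``: the value at 1-based index
    ``ceil(p/100 * N)`` of the sorted depths, for each percentile.
    """
    depths = np.sort(np.asarray(depths))
    if depths.size == 0:
        raise ValueError("empty coverage distribution")

    def rank(p: float) -> int:
        if not 0.0 < p < 100.0:
            raise ConfigError(f"percentile must lie in (0, 100), got {p}")
        return int(depths[max(math.ceil(p / 100.0 * depths.size), 1) - 1])

    return rank(p_low), rank(p_high)


def subsample_counts(site: PooledSiteCounts, target: int, seed) -> PooledSiteCounts | None:
    """Subsample one site to exactly ``target`` reads without replacement.

    Draws from the multiset of retained reads (multivariate hypergeometric).
    Sites with fewer than ``target`` reads are dropped (``None``); the
    maximum-coverage filter is the caller's responsibility.  ``seed`` may be
    an int or a ``numpy.random.Generator``.
    """
    if target < 1:
        raise ConfigError(f"target coverage must be >= 1, got {target}")
    if site.depth_used < target:
        return None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vec = site.count_vector()
    drawn = rng.multivariate_hypergeometric(vec, target)
    return PooledSiteCounts(
        chrom=site.chrom, pos=site.pos, ref=site.ref,
        counts={b: int(drawn[i]) for i, b in enumerate(BASES)},
        indel_flag=site.indel_flag,
    )


def subsample_array(arr: SiteArray, target: int, rng: np.random.Generator) -> SiteArray:
    """Vectorised without-replacement subsampling of every site to ``target``.

    Sequential conditional hypergeometric draws over the four base columns;
    exactly equivalent in distribution to the per-site multivariate
    hypergeometric.  All sites must already have depth >= target.
    """
    depth = arr.depth
    if np.any(depth < target):
        raise ValueError("all sites must have depth >= target before subsampling")
    remaining_total = depth.copy()
    remaining_draw = np.full(len(arr), target, dtype=np.int64)
    out = np.zeros_like(arr.counts)
    for j in range(3):
        ngood = arr.counts[:, j]
        nbad = remaining_total - ngood
        safe = remaining_draw > 0
        x = np.zeros(len(arr), dtype=np.int64)
        if safe.any():
            x[safe] = rng.hypergeometric(ngood[safe], nbad[safe], remaining_draw[safe])
        out[:, j] = x
        remaining_total -= ngood
        remaining_draw -= x
    out[:, 3] = remaining_draw
    return SiteArray(arr.chrom, arr.pos, out, arr.ref_idx, arr.indel)


def call_snp(site: PooledSiteCounts, min_minor: int = 2) -> bool:
    """True iff at least two alleles are observed and the minor (second most
    frequent) allele has at least ``min_minor`` reads."""
    vec = np.sort(site.count_vector())[::-1]
    return int(vec[1]) >= max(min_minor, 1)


@dataclass
class PreparedPool:
    """A pool after the full filter/subsample pipeline."""

    sites: SiteArray
    target_cov: int
    max_cov: int
    n_input: int
    n_after_indel_mask: int
    n_retained: int


def prepare_pool(sites, cfg: FilterConfig = FilterConfig(), seed=0) -> PreparedPool:
    """Apply indel masking, coverage-percentile filters and subsampling.

    The subsampling target is the ``subsample_percentile`` of the pool's own
    coverage distribution and doubles as the minimum coverage: shallower
    sites are dropped, as are sites above the ``max_cov_percentile``
    (repeat/CNV guard).  The max-coverage cut is applied before subsampling.
    """
    arr = SiteArray.coerce(sites)
    n_input = len(arr)
    arr = mask_indel_neighborhood(arr, cfg.indel_mask_radius)
    n_masked = len(arr)
    if n_masked == 0:
        return PreparedPool(arr, 0, 0, n_input, 0, 0)
    target, max_cov = coverage_percentiles(arr.depth, cfg.subsample_percentile,
                                           cfg.max_cov_percentile)
    depth = arr.depth
    arr = arr.subset((depth >= target) & (depth <= max_cov))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = subsample_array(arr, target, rng)
    return PreparedPool(arr, target, max_cov, n_input, n_masked, len(arr))


# ---------------------------------------------------------------------------
# sync-like interchange format
# ---------------------------------------------------------------------------

def write_sync(pool_sites: Mapping[str, Sequence[PooledSiteCounts]], path) -> None:
    """Write the pipeline interchange TSV: chrom, pos, ref, then one
    ``A:C:G:T`` count column per pool (``.:.:.:.`` when a pool lacks the site)."""
    pool_ids = list(pool_sites)
    arrays = {pid: SiteArray.coerce(s) for pid, s in pool_sites.items()}
    index: dict[tuple[str, int], dict[str, str]] = {}
    refs: dict[tuple[str, int], str] = {}
    for pid, arr in arrays.items():
        for i in range(len(arr)):
            key = (arr.chrom, int(arr.pos[i]))
            refs.setdefault(key, BASES[arr.ref_idx[i]])
            index.setdefault(key, {})[pid] = ":".join(str(int(c)) for c in arr.counts[i])
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\t" + "\t".join(pool_ids) + "\n")
        for key in sorted(index):
            row = index[key]
            cols = [row.get(pid, ".:.:.:.") for pid in pool_ids]
            fh.write(f"{key[0]}\t{key[1]}\t{refs[key]}\t" + "\t".join(cols) + "\n")


def read_sync(path) -> dict[str, list[PooledSiteCounts]]:
    """Read the interchange TSV back into per-pool site lists."""
    out: dict[str, list[PooledSiteCounts]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        pool_ids = header[3:]
        for pid in pool_ids:
            out[pid] = []
        for ln, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            chrom, pos, ref = fields[0], int(fields[1]), fields[2]
            for pid, col in zip(pool_ids, fields[3:]):
                if col == ".:.:.:.":
                    continue
                vals = [int(x) for x in col.split(":")]
                if len(vals) != 4:
                    raise ParseError(f"bad count column at line {ln}")
                out[pid].append(PooledSiteCounts(
                    chrom=chrom, pos=pos, ref=ref,
                    counts=dict(zip(BASES, vals))))
    return out
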