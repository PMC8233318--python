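"""Seeded synthetic-data generators with known truth.

Three generators emulate the statistical structure the analysis assumes,
so every downstream stage is testable without external data:

* a single-pool neutral generator: each site segregates at chromosome count
  k (1 <= k < n) with probability theta/k — the standard neutral frequency
  spectrum — and reads are drawn binomially over the site frequency with
  optional uniform miscalls;
* a two-group Pool-seq generator: seven spring-like and seven autumn-like
  pools over a shared neutral background, plus a localized divergent region
  carrying group-specific allele frequencies and a diversity reduction
  (a selective-sweep analogue);
* a toy locus generator: haplotype S carries an LTR-internal-LTR element and
  a tandem-repeat array, haplotype A the solo-LTR recombinant with a
  different copy number, and an outgroup haplotype carries the element with
  identical (ancestral) LTR copies.

Everything is deterministic given the config seed; per-pool random streams
are keyed by pool index so adding a pool never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, GenerationError
from .poolio import BASES, PoolSpec, SiteArray, write_mpileup

_CHROM = "sim1"


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumSimConfig:
    """Neutral single-pool Pool-seq generator settings.

    theta is the per-site scaled diversity; n_chrom the number of pooled
    chromosomes (2 x diploids); mean_depth the expected reads per site
    (Poisson); seq_error the per-read miscall probability (uniform over the
    other three bases); n_sites the genome length in bp.
    """

    theta: float = 0.005
    n_chrom: int = 80
    mean_depth: float = 60.0
    seq_error: float = 0.001
    n_sites: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chrom < 2:
            raise ConfigError(f"n_chrom must be >= 2, got {self.n_chrom}")
        if self.theta < 0:
            raise ConfigError(f"theta must be >= 0, got {self.theta}")
        a1 = float(np.sum(1.0 / np.arange(1, self.n_chrom)))
        if self.theta * a1 >= 1.0:
            raise ConfigError(
                f"theta={self.theta} too large: theta * a1(n_chrom) must be < 1")
        if self.mean_depth <= 0:
            raise ConfigError(f"mean_depth must be > 0, got {self.mean_depth}")
        if not 0.0 <= self.seq_error < 1.0:
            raise ConfigError(f"seq_error must lie in [0, 1), got {self.seq_error}")
        if self.n_sites < 1:
            raise ConfigError(f"n_sites must be >= 1, got {self.n_sites}")


def default_pools(n_per_group: int = 7, n_diploids: int = 50,
                  groups: tuple[str, str] = ("spring", "autumn")) -> list[PoolSpec]:
    """The default 7 + 7 pool design of ~50 diploids each."""
    out = []
    for g in groups:
        for i in range(n_per_group):
            out.append(PoolSpec(pool_id=f"{g}{i + 1}", group=g, n_diploids=n_diploids))
    return out


@dataclass(frozen=True)
class TwoGroupSimConfig:
    """Two-group genome-scan generator settings.

    Background sites follow the neutral spectrum of ``background`` with one
    frequency shared by every pool (read sampling is then the only noise, the
    null the chi-square test assumes).  The ``n_divergent_snps`` planted SNPs
    inside ``divergent_region`` get group-specific population frequencies,
    and each pool resamples its own frequency as Binomial(2n, p_group)/(2n)
    before read sampling (finite-pool noise).  ``sweep_theta_factor`` thins
    background segregation inside the region, emulating the diversity loss
    of a selective sweep.  ``emit_monomorphic=False`` restricts output to
    segregating sites (sufficient for the scan; window-diversity analyses
    need the default True).
    """

    pools: tuple[PoolSpec, ...] = tuple(default_pools())
    genome_length: int = 1_000_000
    background: SpectrumSimConfig = SpectrumSimConfig()
    divergent_region: tuple[int, int] = (450_000, 550_000)
    n_divergent_snps: int = 20
    freq_group1: float = 0.95
    freq_group2: float = 0.05
    sweep_theta_factor: float = 0.2
    emit_monomorphic: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len({p.group for p in self.pools}) != 2:
            raise ConfigError("pools must span exactly 2 groups")
        s, e = self.divergent_region
        if not (0 <= s < e <= self.genome_length):
            raise ConfigError(
                f"divergent_region {self.divergent_region} not within genome")
        for name in ("freq_group1", "freq_group2"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {f}")
        if not 0.0 < self.sweep_theta_factor <= 1.0:
            raise ConfigError(
                f"sweep_theta_factor must lie in (0, 1], got {self.sweep_theta_factor}")
        if self.n_divergent_snps > e - s:
            raise GenerationError("more divergent SNPs than region positions")


@dataclass(frozen=True)
class LocusSimConfig:
    """Toy locus generator settings (lengths in bp).

    Defaults draw a ~470 bp LTR pair around a ~4.7 kb internal sequence, so
    the hapS-vs-hapA indel (internal + one LTR) is ~5.2 kb; a 66-bp tandem
    unit (22 codons) with 3 copies on hapS and 5 on hapA; and printed-offset
    gaps of 1.9 kb (peak to insertion) and 2.15 kb (insertion to TSS).
    """

    ltr_length: int = 470
    internal_length: int = 4_730
    ltr_mismatches: int = 4
    solo_origin: str = "right"
    solo_vs_origin_mismatches: int = 1
    repeat_unit_length: int = 66
    copies_hapS: int = 3
    copies_hapA: int = 5
    gap_peak_to_insertion: int = 1_900
    gap_insertion_to_tss: int = 2_150
    flank_length: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ltr_mismatches > self.ltr_length:
            raise ConfigError("ltr_mismatches cannot exceed ltr_length")
        if self.solo_vs_origin_mismatches > self.ltr_length - self.ltr_mismatches:
            raise ConfigError("solo_vs_origin_mismatches leaves no disjoint positions")
        if self.solo_origin not in ("left", "right"):
            raise ConfigError(f"solo_origin must be 'left' or 'right', got {self.solo_origin!r}")
        for name in ("copies_hapS", "copies_hapA"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("ltr_length", "internal_length", "repeat_unit_length"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")


# ---------------------------------------------------------------------------
# neutral spectrum pool
# ---------------------------------------------------------------------------

@dataclass
class SpectrumTruth:
    """Ground truth of one neutral pool simulation."""

    theta: float
    table: pd.DataFrame  # pos (1-based), k, ref, alt — every segregating site


def _draw_spectrum(rng: np.random.Generator, theta: float, n_chrom: int,
                   n_sites: int, seg_scale: np.ndarray | None = None) -> np.ndarray:
    """Per-site chromosome count k of the derived allele (0 = monomorphic).

    ``seg_scale`` optionally multiplies the segregation probability per site
    (sweep thinning).
    """
    k_vals = np.arange(1, n_chrom)
    probs = theta / k_vals
    cum = np.cumsum(probs)
    total = cum[-1] if len(cum) else 0.0
    u = rng.random(n_sites)
    if seg_scale is not None:
        u = u / seg_scale  # shrinking the effective u-range thins segregation
    k = np.where(u < total, np.searchsorted(cum, u, side="right") + 1, 0)
    return k.astype(np.int64)


def _apply_seq_error(rng: np.random.Generator, counts: np.ndarray, seq_error: float
                     ) -> np.ndarray:
    """Miscall each read with probability seq_error, uniformly to the other
    three bases (strand-agnostic)."""
    if seq_error <= 0:
        return counts
    out = counts.copy()
    for j in range(4):
        errs = rng.binomial(counts[:, j], seq_error)
        out[:, j] -= errs
        dest = [d for d in range(4) if d != j]
        spread = rng.multinomial(errs, [1 / 3] * 3)
        for t, d in enumerate(dest):
            out[:, d] += spread[:, t]
    return out


def _reads_from_freq(rng: np.random.Generator, depth: np.ndarray, p_alt: np.ndarray,
                     ref_idx: np.ndarray, alt_idx: np.ndarray, seq_error: float
                     ) -> np.ndarray:
    """Binomial read sampling over per-site alternative-allele frequencies."""
    n = depth.size
    alt_reads = rng.binomial(depth, p_alt)
    counts = np.zeros((n, 4), dtype=np.int64)
    rows = np.arange(n)
    counts[rows, ref_idx] = depth - alt_reads
    counts[rows, alt_idx] += alt_reads
    return _apply_seq_error(rng, counts, seq_error)


def simulate_spectrum_pool(cfg: SpectrumSimConfig) -> tuple[SiteArray, SpectrumTruth]:
    """Simulate one pool under the neutral spectrum.

    Returns the sites (sequence of per-site counts; zero-depth sites are
    omitted) and the truth record of every planted segregating site.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    k = _draw_spectrum(rng, cfg.theta, cfg.n_chrom, cfg.n_sites)
    ref_idx = rng.integers(0, 4, cfg.n_sites).astype(np.int8)
    alt_idx = ((ref_idx + rng.integers(1, 4, cfg.n_sites)) % 4).astype(np.int8)
    depth = rng.poisson(cfg.mean_depth, cfg.n_sites)
    p_alt = k / cfg.n_chrom
    counts = _reads_from_freq(rng, depth, p_alt, ref_idx, alt_idx, cfg.seq_error)
    pos = np.arange(1, cfg.n_sites + 1)
    seg = k > 0
    truth = SpectrumTruth(
        theta=cfg.theta,
        table=pd.DataFrame({
            "pos": pos[seg], "k": k[seg],
            "ref": np.array(list(BASES))[ref_idx[seg]],
            "alt": np.array(list(BASES))[alt_idx[seg]],
        }))
    keep = depth > 0
    sites = SiteArray(_CHROM, pos[keep], counts[keep], ref_idx[keep])
    return sites, truth


# ---------------------------------------------------------------------------
# two-group scan
# ---------------------------------------------------------------------------

@dataclass
class TwoGroupSimResult:
    """Per-pool sites, ground truth and (optionally) the files written."""

    pool_sites: dict[str, SiteArray]
    truth: pd.DataFrame
    pools: tuple[PoolSpec, ...]
    pileup_paths: dict[str, Path] = field(default_factory=dict)


def simulate_two_group_scan(cfg: TwoGroupSimConfig, outdir=None) -> TwoGroupSimResult:
    """Simulate the 7-vs-7 Pool-seq design with a planted divergent region.

    When ``outdir`` is given, writes one mpileup file per pool, the truth
    table as TSV and the config as a flat key=value file.
    """
    # group order = first appearance in the pool list, so freq_group1 always
    # belongs to the first-listed group
    groups = list(dict.fromkeys(p.group for p in cfg.pools))
    bg = cfg.background
    master = np.random.default_rng([cfg.seed, 0])

    # shared background spectrum, thinned inside the swept region
    pos = np.arange(1, cfg.genome_length + 1)
    s, e = cfg.divergent_region
    in_region = (pos > s) & (pos <= e)  # region is 0-based half-open
    seg_scale = np.where(in_region, cfg.sweep_theta_factor, 1.0)
    k = _draw_spectrum(master, bg.theta, bg.n_chrom, cfg.genome_length, seg_scale)
    ref_idx = master.integers(0, 4, cfg.genome_length).astype(np.int8)
    alt_idx = ((ref_idx + master.integers(1, 4, cfg.genome_length)) % 4).astype(np.int8)
    p_shared = k / bg.n_chrom

    # planted divergent SNPs (distinct positions within the region)
    region_pos = pos[in_region]
    div_pos = np.sort(master.choice(region_pos, size=cfg.n_divergent_snps, replace=False)) \
        if cfg.n_divergent_snps else np.array([], dtype=np.int64)
    if np.unique(div_pos).size != div_pos.size:
        raise GenerationError("overlapping divergent SNPs at one position")
    div_idx = div_pos - 1
    group_freq = {groups[0]: cfg.freq_group1, groups[1]: cfg.freq_group2}

    if cfg.emit_monomorphic:
        emit = np.ones(cfg.genome_length, dtype=bool)
    else:
        emit = k > 0
        emit[div_idx] = True

    pool_sites: dict[str, SiteArray] = {}
    truth_pool_freqs: dict[str, np.ndarray] = {}
    for i, pool in enumerate(cfg.pools):
        prng = np.random.default_rng([cfg.seed, 1000 + i])
        depth = prng.poisson(bg.mean_depth, cfg.genome_length)
        p_alt = p_shared.copy()
        # finite-pool resampling at the divergent SNPs
        n2 = pool.n_chrom
        p_pool = prng.binomial(n2, group_freq[pool.group], size=div_idx.size) / n2
        p_alt[div_idx] = p_pool
        truth_pool_freqs[pool.pool_id] = p_pool
        keep = emit & (depth > 0)
        counts = _reads_from_freq(prng, depth[keep], p_alt[keep], ref_idx[keep],
                                  alt_idx[keep], bg.seq_error)
        pool_sites[pool.pool_id] = SiteArray(_CHROM, pos[keep], counts, ref_idx[keep])

    mean1 = np.mean([truth_pool_freqs[p.pool_id] for p in cfg.pools
                     if p.group == groups[0]], axis=0) if div_idx.size else []
    mean2 = np.mean([truth_pool_freqs[p.pool_id] for p in cfg.pools
                     if p.group == groups[1]], axis=0) if div_idx.size else []
    truth = pd.DataFrame({
        "chrom": _CHROM, "pos": div_pos,
        "ref": np.array(list(BASES))[ref_idx[div_idx]],
        "alt": np.array(list(BASES))[alt_idx[div_idx]],
        f"freq_{groups[0]}": cfg.freq_group1,
        f"freq_{groups[1]}": cfg.freq_group2,
        "daf_true": abs(cfg.freq_group1 - cfg.freq_group2),
    })
    for pool in cfg.pools:
        truth[f"pool_freq_{pool.pool_id}"] = truth_pool_freqs[pool.pool_id]

    result = TwoGroupSimResult(pool_sites=pool_sites, truth=truth, pools=cfg.pools)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for pid, sites in pool_sites.items():
            path = outdir / f"{pid}.pileup"
            write_mpileup(sites, path)
            result.pileup_paths[pid] = path
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        with open(outdir / "config.txt", "w") as fh:
            for name in ("genome_length", "n_divergent_snps", "freq_group1",
                         "freq_group2", "sweep_theta_factor", "seed"):
                fh.write(f"{name}={getattr(cfg, name)}\n")
            fh.write(f"divergent_region={cfg.divergent_region[0]}-{cfg.divergent_region[1]}\n")
            fh.write(f"background_theta={bg.theta}\n")
            fh.write(f"pools={','.join(p.pool_id for p in cfg.pools)}\n")
    return result


# ---------------------------------------------------------------------------
# toy locus sequences
# ---------------------------------------------------------------------------

@dataclass
class LocusTruth:
    """Planted feature coordinates (0-based half-open, per haplotype) and the
    exact sequences/mismatch positions needed by downstream checks."""

    ltr_left: tuple[int, int]
    ltr_right: tuple[int, int]
    internal: tuple[int, int]
    solo_ltr: tuple[int, int]           # on hapA
    repeat_region_S: tuple[int, int]
    repeat_region_A: tuple[int, int]
    tss_S: int
    tss_A: int
    ltr_mismatch_positions: tuple[int, ...]      # offsets within the LTR
    solo_mismatch_positions: tuple[int, ...]
    solo_origin: str
    repeat_unit: str
    ltr_left_seq: str
    ltr_right_seq: str
    solo_seq: str


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, length)])


def _mutate(rng: np.random.Generator, seq: str, positions: Sequence[int]) -> str:
    out = list(seq)
    for p in positions:
        out[p] = BASES[(BASES.index(out[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def simulate_locus_sequences(cfg: LocusSimConfig
                             ) -> tuple[list[SeqRecord], LocusTruth]:
    """Build the hapS / hapA / outgroup toy haplotypes.

    hapS:   flank | LTR_left | internal | LTR_right | gap-to-TSS | TSS |
            coding head | tandem repeats (copies_hapS) | flank
    hapA:   same flanks, solo LTR (origin copy + extra mismatches) instead of
            the element, tandem repeats with copies_hapA.
    outgrp: element with two *identical* ancestral LTR copies.

    The two LTR copies of hapS differ at exactly ``ltr_mismatches`` planted
    positions; the solo LTR adds ``solo_vs_origin_mismatches`` differences to
    its origin copy at positions disjoint from those, so mismatch distances
    to the two copies are unambiguous by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    ltr_anc = _random_seq(rng, cfg.ltr_length)
    internal = _random_seq(rng, cfg.internal_length)
    flank5 = _random_seq(rng, cfg.flank_length)
    gap_tss = _random_seq(rng, cfg.gap_insertion_to_tss)
    coding_head = _random_seq(rng, 120)
    unit = _random_seq(rng, cfg.repeat_unit_length)
    flank3 = _random_seq(rng, cfg.flank_length)

    # plant substitutions away from the copy termini so the repeat boundaries
    # stay identifiable to a truth-free detector (margin shrinks if needed)
    margin = 15
    n_mut = cfg.ltr_mismatches + cfg.solo_vs_origin_mismatches
    while margin > 0 and cfg.ltr_length - 2 * margin < n_mut:
        margin -= 1
    all_pos = rng.permutation(np.arange(margin, cfg.ltr_length - margin))
    mm_ltr = tuple(sorted(int(x) for x in all_pos[:cfg.ltr_mismatches]))
    mm_solo = tuple(sorted(int(x) for x in
                           all_pos[cfg.ltr_mismatches:cfg.ltr_mismatches
                                   + cfg.solo_vs_origin_mismatches]))
    ltr_left = ltr_anc
    ltr_right = _mutate(rng, ltr_anc, mm_ltr)
    origin_seq = ltr_right if cfg.solo_origin == "right" else ltr_left
    solo = _mutate(rng, origin_seq, mm_solo)

    def assemble(element: str, copies: int) -> tuple[str, dict[str, int]]:
        marks = {}
        parts = [flank5]
        marks["element_start"] = len(flank5)
        parts.append(element)
        marks["element_end"] = marks["element_start"] + len(element)
        parts.append(gap_tss)
        marks["tss"] = marks["element_end"] + len(gap_tss)
        parts.append(coding_head)
        marks["repeat_start"] = marks["tss"] + len(coding_head)
        parts.append(unit * copies)
        marks["repeat_end"] = marks["repeat_start"] + len(unit) * copies
        parts.append(flank3)
        return "".join(parts), marks

    element_S = ltr_left + internal + ltr_right
    element_O = ltr_anc + internal + ltr_anc
    hapS, mS = assemble(element_S, cfg.copies_hapS)
    hapA, mA = assemble(solo, cfg.copies_hapA)
    outg, _ = assemble(element_O, cfg.copies_hapS)

    truth = LocusTruth(
        ltr_left=(mS["element_start"], mS["element_start"] + cfg.ltr_length),
        ltr_right=(mS["element_end"] - cfg.ltr_length, mS["element_end"]),
        internal=(mS["element_start"] + cfg.ltr_length,
                  mS["element_end"] - cfg.ltr_length),
        solo_ltr=(mA["element_start"], mA["element_end"]),
        repeat_region_S=(mS["repeat_start"], mS["repeat_end"]),
        repeat_region_A=(mA["repeat_start"], mA["repeat_end"]),
        tss_S=mS["tss"], tss_A=mA["tss"],
        ltr_mismatch_positions=mm_ltr,
        solo_mismatch_positions=mm_solo,
        solo_origin=cfg.solo_origin,
        repeat_unit=unit,
        ltr_left_seq=ltr_left, ltr_right_seq=ltr_right, solo_seq=solo,
    )
    records = [
        SeqRecord(Seq(hapS), id="hapS", description="insertion haplotype (synthetic)"),
        SeqRecord(Seq(hapA), id="hapA", description="solo-LTR haplotype (synthetic)"),
        SeqRecord(Seq(outg), id="outgroup", description="ancestral element haplotype (synthetic)"),
    ]
    return records, truth
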