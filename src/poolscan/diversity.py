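"""Pooled nucleotide diversity, Watterson's theta and Tajima's D.

Pool-seq estimators differ from individual-based ones in two ways: reads are
a sample (with replacement) of the ``n`` pooled chromosomes, and a minor
allele must be seen in at least ``b`` reads to be called, truncating the
observable allele-frequency spectrum.  Both effects are absorbed into
denominators computed under the standard neutral 1/k spectrum:

for a pool of ``n`` chromosomes sequenced at coverage ``M`` with minimum
minor count ``b``,

    C_pi(n, M, b) = sum_{k=1}^{n-1} 1/k * sum_{m=b}^{M-b}
                    Binom(m; M, k/n) * 2 m (M - m) / (M (M - 1))

    C_S(n, M, b)  = sum_{k=1}^{n-1} 1/k * sum_{m=b}^{M-b} Binom(m; M, k/n)

so that summing the measured per-site heterozygosity h (for pi) or 1 (for
theta_W) over called SNPs and dividing by the matching denominator yields an
estimator whose expectation is theta per covered site.  Tajima's D is formed
from the corrected sums with Tajima's classical variance constants evaluated
at an effective sample size (the pool chromosome count by default).

Window statistics follow the usual Pool-seq sliding-window practice: per-bp
values are normalised by the number of covered positions, and windows whose
covered fraction falls below a threshold are reported but flagged undefined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError
from .poolio import BASES, PoolSpec, SiteArray

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrectionKey:
    """Parameters indexing one truncated-spectrum correction: pool chromosome
    count ``n_chrom``, subsampled coverage ``M`` and minimum minor count ``b``."""

    n_chrom: int
    M: int
    b: int

    def __post_init__(self) -> None:
        if self.n_chrom < 2:
            raise ConfigError(f"n_chrom must be >= 2, got {self.n_chrom}")
        if self.b < 1:
            raise ConfigError(f"b must be >= 1, got {self.b}")
        if self.b > self.M / 2:
            raise ConfigError(
                f"b={self.b} with M={self.M} leaves an empty truncation range")


@dataclass
class WindowStat:
    """Sliding-window summary; statistics are NaN when undefined (no SNPs, or
    covered fraction below the analysis threshold)."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    window_size: int
    step: int
    covered: int
    covered_fraction: float
    S: int
    pi: float
    theta_w: float
    tajima_d: float
    usable: bool  # covered_fraction >= min_frac


def site_heterozygosity(site) -> float:
    """Small-sample-corrected heterozygosity of one site.

    h = (M/(M-1)) * (1 - sum_a (c_a/M)^2) over the full base-count vector;
    tri-allelic sites contribute through every allele.  Undefined for M < 2.
    """
    vec = site.count_vector() if hasattr(site, "count_vector") else np.asarray(site)
    M = int(vec.sum())
    if M < 2:
        logger.info("site with depth < 2 skipped in heterozygosity")
        return float("nan")
    freqs = vec / M
    return M / (M - 1) * (1.0 - float(np.square(freqs).sum()))


@lru_cache(maxsize=None)
def _denominators(n: int, M: int, b: int) -> tuple[float, float]:
    m = np.arange(b, M - b + 1)
    h_weight = 2.0 * m * (M - m) / (M * (M - 1.0)) if M > 1 else np.zeros_like(m, float)
    c_pi = 0.0
    c_s = 0.0
    for k in range(1, n):
        pmf = stats.binom.pmf(m, M, k / n)
        c_pi += float(np.dot(pmf, h_weight)) / k
        c_s += float(pmf.sum()) / k
    return c_pi, c_s


def pi_denominator(key: CorrectionKey) -> float:
    """Expected per-theta heterozygosity mass that survives the minor-count
    truncation; divides the summed site heterozygosities."""
    return _denominators(key.n_chrom, key.M, key.b)[0]


def thetaw_denominator(key: CorrectionKey) -> float:
    """Expected per-theta number of *detected* segregating sites; divides the
    SNP count (each SNP contributes 1)."""
    return _denominators(key.n_chrom, key.M, key.b)[1]


def tajima_constants(n_eff: int) -> tuple[float, float, float, float, float, float, float, float]:
    """Tajima's variance constants (a1, a2, b1, b2, c1, c2, e1, e2) at sample
    size ``n_eff``; requires n_eff >= 3 for the variance to be defined."""
    n = n_eff
    if n < 3:
        raise ConfigError(f"n_eff must be >= 3 for Tajima's D, got {n}")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def daf(freqs: Sequence[float], groups: Sequence[str]) -> float:
    """Absolute difference of per-group mean pool allele frequencies.

    ``freqs`` holds one alternative-allele frequency per pool (NaN where the
    pool has no coverage); ``groups`` the matching group labels, exactly two
    distinct.  Returns NaN (and logs) when either group has no covered pool.
    """
    freqs = np.asarray(freqs, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ConfigError(f"daf needs exactly 2 group labels, got {labels}")
    means = []
    for lab in labels:
        vals = freqs[groups == lab]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            logger.info("site skipped: group %r has no covered pools", lab)
            return float("nan")
        means.append(float(vals.mean()))
    return abs(means[0] - means[1])


def window_stats(sites, pool: PoolSpec, *, window: int = 10_000, step: int = 2_000,
                 min_frac: float = 0.5, b: int = 2, genome_length: int | None = None,
                 neff_mode: str = "n_chrom") -> list[WindowStat]:
    """Corrected pi, theta_W and Tajima's D in sliding windows for one pool.

    ``sites`` must be filtered/subsampled and position-sorted.  Windows are
    0-based half-open, laid every ``step`` bp while fully inside the genome
    (length = ``genome_length`` or the last covered position).  Per-bp values
    divide by covered positions; windows with covered fraction below
    ``min_frac`` carry NaN statistics and ``usable=False`` so downstream
    summaries can apply the coverage rule exactly.

    ``neff_mode`` picks the sample size for Tajima's constants: the pool
    chromosome count (``"n_chrom"``, default) or ``min(n_chrom, M)``
    (``"min_nm"``).
    """
    if window <= 0 or step <= 0:
        raise ConfigError(f"window and step must be positive, got {window}/{step}")
    if neff_mode not in ("n_chrom", "min_nm"):
        raise ConfigError(f"unknown neff_mode {neff_mode!r}")
    arr = SiteArray.coerce(sites)
    n = pool.n_chrom
    if len(arr) == 0:
        return []
    if np.any(np.diff(arr.pos) < 0):
        raise ConfigError("sites must be sorted by position")

    depth = arr.depth
    ok = depth >= 2
    sorted_counts = np.sort(arr.counts, axis=1)
    minor = sorted_counts[:, -2]
    is_snp = ok & (minor >= b)

    with np.errstate(invalid="ignore", divide="ignore"):
        freqs_sq = np.square(arr.counts / depth[:, None]).sum(axis=1)
        h = np.where(ok, depth / np.maximum(depth - 1.0, 1.0) * (1.0 - freqs_sq), 0.0)

    pi_contrib = np.zeros(len(arr))
    w_contrib = np.zeros(len(arr))
    for M in np.unique(depth[is_snp]):
        key = CorrectionKey(n, int(M), b)
        c_pi, c_s = pi_denominator(key), thetaw_denominator(key)
        sel = is_snp & (depth == M)
        pi_contrib[sel] = h[sel] / c_pi
        w_contrib[sel] = 1.0 / c_s

    p0 = arr.pos - 1  # 0-based
    L = int(genome_length) if genome_length is not None else int(p0.max()) + 1
    starts = np.arange(0, L - window + 1, step, dtype=np.int64)
    if starts.size == 0:
        return []

    cum_cov = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
    cum_S = np.concatenate([[0], np.cumsum(is_snp.astype(np.int64))])
    cum_pi = np.concatenate([[0.0], np.cumsum(pi_contrib)])
    cum_w = np.concatenate([[0.0], np.cumsum(w_contrib)])
    cum_M = np.concatenate([[0], np.cumsum(np.where(ok, depth, 0))])

    lo = np.searchsorted(p0, starts, side="left")
    hi = np.searchsorted(p0, starts + window, side="left")

    out: list[WindowStat] = []
    const_cache: dict[int, tuple] = {}
    for s, i0, i1 in zip(starts, lo, hi):
        covered = int(cum_cov[i1] - cum_cov[i0])
        frac = covered / window
        S = int(cum_S[i1] - cum_S[i0])
        pi_abs = float(cum_pi[i1] - cum_pi[i0])
        w_abs = float(cum_w[i1] - cum_w[i0])
        usable = frac >= min_frac
        pi = theta_w = tajima_d = float("nan")
        if usable and covered > 0:
            pi = pi_abs / covered
            theta_w = w_abs / covered
            if S >= 1:
                if neff_mode == "n_chrom":
                    n_eff = n
                else:
                    mean_M = (cum_M[i1] - cum_M[i0]) / covered
                    n_eff = min(n, max(int(round(mean_M)), 3))
                if n_eff not in const_cache:
                    const_cache[n_eff] = tajima_constants(n_eff)
                e1, e2 = const_cache[n_eff][6], const_cache[n_eff][7]
                var = e1 * S + e2 * S * (S - 1)
                if var > 0:
                    tajima_d = (pi_abs - w_abs) / math.sqrt(var)
        out.append(WindowStat(
            chrom=arr.chrom, start=int(s), end=int(s + window), window_size=window,
            step=step, covered=covered, covered_fraction=frac, S=S,
            pi=pi, theta_w=theta_w, tajima_d=tajima_d, usable=usable))
    return out


def write_window_tsv(windows: Sequence[WindowStat], path) -> None:
    """Window TSV with BED-compatible coordinates; undefined statistics are
    emitted as explicit ``NA`` tokens, never 0."""

    def fmt(x: float) -> str:
        return "NA" if (x is None or (isinstance(x, float) and math.isnan(x))) else f"{x:.6g}"

    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcovered_fraction\tS\tpi\ttheta_w\ttajima_d\n")
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.covered_fraction:.4f}\t{w.S}\t"
                     f"{fmt(w.pi)}\t{fmt(w.theta_w)}\t{fmt(w.tajima_d)}\n")


def pool_theta_estimates(sites, pool: PoolSpec, b: int = 2) -> tuple[float, float, int]:
    """Whole-input per-bp corrected theta_pi and theta_W for one pool.

    Returns ``(theta_pi, theta_w, covered_sites)``; a convenience wrapper for
    estimator-recovery checks that avoids windowing.
    """
    arr = SiteArray.coerce(sites)
    depth = arr.depth
    ok = depth >= 2
    sorted_counts = np.sort(arr.counts, axis=1)
    is_snp = ok & (sorted_counts[:, -2] >= b)
    covered = int(ok.sum())
    if covered == 0:
        return float("nan"), float("nan"), 0
    pi_sum = 0.0
    w_sum = 0.0
    n = pool.n_chrom
    for M in np.unique(depth[is_snp]):
        key = CorrectionKey(n, int(M), b)
        sel = is_snp & (depth == M)
        freqs_sq = np.square(arr.counts[sel] / M).sum(axis=1)
        h = M / (M - 1.0) * (1.0 - freqs_sq)
        pi_sum += float(h.sum()) / pi_denominator(key)
        w_sum += float(sel.sum()) / thetaw_denominator(key)
    return pi_sum / covered, w_sum / covered, covered
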