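"""Two-group allele-frequency differentiation scan.

Pools are split into two groups (e.g. spring vs autumn spawners); at every
SNP the reads supporting the reference and the alternative allele are summed
within each group and compared with a 2x2 contingency chi-square test
(1 df, no continuity correction — the conventional choice at genome scale).
Significance is controlled by Bonferroni correction over the number of SNPs
actually tested.  A rank-based contrast (Wilcoxon rank-sum) compares per-SNP
or per-window statistics inside a candidate region against the background.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .poolio import BASES, PoolSpec, SiteArray

logger = logging.getLogger(__name__)

#: reason codes for sites excluded from the chi-square test
SKIP_ZERO_MARGINAL = "zero_marginal"
SKIP_NOT_SNP = "not_snp"


def chi2_site(r1: int, a1: int, r2: int, a2: int) -> tuple[float, float]:
    """2x2 contingency chi-square for group-summed read counts.

    chi2 = N (r1*a2 - a1*r2)^2 / ((r1+a1)(r2+a2)(r1+r2)(a1+a2)) with one
    degree of freedom and no continuity correction; p is the upper tail.
    All four marginals must be positive.
    """
    r1, a1, r2, a2 = int(r1), int(a1), int(r2), int(a2)
    if min(r1, a1, r2, a2) < 0:
        raise ConfigError("read counts must be non-negative")
    n = r1 + a1 + r2 + a2
    marg = (r1 + a1, r2 + a2, r1 + r2, a1 + a2)
    if n == 0 or 0 in marg:
        raise ConfigError("chi2_site requires all marginals > 0")
    chi2 = n * (r1 * a2 - a1 * r2) ** 2 / float(np.prod([float(m) for m in marg]))
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class ScanResult:
    """Genome-scan output: one row per tested SNP plus the multiple-testing
    context needed to interpret the ``significant`` flags."""

    records: pd.DataFrame  # chrom,pos,ref,alt,ref_reads_g1,... see genome_scan
    n_tested: int
    alpha: float
    bonferroni_threshold: float
    skipped: pd.DataFrame  # chrom,pos,reason

    def summary(self) -> dict:
        top = self.records.nlargest(min(10, len(self.records)), "neglog10p")
        return {
            "n_tested": self.n_tested,
            "alpha": self.alpha,
            "bonferroni_threshold": self.bonferroni_threshold,
            "n_significant": int(self.records["significant"].sum()),
            "top_hits": top[["chrom", "pos", "neglog10p", "daf"]].to_dict("records"),
        }


def bonferroni_threshold(alpha: float, n_tested: int) -> float:
    if n_tested < 1:
        raise ConfigError("n_tested must be >= 1")
    return alpha / n_tested


def genome_scan(pool_sites: Mapping[str, Sequence], pools: Sequence[PoolSpec],
                alpha: float = 0.05, min_minor: int = 2) -> ScanResult:
    """Run the two-group chi-square scan over per-pool site counts.

    ``pool_sites`` maps pool id to that pool's (filtered) sites; pools are
    grouped by ``PoolSpec.group`` (exactly two labels required).  Per site the
    reference allele is taken from the pileup and the alternative allele is
    the most frequent non-reference base over all pools; only sites whose
    pooled minor count reaches ``min_minor`` are tested.  Sites with a zero
    test marginal are skipped with a reason code rather than raising.  dAF is
    the absolute difference of group-mean per-pool alternative-allele
    frequencies.
    """
    groups = sorted({p.group for p in pools})
    if len(groups) != 2:
        raise ConfigError(f"genome_scan needs exactly 2 groups, got {groups}")
    by_id = {p.pool_id: p for p in pools}
    if set(pool_sites) - set(by_id):
        raise ConfigError("pool_sites contains ids missing from pools")

    arrays = {pid: SiteArray.coerce(s) for pid, s in pool_sites.items()}
    # union of positions (single chromosome assumed, as produced by poolio)
    chroms = {a.chrom for a in arrays.values() if len(a)}
    if len(chroms) > 1:
        raise ConfigError("genome_scan expects sites from a single chromosome")
    chrom = chroms.pop() if chroms else ""

    all_pos = np.unique(np.concatenate([a.pos for a in arrays.values()]))
    n_pos = all_pos.size
    pool_ids = list(arrays)
    # per-pool count matrices aligned on the union of positions
    counts = np.zeros((len(pool_ids), n_pos, 4), dtype=np.int64)
    ref_idx = np.full(n_pos, -1, dtype=np.int8)
    for pi, pid in enumerate(pool_ids):
        a = arrays[pid]
        idx = np.searchsorted(all_pos, a.pos)
        counts[pi, idx] = a.counts
        ref_idx[idx] = a.ref_idx
    total = counts.sum(axis=0)  # n_pos x 4

    # alternative allele: most frequent non-reference base over all pools
    masked = total.copy()
    masked[np.arange(n_pos), ref_idx] = -1
    alt_idx = masked.argmax(axis=1).astype(np.int8)

    sorted_tot = np.sort(total, axis=1)
    is_snp = sorted_tot[:, -2] >= min_minor

    g_of = np.array([groups.index(by_id[pid].group) for pid in pool_ids])
    ref_reads = np.zeros((2, n_pos), dtype=np.int64)
    alt_reads = np.zeros((2, n_pos), dtype=np.int64)
    row = np.arange(n_pos)
    for pi in range(len(pool_ids)):
        g = g_of[pi]
        ref_reads[g] += counts[pi, row, ref_idx]
        alt_reads[g] += counts[pi, row, alt_idx]

    r1, a1 = ref_reads[0], alt_reads[0]
    r2, a2 = ref_reads[1], alt_reads[1]
    n = r1 + a1 + r2 + a2
    marg_ok = ((r1 + a1) > 0) & ((r2 + a2) > 0) & ((r1 + r2) > 0) & ((a1 + a2) > 0)
    tested = is_snp & marg_ok

    with np.errstate(invalid="ignore", divide="ignore"):
        denom = ((r1 + a1) * (r2 + a2)).astype(float) * ((r1 + r2) * (a1 + a2)).astype(float)
        chi2 = np.where(tested, n * (r1 * a2 - a1 * r2).astype(float) ** 2 / np.where(denom > 0, denom, 1.0), np.nan)
    p = stats.chi2.sf(chi2, df=1)

    # per-pool alt frequencies for dAF
    pool_depth = counts[:, row, ref_idx] + counts[:, row, alt_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        pool_freq = np.where(pool_depth > 0, counts[:, row, alt_idx] / pool_depth, np.nan)
    import warnings

    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pool columns
        mean0 = np.nanmean(pool_freq[g_of == 0], axis=0)
        mean1 = np.nanmean(pool_freq[g_of == 1], axis=0)
    daf_vals = np.abs(mean0 - mean1)

    n_tested = int(tested.sum())
    thr = bonferroni_threshold(alpha, max(n_tested, 1))
    with np.errstate(divide="ignore"):
        neglog = -np.log10(np.where(p > 0, p, np.nextafter(0, 1)))

    records = pd.DataFrame({
        "chrom": chrom, "pos": all_pos[tested],
        "ref": np.array(list(BASES))[ref_idx[tested]],
        "alt": np.array(list(BASES))[alt_idx[tested]],
        "ref_reads_g1": r1[tested], "alt_reads_g1": a1[tested],
        "ref_reads_g2": r2[tested], "alt_reads_g2": a2[tested],
        "chi2": chi2[tested], "p": p[tested], "neglog10p": neglog[tested],
        "daf": daf_vals[tested],
        "significant": p[tested] < thr,
    })
    skipped = pd.DataFrame({
        "chrom": chrom, "pos": all_pos[is_snp & ~marg_ok],
        "reason": SKIP_ZERO_MARGINAL,
    })
    if len(skipped):
        logger.info("%d SNP sites skipped (%s)", len(skipped), SKIP_ZERO_MARGINAL)
    return ScanResult(records=records, n_tested=n_tested, alpha=alpha,
                      bonferroni_threshold=thr, skipped=skipped)


def exact_ranksum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Exact Wilcoxon rank-sum p by full enumeration of rank assignments.

    Uses midranks, so ties are handled exactly; feasible for small samples
    (C(n1+n2, n1) assignments).  Returns (U of x, p).
    """
    from itertools import combinations

    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n_total = 0
    n_le = n_ge = n_extreme = 0
    eps = 1e-12
    for idx in combinations(range(n1 + n2), n1):
        u = float(ranks[list(idx)].sum()) - n1 * (n1 + 1) / 2.0
        n_total += 1
        if u <= u_obs + eps:
            n_le += 1
        if u >= u_obs - eps:
            n_ge += 1
        if abs(u - mu) >= abs(u_obs - mu) - eps:
            n_extreme += 1
    if alternative == "less":
        p = n_le / n_total
    elif alternative == "greater":
        p = n_ge / n_total
    elif alternative == "two-sided":
        p = n_extreme / n_total
    else:
        raise ConfigError(f"unknown alternative {alternative!r}")
    return u_obs, min(p, 1.0)


def region_contrast(values_inside: Sequence[float], values_outside: Sequence[float],
                    alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum contrast of a statistic inside vs outside a region.

    Exact enumeration (midranks, so ties are exact) when both samples have
    size <= 10; otherwise the normal approximation with tie correction.
    Returns the Mann-Whitney U of the inside sample and the p-value.
    """
    x = np.asarray(list(values_inside), dtype=float)
    y = np.asarray(list(values_outside), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigError("region_contrast requires non-empty samples on both sides")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # degenerate all-tied case
        return float(x.size * y.size / 2.0), 1.0
    if x.size <= 10 and y.size <= 10:
        return exact_ranksum(x, y, alternative)
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def write_scan_outputs(result: ScanResult, tsv_path, json_path=None) -> None:
    result.records.to_csv(tsv_path, sep="\t", index=False, na_rep="NA")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(result.summary(), fh, indent=2, default=float)
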