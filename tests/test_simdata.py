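"""Synthetic-data generators: determinism, truth consistency, calibration."""

import numpy as np
import pytest

from poolscan import ConfigError, structvar as sv
from poolscan import poolio as po
from poolscan import simdata as sd


class TestSpectrumPool:
    def test_theta_zero_no_segregating_sites(self):
        cfg = sd.SpectrumSimConfig(theta=0.0, n_sites=5_000, seed=1)
        sites, truth = sd.simulate_spectrum_pool(cfg)
        assert len(truth.table) == 0
        assert np.all(sites.counts.sum(axis=1) == sites.depth)

    def test_deterministic_given_seed(self):
        cfg = sd.SpectrumSimConfig(n_sites=3_000, seed=7)
        s1, t1 = sd.simulate_spectrum_pool(cfg)
        s2, t2 = sd.simulate_spectrum_pool(cfg)
        assert np.array_equal(s1.counts, s2.counts)
        assert np.array_equal(s1.pos, s2.pos)
        assert t1.table.equals(t2.table)

    def test_different_seed_differs(self):
        a, _ = sd.simulate_spectrum_pool(sd.SpectrumSimConfig(n_sites=3_000, seed=1))
        b, _ = sd.simulate_spectrum_pool(sd.SpectrumSimConfig(n_sites=3_000, seed=2))
        assert not np.array_equal(a.counts, b.counts)

    def test_truth_segregating_sites_have_alt_reads_without_error(self):
        cfg = sd.SpectrumSimConfig(theta=0.01, n_chrom=10, mean_depth=80,
                                   seq_error=0.0, n_sites=20_000, seed=3)
        sites, truth = sd.simulate_spectrum_pool(cfg)
        by_pos = {int(p): i for i, p in enumerate(sites.pos)}
        # high-frequency planted sites (k >= 3 of 10) are visible in the reads
        strong = truth.table[truth.table.k >= 3]
        seen = 0
        for row in strong.itertuples():
            i = by_pos.get(row.pos)
            if i is None:
                continue
            alt_col = po.BASES.index(row.alt)
            seen += sites.counts[i, alt_col] > 0
        assert seen / len(strong) > 0.95

    @pytest.mark.parametrize("kwargs,field", [
        (dict(n_chrom=1), "n_chrom"),
        (dict(theta=-0.1), "theta"),
        (dict(theta=0.5), "theta"),          # theta * a1 >= 1
        (dict(mean_depth=0), "mean_depth"),
        (dict(seq_error=1.5), "seq_error"),
    ])
    def test_config_errors_name_the_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            sd.SpectrumSimConfig(**kwargs)


class TestTwoGroupScan:
    def small_cfg(self, **kw):
        pools = tuple(sd.default_pools(n_per_group=2, n_diploids=30))
        base = dict(pools=pools, genome_length=20_000,
                    background=sd.SpectrumSimConfig(theta=0.005, n_chrom=60,
                                                    mean_depth=30, seq_error=0.0,
                                                    n_sites=1),
                    divergent_region=(5_000, 15_000), n_divergent_snps=10, seed=9)
        base.update(kw)
        return sd.TwoGroupSimConfig(**base)

    def test_pileup_files_deterministic_and_parseable(self, tmp_path):
        cfg = self.small_cfg()
        r1 = sd.simulate_two_group_scan(cfg, outdir=tmp_path / "a")
        r2 = sd.simulate_two_group_scan(cfg, outdir=tmp_path / "b")
        f1 = (tmp_path / "a" / "spring1.pileup").read_bytes()
        f2 = (tmp_path / "b" / "spring1.pileup").read_bytes()
        assert f1 == f2  # byte-identical given config + seed
        parsed = po.read_mpileup(tmp_path / "a" / "spring1.pileup")
        arr = po.SiteArray.from_sites(parsed)
        orig = r1.pool_sites["spring1"]
        assert np.array_equal(arr.counts, orig.counts)

    def test_truth_lists_all_planted_snps_within_region(self, tmp_path):
        cfg = self.small_cfg()
        res = sd.simulate_two_group_scan(cfg, outdir=tmp_path)
        assert len(res.truth) == 10
        s, e = cfg.divergent_region
        assert res.truth.pos.between(s + 1, e).all()
        # truth file roundtrip: planted features recoverable by coordinate lookup
        import pandas as pd
        back = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert set(back.pos) == set(res.truth.pos)

    def test_identical_group_freqs_zero_true_daf(self):
        cfg = self.small_cfg(freq_group1=0.4, freq_group2=0.4)
        res = sd.simulate_two_group_scan(cfg)
        assert (res.truth.daf_true == 0).all()

    def test_adding_a_pool_does_not_perturb_existing_streams(self):
        cfg14 = self.small_cfg()
        pools_extra = tuple(list(cfg14.pools)
                            + [po.PoolSpec("extra", "spring", 30)])
        cfg15 = self.small_cfg(pools=pools_extra)
        r14 = sd.simulate_two_group_scan(cfg14)
        r15 = sd.simulate_two_group_scan(cfg15)
        assert np.array_equal(r14.pool_sites["autumn2"].counts,
                              r15.pool_sites["autumn2"].counts)

    def test_frequency_calibration_three_se(self):
        """Mean observed pool alt-read fraction at planted sites within 3
        standard errors of the population frequency, over >= 1e4 sites."""
        pools = tuple(sd.default_pools(n_per_group=1, n_diploids=50))
        cfg = sd.TwoGroupSimConfig(
            pools=pools, genome_length=60_000,
            background=sd.SpectrumSimConfig(theta=0.0, n_chrom=100,
                                            mean_depth=60, seq_error=0.0, n_sites=1),
            divergent_region=(0, 60_000), n_divergent_snps=12_000,
            freq_group1=0.7, freq_group2=0.3, seed=11)
        res = sd.simulate_two_group_scan(cfg)
        arr = res.pool_sites["spring1"]
        idx = {int(p): i for i, p in enumerate(arr.pos)}
        fracs = []
        for row in res.truth.itertuples():
            i = idx.get(row.pos)
            if i is None:
                continue
            alt_col = po.BASES.index(row.alt)
            depth = arr.counts[i].sum()
            fracs.append(arr.counts[i, alt_col] / depth)
        fracs = np.asarray(fracs)
        assert fracs.size >= 10_000
        se = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert abs(fracs.mean() - 0.7) < 3 * se

    def test_region_outside_genome_rejected(self):
        with pytest.raises(ConfigError):
            self.small_cfg(divergent_region=(10_000, 30_000))


class TestLocusSequences:
    def test_truth_coordinates_extract_planted_features(self, locus):
        cfg, records, truth = locus
        hapS, hapA, outg = (str(r.seq) for r in records)
        assert hapS[slice(*truth.ltr_left)] == truth.ltr_left_seq
        assert hapS[slice(*truth.ltr_right)] == truth.ltr_right_seq
        assert hapA[slice(*truth.solo_ltr)] == truth.solo_seq
        mism, _ = sv.hamming_divergence(truth.ltr_left_seq, truth.ltr_right_seq)
        assert mism == cfg.ltr_mismatches
        # repeat regions carry the configured copy numbers
        sS = hapS[slice(*truth.repeat_region_S)]
        assert sS == truth.repeat_unit * cfg.copies_hapS
        sA = hapA[slice(*truth.repeat_region_A)]
        assert sA == truth.repeat_unit * cfg.copies_hapA

    def test_indel_between_haplotypes_is_insertion_size(self, locus):
        cfg, records, truth = locus
        diff = len(records[0].seq) - len(records[1].seq)
        repeat_diff = (cfg.copies_hapS - cfg.copies_hapA) * cfg.repeat_unit_length
        assert diff - repeat_diff == cfg.internal_length + cfg.ltr_length  # ~5.2 kb

    def test_solo_distances_by_construction(self, locus):
        cfg, _, truth = locus
        origin, d_left, d_right = sv.classify_solo_origin(
            truth.solo_seq, truth.ltr_left_seq, truth.ltr_right_seq)
        assert origin == cfg.solo_origin == "right"
        assert d_right == cfg.solo_vs_origin_mismatches
        assert d_left == cfg.ltr_mismatches + cfg.solo_vs_origin_mismatches

    def test_left_origin_variant(self):
        cfg = sd.LocusSimConfig(solo_origin="left", seed=5)
        _, truth = sd.simulate_locus_sequences(cfg)
        origin, d_left, d_right = sv.classify_solo_origin(
            truth.solo_seq, truth.ltr_left_seq, truth.ltr_right_seq)
        assert origin == "left" and d_left == 1 and d_right == 5

    def test_outgroup_ltrs_identical(self, locus):
        _, records, _ = locus
        pairs = sv.find_direct_repeats(str(records[2].seq))
        assert len(pairs) == 1 and pairs[0].mismatches == 0

    def test_deterministic(self):
        cfg = sd.LocusSimConfig(seed=13)
        r1, _ = sd.simulate_locus_sequences(cfg)
        r2, _ = sd.simulate_locus_sequences(cfg)
        assert all(str(a.seq) == str(b.seq) for a, b in zip(r1, r2))

    def test_excessive_mismatches_rejected(self):
        with pytest.raises(ConfigError):
            sd.LocusSimConfig(ltr_mismatches=471)
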