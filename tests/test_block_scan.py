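"""Outlier-block and ancestry-desert detection on admixture profiles."""

import numpy as np
import pytest

from introscan import (
    block_size,
    chromosome_stats,
    detect_ancestry_deserts,
    detect_outlier_blocks,
    snp_admixture_profile,
    summarize_blocks,
)
from introscan.block_scan import SNPAdmixtureProfile
from introscan.datasets import reference_blocks_as_records
from introscan.types import AncestryDosageMatrix, GeneAnnotation


def make_profile(values, chrom=None):
    values = np.asarray(values, dtype=float)
    if chrom is None:
        chrom = np.full(len(values), "chr1", dtype=object)
    return SNPAdmixtureProfile(
        chrom=np.asarray(chrom, dtype=object),
        pos_bp=np.arange(1, len(values) + 1) * 1000,
        admix_prop=values,
        n_individuals=10,
    )


class TestProfile:
    def test_single_individual_dosage_halved(self):
        mat = AncestryDosageMatrix(
            chrom=np.array(["chr1"] * 3, dtype=object),
            pos_bp=np.array([10, 20, 30]),
            dosage=np.array([[0.0, 1.0, 2.0]]),
            individual_ids=["a"],
        )
        prof = snp_admixture_profile(mat)
        np.testing.assert_allclose(prof.admix_prop, [0.0, 0.5, 1.0])

    def test_mean_over_individuals(self):
        mat = AncestryDosageMatrix(
            chrom=np.array(["chr1"], dtype=object),
            pos_bp=np.array([10]),
            dosage=np.array([[2.0], [0.0]]),
            individual_ids=["a", "b"],
        )
        assert snp_admixture_profile(mat).admix_prop[0] == 0.5

    def test_matches_brute_force_mean(self, rng):
        dosage = rng.uniform(0, 2, size=(5, 8))
        mat = AncestryDosageMatrix(
            chrom=np.array(["chr1"] * 8, dtype=object),
            pos_bp=np.arange(1, 9) * 100,
            dosage=dosage,
            individual_ids=[f"i{k}" for k in range(5)],
        )
        ids = ["i1", "i3", "i4"]
        prof = snp_admixture_profile(mat, admixed_ids=ids)
        expected = dosage[[1, 3, 4]].mean(axis=0) / 2
        np.testing.assert_allclose(prof.admix_prop, expected)
        assert prof.n_individuals == 3

    def test_empty_id_set_rejected(self):
        mat = AncestryDosageMatrix(
            chrom=np.array(["chr1"], dtype=object),
            pos_bp=np.array([10]),
            dosage=np.array([[1.0]]),
            individual_ids=["a"],
        )
        with pytest.raises(ValueError):
            snp_admixture_profile(mat, admixed_ids=[])


class TestChromStats:
    def test_constant_profile(self):
        stats = chromosome_stats(make_profile([0.03] * 20))
        m, sd, n = stats.per_chrom["chr1"]
        assert m == pytest.approx(0.03)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert n == 20

    def test_two_point(self):
        stats = chromosome_stats(make_profile([0.0, 1.0]))
        m, sd, _ = stats.per_chrom["chr1"]
        assert m == 0.5 and sd == 0.5  # population SD

    def test_global_sd_exceeds_mean_within_chrom_sd(self):
        """Shifted per-chromosome means inflate the global SD above the mean
        of the within-chromosome SDs (the pattern that makes a global
        threshold miss local outliers)."""
        rng = np.random.default_rng(0)
        vals, chroms = [], []
        for i, centre in enumerate([0.02, 0.2, 0.5]):
            vals.append(np.clip(centre + rng.normal(0, 0.01, 50), 0, 1))
            chroms.append(np.full(50, f"chr{i + 1}", dtype=object))
        prof = make_profile(np.concatenate(vals), np.concatenate(chroms))
        stats = chromosome_stats(prof)
        mean_within = np.mean([sd for _, sd, _ in stats.per_chrom.values()])
        assert stats.global_sd > mean_within

    def test_single_snp_chromosome_excluded(self):
        prof = make_profile([0.1, 0.2, 0.3], chrom=["chr1", "chr1", "chr2"])
        with pytest.warns(UserWarning):
            stats = chromosome_stats(prof)
        assert "chr2" not in stats.per_chrom
        assert stats.n_snps == 2


class TestOutlierBlocks:
    def background(self, rng, n=500):
        return np.clip(rng.normal(0.03, 0.005, n), 0, 1)

    def test_all_below_threshold_empty(self, rng):
        prof = make_profile(self.background(rng))
        assert detect_outlier_blocks(prof) == []

    def test_planted_12_snp_run_detected(self, rng):
        vals = self.background(rng)
        base = chromosome_stats(make_profile(vals))
        m, sd, _ = base.per_chrom["chr1"]
        vals[100:112] = m + 5 * sd
        prof = make_profile(vals)
        blocks = detect_outlier_blocks(prof)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.n_snps == 12
        assert (b.start_idx, b.end_idx) == (100, 111)
        # every member SNP satisfies the inequality under the final stats
        stats = chromosome_stats(prof)
        m2, sd2, _ = stats.per_chrom["chr1"]
        assert (prof.admix_prop[100:112] > m2 + 3 * sd2).all()

    def test_9_snp_run_below_min_discarded(self, rng):
        vals = self.background(rng)
        base = chromosome_stats(make_profile(vals))
        m, sd, _ = base.per_chrom["chr1"]
        vals[100:109] = m + 5 * sd
        assert detect_outlier_blocks(make_profile(vals), min_snps=10) == []

    def test_completeness_exhaustive(self, rng):
        """Every qualifying run is reported; every reported SNP qualifies."""
        vals = self.background(rng, 200)
        vals[20:35] = 0.2
        vals[50:61] = 0.2
        vals[100:105] = 0.2  # too short
        prof = make_profile(vals)
        stats = chromosome_stats(prof)
        m, sd, _ = stats.per_chrom["chr1"]
        mask = prof.admix_prop > m + 3 * sd
        blocks = detect_outlier_blocks(prof, stats)
        covered = np.zeros(200, dtype=bool)
        for b in blocks:
            assert b.n_snps >= 10
            assert mask[b.start_idx : b.end_idx + 1].all()
            covered[b.start_idx : b.end_idx + 1] = True
        # any uncovered qualifying run must be shorter than min_snps
        run = 0
        for i in range(200):
            run = run + 1 if mask[i] and not covered[i] else 0
            assert run < 10

    def test_invariant_to_padding(self, rng):
        vals = self.background(rng, 300)
        vals[100:115] = 0.5
        prof = make_profile(vals)
        blocks = detect_outlier_blocks(prof)
        padded = make_profile(np.concatenate([[0.03] * 5, vals, [0.03] * 5]))
        blocks_p = detect_outlier_blocks(padded)
        assert len(blocks) == len(blocks_p) == 1
        assert blocks_p[0].start_idx == blocks[0].start_idx + 5
        assert blocks_p[0].n_snps == blocks[0].n_snps

    def test_neutral_iid_noise_rarely_triggers(self):
        total = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            prof = make_profile(np.clip(r.normal(0.03, 0.01, 1000), 0, 1))
            total += len(detect_outlier_blocks(prof))
        assert total <= 2

    def test_global_scope_uses_global_stats(self, rng):
        # chr2 carries a 20-SNP elevated run: too mild for its own inflated
        # per-chromosome SD, but an outlier against the global spread
        vals1 = np.clip(rng.normal(0.02, 0.001, 900), 0, 1)
        vals2 = np.clip(rng.normal(0.02, 0.001, 100), 0, 1)
        vals2[40:60] = 0.30
        prof = make_profile(
            np.concatenate([vals1, vals2]),
            np.concatenate([np.full(900, "chr1", object), np.full(100, "chr2", object)]),
        )
        assert detect_outlier_blocks(prof, scope="per_chromosome") == []
        g = detect_outlier_blocks(prof, scope="global")
        assert len(g) == 1 and g[0].chrom == "chr2" and g[0].n_snps == 20


class TestDeserts:
    def test_all_zero_single_desert(self):
        prof = make_profile(np.zeros(38))
        deserts = detect_ancestry_deserts(prof)
        assert len(deserts) == 1
        assert deserts[0].n_snps == 38
        assert deserts[0].block_type == "desert"

    def test_uniform_above_threshold_empty(self):
        assert detect_ancestry_deserts(make_profile([0.05] * 50)) == []

    def test_planted_zero_run(self, rng):
        vals = np.full(200, 0.05)
        vals[60:75] = 0.0
        deserts = detect_ancestry_deserts(make_profile(vals))
        assert len(deserts) == 1 and deserts[0].n_snps == 15

    def test_sd_below_mode(self, rng):
        vals = np.clip(rng.normal(0.5, 0.01, 300), 0, 1)
        vals[40:55] = 0.0
        deserts = detect_ancestry_deserts(make_profile(vals), mode="sd_below")
        assert len(deserts) == 1 and deserts[0].n_snps == 15


class TestBlockSize:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(118527129, 118918741, 391_612), (108262, 4593585, 4_485_323), (100, 101, 1)],
    )
    def test_examples(self, start, end, expected):
        assert block_size(start, end) == expected

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            block_size(10, 10)


class TestSummaries:
    def test_reference_wolf_means(self):
        df = summarize_blocks(reference_blocks_as_records("wolf"))
        mean = df[df["chrom"] == "Mean"].iloc[0]
        assert round(mean["size_bp"]) == 818_737
        assert round(mean["mean_ancestry"], 3) == 0.098
        # 580/16 = 36.25, printed as 36.3 under half-up rounding
        assert mean["n_snps"] == pytest.approx(36.25)

    def test_reference_frd_means(self):
        df = summarize_blocks(reference_blocks_as_records("frd"))
        mean = df[df["chrom"] == "Mean"].iloc[0]
        assert round(mean["size_bp"]) == 1_918_537
        assert round(mean["mean_ancestry"], 3) == 0.106

    def test_gene_overlap_rule(self):
        from introscan.types import AncestryBlock

        block = AncestryBlock("chr1", 1000, 2000, 12, 0.1)
        genes = [
            GeneAnnotation("inside", "chr1", 1200, 1400),
            GeneAnnotation("edge", "chr1", 2000, 3000),  # 1 bp overlap
            GeneAnnotation("outside", "chr1", 2001, 3000),
            GeneAnnotation("other_chrom", "chr2", 1000, 2000),
        ]
        df = summarize_blocks([block], genes=genes)
        assert df.iloc[0]["n_genes"] == 2
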