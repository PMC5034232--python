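"""Target design and capture-performance metrics."""

import numpy as np
import pytest

from primex.capture import (
    DepthProfile,
    build_target_regions,
    depth_distribution_stats,
    gene_coverage,
    merge_orthologous_targets,
    platform_discordance,
    replicate_reproducibility,
    saturation_curve,
)
from primex.io import GenomicInterval


class TestMergeOrthologousTargets:
    def test_identical_pair_merges(self):
        (t,) = merge_orthologous_targets([("r1", "ACGT" * 75, "ACGT" * 75)])
        assert t.merged and len(t.sequence) == 300

    def test_two_mismatches_merge(self):
        a = "A" * 300
        b = "C" + "A" * 298 + "C"
        (t,) = merge_orthologous_targets([("r1", a, b)])
        assert t.merged and t.sequence == a  # first genome is representative

    def test_three_mismatches_stay_separate(self):
        a = "A" * 300
        b = "CCC" + "A" * 297
        targets = merge_orthologous_targets([("r1", a, b)])
        assert len(targets) == 2 and not any(t.merged for t in targets)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            merge_orthologous_targets([("r1", "AAAA", "AAA")])


class TestBuildTargetRegions:
    def test_single_cds_gains_both_flanks(self):
        regions = build_target_regions([GenomicInterval("chr1", 1000, 1500)], flank=100)
        (iv,) = regions.intervals
        assert (iv.start, iv.end) == (900, 1600)
        assert regions.total_length == 700

    def test_nearby_targets_merge_through_flanks(self):
        targets = [GenomicInterval("chr1", 1000, 1100), GenomicInterval("chr1", 1150, 1250)]
        regions = build_target_regions(targets, flank=100)
        assert len(regions.intervals) == 1
        assert regions.total_length == (1250 + 100) - (1000 - 100)

    def test_clipping_at_chromosome_start(self):
        regions = build_target_regions([GenomicInterval("chr1", 30, 130)], flank=100)
        assert regions.intervals[0].start == 0

    def test_order_invariance_and_idempotence(self):
        targets = [
            GenomicInterval("chr2", 5000, 5200),
            GenomicInterval("chr1", 1000, 1100),
            GenomicInterval("chr1", 1150, 1250),
        ]
        fwd = build_target_regions(targets, flank=100)
        rev = build_target_regions(targets[::-1], flank=100)
        assert fwd.intervals == rev.intervals
        again = build_target_regions(fwd.intervals, flank=0)
        assert again.intervals == fwd.intervals

    def test_theoretical_coverage_is_one_for_self_targets(self):
        targets = [GenomicInterval("chr1", 100, 400), GenomicInterval("chr1", 600, 900)]
        regions = build_target_regions(targets, flank=100)
        assert regions.theoretical_coverage == 1.0
        assert regions.source_exonic_length == 600

    def test_outside_genome_extent_rejected(self):
        with pytest.raises(ValueError, match="outside genome extent"):
            build_target_regions([GenomicInterval("chr1", 0, 2000)],
                                 genome_extent={"chr1": 1000})


class TestGeneCoverage:
    def test_full_coverage_successful(self):
        stat = gene_coverage(DepthProfile("g", np.full(100, 25)))
        assert stat.coverage_fraction == 1.0 and stat.classification == "successful"

    def test_threshold_is_strict_at_twenty(self):
        depths = np.array([19] * 50 + [21] * 50)
        stat = gene_coverage(DepthProfile("g", depths))
        assert stat.coverage_fraction == 0.5 and stat.classification == "intermediate"
        assert gene_coverage(DepthProfile("g", np.full(10, 20))).coverage_fraction == 1.0

    def test_low_coverage_failed(self):
        depths = np.array([25] * 15 + [0] * 85)
        assert gene_coverage(DepthProfile("g", depths)).classification == "failed"

    def test_boundaries_are_intermediate(self):
        exactly_20 = np.array([25] * 20 + [0] * 80)
        exactly_80 = np.array([25] * 80 + [0] * 20)
        assert gene_coverage(DepthProfile("g", exactly_20)).classification == "intermediate"
        assert gene_coverage(DepthProfile("g", exactly_80)).classification == "intermediate"

    def test_matches_brute_force_counting(self, rng):
        for _ in range(10):
            depths = rng.integers(0, 60, size=200)
            stat = gene_coverage(DepthProfile("g", depths), depth_threshold=20)
            oracle = sum(1 for d in depths if d >= 20) / 200
            assert stat.coverage_fraction == pytest.approx(oracle)


class TestPlatformDiscordance:
    def _stats(self, fractions):
        return {
            g: gene_coverage(DepthProfile(g, np.array([25 if i < f * 100 else 0
                                                       for i in range(100)])))
            for g, f in fractions.items()
        }

    def test_identical_platforms_no_discordance(self):
        s = self._stats({"g1": 0.9, "g2": 0.1})
        assert platform_discordance(s, s)[:2] == (0, 0)

    def test_one_directional_discordance(self):
        a = self._stats({"g1": 0.9, "g2": 0.5})
        b = self._stats({"g1": 0.1, "g2": 0.5})
        n_ab, n_ba, genes_ab, genes_ba = platform_discordance(a, b)
        assert (n_ab, n_ba) == (1, 0) and genes_ab == ["g1"]
        # symmetric under swap
        assert platform_discordance(b, a)[:2] == (0, 1)

    def test_universe_mismatch_rejected(self):
        a = self._stats({"g1": 0.9})
        b = self._stats({"g2": 0.9})
        with pytest.raises(ValueError, match="universe"):
            platform_discordance(a, b)


class TestSaturationCurve:
    def test_full_fraction_reproduces_direct_computation(self, rng):
        profiles = {f"g{i}": DepthProfile(f"g{i}", rng.integers(0, 80, 300))
                    for i in range(5)}
        rows = saturation_curve(profiles, [1.0], seed=0)
        all_depths = np.concatenate([p.depths for p in profiles.values()])
        assert rows[0]["coverage_at_1x"] == pytest.approx(np.mean(all_depths >= 1))
        assert rows[0]["coverage_at_20x"] == pytest.approx(np.mean(all_depths >= 20))

    def test_coverage_vanishes_at_tiny_fraction(self, rng):
        profiles = {"g": DepthProfile("g", rng.integers(10, 40, 2000))}
        rows = saturation_curve(profiles, [0.001], seed=1)
        assert rows[0]["coverage_at_20x"] == 0.0
        assert rows[0]["coverage_at_1x"] < 0.1

    def test_one_read_curve_dominates_twenty_read_curve(self, rng):
        profiles = {"g": DepthProfile("g", rng.integers(0, 120, 5000))}
        rows = saturation_curve(profiles, [0.1, 0.3, 0.5, 0.8, 1.0], seed=2)
        for row in rows:
            assert row["coverage_at_1x"] >= row["coverage_at_20x"]

    def test_monotone_in_effort_within_noise(self, rng):
        """cov@20x rises with effort; allow <= 1% adjacent-bin violations."""
        depths = rng.poisson(100, size=20000)
        profiles = {"g": DepthProfile("g", depths)}
        fractions = list(np.linspace(0.02, 1.0, 50))
        rows = saturation_curve(profiles, fractions, seed=3)
        cov = [r["coverage_at_20x"] for r in rows]
        violations = sum(1 for a, b in zip(cov, cov[1:]) if b < a - 1e-9)
        assert violations <= 1


class TestReproducibility:
    def test_identical_replicates_r_one(self):
        cov = {"r1": {"g1": 0.5, "g2": 0.9, "g3": 0.2},
               "r2": {"g1": 0.5, "g2": 0.9, "g3": 0.2}}
        R, mean_r, _, _ = replicate_reproducibility(cov)
        assert mean_r == pytest.approx(1.0)

    def test_anticorrelated_replicate(self):
        g = {f"g{i}": v for i, v in enumerate([0.1, 0.5, 0.9])}
        flipped = {k: 1.0 - v for k, v in g.items()}
        R, mean_r, _, _ = replicate_reproducibility({"a": g, "b": flipped})
        assert mean_r == pytest.approx(-1.0)

    def test_zero_variance_replicate_reported_missing(self):
        cov = {"a": {"g1": 0.5, "g2": 0.5}, "b": {"g1": 0.2, "g2": 0.9}}
        R, mean_r, sd_r, names = replicate_reproducibility(cov)
        assert np.isnan(R[0, 1]) and np.isnan(mean_r)

    def test_noisy_replicates_of_shared_truth_highly_correlated(self, rng):
        """Replicates = truth + 5%-of-mean noise on 1000 genes: mean r > 0.97."""
        truth = rng.uniform(0.2, 1.0, size=1000)
        noise_sd = 0.05 * truth.mean()
        cov = {
            f"rep{k}": {f"g{i}": float(np.clip(truth[i] + rng.normal(0, noise_sd), 0, 1))
                        for i in range(1000)}
            for k in range(4)
        }
        _, mean_r, sd_r, _ = replicate_reproducibility(cov)
        assert mean_r > 0.97


class TestDepthDistributionStats:
    def test_constant_depth(self):
        summary, _ = depth_distribution_stats(
            {"chr1": [DepthProfile("g", np.full(50, 30))]}
        )
        assert summary["chr1"]["mean"] == 30 and summary["chr1"]["median"] == 30

    def test_skewed_depths(self):
        summary, hist = depth_distribution_stats(
            {"chr1": [DepthProfile("g", np.array([1, 2, 3, 4, 100]))]}
        )
        assert summary["chr1"]["median"] == 3 and summary["chr1"]["mean"] == 22
        assert hist[100] == 1
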