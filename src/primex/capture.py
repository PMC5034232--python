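"""Capture-design computation and capture-performance metrics.

Design side: orthologous CDS region pairs are merged into a single probe
target when fewer than 3 bases mismatch; merged targets are extended by a
100 bp flank on both sides and overlapping extensions merged into the final
target-region set.

Evaluation side: "gene coverage" is the fraction of a gene's coding bases
sequenced to at least 20 reads; a gene is failed below 20% coverage,
successful above 80%, intermediate otherwise.  On top of that sit platform
discordance counts, coverage-vs-effort saturation curves (by binomial
thinning of per-base depths), replicate reproducibility (Pearson r), and
per-chromosome depth summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GenomicInterval


# ---------------------------------------------------------------------------
# target design


@dataclass
class MergedTarget:
    """A designed capture target: representative sequence plus origin."""

    target_id: str
    sequence: str
    merged: bool  # True when one probe covers both genomes' regions


def merge_orthologous_targets(
    cds_pairs: list[tuple[str, str, str]], max_mismatch: int = 2
) -> list[MergedTarget]:
    """Merge aligned orthologous CDS region pairs into probe targets.

    Each pair is (region_id, seq_a, seq_b): equal-length, gap-free aligned
    regions from the two genomes.  A pair collapses to one target
    (representative: the first genome's sequence) when its mismatch count is
    <= max_mismatch (default 2, i.e. "fewer than 3"); otherwise both regions
    are emitted separately.
    """
    targets = []
    for region_id, seq_a, seq_b in cds_pairs:
        if len(seq_a) != len(seq_b):
            raise ValueError(f"{region_id}: aligned pair has unequal lengths")
        mismatches = sum(a != b for a, b in zip(seq_a.upper(), seq_b.upper()))
        if mismatches <= max_mismatch:
            targets.append(MergedTarget(target_id=region_id, sequence=seq_a, merged=True))
        else:
            targets.append(MergedTarget(f"{region_id}_a", seq_a, merged=False))
            targets.append(MergedTarget(f"{region_id}_b", seq_b, merged=False))
    return targets


@dataclass
class TargetRegionSet:
    """Final designed capture intervals plus design bookkeeping."""

    intervals: list[GenomicInterval]
    total_length: int
    source_exonic_length: int
    theoretical_coverage: float


def _merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def build_target_regions(
    targets: list[GenomicInterval],
    flank: int = 100,
    genome_extent: dict[str, int] | None = None,
) -> TargetRegionSet:
    """Extend targets by a flank, clip at chromosome bounds, and merge.

    ``genome_extent`` maps chromosome name to length; extensions are clipped
    to [0, length).  Theoretical coverage is the fraction of the input
    exonic bases contained in the final intervals (1.0 by construction when
    the targets are the exons themselves).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    extended = []
    for iv in targets:
        limit = (genome_extent or {}).get(iv.chrom)
        if limit is not None and iv.end > limit:
            raise ValueError(f"target {iv.chrom}:{iv.start}-{iv.end} outside genome extent")
        start = max(0, iv.start - flank)
        end = iv.end + flank if limit is None else min(limit, iv.end + flank)
        extended.append(GenomicInterval(iv.chrom, start, end))
    merged = _merge_intervals(extended)
    total = sum(len(iv) for iv in merged)
    source = _merge_intervals(targets)
    source_len = sum(len(iv) for iv in source)
    covered = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for iv in source:
        for m in by_chrom.get(iv.chrom, []):
            covered += max(0, min(iv.end, m.end) - max(iv.start, m.start))
    coverage = covered / source_len if source_len else 0.0
    return TargetRegionSet(
        intervals=merged,
        total_length=total,
        source_exonic_length=source_len,
        theoretical_coverage=coverage,
    )


# ---------------------------------------------------------------------------
# coverage metrics


@dataclass
class DepthProfile:
    """Integer read depth at every coding base of one gene."""

    gene_id: str
    depths: np.ndarray

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.ndim != 1 or self.depths.size == 0:
            raise ValueError("depth profile must be a non-empty 1-D array")
        if np.any(self.depths < 0):
            raise ValueError("depths must be >= 0")


@dataclass
class GeneCoverageStat:
    gene_id: str
    coverage_fraction: float
    depth_threshold: int
    classification: str  # failed | intermediate | successful


def gene_coverage(
    profile: DepthProfile,
    depth_threshold: int = 20,
    failed_below: float = 0.20,
    success_above: float = 0.80,
) -> GeneCoverageStat:
    """Fraction of coding bases at depth >= threshold, plus its class.

    Boundaries are strict: exactly 20% or 80% coverage is intermediate.
    """
    frac = float(np.mean(profile.depths >= depth_threshold))
    if frac < failed_below:
        cls = "failed"
    elif frac > success_above:
        cls = "successful"
    else:
        cls = "intermediate"
    return GeneCoverageStat(
        gene_id=profile.gene_id,
        coverage_fraction=frac,
        depth_threshold=depth_threshold,
        classification=cls,
    )


def platform_discordance(
    stats_a: dict[str, GeneCoverageStat], stats_b: dict[str, GeneCoverageStat]
) -> tuple[int, int, list[str], list[str]]:
    """Genes successful on one platform but failed on the other.

    Returns (n successful-in-A-failed-in-B, n successful-in-B-failed-in-A,
    and the two gene lists).  Swapping the inputs swaps the two directions.
    """
    if set(stats_a) != set(stats_b):
        raise ValueError("platform comparisons need the same gene universe")
    a_not_b = sorted(
        g
        for g in stats_a
        if stats_a[g].classification == "successful" and stats_b[g].classification == "failed"
    )
    b_not_a = sorted(
        g
        for g in stats_a
        if stats_b[g].classification == "successful" and stats_a[g].classification == "failed"
    )
    return len(a_not_b), len(b_not_a), a_not_b, b_not_a


def saturation_curve(
    profiles: dict[str, DepthProfile],
    fractions: list[float],
    depth_thresholds: tuple[int, ...] = (1, 20),
    seed: int = 0,
) -> list[dict]:
    """Exome-wide coverage versus sequencing effort by binomial thinning.

    For each effort fraction f, every base's depth is thinned
    Binomial(depth, f) — the depth distribution that uniform random read
    subsampling induces — and the fraction of all coding bases at depth >=
    each threshold recomputed.  f = 1 skips thinning, reproducing the
    full-depth coverage exactly.
    """
    rng = np.random.default_rng(seed)
    all_depths = np.concatenate([p.depths for p in profiles.values()])
    rows = []
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        thinned = all_depths if f == 1.0 else rng.binomial(all_depths, f)
        row = {"fraction": f}
        for thr in depth_thresholds:
            row[f"coverage_at_{thr}x"] = float(np.mean(thinned >= thr))
        rows.append(row)
    return rows


def replicate_reproducibility(
    coverage_by_replicate: dict[str, dict[str, float]],
) -> tuple[np.ndarray, float, float, list[str]]:
    """Pairwise Pearson r between replicate gene-coverage vectors.

    Returns (r matrix in replicate order, mean r, sd of r over pairs,
    replicate names).  A zero-variance replicate yields NaN against every
    partner; NaN pairs are excluded from the summary.
    """
    names = sorted(coverage_by_replicate)
    if len(names) < 2:
        raise ValueError("need >= 2 replicates")
    gene_sets = {frozenset(coverage_by_replicate[n]) for n in names}
    if len(gene_sets) != 1:
        raise ValueError("replicates must share the same gene set")
    genes = sorted(next(iter(gene_sets)))
    X = np.array([[coverage_by_replicate[n][g] for g in genes] for n in names])
    k = len(names)
    R = np.full((k, k), np.nan)
    np.fill_diagonal(R, 1.0)
    pair_rs = []
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = X[i], X[j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            r = float(np.corrcoef(xi, xj)[0, 1])
            R[i, j] = R[j, i] = r
            pair_rs.append(r)
    if pair_rs:
        mean_r, sd_r = float(np.mean(pair_rs)), float(np.std(pair_rs, ddof=1) if len(pair_rs) > 1 else 0.0)
    else:
        mean_r, sd_r = float("nan"), float("nan")
    return R, mean_r, sd_r, names


def depth_distribution_stats(
    profiles_by_chrom: dict[str, list[DepthProfile]],
) -> tuple[dict[str, dict[str, float]], np.ndarray]:
    """Per-chromosome mean/median depth and a pooled depth histogram."""
    if not profiles_by_chrom:
        raise ValueError("no depth profiles given")
    summary = {}
    pooled = []
    for chrom, profiles in profiles_by_chrom.items():
        if not profiles:
            raise ValueError(f"{chrom}: empty profile group")
        depths = np.concatenate([p.depths for p in profiles])
        summary[chrom] = {
            "mean": float(np.mean(depths)),
            "median": float(np.median(depths)),
            "n_bases": int(depths.size),
        }
        pooled.append(depths)
    pooled_depths = np.concatenate(pooled)
    histogram = np.bincount(pooled_depths)
    return summary, histogram
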