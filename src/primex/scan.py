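"""The genome-scan layer: FDR control, gene trees, the two-stage
dual-tree positive-selection scan, and chromosome enrichment.

Scan logic: stage 1 tests every gene with the M7-M8 LRT on the fixed
species topology and converts p-values to q-values; stage 2 re-tests only
the stage-1 hits (q < cutoff) on each gene's own neighbor-joining tree,
with q-values recomputed within the hit set.  A gene is finally selected
only when both stages put it below the FDR cutoff — requiring the signal
to survive under both tree hypotheses suppresses false positives caused by
gene-tree/species-tree discordance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import PhyloTree, parse_newick
from .likelihood import (
    GeneLikelihood,
    LrtRecord,
    SiteModelFit,
    fit_m0,
    fit_site_model,
    lrt_m7_m8,
)
from .qc import CodonAlignment

# ---------------------------------------------------------------------------
# q-values


def estimate_qvalues(pvalues, min_tests_for_storey: int = 100) -> np.ndarray:
    """Storey q-values with spline-smoothed pi0; BH when the test set is small.

    pi0 is estimated on the grid lambda = 0.05, 0.10, ..., 0.95 as
    mean(p > lambda)/(1 - lambda), smoothed with a cubic spline and read off
    at lambda = 0.95.  With fewer than ``min_tests_for_storey`` tests, or a
    non-positive pi0 estimate, the method falls back to Benjamini-Hochberg
    (pi0 = 1).  Output is monotone non-decreasing in p and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    pi0 = 1.0
    if m >= min_tests_for_storey:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
        try:
            spline = UnivariateSpline(lam, pi0_lam, k=3)
            pi0_hat = float(spline(lam[-1]))
        except Exception:
            pi0_hat = float(pi0_lam[-1])
        if pi0_hat > 0:
            pi0 = min(pi0_hat, 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]  # step-up
    q = np.empty(m)
    q[order] = np.minimum(pi0 * q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# gene trees: K80 ML distances + neighbor joining


def _k80_distance(seq_a: str, seq_b: str, mask_a=None, mask_b=None, cap: float = 5.0) -> float:
    """Kimura 2-parameter ML distance between two aligned sequences.

    Sites where either sequence is gapped, ambiguous, or masked are
    excluded.  Saturated pairs (log argument <= 0) are capped.
    """
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    n = ts = tv = 0
    for i, (a, b) in enumerate(zip(seq_a, seq_b)):
        if a not in "ACGT" or b not in "ACGT":
            continue
        if (mask_a is not None and mask_a[i]) or (mask_b is not None and mask_b[i]):
            continue
        n += 1
        if a != b:
            if (a, b) in transitions:
                ts += 1
            else:
                tv += 1
    if n == 0:
        return cap
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return cap
    return min(cap, -0.5 * np.log(w1) - 0.25 * np.log(w2))


def infer_nj_tree(alignment: CodonAlignment) -> PhyloTree:
    """Neighbor-joining tree on pairwise K80 ML nucleotide distances.

    Negative NJ branch lengths are clamped to zero.  With fewer than three
    taxa a trivial star tree is returned.  Deterministic: ties resolve by
    the (fixed) taxon input order.
    """
    taxa = alignment.taxa
    if len(taxa) < 3:
        newick = "(" + ",".join(f"{t}:0.0" for t in taxa) + ");"
        return parse_newick(newick)
    from skbio import DistanceMatrix
    from skbio.tree import nj

    k = len(taxa)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = _k80_distance(
                alignment.sequences[i],
                alignment.sequences[j],
                alignment.mask[i],
                alignment.mask[j],
            )
    sk_tree = nj(DistanceMatrix(D, ids=taxa))
    tree = parse_newick(str(sk_tree))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# the dual-tree scan


@dataclass
class GeneScanRecord:
    gene_id: str
    species: LrtRecord
    gene_tree: LrtRecord | None = None
    final_selected: bool = False
    m0_omega: float | None = None
    m8_omega_s: float | None = None


@dataclass
class ScanResult:
    records: dict[str, GeneScanRecord]
    fdr_cutoff: float

    @property
    def stage1_hits(self) -> list[str]:
        return [g for g, r in self.records.items()
                if r.species.qvalue is not None and r.species.qvalue < self.fdr_cutoff]

    @property
    def selected_genes(self) -> list[str]:
        return sorted(g for g, r in self.records.items() if r.final_selected)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, r in sorted(self.records.items()):
            rows.append(
                {
                    "gene": g,
                    "lnL7": r.species.lnl_m7,
                    "lnL8": r.species.lnl_m8,
                    "D": r.species.statistic,
                    "p_species": r.species.pvalue,
                    "q_species": r.species.qvalue,
                    "p_gene_tree": r.gene_tree.pvalue if r.gene_tree else np.nan,
                    "q_gene_tree": r.gene_tree.qvalue if r.gene_tree else np.nan,
                    "omega_s": r.m8_omega_s,
                    "final_selected": r.final_selected,
                }
            )
        return pd.DataFrame(rows)


def fit_gene_lrt(
    alignment: CodonAlignment,
    tree: PhyloTree,
    gene_id: str,
    tree_kind: str = "species",
    ncat: int = 10,
    full_multistart: bool = False,
) -> tuple[LrtRecord, SiteModelFit, SiteModelFit, SiteModelFit]:
    """M0 branch lengths, then fixed-branch-length M7 and M8 fits and LRT."""
    engine = GeneLikelihood(alignment, tree)
    m0 = fit_m0(alignment, tree, gene_id=gene_id, engine=engine)
    m7 = fit_site_model(
        alignment, tree, "M7", gene_id=gene_id, branch_lengths=m0.branch_lengths,
        kappa_init=m0.kappa, ncat=ncat, engine=engine, full_multistart=full_multistart,
    )
    m8 = fit_site_model(
        alignment, tree, "M8", gene_id=gene_id, branch_lengths=m0.branch_lengths,
        m7_fit=m7, ncat=ncat, engine=engine, full_multistart=full_multistart,
    )
    return lrt_m7_m8(m7, m8, tree_kind=tree_kind), m0, m7, m8


def dual_tree_scan(
    genes: dict[str, CodonAlignment],
    species_tree: PhyloTree,
    fdr_cutoff: float = 0.1,
    ncat: int = 10,
    full_multistart: bool = False,
    progress=None,
) -> ScanResult:
    """Two-stage positive-selection scan over QC-passed gene alignments.

    Stage 1 runs the M7-M8 LRT on the species topology for all genes and
    computes q-values across them; stage 2 re-tests only stage-1 hits on
    their own NJ gene trees, with q-values recomputed within the hit set.
    ``final_selected`` requires q < cutoff in both stages.
    """
    records: dict[str, GeneScanRecord] = {}
    gene_ids = sorted(genes)
    for i, gid in enumerate(gene_ids):
        lrt, m0, _, m8 = fit_gene_lrt(
            genes[gid], species_tree, gid, tree_kind="species",
            ncat=ncat, full_multistart=full_multistart,
        )
        records[gid] = GeneScanRecord(
            gene_id=gid, species=lrt, m0_omega=m0.omega, m8_omega_s=m8.omega_s
        )
        if progress is not None:
            progress(i + 1, len(gene_ids))
    qvals = estimate_qvalues([records[g].species.pvalue for g in gene_ids])
    for g, q in zip(gene_ids, qvals):
        records[g].species.qvalue = float(q)

    hits = [g for g in gene_ids if records[g].species.qvalue < fdr_cutoff]
    for gid in hits:
        gene_tree = infer_nj_tree(genes[gid])
        lrt, _, _, _ = fit_gene_lrt(
            genes[gid], gene_tree, gid, tree_kind="gene",
            ncat=ncat, full_multistart=full_multistart,
        )
        records[gid].gene_tree = lrt
    if hits:
        q2 = estimate_qvalues([records[g].gene_tree.pvalue for g in hits])
        for g, q in zip(hits, q2):
            records[g].gene_tree.qvalue = float(q)
            records[g].final_selected = (
                records[g].species.qvalue < fdr_cutoff and float(q) < fdr_cutoff
            )
    return ScanResult(records=records, fdr_cutoff=fdr_cutoff)


# ---------------------------------------------------------------------------
# chromosome enrichment


def chromosome_enrichment(
    selected_genes: list[str], gene_chromosomes: dict[str, str]
) -> pd.DataFrame:
    """Per-chromosome over-representation of selected genes.

    One-sided hypergeometric test of each chromosome's selected-gene count
    against the background composition, BH-adjusted across chromosomes.
    """
    missing = [g for g in selected_genes if g not in gene_chromosomes]
    if missing:
        raise ValueError(f"selected genes missing from background: {', '.join(missing[:5])}")
    chroms = sorted(set(gene_chromosomes.values()))
    M = len(gene_chromosomes)
    n_sel = len(selected_genes)
    rows = []
    for chrom in chroms:
        K = sum(1 for c in gene_chromosomes.values() if c == chrom)
        x = sum(1 for g in selected_genes if gene_chromosomes[g] == chrom)
        p = float(hypergeom.sf(x - 1, M, K, n_sel)) if n_sel > 0 else 1.0
        rows.append({"chrom": chrom, "n_background": K, "n_selected": x, "pvalue": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["padj"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    return df
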