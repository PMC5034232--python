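"""Synthetic-data generators for every pipeline stage.

The simulators emulate the statistical structure of a macaque exome study:

* codon alignments evolved along a seven-taxon primate tree (chimpanzee CM,
  human HM, Indian rhesus IR, Chinese rhesus CR, and Vietnamese/Indonesian/
  Mauritian cynomolgus CC/IC/MC) under GY94 site-class models — M7 (neutral
  purifying mix) for null genes and M8 (with a positively selected class)
  for selected genes;
* cohort genotype tables with stop-gain/frameshift disruptions against a
  configurable carrier matrix;
* per-base capture depth profiles whose efficiency decays logistically with
  probe-target divergence on a cross-species platform (midpoint 5%
  divergence) but not on a species-specific platform.

Every generator is a pure function of its spec including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .capture import DepthProfile
from .codon import (
    N_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
    build_unnormalized_rate_matrix,
    site_class_distribution,
    spectral_decomposition,
    transition_matrix,
    uniform_codon_frequencies,
    validate_codon_frequencies,
)
from .io import GeneModel, GenomicInterval, PhyloTree, parse_newick
from .qc import CodonAlignment

#: The seven-taxon primate species topology used throughout, with branch
#: lengths in expected codon substitutions per codon site (our choice of a
#: primate-realistic depth; the topology itself is
#: ((CM,HM),(IR,(CR,(CC,(IC,MC)))))).
DEFAULT_SPECIES_TREE_NEWICK = (
    "((CM:0.06,HM:0.06):0.12,"
    "(IR:0.03,(CR:0.02,(CC:0.015,(IC:0.01,MC:0.01):0.008):0.01):0.02):0.12);"
)


def default_species_tree() -> PhyloTree:
    return parse_newick(DEFAULT_SPECIES_TREE_NEWICK)


# ---------------------------------------------------------------------------
# codon alignment simulation


@dataclass
class SimulationSpec:
    """One gene's simulation settings.

    ``model`` is "M0", "M7", or "M8" with the matching parameters supplied;
    omega is drawn per site from the model's site-class distribution and
    the site then evolves down the tree under GY94 transition probabilities.
    """

    tree: PhyloTree
    n_codons: int
    model: str = "M7"
    p: float | None = 0.5
    q: float | None = 1.5
    p0: float | None = None
    omega_s: float | None = None
    omega: float | None = None
    kappa: float = 2.0
    codon_frequencies: np.ndarray = field(default_factory=uniform_codon_frequencies)
    ncat: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_codons <= 0:
            raise ValueError("n_codons must be > 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        self.codon_frequencies = validate_codon_frequencies(self.codon_frequencies)

    def class_distribution(self):
        return site_class_distribution(
            self.model,
            p=self.p,
            q=self.q,
            p0=self.p0,
            omega_s=self.omega_s,
            omega=self.omega,
            ncat=self.ncat,
        )


def _tree_arrays(tree: PhyloTree):
    """Rooted traversal arrays: list of (parent_idx, child_idx, branch length),
    preorder, plus leaf labels by node index."""
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    edges = []
    for node in nodes[1:]:
        bl = node.edge.length if node.edge.length is not None else 0.0
        if bl < 0:
            raise ValueError("branch lengths must be non-negative")
        edges.append((index[id(node.parent_node)], index[id(node)], float(bl)))
    leaves = [(index[id(n)], n.taxon.label) for n in nodes if n.is_leaf()]
    return len(nodes), edges, leaves


def simulate_codon_alignment(spec: SimulationSpec) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve a codon alignment down the tree; returns (alignment, classes).

    ``classes[s]`` is the latent site-class index of codon site s.  The root
    state is drawn from the stationary codon frequencies; each branch applies
    expm(Q(omega_class) * t / mean_rate), the same normalization the
    likelihood engine uses, so branch lengths are expected substitutions per
    codon at the model's mean rate.
    """
    rng = np.random.default_rng(spec.seed)
    values, weights = spec.class_distribution()
    nclass = len(values)
    n_nodes, edges, leaves = _tree_arrays(spec.tree)
    if len(leaves) < 2:
        raise ValueError("tree must have >= 2 leaves")
    pi = spec.codon_frequencies
    decomps = []
    rates = np.empty(nclass)
    for c, w in enumerate(values):
        Q = build_unnormalized_rate_matrix(spec.kappa, float(w), pi)
        rates[c] = -float(pi @ np.diag(Q))
        decomps.append(spectral_decomposition(Q, pi))
    mean_rate = float(weights @ rates)

    classes = rng.choice(nclass, size=spec.n_codons, p=weights)
    states = np.empty((n_nodes, spec.n_codons), dtype=np.int64)
    states[0] = rng.choice(N_CODONS, size=spec.n_codons, p=pi)
    for parent, child, bl in edges:
        if bl == 0.0:
            states[child] = states[parent]
            continue
        t = bl / mean_rate
        child_states = np.empty(spec.n_codons, dtype=np.int64)
        for c in range(nclass):
            sites = np.nonzero(classes == c)[0]
            if sites.size == 0:
                continue
            A, lam, B = decomps[c]
            P = transition_matrix(A, lam, B, t)
            rows = P[states[parent][sites]]
            rows /= rows.sum(axis=1, keepdims=True)
            cum = np.cumsum(rows, axis=1)
            u = rng.random(sites.size)
            child_states[sites] = np.minimum(
                (u[:, None] > cum).sum(axis=1), N_CODONS - 1
            )
        states[child] = child_states

    taxa = [label for _, label in leaves]
    sequences = [
        "".join(SENSE_CODONS[s] for s in states[node_idx]) for node_idx, _ in leaves
    ]
    return CodonAlignment(taxa=taxa, sequences=sequences), classes


# ---------------------------------------------------------------------------
# ortholog panels


@dataclass
class SimulatedGene:
    gene_id: str
    alignment: CodonAlignment
    truth: str  # "null" | "selected"
    disrupted_taxa: list[str] = field(default_factory=list)


def _inject_premature_stop(seq: str, rng: np.random.Generator) -> str:
    """Replace a mid-sequence codon with a random stop codon."""
    n_codons = len(seq) // 3
    site = int(rng.integers(1, max(2, n_codons - 1)))
    stop = STOP_CODONS[int(rng.integers(0, 3))]
    return seq[: 3 * site] + stop + seq[3 * site + 3 :]


def _inject_frameshift(seq: str, rng: np.random.Generator, length: int | None = None) -> str:
    """Gap out 1 or 2 bases (or a given length) at a random position."""
    if length is None:
        length = int(rng.integers(1, 3))
    pos = int(rng.integers(3, max(4, len(seq) - length - 3)))
    return seq[:pos] + "-" * length + seq[pos + length :]


def simulate_ortholog_panel(
    n_genes: int,
    tree: PhyloTree | None = None,
    null_fraction: float = 1.0,
    selected_fraction: float = 0.0,
    disruption_rate: float = 0.0,
    seed: int = 0,
    n_codons: int = 300,
    null_p: float = 0.5,
    null_q: float = 1.5,
    selected_p0: float = 0.9,
    selected_omega_s: float = 4.0,
    kappa: float = 2.0,
    max_disrupted_taxa: int = 4,
) -> list[SimulatedGene]:
    """Simulate an ortholog panel with known truth labels.

    The first ``round(selected_fraction * n_genes)`` genes evolve under M8
    (beta plus a selected class at omega_s), the rest under M7; a
    ``disruption_rate`` fraction of genes get premature stops or frameshift
    gaps injected into 1..max_disrupted_taxa random taxa, to exercise the
    intactness filter.  Fully deterministic given the seed.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be > 0")
    if not (0 <= null_fraction <= 1 and 0 <= selected_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if null_fraction + selected_fraction > 1 + 1e-9:
        raise ValueError("fractions must sum to <= 1")
    tree = tree if tree is not None else default_species_tree()
    rng = np.random.default_rng(seed)
    n_selected = int(round(selected_fraction * n_genes))
    genes: list[SimulatedGene] = []
    for g in range(n_genes):
        truth = "selected" if g < n_selected else "null"
        gene_seed = int(rng.integers(0, 2**31 - 1))
        if truth == "selected":
            spec = SimulationSpec(
                tree=tree, n_codons=n_codons, model="M8", p=null_p, q=null_q,
                p0=selected_p0, omega_s=selected_omega_s, kappa=kappa, seed=gene_seed,
            )
        else:
            spec = SimulationSpec(
                tree=tree, n_codons=n_codons, model="M7", p=null_p, q=null_q,
                kappa=kappa, seed=gene_seed,
            )
        alignment, _ = simulate_codon_alignment(spec)
        disrupted: list[str] = []
        if disruption_rate > 0 and rng.random() < disruption_rate:
            k = int(rng.integers(1, max_disrupted_taxa + 1))
            victims = rng.choice(len(alignment.taxa), size=k, replace=False)
            seqs = list(alignment.sequences)
            for v in victims:
                if rng.random() < 0.5:
                    seqs[v] = _inject_premature_stop(seqs[v], rng)
                else:
                    seqs[v] = _inject_frameshift(seqs[v], rng)
                disrupted.append(alignment.taxa[v])
            alignment = CodonAlignment(taxa=list(alignment.taxa), sequences=seqs)
        genes.append(
            SimulatedGene(
                gene_id=f"gene{g:04d}", alignment=alignment, truth=truth,
                disrupted_taxa=disrupted,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# cohort variant tables


def simulate_cohort_variants(
    genes: list[str],
    n_individuals: int,
    pseudogene_genes: list[str] | None = None,
    carrier_matrix: dict[tuple[str, str], str] | None = None,
    seed: int = 0,
    gene_length: int = 900,
    background_rate: float = 1.0,
):
    """Generate a cohort variant table with known pseudogene truth.

    ``carrier_matrix[(gene, individual)]`` in {"none", "het", "hom"} states
    which individuals carry a disruptive (stop-gain or frameshift) variant;
    if omitted, every individual is "hom" for every gene listed in
    ``pseudogene_genes`` and "none" elsewhere.  Background synonymous and
    missense records are added at ``background_rate`` expected records per
    gene-individual pair.
    """
    from .pseudogene import CohortVariantTable, VariantRecord

    if n_individuals <= 0:
        raise ValueError("n_individuals must be > 0")
    individuals = [f"ind{i + 1}" for i in range(n_individuals)]
    pseudogene_genes = pseudogene_genes or []
    rng = np.random.default_rng(seed)
    records = []
    for gene in genes:
        for ind in individuals:
            if carrier_matrix is not None:
                status = carrier_matrix.get((gene, ind), "none")
            else:
                status = "hom" if gene in pseudogene_genes else "none"
            if status not in ("none", "het", "hom"):
                raise ValueError(f"invalid carrier status {status!r}")
            if status != "none":
                pos = int(rng.integers(0, gene_length - 3))
                if rng.random() < 0.5:
                    records.append(
                        VariantRecord(
                            individual=ind, gene_id=gene, chrom="chr1", pos=pos,
                            ref="C", alt="T", effect="stop_gain", zygosity=status,
                            indel_length=0,
                        )
                    )
                else:
                    dlen = int(rng.integers(1, 3))
                    records.append(
                        VariantRecord(
                            individual=ind, gene_id=gene, chrom="chr1", pos=pos,
                            ref="A" * (dlen + 1), alt="A", effect="frameshift",
                            zygosity=status, indel_length=-dlen,
                        )
                    )
            for _ in range(rng.poisson(background_rate)):
                pos = int(rng.integers(0, gene_length))
                effect = "synonymous" if rng.random() < 0.5 else "missense"
                zyg = "het" if rng.random() < 0.7 else "hom"
                records.append(
                    VariantRecord(
                        individual=ind, gene_id=gene, chrom="chr1", pos=pos,
                        ref="G", alt="A", effect=effect, zygosity=zyg, indel_length=0,
                    )
                )
    return CohortVariantTable(records=records, cohort_individuals=individuals)


# ---------------------------------------------------------------------------
# capture experiments


@dataclass
class CaptureSimSpec:
    """Settings for a simulated capture experiment.

    Capture efficiency is 1 for the species-specific platform and decays
    logistically with probe-target divergence d for the cross-species
    platform: eff(d) = 1 / (1 + exp(steepness * (d - d0))), halving at
    ``d0`` (default 5% divergence).  Per-base depth is negative-binomial
    with mean ``mean_depth * eff`` and the given dispersion.
    """

    genes: list[GeneModel]
    divergence: dict[str, float]
    platform: str = "species_specific"  # or "cross_species"
    mean_depth: float = 100.0
    d0: float = 0.05
    steepness: float = 150.0
    dispersion: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if not self.genes:
            raise ValueError("genes must be non-empty")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 < self.d0 < 1:
            raise ValueError("d0 must be in (0, 1)")
        if self.platform not in ("species_specific", "cross_species"):
            raise ValueError(f"unknown platform {self.platform!r}")
        for gene in self.genes:
            d = self.divergence.get(gene.gene_id)
            if d is None or not 0 <= d <= 1:
                raise ValueError(f"{gene.gene_id}: divergence must be given in [0, 1]")


def capture_efficiency(d: float, platform: str, d0: float = 0.05, steepness: float = 150.0) -> float:
    if platform == "species_specific":
        return 1.0
    return float(1.0 / (1.0 + np.exp(steepness * (d - d0))))


def simulate_capture_experiment(spec: CaptureSimSpec) -> dict[str, DepthProfile]:
    """Per-gene per-base depth profiles under the spec's efficiency model."""
    rng = np.random.default_rng(spec.seed)
    profiles = {}
    k = spec.dispersion
    for gene in spec.genes:
        eff = capture_efficiency(
            spec.divergence[gene.gene_id], spec.platform, spec.d0, spec.steepness
        )
        mean = spec.mean_depth * eff
        L = gene.coding_length
        if mean <= 1e-12:
            depths = np.zeros(L, dtype=np.int64)
        else:
            depths = rng.negative_binomial(n=k, p=k / (k + mean), size=L)
        profiles[gene.gene_id] = DepthProfile(gene_id=gene.gene_id, depths=depths)
    return profiles


def make_gene_panel(
    n_genes: int,
    length: int = 900,
    divergence_range: tuple[float, float] = (0.0, 0.10),
    seed: int = 0,
) -> tuple[list[GeneModel], dict[str, float]]:
    """A flat panel of single-exon genes with uniform-random divergences."""
    rng = np.random.default_rng(seed)
    genes, divergence = [], {}
    pos = 1000
    for g in range(n_genes):
        gid = f"gene{g:04d}"
        genes.append(
            GeneModel(
                gene_id=gid, chrom="chr1", strand="+",
                cds_intervals=[GenomicInterval("chr1", pos, pos + length, name=gid)],
            )
        )
        divergence[gid] = float(rng.uniform(*divergence_range))
        pos += length + 200
    return genes, divergence
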