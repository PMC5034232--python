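"""Cohort pseudogene calling from disruptive coding variants.

A gene is called pseudogenized when *every* individual in the cohort
carries at least one homozygous disruptive variant (premature stop-gain or
frameshift indel) in it — the disruptive site need not be shared across
individuals (strict same-site mode available).  The module also classifies
raw variant effects against gene models and summarizes the reading-frame
spectrum of coding indels, whose real-data counterpart is the enrichment of
3N lengths that preserve frame.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from scipy.stats import binomtest

from .codon import is_stop, translate_codon
from .io import GeneModel

DISRUPTIVE_EFFECTS = ("stop_gain", "frameshift")
VALID_EFFECTS = ("stop_gain", "frameshift", "inframe_indel", "missense", "synonymous", "other")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class VariantRecord:
    """One per-individual coding variant."""

    individual: str
    gene_id: str
    chrom: str
    pos: int  # 0-based genomic
    ref: str
    alt: str
    effect: str
    zygosity: str  # hom | het
    indel_length: int = 0  # signed; 0 for SNVs

    def __post_init__(self):
        if self.effect not in VALID_EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"zygosity must be hom or het, got {self.zygosity!r}")
        if self.effect == "frameshift" and abs(self.indel_length) % 3 == 0:
            raise ValueError("frameshift requires |indel_length| mod 3 != 0")
        if self.effect == "inframe_indel" and (
            self.indel_length == 0 or abs(self.indel_length) % 3 != 0
        ):
            raise ValueError("inframe_indel requires a nonzero 3N indel_length")

    @property
    def is_disruptive(self) -> bool:
        return self.effect in DISRUPTIVE_EFFECTS


@dataclass
class CohortVariantTable:
    """All variant records of a cohort, with the cohort roster."""

    records: list[VariantRecord]
    cohort_individuals: list[str]

    def __post_init__(self):
        roster = set(self.cohort_individuals)
        for r in self.records:
            if r.individual not in roster:
                raise ValueError(f"record individual {r.individual!r} not in cohort")

    def by_gene(self) -> dict[str, list[VariantRecord]]:
        grouped: dict[str, list[VariantRecord]] = defaultdict(list)
        for r in self.records:
            grouped[r.gene_id].append(r)
        return dict(grouped)


@dataclass
class PseudogeneCall:
    gene_id: str
    n_supporting: int
    representative_variants: list[VariantRecord] = field(default_factory=list)


def classify_effect(variant: VariantRecord, gene_model: GeneModel, cds_sequence: str) -> str:
    """Classify a variant's effect on the protein from first principles.

    ``cds_sequence`` is the spliced sense-strand CDS.  ref/alt are given on
    the genomic plus strand; minus-strand genes are handled by reverse
    complementing before codon translation.  An SNV creating a stop before
    the final codon is stop_gain (a stop in the final codon is "other");
    indels are frameshift iff |length| mod 3 != 0, inframe_indel otherwise.
    """
    cds = cds_sequence.upper()
    cds_pos = gene_model.genomic_to_cds(variant.pos)
    if variant.indel_length != 0 or len(variant.ref.replace("-", "")) != len(
        variant.alt.replace("-", "")
    ):
        length = variant.indel_length or (
            len(variant.alt.replace("-", "")) - len(variant.ref.replace("-", ""))
        )
        return "frameshift" if abs(length) % 3 != 0 else "inframe_indel"
    ref = variant.ref if gene_model.strand == "+" else reverse_complement(variant.ref)
    alt = variant.alt if gene_model.strand == "+" else reverse_complement(variant.alt)
    if cds[cds_pos] != ref:
        raise ValueError(
            f"{variant.gene_id}: ref mismatch at genomic pos {variant.pos} "
            f"(CDS offset {cds_pos}): expected {cds[cds_pos]}, record says {ref}"
        )
    codon_idx = cds_pos // 3
    within = cds_pos % 3
    codon = cds[3 * codon_idx : 3 * codon_idx + 3]
    mutated = codon[:within] + alt + codon[within + 1 :]
    last_codon = len(cds) // 3 - 1
    if is_stop(mutated):
        return "stop_gain" if codon_idx < last_codon else "other"
    return "synonymous" if translate_codon(mutated) == translate_codon(codon) else "missense"


def call_pseudogenes(table: CohortVariantTable, same_site: bool = False) -> list[PseudogeneCall]:
    """Call genes pseudogenized across the whole cohort.

    Default mode: a gene is called iff every cohort individual carries at
    least one homozygous disruptive variant in it (any site).  Strict
    ``same_site`` mode requires one identical disruptive site shared
    homozygously by all individuals.
    """
    if not table.cohort_individuals:
        raise ValueError("cohort must be non-empty")
    cohort = set(table.cohort_individuals)
    calls = []
    for gene_id, records in sorted(table.by_gene().items()):
        disruptive = [r for r in records if r.is_disruptive and r.zygosity == "hom"]
        if same_site:
            by_site: dict[tuple, set[str]] = defaultdict(set)
            for r in disruptive:
                by_site[(r.chrom, r.pos, r.ref, r.alt)].add(r.individual)
            shared = [site for site, carriers in by_site.items() if carriers == cohort]
            if shared:
                site = min(shared)
                reps = [r for r in disruptive if (r.chrom, r.pos, r.ref, r.alt) == site]
                calls.append(
                    PseudogeneCall(gene_id=gene_id, n_supporting=len(cohort),
                                   representative_variants=reps)
                )
        else:
            carriers = {r.individual for r in disruptive}
            if carriers == cohort:
                reps = []
                seen = set()
                for r in disruptive:
                    if r.individual not in seen:
                        reps.append(r)
                        seen.add(r.individual)
                calls.append(
                    PseudogeneCall(gene_id=gene_id, n_supporting=len(cohort),
                                   representative_variants=reps)
                )
    return calls


@dataclass
class IndelFrameSpectrum:
    counts: dict[int, int]  # |length| -> count
    n_indels: int
    fraction_3n: float
    null_proportion: float
    pvalue: float


def indel_frame_spectrum(indel_lengths: list[int], max_length: int | None = None) -> IndelFrameSpectrum:
    """Reading-frame spectrum of coding indels.

    Builds the histogram of |length| over 1..L (L = ``max_length`` or the
    largest observed length), the fraction of frame-preserving 3N lengths,
    and a two-sided exact binomial test of the 3N count against the null
    proportion (#3N lengths <= L) / L, i.e. lengths uniform on 1..L.
    """
    lengths = [abs(x) for x in indel_lengths]
    if any(x < 1 for x in lengths):
        raise ValueError("indel lengths must be >= 1")
    if not lengths:
        return IndelFrameSpectrum(counts={}, n_indels=0, fraction_3n=0.0,
                                  null_proportion=0.0, pvalue=1.0)
    L = max_length if max_length is not None else max(lengths)
    if L < max(lengths):
        raise ValueError("max_length smaller than the largest observed indel")
    counts = {k: 0 for k in range(1, L + 1)}
    for x in lengths:
        counts[x] += 1
    n = len(lengths)
    n_3n = sum(1 for x in lengths if x % 3 == 0)
    null_p = (L // 3) / L
    pvalue = float(binomtest(n_3n, n, null_p).pvalue) if 0 < null_p < 1 else 1.0
    return IndelFrameSpectrum(
        counts=counts,
        n_indels=n,
        fraction_3n=n_3n / n,
        null_proportion=null_p,
        pvalue=pvalue,
    )
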