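"""Readers and writers for the plain-text formats the pipeline touches.

All interval arithmetic is 0-based half-open (BED convention) everywhere
inside the package; 1-based inclusive coordinates appear only in external
dialects, converted on the way in/out.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# intervals and gene models


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class GeneModel:
    """A gene's coding structure: ordered, non-overlapping CDS intervals."""

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        ivs = sorted(self.cds_intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
        self.cds_intervals = ivs
        if self.coding_length <= 0:
            raise ValueError(f"{self.gene_id}: coding length must be > 0")

    @property
    def coding_length(self) -> int:
        return sum(len(iv) for iv in self.cds_intervals)

    def genomic_to_cds(self, pos: int) -> int:
        """Map a genomic position to its 0-based offset in the spliced CDS.

        Strand-aware: on '-' genes offset 0 is the 3'-most genomic base.
        Raises ValueError if pos is not inside any CDS interval.
        """
        offset = 0
        for iv in self.cds_intervals:
            if iv.start <= pos < iv.end:
                fwd = offset + (pos - iv.start)
                if self.strand == "-":
                    return self.coding_length - 1 - fwd
                return fwd
            offset += len(iv)
        raise ValueError(f"position {pos} not in CDS of {self.gene_id}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ordered (name, sequence) pairs.

    Sequences are uppercased and RNA U is normalized to T.  An empty file
    yields an empty list; a record with no sequence, or sequence data before
    the first header, is a ParseError naming the offending line.
    """
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                if name is not None:
                    if not chunks:
                        raise ParseError(f"{path}:{lineno}: record {name!r} has no sequence")
                    records.append((name, "".join(chunks)))
                name, chunks = header, []
            else:
                if name is None:
                    raise ParseError(f"{path}:{lineno}: sequence data before first header")
                chunks.append(line.upper().replace("U", "T"))
    if name is not None:
        if not chunks:
            raise ParseError(f"{path}: last record {name!r} has no sequence")
        records.append((name, "".join(chunks)))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PHYLIP (relaxed sequential)


def read_phylip(path: str | Path) -> list[tuple[str, str]]:
    """Relaxed sequential PHYLIP: header 'ntaxa nchar', then 'name seq' lines."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        return []
    try:
        ntaxa, nchar = (int(x) for x in lines[0].split()[:2])
    except ValueError as exc:
        raise ParseError(f"{path}:1: malformed PHYLIP header") from exc
    records = []
    for ln in lines[1 : 1 + ntaxa]:
        parts = ln.split()
        if len(parts) < 2:
            raise ParseError(f"{path}: malformed PHYLIP record {ln!r}")
        name, seq = parts[0], "".join(parts[1:]).upper().replace("U", "T")
        if len(seq) != nchar:
            raise ParseError(f"{path}: {name}: expected {nchar} characters, got {len(seq)}")
        records.append((name, seq))
    if len(records) != ntaxa:
        raise ParseError(f"{path}: expected {ntaxa} records, found {len(records)}")
    return records


def write_phylip(records: list[tuple[str, str]], path: str | Path) -> None:
    if records:
        nchar = len(records[0][1])
        if any(len(seq) != nchar for _, seq in records):
            raise ValueError("PHYLIP requires equal-length sequences")
    with open(path, "w") as fh:
        fh.write(f" {len(records)} {len(records[0][1]) if records else 0}\n")
        for name, seq in records:
            fh.write(f"{name}  {seq}\n")


# ---------------------------------------------------------------------------
# BED and BEDGRAPH


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED 3-6 columns, 0-based half-open."""
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            strand = cols[5] if len(cols) > 5 else "."
            try:
                intervals.append(GenomicInterval(cols[0], start, end, name=name, strand=strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is None and iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, int]]:
    """BEDGRAPH depth track rows (chrom, start, end, depth)."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError(f"{path}:{lineno}: BEDGRAPH needs 4 columns")
            chrom, start, end, depth = cols[0], int(cols[1]), int(cols[2]), int(float(cols[3]))
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            rows.append((chrom, start, end, depth))
    return rows


def write_bedgraph(rows: list[tuple[str, int, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, depth in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{depth}\n")


def read_gene_models_bed(path: str | Path) -> dict[str, GeneModel]:
    """Build GeneModels from a BED file whose name column carries gene ids.

    Multiple rows with the same gene id become that gene's CDS intervals.
    """
    by_gene: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for iv in read_bed(path):
        if iv.name is None:
            raise ParseError(f"{path}: gene-model BED rows need a name column")
        by_gene.setdefault(iv.name, []).append(iv)
        meta.setdefault(iv.name, (iv.chrom, iv.strand if iv.strand != "." else "+"))
    return {
        gid: GeneModel(gene_id=gid, chrom=meta[gid][0], strand=meta[gid][1], cds_intervals=ivs)
        for gid, ivs in by_gene.items()
    }


# ---------------------------------------------------------------------------
# Newick trees (dendropy containers)

PhyloTree = dendropy.Tree


def read_newick(path: str | Path) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"{path}: invalid Newick: {exc}") from exc
    return tree


def parse_newick(newick: str) -> PhyloTree:
    try:
        return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise ParseError(f"invalid Newick string: {exc}") from exc


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True)


def tree_to_newick(tree: PhyloTree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True).strip()


def rf_distance(tree_a: PhyloTree, tree_b: PhyloTree) -> int:
    """Unrooted Robinson-Foulds (symmetric bipartition) distance."""
    tns = dendropy.TaxonNamespace()
    ta = parse_newick(tree_to_newick(tree_a))
    tb = parse_newick(tree_to_newick(tree_b))
    ta.taxon_namespace = tns
    tb.taxon_namespace = tns
    ta.migrate_taxon_namespace(tns)
    tb.migrate_taxon_namespace(tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))


# ---------------------------------------------------------------------------
# variant tables (minimal VCF-like TSV dialect)

VARIANT_COLUMNS = ["individual", "gene_id", "chrom", "pos", "ref", "alt", "effect", "zygosity"]

_EFFECT_ALIASES = {
    "stop_gain": "stop_gain",
    "stopgain": "stop_gain",
    "nonsense": "stop_gain",
    "frameshift": "frameshift",
    "frame_shift": "frameshift",
    "inframe_indel": "inframe_indel",
    "inframe": "inframe_indel",
    "nonframeshift": "inframe_indel",
    "missense": "missense",
    "nonsynonymous": "missense",
    "synonymous": "synonymous",
    "silent": "synonymous",
    "other": "other",
}


def canonical_effect(effect: str) -> str:
    key = re.sub(r"[\s\-]+", "_", effect.strip().lower())
    if key not in _EFFECT_ALIASES:
        raise ParseError(f"unknown variant effect {effect!r}")
    return _EFFECT_ALIASES[key]


def read_variant_table(path: str | Path):
    """Read the TSV variant dialect into a CohortVariantTable.

    Columns: individual, gene_id, chrom, pos, ref, alt, effect, zygosity
    (optional: indel_length, derived from ref/alt when absent).  Effect
    strings are canonicalized via an alias table; zygosity is case-folded.
    """
    from .pseudogene import CohortVariantTable, VariantRecord

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        zyg = str(row.zygosity).strip().lower()
        if zyg not in ("hom", "het"):
            raise ParseError(f"{path}: invalid zygosity {row.zygosity!r}")
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if hasattr(row, "indel_length") and not pd.isna(row.indel_length):
            indel_length = int(row.indel_length)
        else:
            indel_length = (len(alt.replace("-", "")) - len(ref.replace("-", ""))) if ref != alt else 0
        records.append(
            VariantRecord(
                individual=str(row.individual),
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=ref,
                alt=alt,
                effect=canonical_effect(str(row.effect)),
                zygosity=zyg,
                indel_length=indel_length,
            )
        )
    individuals = sorted({r.individual for r in records})
    return CohortVariantTable(records=records, cohort_individuals=individuals)


def write_variant_table(table, path: str | Path) -> None:
    rows = [
        {
            "individual": r.individual,
            "gene_id": r.gene_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "effect": r.effect,
            "zygosity": r.zygosity,
            "indel_length": r.indel_length,
        }
        for r in table.records
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["indel_length"]).to_csv(path, sep="\t", index=False)
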