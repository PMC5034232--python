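"""Pre-scan alignment quality control.

Two bespoke filters precede the selection scan:

* ortholog intactness — a taxon's sequence is "intact" if it carries no
  premature stop codon and no reading-frame-breaking gap; a gene enters the
  scan only if at least ``min_intact`` taxa (default 6) are intact, and the
  non-intact taxa are dropped from its alignment;
* block-substitution masking — >= 6 mismatches against the consensus of the
  other sequences within any 9 aligned bp are treated as alignment or
  sequencing artifacts and masked (as missing data, whole codons) in the
  deviant sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .codon import is_stop

ALPHABET = set("ACGT-N")


@dataclass
class CodonAlignment:
    """Aligned coding sequences with a per-(taxon, position) mask.

    All sequences have equal length divisible by 3 over {A,C,G,T,-,N}.
    ``mask[i, j] == True`` marks nucleotide j of taxon i as masked: treated
    as missing data by the likelihood machinery.
    """

    taxa: list[str]
    sequences: list[str]
    mask: np.ndarray = field(default=None)  # bool (ntaxa, length)

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences must align")
        if self.sequences:
            L = len(self.sequences[0])
            if any(len(s) != L for s in self.sequences):
                raise ValueError("all sequences must have equal length")
            if L % 3 != 0:
                raise ValueError("alignment length must be divisible by 3")
            bad = set("".join(self.sequences)) - ALPHABET
            if bad:
                raise ValueError(f"illegal alignment characters: {sorted(bad)}")
        if self.mask is None:
            self.mask = np.zeros((len(self.taxa), self.length), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (len(self.taxa), self.length):
                raise ValueError("mask shape must be (ntaxa, length)")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def subset(self, taxa: list[str]) -> "CodonAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(
            taxa=[self.taxa[i] for i in idx],
            sequences=[self.sequences[i] for i in idx],
            mask=self.mask[idx].copy(),
        )

    def records(self) -> list[tuple[str, str]]:
        return list(zip(self.taxa, self.sequences))


@dataclass
class IntactnessReport:
    """Per-taxon nonsense/frameshift status of one gene alignment."""

    taxa: list[str]
    has_premature_stop: dict[str, bool]
    has_frameshift: dict[str, bool]

    @property
    def intact_taxa(self) -> list[str]:
        return [
            t
            for t in self.taxa
            if not self.has_premature_stop[t] and not self.has_frameshift[t]
        ]

    @property
    def n_intact(self) -> int:
        return len(self.intact_taxa)


def _sequence_flags(seq: str) -> tuple[bool, bool]:
    """(premature stop, frameshift) for one aligned sequence.

    Premature stop: an in-frame TAA/TAG/TGA strictly before the final codon
    of the gap-stripped sequence.  Frameshift: any gap run of length not a
    multiple of 3, or a gap-stripped length not a multiple of 3.
    """
    frameshift = False
    run = 0
    for ch in seq:
        if ch == "-":
            run += 1
        elif run:
            if run % 3 != 0:
                frameshift = True
            run = 0
    if run and run % 3 != 0:
        frameshift = True
    ungapped = seq.replace("-", "")
    if len(ungapped) % 3 != 0:
        frameshift = True
    premature_stop = False
    n_codons = len(ungapped) // 3
    for i in range(n_codons - 1):
        codon = ungapped[3 * i : 3 * i + 3]
        if is_stop(codon):
            premature_stop = True
            break
    return premature_stop, frameshift


def assess_intactness(alignment: CodonAlignment) -> IntactnessReport:
    """Check each taxon's sequence for premature stops and frameshifts."""
    stops, shifts = {}, {}
    for taxon, seq in zip(alignment.taxa, alignment.sequences):
        stops[taxon], shifts[taxon] = _sequence_flags(seq)
    return IntactnessReport(
        taxa=list(alignment.taxa), has_premature_stop=stops, has_frameshift=shifts
    )


def filter_orthologs(
    gene_alignments: dict[str, CodonAlignment], min_intact: int = 6
) -> dict[str, CodonAlignment]:
    """Retain genes with >= min_intact intact taxa, dropping broken taxa.

    The retained alignment keeps only intact taxa, so downstream models are
    never fed disrupted sequences.
    """
    if min_intact < 1:
        raise ValueError("min_intact must be >= 1")
    retained = {}
    for gene_id, aln in gene_alignments.items():
        report = assess_intactness(aln)
        if report.n_intact >= min_intact:
            retained[gene_id] = aln.subset(report.intact_taxa)
    return retained


_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def mask_block_substitutions(
    alignment: CodonAlignment, window: int = 9, min_subs: int = 6
) -> CodonAlignment:
    """Mask dense substitution blocks in each sequence.

    For every sequence, mismatches are counted against the column-wise
    majority consensus of the *other* sequences (ties broken alphabetically;
    columns where the sequence or the consensus is undefined are skipped).
    Any window of ``window`` aligned positions holding >= ``min_subs``
    mismatches is masked in that sequence, extended to whole codons.
    Masking only ever adds to the existing mask, so it is idempotent.
    """
    if not (window >= min_subs >= 1):
        raise ValueError("need window >= min_subs >= 1")
    L = alignment.length
    if L < window:
        warnings.warn("alignment shorter than masking window; nothing masked")
        return alignment
    n = len(alignment.taxa)
    codes = np.full((n, L), -1, dtype=np.int8)
    for i, seq in enumerate(alignment.sequences):
        for j, ch in enumerate(seq):
            codes[i, j] = _BASE_TO_CODE.get(ch, -1)
    # column base counts over all sequences, then leave-one-out per sequence
    counts = np.zeros((4, L), dtype=np.int32)
    for b in range(4):
        counts[b] = (codes == b).sum(axis=0)
    new_mask = alignment.mask.copy()
    for i in range(n):
        loo = counts.copy()
        own = codes[i]
        valid_own = own >= 0
        loo[own[valid_own], np.nonzero(valid_own)[0]] -= 1
        has_consensus = loo.sum(axis=0) > 0
        # argmax on first axis breaks ties toward the alphabetically first base
        consensus = loo.argmax(axis=0)
        mismatch = valid_own & has_consensus & (consensus != own)
        # windowed mismatch counts via cumulative sum
        cum = np.concatenate([[0], np.cumsum(mismatch)])
        win_counts = cum[window:] - cum[:-window]  # count in [j, j+window)
        for j in np.nonzero(win_counts >= min_subs)[0]:
            start = (j // 3) * 3
            end = ((j + window + 2) // 3) * 3
            new_mask[i, start : min(end, L)] = True
    return CodonAlignment(
        taxa=list(alignment.taxa), sequences=list(alignment.sequences), mask=new_mask
    )
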