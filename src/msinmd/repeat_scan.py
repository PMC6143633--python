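"""Mononucleotide microsatellite detection and genomic-context annotation.

MSI tumors accumulate slippage indels in homopolymer runs. Coding runs take
1-2 bp frameshift indels; the HSP110-like intronic T17 run takes larger
deletions that perturb splicing. This module finds maximal single-base runs
and places them relative to a transcript's exon/CDS structure, which feeds
the last-exon (LE) vs before-last-exon (NLE) mutation classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from itertools import groupby
from typing import Optional

from .gene_models import (
    GenomeSequence,
    IntronicPosition,
    TranscriptModel,
    genome_to_transcript,
)

log = logging.getLogger(__name__)


class RepeatContext(str, Enum):
    CODING = "CODING"
    INTRONIC = "INTRONIC"
    UTR_OTHER = "UTR_OTHER"


@dataclass(frozen=True)
class RepeatRun:
    """A maximal homopolymer run in a scanned sequence (local offsets)."""

    start: int
    end: int
    base: str

    @property
    def run_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatLocus:
    """A mononucleotide run anchored to genome and transcript.

    ``start``/``end`` are genomic 0-based half-open; ``base`` is the genomic
    (plus-strand) base. Context fields are filled by
    :func:`annotate_repeat_context`; ``exon_or_intron_index`` is 1-based in
    transcript orientation and ``distance_to_downstream_acceptor`` is the
    number of intronic nucleotides between the run's 3'-most base (transcript
    orientation) and the downstream splice acceptor.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    base: str
    run_length: int
    context: Optional[RepeatContext] = None
    exon_or_intron_index: Optional[int] = None
    distance_to_downstream_acceptor: Optional[int] = None


def find_mononucleotide_repeats(seq: str, min_run_length: int = 8) -> list[RepeatRun]:
    """All maximal single-base runs of length >= ``min_run_length``.

    Runs are reported left to right and are non-overlapping by construction
    (a maximal run of one base cannot intersect a maximal run of another).
    N runs are not reported.
    """
    if min_run_length < 5:
        raise ValueError("min_run_length must be >= 5")
    out: list[RepeatRun] = []
    pos = 0
    for base, group in groupby(seq.upper()):
        ln = sum(1 for _ in group)
        if ln >= min_run_length and base in "ACGT":
            out.append(RepeatRun(pos, pos + ln, base))
        pos += ln
    return out


def annotate_repeat_context(t: TranscriptModel, locus: RepeatLocus) -> RepeatLocus:
    """Classify a locus as CODING / INTRONIC / UTR_OTHER on a transcript.

    A run is classified by its 5'-most base in transcript orientation (a
    deterministic tie-break for runs spanning an exon boundary): CODING if
    that base falls inside the CDS, INTRONIC if inside an intron (with the
    distance to the downstream acceptor recorded), UTR_OTHER (excluded from
    downstream decay analyses) if in a UTR.
    """
    five_prime = locus.start if t.strand == "+" else locus.end - 1
    mapped = genome_to_transcript(t, five_prime)
    if isinstance(mapped, IntronicPosition):
        down = t.exons[mapped.downstream_exon - 1]
        if t.strand == "+":
            dist = down[0] - locus.end
        else:
            dist = locus.start - down[1]
        return replace(
            locus,
            context=RepeatContext.INTRONIC,
            exon_or_intron_index=mapped.intron_index,
            distance_to_downstream_acceptor=dist,
        )
    exon_idx = t.exon_index_of(mapped)
    if t.cds_start_tx <= mapped < t.cds_end_tx:
        return replace(
            locus,
            context=RepeatContext.CODING,
            exon_or_intron_index=exon_idx,
            distance_to_downstream_acceptor=None,
        )
    log.info(
        "repeat %s:%d-%d on %s lies in a UTR; excluded from decay analyses",
        locus.chrom,
        locus.start,
        locus.end,
        t.transcript_id,
    )
    return replace(
        locus,
        context=RepeatContext.UTR_OTHER,
        exon_or_intron_index=exon_idx,
        distance_to_downstream_acceptor=None,
    )


def scan_transcript_region(
    t: TranscriptModel, genome: GenomeSequence, min_run_length: int = 8
) -> list[RepeatLocus]:
    """Scan a transcript's genomic span (exons and introns) for runs.

    Returns annotated loci in genomic order. Runs extending beyond the
    transcript span are truncated at the span edges by construction of the
    scan window; callers scanning whole chromosomes should widen the window.
    """
    lo, hi = t.genomic_span
    seq = genome.fetch(t.chrom, lo, hi)
    loci = []
    for run in find_mononucleotide_repeats(seq, min_run_length):
        locus = RepeatLocus(
            gene_id=t.gene_id,
            transcript_id=t.transcript_id,
            chrom=t.chrom,
            start=lo + run.start,
            end=lo + run.end,
            base=run.base,
            run_length=run.run_length,
        )
        loci.append(annotate_repeat_context(t, locus))
    return loci
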