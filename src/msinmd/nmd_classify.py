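"""Apply repeat indels to transcripts, locate PTCs, classify NMD sensitivity.

The decision rule is the positional one used for mammalian transcripts: a
premature termination codon (PTC) is recognized by the surveillance
machinery when it lies in the coding sequence outside the last exon and more
than 55 nt upstream of the last exon-exon junction. PTCs in the last exon,
or within 55 nt of the last junction, escape decay. The boundary is strict:
a PTC at exactly 55 nt is INSENSITIVE, 56 nt is SUBSTRATE.

Distances are measured from the *first base* of the stop codon to the
last-junction offset, in mutant transcript coordinates. Indels are applied
at the 3' end of the repeat run (right-aligned): slippage position within a
homopolymer is unobservable, so a deterministic convention is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .gene_models import (
    GenomeSequence,
    IntronicPosition,
    ModelError,
    TranscriptModel,
    genome_to_transcript,
    transcript_sequence,
)
from .repeat_scan import RepeatLocus
from .splice_model import (
    SpliceModelParams,
    SpliceOutcome,
    build_skipped_transcript,
    predict_splicing_outcome,
)

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


class NMDClass(str, Enum):
    SUBSTRATE = "SUBSTRATE"
    INSENSITIVE = "INSENSITIVE"
    NO_PTC = "NO_PTC"


class LocationClass(str, Enum):
    LE = "LE"  # mutation in the last exon
    NLE = "NLE"  # mutation before the last exon (earlier exons and all introns)


class MutationKind(str, Enum):
    CODING_FRAMESHIFT = "CODING_FRAMESHIFT"
    INTRONIC_REPEAT_DELETION = "INTRONIC_REPEAT_DELETION"


@dataclass(frozen=True)
class NMDRuleParams:
    """The junction-window parameter of the positional NMD rule (55 nt)."""

    junction_window_nt: int = 55

    def __post_init__(self):
        if self.junction_window_nt <= 0:
            raise ValueError("junction_window_nt must be positive")


@dataclass(frozen=True)
class MutationCall:
    """An indel applied to a repeat locus of one transcript."""

    gene_id: str
    transcript_id: str
    locus: RepeatLocus
    delta_bp: int
    kind: MutationKind

    def __post_init__(self):
        if self.delta_bp == 0:
            raise ValueError("delta_bp must be nonzero")
        # In-frame coding indels (|delta| a multiple of 3) are accepted: they
        # shift no frame and classify as NO_PTC unless a stop is created.
        if self.kind is MutationKind.INTRONIC_REPEAT_DELETION and self.delta_bp >= 0:
            raise ValueError("INTRONIC_REPEAT_DELETION requires delta_bp < 0")


@dataclass(frozen=True)
class PTCAnnotation:
    """Classification result for one mutant transcript.

    ``ptc_tx_pos`` is the 0-based offset of the stop codon's first base in
    the *mutant* transcript; ``ptc_exon_index`` is 1-based in the mutant
    exon structure. ``distance_to_last_junction`` is last-junction offset
    minus PTC offset. ``no_stop`` marks nonstop transcripts (no termination
    codon at all), which are excluded from decay statistics.
    """

    transcript_id: str
    nmd_class: NMDClass
    location_class: Optional[LocationClass] = None
    ptc_tx_pos: Optional[int] = None
    ptc_exon_index: Optional[int] = None
    distance_to_last_junction: Optional[int] = None
    mutant_cds: str = ""
    no_stop: bool = False
    splice_outcome: Optional[SpliceOutcome] = None


# ---------------------------------------------------------------------------
# sequence edits
# ---------------------------------------------------------------------------


def apply_coding_indel(
    t: TranscriptModel, genome: GenomeSequence, m: MutationCall
) -> tuple[str, tuple[int, ...]]:
    """Mutant transcript sequence and mutant exon lengths for a coding indel.

    The edit is right-aligned: a deletion removes ``|delta_bp|`` copies of
    the repeat base from the 3' end of the run, an insertion adds them
    there. Exon lengths downstream of nothing change — only the exon
    containing the edit point changes length, which shifts every downstream
    junction offset by ``delta_bp``.
    """
    if m.kind is not MutationKind.CODING_FRAMESHIFT:
        raise ValueError("apply_coding_indel expects a CODING_FRAMESHIFT call")
    if abs(m.delta_bp) >= m.locus.run_length:
        raise ModelError(
            f"{t.transcript_id}: |delta_bp|={abs(m.delta_bp)} >= run_length="
            f"{m.locus.run_length}"
        )
    five_prime = m.locus.start if t.strand == "+" else m.locus.end - 1
    three_prime = m.locus.end - 1 if t.strand == "+" else m.locus.start
    r0 = genome_to_transcript(t, five_prime)
    r_last = genome_to_transcript(t, three_prime)
    if isinstance(r0, IntronicPosition) or isinstance(r_last, IntronicPosition):
        raise ModelError(f"{t.transcript_id}: repeat run is not fully exonic")
    if r_last != r0 + m.locus.run_length - 1:
        raise ModelError(f"{t.transcript_id}: repeat run spans a splice junction")
    if not t.cds_start_tx <= r0 < t.cds_end_tx:
        raise ModelError(f"{t.transcript_id}: repeat run outside the CDS")
    if r0 < t.cds_start_tx + 3:
        raise ModelError(f"{t.transcript_id}: repeat run overlaps the start codon")

    run_end = r0 + m.locus.run_length
    wt = transcript_sequence(t, genome)
    tx_base = m.locus.base if t.strand == "+" else _COMPLEMENT_BASE[m.locus.base]
    if m.delta_bp < 0:
        k = -m.delta_bp
        mutant = wt[: run_end - k] + wt[run_end:]
    else:
        mutant = wt[:run_end] + tx_base * m.delta_bp + wt[run_end:]

    lengths = list(t.exon_lengths)
    edit_exon = t.exon_index_of(run_end - 1)
    lengths[edit_exon - 1] += m.delta_bp
    return mutant, tuple(lengths)


# ---------------------------------------------------------------------------
# PTC scanning and the positional rule
# ---------------------------------------------------------------------------


def find_ptc(
    mutant_sequence: str, cds_start_tx: int, native_stop_tx: int
) -> tuple[Optional[int], bool]:
    """First in-frame stop strictly upstream of the native stop.

    Scans codons from ``cds_start_tx``. Returns ``(ptc_pos, no_stop)``:
    ``ptc_pos`` is the offset of the stop codon's first base, or None when
    the first stop encountered is the native stop (or lies at/after it).
    ``no_stop`` is True when no stop exists before the transcript end
    (a nonstop transcript, handled by a different decay pathway).
    """
    seq = mutant_sequence
    for i in range(cds_start_tx, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            if i < native_stop_tx:
                return i, False
            return None, False
    return None, True


def classify_nmd_sensitivity(
    ptc_tx_pos: Optional[int],
    mutant_exon_lengths: Sequence[int],
    params: NMDRuleParams = NMDRuleParams(),
) -> NMDClass:
    """Positional rule on the mutant exon geometry.

    NO_PTC without a PTC; INSENSITIVE for a PTC in the last exon or within
    ``junction_window_nt`` of the last junction (and for single-exon
    transcripts, which have no junction); SUBSTRATE otherwise. Pure function
    of its arguments.
    """
    if ptc_tx_pos is None:
        return NMDClass.NO_PTC
    if len(mutant_exon_lengths) < 2:
        log.info("single-exon transcript: no junction, PTC is INSENSITIVE")
        return NMDClass.INSENSITIVE
    junction = sum(mutant_exon_lengths[:-1])
    if ptc_tx_pos >= junction:
        return NMDClass.INSENSITIVE
    if junction - ptc_tx_pos <= params.junction_window_nt:
        return NMDClass.INSENSITIVE
    return NMDClass.SUBSTRATE


def classify_mutation_location(t: TranscriptModel, m: MutationCall) -> LocationClass:
    """LE if the mutation's 5'-most base lies in the last exon, else NLE.

    Intronic mutations are always NLE. Single-exon transcripts are LE (with
    a logged note) — there is no "before the last exon" there.
    """
    if t.n_exons == 1:
        log.info("%s: single-exon transcript, mutation classed LE", t.transcript_id)
        return LocationClass.LE
    five_prime = m.locus.start if t.strand == "+" else m.locus.end - 1
    mapped = genome_to_transcript(t, five_prime)
    if isinstance(mapped, IntronicPosition):
        return LocationClass.NLE
    return (
        LocationClass.LE if t.exon_index_of(mapped) == t.n_exons else LocationClass.NLE
    )


def _exon_index_in(lengths: Sequence[int], tx_pos: int) -> int:
    off = 0
    for i, ln in enumerate(lengths, start=1):
        if tx_pos < off + ln:
            return i
        off += ln
    raise ValueError(f"offset {tx_pos} beyond transcript of length {off}")


def classify_variant(
    t: TranscriptModel,
    genome: GenomeSequence,
    m: MutationCall,
    params: NMDRuleParams = NMDRuleParams(),
    splice_params: Optional[SpliceModelParams] = None,
) -> PTCAnnotation:
    """Full classification of one mutation call.

    Coding frameshifts are applied directly to the spliced sequence.
    Intronic repeat deletions are routed through the splice model: small
    deletions leave the wild-type transcript (NO_PTC), large ones skip the
    downstream exon and the skipped transcript is scanned for a PTC.
    """
    location = classify_mutation_location(t, m)
    splice_outcome: Optional[SpliceOutcome] = None

    if m.kind is MutationKind.CODING_FRAMESHIFT:
        mutant_seq, mutant_lengths = apply_coding_indel(t, genome, m)
        cds_start = t.cds_start_tx
        native_stop = t.cds_end_tx - 3 + m.delta_bp
    else:
        if splice_params is None:
            if (
                m.locus.exon_or_intron_index is None
                or m.locus.distance_to_downstream_acceptor is None
            ):
                raise ModelError(
                    f"{t.transcript_id}: intronic call needs an annotated locus "
                    "or explicit splice_params"
                )
            splice_params = SpliceModelParams(
                skipped_exon_index=m.locus.exon_or_intron_index + 1
            )
        splice_outcome = predict_splicing_outcome(-m.delta_bp, splice_params)
        if splice_outcome is SpliceOutcome.NORMAL:
            mutant_seq = transcript_sequence(t, genome)
            mutant_lengths = t.exon_lengths
            cds_start = t.cds_start_tx
            native_stop = t.cds_end_tx - 3
        else:
            skipped = build_skipped_transcript(t, splice_params.skipped_exon_index)
            a, b = t.tx_interval_of_exon(splice_params.skipped_exon_index)
            stop_first = t.cds_end_tx - 3
            if a >= t.cds_end_tx:  # exon entirely in the 3' UTR
                shift = 0
            elif b <= stop_first:
                shift = b - a
            else:
                raise ModelError(
                    f"{t.transcript_id}: skipped exon overlaps the native stop codon"
                )
            mutant_seq = transcript_sequence(skipped, genome)
            mutant_lengths = skipped.exon_lengths
            cds_start = skipped.cds_start_tx
            native_stop = stop_first - shift

    ptc, no_stop = find_ptc(mutant_seq, cds_start, native_stop)
    nmd = classify_nmd_sensitivity(ptc, mutant_lengths, params)

    if ptc is not None:
        exon_idx = _exon_index_in(mutant_lengths, ptc)
        junction = (
            sum(mutant_lengths[:-1]) if len(mutant_lengths) > 1 else None
        )
        distance = junction - ptc if junction is not None else None
        cds_stop = ptc + 3
    else:
        exon_idx = None
        distance = None
        cds_stop = native_stop + 3 if not no_stop else len(mutant_seq)

    return PTCAnnotation(
        transcript_id=t.transcript_id,
        nmd_class=nmd,
        location_class=location,
        ptc_tx_pos=ptc,
        ptc_exon_index=exon_idx,
        distance_to_last_junction=distance,
        mutant_cds=mutant_seq[cds_start:cds_stop],
        no_stop=no_stop,
        splice_outcome=splice_outcome,
    )


def ptc_location_class(
    annotation: PTCAnnotation, mutant_exon_lengths: Sequence[int]
) -> Optional[LocationClass]:
    """Alternative LE/NLE labelling by PTC position rather than mutation site.

    The cohort contrast uses mutation position by default (matching how the
    LE/NLE classes are defined on the mutation's microsatellite); this
    variant labels by where the resulting PTC falls, for sensitivity checks.
    Returns None when there is no PTC.
    """
    if annotation.ptc_tx_pos is None:
        return None
    idx = _exon_index_in(mutant_exon_lengths, annotation.ptc_tx_pos)
    return LocationClass.LE if idx == len(mutant_exon_lengths) else LocationClass.NLE
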