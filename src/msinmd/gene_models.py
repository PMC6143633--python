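"""Transcript models, genome sequences, and coordinate arithmetic.

Everything downstream (repeat annotation, PTC scanning, exon-skip
reconstruction) works in *transcript coordinates*: 0-based offsets along the
spliced mRNA, 5'->3'. This module owns the mapping between those offsets and
genomic positions, and the exon-junction geometry that the NMD rule needs.

Conventions
-----------
* Internal coordinates are 0-based half-open; GTF input/output is the standard
  1-based inclusive dialect.
* Minus-strand transcripts are normalized at load time: ``exons[0]`` is always
  the 5'-most exon of the mRNA, so all downstream logic is strand-free.
* ``cds_start_tx``/``cds_end_tx`` delimit the coding region *including* the
  native stop codon, which makes "PTC upstream of the native stop" a plain
  offset comparison. GTF CDS features emitted by this package follow the same
  convention (stop codon inside the CDS feature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


class ModelError(ValueError):
    """A transcript model violates its structural invariants."""


class CoordinateError(ValueError):
    """A position falls outside the queried transcript's genomic span."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IntronicPosition:
    """Marker returned when a genomic position maps into an intron.

    ``intron_index`` is 1-based and equals the index of the upstream exon in
    transcript orientation (the T17 run of the HSP110-like gene sits in
    intron 8, between exons 8 and 9).
    """

    intron_index: int
    upstream_exon: int
    downstream_exon: int


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure and CDS of one transcript.

    ``exons`` are genomic 0-based half-open intervals ordered 5'->3' in
    transcript orientation (descending genomic coordinate on the minus
    strand). ``cds_start_tx``/``cds_end_tx`` are transcript offsets; the
    native stop codon occupies ``[cds_end_tx - 3, cds_end_tx)``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_tx: int
    cds_end_tx: int

    # -- geometry -----------------------------------------------------------

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    @property
    def length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_tx_starts(self) -> tuple[int, ...]:
        """Transcript offset of the first base of each exon."""
        starts, off = [], 0
        for ln in self.exon_lengths:
            starts.append(off)
            off += ln
        return tuple(starts)

    @property
    def genomic_span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    def exon_index_of(self, tx_pos: int) -> int:
        """1-based exon index containing a transcript offset."""
        if not 0 <= tx_pos < self.length:
            raise CoordinateError(
                f"{self.transcript_id}: transcript offset {tx_pos} outside [0, {self.length})"
            )
        off = 0
        for i, ln in enumerate(self.exon_lengths, start=1):
            if tx_pos < off + ln:
                return i
            off += ln
        raise AssertionError("unreachable")

    def tx_interval_of_exon(self, exon_index: int) -> tuple[int, int]:
        """Transcript-coordinate interval of a 1-based exon index."""
        if not 1 <= exon_index <= self.n_exons:
            raise CoordinateError(f"exon index {exon_index} out of range")
        start = self.exon_tx_starts[exon_index - 1]
        return (start, start + self.exon_lengths[exon_index - 1])

    # -- validation ---------------------------------------------------------

    def validate(self, require_coding_frame: bool = True) -> None:
        """Raise ModelError on any invariant violation.

        ``require_coding_frame=False`` relaxes the CDS-length-multiple-of-3
        check for mutant models produced by indels or exon skipping.
        """
        if self.strand not in ("+", "-"):
            raise ModelError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ModelError(f"{self.transcript_id}: no exons")
        for s, e in self.exons:
            if not 0 <= s < e:
                raise ModelError(f"{self.transcript_id}: bad exon interval [{s}, {e})")
        # non-overlapping and strictly ordered in transcript orientation
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            ok = e1 <= s2 if self.strand == "+" else e2 <= s1
            if not ok:
                raise ModelError(
                    f"{self.transcript_id}: exons out of order or overlapping"
                )
        if not 0 <= self.cds_start_tx < self.cds_end_tx <= self.length:
            raise ModelError(
                f"{self.transcript_id}: CDS [{self.cds_start_tx}, {self.cds_end_tx}) "
                f"outside transcript of length {self.length}"
            )
        if require_coding_frame and (self.cds_end_tx - self.cds_start_tx) % 3 != 0:
            raise ModelError(
                f"{self.transcript_id}: CDS length not a multiple of 3"
            )


class GenomeSequence:
    """Chromosome-id -> nucleotide string mapping over {A, C, G, T, N}."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {str(k): str(v).upper() for k, v in sequences.items()}
        for chrom, seq in self._seqs.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ModelError(f"{chrom}: non-ACGTN symbols {sorted(bad)}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def chroms(self) -> list[str]:
        return sorted(self._seqs)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs[chrom]
        if not 0 <= start <= end <= len(seq):
            raise CoordinateError(
                f"{chrom}:[{start}, {end}) outside sequence of length {len(seq)}"
            )
        return seq[start:end]

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        try:
            return cls({name: str(fa[name][:]) for name in fa.keys()})
        finally:
            fa.close()

    def to_fasta(self, path: Union[str, Path], width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms():
                fh.write(f">{chrom}\n")
                seq = self._seqs[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# coordinate operations
# ---------------------------------------------------------------------------


def transcript_sequence(t: TranscriptModel, genome: GenomeSequence) -> str:
    """Spliced mRNA sequence: exon sequences concatenated 5'->3'.

    Minus-strand exons are reverse-complemented; length equals the sum of
    exon lengths.
    """
    parts = []
    for s, e in t.exons:
        chunk = genome.fetch(t.chrom, s, e)
        parts.append(chunk if t.strand == "+" else reverse_complement(chunk))
    return "".join(parts)


def genome_to_transcript(
    t: TranscriptModel, genomic_pos: int
) -> Union[int, IntronicPosition]:
    """Map a genomic position to a transcript offset, or an intron marker."""
    lo, hi = t.genomic_span
    if not lo <= genomic_pos < hi:
        raise CoordinateError(
            f"{t.transcript_id}: genomic position {genomic_pos} outside span [{lo}, {hi})"
        )
    off = 0
    for i, (s, e) in enumerate(t.exons, start=1):
        if s <= genomic_pos < e:
            within = genomic_pos - s if t.strand == "+" else e - 1 - genomic_pos
            return off + within
        off += e - s
    # intronic: find flanking exons in transcript orientation
    for i in range(t.n_exons - 1):
        up, down = t.exons[i], t.exons[i + 1]
        gap = (up[1], down[0]) if t.strand == "+" else (down[1], up[0])
        if gap[0] <= genomic_pos < gap[1]:
            return IntronicPosition(
                intron_index=i + 1, upstream_exon=i + 1, downstream_exon=i + 2
            )
    raise AssertionError("position inside span but in no exon or intron")


def transcript_to_genome(t: TranscriptModel, tx_pos: int) -> int:
    """Inverse of genome_to_transcript on exonic positions."""
    if not 0 <= tx_pos < t.length:
        raise CoordinateError(
            f"{t.transcript_id}: transcript offset {tx_pos} outside [0, {t.length})"
        )
    off = 0
    for s, e in t.exons:
        ln = e - s
        if tx_pos < off + ln:
            within = tx_pos - off
            return s + within if t.strand == "+" else e - 1 - within
        off += ln
    raise AssertionError("unreachable")


def transcript_to_genome_intervals(
    t: TranscriptModel, tx_start: int, tx_end: int
) -> list[tuple[int, int]]:
    """Genomic intervals (0-based half-open) covered by a transcript interval.

    Returned in transcript orientation, one interval per overlapped exon.
    """
    if not 0 <= tx_start <= tx_end <= t.length:
        raise CoordinateError(f"transcript interval [{tx_start}, {tx_end}) out of range")
    out: list[tuple[int, int]] = []
    off = 0
    for s, e in t.exons:
        ln = e - s
        a, b = max(tx_start, off), min(tx_end, off + ln)
        if a < b:
            if t.strand == "+":
                out.append((s + (a - off), s + (b - off)))
            else:
                out.append((e - (b - off), e - (a - off)))
        off += ln
    return out


def last_junction_tx(t: TranscriptModel) -> Optional[int]:
    """Transcript offset of the first base of the last exon, or None.

    The last exon-exon junction lies between offsets ``j - 1`` and ``j`` for
    the returned ``j``. Single-exon transcripts have no junction.
    """
    if t.n_exons < 2:
        return None
    return t.length - t.exon_lengths[-1]


# ---------------------------------------------------------------------------
# GTF / FASTA I/O
# ---------------------------------------------------------------------------


def load_gene_models(
    gtf_source: Union[str, Path], fasta_source: Union[str, Path]
) -> tuple[list[TranscriptModel], GenomeSequence]:
    """Read transcript models from a GTF and the genome from a FASTA.

    Exon and CDS features are grouped by their ``transcript_id`` attribute.
    Transcripts without a CDS are skipped with a warning; an exon beyond the
    FASTA bounds is a hard error. Minus-strand exon lists are re-ordered
    5'->3' so downstream logic is strand-free.
    """
    import gffutils

    genome = GenomeSequence.from_fasta(fasta_source)
    db = gffutils.create_db(
        str(gtf_source),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for kind, store in (("exon", exons), ("CDS", cds)):
        for feat in db.features_of_type(kind):
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
            meta.setdefault(tid, (gid, feat.seqid, feat.strand))
            # GTF 1-based inclusive -> 0-based half-open
            store.setdefault(tid, []).append((feat.start - 1, feat.end))

    models: list[TranscriptModel] = []
    for tid in sorted(exons):
        gid, chrom, strand = meta[tid]
        if tid not in cds:
            log.warning("transcript %s has no CDS feature; skipped", tid)
            continue
        if chrom not in genome:
            raise ModelError(f"{tid}: chromosome {chrom} absent from FASTA")
        chrom_len = len(genome[chrom])
        ex = sorted(exons[tid])
        for s, e in ex:
            if e > chrom_len or s < 0:
                raise CoordinateError(
                    f"{tid}: exon [{s}, {e}) outside {chrom} (length {chrom_len})"
                )
        if strand == "-":
            ex = ex[::-1]
        # provisional model for coordinate mapping of the CDS span
        prov = TranscriptModel(tid, gid, chrom, strand, tuple(ex), 0, 3)
        cds_iv = sorted(cds[tid])
        cds_len = sum(e - s for s, e in cds_iv)
        g5 = cds_iv[0][0] if strand == "+" else cds_iv[-1][1] - 1
        g3 = cds_iv[-1][1] - 1 if strand == "+" else cds_iv[0][0]
        cds_start = genome_to_transcript(prov, g5)
        cds_end_incl = genome_to_transcript(prov, g3)
        if not isinstance(cds_start, int) or not isinstance(cds_end_incl, int):
            raise ModelError(f"{tid}: CDS boundary not exonic")
        if cds_end_incl - cds_start + 1 != cds_len:
            raise ModelError(f"{tid}: CDS features not contiguous in transcript space")
        model = TranscriptModel(
            tid, gid, chrom, strand, tuple(ex), cds_start, cds_end_incl + 1
        )
        model.validate()
        models.append(model)
    return models, genome


def write_gene_models(
    models: Iterable[TranscriptModel],
    genome: GenomeSequence,
    gtf_path: Union[str, Path],
    fasta_path: Union[str, Path],
) -> None:
    """Emit the fixture GTF (1-based inclusive) and FASTA for a model set."""
    with open(gtf_path, "w") as fh:
        for t in models:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for s, e in sorted(t.exons):
                fh.write(
                    f"{t.chrom}\tmsinmd\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            for s, e in sorted(
                transcript_to_genome_intervals(t, t.cds_start_tx, t.cds_end_tx)
            ):
                fh.write(
                    f"{t.chrom}\tmsinmd\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t0\t{attrs}\n"
                )
    genome.to_fasta(fasta_path)


def canonical_transcripts(models: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    """One transcript per gene: the longest CDS wins, ties by transcript id.

    The cohort analyses are per-gene; when a gene carries several isoforms the
    longest-CDS one is marked canonical and used downstream.
    """
    by_gene: dict[str, TranscriptModel] = {}
    for t in models:
        cur = by_gene.get(t.gene_id)
        key = (t.cds_end_tx - t.cds_start_tx, t.transcript_id)
        if cur is None or key > (cur.cds_end_tx - cur.cds_start_tx, cur.transcript_id):
            by_gene[t.gene_id] = t
    return [by_gene[g] for g in sorted(by_gene)]
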