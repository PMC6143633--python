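"""Plain-text table I/O: the TSV dialects shared by the pipeline stages.

All tables are tab-separated with a header row and deterministic column
order. Genomic coordinates in the mutation table are 1-based (the repeat
start), matching the GTF dialect; everything internal stays 0-based.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .gene_models import TranscriptModel
from .nmd_classify import MutationCall, MutationKind, PTCAnnotation
from .repeat_scan import RepeatLocus, annotate_repeat_context

PathLike = Union[str, Path]

MUTATION_COLUMNS = [
    "gene_id",
    "transcript_id",
    "chrom",
    "repeat_start",
    "base",
    "run_length",
    "delta_bp",
    "kind",
]

REPEAT_COLUMNS = [
    "gene_id",
    "transcript_id",
    "chrom",
    "start",
    "end",
    "base",
    "run_length",
    "context",
    "index",
    "distance_to_acceptor",
]

CLASSIFICATION_COLUMNS = [
    "gene_id",
    "transcript_id",
    "kind",
    "delta_bp",
    "location_class",
    "nmd_class",
    "splice_outcome",
    "ptc_tx_pos",
    "ptc_exon_index",
    "distance_to_last_junction",
    "no_stop",
]


def write_mutations(calls: Iterable[MutationCall], path: PathLike) -> None:
    rows = []
    for m in calls:
        rows.append(
            {
                "gene_id": m.gene_id,
                "transcript_id": m.transcript_id,
                "chrom": m.locus.chrom,
                "repeat_start": m.locus.start + 1,
                "base": m.locus.base,
                "run_length": m.locus.run_length,
                "delta_bp": m.delta_bp,
                "kind": m.kind.value,
            }
        )
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutations(
    path: PathLike, models: Mapping[str, TranscriptModel]
) -> list[MutationCall]:
    """Read mutation calls and annotate each repeat locus on its transcript.

    ``models`` maps transcript_id to TranscriptModel; unknown transcript ids
    are collected and reported together.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    unknown = sorted(set(df["transcript_id"]) - set(models))
    if unknown:
        raise KeyError(f"unknown transcript ids in mutation table: {unknown}")
    calls = []
    for row in df.itertuples():
        t = models[row.transcript_id]
        start = int(row.repeat_start) - 1
        locus = RepeatLocus(
            gene_id=row.gene_id,
            transcript_id=row.transcript_id,
            chrom=row.chrom,
            start=start,
            end=start + int(row.run_length),
            base=str(row.base),
            run_length=int(row.run_length),
        )
        locus = annotate_repeat_context(t, locus)
        calls.append(
            MutationCall(
                gene_id=row.gene_id,
                transcript_id=row.transcript_id,
                locus=locus,
                delta_bp=int(row.delta_bp),
                kind=MutationKind(row.kind),
            )
        )
    return calls


def write_repeats(loci: Iterable[RepeatLocus], path: PathLike) -> None:
    rows = []
    for r in loci:
        rows.append(
            {
                "gene_id": r.gene_id,
                "transcript_id": r.transcript_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "base": r.base,
                "run_length": r.run_length,
                "context": r.context.value if r.context else "",
                "index": -1 if r.exon_or_intron_index is None else r.exon_or_intron_index,
                "distance_to_acceptor": (
                    -1
                    if r.distance_to_downstream_acceptor is None
                    else r.distance_to_downstream_acceptor
                ),
            }
        )
    pd.DataFrame(rows, columns=REPEAT_COLUMNS).to_csv(path, sep="\t", index=False)


def classification_frame(
    items: Sequence[tuple[MutationCall, PTCAnnotation]]
) -> pd.DataFrame:
    rows = []
    for call, ann in items:
        rows.append(
            {
                "gene_id": call.gene_id,
                "transcript_id": call.transcript_id,
                "kind": call.kind.value,
                "delta_bp": call.delta_bp,
                "location_class": ann.location_class.value if ann.location_class else "",
                "nmd_class": ann.nmd_class.value,
                "splice_outcome": ann.splice_outcome.value if ann.splice_outcome else "",
                "ptc_tx_pos": -1 if ann.ptc_tx_pos is None else ann.ptc_tx_pos,
                "ptc_exon_index": -1 if ann.ptc_exon_index is None else ann.ptc_exon_index,
                "distance_to_last_junction": (
                    -1
                    if ann.distance_to_last_junction is None
                    else ann.distance_to_last_junction
                ),
                "no_stop": ann.no_stop,
            }
        )
    return pd.DataFrame(rows, columns=CLASSIFICATION_COLUMNS)


def write_classification(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_classification(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(expr: pd.DataFrame, path: PathLike) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


def read_expression(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_metadata(metadata: pd.DataFrame, path: PathLike) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", keep_default_na=False)
    for col in ("group", "treatment", "pair_id"):
        if col not in df.columns:
            raise ValueError(f"metadata missing column {col!r}")
        df[col] = df[col].astype(str)
    return df
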