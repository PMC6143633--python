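"""Deletion-size-dependent exon skipping (HSP110 T17-type rule).

Large deletions in an intronic T-run adjacent to a splice acceptor abolish
recognition of the downstream exon; small deletions leave splicing intact.
The rule is deterministic and binary: deletions of at most
``skip_threshold_bp`` (default 4) splice normally, anything larger skips the
single exon immediately downstream of the repeat-bearing intron. No partial
or stochastic skipping is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Union

from .gene_models import ModelError, TranscriptModel


class SpliceOutcome(str, Enum):
    NORMAL = "NORMAL"
    EXON_SKIP = "EXON_SKIP"


@dataclass(frozen=True)
class SpliceModelParams:
    """Per-gene skipping rule.

    ``skipped_exon_index`` (1-based) is the exon immediately downstream of
    the repeat-bearing intron — exon 9 for the HSP110-like gene.
    """

    skipped_exon_index: int
    skip_threshold_bp: int = 4

    def __post_init__(self):
        if self.skip_threshold_bp < 1:
            raise ValueError("skip_threshold_bp must be >= 1")


def predict_splicing_outcome(
    deletion_bp: int, params: SpliceModelParams
) -> SpliceOutcome:
    """NORMAL iff the deletion is <= the threshold, EXON_SKIP otherwise."""
    if deletion_bp <= 0:
        raise ValueError(f"deletion_bp must be positive, got {deletion_bp}")
    if deletion_bp <= params.skip_threshold_bp:
        return SpliceOutcome.NORMAL
    return SpliceOutcome.EXON_SKIP


def build_skipped_transcript(t: TranscriptModel, exon_index: int) -> TranscriptModel:
    """Transcript model with one internal exon removed.

    The first and last exons cannot be skipped. CDS offsets are recomputed;
    if the skipped exon length is not a multiple of 3 the downstream frame
    shifts, so the mutant model is validated without the coding-frame
    requirement. Skipping an exon that contains the start codon is an error.
    """
    if not 1 < exon_index < t.n_exons:
        raise ModelError(
            f"{t.transcript_id}: cannot skip exon {exon_index} of {t.n_exons} "
            "(first and last exons are not skippable)"
        )
    a, b = t.tx_interval_of_exon(exon_index)
    if a < t.cds_start_tx + 3 and t.cds_start_tx < b:
        raise ModelError(
            f"{t.transcript_id}: skipping exon {exon_index} would remove the start codon"
        )
    removed_before_start = b - a if b <= t.cds_start_tx else 0
    overlap_cds_end = max(0, min(b, t.cds_end_tx) - min(a, t.cds_end_tx))
    mutant = TranscriptModel(
        transcript_id=t.transcript_id,
        gene_id=t.gene_id,
        chrom=t.chrom,
        strand=t.strand,
        exons=t.exons[: exon_index - 1] + t.exons[exon_index:],
        cds_start_tx=t.cds_start_tx - removed_before_start,
        cds_end_tx=t.cds_end_tx - overlap_cds_end,
    )
    mutant.validate(require_coding_frame=False)
    return mutant


# ---------------------------------------------------------------------------
# per-gene splice-rule table
# ---------------------------------------------------------------------------

_RULE_COLUMNS = ["gene_id", "intron_index", "skip_threshold_bp", "skipped_exon_index"]


def write_splice_rules(
    rules: dict[str, SpliceModelParams], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_RULE_COLUMNS) + "\n")
        for gene_id in sorted(rules):
            p = rules[gene_id]
            fh.write(
                f"{gene_id}\t{p.skipped_exon_index - 1}\t{p.skip_threshold_bp}\t"
                f"{p.skipped_exon_index}\n"
            )


def read_splice_rules(path: Union[str, Path]) -> dict[str, SpliceModelParams]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = set(_RULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"splice rule table missing columns: {sorted(missing)}")
    return {
        row.gene_id: SpliceModelParams(
            skipped_exon_index=int(row.skipped_exon_index),
            skip_threshold_bp=int(row.skip_threshold_bp),
        )
        for row in df.itertuples()
    }
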