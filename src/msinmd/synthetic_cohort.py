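"""Synthetic MSI/MSS cohort generator.

Builds gene models with embedded mononucleotide repeats, slippage mutation
calls, and log2 expression matrices with the statistical structure the decay
analysis assumes, so the whole pipeline is testable without controlled-access
tumor data. Generation is a pure function of the parameter set: the same
seed yields a byte-identical cohort.

What is emulated
----------------
* multi-exon genes whose coding or intronic homopolymer runs carry 1-2 bp
  coding indels or 1-14 bp intronic T-run deletions;
* one flagship HSP110-like 18-exon gene with an intron-8 T17 run three
  nucleotides upstream of the exon-9 acceptor, whose exon 9 has length not
  divisible by 3 and whose exon 10 carries an out-of-frame stop, so that
  large T17 deletions produce an exon-9-skipped transcript with a PTC in
  exon 10;
* Gaussian log2 expression noise around per-gene baselines, with a
  multiplicative decay effect restricted to NMD-substrate mutant genes in
  MSI samples;
* an MSI-vs-MSS shift of the NMD-factor panel, with the UPF3A-like factor
  down-regulated;
* treated/untreated pairs in which NMD inhibition rescues substrate
  expression only.

Expression is simulated directly on the log2 scale (microarray-style
intensities), not as sequencing counts. Allele dosage is collapsed to a
homozygous-equivalent effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .decay_stats import NMD_FACTORS
from .gene_models import (
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
)
from .nmd_classify import (
    MutationCall,
    MutationKind,
    NMDClass,
    NMDRuleParams,
    classify_variant,
)
from .repeat_scan import RepeatContext, RepeatLocus, annotate_repeat_context
from .splice_model import SpliceModelParams

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
SENSE_CODONS = np.array(
    [a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS]
)

FLAGSHIP_GENE_ID = "HSPH1L"

_UTR5 = 12
_UTR3 = 30
_MIN_EXON = 25
_EDGE_MARGIN = 40
_PAD = 25


class GenerationError(RuntimeError):
    """The requested constraints cannot be satisfied (e.g. exon too short)."""


@dataclass(frozen=True)
class SyntheticCohortParams:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: 667 mutated genes (569 NLE + 98 LE),
    40 MSI / 48 MSS tumors and 42 normal mucosa samples, a -1 log2 decay
    effect on NMD-substrate mutant transcripts, 0.5 log2 Gaussian noise, a
    0.5 log2 NMD-factor shift in MSI (UPF3A-like factor negated), and a +1
    log2 rescue under NMD inhibition.
    """

    n_genes: int = 667
    n_msi_samples: int = 40
    n_mss_samples: int = 48
    n_normal_samples: int = 42
    fraction_le_repeats: float = 98 / 667
    fraction_intronic_repeats: float = 0.05
    fraction_mutated_in_msi: float = 1.0
    decay_effect_log2: float = -1.0
    noise_sd_log2: float = 0.5
    factor_shift_log2: float = 0.5
    inhibition_rescue_log2: float = 1.0
    min_run_length: int = 8
    include_flagship_gene: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "fraction_le_repeats",
            "fraction_intronic_repeats",
            "fraction_mutated_in_msi",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise_sd_log2 must be positive")
        if self.decay_effect_log2 > 0:
            raise ValueError("decay_effect_log2 must be <= 0")
        for name in ("n_genes", "n_msi_samples", "n_mss_samples", "n_normal_samples"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.min_run_length < 5:
            raise ValueError("min_run_length must be >= 5")


@dataclass
class GeneModelSet:
    """Gene models plus the designated repeat locus of every gene."""

    models: list[TranscriptModel]
    genome: GenomeSequence
    designated_loci: dict[str, RepeatLocus]
    splice_rules: dict[str, SpliceModelParams]

    def model_for(self, gene_id: str) -> TranscriptModel:
        for m in self.models:
            if m.gene_id == gene_id:
                return m
        raise KeyError(gene_id)


@dataclass
class SyntheticCohort:
    params: SyntheticCohortParams
    model_set: GeneModelSet
    mutations: list[MutationCall]
    truth: pd.DataFrame
    expression: pd.DataFrame
    metadata: pd.DataFrame


# ---------------------------------------------------------------------------
# sequence construction helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, n)])


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(SENSE_CODONS[rng.integers(0, len(SENSE_CODONS), n_codons - 2)])
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + body + stop


def _run_segment(base: str, run_length: int) -> str:
    """Codon-aligned segment holding a maximal run, stop-free in frame.

    One filler base before the run and 1-3 after pad the segment to a codon
    multiple; the filler differs from the run base (maximality) and is C
    (or G for C-runs), which cannot complete a stop codon in any register.
    """
    filler = "C" if base != "C" else "G"
    suffix = 3 - (1 + run_length) % 3
    return filler + base * run_length + filler * suffix


def _sample_junctions(
    rng: np.random.Generator, total: int, n_exons: int
) -> Optional[list[int]]:
    if n_exons == 1:
        return []
    lo, hi = _EDGE_MARGIN, total - _EDGE_MARGIN
    if hi - lo < (n_exons - 1) * _MIN_EXON:
        return None
    for _ in range(40):
        js = np.sort(rng.integers(lo, hi, n_exons - 1))
        if len(js) == 1 or np.diff(js).min() >= _MIN_EXON:
            return [int(j) for j in js]
    return None


def _split_exons(total: int, junctions: list[int]) -> list[tuple[int, int]]:
    bounds = [0] + junctions + [total]
    return list(zip(bounds[:-1], bounds[1:]))


@dataclass
class _GeneDraft:
    """Forward-layout pieces of one gene before genomic placement."""

    gene_id: str
    exon_seqs: list[str]
    intron_seqs: list[str]
    cds_start: int
    cds_end: int
    run_forward: tuple[int, int]  # forward offsets incl. introns
    run_base_tx: str
    run_length: int
    expected_context: RepeatContext
    splice_rule: Optional[SpliceModelParams] = None


def _place_gene(
    draft: _GeneDraft, strand: str, rng: np.random.Generator
) -> tuple[TranscriptModel, str, RepeatLocus]:
    """Assemble contig sequence and genomic coordinates for a draft gene."""
    pieces, fwd_exons, off = [], [], 0
    for i, exon in enumerate(draft.exon_seqs):
        pieces.append(exon)
        fwd_exons.append((off, off + len(exon)))
        off += len(exon)
        if i < len(draft.intron_seqs):
            pieces.append(draft.intron_seqs[i])
            off += len(draft.intron_seqs[i])
    gene_seq = "".join(pieces)
    G = len(gene_seq)
    left, right = _random_seq(rng, _PAD), _random_seq(rng, _PAD)
    fa, fb = draft.run_forward
    if strand == "+":
        contig = left + gene_seq + right
        exons = tuple((_PAD + a, _PAD + b) for a, b in fwd_exons)
        g_start, g_end = _PAD + fa, _PAD + fb
        g_base = draft.run_base_tx
    else:
        contig = left + reverse_complement(gene_seq) + right
        exons = tuple((_PAD + G - b, _PAD + G - a) for a, b in fwd_exons)
        g_start, g_end = _PAD + G - fb, _PAD + G - fa
        g_base = reverse_complement(draft.run_base_tx)

    tid = f"{draft.gene_id}.t1"
    chrom = f"chr_{draft.gene_id}"
    model = TranscriptModel(
        transcript_id=tid,
        gene_id=draft.gene_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start_tx=draft.cds_start,
        cds_end_tx=draft.cds_end,
    )
    model.validate()
    locus = RepeatLocus(
        gene_id=draft.gene_id,
        transcript_id=tid,
        chrom=chrom,
        start=g_start,
        end=g_end,
        base=g_base,
        run_length=draft.run_length,
    )
    locus = annotate_repeat_context(model, locus)
    if locus.context is not draft.expected_context:
        raise GenerationError(
            f"{draft.gene_id}: designated locus annotated {locus.context}, "
            f"expected {draft.expected_context}"
        )
    if contig[g_start:g_end] != g_base * draft.run_length or (
        contig[g_start - 1] == g_base or contig[g_end] == g_base
    ):
        raise GenerationError(f"{draft.gene_id}: designated run is not maximal")
    return model, contig, locus


def _build_coding_gene(
    gene_id: str, rng: np.random.Generator, last_exon: bool
) -> _GeneDraft:
    """A gene whose designated repeat sits in coding sequence.

    ``last_exon=True`` places the run in the CDS portion of the last exon
    (an LE mutation target); otherwise in an earlier exon.
    """
    for _ in range(100):
        n_codons = int(rng.integers(140, 240))
        n_exons = int(rng.integers(3, 9))
        orf = _random_orf(rng, n_codons)
        total = _UTR5 + len(orf) + _UTR3
        junctions = _sample_junctions(rng, total, n_exons)
        if junctions is None:
            continue
        exon_bounds = _split_exons(total, junctions)
        target = n_exons if last_exon else int(rng.integers(1, n_exons))
        a, b = exon_bounds[target - 1]
        run_length = int(rng.integers(8, 11))
        base = _BASES[rng.choice(4, p=[0.4, 0.1, 0.1, 0.4])]
        seg = _run_segment(base, run_length)
        c_lo = max(1, math.ceil((a - _UTR5) / 3))
        c_hi = min(
            n_codons - 1 - len(seg) // 3, math.floor((b - _UTR5 - len(seg)) / 3)
        )
        if c_lo > c_hi:
            continue
        c = int(rng.integers(c_lo, c_hi + 1))
        orf = orf[: 3 * c] + seg + orf[3 * c + len(seg) :]
        tx = _random_seq(rng, _UTR5) + orf + _random_seq(rng, _UTR3)
        run_tx_start = _UTR5 + 3 * c + 1

        exon_seqs = [tx[s:e] for s, e in exon_bounds]
        intron_lengths = [int(rng.integers(50, 91)) for _ in range(n_exons - 1)]
        intron_seqs = [_random_seq(rng, ln) for ln in intron_lengths]
        # forward offset of the run: add lengths of introns upstream of it
        intron_before = sum(
            ln for (s, _), ln in zip(exon_bounds[1:], intron_lengths) if s <= run_tx_start
        )
        fa = run_tx_start + intron_before
        return _GeneDraft(
            gene_id=gene_id,
            exon_seqs=exon_seqs,
            intron_seqs=intron_seqs,
            cds_start=_UTR5,
            cds_end=_UTR5 + len(orf),
            run_forward=(fa, fa + run_length),
            run_base_tx=base,
            run_length=run_length,
            expected_context=RepeatContext.CODING,
        )
    raise GenerationError(f"{gene_id}: could not embed a coding repeat")


def _build_intronic_gene(gene_id: str, rng: np.random.Generator) -> _GeneDraft:
    """A gene whose designated repeat is an intronic T17 near an acceptor."""
    for _ in range(100):
        n_codons = int(rng.integers(140, 240))
        n_exons = int(rng.integers(5, 10))
        orf = _random_orf(rng, n_codons)
        total = _UTR5 + len(orf) + _UTR3
        junctions = _sample_junctions(rng, total, n_exons)
        if junctions is None:
            continue
        exon_bounds = _split_exons(total, junctions)
        tx = _random_seq(rng, _UTR5) + orf + _random_seq(rng, _UTR3)
        exon_seqs = [tx[s:e] for s, e in exon_bounds]
        # repeat-bearing intron j: skipped exon j+1 must be internal
        j = int(rng.integers(1, n_exons - 1))
        intron_seqs = []
        run_length = 17
        fa = None
        for i in range(n_exons - 1):
            if i + 1 == j:
                head = _random_seq(rng, 40)
                head = head[:-1] + "C"  # guard the run's 5' side
                intron = head + "T" * run_length + "CAG"
                fwd_intron_start = (
                    sum(len(e) for e in exon_seqs[: i + 1])
                    + sum(len(s) for s in intron_seqs)
                )
                fa = fwd_intron_start + len(head)
            else:
                intron = _random_seq(rng, int(rng.integers(50, 91)))
            intron_seqs.append(intron)
        assert fa is not None
        return _GeneDraft(
            gene_id=gene_id,
            exon_seqs=exon_seqs,
            intron_seqs=intron_seqs,
            cds_start=_UTR5,
            cds_end=_UTR5 + len(orf),
            run_forward=(fa, fa + run_length),
            run_base_tx="T",
            run_length=run_length,
            expected_context=RepeatContext.INTRONIC,
            splice_rule=SpliceModelParams(skipped_exon_index=j + 1),
        )
    raise GenerationError(f"{gene_id}: could not place an intronic repeat")


def _build_flagship_gene(rng: np.random.Generator) -> _GeneDraft:
    """The HSP110-like 18-exon gene.

    Fixed geometry: exon 9 is 49 nt (frame-shifting when skipped), intron 8
    carries a T17 run ending 3 nt before the exon-9 acceptor, and the first
    six coding bases of exon 10 are set so that the exon-9-skipped transcript
    reads a TAA in exon 10 (second skipped-frame codon) while the wild-type
    frame stays stop-free.
    """
    exon_tx_lengths = [72] + [60] * 7 + [49] + [60] + [60] * 7 + [89]
    assert len(exon_tx_lengths) == 18
    n_codons = 356  # 1068-nt CDS incl. native stop
    orf = list(_random_orf(rng, n_codons))
    assert len(orf) == 1068
    # exon 10 coding offsets are [529, 589); first six bases pinned
    orf[529:535] = "GCCTAA"
    orf = "".join(orf)
    tx = _random_seq(rng, _UTR5) + orf + _random_seq(rng, _UTR3)
    bounds, off = [], 0
    for ln in exon_tx_lengths:
        bounds.append((off, off + ln))
        off += ln
    exon_seqs = [tx[s:e] for s, e in bounds]
    run_length = 17
    intron_seqs, fa = [], None
    for i in range(17):
        if i + 1 == 8:
            head = _random_seq(rng, 40)
            head = head[:-1] + "C"
            intron = head + "T" * run_length + "CAG"
            fwd = sum(exon_tx_lengths[: i + 1]) + sum(len(s) for s in intron_seqs)
            fa = fwd + len(head)
        else:
            intron = _random_seq(rng, 60)
        intron_seqs.append(intron)
    assert fa is not None
    return _GeneDraft(
        gene_id=FLAGSHIP_GENE_ID,
        exon_seqs=exon_seqs,
        intron_seqs=intron_seqs,
        cds_start=_UTR5,
        cds_end=_UTR5 + len(orf),
        run_forward=(fa, fa + run_length),
        run_base_tx="T",
        run_length=run_length,
        expected_context=RepeatContext.INTRONIC,
        splice_rule=SpliceModelParams(skipped_exon_index=9),
    )


# ---------------------------------------------------------------------------
# generator operations
# ---------------------------------------------------------------------------


def generate_gene_models(params: SyntheticCohortParams) -> GeneModelSet:
    """Gene models, genome, designated loci, and per-gene splice rules."""
    params.validate()
    ss = np.random.SeedSequence(entropy=params.seed, spawn_key=(0,))
    rng = np.random.default_rng(ss)

    n = params.n_genes
    n_flag = 1 if params.include_flagship_gene else 0
    n_le = round(params.fraction_le_repeats * n)
    n_intronic = max(n_flag, round(params.fraction_intronic_repeats * n))
    n_nle_coding = n - n_le - n_intronic
    if n_nle_coding < 0:
        raise GenerationError("LE + intronic fractions exceed the gene count")
    kinds = (
        ["LE"] * n_le + ["INTRONIC"] * (n_intronic - n_flag) + ["NLE"] * n_nle_coding
    )
    kinds = [kinds[i] for i in rng.permutation(len(kinds))]

    models, seqs, loci, rules = [], {}, {}, {}

    def _add(draft: _GeneDraft, strand: str) -> None:
        model, contig, locus = _place_gene(draft, strand, rng)
        models.append(model)
        seqs[model.chrom] = contig
        loci[model.gene_id] = locus
        if draft.splice_rule is not None:
            rules[model.gene_id] = draft.splice_rule

    if params.include_flagship_gene:
        _add(_build_flagship_gene(rng), "+")
    width = len(str(n))
    for i, kind in enumerate(kinds, start=1):
        gene_id = f"G{i:0{width}d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "INTRONIC":
            _add(_build_intronic_gene(gene_id, rng), strand)
        else:
            _add(_build_coding_gene(gene_id, rng, last_exon=(kind == "LE")), strand)

    return GeneModelSet(
        models=models,
        genome=GenomeSequence(seqs),
        designated_loci=loci,
        splice_rules=rules,
    )


def generate_mutations(
    model_set: GeneModelSet,
    params: SyntheticCohortParams,
    nmd_params: NMDRuleParams = NMDRuleParams(),
) -> tuple[list[MutationCall], pd.DataFrame]:
    """One slippage call per mutated gene, plus the truth table.

    Coding loci draw 1-2 bp insertions/deletions; intronic T-runs draw 1-14
    bp deletions spanning both the small (<=4 bp) and large (>4 bp) regimes.
    Truth labels are the classifier's verdicts on the generated calls and
    drive the expression simulation.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=params.seed, spawn_key=(1,)))
    calls: list[MutationCall] = []
    rows = []
    for model in model_set.models:
        if rng.random() >= params.fraction_mutated_in_msi:
            continue
        locus = model_set.designated_loci[model.gene_id]
        if locus.context is RepeatContext.CODING:
            delta = int(rng.choice([-2, -1, 1, 2]))
            kind = MutationKind.CODING_FRAMESHIFT
        else:
            delta = -int(rng.integers(1, 15))
            kind = MutationKind.INTRONIC_REPEAT_DELETION
        call = MutationCall(
            gene_id=model.gene_id,
            transcript_id=model.transcript_id,
            locus=locus,
            delta_bp=delta,
            kind=kind,
        )
        ann = classify_variant(
            model,
            model_set.genome,
            call,
            params=nmd_params,
            splice_params=model_set.splice_rules.get(model.gene_id),
        )
        calls.append(call)
        rows.append(
            {
                "gene_id": model.gene_id,
                "transcript_id": model.transcript_id,
                "kind": kind.value,
                "delta_bp": delta,
                "location_class": ann.location_class.value,
                "nmd_class": ann.nmd_class.value,
                "splice_outcome": (
                    ann.splice_outcome.value if ann.splice_outcome else ""
                ),
                "ptc_tx_pos": -1 if ann.ptc_tx_pos is None else ann.ptc_tx_pos,
                "no_stop": ann.no_stop,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "transcript_id",
            "kind",
            "delta_bp",
            "location_class",
            "nmd_class",
            "splice_outcome",
            "ptc_tx_pos",
            "no_stop",
        ],
    )
    return calls, truth


def _sample_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:03d}" for i in range(1, n + 1)]


def generate_expression(
    model_set: GeneModelSet,
    truth: pd.DataFrame,
    params: SyntheticCohortParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2 expression matrix and sample metadata.

    Per-gene baselines are drawn once; every sample adds Gaussian noise. In
    MSI samples, genes whose mutation is an NMD substrate receive the decay
    effect, and the NMD-factor panel receives the factor shift (UPF3A-like
    factor negated). LE-mutant, INSENSITIVE and NO_PTC genes receive no
    decay shift.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=params.seed, spawn_key=(2,)))
    gene_ids = [m.gene_id for m in model_set.models] + list(NMD_FACTORS)
    msi = _sample_names("MSI", params.n_msi_samples)
    mss = _sample_names("MSS", params.n_mss_samples)
    normal = _sample_names("NORM", params.n_normal_samples)
    samples = msi + mss + normal

    baseline = rng.normal(8.0, 1.2, len(gene_ids))
    mat = baseline[:, None] + rng.normal(
        0.0, params.noise_sd_log2, (len(gene_ids), len(samples))
    )
    expr = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=samples)

    substrate = set(truth.loc[truth["nmd_class"] == NMDClass.SUBSTRATE.value, "gene_id"])
    row_is_sub = expr.index.isin(substrate)
    expr.loc[row_is_sub, msi] += params.decay_effect_log2
    for factor in NMD_FACTORS:
        shift = params.factor_shift_log2 * (-1.0 if factor == "UPF3A" else 1.0)
        expr.loc[factor, msi] += shift

    metadata = pd.DataFrame(
        {
            "group": ["MSI"] * len(msi) + ["MSS"] * len(mss) + ["NORMAL"] * len(normal),
            "treatment": "UNTREATED",
            "pair_id": "",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return expr, metadata


def simulate_inhibition(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: pd.DataFrame,
    params: SyntheticCohortParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add NMD-inhibited copies of the MSI samples, paired to the originals.

    Treated values are the untreated values plus the rescue effect on
    SUBSTRATE mutant genes only, plus fresh measurement noise. Returns the
    extended matrix and metadata (pairing keys set on both members).
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=params.seed, spawn_key=(3,)))
    msi = metadata.index[
        (metadata["group"] == "MSI") & (metadata["treatment"] == "UNTREATED")
    ].tolist()
    if not msi:
        raise ValueError("no untreated MSI samples to treat")
    substrate = set(truth.loc[truth["nmd_class"] == NMDClass.SUBSTRATE.value, "gene_id"])
    rescue = np.where(expr.index.isin(substrate), params.inhibition_rescue_log2, 0.0)

    treated_names = [f"{s}_T" for s in msi]
    treated = (
        expr[msi].to_numpy()
        + rescue[:, None]
        + rng.normal(0.0, params.noise_sd_log2, (expr.shape[0], len(msi)))
    )
    expr_out = pd.concat(
        [expr, pd.DataFrame(treated, index=expr.index, columns=treated_names)], axis=1
    )
    meta_out = metadata.copy()
    meta_out.loc[msi, "pair_id"] = msi
    treated_meta = pd.DataFrame(
        {"group": "MSI", "treatment": "NMD_INHIBITED", "pair_id": msi},
        index=pd.Index(treated_names, name="sample_id"),
    )
    return expr_out, pd.concat([meta_out, treated_meta])


def generate_cohort(
    params: SyntheticCohortParams = SyntheticCohortParams(),
    with_inhibition: bool = True,
) -> SyntheticCohort:
    """Full cohort: models, mutations, truth, expression, metadata."""
    model_set = generate_gene_models(params)
    mutations, truth = generate_mutations(model_set, params)
    expr, metadata = generate_expression(model_set, truth, params)
    if with_inhibition:
        expr, metadata = simulate_inhibition(expr, metadata, truth, params)
    return SyntheticCohort(
        params=params,
        model_set=model_set,
        mutations=mutations,
        truth=truth,
        expression=expr,
        metadata=metadata,
    )
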