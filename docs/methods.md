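# Methods

## The positional NMD model

A transcript is modelled as an ordered list of exons (genomic 0-based
half-open intervals, 5'→3' in transcript orientation) with a CDS given in
transcript coordinates and *including* the native stop codon. Minus-strand
models are normalized at load time so every downstream computation is
strand-free. The classifier is the standard positional rule for mammalian
NMD: a premature termination codon (PTC) triggers decay when it lies in the
coding region outside the last exon and more than 55 nt upstream of the
last exon–exon junction; PTCs in the last exon or within 55 nt of the
junction escape. The boundary is strict — a PTC at exactly 55 nt is
INSENSITIVE — and the distance is measured from the *first base* of the
stop codon to the junction offset in mutant coordinates. The anchor base is
a convention (the rule's source does not fix one); first-base is applied
consistently, and shifting the anchor by two bases would matter only for
PTCs landing exactly at the boundary. Single-exon transcripts have no
junction and are INSENSITIVE. Transcripts whose mutant reading frame
reaches the 3' end without any stop are flagged `no_stop` (nonstop decay is
a different pathway) and excluded from the cohort statistics, as are
transcripts whose first in-frame stop falls at or downstream of the shifted
native stop position (readthrough into the 3' UTR; classified NO_PTC).

Mutations are slippage events in mononucleotide runs. Indels are applied at
the 3' end of the run (right-aligned): the true slippage position within a
homopolymer is unobservable, so a deterministic convention is required, and
right-alignment matches the common normalization for indels in repeats.
In-frame indels (|Δ| a multiple of 3) are accepted and classify as NO_PTC
unless they create a stop. Zygosity is ignored for classification; allele
dosage would only scale the expression effect and is collapsed to a
homozygous-equivalent shift in the simulator.

Intronic T-run deletions are routed through a deterministic splice rule:
deletions of at most `skip_threshold_bp` (default 4) splice normally,
larger ones skip the single exon immediately downstream of the
repeat-bearing intron. The rule is binary because the modelled phenomenon
is reported as all-or-none; no partial or stochastic skipping is simulated.
Only single-exon skipping is supported, parameterized per gene in a small
TSV table.

## Mutation-position vs PTC-position location classes

The LE/NLE label (mutation in the last exon vs before it) is assigned from
the *mutation's* 5'-most base by default, because that is how the cohort
classes are defined on the microsatellite itself; a PTC-position variant
(`ptc_location_class`) is provided for sensitivity analyses. For coding
frameshifts the two labels usually coincide (the first out-of-frame stop
tends to appear near the mutation), but an NLE mutation can produce a
last-exon PTC, which the NMD classifier handles independently of the
location label.

## Cohort statistics

Expression is a genes × samples matrix of log2 intensities
(microarray-style). Fold-changes are differences of group means on the log2
scale; the down-regulation threshold of −0.5 is therefore a log2 threshold
(a negative cutoff is meaningless on a linear ratio scale). Group tests are
Welch (unequal-variance) two-sample t-tests, or one-way ANOVA for more than
two groups; Welch avoids an unstated equal-variance assumption at a
negligible power cost for these group sizes. Multiple testing uses
Benjamini–Hochberg step-up FDR (statsmodels) across the tested gene set. A
`moderated` flag reserves space for an empirical-Bayes variance-shrinkage
variant; it is not implemented, and with ≥ 30 samples per group the
moderated and ordinary t are nearly identical. The significance level for
the down-regulation filter is α = 0.05.

The LE/NLE decay contrast is a Welch t-test comparing per-gene log2
fold-changes between the NLE and LE classes; a negative statistic means NLE
transcripts are more down-regulated. Inhibition response is the per-gene
linear-scale ratio 2^(mean log2 treated − mean log2 untreated) over
pair-validated treated/untreated samples. qPCR quantification is the ΔCt
rule 2^−(target Ct − reference Ct).

## The synthetic cohort

The generator is a pure function of its parameter set (same seed →
byte-identical GTF, FASTA and tables; stage-level streams are spawned from
the seed so models, mutations, expression and treatment noise are
independent). Defaults are the emulated study conditions:

| parameter | default | why |
|---|---|---|
| `n_genes` | 667 | 569 NLE + 98 LE mutated genes in the emulated cohort |
| `fraction_le_repeats` | 98/667 | last-exon share of mutated microsatellites |
| `fraction_intronic_repeats` | 0.05 | a small minority of events are intronic T-run deletions |
| `n_msi / n_mss / n_normal` | 40 / 48 / 42 | tumor and mucosa counts of the emulated expression series |
| `decay_effect_log2` | −1.0 | no measured magnitude exists; a two-fold decay is a typical strong NMD effect |
| `noise_sd_log2` | 0.5 | typical between-sample log2 spread of array intensities |
| `factor_shift_log2` | 0.5 | a modest, clearly significant factor shift at these group sizes |
| `inhibition_rescue_log2` | 1.0 | rescue restoring the decayed two-fold loss |
| `min_run_length` | 8 | detection floor keeping fixtures small but non-trivial |
| coding Δ | ±1, ±2 bp uniform | slippage indel sizes in coding repeats |
| intronic Δ | −1 … −14 bp uniform | spans both the normal-splicing (≤4) and exon-skip (>4) regimes |

Genes are built as valid ORFs from sense codons (so wild-type frames are
stop-free by construction) with a designated maximal homopolymer run
embedded per gene: guard bases flanking the run keep it maximal and
stop-free in frame. Exon boundaries are sampled away from the transcript
edges so start and stop codons stay in the first and last exons. One
flagship HSP110-like gene is constructed deterministically: 18 exons, exon
9 of length 49 nt, a T17 in intron 8 ending 3 nt before the exon-9
acceptor, and the first six coding bases of exon 10 pinned to `GCCTAA` so
that the exon-9-skipped frame reads a stop in exon 10 while the wild-type
frame does not.

Expression is simulated directly on the log2 scale: per-gene baselines ~
N(8, 1.2), i.i.d. Gaussian noise per sample, the decay effect added to
NMD-substrate mutant genes in MSI samples only, and the factor shift added
to the eight-gene NMD-factor panel in MSI samples (negated for the
UPF3A-like factor, which is down- rather than up-regulated). Treated
samples copy their untreated partners, add the rescue to substrate genes
only, and add fresh measurement noise, so treated/untreated pairs are
positively correlated as in a real paired design.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: probe-level array artifacts and normalization,
per-sample mutation heterogeneity (every MSI sample carries every call),
allele dosage, co-occurring mutations in one gene, tumor purity, batch
structure, correlated gene modules, and any sequence context effect on NMD
efficiency beyond the binary positional rule.

## Numerical and implementation choices

- Coordinates are 0-based half-open internally; GTF I/O is 1-based
  inclusive, and CDS features in the emitted GTF include the stop codon.
- One transcript per gene is used downstream; with multiple isoforms the
  longest CDS is canonical (deterministic tie-break by transcript id).
- Repeats spanning an exon boundary are classified by their 5'-most base —
  a deterministic tie-break for an unspecified case.
- Degenerate group tests (zero variance everywhere, equal means) return
  p = 1 rather than NaN.
- Problem sizes in the test suite (200-gene cohorts, 30 + 30 samples,
  1,000-replicate calibrations) were chosen so the full suite completes in
  well under a minute while keeping Monte Carlo bands tight; they are the
  package's own fixture scale, and the generator's defaults reproduce the
  full 667-gene cohort in a fraction of a second.

## Known limitations

- The 55-nt rule is a binary approximation; real NMD efficiency is graded
  and context-dependent (EJC deposition, UTR length, reinitiation).
- The splice model covers only the single-exon-skip, threshold-at-4-bp
  behavior of the HSP110-type locus; it is not a general splice-site
  strength predictor.
- The LE/NLE contrast tests a difference in means of fold-changes; it does
  not model per-gene variance heterogeneity or gene–gene correlation.
- The optional VCF input path is not implemented; mutation calls enter via
  the documented TSV dialect.
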