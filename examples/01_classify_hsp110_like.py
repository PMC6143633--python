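"""Worked example: intronic T17 deletions in the HSP110-like gene.

Builds the synthetic 18-exon HSP110-like gene (T17 run in intron 8, three
nucleotides upstream of the exon-9 acceptor), applies a small (2 bp) and a
large (7 bp) T-run deletion, and classifies the consequences. The large
deletion skips exon 9, shifts the reading frame, and places a premature
termination codon in exon 10, far upstream of the last exon-exon junction:
an NMD substrate. The small deletion leaves splicing intact.
"""

from msinmd import MutationCall, MutationKind, classify_variant
from msinmd.synthetic_cohort import (
    FLAGSHIP_GENE_ID,
    SyntheticCohortParams,
    generate_gene_models,
)

model_set = generate_gene_models(SyntheticCohortParams(n_genes=4, seed=2))
gene = model_set.model_for(FLAGSHIP_GENE_ID)
locus = model_set.designated_loci[FLAGSHIP_GENE_ID]

print(f"{FLAGSHIP_GENE_ID}: {gene.n_exons} exons, transcript length {gene.length} nt")
print(
    f"T{locus.run_length} run in intron {locus.exon_or_intron_index}, "
    f"{locus.distance_to_downstream_acceptor} nt upstream of the acceptor\n"
)

for delta in (-2, -7):
    call = MutationCall(
        FLAGSHIP_GENE_ID, gene.transcript_id, locus, delta,
        MutationKind.INTRONIC_REPEAT_DELETION,
    )
    ann = classify_variant(
        gene, model_set.genome, call,
        splice_params=model_set.splice_rules[FLAGSHIP_GENE_ID],
    )
    print(f"T17 deletion of {-delta} bp -> splicing {ann.splice_outcome.value}")
    if ann.ptc_tx_pos is None:
        print("  no premature termination codon; transcript escapes NMD\n")
    else:
        print(
            f"  PTC at transcript offset {ann.ptc_tx_pos} "
            f"(mutant exon {ann.ptc_exon_index} = original exon "
            f"{ann.ptc_exon_index + 1}), "
            f"{ann.distance_to_last_junction} nt upstream of the last junction"
        )
        print(f"  NMD class: {ann.nmd_class.value}\n")
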