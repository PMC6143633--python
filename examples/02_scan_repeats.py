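"""Scan synthetic transcripts for mononucleotide microsatellites.

Generates a small gene set, scans every transcript region (exons and
introns) for maximal homopolymer runs of at least 8 nt, and tabulates them
by genomic context. CODING runs are the slippage targets that produce
frameshift PTCs; INTRONIC T-runs near acceptors can perturb splicing.
"""

from collections import Counter

from msinmd import scan_transcript_region
from msinmd.synthetic_cohort import SyntheticCohortParams, generate_gene_models

model_set = generate_gene_models(SyntheticCohortParams(n_genes=25, seed=4))

loci = []
for model in model_set.models:
    loci.extend(scan_transcript_region(model, model_set.genome, min_run_length=8))

print(f"{len(loci)} repeat loci in {len(model_set.models)} transcripts\n")
counts = Counter(l.context.value for l in loci)
for context, n in sorted(counts.items()):
    print(f"  {context:<10} {n}")

print("\nfirst five loci:")
for l in loci[:5]:
    print(
        f"  {l.gene_id:<8} {l.chrom}:{l.start}-{l.end} "
        f"{l.base}x{l.run_length:<3} {l.context.value}"
    )
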