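"""Cohort decay statistics on a simulated MSI/MSS cohort.

Simulates a 200-gene cohort (30 MSI, 30 MSS tumors), classifies every
repeat mutation, and runs the decay analysis: per-gene log2 fold-changes
with Welch tests and BH correction, the NLE-vs-LE contrast (decay should
affect before-last-exon mutations only), the down-regulation filter
(q < 0.05 and log2 FC < -0.5), and the NMD-factor panel comparison.
"""

from msinmd.decay_stats import (
    compare_factor_expression,
    decay_test_table,
    le_nle_contrast,
    select_downregulated,
)
from msinmd.synthetic_cohort import SyntheticCohortParams, generate_cohort

params = SyntheticCohortParams(
    n_genes=200, n_msi_samples=30, n_mss_samples=30, n_normal_samples=2, seed=1
)
cohort = generate_cohort(params, with_inhibition=False)
truth = cohort.truth[~cohort.truth["no_stop"]]

results = decay_test_table(cohort.expression, cohort.metadata, truth, group_b="MSS")
contrast = le_nle_contrast(results)
print(
    f"NLE vs LE contrast: t = {contrast.statistic:.2f}, p = {contrast.p_value:.2e}\n"
    f"  mean log2 FC: NLE {contrast.mean_fc_nle:.3f} (n={contrast.n_nle}), "
    f"LE {contrast.mean_fc_le:+.3f} (n={contrast.n_le})"
)
print("  (negative NLE values = decay of before-last-exon mutant transcripts)\n")

down = select_downregulated(results)
print(f"{len(down)} genes pass the down-regulation filter (q<0.05, log2 FC < -0.5)")

factors = compare_factor_expression(cohort.expression, cohort.metadata)
print("\nNMD-factor panel (MSI - MSS):")
print(factors.round(3).to_string(index=False))
print("\nA negative UPF3A shift with positive shifts elsewhere mirrors the")
print("expected MSI overexpression signature of the decay machinery.")
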