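"""Cohort-level decay statistics.

Expression is a genes x samples matrix of log2 intensities (microarray-style)
with per-sample metadata: group (MSI / MSS / NORMAL / ADENOMA), treatment
(UNTREATED / NMD_INHIBITED), and a pairing key for treated/untreated pairs.

Operations: log2 fold-changes (group mean differences on the log scale),
Welch two-sample t-tests (one-way ANOVA for >2 groups), Benjamini-Hochberg
FDR correction, the LE-vs-NLE decay contrast, the down-regulation filter
(q < alpha and log2 FC < -0.5), an NMD-factor MSI-vs-MSS comparison table,
qPCR-style delta-Ct relative quantification, and treated/untreated NMD
inhibition response ratios.

The "fold-change < -0.5" filter threshold is interpreted on the log2 scale
(a negative threshold is meaningless on a linear ratio scale, and the input
intensities are log2 throughout). Welch (unequal-variance) t is used rather
than a pooled or moderated t; a ``moderated`` flag is reserved on
:func:`decay_test_table` for a future empirical-Bayes variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .nmd_classify import LocationClass, NMDClass

GROUPS = ("MSI", "MSS", "NORMAL", "ADENOMA")
TREATMENTS = ("UNTREATED", "NMD_INHIBITED")

#: The NMD-machinery panel compared between MSI and MSS tumors.
NMD_FACTORS = ("UPF1", "UPF2", "UPF3A", "UPF3B", "SMG1", "SMG2", "SMG6", "SMG7")

RESULT_COLUMNS = [
    "gene_id",
    "log2_fc",
    "t_stat",
    "p_value",
    "q_value",
    "location_class",
    "nmd_class",
    "passes_downregulation_filter",
]


@dataclass(frozen=True)
class ContrastResult:
    """Welch contrast of per-gene fold-changes between NLE and LE classes.

    ``statistic`` < 0 means NLE genes are more down-regulated than LE genes
    (the decay signature: NMD acts on before-last-exon mutations only).
    """

    statistic: float
    p_value: float
    mean_fc_nle: float
    mean_fc_le: float
    n_nle: int
    n_le: int


@dataclass(frozen=True)
class QPCRMeasurement:
    """A target/reference Ct pair; expression relative to the reference gene."""

    target_ct: float
    reference_ct: float

    @property
    def relative_expression(self) -> float:
        return float(2.0 ** -(self.target_ct - self.reference_ct))


def _check_samples(expr: pd.DataFrame, samples: Sequence[str], label: str) -> None:
    if len(samples) == 0:
        raise ValueError(f"empty sample group: {label}")
    missing = [s for s in samples if s not in expr.columns]
    if missing:
        raise KeyError(f"samples absent from matrix: {missing}")


def log2_fold_change(
    expr: pd.DataFrame,
    gene: str,
    group_a_samples: Sequence[str],
    group_b_samples: Sequence[str],
) -> float:
    """mean(log2 expr in a) - mean(log2 expr in b)."""
    _check_samples(expr, group_a_samples, "a")
    _check_samples(expr, group_b_samples, "b")
    row = expr.loc[gene]
    return float(row[list(group_a_samples)].mean() - row[list(group_b_samples)].mean())


def group_test(
    expr: pd.DataFrame, gene: str, groups: Sequence[Sequence[str]]
) -> tuple[float, float]:
    """Welch two-sample t (two groups) or one-way ANOVA (more).

    Degenerate input (zero variance in every group, equal means) yields
    (0.0, 1.0) rather than NaN.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for g in groups:
        _check_samples(expr, g, "group")
        if len(g) < 2:
            raise ValueError("each group needs >= 2 samples")
        arrays.append(expr.loc[gene, list(g)].to_numpy(dtype=float))
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        return 0.0, 1.0
    if len(arrays) == 2:
        res = sps.ttest_ind(arrays[0], arrays[1], equal_var=False)
    else:
        res = sps.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """BH step-up q-values, order-preserving, monotonicity enforced."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def le_nle_contrast(results: pd.DataFrame) -> ContrastResult:
    """Welch t comparing per-gene log2 FC between NLE and LE mutation classes."""
    for cls in (LocationClass.NLE, LocationClass.LE):
        if not (results["location_class"] == cls.value).any():
            raise ValueError(f"no genes in location class {cls.value}")
    nle = results.loc[
        results["location_class"] == LocationClass.NLE.value, "log2_fc"
    ].to_numpy(dtype=float)
    le = results.loc[
        results["location_class"] == LocationClass.LE.value, "log2_fc"
    ].to_numpy(dtype=float)
    if len(nle) < 2 or len(le) < 2:
        raise ValueError("each location class needs >= 2 genes for the contrast")
    stat, p = sps.ttest_ind(nle, le, equal_var=False)
    return ContrastResult(
        statistic=float(stat),
        p_value=float(p),
        mean_fc_nle=float(nle.mean()),
        mean_fc_le=float(le.mean()),
        n_nle=len(nle),
        n_le=len(le),
    )


def select_downregulated(
    results: pd.DataFrame, fc_threshold: float = -0.5, alpha: float = 0.05
) -> list[str]:
    """Genes with q < alpha and log2 FC strictly below the threshold.

    Sorted by fold-change ascending (most down-regulated first).
    """
    hit = results[
        (results["q_value"] < alpha) & (results["log2_fc"] < fc_threshold)
    ]
    return hit.sort_values(["log2_fc", "gene_id"])["gene_id"].tolist()


def compare_factor_expression(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    factor_genes: Sequence[str] = NMD_FACTORS,
    group_a: str = "MSI",
    group_b: str = "MSS",
) -> pd.DataFrame:
    """Per-factor log2 FC (MSI - MSS), Welch p, and BH q across the panel.

    Factors absent from the matrix get an NA row so the panel stays complete.
    """
    a = metadata.index[metadata["group"] == group_a].tolist()
    b = metadata.index[metadata["group"] == group_b].tolist()
    rows = []
    for gene in factor_genes:
        if gene not in expr.index:
            rows.append((gene, np.nan, np.nan, np.nan))
            continue
        fc = log2_fold_change(expr, gene, a, b)
        t, p = group_test(expr, gene, [a, b])
        rows.append((gene, fc, t, p))
    out = pd.DataFrame(rows, columns=["factor", "log2_fc", "t_stat", "p_value"])
    present = out["p_value"].notna()
    q = np.full(len(out), np.nan)
    if present.any():
        q[present.to_numpy()] = benjamini_hochberg(out.loc[present, "p_value"])
    out["q_value"] = q
    return out


def relative_expression(q: QPCRMeasurement) -> float:
    """Delta-Ct quantification: 2^-(target_ct - reference_ct)."""
    if not (np.isfinite(q.target_ct) and np.isfinite(q.reference_ct)):
        raise ValueError("Ct values must be finite")
    return q.relative_expression


def inhibition_response_ratio(
    expr: pd.DataFrame, metadata: pd.DataFrame
) -> pd.Series:
    """Per-gene treated/untreated expression ratio on the linear scale.

    Samples are paired by ``pair_id`` across treatment; every pair must have
    exactly one UNTREATED and one NMD_INHIBITED member. The ratio is
    2^(mean log2 treated - mean log2 untreated); values near 2 indicate a
    one-log2 re-expression under NMD inhibition, values near 1 no response.
    """
    paired = metadata[metadata["pair_id"].astype(str).str.len() > 0]
    if paired.empty:
        raise ValueError("no paired treated/untreated samples in metadata")
    treated, untreated = [], []
    for pair_id, grp in paired.groupby("pair_id"):
        tr = grp.index[grp["treatment"] == "NMD_INHIBITED"].tolist()
        ut = grp.index[grp["treatment"] == "UNTREATED"].tolist()
        if len(tr) != 1 or len(ut) != 1:
            bad = grp.index.tolist()
            raise ValueError(
                f"pair {pair_id!r} is not a treated/untreated pair: samples {bad}"
            )
        treated.append(tr[0])
        untreated.append(ut[0])
    diff = expr[treated].mean(axis=1) - expr[untreated].mean(axis=1)
    ratio = np.power(2.0, diff)
    ratio.name = "inhibition_response_ratio"
    return ratio


def decay_test_table(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    classification: pd.DataFrame,
    group_a: str = "MSI",
    group_b: str = "NORMAL",
    alpha: float = 0.05,
    fc_threshold: float = -0.5,
    moderated: bool = False,
) -> pd.DataFrame:
    """Per-gene decay test for every classified (mutated) gene.

    ``classification`` needs columns gene_id, location_class, nmd_class.
    Fold-change and Welch t compare ``group_a`` (mutant-bearing MSI tumors)
    against ``group_b`` (reference tissue); BH correction runs across the
    classified gene set; the filter flag is q < alpha AND log2 FC < threshold.
    Nonstop transcripts (no termination codon) are excluded upstream.
    """
    if moderated:
        raise NotImplementedError("moderated t-statistics are not implemented")
    untreated = metadata[metadata["treatment"] == "UNTREATED"]
    a = untreated.index[untreated["group"] == group_a].tolist()
    b = untreated.index[untreated["group"] == group_b].tolist()
    if not a or not b:
        raise ValueError(f"empty comparison group ({group_a}: {len(a)}, {group_b}: {len(b)})")

    genes = [g for g in classification["gene_id"] if g in expr.index]
    missing = sorted(set(classification["gene_id"]) - set(genes))
    if missing:
        raise KeyError(f"classified genes absent from expression matrix: {missing}")

    sub = expr.loc[genes]
    a_mat = sub[a].to_numpy(dtype=float)
    b_mat = sub[b].to_numpy(dtype=float)
    fc = a_mat.mean(axis=1) - b_mat.mean(axis=1)
    t, p = sps.ttest_ind(a_mat, b_mat, axis=1, equal_var=False)
    q = benjamini_hochberg(p)

    cls = classification.set_index("gene_id")
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "log2_fc": fc,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "location_class": cls.loc[genes, "location_class"].to_numpy(),
            "nmd_class": cls.loc[genes, "nmd_class"].to_numpy(),
        }
    )
    out["passes_downregulation_filter"] = (out["q_value"] < alpha) & (
        out["log2_fc"] < fc_threshold
    )
    return out[RESULT_COLUMNS]
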