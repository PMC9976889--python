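"""Expression-side pipeline: TPM, DE classification and state retention.

RNA-seq counts are length-normalised to transcripts per million (TPM);
transcript variants of one gene collapse to the maximally expressed
variant per sample.  Differential calls use the conjunction the study
applies: BH-adjusted p < 0.05 AND fold change > 2 or < 0.5 (with a
pseudocount of 1 on TPM before ratios).  The internal per-gene test is a
two-sample t on log2(TPM + 1) — an explicitly simplified stand-in for a
count-model DE test; externally computed p-values can be supplied
instead.

"State retention" is the study's signature of delayed differentiation:
the Spearman correlation of the transcriptome between the
undifferentiated (ESC) and differentiated (RA or OPC) state, computed on
replicate-mean expression with the 24 h and 72 h RA timepoints pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import CountsTable
from .genestats import CorrelationReport, compare_group_scores, spearman_correlation

__all__ = [
    "ExpressionMatrix",
    "GeneGroup",
    "tpm_normalize",
    "collapse_variants",
    "classify_de",
    "genes_higher_in",
    "group_expression_compare",
    "state_retention_correlation",
]

DEFAULT_EXCLUDE = frozenset({"chr8"})
RA_POOLED_TIMEPOINTS = (24, 72)


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM with per-sample metadata.

    Fresh output of :func:`tpm_normalize` has column sums of 1e6; gene
    subsetting deliberately does NOT renormalise (document-and-test
    contract) — call :func:`tpm_normalize` again if you need resummed
    columns.
    """

    tpm: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.tpm.columns) != set(self.meta.index):
            raise ValueError("sample mismatch between TPM matrix and metadata")
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        self.meta = self.meta.loc[list(self.tpm.columns)]

    def samples(self, line=None, state=None, timepoint_h=None) -> list:
        sel = pd.Series(True, index=self.meta.index)
        if line is not None:
            sel &= self.meta["line"] == line
        if state is not None:
            sel &= self.meta["state"] == state
        if timepoint_h is not None:
            tps = (timepoint_h,) if np.isscalar(timepoint_h) else tuple(timepoint_h)
            sel &= self.meta["timepoint_h"].isin(tps)
        return list(self.meta.index[sel])

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(tpm=self.tpm.loc[list(genes)], meta=self.meta.copy())


@dataclass
class GeneGroup:
    """A named gene set with the contrast that defined it."""

    name: str
    genes: frozenset
    contrast: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene group {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------


def tpm_normalize(
    counts: CountsTable,
    gene_lengths: Mapping[str, float],
    gene_chroms: Mapping[str, str] | None = None,
    exclude_chroms: Iterable[str] = DEFAULT_EXCLUDE,
) -> ExpressionMatrix:
    """Length-normalise raw counts to TPM (column sums exactly 1e6).

    ``TPM_g = 1e6 * (count_g / length_g) / sum_g'(count_g' / length_g')``.
    Genes on excluded chromosomes are removed BEFORE normalisation (when a
    gene -> chromosome map is supplied), so the excluded signal never
    enters the denominator.
    """
    table = counts.counts
    if gene_chroms is not None:
        excl = set(exclude_chroms)
        keep = [g for g in table.index if gene_chroms.get(g) not in excl]
        table = table.loc[keep]
    lengths = pd.Series({g: float(gene_lengths[g]) for g in table.index})
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = table.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    tpm = rate.div(totals, axis=1) * 1e6
    return ExpressionMatrix(tpm=tpm, meta=counts.meta.copy())


def collapse_variants(expr: ExpressionMatrix, variant_map: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse transcript variants to the maximally expressed variant.

    The maximum is taken per sample independently, so different variants
    may represent the gene in different samples.
    """
    unmapped = [v for v in expr.tpm.index if v not in variant_map]
    if unmapped:
        raise ValueError(f"unmapped variant(s): {unmapped[:5]}")
    grouped = expr.tpm.groupby([variant_map[v] for v in expr.tpm.index]).max()
    return ExpressionMatrix(tpm=grouped, meta=expr.meta.copy())


def classify_de(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    alpha: float = 0.05,
    external_p: pd.Series | None = None,
) -> pd.DataFrame:
    """Classify genes as up / down / ns between two sample groups.

    Fold change is ``(mean_A + 1) / (mean_B + 1)`` on TPM (pseudocount 1);
    the call requires BOTH the fold-change threshold and the BH-adjusted
    p < alpha.  The internal p is a per-gene two-sample t on
    log2(TPM + 1) — a simplified stand-in, not a count-model test; pass
    ``external_p`` (raw p per gene) to slot in a proper DE test's output.
    Returns a DataFrame with columns log2_fc, p, q, call.
    """
    a = expr.tpm[list(group_a)]
    b = expr.tpm[list(group_b)]
    fc = (a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0)
    if external_p is not None:
        p = external_p.reindex(fc.index)
        if p.isna().any():
            raise ValueError("external_p missing values for some genes")
        p = p.to_numpy(dtype=float)
    else:
        if len(group_a) < 2 or len(group_b) < 2:
            raise ValueError(
                "internal test needs >= 2 replicates per group; "
                "supply external_p computed by a dedicated DE tool instead"
            )
        la = np.log2(a.to_numpy() + 1.0)
        lb = np.log2(b.to_numpy() + 1.0)
        p = stats.ttest_ind(la, lb, axis=1).pvalue
        p = np.where(np.isnan(p), 1.0, p)  # both groups constant-equal
    q = stats.false_discovery_control(p, method="bh")
    call = np.where((fc > fc_hi) & (q < alpha), "up",
                    np.where((fc < fc_lo) & (q < alpha), "down", "ns"))
    return pd.DataFrame(
        {"log2_fc": np.log2(fc), "p": p, "q": q, "call": call}, index=fc.index
    )


def genes_higher_in(
    expr: ExpressionMatrix,
    state: str,
    line_a: str,
    line_b: str,
    cutoff: float = 2.0,
    timepoint_h=None,
) -> tuple:
    """Fold-change gene groups between two lines within one state.

    Returns ``(A>B group, B>A group)`` using replicate-mean TPM with a
    pseudocount of 1; groups are disjoint by construction and swapping the
    lines swaps the groups exactly.  A GeneGroup is non-empty by contract,
    so an empty side is returned as ``None``.
    """
    sa = expr.samples(line=line_a, state=state, timepoint_h=timepoint_h)
    sb = expr.samples(line=line_b, state=state, timepoint_h=timepoint_h)
    if not sa or not sb:
        raise ValueError(f"missing samples for {line_a!r}/{line_b!r} in state {state!r}")
    ratio = (expr.tpm[sa].mean(axis=1) + 1.0) / (expr.tpm[sb].mean(axis=1) + 1.0)
    a_up = frozenset(ratio.index[ratio > cutoff])
    b_up = frozenset(ratio.index[ratio < 1.0 / cutoff])
    contrast = dict(state=state, cutoff=cutoff, line_a=line_a, line_b=line_b)
    mk = lambda name, genes: GeneGroup(name, genes, contrast) if genes else None
    return (mk(f"{line_a}>{line_b}@{state}", a_up), mk(f"{line_b}>{line_a}@{state}", b_up))


def group_expression_compare(
    group: GeneGroup,
    expr: ExpressionMatrix,
    samples: Sequence[str],
    background: GeneGroup | None = None,
) -> tuple:
    """Compare mean expression of a gene group against a background group.

    Expression is the replicate-mean TPM over ``samples``; background
    defaults to all genes in the matrix.  Returns
    ``(mean_group, mean_background, p)`` with the two-sided U test for
    unequal group sizes (study convention).
    """
    vec = expr.tpm[list(samples)].mean(axis=1)
    g_genes = [g for g in group.genes if g in vec.index]
    b_index = list(background.genes) if background is not None else list(vec.index)
    b_genes = [g for g in b_index if g in vec.index]
    if not g_genes or not b_genes:
        raise ValueError("empty group after intersection with expression matrix")
    a, b = vec.loc[g_genes].to_numpy(), vec.loc[b_genes].to_numpy()
    _, p = compare_group_scores(a, b, test="t" if len(a) == len(b) else "u")
    return float(a.mean()), float(b.mean()), p


def state_retention_correlation(
    expr: ExpressionMatrix,
    line: str,
    state_pair: tuple = ("ESC", "RA"),
    pooled_timepoints: Mapping[str, tuple] = {"RA": RA_POOLED_TIMEPOINTS},
) -> CorrelationReport:
    """Transcriptome Spearman correlation between two states of one line.

    Replicate means per state; for the differentiated state the 24 h and
    72 h samples are pooled when both exist.  High retention (rho close to
    the undifferentiated state) is the delayed-differentiation signature.
    """
    vectors = []
    for state in state_pair:
        samples = expr.samples(line=line, state=state)
        pool = pooled_timepoints.get(state)
        if pool is not None:
            pooled = expr.samples(line=line, state=state, timepoint_h=pool)
            if pooled:
                samples = pooled
        if not samples:
            raise ValueError(f"no samples for line {line!r} in state {state!r}")
        vectors.append(expr.tpm[samples].mean(axis=1))
    return spearman_correlation(vectors[0], vectors[1])
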