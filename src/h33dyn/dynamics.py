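"""Time-course analyses: target stability and early-binding -> late-expression.

Two questions about incorporation dynamics after induction of the tagged
histone: (1) are the binding targets stable across the 4/8/24/72 h
timepoints (full Spearman matrix over per-timepoint gene score vectors,
optionally across two independent experiments); and (2) does high
binding at an early timepoint predict high expression later?  The latter
is a contingency procedure: per line, take the genes with high binding
at 8 h (empirical-quantile threshold), ask what fraction of them is
highly expressed at 72 h, and compare lines with a two-sided Fisher
exact test on the resulting 2x2 table.

The "high binding" and "highly expressed" thresholds are empirical
quantiles (defaults 0.75 and 0.5) with strict-inequality membership so
ties at the threshold are excluded deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genestats import GeneScoreVector, correlation_matrix

__all__ = [
    "ContingencyTable2x2",
    "RetentionRatioReport",
    "timepoint_stability",
    "high_binding_gene_set",
    "expressed_late_gene_set",
    "retention_ratio_test",
    "fisher_exact_2x2",
]


@dataclass
class ContingencyTable2x2:
    counts: np.ndarray
    row_labels: tuple = ("a", "b")
    col_labels: tuple = ("late", "not_late")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("contingency table is empty")


@dataclass
class RetentionRatioReport:
    """Per-line high-binding -> late-expression ratios plus pairwise Fisher tests."""

    per_line: pd.DataFrame
    comparisons: dict


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table with positive margins.

    The conventional two-sided definition: the sum of probabilities of all
    tables with the observed margins whose conditional hypergeometric
    probability does not exceed the observed table's.
    """
    t = table.counts if isinstance(table, ContingencyTable2x2) else np.asarray(table, dtype=np.int64)
    t = ContingencyTable2x2(t).counts
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _score_values(scores) -> pd.Series:
    return scores.scores if isinstance(scores, GeneScoreVector) else pd.Series(scores, dtype=float)


def _above_quantile(values: pd.Series, quantile: float) -> set:
    vals = values.to_numpy(dtype=float)
    if len(vals) < 4:
        raise ValueError("need at least 4 genes")
    if np.ptp(vals) == 0:
        raise ValueError("scores are constant; quantile threshold undefined")
    threshold = float(np.quantile(vals, quantile))
    return set(values.index[vals > threshold])


def high_binding_gene_set(scores_early, quantile: float = 0.75) -> set:
    """Genes with score strictly above the empirical quantile.

    Ties at the threshold are excluded, which makes the set size
    reproducible under any stable sort of the input.
    """
    return _above_quantile(_score_values(scores_early), quantile)


def expressed_late_gene_set(
    expr, line: str | None = None, timepoint_h=72, state: str | None = None,
    quantile: float = 0.5,
) -> set:
    """Genes with mean TPM at the late timepoint strictly above the quantile."""
    samples = expr.samples(line=line, state=state, timepoint_h=timepoint_h)
    if not samples:
        raise ValueError(f"no samples at timepoint {timepoint_h} for line {line!r}")
    return _above_quantile(expr.tpm[samples].mean(axis=1), quantile)


def retention_ratio_test(lines: Mapping[str, tuple]) -> RetentionRatioReport:
    """Per line: fraction of high-early-binding genes highly expressed late.

    ``lines`` maps line name -> ``(high_set, late_set, universe)``.  For
    every pair of lines a 2x2 table (rows = lines, columns = late /
    not-late among the high-binding genes) is tested with the two-sided
    Fisher exact test.  Universe genes outside the high-binding sets never
    enter the tables, so the result is invariant to them.
    """
    rows = {}
    for line, (high, late, universe) in lines.items():
        high, late, universe = set(high), set(late), set(universe)
        if not high <= universe or not late <= universe:
            raise ValueError(f"{line}: gene sets must be subsets of the universe")
        if not high:
            raise ValueError(f"{line}: empty high-binding set")
        n_late = len(high & late)
        rows[line] = dict(n_high_binding_early=len(high),
                          n_of_those_expressed_late=n_late,
                          ratio=n_late / len(high))
    per_line = pd.DataFrame.from_dict(rows, orient="index")
    comparisons = {}
    names = list(lines)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ha, la, _ = lines[a]
            hb, lb, _ = lines[b]
            ha, la, hb, lb = set(ha), set(la), set(hb), set(lb)
            table = ContingencyTable2x2(
                np.array([[len(ha & la), len(ha - la)],
                          [len(hb & lb), len(hb - lb)]]),
                row_labels=(a, b),
            )
            comparisons[(a, b)] = (table, fisher_exact_2x2(table))
    return RetentionRatioReport(per_line=per_line, comparisons=comparisons)


def timepoint_stability(
    scores_by_timepoint: Mapping[int, GeneScoreVector],
    second_experiment: Mapping[int, GeneScoreVector] | None = None,
) -> pd.DataFrame:
    """Full Spearman matrix of gene scores across timepoints (and experiments).

    When a second experiment is given its vectors are appended, so the
    matrix contains the cross-experiment blocks (each vector against the
    first experiment's, deepTools-free equivalent of the published
    stability panels).
    """
    if len(scores_by_timepoint) < 2 and not second_experiment:
        raise ValueError("need at least 2 timepoints")
    vectors, labels = [], []
    for t in sorted(scores_by_timepoint):
        vectors.append(scores_by_timepoint[t])
        labels.append(f"exp1_t{t}")
    if second_experiment is not None:
        for t in sorted(second_experiment):
            vectors.append(second_experiment[t])
            labels.append(f"exp2_t{t}")
    return correlation_matrix(vectors, labels=labels)
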