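"""Gene-level scores and the study's comparative statistics.

The central quantity is the TSS-flanking window score: the mean binned
signal over the strand-oriented windows -1.2 kb..-0.2 kb and +0.4 kb..
+1.2 kb around each TSS.  With 200 bp bins and the TSS snapped to the
start of its containing bin this selects exactly 5 upstream + 4
downstream bins.  The windows skip the nucleosome-depleted region right
at the TSS and capture the characteristic H3.3 double peak.

Comparative machinery: average-rank Spearman correlation (exact
permutation p below n = 10, t approximation otherwise), two-sample
t / Mann-Whitney U group tests with the convention that the U test is
used for groups of unequal size, a Fisher-z test for comparing two
correlations, hypergeometric over-representation with
Benjamini-Hochberg correction, and the mass-cytometry arcsinh /
standardise / core-histone normalisation used for single-cell chromatin
profiling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import GeneModel
from .tracks import DEFAULT_EXCLUDE, BinnedTrack

logger = logging.getLogger(__name__)

__all__ = [
    "GeneScoreVector",
    "CorrelationReport",
    "CytofMatrix",
    "gene_window_score",
    "spearman_correlation",
    "binding_expression_correlation",
    "correlation_matrix",
    "compare_group_scores",
    "compare_correlations",
    "hypergeometric_enrichment",
    "cytof_normalize",
]

TSS_UPSTREAM_WINDOW = (-1200, -200)
TSS_DOWNSTREAM_WINDOW = (400, 1200)


@dataclass
class GeneScoreVector:
    """Per-gene window scores from one track (genes on excluded chromosomes absent)."""

    scores: pd.Series
    window: tuple = (TSS_UPSTREAM_WINDOW, TSS_DOWNSTREAM_WINDOW)
    sample_meta: dict = field(default_factory=dict)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValueError("gene scores must be finite")


@dataclass
class CorrelationReport:
    rho: float
    n: int
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| must be <= 1")


@dataclass
class CytofMatrix:
    """Cells x markers intensity matrix with marker roles.

    Roles are ``epigenetic`` (normalised against core histones),
    ``core_histone`` or ``other``.
    """

    data: pd.DataFrame
    roles: Mapping[str, str]

    VALID_ROLES = ("epigenetic", "core_histone", "other")

    def __post_init__(self) -> None:
        self.roles = dict(self.roles)
        for marker in self.data.columns:
            role = self.roles.get(marker)
            if role not in self.VALID_ROLES:
                raise ValueError(f"marker {marker!r} has invalid role {role!r}")

    def markers(self, role: str) -> list:
        return [m for m in self.data.columns if self.roles[m] == role]


# ---------------------------------------------------------------------------
# Window score


def gene_window_score(
    track: BinnedTrack,
    genes: Sequence[GeneModel],
    upstream: tuple = TSS_UPSTREAM_WINDOW,
    downstream: tuple = TSS_DOWNSTREAM_WINDOW,
    exclude_chroms: Iterable[str] = DEFAULT_EXCLUDE,
) -> GeneScoreVector:
    """Mean binned signal in the TSS-flanking windows, one score per gene.

    Bin membership is decided by bin midpoint after snapping the TSS to
    the bin boundary at the transcription start, oriented by strand
    (floor on ``+``, ceiling on ``-``); both strands then select the same
    number of bins (9 for the defaults at 200 bp resolution), and the
    operation commutes exactly with mirroring the genome.  Genes whose
    window would leave the chromosome are dropped and counted; genes on
    excluded chromosomes are absent from the result.
    """
    bs = track.layout.bin_size
    (u0, u1), (d0, d1) = upstream, downstream
    if not (u0 < u1 and d0 < d1):
        raise ValueError("window bounds must be increasing")
    excl = set(exclude_chroms)
    span = max(abs(v) for v in (u0, u1, d0, d1)) + bs
    h = bs // 2
    names, scores = [], []
    dropped = 0
    for g in genes:
        if g.chrom in excl or g.chrom not in track.values:
            continue
        length = track.layout.chrom_lengths[g.chrom]
        snap = (g.tss // bs) * bs if g.strand == "+" else -((-g.tss) // bs) * bs
        if snap - span < 0 or snap + span > length:
            dropped += 1
            continue
        ks = np.arange((snap - span) // bs, (snap + span) // bs + 1)
        mid = ks * bs + h
        off = mid - snap if g.strand == "+" else snap - mid
        sel = ((off >= u0) & (off < u1)) | ((off >= d0) & (off < d1))
        names.append(g.name)
        scores.append(float(track.values[g.chrom][ks[sel]].mean()))
    if dropped:
        logger.info("gene_window_score: dropped %d boundary genes", dropped)
    if not names:
        raise ValueError("all genes dropped (boundary or excluded chromosomes)")
    return GeneScoreVector(
        scores=pd.Series(scores, index=names, name="window_score"),
        window=(tuple(upstream), tuple(downstream)),
        sample_meta=dict(track.sample_meta),
        n_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Correlation statistics


def _as_scores(x) -> pd.Series:
    return x.scores if isinstance(x, GeneScoreVector) else pd.Series(x)


def spearman_correlation(x, y) -> CorrelationReport:
    """Average-rank Spearman correlation with an honest small-sample p.

    rho is the Pearson correlation of average ranks (ties allowed).  The
    p-value uses the t approximation for n >= 10 and the exact permutation
    distribution of rho (all n! arrangements) below that.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = xv.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n >= 10:
        method = "spearman, t approximation"
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    else:
        method = "spearman, exact permutation"
        perms = np.array(list(itertools.permutations(ry)))
        rc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(rc) * np.linalg.norm(pc, axis=1)
        rho_perm = (pc @ rc) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    return CorrelationReport(rho=rho, n=n, p_value=min(p, 1.0), method=method)


def binding_expression_correlation(
    scores: GeneScoreVector, expr, sample
) -> CorrelationReport:
    """Spearman correlation between H3.3 window scores and gene expression.

    ``sample`` may be one sample id or a list (replicates are averaged).
    Genes missing on either side are dropped; an intersection below 10
    genes is an error.
    """
    tpm = expr.tpm if hasattr(expr, "tpm") else expr
    vec = tpm[sample] if isinstance(sample, str) else tpm[list(sample)].mean(axis=1)
    common = scores.scores.index.intersection(vec.index)
    n_dropped = (len(scores.scores) - len(common)) + (len(vec) - len(common))
    if len(common) < 10:
        raise ValueError(f"only {len(common)} genes shared between scores and expression")
    if n_dropped:
        logger.info("binding_expression_correlation: %d genes dropped", n_dropped)
    return spearman_correlation(scores.scores.loc[common], vec.loc[common])


def correlation_matrix(score_vectors: Sequence, labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman matrix over the common gene set of several vectors."""
    if len(score_vectors) < 2:
        raise ValueError("need at least 2 score vectors")
    series = [_as_scores(v) for v in score_vectors]
    if labels is None:
        labels = [f"v{i}" for i in range(len(series))]
    common = series[0].index
    for s in series[1:]:
        common = common.intersection(s.index)
    if len(common) < 10:
        raise ValueError(f"common gene set too small ({len(common)})")
    mat = np.eye(len(series))
    for i in range(len(series)):
        for j in range(i + 1, len(series)):
            rho = spearman_correlation(series[i].loc[common], series[j].loc[common]).rho
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=list(labels), columns=list(labels))


def compare_group_scores(a, b, test: str | None = None) -> tuple:
    """Two-sided two-group comparison: Student t or Mann-Whitney U.

    Follows the study's convention: when ``test`` is not forced, groups of
    different size are compared with the U test, equal-sized groups with
    the two-tailed t test.  The U test is exact for small tie-free
    samples, otherwise normal approximation with tie correction.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.size == 0 or bv.size == 0:
        raise ValueError("empty group")
    if test is None:
        test = "t" if av.size == bv.size else "u"
    if test == "t":
        if av.size < 2 or bv.size < 2:
            raise ValueError("t test needs at least 2 observations per group")
        res = stats.ttest_ind(av, bv)
    elif test == "u":
        res = stats.mannwhitneyu(av, bv, alternative="two-sided", method="auto")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def compare_correlations(rho_a: float, n_a: int, rho_b: float, n_b: int) -> tuple:
    """Fisher z-transform test for the difference of two correlations.

    Returns ``(z, two-sided p)``.  This is the population-level construction
    (independent samples); a replicate-level t test is possible when two or
    more replicate correlations exist per group, but z is the default here.
    """
    for rho in (rho_a, rho_b):
        if abs(rho) >= 1:
            raise ValueError("|rho| must be < 1 for the Fisher z transform")
    for n in (n_a, n_b):
        if n < 4:
            raise ValueError("need n >= 4 per correlation")
    z = (np.arctanh(rho_a) - np.arctanh(rho_b)) / np.sqrt(1 / (n_a - 3) + 1 / (n_b - 3))
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Over-representation


def hypergeometric_enrichment(
    gene_set: Iterable[str],
    universe: Iterable[str],
    categories: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set across categories.

    Generic in-repo stand-in for web-based GO tools: upper-tail
    hypergeometric p per category (categories intersected with the
    universe first) and Benjamini-Hochberg q across categories.
    Columns: k (overlap), K (category size), n (set size), N (universe),
    p, q, fold (observed/expected overlap).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    gset = set(gene_set)
    if not gset <= uni:
        raise ValueError("gene_set must be a subset of the universe")
    N, n = len(uni), len(gset)
    rows = {}
    for name, members in categories.items():
        cat = set(members) & uni
        K = len(cat)
        k = len(cat & gset)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        expected = K * n / N
        rows[name] = dict(k=k, K=K, n=n, N=N, p=min(p, 1.0),
                          fold=(k / expected) if expected > 0 else np.nan)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["q"] = stats.false_discovery_control(table["p"].to_numpy(), method="bh")
    return table[["k", "K", "n", "N", "p", "q", "fold"]]


# ---------------------------------------------------------------------------
# CyTOF


def cytof_normalize(m: CytofMatrix, cofactor: float = 5.0) -> CytofMatrix:
    """arcsinh-transform, standardise, and core-histone-normalise CyTOF data.

    Three steps: (1) ``arcsinh(x / cofactor)`` per entry (cofactor 5, the
    field-standard choice for mass cytometry); (2) per-marker
    standardisation to mean 0, sd 1; (3) each epigenetic marker replaced
    by its standardised value minus the per-cell mean of the standardised
    core-histone markers, removing cell-to-cell staining/size variation.
    """
    core = m.markers("core_histone")
    if not core:
        raise ValueError("need at least one core_histone marker")
    if (m.data.to_numpy() < 0).any():
        raise ValueError("intensities must be non-negative")
    trans = np.arcsinh(m.data / cofactor)
    std = trans.std(axis=0, ddof=0)
    flat = std[std == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance marker(s): {flat}")
    z = (trans - trans.mean(axis=0)) / std
    core_level = z[core].mean(axis=1)
    out = z.copy()
    for marker in m.markers("epigenetic"):
        out[marker] = z[marker] - core_level
    return CytofMatrix(data=out, roles=dict(m.roles))
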