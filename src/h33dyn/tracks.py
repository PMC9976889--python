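"""Fixed-bin coverage tracks and track-level summaries.

The genome is analysed at a fixed resolution (200 bp bins by default).
Interval coverage is converted into binned tracks by exact fractional
overlap: a bin's value is the mean per-base coverage within it times the
bin occupancy, so a record covering half a bin at height 1 contributes
0.5.  Tracks are normalised to reads-per-million over the included
chromosomes; chromosomes listed in ``exclude_chroms`` (``chr8`` by
default, which carries a suspected duplication in the assayed clones)
never contribute to the normalisation denominator but are scaled by the
same factor so they stay inspectable.

Downstream summaries: global modification change relative to a reference
track (H3 by convention), genic signal distribution, strand-oriented
anchor profile matrices (deepTools-computeMatrix style) and metagene
curves with 2x standard-error bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import AnchorSet, GeneModel, GenomeLayout, IntervalCoverage

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedTrack",
    "ProfileMatrix",
    "ProfileResult",
    "GenicDistribution",
    "GlobalChangeReport",
    "bin_coverage",
    "rpm_normalize",
    "global_modification_change",
    "genic_distribution",
    "anchor_matrix",
    "metagene_profile",
    "sort_heatmap",
]

DEFAULT_EXCLUDE = frozenset({"chr8"})


@dataclass
class BinnedTrack:
    """Per-chromosome fixed-width bin coverage for one sample.

    ``total_mapped`` is the sum of raw binned signal before any
    normalisation and is preserved by :func:`rpm_normalize`.
    """

    layout: GenomeLayout
    values: dict
    sample_meta: dict = field(default_factory=dict)
    total_mapped: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        for chrom in self.layout.chrom_names:
            if chrom not in self.values:
                raise ValueError(f"track missing chromosome {chrom!r}")
            vec = np.asarray(self.values[chrom], dtype=float)
            if vec.shape != (self.layout.n_bins(chrom),):
                raise ValueError(
                    f"{chrom}: expected {self.layout.n_bins(chrom)} bins, got {vec.shape}"
                )
            self.values[chrom] = vec

    def total(self, exclude_chroms: Iterable[str] = ()) -> float:
        excl = set(exclude_chroms)
        return float(
            sum(self.values[c].sum() for c in self.layout.chrom_names if c not in excl)
        )


@dataclass
class ProfileMatrix:
    """Anchors x offset-bins signal matrix, strand-oriented.

    ``offsets`` holds the oriented bin-start offsets from ``-flank`` to
    ``flank - bin_size``; rows of minus-strand anchors are flipped so that
    positive offsets always point downstream of transcription.
    """

    anchor_ids: list
    offsets: np.ndarray
    values: np.ndarray
    flank: int
    sample_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.anchor_ids), len(self.offsets)):
            raise ValueError("profile matrix shape mismatch")

    def column_slice(self, lo: int, hi: int) -> np.ndarray:
        """Columns whose oriented bin-start offset lies in [lo, hi)."""
        sel = (self.offsets >= lo) & (self.offsets < hi)
        return self.values[:, sel]


@dataclass
class ProfileResult:
    offsets: np.ndarray
    mean: np.ndarray
    se2: np.ndarray
    n_anchors: int


@dataclass
class GenicDistribution:
    fractions: dict
    promoter_window: tuple
    tts_window: tuple

    CATEGORIES = ("promoter", "tts", "gene_body", "intergenic")

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")


@dataclass
class GlobalChangeReport:
    ratio_by_timepoint: dict
    change: float


# ---------------------------------------------------------------------------


def bin_coverage(cov: IntervalCoverage, layout: GenomeLayout) -> BinnedTrack:
    """Bin interval coverage by exact fractional overlap.

    Each bin receives ``value * overlap_bp / bin_size`` from every record
    that intersects it; ``total_mapped`` is the sum over all bins.
    """
    bs = layout.bin_size
    values = {c: np.zeros(layout.n_bins(c)) for c in layout.chrom_names}
    for chrom, start, end, value in cov.records:
        if chrom not in values:
            raise ValueError(f"record on unknown chromosome {chrom!r}")
        if end > layout.chrom_lengths[chrom]:
            raise ValueError(f"record {chrom}:{start}-{end} exceeds chromosome length")
        vec = values[chrom]
        b0, b1 = start // bs, (end - 1) // bs
        if b0 == b1:
            vec[b0] += value * (end - start) / bs
        else:
            vec[b0] += value * ((b0 + 1) * bs - start) / bs
            if b1 > b0 + 1:
                vec[b0 + 1 : b1] += value
            vec[b1] += value * (end - b1 * bs) / bs
    total = float(sum(v.sum() for v in values.values()))
    return BinnedTrack(layout=layout, values=values, total_mapped=total)


def rpm_normalize(
    track: BinnedTrack, exclude_chroms: Iterable[str] = DEFAULT_EXCLUDE
) -> BinnedTrack:
    """Scale a raw track to reads-per-million over the included chromosomes.

    Every chromosome (including excluded ones) is multiplied by
    ``1e6 / total_included``, so relative bin proportions are preserved
    and the included-chromosome sum becomes exactly 1e6.
    """
    if track.normalized:
        raise ValueError("track is already normalized")
    included_total = track.total(exclude_chroms)
    if included_total <= 0:
        raise ValueError("zero total signal over included chromosomes")
    factor = 1e6 / included_total
    return BinnedTrack(
        layout=track.layout,
        values={c: v * factor for c, v in track.values.items()},
        sample_meta=dict(track.sample_meta),
        total_mapped=track.total_mapped,
        normalized=True,
    )


def global_modification_change(
    mod_tracks: Mapping[int, BinnedTrack],
    ref_tracks: Mapping[int, BinnedTrack],
    early: Sequence[int] = (4, 8),
    late: int = 72,
    exclude_chroms: Iterable[str] = DEFAULT_EXCLUDE,
) -> GlobalChangeReport:
    """Global modification-vs-reference ratio change from early to late.

    For each timepoint the total (raw) modification signal is divided by
    the total reference signal (H3 by convention, used for global
    normalisation); the report's ``change`` is the late ratio over the
    mean of the early ratios.  A change < 1 models e.g. the global
    H3K27me3 loss under K27M.
    """
    needed = set(early) | {late}
    for t in sorted(needed):
        if t not in mod_tracks or t not in ref_tracks:
            raise ValueError(f"timepoint {t} missing from modification or reference tracks")
    ratios = {}
    for t in sorted(set(mod_tracks) & set(ref_tracks)):
        if mod_tracks[t].normalized or ref_tracks[t].normalized:
            raise ValueError("global change requires raw (unnormalized) tracks")
        ref_total = ref_tracks[t].total(exclude_chroms)
        if ref_total <= 0:
            raise ValueError(f"zero reference total at timepoint {t}")
        ratios[t] = mod_tracks[t].total(exclude_chroms) / ref_total
    early_mean = float(np.mean([ratios[t] for t in early]))
    return GlobalChangeReport(ratio_by_timepoint=ratios, change=ratios[late] / early_mean)


def _oriented_interval(pos: int, strand: str, window: tuple) -> tuple:
    """Physical half-open interval of a strand-oriented window around pos."""
    w0, w1 = window
    if strand == "+":
        return pos + w0, pos + w1
    return pos - w1, pos - w0


def _midpoint_bins(a: int, b: int, bs: int, n_bins: int) -> tuple:
    """Half-open bin-index range of bins whose midpoint lies in [a, b)."""
    h = bs // 2
    k0 = -(-(a - h) // bs)
    k1 = -(-(b - h) // bs)
    return max(0, k0), min(n_bins, k1)


def genic_distribution(
    track: BinnedTrack,
    genes: Sequence[GeneModel],
    promoter_window: tuple = (-2000, 500),
    tts_window: tuple = (-1000, 1000),
) -> GenicDistribution:
    """Fraction of track signal in promoter / TTS / gene body / intergenic bins.

    Each bin is assigned to exactly one category by its midpoint, with
    precedence promoter > tts > gene_body > intergenic.  Windows are
    strand-oriented around the TSS and TTS.
    """
    if not genes:
        raise ValueError("empty gene list")
    bs = track.layout.bin_size
    codes = {c: np.zeros(track.layout.n_bins(c), dtype=np.int8) for c in track.layout.chrom_names}
    # later passes overwrite earlier ones => precedence by write order
    passes = (
        (1, lambda g: (g.tx_start, g.tx_end)),
        (2, lambda g: _oriented_interval(g.tts, g.strand, tts_window)),
        (3, lambda g: _oriented_interval(g.tss, g.strand, promoter_window)),
    )
    for code, interval_of in passes:
        for g in genes:
            if g.chrom not in codes:
                continue
            a, b = interval_of(g)
            k0, k1 = _midpoint_bins(a, b, bs, track.layout.n_bins(g.chrom))
            if k0 < k1:
                codes[g.chrom][k0:k1] = code
    sums = np.zeros(4)
    for chrom in track.layout.chrom_names:
        vec = track.values[chrom]
        code = codes[chrom]
        sums += np.bincount(code, weights=vec, minlength=4)
    total = sums.sum()
    if total <= 0:
        raise ValueError("track has no signal")
    fractions = {
        "promoter": sums[3] / total,
        "tts": sums[2] / total,
        "gene_body": sums[1] / total,
        "intergenic": sums[0] / total,
    }
    return GenicDistribution(
        fractions=fractions, promoter_window=tuple(promoter_window), tts_window=tuple(tts_window)
    )


def anchor_matrix(track: BinnedTrack, anchors: AnchorSet, flank: int = 10000) -> ProfileMatrix:
    """Extract a strand-oriented anchors x offsets signal matrix.

    Column ``j`` of row ``i`` holds the track value of the bin containing
    ``anchor_i + oriented(offset_j + bin_size/2)``; minus-strand rows come
    out flipped so positive offsets are downstream.  Anchors whose window
    leaves the chromosome are dropped (a count is logged) — padding would
    bias the edge offsets.
    """
    bs = track.layout.bin_size
    if flank % bs != 0 or flank <= 0:
        raise ValueError("flank must be a positive multiple of bin_size")
    offsets = np.arange(-flank, flank, bs)
    centered = offsets + bs // 2
    rows, ids = [], []
    dropped = 0
    for a in anchors:
        if a.chrom not in track.values:
            dropped += 1
            continue
        length = track.layout.chrom_lengths[a.chrom]
        pos = a.position + centered if a.strand == "+" else a.position - centered
        if pos.min() < 0 or pos.max() >= length:
            dropped += 1
            continue
        rows.append(track.values[a.chrom][pos // bs])
        ids.append(a.id)
    if dropped:
        logger.info("anchor_matrix: dropped %d/%d out-of-bounds anchors", dropped, len(anchors))
    if not rows:
        raise ValueError("no anchors survived boundary filtering")
    return ProfileMatrix(
        anchor_ids=ids,
        offsets=offsets,
        values=np.vstack(rows),
        flank=flank,
        sample_meta=dict(track.sample_meta),
    )


def metagene_profile(matrix: ProfileMatrix) -> ProfileResult:
    """Per-offset mean with a 2x standard-error band across anchors."""
    n = matrix.values.shape[0]
    if n < 2:
        raise ValueError("metagene profile needs at least 2 anchors (SE undefined)")
    mean = matrix.values.mean(axis=0)
    se = matrix.values.std(axis=0, ddof=1) / np.sqrt(n)
    return ProfileResult(offsets=matrix.offsets.copy(), mean=mean, se2=2.0 * se, n_anchors=n)


def sort_heatmap(matrix: ProfileMatrix, sort_scores: Mapping[str, float]) -> ProfileMatrix:
    """Reorder rows by descending score (ties broken by anchor id).

    Typical use: sort all lines' heatmaps by H3.3 binding in the WT sample
    so rows are comparable across panels.
    """
    missing = [i for i in matrix.anchor_ids if i not in sort_scores]
    if missing:
        raise ValueError(f"sort scores missing for anchors: {missing[:5]}")
    order = sorted(range(len(matrix.anchor_ids)),
                   key=lambda k: (-float(sort_scores[matrix.anchor_ids[k]]), matrix.anchor_ids[k]))
    return ProfileMatrix(
        anchor_ids=[matrix.anchor_ids[k] for k in order],
        offsets=matrix.offsets.copy(),
        values=matrix.values[order],
        flank=matrix.flank,
        sample_meta=dict(matrix.sample_meta),
    )
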