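"""Text-format I/O for the chromatin-dynamics pipeline.

Every reader and writer in this module uses 0-based, half-open genomic
coordinates: an interval ``[k, k + 1)`` covers exactly base ``k``.  For a
gene on the ``+`` strand the transcription start site (TSS) is ``txStart``;
on the ``-`` strand it is ``txEnd`` (the first transcribed base being
``txEnd - 1``).  "Downstream" always means in the direction of
transcription; strand-oriented offsets are positive downstream.

Supported formats: UCSC bedGraph, BED3/BED6 anchor files, tab-separated
gene tables in the UCSC table-browser dialect (``name chrom strand txStart
txEnd``, extra columns ignored), and tab-separated counts + sample-metadata
tables for RNA-seq.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenomeLayout",
    "IntervalCoverage",
    "GeneModel",
    "Anchor",
    "AnchorSet",
    "CountsTable",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_table",
    "write_gene_table",
    "read_bed_anchors",
    "read_counts_table",
    "tss_anchors",
]


class FormatError(ValueError):
    """An input file violates its format contract."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths plus the fixed analysis bin width (bp).

    The genome is analysed in non-overlapping bins of ``bin_size`` bp
    (200 bp by default); the last bin of a chromosome may be short.
    """

    chrom_names: tuple
    chrom_lengths: Mapping[str, int]
    bin_size: int = 200

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", dict(self.chrom_lengths))
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for name in self.chrom_names:
            if name not in self.chrom_lengths:
                raise ValueError(f"no length given for chromosome {name!r}")
            if self.chrom_lengths[name] < self.bin_size:
                raise ValueError(
                    f"chromosome {name!r} shorter than one bin "
                    f"({self.chrom_lengths[name]} < {self.bin_size})"
                )

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.bin_size)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)


@dataclass
class IntervalCoverage:
    """Sorted, per-chromosome non-overlapping coverage intervals.

    ``records`` is a list of ``(chrom, start, end, value)`` tuples with
    0-based half-open coordinates and non-negative values.  Construction
    sorts records within each chromosome (chromosome blocks keep their
    first-appearance order) and rejects overlaps.
    """

    records: list

    def __post_init__(self) -> None:
        order: dict[str, int] = {}
        clean = []
        for rec in self.records:
            chrom, start, end, value = rec
            start, end, value = int(start), int(end), float(value)
            if start >= end:
                raise ValueError(f"interval start >= end ({chrom}:{start}-{end})")
            if start < 0:
                raise ValueError(f"negative coordinate ({chrom}:{start})")
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"coverage value must be finite and >= 0, got {value!r}")
            order.setdefault(chrom, len(order))
            clean.append((chrom, start, end, value))
        clean.sort(key=lambda r: (order[r[0]], r[1]))
        prev_chrom, prev_end = None, 0
        for chrom, start, end, _ in clean:
            if chrom == prev_chrom and start < prev_end:
                raise ValueError(f"overlapping intervals on {chrom} at {start}")
            prev_chrom, prev_end = chrom, end
        self.records = clean

    @property
    def chroms(self) -> list:
        seen: dict[str, None] = {}
        for chrom, *_ in self.records:
            seen.setdefault(chrom)
        return list(seen)

    def by_chrom(self) -> dict:
        """Per-chromosome ``(starts, ends, values)`` numpy arrays."""
        out: dict[str, tuple] = {}
        for chrom in self.chroms:
            recs = [r for r in self.records if r[0] == chrom]
            out[chrom] = (
                np.array([r[1] for r in recs], dtype=np.int64),
                np.array([r[2] for r in recs], dtype=np.int64),
                np.array([r[3] for r in recs], dtype=float),
            )
        return out

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GeneModel:
    """A transcript interval with a strand-aware TSS (D-convention above)."""

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise ValueError(
                f"gene {self.name}: txStart >= txEnd ({self.tx_start} >= {self.tx_end})"
            )

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tts(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start


@dataclass(frozen=True)
class Anchor:
    chrom: str
    position: int
    strand: str
    id: str


@dataclass
class AnchorSet:
    """Point anchors (TSSs, enhancer midpoints, TTSs) for profile extraction."""

    anchors: list

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self):
        return iter(self.anchors)


@dataclass
class CountsTable:
    """Raw RNA-seq counts (genes x samples) plus per-sample metadata.

    ``meta`` is indexed by sample id and carries ``line``, ``timepoint_h``,
    ``state`` and ``replicate`` columns.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    REQUIRED_META = ("line", "timepoint_h", "state", "replicate")

    def __post_init__(self) -> None:
        if set(self.counts.columns) != set(self.meta.index):
            missing = set(self.counts.columns) ^ set(self.meta.index)
            raise ValueError(f"sample mismatch between counts and metadata: {sorted(missing)}")
        for col in self.REQUIRED_META:
            if col not in self.meta.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        vals = self.counts.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("counts must be finite")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.array_equal(vals, np.floor(vals)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.meta = self.meta.loc[list(self.counts.columns)]

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


# ---------------------------------------------------------------------------
# bedGraph

_HEADER_PREFIXES = ("track", "browser", "#")


def read_bedgraph(path, layout: GenomeLayout | None = None) -> IntervalCoverage:
    """Read a 4-column bedGraph file into an :class:`IntervalCoverage`.

    Track/browser/comment header lines and blank lines are skipped.
    Records are validated against ``layout`` bounds when one is supplied.
    Overlapping records within a chromosome are an error.
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(_HEADER_PREFIXES):
                continue
            parts = stripped.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
                value = float(parts[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate or value") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: interval start >= end")
            if layout is not None:
                if chrom not in layout.chrom_lengths:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if start < 0 or end > layout.chrom_lengths[chrom]:
                    raise FormatError(f"{path}:{lineno}: interval exceeds chromosome bounds")
            records.append((chrom, start, end, value))
    try:
        return IntervalCoverage(records)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_bedgraph(cov: IntervalCoverage, path, layout: GenomeLayout | None = None) -> None:
    """Write coverage as bedGraph.

    Values are written with :func:`repr` (shortest exact decimal), so a
    read -> write -> read round trip is the identity, including zero-valued
    records.  When a ``layout`` is given, chromosome blocks are emitted in
    layout order.
    """
    chrom_order = list(layout.chrom_names) if layout is not None else cov.chroms
    by_chrom: dict[str, list] = {}
    for rec in cov.records:
        by_chrom.setdefault(rec[0], []).append(rec)
    if layout is not None:
        unknown = set(by_chrom) - set(chrom_order)
        if unknown:
            raise ValueError(f"coverage has chromosomes not in layout: {sorted(unknown)}")
    with open(path, "w") as fh:
        for chrom in chrom_order:
            for _, start, end, value in by_chrom.get(chrom, ()):
                fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


# ---------------------------------------------------------------------------
# Gene tables and BED anchors

_GENE_COLUMNS = ("name", "chrom", "strand", "txStart", "txEnd")


def read_gene_table(path) -> list:
    """Read a UCSC-table-browser-style gene table (TSV with header).

    Requires columns ``name chrom strand txStart txEnd``; extra columns are
    ignored.  Duplicated names are kept as transcript variants (collapse
    them downstream with expression-side ``collapse_variants``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        try:
            gene = GeneModel(
                name=str(row.name),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tx_start=int(row.txStart),
                tx_end=int(row.txEnd),
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from None
        genes.append(gene)
    return genes


def write_gene_table(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(f"{g.name}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\n")


def read_bed_anchors(path, default_strand: str = "+") -> AnchorSet:
    """Read BED3/BED6 intervals as point anchors at interval midpoints.

    The anchor position is ``(start + end) // 2``; strand comes from column
    6 when present, otherwise ``default_strand``.  The BED name column, when
    present, becomes the anchor id.
    """
    path = Path(path)
    anchors = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(_HEADER_PREFIXES):
                continue
            parts = stripped.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs at least 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinates") from None
            if start >= end or start < 0:
                raise FormatError(f"{path}:{lineno}: invalid interval {start}-{end}")
            name = parts[3] if len(parts) >= 4 else f"{chrom}:{start}-{end}"
            strand = default_strand
            if len(parts) >= 6:
                if parts[5] not in ("+", "-"):
                    raise FormatError(f"{path}:{lineno}: bad strand {parts[5]!r}")
                strand = parts[5]
            anchors.append(Anchor(chrom, (start + end) // 2, strand, name))
    return AnchorSet(anchors)


def tss_anchors(genes: Iterable[GeneModel], exclude_chroms: Iterable[str] = ()) -> AnchorSet:
    """Strand-aware TSS anchors for a gene list (excluded chromosomes dropped)."""
    excl = set(exclude_chroms)
    return AnchorSet(
        [Anchor(g.chrom, g.tss, g.strand, g.name) for g in genes if g.chrom not in excl]
    )


# ---------------------------------------------------------------------------
# Counts


def read_counts_table(path, metadata_path) -> CountsTable:
    """Read a genes x samples counts TSV plus a sample metadata TSV.

    The metadata file maps sample id (first column) to line, timepoint_h,
    state and replicate.  The sample sets of the two files must match
    exactly; negative or non-integer counts are an error.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        raise FormatError(f"{path}: duplicated gene ids")
    try:
        return CountsTable(counts=counts, meta=meta)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
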