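"""Synthetic Dox-induction experiments with the study's statistical structure.

Generates a complete miniature experiment — genome, gene table, enhancer
BED, RNA-seq counts for WT / K27M / K27L / GSK343 lines in an
undifferentiated (ESC) and a differentiated (RA) state, and ChIP
coverage tracks — so that every pipeline stage is testable without any
download.  The qualitative features emulated:

* H3.3 coverage forms a double peak flanking each TSS (components at
  -400 and +600 bp) whose amplitude scales with expression:
  ``amplitude = amp_scale * u**gamma`` where ``u`` is the percentile of
  a noisy copy of the gene's expression normal-score (gene-level
  heterogeneity ``amp_sigma``), so binding and expression correlate at a
  realistic moderate level without coinciding, and amplitudes stay
  bounded;
* mutant lines carry a multiplicative TSS-proximal incorporation boost
  ``tss_boost`` (and an analogous ``enhancer_boost``) that ramps in with
  Dox-induction kinetics (fraction of steady state 0.4 / 0.6 / 0.85 /
  1.0 at 4 / 8 / 24 / 72 h);
* after differentiation, mutant lines retain a fraction ``retention`` of
  the ESC-program expression at the expense of the differentiation
  program;
* a coupling ``delta`` makes late (72 h) expression depend on early
  binding amplitude in mutant lines (the early-binding -> late-expression
  signature);
* counts are negative-binomial, bin-level ChIP noise is Poisson at a
  configurable read depth, and chromosome ``chr8`` carries a
  configurable share of genes so the exclusion logic is exercised.

All outputs are pure functions of ``(config, seed)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy import stats

from .formats_io import (
    Anchor,
    AnchorSet,
    CountsTable,
    GeneModel,
    GenomeLayout,
    IntervalCoverage,
    write_bedgraph,
    write_gene_table,
)
from .tracks import BinnedTrack

__all__ = [
    "LineParams",
    "ExpressionParams",
    "ChipParams",
    "SimulationConfig",
    "SyntheticGenome",
    "default_lines",
    "make_genome",
    "simulate_expression",
    "simulate_chip",
    "track_to_coverage",
    "generate_bundle",
    "simulate_study",
    "gene_lengths",
    "gene_chroms",
]

ANTIBODIES = ("HA", "H3", "H3K27me3", "H3K27ac")
COUPLING_TIMEPOINT = 72


@dataclass(frozen=True)
class LineParams:
    """Per-line effect sizes (all neutral for WT and the PRC2 inhibitor)."""

    tss_boost: float = 1.0
    enhancer_boost: float = 1.0
    retention: float = 0.0
    coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.tss_boost < 1 or self.enhancer_boost < 1:
            raise ValueError("boosts must be >= 1")
        if not 0 <= self.retention <= 1:
            raise ValueError("retention must be in [0, 1]")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")


def default_lines() -> dict:
    """Study conditions: mutants boosted/retaining/coupled, WT and GSK343 neutral."""
    mutant = LineParams(tss_boost=1.5, enhancer_boost=1.5, retention=0.6, coupling=0.8)
    return {"WT": LineParams(), "K27M": mutant, "K27L": mutant, "GSK343": LineParams()}


@dataclass(frozen=True)
class ExpressionParams:
    """Expression-program structure and count noise.

    Baseline per-gene means are log-normal; pluripotency-program genes
    are shifted up (and differentiation-program genes down) by
    ``exp(program_shift)`` in the ESC state, with the programs swapping in
    the differentiated state.  ``count_depth`` scales expected counts
    (counts are proportional to molar expression times transcript length,
    as for a full-length library).
    """

    n_pluripotency: int = 30
    n_differentiation: int = 30
    log_mu: float = 3.0
    log_sigma: float = 1.0
    program_shift: float = 1.5
    nb_dispersion: float = 0.1
    count_depth: float = 1.0


@dataclass(frozen=True)
class ChipParams:
    """ChIP track shape and noise.

    The double peak sits at ``peak_offsets`` bp from the TSS (oriented),
    with Gaussian widths/heights per component.  ``amp_scale`` sets the
    peak amplitude of a top-percentile gene; ``amp_sigma`` is the sd of
    the Gaussian noise added to the expression normal-score before
    ranking it into the amplitude percentile (0 makes binding a
    deterministic function of expression rank).  ``depth`` is the
    Poisson sampling depth per bin (counts = Poisson(value * depth) /
    depth); a power of two keeps written values exactly representable.
    The line-specific boost applies within ``boost_halfwidth`` of the TSS.
    """

    peak_offsets: tuple = (-400, 600)
    peak_widths: tuple = (250.0, 250.0)
    peak_heights: tuple = (1.0, 0.8)
    gamma: float = 1.0
    amp_scale: float = 3.0
    amp_sigma: float = 1.2
    background: float = 0.2
    depth: float = 32.0
    boost_halfwidth: int = 1200
    gene_span: int = 3000
    enhancer_width: float = 300.0
    enhancer_span: int = 1500
    h3_level: float = 1.0
    me3_level: float = 0.5
    ac_level: float = 0.3
    me3_loss: float = 0.6
    ac_gain: float = 0.5


@dataclass
class SimulationConfig:
    """Everything the generator needs; all outputs are functions of (config, seed)."""

    n_chroms: int = 4
    chrom_length: int = 1_200_000
    n_genes: int = 120
    n_enhancers: int = 40
    bin_size: int = 200
    chr8_share: float = 0.1
    gene_spacing: int = 30_000
    margin: int = 20_000
    lines: dict = field(default_factory=default_lines)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    chip: ChipParams = field(default_factory=ChipParams)
    timepoints: tuple = (4, 8, 24, 72)
    ra_timepoints: tuple = (24, 72)
    dox_ramp: dict = field(default_factory=lambda: {4: 0.4, 8: 0.6, 24: 0.85, 72: 1.0})
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.chrom_length, self.n_genes, self.bin_size) <= 0:
            raise ValueError("sizes must be positive")
        for t in self.timepoints:
            if t not in self.dox_ramp:
                raise ValueError(f"no Dox ramp value for timepoint {t}")
        if self.gene_spacing < 2 * self.chip.boost_halfwidth:
            raise ValueError("gene spacing too small for non-overlapping TSS windows")


@dataclass
class SyntheticGenome:
    layout: GenomeLayout
    genes: list
    enhancers: AnchorSet
    enhancer_amp: np.ndarray


def gene_lengths(genome: SyntheticGenome) -> dict:
    return {g.name: g.length for g in genome.genes}


def gene_chroms(genome: SyntheticGenome) -> dict:
    return {g.name: g.chrom for g in genome.genes}


def _rng(rng) -> Generator:
    if isinstance(rng, Generator):
        return rng
    return default_rng(rng)


# ---------------------------------------------------------------------------


def make_genome(cfg: SimulationConfig, rng=None) -> SyntheticGenome:
    """Place genes on evenly spaced TSS slots with alternating strands.

    TSSs are exactly ``gene_spacing`` apart (>= 30 kb by default, so
    +-10 kb profile windows never overlap); one chromosome is named
    ``chr8`` and carries ``chr8_share`` of the genes to exercise the
    exclusion logic.  Enhancers sit intergenically, halfway between
    adjacent TSS slots on the non-chr8 chromosomes.
    """
    rng = _rng(cfg.seed if rng is None else rng)
    names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    if "chr8" not in names:
        names[-1] = "chr8"
    layout = GenomeLayout(
        chrom_names=names,
        chrom_lengths={c: cfg.chrom_length for c in names},
        bin_size=cfg.bin_size,
    )
    n8 = int(round(cfg.n_genes * cfg.chr8_share))
    others = [c for c in names if c != "chr8"]
    alloc = {c: 0 for c in names}
    alloc["chr8"] = n8
    for i in range(cfg.n_genes - n8):
        alloc[others[i % len(others)]] += 1
    capacity = (cfg.chrom_length - 2 * cfg.margin) // cfg.gene_spacing + 1
    for c, k in alloc.items():
        if k > capacity:
            raise ValueError(
                f"genome too small: {k} genes on {c} but only {capacity} slots "
                f"at {cfg.gene_spacing} bp spacing"
            )
    genes = []
    idx = 0
    for chrom in names:
        for slot in range(alloc[chrom]):
            tss = cfg.margin + slot * cfg.gene_spacing
            length = int(rng.integers(2000, 8001))
            strand = "+" if idx % 2 == 0 else "-"
            if strand == "+":
                tx_start, tx_end = tss, tss + length
            else:
                tx_start, tx_end = tss - length, tss
            genes.append(GeneModel(f"g{idx:04d}", chrom, strand, tx_start, tx_end))
            idx += 1
    anchors = []
    eidx = 0
    slot = 0
    while eidx < cfg.n_enhancers:
        chrom = others[eidx % len(others)]
        pos = cfg.margin + (slot + 0.5) * cfg.gene_spacing
        if pos + cfg.chip.enhancer_span >= cfg.chrom_length - 1:
            raise ValueError("genome too small to place the requested enhancers")
        anchors.append(Anchor(chrom, int(pos), "+", f"e{eidx:03d}"))
        eidx += 1
        if eidx % len(others) == 0:
            slot += 1
    amp = cfg.chip.amp_scale * 0.5 * rng.lognormal(0.0, 0.5, size=cfg.n_enhancers)
    return SyntheticGenome(layout=layout, genes=genes,
                           enhancers=AnchorSet(anchors), enhancer_amp=amp)


def simulate_expression(cfg: SimulationConfig, genome: SyntheticGenome, rng=None):
    """Negative-binomial counts per (line, state, timepoint, replicate).

    ESC state: pluripotency program high, differentiation program low; in
    the differentiated (RA) state the programs swap for WT, while a line
    with retention ``r`` keeps ``r * ESC-level + (1 - r) * WT-RA-level``
    for both programs.  At 72 h the mean is additionally multiplied by
    ``exp(delta * z)`` where ``z`` is the standardised log binding
    amplitude — the early-binding -> late-expression coupling (delta = 0
    leaves it untouched).  Returns ``(CountsTable, truth)``; the truth
    dict is sufficient to recompute every injected effect.
    """
    rng = _rng(cfg.seed if rng is None else rng)
    ex, ch = cfg.expression, cfg.chip
    genes = genome.genes
    n = len(genes)
    names = [g.name for g in genes]
    base_log = rng.normal(ex.log_mu, ex.log_sigma, size=n)
    non8 = [i for i, g in enumerate(genes) if g.chrom != "chr8"]
    n_prog = ex.n_pluripotency + ex.n_differentiation
    if n_prog > len(non8):
        raise ValueError("not enough non-chr8 genes for the expression programs")
    prog = rng.choice(non8, size=n_prog, replace=False)
    pluri = np.array(sorted(prog[: ex.n_pluripotency]))
    diff = np.array(sorted(prog[ex.n_pluripotency :]))
    amp_eps = rng.normal(0.0, 1.0, size=n)

    shift = np.exp(ex.program_shift)
    base = np.exp(base_log)
    esc = base.copy()
    esc[pluri] *= shift
    esc[diff] /= shift
    ra_wt = base.copy()
    ra_wt[pluri] /= shift
    ra_wt[diff] *= shift

    amp_core, amp_w = _amplitudes(esc, amp_eps, ch)
    amp_z = (amp_w - amp_w.mean()) / amp_w.std()

    lengths_kb = np.array([g.length for g in genes]) / 1000.0
    ra_by_line = {}
    columns, meta_rows = {}, {}
    for line, lp in cfg.lines.items():
        ra = ra_wt + lp.retention * (esc - ra_wt)
        ra_by_line[line] = ra
        couple = np.exp(lp.coupling * amp_z)
        for state, tps in (("ESC", cfg.timepoints), ("RA", cfg.ra_timepoints)):
            for t in tps:
                mean = esc if state == "ESC" else ra
                if t == COUPLING_TIMEPOINT:
                    mean = mean * couple
                count_mean = mean * lengths_kb * ex.count_depth
                for rep in range(1, cfg.replicates + 1):
                    lam = rng.gamma(1.0 / ex.nb_dispersion, count_mean * ex.nb_dispersion)
                    counts = rng.poisson(lam)
                    sid = f"{line}_{state}_{t}h_r{rep}"
                    columns[sid] = counts
                    meta_rows[sid] = dict(line=line, timepoint_h=t, state=state, replicate=rep)
    table = CountsTable(
        counts=pd.DataFrame(columns, index=names),
        meta=pd.DataFrame.from_dict(meta_rows, orient="index"),
    )
    truth = dict(
        base_log_mean=base_log,
        esc_mean=esc,
        ra_mean_by_line=ra_by_line,
        pluripotency=[names[i] for i in pluri],
        differentiation=[names[i] for i in diff],
        amp_core=amp_core,
        amp_eps=amp_eps,
        amp_z=amp_z,
        gene_names=names,
    )
    return table, truth


def _amplitudes(state_mean: np.ndarray, amp_eps: np.ndarray, ch: ChipParams):
    """Bounded amplitudes coupled to expression rank.

    The expression normal-score gets independent Gaussian gene-level
    noise (sd ``amp_sigma``); its percentile, raised to ``gamma``, scales
    ``amp_scale``.  Returns ``(amplitude, latent score w)``; ``w`` is
    what the early-binding -> late-expression coupling standardises.
    """
    n = state_mean.size
    perc = (stats.rankdata(state_mean) - 0.5) / n
    w = stats.norm.ppf(perc) + ch.amp_sigma * amp_eps
    u = (stats.rankdata(w) - 0.5) / n
    return ch.amp_scale * u ** ch.gamma, w


def _gaussian_double_peak(offsets: np.ndarray, ch: ChipParams) -> np.ndarray:
    shape = np.zeros_like(offsets, dtype=float)
    for o, w, h in zip(ch.peak_offsets, ch.peak_widths, ch.peak_heights):
        shape += h * np.exp(-0.5 * ((offsets - o) / w) ** 2)
    return shape


def simulate_chip(
    cfg: SimulationConfig,
    genome: SyntheticGenome,
    truth: Mapping,
    line: str,
    timepoint: int,
    rng=None,
    antibodies: Sequence[str] = ("HA",),
    state: str = "ESC",
    replicate: int = 1,
) -> dict:
    """Raw binned ChIP tracks for one (line, timepoint, replicate).

    HA (tagged H3.3): flat background plus the per-gene double peak with
    amplitude ``amp * ramp(t)``, multiplied by the line boost within
    +-``boost_halfwidth`` of the TSS (the boost itself ramps in:
    ``1 + (boost - 1) * ramp``); enhancer peaks analogous with
    ``enhancer_boost``.  H3 is flat (nucleosome occupancy); H3K27me3 /
    H3K27ac totals scale with time under K27M only, mimicking the global
    PRC2 inhibition effect.  Every track gets independent Poisson bin
    noise at ``depth``.
    """
    if line not in cfg.lines:
        raise ValueError(f"unknown line {line!r}")
    if timepoint not in cfg.dox_ramp:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    rng = _rng(rng if rng is not None else cfg.seed)
    lp = cfg.lines[line]
    ch = cfg.chip
    bs = cfg.bin_size
    layout = genome.layout
    ramp = cfg.dox_ramp[timepoint]
    beta_eff = 1.0 + (lp.tss_boost - 1.0) * ramp
    eb_eff = 1.0 + (lp.enhancer_boost - 1.0) * ramp

    if state == "ESC":
        amp = np.asarray(truth["amp_core"], dtype=float)
    else:
        means = np.asarray(truth["ra_mean_by_line"][line], dtype=float)
        amp, _ = _amplitudes(means, np.asarray(truth["amp_eps"]), ch)

    clean_ha = {c: np.full(layout.n_bins(c), ch.background) for c in layout.chrom_names}
    for i, g in enumerate(genome.genes):
        vec = clean_ha[g.chrom]
        k0 = max(0, (g.tss - ch.gene_span) // bs)
        k1 = min(layout.n_bins(g.chrom), (g.tss + ch.gene_span) // bs + 1)
        ks = np.arange(k0, k1)
        mid = ks * bs + bs // 2
        oriented = mid - g.tss if g.strand == "+" else g.tss - mid
        contrib = amp[i] * ramp * _gaussian_double_peak(oriented, ch)
        contrib[np.abs(mid - g.tss) <= ch.boost_halfwidth] *= beta_eff
        vec[ks] += contrib
    for j, a in enumerate(genome.enhancers):
        vec = clean_ha[a.chrom]
        k0 = max(0, (a.position - ch.enhancer_span) // bs)
        k1 = min(layout.n_bins(a.chrom), (a.position + ch.enhancer_span) // bs + 1)
        ks = np.arange(k0, k1)
        mid = ks * bs + bs // 2
        gauss = np.exp(-0.5 * ((mid - a.position) / ch.enhancer_width) ** 2)
        vec[ks] += genome.enhancer_amp[j] * ramp * eb_eff * gauss

    me3_factor = (1.0 - ch.me3_loss * ramp) if line == "K27M" else 1.0
    ac_factor = (1.0 + ch.ac_gain * ramp) if line == "K27M" else 1.0
    flat_levels = {"H3": ch.h3_level, "H3K27me3": ch.me3_level * me3_factor,
                   "H3K27ac": ch.ac_level * ac_factor}

    tracks = {}
    for ab in ANTIBODIES:  # fixed order => stable RNG consumption
        if ab not in antibodies:
            continue
        values = {}
        for chrom in layout.chrom_names:
            base = clean_ha[chrom] if ab == "HA" else np.full(
                layout.n_bins(chrom), flat_levels[ab]
            )
            values[chrom] = rng.poisson(base * ch.depth) / ch.depth
        total = float(sum(v.sum() for v in values.values()))
        tracks[ab] = BinnedTrack(
            layout=layout,
            values=values,
            sample_meta=dict(antibody=ab, line=line, timepoint_h=timepoint,
                             replicate=replicate, state=state),
            total_mapped=total,
        )
    return tracks


def track_to_coverage(track: BinnedTrack) -> IntervalCoverage:
    """Binned track -> bedGraph-ready intervals (zero runs omitted, equal runs merged)."""
    bs = track.layout.bin_size
    records = []
    for chrom in track.layout.chrom_names:
        vals = track.values[chrom]
        length = track.layout.chrom_lengths[chrom]
        bounds = np.flatnonzero(np.diff(vals) != 0) + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [len(vals)]))
        for s, e in zip(starts, ends):
            v = vals[s]
            if v != 0:
                records.append((chrom, int(s) * bs, min(int(e) * bs, length), float(v)))
    return IntervalCoverage(records)


# ---------------------------------------------------------------------------
# Bundles

BUNDLE_FULL_TIMEPOINT_ANTIBODIES = ("HA",)
BUNDLE_REFERENCE_TIMEPOINTS = (4, 8, 72)


def _chip_plan(cfg: SimulationConfig) -> list:
    """Deterministic list of (line, timepoint, antibody, replicate) to write.

    The tagged H3.3 (HA) is written at every timepoint in duplicate; the
    reference (H3) and modification (H3K27me3/H3K27ac) tracks are written
    once per condition at the timepoints the global-change analysis uses.
    """
    plan = []
    for line in cfg.lines:
        for t in cfg.timepoints:
            for rep in range(1, cfg.replicates + 1):
                plan.append((line, t, "HA", rep))
        for t in cfg.timepoints:
            if t in BUNDLE_REFERENCE_TIMEPOINTS:
                for ab in ("H3", "H3K27me3", "H3K27ac"):
                    plan.append((line, t, ab, 1))
    return plan


def generate_bundle(cfg: SimulationConfig, out_dir, force: bool = False) -> dict:
    """Write a complete synthetic experiment to disk; returns the manifest.

    Layout: ``genes.tsv``, ``enhancers.bed``, ``chrom_sizes.tsv``,
    ``counts.tsv`` + ``samples.tsv``, ``chip/<line>_<t>h_<ab>_rep<k>.bedgraph``
    and ``manifest.json`` with a SHA-256 per file.  Re-running with the
    same config and seed reproduces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force=True)")
    ss = SeedSequence(cfg.seed)
    genome_ss, expr_ss, chip_ss = ss.spawn(3)
    genome = make_genome(cfg, default_rng(genome_ss))
    counts, truth = simulate_expression(cfg, genome, default_rng(expr_ss))

    write_gene_table(genome.genes, out / "genes.tsv")
    with open(out / "enhancers.bed", "w") as fh:
        for a in genome.enhancers:
            fh.write(f"{a.chrom}\t{a.position - 200}\t{a.position + 200}\t{a.id}\t0\t{a.strand}\n")
    with open(out / "chrom_sizes.tsv", "w") as fh:
        for c in genome.layout.chrom_names:
            fh.write(f"{c}\t{genome.layout.chrom_lengths[c]}\n")
    counts.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene")
    counts.meta.to_csv(out / "samples.tsv", sep="\t", index_label="sample")

    chip_dir = out / "chip"
    chip_dir.mkdir(exist_ok=True)
    plan = _chip_plan(cfg)
    children = chip_ss.spawn(len(plan))
    for (line, t, ab, rep), child in zip(plan, children):
        tracks = simulate_chip(cfg, genome, truth, line, t, rng=default_rng(child),
                               antibodies=(ab,), replicate=rep)
        cov = track_to_coverage(tracks[ab])
        write_bedgraph(cov, chip_dir / f"{line}_{t}h_{ab}_rep{rep}.bedgraph",
                       layout=genome.layout)

    files = {}
    for path in sorted(out.rglob("*")):
        if path.is_file():
            files[str(path.relative_to(out))] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {"seed": cfg.seed, "config": asdict(cfg), "files": files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


def simulate_study(
    cfg: SimulationConfig,
    seed: int | None = None,
    antibodies: Sequence[str] = ("HA",),
    chip_lines: Sequence[str] | None = None,
    chip_timepoints: Sequence[int] | None = None,
    chip_replicates: int | None = None,
    chip_state: str = "ESC",
) -> dict:
    """In-memory experiment: genome + counts + the requested ChIP tracks.

    Convenience wrapper used by the analysis scripts: tracks come back as
    ``tracks[(line, timepoint, replicate)][antibody]``.  Deterministic in
    ``(cfg, seed)`` for fixed subset arguments.
    """
    ss = SeedSequence(cfg.seed if seed is None else seed)
    genome_ss, expr_ss, chip_ss = ss.spawn(3)
    genome = make_genome(cfg, default_rng(genome_ss))
    counts, truth = simulate_expression(cfg, genome, default_rng(expr_ss))
    lines = list(chip_lines) if chip_lines is not None else list(cfg.lines)
    tps = list(chip_timepoints) if chip_timepoints is not None else list(cfg.timepoints)
    reps = chip_replicates if chip_replicates is not None else cfg.replicates
    combos = [(line, t, rep) for line in lines for t in tps for rep in range(1, reps + 1)]
    children = chip_ss.spawn(len(combos)) if combos else []
    tracks = {}
    for (line, t, rep), child in zip(combos, children):
        tracks[(line, t, rep)] = simulate_chip(
            cfg, genome, truth, line, t, rng=default_rng(child),
            antibodies=antibodies, state=chip_state, replicate=rep,
        )
    return dict(genome=genome, counts=counts, truth=truth, tracks=tracks)
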