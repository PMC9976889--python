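"""Shared fixtures-in-code: independent brute-force oracles and tiny builders.

The oracles here deliberately re-derive every statistic from first
principles (per-base accumulation, full enumeration, closed forms) so
they stay independent of the library code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

import h33dyn as h


# ---------------------------------------------------------------------------
# Builders


def make_layout(lengths=None, bin_size=200):
    lengths = lengths or {"chr1": 10000, "chr2": 8000, "chr8": 6000}
    return h.GenomeLayout(list(lengths), lengths, bin_size=bin_size)


def random_coverage(rng, layout, max_records_per_chrom=15):
    """Random sorted non-overlapping intervals with non-bin-aligned ends."""
    records = []
    for chrom in layout.chrom_names:
        length = layout.chrom_lengths[chrom]
        k = rng.integers(0, max_records_per_chrom + 1)
        cuts = np.sort(rng.choice(length, size=2 * k, replace=False)) if k else []
        for i in range(0, len(cuts), 2):
            start, end = int(cuts[i]), int(cuts[i + 1])
            if start < end:
                records.append((chrom, start, end, float(rng.integers(0, 50)) / 4))
    return h.IntervalCoverage(records)


def constant_track(layout, value=1.0, meta=None):
    values = {c: np.full(layout.n_bins(c), float(value)) for c in layout.chrom_names}
    total = float(sum(v.sum() for v in values.values()))
    return h.BinnedTrack(layout=layout, values=values, sample_meta=meta or {},
                         total_mapped=total)


def random_track(rng, layout):
    values = {c: rng.random(layout.n_bins(c)) for c in layout.chrom_names}
    total = float(sum(v.sum() for v in values.values()))
    return h.BinnedTrack(layout=layout, values=values, total_mapped=total)


def mirror_track(track):
    """Reverse every chromosome's bin vector (chromosome lengths must be bin-aligned)."""
    values = {c: v[::-1].copy() for c, v in track.values.items()}
    return h.BinnedTrack(layout=track.layout, values=values,
                         total_mapped=track.total_mapped, normalized=track.normalized)


def mirror_gene(gene, length):
    flipped = "-" if gene.strand == "+" else "+"
    return h.GeneModel(gene.name, gene.chrom, flipped,
                       length - gene.tx_end, length - gene.tx_start)


# Study-scale generator configurations (problem sizes used by the
# simulation-based checks; small enough to run hundreds of replicates).

def study_config(**overrides):
    base = dict(n_genes=300, chrom_length=2_800_000, n_enhancers=60)
    base.update(overrides)
    return h.SimulationConfig(**base)


def large_config(**overrides):
    base = dict(n_genes=600, chrom_length=5_600_000, n_enhancers=60)
    base.update(overrides)
    return h.SimulationConfig(**base)


def neutral_lines(names=("WT", "K27M")):
    return {name: h.LineParams() for name in names}


def replicate_mean_scores(study, line, timepoint, replicates):
    scores = [
        h.gene_window_score(study["tracks"][(line, timepoint, rep)]["HA"],
                            study["genome"].genes).scores
        for rep in replicates
    ]
    return sum(scores) / len(scores)


def expression_of(study):
    genome, counts = study["genome"], study["counts"]
    return h.tpm_normalize(counts, h.gene_lengths(genome), h.gene_chroms(genome))


# ---------------------------------------------------------------------------
# Oracles


def oracle_bin_coverage(cov, layout):
    """Base-resolution accumulation, then per-bin mean times occupancy."""
    out = {}
    for chrom in layout.chrom_names:
        base = np.zeros(layout.chrom_lengths[chrom])
        for c, start, end, value in cov.records:
            if c == chrom:
                base[start:end] += value
        bs = layout.bin_size
        n = layout.n_bins(chrom)
        bins = np.zeros(n)
        for k in range(n):
            bins[k] = base[k * bs : (k + 1) * bs].sum() / bs
        out[chrom] = bins
    return out


def oracle_window_score(track, gene, upstream=(-1200, -200), downstream=(400, 1200)):
    """Per-base mean over the literal bp windows around the strand-snapped TSS."""
    bs = track.layout.bin_size
    vals = track.values[gene.chrom]
    base = np.repeat(vals, bs)[: track.layout.chrom_lengths[gene.chrom]]
    if gene.strand == "+":
        snap = (gene.tss // bs) * bs
        segs = [(snap + w0, snap + w1) for (w0, w1) in (upstream, downstream)]
    else:
        snap = math.ceil(gene.tss / bs) * bs
        segs = [(snap - w1, snap - w0) for (w0, w1) in (upstream, downstream)]
    picked = np.concatenate([base[a:b] for a, b in segs])
    return picked.mean()


def oracle_average_ranks(v):
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    ranks[order] = np.arange(1, len(v) + 1)
    for val in np.unique(v):
        mask = v == val
        ranks[mask] = ranks[mask].mean()
    return ranks


def oracle_spearman_rho(x, y):
    """Pearson of average ranks, from the covariance definition."""
    rx, ry = oracle_average_ranks(x), oracle_average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


def oracle_two_sample_t(a, b):
    """Pooled-variance two-sample t and its two-sided p (textbook formula)."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, 2 * tdist.sf(abs(t), na + nb - 2)


def oracle_mannwhitney_exact(a, b):
    """Exact two-sided U test by full enumeration of group assignments.

    Valid for tie-free pooled data; p = min(1, 2 * min(P(U<=u), P(U>=u))).
    """
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)

    def u_stat(group_a, group_b):
        return sum((x > y) + 0.5 * (x == y) for x in group_a for y in group_b)

    u_obs = u_stat(a, b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(ga, gb))
    us = np.array(us)
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2 * min(lo, hi))


def oracle_hypergeom_upper(k, N, K, n):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by summation."""
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / math.comb(N, n)


def oracle_bh(ps):
    ps = np.asarray(ps, dtype=float)
    m = len(ps)
    order = np.argsort(ps, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, ps[i] * m / rank_from_top)
        q[i] = running
    return q


def oracle_fisher_2x2(table):
    """Two-sided Fisher p by enumerating all tables with the observed margins."""
    t = np.asarray(table, dtype=np.int64)
    r1, r2 = t.sum(axis=1)
    c1 = t[:, 0].sum()
    n = t.sum()

    def pmf(a):
        return (math.comb(r1, a) * math.comb(r2, c1 - a)) / math.comb(n, c1)

    a_obs = t[0, 0]
    p_obs = pmf(a_obs)
    total = 0.0
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = pmf(a)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)
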