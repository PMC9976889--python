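# Methods

This note documents the models, conventions and design choices behind
`h33dyn`, in the spirit of a statistical-methods appendix. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and orientation conventions

All genomic coordinates are 0-based half-open; an interval `[k, k+1)`
covers exactly base `k`. For a `+`-strand gene the TSS is `txStart`; for
a `-`-strand gene it is `txEnd` (first transcribed base `txEnd − 1`).
Strand-oriented offsets are positive downstream of transcription, and
every profile or window operation orients before extracting, so minus-
strand rows never need post-hoc flipping. This single rule is shared by
every module; it is a convention (standard UCSC arithmetic), not an
inference about any particular upstream tool.

## Track model

Coverage is analysed at a fixed bin width (200 bp default). Binning is
by **exact fractional overlap**: a record contributes
`value · overlap_bp / bin_size` to each bin it intersects, i.e. the bin
value is mean per-base coverage times bin occupancy. This is exact for
coverage-interval inputs (the inputs here are pileups, not reads) and is
verified bin-for-bin against a base-resolution accumulation oracle.

RPM normalisation scales every bin by `10⁶ / (total over included
chromosomes)`. Excluded chromosomes (default `{chr8}`, modelling the
exclusion of an aneuploid chromosome from all analyses) are scaled by
the same factor but never enter the denominator, so they remain
inspectable while the included-chromosome sum is exactly 10⁶. Relative
bin proportions are preserved by construction.

Global modification change takes raw (unnormalised) modification and
reference tracks per timepoint, forms `ratio(t) = mod_total / ref_total`
and reports `ratio(72 h) / mean(ratio(4 h), ratio(8 h))`. The reference
is a caller argument; H3 is the intended reference since it serves as
the global normaliser in multiplexed ChIP. Values below 1 describe a
global loss (e.g. H3K27me3 under K27M).

Profile matrices follow the reference-point logic of
deepTools-computeMatrix: column *j* of row *i* is the bin containing
`anchor_i + oriented(offset_j + bin/2)`. Anchors whose ±flank window
leaves the chromosome are dropped (and counted); padding would bias the
edge offsets. The operation commutes with mirroring the genome
(coordinates reversed, strands flipped) exactly, except for anchors
sitting precisely on a bin midpoint (position ≡ 100 mod 200), where the
containing-bin rule is inherently asymmetric; the property tests avoid
that residue by contract.

Genic distribution assigns each bin by its midpoint to exactly one
category with precedence promoter > TTS > gene body > intergenic.
Window sizes (promoter −2000…+500, TTS ±1000 bp around the oriented
anchors) are common-practice defaults, exposed as parameters because no
single convention is canonical.

## The TSS-flanking window score

The per-gene binding score is the mean binned signal over the oriented
windows **−1.2…−0.2 kb and +0.4…+1.2 kb from the TSS**. These windows
skip the nucleosome-depleted region at the TSS itself and bracket the
characteristic H3.3 double peak. Bin membership is decided by bin
midpoint after snapping the TSS to the bin boundary at the transcription
start, oriented by strand (floor on `+`, ceiling on `-`). With 200 bp
bins this selects exactly 5 upstream + 4 downstream = 9 bins on either
strand, makes the score a deterministic, oracle-checkable function of
the binned track, and makes it commute exactly with genome mirroring.
Sub-bin interpolation was rejected: it adds smoothing noise without a
defined target. Genes whose windows leave the chromosome are dropped
and counted; genes on excluded chromosomes are absent from score
vectors by contract.

## Statistics

* **Spearman correlation** uses average ranks (ties allowed). The
  p-value is the exact permutation distribution of rho for n < 10 and
  the t approximation otherwise. Constant vectors are an error, not
  rho = 0.
* **Group comparisons** follow the study's stated convention: two-tailed
  Student's t for equal-sized groups, Mann–Whitney U for unequal sizes
  (exact for small tie-free samples, otherwise normal approximation with
  tie correction).
* **Comparing two correlations** uses the Fisher z-transform two-sample
  test. The published analyses label their version a "t-test" without
  stating the construction; the z construction is the default here and
  is labelled as such — no claim is made that it reproduces any printed
  p-value.
* **Over-representation** is plain upper-tail hypergeometric per
  category with Benjamini–Hochberg correction across categories — an
  in-repo, database-free stand-in for web GO tools. BH is the only
  multiple-testing procedure in the package.
* **DE classification** requires BOTH BH-adjusted p < 0.05 and fold
  change > 2 or < 0.5, with a pseudocount of 1 on TPM before ratios
  (the pseudocount guards against division by zero and stabilises low
  expressors; its exact value is a design choice). The internal per-gene
  test is a two-sample t on log2(TPM+1) — an explicitly simplified
  stand-in for a count-model DE test (no dispersion shrinkage, no
  size-factor estimation); `external_p` accepts a dedicated DE tool's
  per-gene p-values so real output can be slotted in unchanged.
* **Fisher's exact test** is two-sided by point-probability summation
  (all tables at the observed margins whose probability does not exceed
  the observed), not by doubling a one-sided p; it is verified against a
  full enumeration oracle.
* **CyTOF normalisation**: arcsinh(x/5) (cofactor 5, the mass-cytometry
  standard), per-marker standardisation (population sd; a zero-variance
  marker is an error naming the marker), then each epigenetic marker
  minus the per-cell mean of the standardised core-histone markers.

Quantile gene sets ("high binding at 8 h", "highly expressed at 72 h")
use strict-inequality membership above the empirical quantile, so ties
at the threshold are excluded deterministically. The thresholds are
parameters (defaults 0.75 for binding, 0.5 for expression) because no
canonical values exist; the simulation-based checks fix both at 0.75,
where the high-binding and high-expression strata are sharp enough for
the contingency comparison to be informative.

## The synthetic-data generator

The generator emulates the statistical structure of a Dox-induction
experiment, not its sequence content. Defaults are the study
conditions; everything is a pure function of `(config, seed)`.

* **Genome**: 4 chromosomes (one named `chr8` carrying 10 % of genes to
  exercise the exclusion logic), TSSs on exact 30 kb slots (so ±10 kb
  profile windows never overlap), alternating strands, transcript
  lengths uniform 2–8 kb, enhancers midway between TSS slots.
* **Expression**: per-gene baseline means are log-normal (ln-mean 3,
  ln-sd 1, TPM scale). A pluripotency program (30 genes) is shifted up
  and a differentiation program (30 genes) down by e^1.5 in the ESC
  state; the programs swap in the RA state. A line with retention *r*
  keeps `r·ESC + (1−r)·WT-RA` of both program levels after
  differentiation. Counts are negative-binomial (dispersion 0.1) with
  expected counts proportional to mean × transcript length, so TPM
  recovers the simulated means.
* **ChIP**: H3.3 coverage is a flat background (0.2) plus a per-gene
  double peak with Gaussian components at −400 and +600 bp (widths
  250 bp, heights 1.0/0.8) — the peak offsets are invented modelling
  choices reproducing the qualitative double-peak shape, not measured
  values. Peak amplitude is `amp_scale · u^γ` (γ = 1) where *u* is the
  percentile of a noisy copy of the gene's expression normal-score
  (noise sd `amp_sigma` = 1.2). The rank-based construction keeps
  amplitudes bounded (no heavy tail dominating cross-line comparisons)
  while setting the binding–expression Spearman in the moderate
  (~0.55–0.65) regime typical of chromatin data. Mutant lines multiply
  the TSS-proximal signal (±1.2 kb) by `tss_boost` and enhancer peaks by
  `enhancer_boost`; both ramp in with Dox-induction kinetics (fraction
  of steady state 0.4/0.6/0.85/1.0 at 4/8/24/72 h — an invented but
  monotone induction curve). H3 is flat; H3K27me3/H3K27ac totals scale
  with time under K27M only, mimicking the global PRC2-inhibition
  signature. Bin noise is Poisson at depth 32 reads per unit coverage
  (a power of two keeps written bedGraph values exactly representable,
  which makes byte-identical round trips trivial); this depth puts
  cross-timepoint binding-target correlations in the >0.9 regime
  reported for such experiments.
* **Coupling**: for a line with coupling δ, the 72 h expression mean is
  multiplied by `exp(δ·z)` where *z* is the standardised amplitude
  latent score — the minimal mechanism making early binding predictive
  of late expression over and above the baseline binding–expression
  association.
* **Bundles** write the tagged-H3.3 (HA) tracks at every timepoint in
  duplicate and the reference/modification tracks (H3, H3K27me3,
  H3K27ac) once per condition at 4/8/72 h — the analyte gets replicates,
  the reference tracks one library each, keeping the default bundle
  under 50 MB of plain text.

What the generator does **not** emulate: read-level data (no FASTQ, no
fragment-length or GC structure), mappability, peak shape heterogeneity,
batch effects between the two "experiments", cell-cycle or culture
composition effects, and any sequence-dependent biology. Passing the
simulation-based tests therefore shows that the pipeline recovers the
injected statistical structure at realistic noise levels — not that it
would be robust to every artefact of real sequencing data.

## Simulation-based validation and problem sizes

The validation suite (`tests/test_acceptance.py`) uses 300-gene,
4×2.8 Mb genomes with 2 replicates for the effect-recovery checks
(TSS gain, coupling, retention, stability) over 50 seeds each, and
600-gene genomes for the early-binding → late-expression contingency,
where the Fisher comparison needs ~135 high-binding genes per line to
be well powered at the simulated effect size. These sizes were chosen
so the whole suite completes in about a minute while every comparison
retains clear power margins.

The type-I calibration of the contingency procedure deserves a note.
Within one simulated experiment all lines share a genome, a chromatin
landscape and expression programs — as real cell lines do — so under
parameter-equal lines the per-line "late among high-binding" counts are
strongly positively correlated across lines and the exact test is very
conservative (empirical rejection far below nominal). The calibration
therefore samples under the test's own null model: two **independent**
experiments with identical neutral parameters and the
binding–expression dependence switched off (γ = 0), making each row's
count genuinely hypergeometric. Under that fully null generator the
rejection rate at α = 0.05 sits near nominal (the suite asserts
0.02–0.08 over 500 pairs). In the shared-genome regime the test errs
conservative, never anticonservative.

## Known limitations

* The internal DE test is not a count-model test; use `external_p` for
  real data.
* `global_modification_change` assumes library-comparable raw tracks;
  it refuses normalised input rather than guessing.
* The exact permutation p for Spearman is limited to n < 10 by design
  (n! growth); above that the t approximation is used.
* Collapsing transcript variants by per-sample maximum (the
  maximal-expression convention) means column sums of a collapsed TPM
  matrix are no longer exactly 10⁶; re-normalise explicitly if needed —
  subsetting or collapsing never renormalises silently.
* The CLI carries binned tracks as bedGraph whose intervals are bins;
  sample metadata travels in file names, not in the files.
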