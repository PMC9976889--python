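# h33dyn

Analysis pipeline for **histone H3.3 incorporation dynamics** in
Dox-inducible tagged-histone time-course experiments (Time-Seq ChIP-seq
with matched RNA-seq), built for the comparison of cell lines expressing
WT H3.3, the oncogenic H3.3K27M mutant, the non-modifiable H3.3K27L
control, and PRC2-inhibitor (GSK343) treated cells.

H3.3 is the replication-independent H3 variant deposited by HIRA at
promoters and active enhancers; its incorporation tracks transcription.
H3.3K27M — the driver of most Diffuse Midline Gliomas — dominantly
inhibits PRC2, but also changes H3.3's own deposition behaviour. This
package implements the downstream statistics used to dissect those two
effects: where the tagged histone goes, how fast it accumulates, how its
binding couples to gene expression, and whether differentiated mutant
cells retain a stem-like transcriptome.

## What it computes

* **Tracks** (`h33dyn.tracks`) — bedGraph coverage binned at 200 bp by
  exact fractional overlap; RPM normalisation over included chromosomes
  (chr8 is excluded from denominators by default, mirroring an
  aneuploidy exclusion); strand-oriented anchor profile matrices
  (±10 kb around TSSs/enhancers), metagene curves with 2×SE bands,
  signal-sorted heatmaps, genic signal distribution, and global
  modification change relative to an H3 reference.
* **Gene statistics** (`h33dyn.genestats`) — the TSS-flanking window
  score (mean binned signal over −1.2…−0.2 kb and +0.4…+1.2 kb from the
  TSS, 9 bins at 200 bp), Spearman correlation (exact permutation p at
  small n), binding–expression coupling, correlation matrices, t/U group
  tests (U for unequal group sizes), Fisher-z comparison of
  correlations, hypergeometric over-representation with BH correction,
  and CyTOF arcsinh/standardise/core-histone normalisation.
* **Differentiation** (`h33dyn.differentiation`) — TPM, maximal-variant
  collapse, DE classification (q < 0.05 AND fold change > 2 or < 0.5,
  pseudocount 1), fold-change gene groups between lines, group
  expression comparison, and the ESC↔differentiated state-retention
  Spearman correlation (24 h/72 h RA samples pooled).
* **Dynamics** (`h33dyn.dynamics`) — binding-target stability across
  4/8/24/72 h (full Spearman matrix, two experiments), and the
  early-binding → late-expression contingency procedure: genes with high
  binding at 8 h (empirical quantile), the fraction of them highly
  expressed at 72 h, and two-sided Fisher exact tests between lines.
* **Synthetic data** (`h33dyn.synthetic_data`) — a deterministic
  generator producing a complete miniature experiment (genome, gene
  table, enhancer BED, counts, per-line/timepoint/replicate bedGraphs)
  with the double-peak TSS profile, the mutant TSS/enhancer boost
  ramping in with Dox kinetics, ESC-program retention after RA
  differentiation, and the early-binding → late-expression coupling.

## Worked example

```python
import h33dyn as h

cfg = h.SimulationConfig(n_genes=300, chrom_length=2_800_000, seed=0)
study = h.simulate_study(cfg, seed=0, chip_timepoints=[72])
expr = h.tpm_normalize(study["counts"], h.gene_lengths(study["genome"]),
                       h.gene_chroms(study["genome"]))

for line in ("WT", "K27M", "GSK343"):
    scores = h.gene_window_score(study["tracks"][(line, 72, 1)]["HA"],
                                 study["genome"].genes)
    rho = h.binding_expression_correlation(
        scores, expr, expr.samples(line=line, state="ESC", timepoint_h=72))
    ret = h.state_retention_correlation(expr, line)
    print(f"{line:8s} mean TSS window score {scores.scores.mean():.3f}   "
          f"binding~expression rho {rho.rho:.2f}   ESC<->RA rho {ret.rho:.2f}")
```

prints

```
WT       mean TSS window score 0.940   binding~expression rho 0.55   ESC<->RA rho 0.37
K27M     mean TSS window score 1.319   binding~expression rho 0.80   ESC<->RA rho 0.86
GSK343   mean TSS window score 0.944   binding~expression rho 0.52   ESC<->RA rho 0.36
```

Reading it: the K27M line incorporates ~40 % more tagged H3.3 in the
±1.2 kb TSS windows than WT, its binding correlates more strongly with
expression, and after retinoic-acid differentiation its transcriptome
stays far closer to the undifferentiated state (rho 0.86 vs 0.37) — the
delayed-differentiation signature.  PRC2 inhibition alone (GSK343)
reproduces none of this, the hallmark of a PRC2-independent effect.

The same analyses are available from the shell via the `h33dyn` CLI
(`h33dyn simulate`, `bin`, `normalize`, `profile`, `window-score`,
`tpm`, `retention`, `retention-ratio`, …); every command reads and
writes plain bedGraph/BED/TSV/JSON.

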