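# introdelta

Exon/intron split analysis of bulk RNA-seq for estimating disease-associated
changes in **post-transcriptional gene regulation (ΔPTGR)**, with downstream
inference of candidate RNA-binding-protein (RBP) and miRNA drivers from
3′UTR motif content.

## The idea

In an RNA-seq library, reads falling in introns come almost entirely from
unspliced pre-mRNA and track *transcription*, while exonic reads track
mature mRNA abundance — the combined outcome of transcription and
post-transcriptional regulation (mRNA stability). For each gene, after
median-centering log₂ expression per sample (Δexon, Δintron), the robust
regression slope of Δexon on Δintron within a sample group measures how
mature mRNA responds to transcriptional input. A slope that differs between
disease and control indicates post-transcriptional dysregulation:

```
ΔPTGR = slope_Disease − slope_Ctrl

t  = (slope_Disease − slope_Ctrl) / sqrt(SE²_Disease + SE²_Ctrl)
df = n_Disease + n_Ctrl

ratio = | slope_Disease / slope_Ctrl − 1 |          (PTGR vs TGR contribution)

ΔPTGR_in = Δexon_i − Δintron_i × slope_Ctrl         (per disease individual)
```

ΔPTGR > 0 means mature mRNA is post-transcriptionally up-regulated
(stabilized) in disease. Genes significant at Benjamini–Hochberg FDR < 0.05
are called differentially post-transcriptionally regulated genes (DPRGs).
Candidate drivers are then found by regressing per-gene ΔPTGR on a
genes × motifs binding matrix obtained by scanning 3′UTR sequences with RBP/
miRNA position frequency matrices (PFMs); regulators with coefficient
p < 0.05 are reported with their predicted targets.

## What's in the box

| module | contents |
|---|---|
| `introdelta.annotation` | GTF parsing, composite-exon union, intron complement, GTF/SAF writers |
| `introdelta.counts` | TPM filtering, TMM normalization, log₂ CPM, covariate residualization (`TMMLogCPM`, `CovariateResidualizer`) |
| `introdelta.robust` | vectorized Huber IRLS line fitting (c = 1.345, MAD scale, H1 covariance) |
| `introdelta.ptgr` | median centering, ΔPTGR statistics, DPRG calling (`DeltaPTGREstimator`) |
| `introdelta.motifs` | PFM I/O (MEME minimal / column table), similarity + greedy clustering, UTR affinity scanning (`MotifScanner`), seed/ARE matching, Fisher enrichment |
| `introdelta.rbp` | driver regression (`RegulatorRegression`), regulator selection, target assignment |
| `introdelta.simulate` | negative-binomial exon/intron cohort generator with ground truth; UTR simulator |
| `introdelta.validation` | end-to-end calibration/recovery studies |
| `introdelta.cli` | `introdelta` command-line interface over all of the above |

Transform/fit-shaped stages are sklearn-style estimators (`fit`/`transform`,
`get_params`, trailing-underscore attributes) and compose with sklearn
pipelines; module-level functions are thin wrappers.

## Worked example

Simulate a cohort of 60 controls + 60 disease samples over 500 genes where
10% of genes carry a true disease slope shift of +0.5, then run the full
pipeline:

```python
from introdelta import (SimConfig, simulate_counts, prepare_expression,
                        DeltaPTGREstimator, truth_eval)

cfg = SimConfig(n_genes=500, n_ctrl=60, n_disease=60, seed=42)
exon, intron, samples, truth = simulate_counts(cfg)
ex, im, kept = prepare_expression(exon, intron, samples)
est = DeltaPTGREstimator(control_label="control").fit(
    ex.values, im.values, samples.set_index("sample_id")["diagnosis"])
print(est.summary())
```

```
disease  n_tested  n_dprg  n_up  n_down  mean_abs_ratio
disease       500      54    54       0         0.08566
```

54 DPRGs are called at FDR < 0.05, all in the "up" direction (the planted
shift stabilizes mRNA in disease). The strongest calls recover the planted
slope contrast:

```
gene_id  slope_ctrl  slope_dis  delta_ptgr      t  df  fdr  ratio direction
 G00009       0.975      1.538       0.563 14.448 120  0.0  0.577        up
 G00057       0.969      1.521       0.551 12.624 120  0.0  0.568        up
 G00154       0.965      1.478       0.512 12.707 120  0.0  0.531        up
```

`truth_eval(est.results_, truth)` scores the run against the generator's
ground truth: sensitivity 1.0, observed false-discovery proportion 0.074,
slope RMSE 0.033, direction accuracy 1.0.

The same pipeline is available from the shell:

```bash
introdelta simulate --seed 42 --out-dir sim/
introdelta normalize --exon sim/counts_exon.tsv --intron sim/counts_intron.tsv \
    --samples sim/samples.tsv --lengths sim/exon_lengths.tsv --out-dir norm/
introdelta estimate-ptgr --exon norm/exon_lcpm.tsv --intron norm/intron_lcpm.tsv \
    --samples sim/samples.tsv --control-label control --out-dir ptgr/
```

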