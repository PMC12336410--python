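# Methods

## Model and rationale

Intronic read abundance is treated as a proxy for pre-mRNA (transcription);
exonic read abundance reflects mature mRNA, i.e. transcription plus
post-transcriptional regulation. For gene *g* and group *k* (control or one
disease), after per-gene median centering of log₂ expression over the
reference sample set (Δexon, Δintron), we model

    Δexon_i = α + β_k · Δintron_i + ε_i

by Huber M-estimation and interpret the slope β_k as the exon-per-intron
response. The disease-vs-control slope contrast ΔPTGR = β_D − β_C is tested
with

    t = (β_D − β_C) / sqrt(SE_D² + SE_C²),    df = n_D + n_C,

two-sided p from Student's t, and Benjamini–Hochberg control across genes
(DPRG call at FDR < 0.05). The relative contribution of post-transcriptional
versus transcriptional dysregulation is ratio = |β_D/β_C − 1| (undefined,
never infinite, when |β_C| ≤ 1e−6). Per disease individual *i*,
ΔPTGR_in = Δexon_i − Δintron_i·β_C scores that sample's deviation from the
control line. In a two-condition design without enough samples for
per-group fits (e.g. a knockdown contrast), the score degenerates to
Δexon − Δintron (slope fixed at 1), exposed as `two_condition_delta`.

The df = n_D + n_C convention is kept as the primary definition; a
Welch–Satterthwaite df is available (`df_mode="welch"`) for sensitivity
analysis and, being smaller, is mildly more conservative.

Median centering defaults to the pooled sample set (`center="all"`); a
control-only reference (`center="control"`) is provided because fits are
per group and the choice of reference is a genuine modeling ambiguity.
Centering makes the intercept ≈ 0 but the fit retains it rather than
forcing the line through the origin.

## Robust fitting

The per-gene two-parameter Huber IRLS is vectorized across genes: Huber ψ
with c = 1.345 (95% efficiency at the Gaussian), scale re-estimated each
iteration as median(|r|)/0.6745, at most 50 iterations, convergence at
1e−8. Slope standard errors use the Huber-corrected asymptotic covariance
(the "H1" form: correction factor k = 1 + (p/n)·var(ψ′)/mean(ψ′)², scaled
Σψ² estimate, unweighted (XᵀX)⁻¹). The test suite verifies agreement with
statsmodels RLM fitted gene-by-gene with identical settings to ~1e−6 in
slope and SE. Genes with fewer than `min_fit_n` (default 10) finite pairs
or MAD(Δintron) = 0 are skipped with a recorded reason, not silently
dropped; an exact fit (zero residual scale) reports SE 0, and a zero-SE
contrast with unequal slopes is flagged "exact_separation" with p = 0.

## Counts preparation

Genes are filtered on **exonic** TPM (> 1 in ≥ 50% of samples; strict
inequality on TPM, inclusive on the fraction) and the surviving set is
applied to both matrices. Exonic and intronic matrices are then processed
independently: trimmed-mean-of-M-values (TMM) factors — reference sample by
upper-quartile CPM closest to the mean upper quartile; per pair,
inverse-variance-weighted mean of M-values after trimming 30% of M and 5%
of A tails (average ranks, so tied integer counts are handled as R's
`rank` does); factors rescaled to geometric mean 1 — followed by
log₂ CPM with prior count 0.5: log₂((count + 0.5)/(libsize·factor + 1)·1e6).
This is the de-facto standard parameterization of the cited normalization;
the implementation was checked once against edgeR's `calcNormFactors` to
printed precision, and the suite keeps an independent Python
re-implementation as the oracle.

Nuisance covariates are removed by per-gene least squares with the
diagnosis contrast (and intercept) protected: the design is
[intercept | protected | nuisance], categoricals dummy-coded against a
reference level, exactly collinear nuisance columns dropped with a warning
(aliased *protected* columns raise), and only the fitted nuisance
contribution is subtracted. This fixed-effects residualization approximates
the subject-random-effect mixed model; with one sample per subject the two
coincide, and with repeated measures per-subject collapsing (mean) is the
supported route. Covariate *selection* is out of scope: the covariate list
is user-supplied configuration, since downstream stages consume only the
chosen set.

## Motif toolkit

PFMs are per-position base probability matrices (A,C,G,T/U order; U and T
interchangeable, sequences normalized to T). Zero cells are floored at
1e−3 and rows renormalized — flooring only true zeros keeps
read(write(x)) = x to 1e−9. Affinity of a UTR for a PFM is the energy-like
log₂ Σ_windows Π_positions p(base): smooth, length-robust, and monotone in
the number and quality of candidate sites. A binding *site* is called when
the best window reaches `presence_fraction` (default 0.8) of the motif's
maximum attainable window score; the presence threshold is a package
convention, exposed in configuration, since only the notion of an
"RBP-bound gene" is externally specified. Scanning is sense-strand only
(3′UTRs are already oriented); characters outside the alphabet zero out
their windows with a warning.

Motif similarity is the Pearson correlation of two PFMs' affinities over a
fixed panel of 500 random length-100 sequences (seed 0); a constant-scoring
(e.g. uniform) motif is *degenerate* and given similarity 0. Non-redundant
sets come from greedy clustering in input order against cluster
representatives (first members) at threshold 0.75 — deterministic given
input order.

miRNA seed sites are exact matches of the reverse complement of miRNA bases
2–8 (7mer-m8; 8mer and 7mer-A1 variants selectable); the miRNA sequence is
always an input, never hard-coded. AU-rich elements default to the AUUUA
pentamer; any IUPAC pattern may be supplied. Enrichment uses Fisher's exact
test (one-sided "greater" by default) on the (hit, not-hit) × (in set, out)
table; the reported odds ratio is the sample cross-product ratio with
Haldane's 0.5 correction applied, and flagged, only when a cell is zero.

Gene eligibility for UTR scanning requires all isoforms to share one 3′UTR
start coordinate (alternative-splicing confound control), computed from
`three_prime_utr` GTF features strand-aware.

## Driver regression

Per-gene ΔPTGR (default: restricted to DPRGs; a transcriptome-wide mode
exists) is regressed on all motif affinity columns jointly by OLS, with
predictors standardized, constant and exactly collinear columns dropped.
Regulators at raw p < 0.05 are selected (a BH column is emitted for
information only), ranked by |β| with lexicographic tie-breaks, and the
sign of β is the predicted direction of the stability effect. Binding
*presence* (boolean), not affinity, defines each regulator's predicted
target genes, and the mean ΔPTGR over targets summarizes the predicted
regulatory push. Affinity-as-predictor / presence-as-target-call separates
the dose-like binding vector from the categorical "bound gene" notion.

## Synthetic cohorts

The generator mirrors the structure the estimator assumes, at the count
level so normalization is genuinely exercised. Per gene g, sample i:

- latent intron log₂-expression x_gi ~ N(baseline_g, spread), with
  baseline_g ~ N(7, 1.5) (CPM-scale) and spread = 1.5 — the wide
  inter-individual variation typical of heterogeneous human cohort data;
- latent exon log₂-expression y_gi = a_g + β_{g,k}·x_gi + N(0, σ_res),
  a_g ~ N(1, 0.3) (exonic reads exceed intronic), σ_res = 0.3;
- β_{g,control} = 1; a configured fraction (default 10%) of genes gets
  β_{g,disease} = 1 + δ with δ = 0.5;
- counts ~ NB(mean = 2^latent · libsize/1e6, dispersion 0.005), library
  sizes uniform on 5–10 M — per-gene coverage matching a ~30 M-read,
  20 k-gene library scaled to this 2000-gene panel, with dispersion at the
  technical-replicate level since biological variation is already carried
  by the latent layer;
- optional batch effects shift both latents per gene (exercised by the
  residualization stage); everything is deterministic given the seed.

Default sizes (2000 genes, 100 + 100 samples) keep a full pipeline run
under ~2 s. What the generator does **not** emulate: splicing variation
and retained introns, 3′UTR isoform switching, length biases, GC effects,
correlated gene modules, or subject-level repeated measures. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated model, not robustness to every artifact of real
tissue data.

With these defaults the ΔPTGR test is close to nominal (fraction of null
raw p < 0.05 ≈ 0.05–0.065 across seeds). The small residual inflation is
structural: count noise acts as errors-in-variables on Δintron and makes
residual variance expression-dependent, which the H1 covariance does not
model; on the latent (noise-free) scale the test is exactly calibrated.
Deeper simulated libraries shrink the effect.

## Numerical conventions

- Internal coordinates are 0-based half-open; GTF/SAF are 1-based closed,
  converted only at I/O boundaries. Interval union/complement is verified
  per-base against brute-force masks.
- Cross-gene intron masking (removing intron bases overlapping another
  gene's same-strand exons) is available behind a flag; the default is pure
  per-gene subtraction, the plainly stated procedure.
- Genes split across chromosomes/strands in the input GTF are dropped with
  a warning.
- BH adjustment via statsmodels `multipletests`; Fisher p via
  scipy `fisher_exact`; t tails via scipy.
- All randomness flows through numpy `default_rng` seeds; greedy clustering
  and tie-breaks are deterministic given input order.

## Known limitations

- The fixed-effects residualization understates uncertainty relative to a
  mixed model when subjects contribute many samples.
- df = n_D + n_C overstates the information in the contrast relative to a
  Welch df; kept as the primary convention (see above), with the
  alternative exposed.
- The affinity score ignores RNA secondary structure and positional effects
  within the UTR.
- The ratio |β_D/β_C − 1| inflates under estimation noise (|·| of a noisy
  quantity); the validation studies quantify the effect (~0.025 upward at
  default conditions).
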