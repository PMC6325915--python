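# Methods

## Dosage statistics

For a sample with TPM values `t_g`, a gene annotation partitions genes into
X-linked and autosomal sets (the Y chromosome and mitochondrion, when
present, belong to neither).  The relative X expression is

    RXE = log2( mean_{g in X} t_g ) − log2( mean_{g in A} t_g )

the log of the gene-set mean, not the mean of logs.  Both readings of
"log2-transformed mean TPM" are defensible; the log-of-mean form is the
default because it makes RXE the log2 of the X:A ratio of mean expression
(the quantity the compensation thresholds are stated on), and it is invariant
under any rescaling of the sample's column, so it does not depend on whether
columns were renormalized.  `compute_rxe(..., method="mean_of_log")` exposes
the alternative; mean-of-log weights genes equally instead of
expression-proportionally and diverges when a subgroup contains a zero.

Per-autosome activity is measured the same way: for autosome *i*,
`RGE_i = log2(mean on i) − log2(mean on all other autosomes)`; the X never
enters either side.  An RXE within the spread of the autosomal RGE values
means the single active X behaves like an ordinary chromosome.

Compensation classes partition the real line: complete (`RXE ≥ 0`), partial
(`−1 < RXE < 0`), none (`RXE ≤ −1`).  Values below −1 are classified "none":
they are a fortiori uncompensated.

RXE is computed per sample; tissue- or treatment-level values are arithmetic
means of per-sample RXE (`tissue_mean_rxe`), never pooled-then-averaged.

## Gene subgroups

Four nested views control which genes enter the means:

| subgroup | rule |
|---|---|
| ALL | every annotated gene in the matrix |
| EXPRESSED | TPM ≥ threshold (default 1.0, inclusive) in the queried sample |
| XCI_SUBJECT | EXPRESSED minus pseudoautosomal (PAR) genes |
| DOSAGE_SENSITIVE | TPM ≥ threshold in **every** sample of the matrix |

EXPRESSED is evaluated per sample — a gene may be expressed in one sample and
not another — because the per-sample reading is the least-assuming one for a
per-sample statistic.  DOSAGE_SENSITIVE quantifies ubiquitously expressed,
largely housekeeping genes and is evaluated over all samples of the loaded
matrix.  PAR genes sit in the X/Y homologous region, escape X inactivation
and are expressed from both sex chromosomes; only PAR genes are removed from
XCI_SUBJECT because genome-wide catalogs of non-PAR escape genes are not
available for sheep.

## Boxplot summaries

`summarize_group` computes Tukey statistics: hinges at the 25th/75th
percentiles by linear interpolation between order statistics (the default of
the common plotting systems), IQR, whiskers at the most extreme data points
within 1.5 × IQR of the hinges, and labeled outliers beyond the whiskers.
Only the 1.5 × IQR whisker rule is implemented; confidence-interval whiskers
are a different convention and are not offered.

## Bootstrap differential expression

Between two groups (reference, alternative), with the sample column as the
resampling unit (the pipeline ingests gene-level TPM; reads are upstream of
its inputs):

1. observed group means per gene; reported `log2_fc` is the log2 ratio of
   observed means with the conventions 0/0 → 0, x/0 → +∞, 0/x → −∞;
2. B resamples (default 200) of each group's columns with replacement,
   stratified by group; bootstrap fold change `FC_b` with 0/0 → 1,
   x/0 → +∞, 0/x → 0;
3. empirical two-sided p-value `2 · min(P(FC_b ≥ 1), P(FC_b ≤ 1))`, clipped
   to `[1/B, 1]` so a finite resample never reports zero;
4. significant iff `|log2_fc| > 1` and `p ≤ 0.05` (both configurable).

Each group's resampling stream is seeded from the run seed via the sorted
group labels, which makes results deterministic and exactly symmetric under
relabeling (p unchanged, log2 FC negated).  No multiple-testing correction is
applied by default (raw p ≤ 0.05 is the convention the pipeline reports); a
Benjamini–Hochberg option exists.  No expression prefilter is applied by
default — sub-1-TPM genes are testable, and near-silent genes legitimately
produce infinite fold changes.

Calibration: this is a percentile-bootstrap interval test.  At the default
group sizes (7 vs 4) the plug-in bootstrap SD underestimates the sampling SD
by roughly √((n−1)/n) per group and the implicit critical value is normal
rather than t, so the realized type-I rate at α = 0.05 is about 0.08–0.09 on
null genes with the generator's default noise (silent genes report p = 1 and
dilute genome-wide fractions).  Users needing strict α control at small n
should raise the fold-change threshold or lower α; the defaults reproduce the
conventional procedure, not a calibrated one.

## Group statistics

- Sex comparison of RXE: two-sided two-sample t-test, pooled-variance
  (classic Student) by default with a Welch option; run per tissue by the
  pipeline.
- Diet comparison of RXE: two-sided Wilcoxon rank-sum; exact null enumeration
  when both groups have ≤ 8 observations and no ties, otherwise the normal
  approximation with tie and continuity correction.  All-tied inputs return
  p = 1 (no evidence of shift in either direction).
- Expressed X-linked gene counts (TPM ≥ 1 per sample, inclusive): one-way
  ANOVA across treatments, per tissue, with the convention F = 0, p = 1 when
  every group is constant at a common value.

## Synthetic data generator

The generator emulates the statistical shape of a sheep fetal RNA-seq study
and provides the ground truth for parameter-recovery tests.

Model: per-gene baseline rate `b_g ~ 2^Normal(μ, σ)`; an autosomal gene
contributes `2·b_g` (diploid), a non-PAR X-linked gene `u·b_g` (single active
copy upregulated by the factor *u*), a PAR gene `2·b_g` (XCI escape, both sex
chromosomes active); multiplicative per-gene/per-sample noise
`2^Normal(0, σ_s)`; planted diet effects multiply designated genes by
`2^effect` in every sample of the designated treatment; a silent fraction of
genes (never planted ones) is zeroed; columns are renormalized to TPM.
Renormalization rescales a whole column and therefore never changes RXE or
RGE.  Ignoring the 20 PAR genes, the expected RXE is analytic:

    RXE_true = log2(u) − 1.

Defaults and rationale:

| parameter | default | why |
|---|---|---|
| genes_per_chromosome | 19,291 autosomal genes over 26 autosomes (by chromosome size) + 1,228 X | sheep annotation scale |
| n_par_genes | 20 | annotated ovine PAR genes |
| baseline_log2_mean / sd | 3.0 / 2.0 | typical TPM scale; expression spanning ~4 orders of magnitude |
| sample_noise_log2_sd | 0.25 | replicate-level biological + technical CV ≈ 18% |
| upregulation_factor_u | 1.8 | partial compensation, true RXE ≈ −0.152 |
| silent_fraction | 0.4 | roughly the fraction of annotated genes unexpressed per tissue |
| design | brain/kidney/lung × Con n=7 (4F/3M), Over n=4 (2F/2M), Res n=4 (2F/2M) | the emulated study design |
| planted_degs | 8 X-linked genes, \|log2 effect\| 3.3–5.5, in Over/Res | strong diet-responsive effects |

Dispersion defaults are chosen for test power and plausibility, not fitted to
any tissue.  The generator is deterministic under a fixed seed: gene lengths,
baselines, the silent mask and the noise matrix come from four independent
child streams of the seed, so `truth_table(config)` reproduces the baselines
and silent mask without regenerating the matrix.

What the generator does *not* emulate: count-level sampling noise (the
statistics operate on TPM means, so a negative-binomial count layer would add
nothing testable here), batch/library effects, correlated co-expression,
gene-length-dependent expression, or lower-than-average PAR baselines.  On
that last point: with two copies against u = 1.8 per active X copy, generated
PAR genes are slightly *above* the X average, so removing them can move RXE
in either direction within sampling noise — real PAR genes tend to be
lowly expressed, an effect of baselines rather than copy number.  Passing
recovery tests therefore demonstrates correctness of the estimators under a
multiplicative log-normal model, not robustness to every artifact of real
RNA-seq.

## Parameter recovery and problem sizes

The recovery checks run at the generator's default scale (20,519 genes × 45
samples, 50 repeats): mean RXE bias on control samples stays within ±0.05 of
`log2(u) − 1`, and bootstrap DE at default thresholds recovers planted
|log2 effect| ≥ 3 genes with sensitivity ≥ 0.9 and false-discovery
proportion ≤ 0.1.  Recovery of *u* is evaluated on control samples because
the planted diet effects are deliberate departures from the dosage model in
the treated groups (their net effect inflates treated X means by a few
hundredths in log2).  Smaller universes (≲ 2,000 genes) are avoided for DE
recovery: with a heavy-tailed baseline distribution a single strongly boosted
gene can occasionally dominate a column's TPM total and compositionally
depress every other gene — a desk-scale artifact, not an estimator property.

## Numerical choices and degenerate inputs

- Chromosome labels: strip a leading `chr` (case-insensitive), uppercase the
  sex chromosome; normalization is idempotent.
- GTF genes: 1-based inclusive coordinates; an explicit `length` attribute
  wins over `end − start + 1`.  The TSV `length_bp` column is authoritative
  when both exist.
- TPM: `rate_g = count_g / (length_g/1000)`, column-normalized to 1e6;
  all-zero samples are rejected (TPM undefined).
- Empty subgroups, zero gene-set means, non-finite RXE, all-zero groups and
  sub-minimal group sizes raise `ValidationError` naming the offending set.
- p-values are never reported as 0 (bootstrap clipping at 1/B).
- Pipeline reruns with identical config + seed are byte-identical; the run
  manifest records the seed, package version and SHA-256 of every output.

## Known limitations

- The bootstrap DE p-value is anti-conservative at very small group sizes
  (see calibration note above); it reproduces the resampling convention
  rather than a studentized or calibrated interval.
- XCI_SUBJECT removes only PAR genes; non-PAR escape genes are unknown for
  sheep and remain in the subgroup.
- The generator's log-normal model has no count layer; statistics that
  depend on count-level variance (e.g. dispersion shrinkage) are out of
  scope by design.
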