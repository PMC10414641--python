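# monomeg

Identification of genes — in the motivating application, long non-coding
RNAs — whose expression changes **strictly monotonically** across ordered
breast-cancer pathologic stages (normal → I → II → III), with a
variational-autoencoder latent-space check that the selected sets really
carry a monotone per-stage signal.

The package is aimed at computational biologists working with bulk
expression cohorts annotated by an ordered clinical factor: it provides the
screening statistics, the monotone filter, the VAE validation and an
external-cohort staging check as a tested library with a CLI, plus a seeded
synthetic-data generator so the whole procedure can be exercised and
benchmarked without any data download.

## Method

Given an FPKM-scale genes × samples matrix with group labels
(normal, I, II, III), the pipeline:

1. **Preprocesses**: `log2(x + 1)` (optional) then per-gene z-scoring.
2. **Screens** each stage against normal with empirical-Bayes **moderated
   t-tests**. Per gene *g*, with pooled variance *s²_g* on *d_g* degrees of
   freedom and a scaled inverse-chi-square variance prior (*d₀*, *s₀²*)
   fitted by digamma/trigamma log-moment matching,

       s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)
       t_g  = LFC_g / (s̃_g · √(1/n₁ + 1/n₀)),   t_g ~ t(d₀ + d_g) under H₀,

   with Benjamini–Hochberg FDR control per comparison (cutoff 0.01).
3. **Filters for monotonicity**: a gene is *monotone decreasing* when it is
   a significant under-expressed DEG in **all three** comparisons and
   LFC_I > LFC_II > LFC_III strictly; *monotone increasing* is the mirror
   image. The strict ordering discards U-shaped and waved nuisance patterns.
4. **Validates in latent space**: a VAE (dense encoder input→32→8→
   {mean, log-variance} over a 1-D Gaussian latent, mirrored linear-output
   decoder, Adam, 20 epochs) is trained on each selected gene set; the
   per-sample posterior means are compared across stages with adjacent-stage
   Welch t-tests and a joint one-way ANOVA of
   H₀: μ_normal = μ_I = μ_II = μ_III.
5. **Stages an external cohort**: an overall VAE trained on the genes shared
   between cohorts (each standardized within its own dataset) embeds all
   samples; external samples are assigned the stage of the nearest latent
   centroid and the misclassification rate is reported.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort mirroring the TCGA BRCA stage composition (105/140/480/180 samples;
5,000 genes with 100 planted monotone-decreasing, 50 increasing, 100
U-shaped, 100 waved, 4,650 null; one noise-SD shift per stage step):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_screen_differential_expression.py
python analysis/03_filter_monotone_genes.py
python analysis/04_validate_latent_monotonicity.py
python analysis/05_stage_external_cohort.py
```

Step 02 prints the per-comparison screens, e.g.

```
I_vs_normal: prior d0=257.8, s0^2=0.973; 204 down- and 154 up-regulated DEGs at FDR < 0.01
```

— after standardization the variance prior is tight (large d₀, s₀² ≈ 1), and
each screen calls a few hundred DEGs out of 5,000 genes. Step 03 reports

```
monotone decreasing: 100 genes; increasing: 50 genes
  decreasing: sensitivity 1.000 (100/100 planted), 0 false selections
  U-shaped/waved patterns selected: 0
```

— the intersection + strict-ordering filter recovers every planted monotone
gene and rejects every nuisance pattern. Step 04 shows the latent check:

```
Per-stage latent means:
   normal: n= 105  mean=+2.8707  var=0.0518
        I: n= 140  mean=+1.2267  var=0.0262
       II: n= 480  mean=-0.3118  var=0.0439
      III: n= 180  mean=-2.1938  var=0.0391
Joint one-way ANOVA: F=16073.165  p=0
Verdict: decreasing
```

— the latent means of the decreasing set fall strictly with stage and every
adjacent-stage Welch test is significant. Step 05 stages an independent
synthetic cohort over a 50-gene shared panel with 0/120 misclassifications
at 3-SD stage separation.

The same steps are available as CLI subcommands
(`monomeg simulate | diffexpr | filter-monotone | vae-train | validate |
external-validate | run-all`); `run-all` writes every intermediate artifact
plus a `summary.json` that is byte-identical across re-runs with the same
configuration and seed.

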