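# Methods

This note documents the generative models, estimators and numerical
choices behind `cavspipe`, and what the synthetic validation does and
does not establish about real data.

## Synthetic data model

**Genotypes.** Haplotypes come from a blockwise AR(1) latent-Gaussian
threshold model: within a block of `block_size` variants, adjacent latent
Gaussians correlate at `rho`; thresholding at Φ⁻¹(MAF) yields 0/1 alleles
and dosages in {0, 1, 2}. Variants within a block share their allele
frequency, as tightly linked variants do — with independent per-variant
frequencies the binary thresholding caps attainable r² far below the
latent `rho`. Blocks are mutually independent, so r² between blocks is
~0 and decays geometrically within a block; `rho = 0.95` (the default)
gives adjacent-dosage r² around 0.55–0.7. The model has no recombination
map, phasing, sex chromosomes or population structure (declared
non-goals); because there is no structure, "ancestry principal
components" are simulated as independent noise covariates rather than
from the SVD of the locus-sized panel, whose components would be linear
combinations of the tested variants and would distort single-variant
association estimates.

**Phenotypes.** Disease liability is

  L = Σ_v β_v g_v + θ · x̃_G + 0.05·age_z + 0.10·sex + ε,  ε ~ Logistic(0, 1)

with case status by thresholding at the quantile matching the configured
prevalence. The logistic (rather than normal) latent makes every β an
exact log odds ratio per allele dose, which logistic regression recovers
without scale conversion; with a probit latent all recovered effects
would be inflated ≈1.7× relative to their nominal values. The default
scenario uses prevalence 0.5, i.e. a balanced case-control design like a
surgical case-control cohort; log odds ratios are invariant to such
outcome-dependent sampling.

**Expression and the mediator scale.** A gene's biological latent is
x = Σ_j s_j√(pve_j)·z(g_j) + √(1−Σpve)·ε with z(·) the standardized
dosage. Counts are negative-binomial (gamma–Poisson) around
lib_s · softmax-normalized rates exp(base_g + σ_log·x), with σ_log = 0.5
(one latent SD ≈ 1.65-fold rate change, typical for variable bulk RNA-seq
genes) and dispersion 0.1 (typical bulk RNA-seq). The *measured*
expression that the eQTL/TWAS/MR stages analyze therefore mixes biology
and count noise in the proportion κ = σ_log²/(σ_log² + dispersion) ≈ 0.71.
The mediation effect θ is defined on this measured scale: the liability
mediator is x̃ = √κ·x + √(1−κ)·ε₂, so the exposure the MR stage estimates
and the outcome effect it divides by live on the same scale and the MR
estimand equals θ. Two residual approximations remain: the NB count
noise is treated as Gaussian on the log scale when forming κ, and count
compositionality (fixed library size) slightly damps each gene's own
measured slope by its library share — at the default ten genes this
inflates the MR estimand by roughly +5%. Both shrink as the gene count
grows; calibration under the global null is unaffected.

**Tissue panel.** Median log₂ TPM across 44 tissues (valve + 43 others),
uniform for undesignated genes; a designated gene's valve median is
constructed so its expression specificity score equals the configured
share exactly. The panel is generated independently of the expression
study (it stands in for an external atlas); the high-expression flag, by
contrast, is computed from the study's own observed valve medians on
log₂(TPM+1) (the offset convention; raw log₂ TPM with negative-median
clamping is available through `ess_table` on any table the caller
builds).

## Reference scenario (the defaults)

Sixty variants in six LD blocks; five blocks cluster near a ten-gene
region, the sixth sits 1.3 Mb away and carries a variant with a direct
log-OR 0.25 effect (a locus with no transcriptomic support, serving as a
negative control). The causal gene has total cis-PVE 0.3 split over a
primary variant (0.12, intronic in the gene) and three secondaries (0.06
each) in distinct blocks, mediation effect θ = 0.3 per measured-expression
SD; two GWAS cohorts of 10,000 (balanced case-control) and a 400-sample
expression study. The causal gene's valve ESS is designated 0.2. At this
scale the primary variant's expected GWAS z is ≈6.2 and its eQTL z ≈6,
so the locus is found in most but not all replicates — the causal gene
still reaches ≥ 4 evidence features without it (gene-level test, valve
specificity, TWAS, coloc). Hidden-expression covariates default to zero
components: with ten genes the top expression PCs load on the causal
gene's own variation and absorb its signal (~2× attenuation of
instrument strength), unlike at transcriptome scale where such factors
capture shared technical structure. The PCA covariate operation itself
is validated separately by batch-factor recovery.

## Estimators and numerical choices

* **Meta-analysis.** Fixed-effect IVW; heterogeneity p from χ²(k−1)
  (p = 1 at k = 1); I² floored at 0. Harmonization keys on (chrom, pos);
  swapped allele pairs flip β and EAF; strand-ambiguous A/T–G/C variants
  with MAF > 0.4 are dropped; irreconcilable pairs are dropped.
* **Clumping.** Greedy by ascending p with ties broken by position then
  id; r² is squared Pearson correlation of dosages. Variants absent from
  the LD matrix are treated as unlinked.
* **Fine-mapping.** Single-causal-variant posterior ∝ ABF with a flat
  prior over locus variants; prior SD 0.2 on the log-OR scale; log ABFs
  are max-shifted before exponentiation. If all posteriors are equal the
  set is flagged uninformative.
* **TMM.** Reference sample = column whose 75th count-fraction
  percentile is closest to the mean; M-values trimmed 30% per tail,
  A-values 5%; inverse-delta-method precision weights; factors rescaled
  to zero log-mean. Cross-checked against edgeR's `calcNormFactors` in
  the test suite (agreement within 2%).
* **Inverse-normal transform.** Φ⁻¹((rank − 0.5)/n), ties by average
  rank; constant genes are excluded.
* **eQTL.** Expression and dosage are residualized on the covariates and
  regressed residual-on-residual; by Frisch–Waugh this equals the full
  multiple-regression coefficient (verified numerically), with
  t-tests on n − #covariates − 2 degrees of freedom. The permutation
  pass permutes the expression vector (covariates fixed), records the
  best nominal p per permutation, fits Beta(a, b) by maximum likelihood
  to the minima, and uses its CDF as the smoothed empirical p (direct
  (r+1)/(B+1) as fallback on degenerate fits). eGenes by
  Benjamini–Hochberg on empirical p at 5%; the per-gene nominal
  threshold inverts the fitted beta CDF at the midpoint between the
  largest passing and smallest failing empirical p. B = 1000 by default.
* **Enrichment.** 2×2 Pearson chi-squared *with* continuity correction
  (required to reproduce the published statistic on its printed counts);
  Wilcoxon rank-sum via the normal approximation with tie correction.
* **TWAS.** Elastic net with mixing 0.5, 5 outer × 5 inner folds,
  penalty path of 25 values chosen only inside inner folds; per-fold
  out-of-fold Pearson r averaged for qualification, pooled out-of-fold
  predictions for the correlation t-test (one-sided for positive r; a
  two-sided switch exists). σ_l and σ_g come from the training panel,
  which doubles as the LD reference.
* **Colocalization.** Priors p1 = p2 = 1e-4, p12 = 1e-5; prior effect SD
  0.2 for the binary trait, 0.15 for expression; all hypothesis sums in
  log space with an exact log-difference for H3; the GWAS track is
  restricted to ±1 Mb of the gene.
* **MR.** F per instrument = (bx/bx_se)². IVW is the weighted regression
  through the origin with fixed-effect SE; because the scaled-down
  instruments carry non-negligible exposure-side measurement error, the
  result also reports a second-order (exposure-adjusted) estimate and SE
  with weights 1/(by_se² + θ̂²bx_se²) — the appropriate confidence
  interval when the no-measurement-error assumption fails, and the one
  whose coverage the validation measures. Weighted-median SE by 1000
  seeded parametric bootstrap draws. Egger intercept t-test on k − 2 df.
  Gene screen: drop Q p < 0.01, BH-adjust IVW and WM p separately at 5%,
  candidate requires both plus intercept p > 0.05; the unadjusted
  feature rule (IVW p < 0.05, WM p < 0.05, Q p > 0.01) feeds the
  evidence ledger.
* **Gene-level test.** Mean squared z over the gene window (±10 kb);
  null = eigenvalue-weighted sum of χ²₁ from the LD correlation matrix
  (eigenvalues clipped at 1e-8), p by Satterthwaite moment matching.
  This is a calibration-faithful LD-aware test, not a numerical clone of
  any external gene-based tool. BH at 5% across tested genes.
* **Positional mapping.** Genes within 10 kb of any genome-wide
  significant SNP; intergenic leads add both flanking genes; "intronic"
  uses exon blocks when provided and whole-body containment otherwise.

## Validation scale and what it shows

The simulation studies run at desk scale, chosen so each completes in
minutes on one CPU: 500-variant null GWAS panels (n = 2000; 20,000
pooled Wald p-values at n = 4000 for the inflation factor, whose
median-based estimate needs many variants), 500 null genes for empirical
eQTL calibration, 500 summary-level MR replicates, 200 replicates for
IVW coverage and 10–20 full pipeline replicates for end-to-end recovery.
Under the global null, the GWAS, eQTL (nominal and empirical) and MR
tests reject at the nominal 5% rate within binomial bounds and λ ≈ 1.

Passing these tests shows the estimators are implemented correctly and
calibrated under the generator's assumptions. It does not establish
performance on real data, where LD is irregular, counts are far more
heterogeneous, expression confounding is structured, instruments can be
pleiotropic, and instrument selection in the same sample induces
winner's-curse attenuation — visible here too: the end-to-end
selected-instrument IVW estimate is ≈0.23–0.28 against a true 0.3, which
is why the coverage experiment designates the truth's causal variants as
instruments and re-estimates their effects from fresh data. Real studies
mitigate this with much stronger instruments; at cis-PVE 0.3 split over
four variants in 400 samples the selection threshold sits in the middle
of the instrument-strength distribution.

## Known limitations

* The LD model produces piecewise-stationary blocks, not empirical LD.
* No imputation uncertainty is simulated (INFO defaults to 1; the QC
  rules are exercised on constructed records).
* The tissue panel is generated independently of the expression study.
* MAGMA-style gene tests, PEER factors and CAVIAR fine-mapping are
  represented by calibration-faithful analogues (mean-χ² with an LD-aware
  null; PCA components; single-causal ABF posteriors), not by ports of
  those tools.
* The ten-feature ledger treats missing upstream evidence as feature
  absence, matching how incomplete annotation behaves in practice.
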