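# Methods

## The Gxθ model

For one SNP with dosage vector `x` and global ancestry `θ` the alternative
model is

    y = μ + β x + δ θ + β_Gxθ (θ ∘ x) + u + e,
    u ~ N(0, σg² K [+ σθ² K_A]),  e ~ N(0, σe² I),

and the null model drops only the interaction column.  The test statistic is
the likelihood-ratio 2(ℓ_alt − ℓ_null) referred to χ²(1).  Dosages and θ
both live on [0, 1] — dosage is the fraction of alleles from the designated
reference founder (so inbred panels occupy {0, 1}, intercross panels
{0, ½, 1}), and θ is the fraction of ancestry-informative SNPs from that
founder.  Putting both regressors on the same scale keeps β and β_Gxθ
commensurable.  The likelihood-ratio statistic is invariant to affine
rescaling of y, to centering of θ, and to flipping the allele coding of x
(the column span of the design is unchanged), all of which the test suite
checks.

**Estimation.**  Maximum likelihood (not REML), following the EMMA/pyLMM
lineage.  With a single GRM, K is eigendecomposed once and the likelihood
profiled over the heritability ratio h = σg²/(σg²+σe²) by a 21-point grid
plus bounded scalar refinement; the residual scale is profiled analytically.
With two GRMs the components cannot be jointly diagonalized, so the
(σg², σθ²) proportions are optimized by a coarse simplex grid followed by
Nelder–Mead in softmax coordinates, with a Cholesky factorization per
likelihood evaluation.

**Per-SNP fits.**  Variance components are estimated once per trait under
the no-SNP covariate model (intercept, covariates, θ) and the implied
covariance is held fixed for all per-SNP null/alternative GLS fits.  With
the covariance fixed and the scale profiled, the LRT reduces to
n·log(RSS_null/RSS_alt) on whitened data, which coincides exactly with the
classic nested-OLS likelihood ratio when K = I (a tested oracle
equivalence).  Re-optimizing the variance components under both models for
every SNP is available via `exact=True`; the approximation is the standard
one for this model family and the default for scans.

**Main-effect p-value** (`p_g`) is a Wald z-test of β in the alternative
model using the ML residual variance.  With ~100 samples and six fixed
effects the ML variance is biased low by a factor (n−k)/n, so the realized
size of this test at α = 0.05 is ≈ 0.057 rather than 0.050.  We keep the ML
convention deliberately; the acceptance suite's "stays ≈ α" bands
([0.03, 0.075]) account for it.

**Numerical choices.**  p-values are floored at 1e-300; LRT values in
[−1e-8, 0) are set to 0 and anything more negative raises a warning;
eigenvalue weights are floored at 1e-12; the two-GRM covariance gets a
1e-10 jitter before Cholesky.  Degenerate inputs fail loudly: a constant
SNP, a constant θ, or a rank-deficient design (θ∘x collinear with existing
columns) raise errors naming the offending SNP; genome scans skip such SNPs
with a warning.

**Multiple testing.**  Fixed genome-wide thresholds from configuration
(defaults 4.2e-6 for HMDP-like inbred panels and 8.06e-6 for AIL-like
cohorts — both values circulate for these panels and are configurable), or
per-scan Benjamini–Hochberg at 5% FDR for segregant-panel use.

## Ancestry calling

Informative sites are SNPs at which both parents are homozygous and differ;
heterozygous or missing parental calls are skipped.  θ is the *unweighted
mean* over informative sites of the reference-founder dosage (missing cells
excluded per individual) — SNP-proportion semantics, not genetic-map
weighting.  The per-site frequency θᵢ averages over individuals instead;
in multi-subpanel designs a site only enters the average for individuals
whose cross actually segregates it (cross-level eligibility).  Swapping the
designated founder maps θ → 1−θ.

## Allelic-imbalance scan

Per site, W = (θ̄ − θᵢ)²/var(θ) referred to χ²(1), with θ̄ and var(θ)
computed across **all** sites (per-site frequency mean; a supplied
θ̄/var(θ) is accepted for sensitivity analyses).  Using the global variance
assumes most sites are null and is conservative when large genomic regions
are genuinely distorted — a strong selective sweep inflates the variance
and suppresses every W, which is visible in the planted-selection
simulations.  Significance is Benjamini–Hochberg at 5% FDR; significant
sites on a chromosome are chained single-linkage with a 2 Mb gap (an LD
block scale for mouse panels; the chaining gap is an inference, not a
published rule) and chains of ≥ 5 sites become distortion regions reported
with mean founder ancestry (%) and mean p.

The neutral background is Bernoulli: with n independent lines the exact
two-sided tail P(X ≥ ⌈f·n⌉) + P(X ≤ ⌊(1−f)·n⌋) of Binomial(n, ½), summed in
log space, gives the chance of an imbalance at majority fraction f.  The
two-sided convention is the default (one-sided available); expected
genome-wide counts multiply by the SNP count under independence, which
overstates the effective number of independent trials and is therefore an
upper-bound-style expectation.

## Simulation framework

Four generators combine one fixed effect with a multivariate-normal
polygenic background: `y = β x + MVN(0, σg²K + σe²I)` (and the 2-GRM
variant adding σθ²K_A), and the interaction versions with β_Gxθ·(θ∘x) as
the fixed part.  Defaults σg² = 0.4, σθ² = 0.2 when present, σe² the
remainder so the background sums to 1.  Phenotypes are standardized to unit
variance before testing (the LRT is invariant to this; it only fixes the
reported effect scale).  SNPs enter simulations from the frequency window
(0.25, 0.75).  Effect grids default to 20 points on [0, 1] × 200 replicates
for desk runs; the full-scale experiment (200 points 0.005 apart × 1,000
replicates) is available via configuration / `--paper-scale`.

**Composite SNPs.**  Higher-order epistasis is emulated by a composite
dosage vector carrying the minor (non-reference-founder) allele only where
the test SNP *and* every partner SNP carry theirs; monomorphic composites
are redrawn within a budget.  The composite's effect size is calibrated so
the 1-df GLS association statistic has non-centrality 20 under
V = σg²K + σe²I: β = √(target / x̃ᵀPx̃) with P the covariate-residualizing
GLS projector.  "Statistic set to 20" is interpreted as the non-centrality
(realized statistics then fluctuate around ≈ 21); fixing the realized
statistic per replicate would make β a function of the noise draw.

A single pseudo-random stream per run (numpy `default_rng` from the given
seed) covers SNP selection, MVN draws and redraws, so every table is
exactly reproducible.

## Synthetic panels

The simulators produce the idealized versions of the three population
designs with full truth (founder mosaics, θ, block maps):

- **RI**: per strain, an F1×F1 cross yields a sibling pair which is
  sib-mated until all four chromatids agree at every marker; a 60-generation
  cap triggers a coin-flip fix of residual heterozygous blocks (logged;
  < 5% of blocks in practice, asserted in tests).
- **AIL**: a constant-size population random-mates for n generations
  (default 50) after the F1; dosages stay on {0, ½, 1}.  Its θ variance is
  far below a matched RI panel's, reproducing the power gap between the two
  designs.
- **haploid-cross**: one meiosis per progeny from the F1 diploid.

Meiosis follows the Haldane (no-interference) map — adjacent markers d
Morgans apart recombine with probability (1 − e^(−2d))/2, a Markov
switching process along the chromosome.  Viability selection at chosen loci
is rejection sampling: an offspring carrying ≥ 1 disfavored allele dies
with probability s (gamete-level drive would be an alternative; viability
was chosen as the simpler mechanism consistent with either interpretation
of panel-derivation selection).  Marker coordinates use 2 Mb/cM, mouse-like.

The default fixture — 100 strains, 5 chromosomes × 80 cM × 400 markers —
gives genome-wide θ SD ≈ 0.12 (a bit above the 6–8% of real mouse RI
panels, since 5 chromosomes carry fewer independent segments than 19) and
simulates in under a second.

## What the synthetic panels do and do not show

The panels are single biparental crosses: every polymorphic SNP is
ancestry-informative, genotyping is error-free and complete, markers are
evenly spaced, and there is no subpanel structure.  Consequences worth
knowing:

- **K_A degeneracy.**  The ancestry-informative GRM equals the genome-wide
  GRM, so the two variance components are identified only through their
  sum.  The two-GRM code path is still exercised end-to-end (and agrees
  with the one-GRM analysis when σθ² = 0, as it must), but synthetic runs
  cannot demonstrate a *benefit* of the second GRM; on real multi-subpanel
  data the two matrices differ.
- **Interaction-test power scale.**  With θ SD ≈ 0.1 and both regressors on
  [0, 1], the interaction non-centrality at β_Gxθ = 1 is below 1 for 100
  strains, so interaction "power curves" on these panels rise only a few
  points above α across the default grid.  The acceptance checks therefore
  compare pooled rejection rates (top vs bottom of the grid) rather than
  asserting a saturating sigmoid; detecting strong planted interactions
  requires effects larger than 1 on this scale (as in the README example).
- **Composite-SNP carrier exhaustion.**  With 100 lines and a single cross,
  a composite over many partners usually has 0–2 carriers; polymorphic
  composites are kept by redrawing.  The decay of main-SNP detection with
  partner count reproduces cleanly; the *rise* of interaction detection
  seen on real panels — where subpanel structure keeps composite carriers
  numerous and strongly θ-stratified — appears here only as persistent
  interaction-p inflation (λ > 1) and a non-monotone detection profile.
  The epistasis acceptance check tests decay of the main effect plus
  statistical consistency of the interaction profile with monotonicity,
  not a strict rise.
- **Sweep-scale distortion.**  Viability selection at one locus drags a
  multi-megabase neighborhood with it (hitchhiking), so "the planted locus
  is top-ranked" is evaluated at sweep scale (top W within 10 cM of the
  target), and the sweep's own contribution to the global variance makes
  the Wald scan conservative on selected panels — the documented behavior
  of the global-variance choice.

## Problem sizes

Default test and acceptance runs use: 100-strain panels (200 for
heritability recovery), 2,000 markers, 1,000 null tests for calibration,
20 × 200 effect grids, 10 × 500 epistasis replicates, and 50 panels per arm
of the imbalance pipeline check — sizes chosen so the whole suite completes
in a few minutes on one CPU while keeping Monte-Carlo error well inside the
asserted bands.

## Known limitations

Missing genotypes are mean-imputed for association (pyLMM convention) and
excluded per-cell for ancestry and imbalance frequencies; no imputation
model is provided.  No local-ancestry inference, no >2-founder crosses, no
X-linked inheritance, no mutation or genotyping-error models, no SNP–SNP
pairwise epistasis testing.  The p_g Wald test inherits mild small-sample
anticonservatism from the ML variance (quantified above).
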