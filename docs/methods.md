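# Methods

## The analysis model

The outcome of every association model is a mammogram risk score (MRS):
a mammographic-density measure transformed toward normality, residualized
on age and inverse BMI, and standardized to mean 0, SD 1. Five measures
are carried through the pipeline — dense area (Cumulus), percent dense
area, bright area (Altocumulus), brightest area (Cirrocumulus) and the
white-not-bright area (Cumulus-white = dense − bright) — with the nesting
invariant brightest ≤ bright ≤ dense ≤ total breast area.

**Transformation.** The Box–Cox power is selected per measure by
maximizing the profile log-likelihood over the interpretable grid
{−1, −1/2, 0 (log), 1/3, 1/2, 1}; a continuous-MLE mode exists behind
`lambda_grid=None`. Measures that can be exactly zero (brightest area,
white area) receive an offset of half their smallest positive value
before transformation; both the offset and the selected power are stored
in the fit metadata. Snapping to the grid rather than reporting the
continuous MLE reflects how such transformations are conventionally
reported (cube root, square root, log). Residualization is OLS on an
intercept, age (years) and 1/BMI (m²/kg), fitted on the full analysis
sample; standardization uses the n−1 SD. Individuals missing age or BMI
are excluded from the estimation sample and counted in the metadata.

**Genotype QC and PRS.** Quality control applies sample filters first
(call rate ≥ 95%, heterozygosity within 4.89 SD of the sample mean), then
SNP filters on the survivors (call rate ≥ 95%, exact Hardy–Weinberg test
at p ≥ 1e-7, MAF ≥ 0.01); the report records per-filter removal counts in
application order, because the counts depend on it. Fractional (imputed)
dosages are accepted everywhere; the HWE test and heterozygosity
statistic operate on hard calls at thresholds 0.5/1.5, used for QC only.
PRS weight-file SNPs may legitimately sit below the GWAS MAF floor
(fine-mapped rare variants), so `qc_filter` accepts an exemption list —
the CLI exempts the weight SNPs from the MAF filter by default and logs
every exemption. PRS computation orients each panel SNP to the weight
file's effect allele (flipping dosage to 2−X where needed, attempting
strand complements, warning on A/T and C/G ambiguity) and mean-imputes
missing dosages to 2·MAF. Principal components are computed from the
column-standardized dosage matrix with mean-imputed missing values, all
SNPs included (the synthetic SNPs are unlinked, so LD pruning would be a
no-op).

**Mixed model.** Associations are estimated with a variance-components
linear mixed model: fixed effects are the predictor (PRS, SNP dosage, or
another MRS) plus the first 10 genotype principal components and an
intercept; random effects are a family intercept (variance σ²_f) shared
by all family members and an extra MZ-pair intercept (σ²_z), with
residual σ²_e. "Family plus zygosity" random effects admit more than one
reading; this nested-intercept form — MZ covariance σ²_f + σ²_z
exceeding the DZ/sister covariance σ²_f — is the package default and is
documented as an interpretation. The alternative reading (zygosity-
specific pair intercepts for both twin types, four components) is
available via `FamilyLMM(..., structure="zygosity_pairs")`.

REML estimation works family-blockwise. Families are grouped by
covariance pattern (size plus twin-pair labelling), so each distinct
block matrix is assembled and inverted once per likelihood evaluation;
cross-products accumulate by einsum over stacked families. The two (or
three) variance ratios γ_c = σ²_c/σ²_e are optimized on the log scale
with L-BFGS-B (bounds e±15, numerical gradients — with two or three
parameters and sub-millisecond evaluations an analytic gradient buys
nothing), and σ²_e is profiled out in closed form, which removes the
scale direction from the search and keeps the line search away from
numerically singular covariance corners. Ratios reaching the lower
boundary are snapped to exactly 0. Structurally unidentified components
are pinned to zero up front: σ²_z when the cohort has no MZ pairs, σ²_f
when no family has two members, and σ²_f in MZ-pairs-only cohorts, where
family and pair intercepts are exactly confounded (the identified sum is
then reported through σ²_z). Non-convergence triggers perturbed restarts;
persistent failure raises an error carrying the optimizer trajectory.

Fixed effects come from GLS at the REML optimum, with Wald inference on
a normal reference (no small-sample correction; the intended cohorts have
thousands of individuals). BIC is computed from the *maximum-likelihood*
log-likelihood evaluated at the REML components, with parameter count
p + n_vc and n = individuals; ML avoids REML's design-dependent constant,
and BIC differences across models with the same fixed-effect dimension
are unaffected by the parameter-count convention. BIC differences are
labelled by Kass–Raftery-style bins (<2 negligible, 2–6 positive, 6–10
strong, >10 very strong).

The implied within-pair correlations of a fitted model are
(σ²_f+σ²_z)/(σ²_f+σ²_z+σ²_e) for MZ pairs and σ²_f/(σ²_f+σ²_e) for
DZ/sister pairs — note the MZ-member variance carries the extra pair
component under the nested structure, so the model cannot represent data
in which MZ and DZ members have exactly equal variances; with
mixed-zygosity data the REML estimates compromise between matching
covariances and variances. Parameter-recovery checks therefore use
single-zygosity cohorts, where the structure is exact.

**OPERA scaling.** A reported coefficient is the raw mixed-model
coefficient multiplied by the SD (n−1) of the predictor's OLS residuals
on the model's other fixed effects: the change in MRS per
covariate-adjusted SD of the predictor. CIs scale identically; the Wald
p-value is scale-invariant.

**Correlations.** `family_corr` reports the plain Pearson correlation
with a percentile bootstrap CI that resamples whole families (implemented
via per-family sufficient statistics and multinomial count draws —
distributionally identical to naive cluster resampling; CI endpoints use
median-unbiased quantiles). Two p-values accompany it: a clustered Fisher
z with effective sample size equal to the number of families, and the
naive individual-level Fisher z. Correlation-table BICs come from the
matching one-predictor mixed model (intercept + standardized PRS, no
PCs), an interpretation flagged here because correlation BICs only make
sense inside a likelihood model.

**SNP screen.** Each SNP × MRS cell is a separate mixed-model fit with
the dosage as predictor and 10 PCs as covariates. Monomorphic SNPs are
skipped and excluded from the test count; Bonferroni adjustment uses the
number of SNPs actually tested (plain Bonferroni, min(1, p·n_tests);
Holm's step-down would be uniformly more powerful but plain Bonferroni is
the convention reported here). The excess-significance summary compares
the nominal-hit count against Binomial(n_tests, α) with a one-sided
tail; this assumes independent SNPs and is anti-conservative when the
list contains correlated fine-mapped variants — the result object carries
that caveat. Direction consistency is counted among nominal hits against
an expected direction per MRS (default: positive for all five, since each
measure is positively associated with breast-cancer risk).

## The synthetic cohort generator

The generator emulates the study design, not mammograms: pedigrees of MZ
pairs, DZ pairs and sister families (sizes 1–3; twins share age; sister
ages scatter ±5 y around a family mean; BMI is drawn independently per
woman, N(26.1, 5.2²) floored at 15; ages N(54, 8.4²) clipped to 30–80).

**Genotypes** are unlinked SNPs with MAFs uniform on a configurable
range. Two founder parents per family are drawn from Hardy–Weinberg
proportions and each child receives one sampled gamete per parent; MZ
co-twins copy one child genome. Sibling dosage correlation (expected 0.5)
is therefore mechanistic rather than imposed. A configurable fraction of
calls can be nulled to exercise QC. Synthetic PRS weight tables draw
log-odds weights N(0, 0.08²) with the three endpoint columns sharing a
common core, mimicking the correlated overall/ER−/ER+ weight sets.

**Density traits.** Each generated measure m (dense, bright, brightest
area and total breast area) has a latent trait on its transformed scale:

    z_m = √a²_m·A + √c²_m·C + √e²_m·E_m + β_age·(age−ā)
          + β_1/BMI·(1/BMI − mean) + β_PRS,m·std(PRS)

with A = A_family + A_segregation (variance split ½–½; the segregation
part is one draw per MZ pair and one per individual otherwise), giving
within-pair correlations a² (MZ) and a²/2 (DZ/sisters) exactly; C is one
draw per family. Half of the unique variance E_m is shared across
measures, inducing the strong cross-measure correlation of real
thresholded measures without touching the familial correlations.
Covariates enter centred so the location calibration is unaffected.
Measures are produced by inverting the normalizing transforms (cube for
the dense and bright areas, exp for the brightest area and total area)
with locations and scales placing medians near values typical of
screening-age women (dense ≈ 29 cm², bright ≈ 11 cm², brightest
≈ 1.6 cm², total ≈ 110 cm²); default additive fractions are 0.6 (dense,
bright, total) and 0.4 (brightest), shared environment 0, default PRS
effects 0.06/0.08/0.05/0 on the transformed scale — magnitudes chosen to
mirror the weak observed MRS–PRS correlations (≈0.05–0.08), with the
bright area carrying the largest effect. Non-positive back-transformed
areas are clipped at a floor (default 0.01 cm²) and logged; nesting is
enforced by clipping (brightest ≤ bright ≤ dense ≤ 0.99·total), and the
percent and white measures are then derived exactly, so the invariants
hold by construction. Percent and white consequently have emergent (not
prescribed) distributions.

**Mediation mode.** `simulate_density(..., mediation={"cumulus":
("altocumulus", λ)})` builds the dense-area latent as λ·z_bright +
√(1−λ²)·z_own with the own-part drawn from fresh familial components.
This mirrors the physical fact that the dense area *contains* the bright
area: a PRS effect on the bright area then appears in the dense area
marginally but vanishes (exactly, at the latent level) once the
bright-area score is adjusted for. Without this wiring, adjusting for the
bright-area MRS conditions on a collider and *induces* a spurious
association of the opposite sign — the targeted mutual-adjustment
simulations use the mediated mode for that reason.

**What the generator does not emulate:** mammographic images and reader
variability, linkage disequilibrium and imputation uncertainty,
population stratification or admixture, X-chromosome loci, assortative
mating, and BMI/age correlation between relatives beyond shared twin age.
Passing tests on this generator validate the statistical machinery and
the design's familial structure; they say nothing about image-derived
measurement error in real data.

## Numerical choices and problem sizes

- Simulation-based checks use: 5,000 pairs for familial-correlation and
  intraclass recovery (Monte-Carlo SE ≈ 0.01, asserted within 3 SEs);
  200 replicates at the full study composition (2,559 women) for CI
  coverage of an induced trait–PRS correlation of 0.08; 1,500 study-sized
  replicates for null p-value uniformity, rotating through the 15
  MRS × PRS cells so each cell is sampled 100 times and the pooled
  p-values stay independent; 100 study-sized replicates for Box–Cox power
  recovery; 25 replicates of ~1,250 women for the mediated
  mutual-adjustment check. These sizes make each check's Monte-Carlo
  error small relative to the quantity it bounds while keeping the whole
  suite fast on one core.
- Excess-significance calibration is evaluated by feeding uniform
  p-values through the summary machinery (1,000 replicates), isolating
  the binomial-tail implementation from mixed-model calibration, which
  is tested separately.
- The HWE exact test's null uniformity is checked at 10,000 individuals
  per site (2,000 sites); at small n the exact test is conservative by
  construction, which is expected behavior, not an error.
- Determinism: every stochastic routine takes a seed; stage seeds are
  derived from a master seed via `SeedSequence`. Same seed → byte-
  identical output tables. REML fits are deterministic (fixed start,
  restarts only on non-convergence).

## Known limitations

- The nested random-intercept structure cannot reproduce equal MZ/DZ
  member variances (see above); with ACE-generated data and a familial
  predictor this yields mild anti-conservatism of Wald p-values in small
  cohorts (~7–9% at α = 5% at a few hundred individuals), which
  dissipates at the study's size where calibration is indistinguishable
  from nominal. This mirrors the analysis model's own behavior on real
  family data.
- The percentile cluster bootstrap CI for correlations sits at the lower
  edge of nominal coverage (~94–95% at ~1,300 families), typical of
  first-order bootstrap intervals.
- The excess-significance binomial test ignores inter-SNP correlation.
- Strand-ambiguous (A/T, C/G) SNPs are flagged and optionally dropped;
  no frequency-based strand resolution is attempted.
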