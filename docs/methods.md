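# Methods

## Model and assumptions

`protmr` performs two-sample summary-statistics MR: per-SNP associations
with a protein (exposure) and with a disease (outcome) come from
non-overlapping GWASs. A valid instrument must associate with the protein,
affect the outcome only through it, and be independent of confounders. The
causal effect θ is on the outcome scale per SD of protein — a log odds
ratio for case-control outcomes — and is reported as `exp(θ)` with a
normal-theory 95% CI (`exp(θ ± 1.95996·se)`).

Estimators (all operating on allele-harmonized pairs):

- **Wald ratio** (1 instrument): `β_y/β_x`, first-order delta SE
  `se_y/|β_x|`.
- **IVW**: `θ̂ = Σ(β_x β_y/se_y²)/Σ(β_x²/se_y²)`; fixed-effects SE
  `[Σ β_x²/se_y²]^(-1/2)`; multiplicative random effects multiply it by
  `max(1, √(Q/(L−1)))`. Mode `auto` uses multiplicative iff Cochran's Q
  p < 0.05 (the package's reading of "heterogeneity detected").
- **Egger**: WLS of β_y on β_x with intercept, weights `1/se_y²`, exposure
  effects oriented positive; residual scale floored at 1; p-values from
  t(L−2). The intercept estimates directional pleiotropy.
- **Weighted median**: ratios ordered with normalized weights
  `(β_x/se_y)²`; the estimate interpolates the cumulative weight midpoints
  at 0.5; consistent while < 50% of weight is invalid.
- **Cochran's Q**, **leave-one-out**, **Steiger**
  (`r² = z²/(z²+n)` per side; Fisher-z comparison), **MR-PRESSO**
  (weighted leave-one-out RSS with a parametric simulated null;
  Bonferroni-corrected empirical outlier p-values; note the empirical
  floor — flagging at level α needs `n_sim > L/α`).
- **Power** for binary outcomes uses the mRnd formula: the attenuated
  observed-scale effect `b = K(OR/(1+K(OR−1)) − 1)` with case fraction K,
  `v = (K(1−K) − b²)/(N·r2)`, and a two-sided χ²(1) test with
  noncentrality `b²/v`. At OR = 1 power equals α.

### Weighted-median standard error

The SE comes from a seeded *model-centered* parametric bootstrap: exposure
betas are redrawn from `N(β̂_x, se_x)` and outcome betas around the fitted
values `N(θ̂_wm β̂_x, se_y)`. The common observation-centered variant
(centering on the raw β̂_y) spreads the bootstrap ratio centers around the
median and systematically overstates the SE when all instruments are valid
(we measured ~12% inflation, pushing CI coverage to ~0.975); centering on
the fit restores nominal coverage (0.949 measured at 1500 replicates).
Under strong violations of instrument validity this SE can be optimistic —
it should be read together with Q, the Egger intercept and MR-PRESSO.

## Instrument selection

Filters (in order, with per-rule removal counts): p < 5×10⁻⁸; F =
(β/se)² ≥ 10; outside the extended MHC (chr6:27,477,797–34,448,354,
GRCh37); associated with ≤ 5 proteins (counted over genome-wide-significant
associations, after the significance filter); not protein-coding-altering
(missense, stop gained/lost, start lost, frameshift, in-frame indel).
Cis means within ±1 Mb of the gene TSS (field-standard window; boundary
inclusive); sentinel selection greedily takes the lowest-p SNP per ±1 Mb
region (ties: larger F, then lexicographic id). LD clumping is greedy by
ascending p and prunes r² ≥ 0.1. Conditionally independent cis signals are
found by stepwise forward selection on the standardized scale (joint
effects `R⁻¹b`, joint variance `(R⁻¹)_jj/n`), skipping candidates with
r² > 0.9 against the selected set, adding while conditional p < 5×10⁻⁸ —
run per region. Group A is never clumped (it is a single sentinel); B/C/D
are clumped.

## Two-cohort decision rule and colocalization

BH-FDR is computed within each instrument group over that group's tested
proteins, in the discovery cohort only; replication uses nominal α = 0.05
plus direction concordance (the replication threshold is the package's
choice). When a protein is significant in several groups the reported
result follows the preference A > B > D > C. Colocalization runs only for
proteins that pass both cohorts: per-SNP log-ABFs in the sentinel's
region (window "2 Mb" read as ±1 Mb; the radius is configurable), priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵, effect prior SD 0.15 for quantitative and 0.20
for case-control traits (standard defaults, configurable). Hypothesis
evidence is accumulated by log-sum-exp; H3's `i ≠ j` sum is the
log-difference of `LSE(L1)+LSE(L2)` and `LSE(L1+L2)` (exact, stable); a
single-SNP region has PP.H3 ≡ 0 and is flagged. Decisions use the
PP > 0.8 rule; `distinct` (PP.H3 > 0.8) excludes the protein as
LD-confounded, `shared` (PP.H4 > 0.8) upgrades it. A conditional-analysis
check reports regions violating the single-causal-variant assumption per
trait; eQTL colocalization is informational (protein source tissue) and
never gates the verdict.

## Synthetic data: what it emulates, and what it does not

Marginal standardized effects in a region are `b̂ = R b + e`,
`e ~ MVN(0, R/n_eff)` with AR(1) (`R_ij = ρ^|i−j|`, default ρ = 0.9,
5 kb spacing) or constant-block LD; `n_eff = n` for quantitative traits and
`nK(1−K)` for case-control. Allelic betas/SEs follow from MAF ~ U(0.05,
0.5) via `se = [2·maf(1−maf)·n_eff]^(-1/2)` — the standard large-sample
log-OR approximation, matching the power formula's assumptions. Cohort
shapes mirror the study design: exposure n = 35,000 (pooled-proteome
scale), discovery 8021/24,510 cases, replication 346/208,094.

Independent-instrument draws (`simulate_mr_instruments`) use standardized
exposure effects with magnitudes U(0.05, 0.20) (spread is needed for the
Egger slope to be identified) and outcome effects `θβ_x` plus an optional
directional offset on an invalid fraction, applied in the Egger
orientation. The proteome generator gives every protein one cis signal
(magnitude U(0.10, 0.18) so that strong causal effects can replicate at
346 cases), ~15% a second independent cis signal or trans SNPs, one trans
SNP shared by six proteins (pleiotropy filter), some trans SNPs inside the
MHC, occasional coding variants; causal proteins use θ ∈ {−1.2, −1.0, 0.9,
−0.35, 0.3} (strong → replicated, weak → discovery-only); LD-confounded
proteins place the outcome's causal variant at r² ≈ 0.6 from the pQTL with
no protein effect. Ground truth is emitted alongside and never read by the
analysis.

Not emulated: real human LD maps and allele-frequency spectra,
individual-level genotypes, population structure, sample overlap,
platform (Olink/SomaScan) heterogeneity, genome-build issues, and
strand-ambiguity errors beyond the palindromic-drop rule. Passing tests
therefore demonstrate the statistical machinery's correctness and
calibration under the stated generative model, not robustness to those
real-data pathologies.

## Numerical and design choices

- z/p consistency on intake: tolerance 10% relative on the z scale with an
  absolute floor of 0.2 (rounded near-null p-values survive; column
  mix-ups do not); the check is skipped once p underflows doubles (z > 37).
- Palindromic SNPs are always dropped at harmonization (no frequency
  alignment); alleles reconcile only exactly or swapped — no strand
  complementing.
- Meta-analysis of pooled exposure GWASs is fixed-effect inverse-variance
  (the general-purpose scheme); single-study SNPs pass through flagged.
- Clumping boundary: r² exactly at the threshold is pruned.
- p-values are clipped at 10⁻³⁰⁰ to keep them in (0, 1].
- Determinism: every stochastic routine takes an explicit seed or
  `numpy.random.Generator`; reports are byte-identical across reruns.

## Problem sizes used in the validation suite

CI coverage: 500 replicates of 50 instruments. Null calibration: 1000
replicates of 10 instruments (MR-PRESSO at 500 simulations each).
Colocalization discrimination: 200 regions of 200 SNPs per scenario.
End-to-end: 20 seeds of a 100-protein study (5 causal, 2 LD-confounded,
60 SNPs per cis region). Law-of-large-numbers and oracle checks use
smaller instances with exact or enumeration references.

## Known limitations

- The conditional (joint) analysis assumes the supplied LD matrix matches
  the GWAS sample; LD mismatch is a known failure mode of summary-statistic
  conditional analysis and is not modeled.
- MR-PRESSO's distortion test is not implemented (the workflow uses the
  global test and outlier removal only).
- Single-causal-variant colocalization only; multi-signal regions are
  flagged, not decomposed.
- No sample-overlap correction, multivariable MR, or genome-build liftover.
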