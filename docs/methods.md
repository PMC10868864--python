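# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the limits of what the test suite
demonstrates.

## The twin model

The classical twin design attributes phenotypic resemblance between
co-twins to three latent sources: additive genetic effects **A**
(correlation 1 between MZ co-twins, 0.5 between DZ co-twins, reflecting
the expected share of segregating genes), shared environment **C**
(correlation 1 within any pair reared together), and unique environment
**E** (uncorrelated; absorbs measurement error). With variances σ²_a,
σ²_c, σ²_e and total σ², the implied pair correlations are
r_MZ = (σ²_a + σ²_c)/σ² and r_DZ = (σ²_a/2 + σ²_c)/σ². The model
assumes equal environments across zygosity, random mating, no
gene–environment interaction or correlation, and no dominance.
Dominance is deliberately excluded: with twins reared together, A, D
and C are not jointly identifiable, so the ladder is ACE/AE/CE/E only.

Binary traits are handled on the **liability scale**: a standard-normal
latent liability with threshold τ = Φ⁻¹(1 − prevalence) generates the
observed 0/1 trait, and co-twin liabilities are bivariate normal with
the zygosity-specific correlation above. Estimated proportions then
refer to liability variance, not observed-scale variance. An
observed-scale option (the Gaussian likelihood applied to 0/1 values)
is retained as a sensitivity analysis because observed-scale and
liability-scale decompositions of the same data can differ noticeably
(the phi correlation is attenuated relative to the tetrachoric).

## Estimators

**Falconer moments.** h² = 2(r_MZ − r_DZ), c² = 2r_DZ − r_MZ,
e² = 1 − h² − c². Negative raw components are truncated to zero;
additionally h² is capped at 1 and c² at 1 − h², so the reported triple
is a valid decomposition for any input correlations (without the cap,
e.g. r_MZ = 0.9, r_DZ = 0.1 would yield e² < 0). Raw pre-truncation
values are kept on the result for diagnostics. No standard errors are
attached — it is a moment method used for initialization and worked
examples.

**Continuous ML.** The exact pair log-likelihood (bivariate normal with
mean X_ij β and the structured covariance) is maximized by Nelder-Mead
over (β, √σ_a, √σ_c, √σ_e), the square-root parameterization keeping
variances nonnegative while letting them reach zero smoothly. Three
starts: a moment-based start plus two multiplicative jitters drawn with
a fixed seed. Covariates enter the mean; by default only an intercept
is fitted. Standard errors come from the numerically differentiated
observed information in (β, σ²-components) at the optimum, delta-methoded
to the proportions; at a zero-boundary optimum no SEs are reported
(Wald theory does not apply there).

**Binary ML.** With no covariates the sufficient statistics are the two
2×2 concordance tables; the log-likelihood is multinomial with cell
probabilities built from bivariate-normal orthant probabilities. SLSQP
maximizes over (τ, h², c²) with bounds [0, 1] and h² + c² ≤ 1, again
from three deterministic starts (tetrachoric-based moments plus
jitters). The orthant probability is evaluated via Owen's T function
(absolute accuracy ~1e-14), because the pair likelihood needs
tail-stable cell probabilities; |ρ| = 1 uses the degenerate closed
forms.

**Model comparison and reduction.** BIC = −2·logLik + k·ln(n_pairs),
with the number of *pairs* as the sample size — pairs are the
independent units. BIC values are therefore comparable within this
package but not to software that uses individuals (or another n) in the
penalty. The reported model is AE whenever the full-model ĉ² lies at
the zero boundary (< 1e-6), CE symmetrically for ĥ²; otherwise the
BIC minimizer. Wald CIs are untruncated (lower bounds may be negative)
and p-values are two-sided Wald; both are boundary-fragile, which is
why boundary components are reported without intervals.

## Descriptive statistics under clustering

Prevalences use the Taylor-linearized cluster-robust variance of a
ratio mean with the family as cluster, and Wald CIs clipped to
[0, 100]%. Group comparisons use the first-order Rao-Scott corrected
chi-square: the Pearson statistic on the individual-level table divided
by d̂ = [Σ_jk d_jk(1−p_jk) − Σ_j d_j(1−p_j·) − Σ_k d_k(1−p_·k)] /
((R−1)(C−1)), with all design effects estimated from the cluster-robust
variances. A null calibration suite (family-level grouping, within-pair
phi 0.5, 5,000 replicates) checks the empirical size stays near the
nominal 5%. The second-order (Satterthwaite) correction is not
implemented; with two-member clusters and the modest design effects of
twin data the first-order correction is adequate, and the calibration
test would expose it if it were not. No survey weights are supported —
clustering is the only design feature honored.

Cronbach's alpha is the standard (k/(k−1))(1 − Σ item variances /
total-score variance), undefined (reported missing) when the total
score has zero variance.

## Phenotype derivation

`sips` follows the gated questionnaire: heard-of-alcohol = yes and
sipped = yes gives 1; heard = yes, sipped = no gives 0; heard = no gives
0 (the gate implies never-use); blanks propagate to missing. `intent`
is defined among never-users only: 0 requires the floor answer on all
three susceptibility items ("Not at all curious", "Definitely not",
"Definitely not"); any single answer above the floor gives 1 even when
other items are blank, because one non-floor answer already falsifies
the "not susceptible" class; otherwise missing. Ever-users receive
not-applicable, and prevalence of intent is always computed over the
never-user denominator. Children who have never heard of alcohol are
treated as never-users eligible for the susceptibility items; the
opposite convention (skip the items entirely) would only move such
children from {0,1} to missing, and the derivation function is the
single place to change it.

## Exclusion rules

Families are excluded in a fixed order — missing zygosity for any
member, then within-family discordant zygosity labels, then families
without exactly two member rows — so each family is counted under
exactly one rule; the published counts do not state a precedence, and
the fixed order makes the ledger reproducible. Triplets and larger
sibships fall under the ≠2-members rule. "Inconsistent zygosity" is
interpreted as a within-family label conflict; a conflict between
inference methods is not representable in a single-label schema.

## Synthetic-data generator

The generator emulates the baseline same-sex twin-hub sample: ~60.4/39.6
DZ/MZ mix, sex × race/ethnicity strata with weights from the reported
margins, age ~ N(121.2, 6.7²) months, and two binary liability-threshold
traits whose default prevalences and sex-specific variance components
follow the reported marginal estimates (intent ≈ 23.5% overall with
a² ≈ 0.38/0.39 and c² = 0 by sex; sips ≈ 25.4% with c² = 0.55/0.63).
Stratum-specific prevalences combine the sex and race margins additively
on the probit scale — a modeling default, not a calibrated claim, since
joint sex × race prevalences are not published. Record defects (blanked
zygosity, a flipped member-2 label, a dropped member-2 row) are injected
after generation from a separately spawned RNG stream, so the pristine
draws never depend on defect settings. All per-pair draws are made
vectorized in a fixed order keyed by pair position under the master
seed, which makes output bit-reproducible and independent of row order.

What the generator does **not** emulate: item nonresponse in the
questionnaire items (missingness enters only via the structural gate),
opposite-sex pairs, genotypes, longitudinal waves, survey weights,
cross-trait correlation between intent and sips liabilities, and
gene–environment interplay. One deliberate realism consequence: because
strata differ in thresholds (e.g. sips prevalence 8% vs 29% across
race/ethnicity groups), pooling strata inflates within-pair concordance
— population stratification masquerades as shared environment. Tests on
pooled default cohorts therefore exercise the pipeline, while
parameter-recovery tests use single-stratum configurations where the
generative truth is the estimand. Passing tests show the estimators
recover the generative liability model; they cannot show that real
questionnaire data satisfy the equal-environment or no-GxE assumptions.

## Power analysis

Power is estimated by simulation: replicate cohorts under a specified
truth, an AE fit and an E fit per replicate, rejection when
2(llAE − llE) exceeds the χ²₁ critical value at α. Because the null
places σ²_a on the boundary, the χ²₁ reference is conservative (the
asymptotic null is the 50:50 χ²₀/χ²₁ mixture, available via
`reference="mixture"`). Replicates that fail to converge are retried
with extra starts and counted if they persist. The default protocol —
800 pairs (400 MZ/400 DZ), continuous trait, a² = 0.3, c² = 0, 500
replicates — is the package's own explicit protocol for the twin-hub
design-power claim; the original power computation for that design was
published without formulas, so no attempt is made to mimic its
internals.

## Numerical choices and degenerate inputs

- Bivariate-normal CDF via Owen's T (scipy.special.owens_t); zero
  thresholds nudged by 1e-15 (error < 4e-16) to avoid the sign rules'
  singular case; |ρ| ≥ 1 − 1e-12 routed to closed forms.
- Tetrachoric ML: thresholds fixed at margin quantiles, bounded 1-D
  search on ρ ∈ (−1, 1), xatol 1e-8; SE from the numerical observed
  information; empty concordance cells give a boundary estimate with a
  warning status instead of an exception.
- Correlations need ≥ 3 complete pairs and nonzero variance in both
  member vectors; otherwise a status string is reported, not a crash.
- Stratified fits require ≥ 30 complete pairs per zygosity; below that
  a stratum row carries descriptives only.
- ICC(1) is clamped to [−1, 1]; pair ordering follows member_index as
  read (single-entry), with double-entry available when order invariance
  matters. Single-entry is the default because published r-vs-ICC
  discrepancies in this literature are consistent with single-entry
  Pearson correlations.

## Problem sizes used by the test suite

Moment-convergence checks run at 50,000 pairs (correlations ±0.02,
prevalence and zygosity mix ±0.01); ML recovery at 5,000 pairs
(continuous, mean bias ≤ 0.02) and 10,000 pairs (binary at prevalence
0.25, mean bias ≤ 0.04) across 17 replicates per truth point; the
Rao-Scott size check at 5,000 replicates of 300 families; the power
claim at 500 replicates of 800 pairs. These sizes give Monte-Carlo
error comfortably below each asserted tolerance while keeping the whole
suite to a few minutes.

## Known limitations

- Wald p-values and CIs near the h²/c² boundary are approximate; a
  likelihood-ratio or profile-likelihood interval would be preferable
  there and is not implemented.
- The binary fitter's covariate path evaluates the likelihood pair by
  pair (no sufficient-statistic shortcut) and reports no SEs; it is
  meant for modest cohort sizes and sensitivity checks.
- BIC values are internally comparable only (pair-based n).
- No ordinal-trait likelihood, no bivariate (cross-trait) models, no
  sex-limitation or GxE models, no survey weighting.
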