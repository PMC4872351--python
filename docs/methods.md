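# Methods

This note records the statistical model behind `apoescore`, the
choices made where a design was genuinely open, and what the synthetic
cohorts do and do not emulate.

## Markers and ε genotypes

The default panel holds 14 biallelic markers around *APOE*: the three
promoter SNPs −491A/T (rs449647), −427T/C (rs769446), −219T/G
(rs405509), the intron-1 SNP +113G/C (rs440446), the two exon-4 coding
SNPs rs429358 and rs7412, and eight rare promoter-region variants from
the screened set (rs439382, rs1799981, rs1081103, rs72654465,
rs1799982, rs72654466, rs72654467, rs9282609). Each marker carries a
fixed minor allele, chosen once (pooled over both groups at load time
for panels inferred from data) and never re-polarized per group — a
group-specific "minor"-allele frequency above 50 % is therefore legal
and preserved.

ε genotypes follow the haplotype definitions ε2 = (rs429358-T,
rs7412-T), ε3 = (T, C), ε4 = (C, C). The double heterozygote (C/T at
both sites) is compatible with ε2/ε4 and ε1/ε3; it is called ε2/ε4
with an explicit ambiguity flag, the standard clinical convention
given that ε1 (C, T) is essentially absent from European populations.
Genotype combinations that force ε1 raise an error rather than being
silently miscalled.

## Quality control

Markers with pooled MAF below the threshold (default 5 %) are
excluded. The *pooled* frequency is the filter statistic: a marker
rare in one group but common overall stays in, which is the only rule
under which a marker with a 3.9 % case MAF and a 6.4 % control MAF
(pooled 5.15 %) survives a 5 % cut. Note that 5.15 % sits ~0.4
binomial SE above the threshold at 110+110 subjects, so at study scale
the realized filter outcome for such a marker is close to a coin flip;
the structural "6 of 14 retained" check is therefore run at a sample
size (100 000 per group) where the margin exceeds 4 SE. Genotype
handling is pairwise-complete; no imputation is implemented (the
emulated study reports a 100 % genotyping rate).

Hardy-Weinberg tests default to the conditional exact test (tail =
total probability of heterozygote counts no more probable than the
observed one, given the allele totals) when any χ² expected cell is
below 5, and to the 1-df goodness-of-fit χ² otherwise.

## Association tests

2×2 comparisons (allele counts; carrier vs non-carrier) report the
cross-product odds ratio with a Wald log-scale 95 % interval; a zero
cell triggers the Haldane-Anscombe +0.5 correction, flagged in the
output. The test is Yates-corrected χ² unless an expected cell is
below 5, in which case the exact conditional test is used. Genotypic
(2×3) comparisons use the Freeman-Halton extension of Fisher's exact
test, computed by full enumeration of first-row compositions under the
multivariate hypergeometric null; an enumeration budget (default
n ≤ 500) guards runaway inputs. All tests are two-sided. Bonferroni
adjustment uses the number of markers tested per family by default
(configurable). Serum comparisons use Mann-Whitney (exact for small
tie-free samples, else the tie-corrected normal approximation),
Kruskal-Wallis, and Spearman rank correlations on mid-ranks.

## Two-locus LD

Haplotype frequencies are maximum-likelihood estimates under the
multinomial phase-marginalized likelihood, fitted by EM over the
double-heterozygote ambiguity: initialization at linkage equilibrium,
convergence when the log-likelihood gain drops below 1e-10 (at most
1000 iterations), with the log-likelihood asserted non-decreasing at
every step. The equilibrium start resolves the symmetric tie of
double-het-only data deterministically and seed-free. From the fitted
frequencies: D = p_AB − p_A p_B; |D′| = |D| / D_max with D_max =
min(p_A q_B, q_A p_B) for D > 0 and min(p_A p_B, q_A q_B) otherwise;
r² = D² / (p_A q_A p_B q_B); LOD = (ℓ_MLE − ℓ_independence)/ln 10 with
the independence log-likelihood evaluated at the same (observed)
allele frequencies. A marker monomorphic in the data leaves the
haplotype frequencies determined (no phase ambiguity, gametes counted
directly) but the LD summaries undefined.

## The preventive score

Relative scores: 1 point per protective heterozygote and 2 per
protective homozygote at rs449647 (allele T) and rs405509 (allele G);
all other genotypes score 0. The per-subject score is the sum
(0–4 with the shipped table); a missing scored genotype voids the
subject's score rather than producing a biased partial sum. With the
shipped table the score equals the protective-allele dosage, so the
group mean equals twice the sum of the two protective-allele
frequencies — an exact identity used as a cohort-wide invariant test.
Downstream models treat the score as numeric 0–4 (a per-point odds
ratio); the table is user-overridable. The intron-1 rs440446-C allele,
although correlated with ε2, deliberately receives no score, matching
the published scoring.

## Multivariable models

Unconditional logistic regression is fitted by Newton/IRLS
(statsmodels) on complete cases, with Wald intervals from the inverse
observed information. Separation is detected (perfect-prediction
warnings, or any |coefficient| > 15) and flagged rather than silently
diverging; singular designs raise naming the collinear terms. The
best-subsets search fits every subset of the candidate predictors on
the complete cases of the full candidate set (so criteria are
comparable) and ranks by AIC by default; BIC and raw log-likelihood
are available. AIC is the default because ranking by raw likelihood
always selects the full model, so some penalty is necessarily implied
by "best subset"; the predictor-recovery simulations use BIC, whose
consistency property is what a recovery-rate claim needs (AIC admits
a ~16 % per-noise-term inclusion rate by construction). Education is
coded ordinal 1–4 (1 = primary, 4 = university), residence as a
large-city indicator, the score as numeric. ε-stratified refits
(ε2 carriers excluded / ε4 carriers excluded / ε3ε3 only / ε4 carriers
only) skip strata with an empty outcome class and attach small-stratum
warnings below n = 50.

## The synthetic cohort generator

The generator emulates the *summary statistics* of a 110+110
case-control study of the Polish population, not its raw data:

- **Haplotype pools.** Separate case and control pools over the six
  analysed loci. One-locus marginals are the published group MAFs
  (cases: 15.0/5.9/39.8/33.5/28.9/3.9 %; controls:
  21.8/6.8/55.9/38.6/9.1/6.4 %), matched exactly by iterative
  proportional fitting (IPF). Two pairwise |D′| targets are imposed —
  0.956 between rs440446 and rs429358 and 0.925 between rs440446 and
  rs405509, the two published values — with signs chosen from the
  published carrier-enrichment directions: rs440446-C is coupled to
  rs405509-G and repelled from rs429358-C. Other pairs default to the
  IPF maximum-entropy solution (≈ independence given the imposed
  margins); calibration residuals are returned, never hidden. A
  structural zero removes the ε1 (rs429358-C/rs7412-T) haplotype.
- **ε2/ε2 exclusion.** Independent haplotype pairing gives ε2/ε2 a
  probability of f(ε2)²; since the emulated study observed none, such
  pairs are rejected and redrawn. Rejection reweights haplotypes by a
  factor (1 − 1{ε2}·f(ε2))/(1 − f(ε2)²); the rs7412 calibration target
  is pre-compensated (pool frequency t/(1−t) for a desired realized
  frequency t), so realized allele frequencies match the published
  values in expectation; the residual perturbation at the other loci
  is below 0.05 % absolute.
- **Rare markers.** The eight rare variants are drawn independently
  with MAFs 0.5–3.0 % (the study prints no frequencies for its
  excluded markers; these values are package choices placed well below
  the 5 % threshold).
- **Serum ApoE** is Normal conditional on ε genotype (ε4/ε4 3.72±0.80,
  ε3/ε4 5.54±1.20, ε3/ε3 6.38±1.48, ε2/ε3 7.04±1.36, ε2/ε4 7.23±0.50
  mg/dl), truncated at zero by redraw. Because the published means are
  not stratified by case status, the simulated case-control serum
  difference arises only through genotype-frequency differences and is
  smaller than the study's observed 5.7 vs 6.5 mg/dl contrast — a
  documented limitation, not an assertion.
- **Covariates.** Sex (51 F/59 M cases, 85 F/25 M controls), age
  (Normal 71.2±9 cases, 66.8±7.5 controls, clamped to a wide 40–100
  plausibility range — the published 48–89/55–94 ranges are sample
  minima/maxima, and redrawing into them would bias the means),
  age at onset (interview age minus a 3.6±1.9-year lag truncated to
  1–10), education over four ordered levels from the published counts,
  and residence over {large city, town, rural} with package-chosen
  group-specific probabilities (the study prints the large-city
  contrast but no distribution). Covariates affect disease only
  through these group-specific marginals; no individual-level
  liability model is simulated.

Everything is deterministic given the seed (byte-identical TSV output,
independent of pool dictionary ordering).

What passing tests show, and don't: the generator reproduces the
published group frequencies, the two targeted |D′| values, the
ε-conditional serum structure and the demographic marginals, so
pipeline results agree with the published analysis in direction and
(where an identity applies) in value. It does not reproduce
unpublished quantities — per-haplotype frequencies beyond the imposed
margins, covariate-disease effects conditional on genotype, or the
exact multivariable odds ratios, which depend on the undeposited raw
data.

## Numerical choices and problem sizes

Exact tests enumerate in log-space (gammaln) with a 1e-9 relative
guard on the "no more probable" comparison. EM tolerance 1e-10, ≤1000
iterations; logistic Newton tolerance 1e-10, ≤100 iterations; IPF
tolerance 1e-12, ≤5000 cycles. Test problem sizes: law-of-large-number
checks at 50 000 subjects per arm (3-SE bands), replicate-based checks
at 1000×(110+110) for frequency fidelity, 100 replicates for
direction-of-effect agreement, 50 replicates at 2000/group for
predictor-set recovery, and the filter-survivor count at 100 000 per
group as explained above.

## Known limitations

- Phase is never ascertained from data: the −491AA/−219TT/ε4 "compound
  genotype" is an unphased predicate, not an in-cis haplotype claim.
- No trend tests, stratified (CMH) analysis, penalized regression or
  haplotype-block detection; multi-allelic markers are out of scope.
- The exact Freeman-Halton enumeration is limited to two-row tables.
- Within-group genotype distributions are Hardy-Weinberg by
  construction (random pairing), so departures from HWE cannot be
  emulated.
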