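# Methods

## The generative model

`genrisksim` builds individual-level data for a hypothetical cohort from
three kinds of published parameters: per-SNP risk-allele frequencies (RAF),
per-allele odds ratios (OR), and a population disease risk *d*.

**Genotypes.** Each SNP's genotype (risk-allele count 0/1/2) is sampled as
Binomial(2, RAF) — exactly the Hardy-Weinberg trinomial — independently per
individual and per locus. Loci are therefore in linkage equilibrium by
construction; LD structure is deliberately out of scope. Genotype counts
are *sampled*, not allocated as expected counts, so every realized cohort
carries ordinary binomial sampling noise around the input frequencies.

**Per-genotype risks.** For each SNP the three genotype risks are pinned
down by two requirements: adjacent genotypes differ in odds by exactly the
per-allele OR (log-additive model), and the HWE-weighted mean risk equals
*d*. Writing odds_i = odds₀·ORⁱ, the mean risk is strictly increasing in
odds₀, so the solution is unique; we find it by bisection on ln(odds₀) over
[−40, 40], iterating until the prevalence residual is ≤ 1e−12. The
likelihood ratios LR_i = P(genotype | case)/P(genotype | control) then
satisfy LR_i/LR₀ = ORⁱ and Σᵢ P(genotype i | control)·LR_i = 1 identically;
the test suite checks both to 1e−9. (scipy's `brentq` on the same equation
serves as an independent oracle in the tests, never as the implementation.)

**Individual risks and status.** Posterior odds multiply the prior odds
d/(1−d) by the product of each carried genotype's LR (naive-Bayes
independence of SNP effects), accumulated on the log scale for numerical
stability. Disease status is 1 iff the posterior risk exceeds an
independent Uniform(0,1) draw. Mean posterior risk and realized prevalence
therefore match *d* up to Monte-Carlo error (for G > 1 the naive-Bayes
construction makes mean risk only approximately *d*; at the panel sizes and
effect sizes shipped here the deviation is far below Monte-Carlo noise —
enumeration of the 18-SNP panel gives mean risk 0.199997 at d = 0.2).

## Scores and AUC

Unweighted score: Σ genotype counts. Weighted score: Σ count·ln(OR).
Bayes score: the posterior risk itself. Replications of published
weighted-score and logistic-regression models both use the Bayes score —
AUC depends only on ranks, and posterior odds are monotone in the weighted
sum of log LRs, so the choice is rank-equivalent; `refit_logistic_auc`
exists as a validation utility confirming that an in-sample logistic refit
reproduces the Bayes-score AUC within Monte-Carlo error under linkage
equilibrium.

AUC is the tie-aware Mann-Whitney statistic — P(case score > control score)
+ ½·P(tie) — computed from average ranks in O(n log n). Half-credit ties
are essential for integer allele-count scores and make the statistic equal
the trapezoidal area under the empirical ROC curve (asserted to 1e−12 in
tests). `analytic_auc` enumerates all 3^G genotype combinations (refusing
G > 12), weights each by probability·risk (cases) and probability·(1−risk)
(controls), and returns the exact tie-aware AUC; it is the convergence
target for the finite-cohort simulator.

## Replication protocol

Each study runs `n_iter` = 100 iterations of `n_sim` = 100,000 individuals
(the shipped defaults). Iteration k derives all randomness from
base_seed + k; identical study, seed and strategy reproduce bit-identical
results. Two OR strategies: `point` uses the published point estimates;
`ci_sampled` redraws each SNP's ln(OR) once per iteration (the draw defines
that iteration's generating model) from Normal(ln OR, sd) with
sd = (ln ci_high − ln ci_low)/(2·1.959964) — i.e. the OR is log-normal,
the standard sampling model for a ratio, which keeps draws positive. The
OR redraw uses an RNG stream separate from cohort sampling so both
strategies see the same genotype noise. Draws below 1 are flipped to the
other allele (RAF → 1−RAF, OR → 1/OR) rather than truncated, preserving
the sampling distribution while keeping the risk-allele convention. The
same flip rule normalizes panel rows on input; it is an involution, so
normalizing twice is the identity.

Comparisons against published AUC values round both sides to 2 decimals
first (published AUCs are printed at that precision), take per-row absolute
differences, and summarize per model type as median (midpoint for
even-sized groups), minimum and maximum, rounded half-away-from-zero.

## Packaged inputs

- `t2d_godarts.tsv`, `t2d_rotterdam.tsv`: the two 18-SNP type 2 diabetes
  panels with the ORs and 95% CIs reported by the GWASs each prediction
  study cited. They differ at rs5219, rs757210 and rs7903146, where the
  two studies cited different GWASs.
- `t2d_raf_synthetic.tsv`: a **synthetic stand-in** for the risk-allele
  frequencies. The exact frequencies used by the original replication are
  not distributed with the package; these are typical European-ancestry
  values for the same SNPs, chosen once from the literature. Panels ship
  without a RAF column so that real analyses must supply frequencies
  explicitly.
- `disease_risks.tsv`: population disease risks for the six diseases
  covered by the replicated studies (type 2 diabetes 0.20, prostate cancer
  0.15, type 1 diabetes 0.002, AMD 0.065, colorectal cancer 0.048, Crohn
  disease 0.002). Control allele frequencies are treated as population
  frequencies throughout; for diseases at these prevalences the
  approximation is the one the method itself makes.
- `table1_replication.tsv`: published vs simulation-estimated AUC for the
  29 replicated risk models, the input to the comparison-report arithmetic.

## What the simulations do and do not show

The generator emulates a cohort in HWE and linkage equilibrium with purely
multiplicative, mutually independent SNP effects and no covariates,
genotyping error or missingness. Passing tests therefore demonstrate the
internal consistency of the method and its convergence to the exact
enumeration oracle — not that real cohorts satisfy those assumptions. Two
properties of the construction deserve emphasis:

- **OR non-collapsibility.** The per-allele OR re-estimated from a 2×2
  allele-by-status table of a simulated cohort is slightly attenuated
  relative to the input genotype OR whenever the disease is common and
  effects are strong (marginalizing over other loci and collapsing
  genotypes to alleles both shrink an odds ratio). Enumeration shows the
  bias is ≤ 0.03 Woolf SE (at n = 100,000) for the shipped panels at
  d = 0.20, but reaches ~0.7 SE for an OR of 1.47 inside an 18-SNP panel
  and grows with effect size. Parameter-recovery tests target the
  enumerated exact allelic OR for strong effects and the input OR under
  study-condition effect sizes, with CI coverage assessed pooled across a
  panel's SNPs (per-SNP counts over 100 replicates fluctuate binomially,
  sd ≈ 2.2, around the nominal 95).
- **In-sample weight advantage.** Simulated weighted/Bayes scores use the
  same ORs that generated the data, a better model fit than any empirical
  study can achieve; estimated AUCs are accordingly expected to sit
  slightly above published values for weighted-score studies.

## Numerical and design choices

- Quintile odds-ratio tables default to 20/40/60/80-percentile cut-points
  of the simulated score distribution; external thresholds can be injected
  to mimic a published study's cuts. Heavily discrete scores (few distinct
  values) can make percentile cut-points coincide, leaving empty strata;
  the function raises rather than applying a silent continuity correction,
  and the same policy applies to zero cells in any 2×2 table
  (`ci_from_counts`).
- The scatter plot's R² is the squared Pearson correlation between allele
  count and posterior risk, recorded in the plot's metadata file; with
  heterogeneous weights or logistic curvature it is below 1 by design.
- For plot reproduction the cohort should be regenerated at the published
  study's sample size and disease risk (`--published-n`), since both drive
  the quintile CIs' width and the absolute risks in the scatter.
- Fixed problem sizes in the test suite: protocol checks run the full
  100 × 100,000 design for the 18-SNP panels; convergence and recovery
  checks use 100 seeds at n = 100,000 with panels of 3–5 SNPs; null-model
  checks use 5 iterations at n = 100,000. These sizes put Monte-Carlo
  noise well inside the asserted tolerances (e.g. AUC SE ≈ 0.002 per
  null-model cohort).
- AUC values are reported to users rounded to 2 decimals; full precision
  is retained internally and in per-iteration outputs.

## Known limitations

No LD, no dominance/recessive or interaction models, no covariates, no
rare-variant burden modelling, no confidence intervals on AUC, and no
calibration or reclassification metrics — the package measures
discrimination only. The CI-resampling strategy assumes normality on the
log-OR scale; the point-vs-resampled comparison in the tests shows the
choice is immaterial for the shipped panels (mean AUCs differ by < 0.01),
mirroring the insensitivity the replication protocol itself exhibits.
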