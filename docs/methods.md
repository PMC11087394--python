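# Methods

## Statistical model

The package performs two-sample Mendelian randomization: instrument–exposure
associations (β̂ₓⱼ, σₓⱼ) and instrument–outcome associations (β̂ᵧⱼ, σᵧⱼ) come
from GWAS of non-overlapping samples. Under the instrumental-variable
assumptions (relevance, exclusion restriction, independence from
confounders), each SNP gives a Wald-ratio estimate β̂ᵧⱼ/β̂ₓⱼ of the causal
effect of the exposure on the outcome, and the IVW estimator pools them with
weights wⱼ = β̂ₓⱼ²/σᵧⱼ²:

    β̂ = Σ wⱼ (β̂ᵧⱼ/β̂ₓⱼ) / Σ wⱼ = Σ (β̂ₓⱼ β̂ᵧⱼ/σᵧⱼ²) / Σ (β̂ₓⱼ²/σᵧⱼ²)

This is exactly weighted least squares of β̂ᵧ on β̂ₓ through the origin — the
test suite exploits the identity by checking the closed-form implementation
against a statsmodels weighted regression as an independent oracle.

Standard-error conventions:

* **Fixed effect**: se = √(1/Σwⱼ). Exactly calibrated when all instruments
  estimate the same ratio (no heterogeneity, no pleiotropy); under that null
  the z statistic is exactly standard normal conditional on the exposure
  effects, because the outcome statistics come from an independent sample.
* **Multiplicative random effects** (default for screens): se inflated by
  √max(1, Q/(J−1)), where Q = Σ wⱼ(β̂ᵧⱼ/β̂ₓⱼ − β̂)² is Cochran's statistic on
  J−1 df. The floor at 1 means the SE never deflates below fixed-effect and
  the two modes coincide exactly for homogeneous instruments. The floor also
  makes the default mildly conservative under an exact null, which is why
  calibration experiments (type-I error) use the fixed-effect mode — the
  matched estimator for a homogeneous no-pleiotropy null.

Throughout, 95% intervals use the fixed multiplier 1.959964 so that
reconstruction of printed confidence intervals is bit-stable, and p-values
are floored at 1e-300 to stay inside (0, 1]. Wald-ratio and IVW standard
errors use the first-order (no-measurement-error) approximation that ignores
uncertainty in β̂ₓ; it is accurate for genome-wide-significant instruments,
which is what the selection stage guarantees.

Sensitivity battery per exposure–outcome pair: Cochran's Q with a χ²(J−1)
p-value (J ≥ 2); the Egger intercept as a probe for directional pleiotropy
(J ≥ 3), estimated by weighted regression of β̂ᵧ on β̂ₓ with intercept after
orienting every pair so β̂ₓ ≥ 0, with the residual scale floored at 1 (same
convention as the IVW default) and t(J−2) p-values; and leave-one-out IVW
refits (J ≥ 2). Egger regression is delegated to statsmodels WLS; the test
suite checks it against explicit normal equations.

## Instrument selection and harmonization

Candidates are records with p < 5×10⁻⁸, *strictly*; ties between p-values
are broken by lexicographic variant id so clumping is deterministic under
any row permutation. Greedy clumping repeatedly takes the best remaining
candidate as an index and discards same-chromosome candidates within
10,000 kb (index-to-candidate distance) whose r² ≥ 0.001. Cross-chromosome
pairs are always independent; variants absent from the LD matrix are treated
as uncorrelated with everything and logged, since a reference panel is not
part of the package's inputs; identical variant ids are treated as r² = 1,
so exact duplicates collapse onto the lowest-p copy.

Harmonization inner-joins instruments and outcome on variant id (rsID
convention, not position), then resolves allele orientation: identical pairs
kept, swapped pairs sign-flip the outcome beta, strand-complement pairs are
complemented first. Palindromic variants (A/T, C/G) are excluded
unconditionally rather than resolved by allele frequency — the conservative
reading, since strand orientation is unresolvable from summary data alone.
Duplicated ids in either source are removed entirely (every copy), and
irreconcilable allele sets are dropped as incompatible. Every drop is
recorded with a reason in an audit table. Inputs are assumed already
expressed on a common reference build; no genome FASTA lookup is performed.

## Mediation

Two-step MR: the exposure→mediator and exposure→outcome legs use the
exposure's instruments; the mediator→outcome leg uses the mediator's own
instruments, as univariable MR. (A multivariable formulation that adjusts
the mediator→outcome leg for the exposure is a deliberate non-goal; the
univariable reading matches the summary-statistic workflow the package
implements, and the two differ only when the exposure directly affects the
outcome through paths correlated with the mediator's instruments.)

The delta-method variance of the product β̂_EM·β̂_MO drops the covariance
term on the two-sample independence assumption and the second-order term
σ_EM²σ_MO²; both are negligible for strong instruments, and the Monte-Carlo
agreement checks are therefore run in the strong-signal regime (|β| ≥ ~0.5,
σ ≤ ~0.08) where the first-order expansion is valid to well under 2%.
Proportions mediated outside [0, 1] (inconsistent mediation) are reported
verbatim with a sign-discordance flag, never clamped; a zero total effect
makes the proportion undefined and is flagged rather than imputed.

## Multiple testing and screen reporting

Screens and PheWAS scans label rather than filter: raw p-values are reported
alongside Bonferroni (divisor = number of pairs actually tested, not
supplied) and Benjamini–Hochberg columns, and PheWAS rows carry a
significance tier (bonferroni / bh / nominal / none). Nominal significance
uses α = 0.05. Phenotypes with no harmonizable instruments appear as
explicit missing rows so the row count always equals the phenotype count.

## Synthetic-data generator

The generator emulates the summary statistics such a study consumes, with a
known structural model so every stage is testable end to end:

* per-SNP true exposure effects γⱼ for the instruments; mediator truth
  β_EM·γⱼ plus the mediator's own instruments δₖ; outcome truth
  β_direct·γⱼ + β_MO·(mediator truth). Total exposure→outcome effect
  β_direct + β_EM·β_MO; implied proportion mediated
  β_EM·β_MO/(β_direct + β_EM·β_MO).
* observed betas add independent normal noise per table (the two-sample
  assumption) with the standard per-allele SE approximation
  1/√(2·n·eaf·(1−eaf)); p-values are two-sided normal, floored at 1e-300.
* LD is block-diagonal: each instrument heads a block whose other members
  are tagging nulls with marginal truth √r²·γⱼ, so the clumping stage has
  genuine work; blocks are spread over 22 autosomes with 20 Mb between
  block starts and 5 kb between members.
* contamination: a configurable fraction of variants get palindromic allele
  pairs, and a fraction of ids are duplicated verbatim, exercising the
  harmonization drop rules.

Default parameters are the package's reference study conditions: 50
exposure instruments and 50 mediator instruments with per-allele magnitudes
0.3–0.8 (random sign, eaf ∈ (0.1, 0.9)) at an exposure GWAS of n = 3,300 —
proteomic-GWAS scale, where such effects sit comfortably past genome-wide
significance — 450 background nulls, biobank-scale mediator and outcome
GWAS (n = 450,000 and 350,000), LD blocks of 5 at r² = 0.3, 4% palindromic
and 1% duplicated variants, and structural effects β_EM = −0.02,
β_MO = 1.5, β_direct = −0.09, giving a total effect of −0.12 and a true
proportion mediated of 0.25 (a small protective protein effect routed partly
through a strong mediator–disease relationship, the shape of the mediation
findings this pipeline is designed to screen for). Binary traits are drawn
directly on the log-odds scale; no individual-level genotypes exist anywhere
in the package.

Reproducibility: each output stream gets its own child of
`numpy.random.SeedSequence(seed)` (grid, exposure noise, mediator noise,
outcome noise, phenotype battery, in that order), so a fixed seed yields
byte-identical files and each table is independently reproducible.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: sample overlap between GWAS (real biobank
exposure and outcome panels overlap, inducing correlation the delta method
and IVW ignore), population stratification and relatedness, horizontal
pleiotropy (instrument truth routes only through the modeled paths),
winner's-curse bias in instrument discovery, noise correlation between LD
partners (tagging affects the means but draws are independent), and
realistic minor-allele-frequency spectra.

## Replicate-scale experiment sizes

Calibration experiments use a reduced grid — 50 instruments per trait, 50
background nulls, trivial LD, no contamination — chosen so that each
replicate isolates the estimator property under test rather than the
selection machinery, and so that the full suites (1,000 null screens for
type-I error, 1,000 triplets for CI coverage, 200 for proportion recovery,
500 random tables for the IVW oracle, 200 instances for the clumping
oracle, 10⁶ Monte-Carlo draws for the delta-method check) run in a few
minutes on one core. The measured values for a given seed are written by
`scripts/acceptance.py`; nothing in the documentation quotes numbers the
code does not recompute.

## Known limitations

* No weighted-median or mode estimators, MR-PRESSO, Steiger filtering, or
  proxy-SNP lookup; the sensitivity battery is Q, Egger and leave-one-out.
* No multivariable MR; mediators are analyzed one at a time.
* SNPs only: indels and multi-allelic records are rejected at validation.
* LD must be supplied (dense matrix or long-format pairs); the package
  never computes it from genotypes.
* The delta-method CI undercovers when legs are weakly estimated (the
  dropped σ²σ² term and non-normality of the product become material).
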