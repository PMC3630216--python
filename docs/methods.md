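# Methods

## Design

`gistsig` implements a case-only association analysis: all subjects are GIST
cases, and each of seven somatic mutation-signature categories defines a
dichotomy contrasting subjects whose tumor carries that signature against
all other cases. There is no unaffected control group, so every estimate is
an association between a germline variant and *which* signature a tumor
acquires, not with GIST risk itself.

## Signature categories

A validated somatic record (gene, exon, mutation type, codon span) maps
deterministically to exactly one category:

| category | definition |
|---|---|
| `kit_ex11_557_558_del` | KIT exon 11 deletion whose codon span covers both 557 and 558 |
| `kit_ex11_other_del`   | any other KIT exon 11 deletion |
| `kit_ex11_ins`         | KIT exon 11 insertion |
| `kit_ex11_point`       | KIT exon 11 point mutation |
| `kit_other_exon`       | KIT exon 9, 13, 14 or 17, any type (individually too rare to analyse) |
| `pdgfra`               | PDGFRA exon 12 or 18, any type |
| `wild_type`            | no KIT/PDGFRA mutation detected |

Two conventions were genuinely open and are fixed here: a deletion spanning
557–558 *plus further codons* counts as the canonical 557-8 deletion
(span-covers rule), and exon 17 is included in the pooled KIT category even
though it is grammatically rare to absent in practice. A subject with no
somatic record at all is *missing mutation data* — distinct from an explicit
wild-type record — and is excluded by the sample QC, never classified.

## QC cascade

Samples: (1) drop subjects with no mutation record; (2) drop subjects whose
fraction of missing genotype calls strictly exceeds 10% (a subject at
exactly 10.0% is retained). Variants, after orientation, in fixed order with
each variant attributed to the first rule it violates: (1) mono-allelic;
(2) MAF strictly below 5% (exactly 5% is retained); (3) poor array
clustering — an intensity-level property that cannot be recomputed from
dosages, consumed as a boolean metadata flag; (4) no minor-allele homozygote
on some side of some outcome dichotomy. Rule 4's published wording is
ambiguous about which outcome levels were meant; the default
operationalization checks both sides of all seven dichotomies
(`any-side`), with `case-side` and `off` available, and the report records
which convention ran. MAF denominators exclude missing calls throughout.
Orientation designates the less frequent allele as minor and flips dosages
(d → 2−d) where needed; an exact 0.5 tie keeps the alphabetically-first
allele, implemented so the operation is idempotent (the currently-coded
allele is tracked, and the recorded MAF is recomputed from the flipped calls
so repeated application is bit-stable).

GSTM1/GSTT1 copy-deletion assays are pseudo-binary variants: dosage 1 is the
null genotype, 0 is one-or-two copies. They are never orientation-flipped
(their reported frequency is the null-genotype frequency and may exceed
0.5 — the frequency filter uses min(f, 1−f)), the per-allele OR reduces to a
binary contrast, and the IBS kernel applies the same 2−|a−b| formula to
their {0,1} dosages.

## Per-variant screen

Each variant × dichotomy is a maximum-likelihood logistic regression of the
outcome on additive minor-allele dosage adjusted for race (white vs. other),
sex and age in years, untransformed. Estimation uses Newton iterations with
relative tolerance 1e-8 and a 100-iteration cap. Complete-case per variant:
a missing call drops the subject for that variant only. Quasi-complete
separation is detected (dosage ranges of cases and referents disjoint,
statsmodels' perfect-separation signal, or |log-OR| > 15) and reported as
`status="separated"` with no estimate, rather than silently penalized —
changing the estimand implicitly would be worse than refusing to report.
Confidence intervals are Wald, matching standard "OR (95% CI)" reporting,
so CI-excludes-1 and p < 0.05 are exactly dual.

FDR control is Benjamini–Hochberg step-up (via statsmodels) within each
outcome family — seven families of ~208 tests, matching the per-outcome
presentation of the results — with a pooled single family as a config
option; failed fits are excluded from the family size. In site-restricted
sub-screens, adjustment covariates that become constant within the subset
are dropped (never the dosage term).

## Gene-level kernel test

The logistic kernel-machine model adds a subject-level random effect
h(Z_i) with variance τK to the covariate-only linear predictor; H₀: τ = 0
is tested with the score statistic Q = (y − μ̂)ᵀK(y − μ̂), where μ̂ comes
from the covariate-only fit. τ is tested, never estimated. The kernel is
identity-by-state, normalized by 2p so K_ii = 1; missing dosages are
mean-imputed per variant before kernel construction (keeping K positive
semidefinite and the subject count fixed — a deliberate divergence from the
screen's complete-case rule, since the kernel needs a common subject set).
Any positive rescaling of K leaves the p-value invariant because the scale
parameter absorbs it (property-tested).

Three tail evaluations:

* **moments** (default): κ = Var[Q]/2E[Q], ν = 2E[Q]²/Var[Q] with
  E[Q] = tr(P₀K), Var[Q] = 2tr(P₀KP₀K),
  P₀ = V − VX(XᵀVX)⁻¹XᵀV, V = diag(μ̂(1−μ̂)).
* **exact**: the tail of Σλ_j χ²₁ with λ_j the eigenvalues of
  P₀^{1/2}KP₀^{1/2}, computed by Imhof's characteristic-function inversion
  (`scipy.integrate.quad`).
* **permutation**: outcome labels re-permuted within deciles of μ̂
  (approximately respecting covariates), Q recomputed against the fixed μ̂,
  add-one estimator (1 + #{Q_perm ≥ Q_obs})/(1 + n_perm).

Known limitation: the analytic moments describe the *unconditional* null
(independent Bernoulli(μ̂) outcomes with the null model refit), whereas
label permutation conditions on the observed case count. At n = 20 this
conditioning alone shifts E[Q] by a factor ≈ n/(n−1) and shrinks Var[Q]
(binary residuals are platykurtic near balance), so analytic and permutation
p-values can differ by up to ~0.05 in the mid-range; against a parametric
bootstrap of the unconditional null the analytic p agrees to within ~0.016
on the same toys, and at n = 300 the permutation moments match tr(P₀K) and
2tr(P₀KP₀K) to 0.2% and ~3%. Small-sample moment corrections are out of
scope; at the study's n = 279 the moment-matched test holds its size (type-I
error ≈ 0.05 at α = 0.05 in the null battery).

## Synthetic cohort generator

The generator's defaults are the study conditions: 279 analysis subjects in
two race strata (82% white / 18% other); a 39-gene, 208-variant candidate
panel (including the two copy-deletion pseudo-variants, and the published
variant ids for the CYP1B1/ERCC2/GSTM1/GSTT1/RAD23B blocks); baseline
category probabilities equal to the observed signature counts
66/45/28/56/19/29/36 of 279; age truncated-normal mean 57, sd 13 on
[18, 85]; 51% male; tumor-site multinomial (stomach .66, small intestine
.31, rectum .01, other .02). White-stratum allele frequencies are drawn once
per spec from U[0.10, 0.45], mirroring the panel's ≥10% selection threshold;
other-stratum frequencies are a logit-scale N(0, 0.5) perturbation. Within a
gene, genotypes come from a latent Gaussian copula with AR(1) correlation ρ
between adjacent variants, thresholded at the per-stratum Hardy–Weinberg
cumulative probabilities; ρ defaults to 0.4, a moderate-LD choice made once
(the panel's true LD is unreported, so ρ is a free parameter, not a
calibration). Genotype calls go missing independently at rate 0.005.

Outcomes follow a multinomial logit: category-k log-odds = log(baseline
probability) + Σ dosage × per-allele log-OR over planted effects targeting
k, optionally restricted to a tumor-site stratum (tumor site is otherwise
independent of genotype, so the site-restricted sub-screen tests a true null
by default). Exactly one category per subject by construction, and the
emitted record carries gene/exon/type/codon span so the classifier is
genuinely exercised downstream. Under this generation scheme the per-allele
log-OR of the dichotomized target category given dosage is *exactly* the
planted coefficient, which is what makes round-trip recovery a sharp test.
All randomness descends from one integer seed through named seed-sequence
substreams.

What the simulator does **not** emulate: haplotype-resolved or coalescent
LD, population structure beyond two labeled strata, genotyping batch
effects, secondary/resistance mutations, tumors with two primary mutations,
covariate-dependent outcome risk. Passing tests therefore certify the
statistics under HWE-with-AR(1)-copula genotypes and a correctly specified
outcome model, not robustness to real-data pathologies.

The engineered pre-QC cohort (`make_study_fixture`) extends the default
panel to 333 subjects and 225 variants with exactly the published casualty
counts: 52 subjects without a mutation record, 2 with >10% missing calls,
3 mono-allelic variants, 6 below the 5% frequency floor, 7 flagged for poor
clustering, and 1 variant stripped of minor homozygotes in the smallest
outcome category. Because the default homozygote rule is strict and small
categories rarely contain minor homozygotes by chance, the fixture plants at
least one homozygote per category for every intended survivor — a property
of this engineered fixture, not of real panels. It also carries a 27-pair
duplicate panel with one planted discordant call per ~1000 jointly
non-missing calls (pooled concordance 99.9%).

## Problem sizes in the test and acceptance batteries

SKAT calibration uses 30 null cohorts of n = 300 with ten 5-variant genes
(2,100 gene × outcome tests); trend calibration 2,000 null variants at
n = 500; odds-ratio recovery 200 seeds at n = 5,000; the permutation
comparison 30 twenty-subject toys at 50,000 permutations; BH verification
1,000 random p-vectors against literal step-up enumeration. These sizes give
binomial Monte-Carlo error well inside the asserted bands while keeping the
default suite in the minutes range.

## Numerical choices

* Logistic fits: statsmodels Newton/IRLS; null-model GLM tolerance 1e-10.
* P₀ is symmetrized after assembly and verified to annihilate the design
  columns to 1e-6.
* Mixture eigenvalues below 1e-10 × λ_max are discarded before Imhof
  integration; p-values are floored at the smallest positive float.
* Degenerate inputs are statuses, not exceptions, wherever a scan should
  continue past a single bad variant or gene (`degenerate`, `separated`,
  `failed`, `null_model_failed`); specification errors (bad frequencies,
  unknown planted variants, malformed tables) raise immediately.
* The Freeman–Halton exact test for 2×3 genotype tables enumerates all
  tables with the observed margins in log-gamma space; it reduces exactly to
  Fisher's test on 2×2 tables, which is cross-checked against scipy.
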