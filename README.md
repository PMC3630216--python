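# gistsig

Case-only association of inherited candidate-gene variants with the somatic
mutation "signature" of gastrointestinal stromal tumors (GISTs).

Nearly all GISTs are driven by an acquired mutation in *KIT* or *PDGFRA*,
and the specific lesion (e.g. a *KIT* exon 11 codon 557–558 deletion vs. a
*PDGFRA* exon 18 point mutation) behaves like a mutational signature.
`gistsig` implements, as a tested and reusable pipeline, a case-only design
that asks whether germline variants in candidate genes (xenobiotic
metabolism, dioxin response, DNA repair) are associated with which signature
a patient's tumor carries:

1. **QC cascade** — sample exclusions (no somatic mutation record; >10%
   missing genotype calls), minor-allele orientation, and an ordered variant
   filter (mono-allelic, MAF < 5%, poor array clustering, no minor-allele
   homozygote at some outcome level), plus duplicate-sample concordance and
   race-stratified genotype-frequency contrasts (Pearson χ² with an exact
   test whenever a cell count is below 5).
2. **Signature classification** — each subject's somatic record is mapped to
   one of seven mutually exclusive categories (KIT ex11 557-8 deletion /
   other ex11 deletion / ex11 insertion / ex11 point / KIT ex9-13-14-17 /
   PDGFRA ex12-18 / wild type), yielding seven case-only dichotomies.
3. **Per-variant logistic screen** — for each variant × outcome, a
   maximum-likelihood logistic fit of the dichotomy on additive minor-allele
   dosage (0/1/2) adjusted for race, sex and age: per-allele OR, Wald 95%
   CI, 1-df trend p, Benjamini–Hochberg FDR within each outcome family, and
   a tumor-site-restricted sub-screen.
4. **Gene-level SKAT** — a from-scratch logistic kernel-machine
   variance-component score test with identity-by-state kernel
   K<sub>ij</sub> = Σ<sub>s</sub>(2 − |g<sub>is</sub> − g<sub>js</sub>|)/2p.
   The score statistic Q = (y − μ̂)ᵀK(y − μ̂) is referred to a scaled χ²
   with Satterthwaite moments κ = Var[Q]/2E[Q], ν = 2E[Q]²/Var[Q], where
   E[Q] = tr(P₀K) and Var[Q] = 2tr(P₀KP₀K) under the covariate-only null
   model; an exact χ²-mixture tail (Imhof inversion) and a seeded
   permutation oracle are available as alternatives.
5. **Synthetic cohort generator** — because the underlying trial's
   individual-level data are not deposited, a fully parameterized simulator
   (two race strata in Hardy–Weinberg equilibrium, within-gene AR(1)
   Gaussian-copula LD, truncated-normal age, multinomial-logit outcomes with
   optional planted per-allele effects, GSTM1/GSTT1 null-genotype
   pseudo-variants) provides every input, with ground truth recorded.

The statistical engines are scikit-learn-style estimators
(`VariantAssociationScan`, `SkatTest`, `SampleFilter`, `VariantFilter`)
with `fit`/`transform` and fitted `results_` attributes; module-level
functions (`scan`, `gene_scan`, `exclude_samples`, ...) are thin wrappers.

## Worked example

```python
import gistsig as g

# engineered study-scale cohort: 333 enrolled subjects, 225 panel variants
fx = g.make_study_fixture(seed=1)
cohort = fx.cohort

panel, sample_report = g.exclude_samples(cohort.panel, cohort.mutations)
panel = g.compute_maf_and_orient(panel)
outcomes = g.build_outcome_matrix(
    cohort.mutations[cohort.mutations.subject_id.isin(panel.subjects)])
panel, variant_report = g.apply_variant_filters(panel, outcomes)

print(sample_report.to_frame().to_string(index=False))
print(variant_report.to_frame().to_string(index=False))

assoc = g.scan(panel, outcomes, cohort.covariates, q=0.25)
skat = g.gene_scan(panel, outcomes, cohort.covariates)
print(len(assoc), "variant rows;", len(skat), "gene rows")
```

prints

```
  stage                        rule   n
samples       missing_mutation_data  52
samples genotype_missingness_gt_0.1   2
samples                    retained 279
   stage                            rule   n
variants                    mono_allelic   3
variants                     maf_lt_0.05   6
variants                 poor_clustering   7
variants no_outcome_homozygote[any-side]   1
variants                        retained 208
1456 variant rows; 273 gene rows
```

i.e. 52 subjects without a somatic mutation record and 2 with more than 10%
missing genotype calls leave 279 analysis subjects; the four-rule variant
cascade trims the 225-variant panel to 208; screening 208 variants against
7 outcome dichotomies yields 1456 logistic fits and 39 genes × 7 outcomes
yield 273 SKAT results.

The same analysis runs from the shell on materialized files:

```sh
gistsig simulate --spec cohort_spec.json --out fixture/
gistsig run-all --genotypes fixture/genotypes.tsv --annotations fixture/annotations.tsv \
    --covariates fixture/covariates.tsv --mutations fixture/mutations.tsv --out results/
```

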