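"""One-command orchestration of the full case-only analysis.

Stage order: sample exclusions -> minor-allele orientation -> variant QC
cascade -> signature classification -> per-variant logistic screen
(+ optional site-restricted screen) -> gene-level SKAT -> result files.
Every stage's counts land in the run manifest, and any stage error aborts
with the stage name attached.  Execution is single-process and
deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as gio
from .cohort import reconcile_subjects
from .outcomes import build_outcome_matrix
from .qc import (
    apply_variant_filters,
    compute_maf_and_orient,
    exclude_samples,
    stratified_frequency_test,
)
from .screen import scan, subset_scan
from .simulate import CohortSpec, SyntheticCohort, simulate_cohort
from .skat import gene_scan

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_fixture"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    genotypes: str
    covariates: str
    mutations: str
    outdir: str
    genotype_format: str = "dosage-tsv"
    annotations: str | None = None
    reference: str | None = None
    missingness_max: float = 0.10
    maf_min: float = 0.05
    homozygote_rule: str = "any-side"
    fdr_q: float = 0.25
    family: str = "per-outcome"
    kernel: str = "ibs"
    pvalue_mode: str = "moments"
    n_perm: int = 2000
    site_filter: str | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("genotypes", "covariates", "mutations"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError(f"stage config: {name} file not found: {p}")
        if self.annotations is not None and not Path(self.annotations).exists():
            raise PipelineError(f"stage config: annotations file not found: {self.annotations}")
        if self.reference is not None and not Path(self.reference).exists():
            raise PipelineError(f"stage config: reference file not found: {self.reference}")
        if not 0 < self.missingness_max <= 1:
            raise PipelineError("stage config: missingness_max must lie in (0, 1]")
        if not 0 < self.fdr_q < 1:
            raise PipelineError("stage config: fdr_q must lie in (0, 1)")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name}: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel = _stage("read_genotypes")(gio.read_genotypes)(
        config.genotypes, config.genotype_format, annotations=config.annotations
    )
    cov, mut, ref = _stage("read_tables")(gio.read_tables)(
        config.covariates, config.mutations, config.reference
    )
    recon = reconcile_subjects(panel, cov, mut)
    recon.to_csv(outdir / "subject_reconciliation.tsv", sep="\t", index=False)

    panel1, sample_report = _stage("exclude_samples")(exclude_samples)(
        panel, mut, missingness_threshold=config.missingness_max
    )
    panel1 = _stage("orient")(compute_maf_and_orient)(panel1)
    outcomes = _stage("classify_outcomes")(build_outcome_matrix)(
        mut[mut["subject_id"].isin(panel1.subjects)]
    )
    panel2, variant_report = _stage("variant_filters")(apply_variant_filters)(
        panel1, outcomes, maf_min=config.maf_min, homozygote_rule=config.homozygote_rule
    )
    cov_used = cov[cov["subject_id"].isin(panel2.subjects)].reset_index(drop=True)

    freq = _stage("race_frequency_test")(stratified_frequency_test)(panel2, covariates=cov_used)
    freq.to_csv(outdir / "race_frequency_tests.tsv", sep="\t", float_format="%.6g")
    if ref is not None:
        rfreq = _stage("reference_frequency_test")(stratified_frequency_test)(
            panel2.subset(
                subjects=[s for s, r in zip(cov_used["subject_id"], cov_used["race"]) if r == "white"]
            ),
            reference=ref,
        )
        rfreq.to_csv(outdir / "reference_frequency_tests.tsv", sep="\t", float_format="%.6g")

    assoc = _stage("variant_scan")(scan)(
        panel2, outcomes, cov_used, q=config.fdr_q, family=config.family
    )
    if config.site_filter is not None:
        assoc_site = _stage("site_subset_scan")(subset_scan)(
            panel2, outcomes, cov_used, config.site_filter, q=config.fdr_q, family=config.family
        )
        assoc_site.to_csv(
            outdir / f"variant_associations_{config.site_filter}.tsv",
            sep="\t", index=False, float_format="%.6g",
        )
    skat = _stage("gene_scan")(gene_scan)(
        panel2, outcomes, cov_used,
        kernel=config.kernel, pvalue=config.pvalue_mode, n_perm=config.n_perm, seed=config.seed,
    )

    qc_frame = pd.concat([sample_report.to_frame(), variant_report.to_frame()])
    qc_frame.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    outcomes.reset_index().to_csv(outdir / "outcome_matrix.tsv", sep="\t", index=False)

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": gio.config_hash(dataclasses.asdict(config)),
        "seed": config.seed,
        "n_subjects_input": panel.n_subjects,
        "n_subjects_retained": panel1.n_subjects,
        "n_variants_input": panel.n_variants,
        "n_variants_retained": panel2.n_variants,
        "sample_exclusions": {r["rule"]: r["n_excluded"] for r in sample_report.rules},
        "variant_exclusions": {r["rule"]: r["n_excluded"] for r in variant_report.rules},
        "category_counts": outcomes["category"].value_counts().to_dict(),
    }
    _stage("write_results")(gio.write_results)(assoc, skat, outdir, metadata=manifest)
    return outdir


def make_fixture(spec: CohortSpec | str | Path, outdir: str | Path) -> dict[str, Path]:
    """Materialize a synthetic cohort (native formats + truth record).

    ``spec`` is either a :class:`CohortSpec` or a path to its JSON form.
    Writes genotypes in both VCF and dosage-TSV, the annotation table, the
    covariate and mutation tables, the serialized spec, and the planted-
    effect truth record.
    """
    if not isinstance(spec, CohortSpec):
        spec = gio.read_spec(spec)
    spec.validate()
    cohort: SyntheticCohort = simulate_cohort(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "dosages": outdir / "genotypes.tsv",
        "annotations": outdir / "annotations.tsv",
        "covariates": outdir / "covariates.tsv",
        "mutations": outdir / "mutations.tsv",
        "spec": outdir / "cohort_spec.json",
        "truth": outdir / "truth.json",
    }
    gio.write_genotypes(cohort.panel, paths["vcf"], "vcf")
    gio.write_genotypes(cohort.panel, paths["dosages"], "dosage-tsv")
    gio.write_annotations(cohort.panel, paths["annotations"])
    gio.write_tables(cohort.covariates, cohort.mutations, outdir)
    gio.write_spec(spec, paths["spec"])
    truth = dict(cohort.truth)
    truth["effects"] = [dataclasses.asdict(e) for e in truth["effects"]]
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return paths
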