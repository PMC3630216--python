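"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel either as VCF 4.2 (GT fields only, bi-allelic sites,
parsed with cyvcf2) or as the native dosage-TSV dialect: samples as rows,
variants as columns, a header row of variant ids, dosages in {0, 1, 2} and
missing calls written as ``NA``.  Either way a variant annotation TSV
(variant_id, gene, ref, alt, func_class, clustering_pass, is_binary)
supplies the metadata the QC cascade needs; the copy-deletion pseudo-
variants (GSTM1/GSTT1 null genotypes, dosage in {0, 1}) are flagged there.

Covariate / mutation / reference tables are TSV with the documented headers
(see :mod:`gistsig.cohort`); an empty mutation row (gene blank) is an
explicit wild-type record.  Result writers emit a long-form per-variant
table, variant x outcome and gene x outcome matrices of -log10 p, and a JSON
run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .cohort import (
    GenotypePanel,
    SchemaError,
    validate_covariates,
    validate_mutations,
    validate_reference,
)
from .simulate import CohortSpec, GeneSpec, PlantedEffect, Stratum

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_annotations",
    "write_annotations",
    "read_tables",
    "write_tables",
    "write_results",
    "read_spec",
    "write_spec",
]

_ANNOT_COLUMNS = ("variant_id", "gene", "ref", "alt", "func_class", "clustering_pass", "is_binary")


class ParseError(ValueError):
    """Malformed input file."""


# ----------------------------------------------------------------------
# variant annotations
# ----------------------------------------------------------------------


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_ANNOT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"annotation table missing columns: {sorted(missing)}")
    df = df.set_index("variant_id")
    df["clustering_pass"] = df["clustering_pass"].map({"True": True, "False": False, "1": True, "0": False})
    df["is_binary"] = df["is_binary"].map({"True": True, "False": False, "1": True, "0": False})
    if df["clustering_pass"].isna().any() or df["is_binary"].isna().any():
        raise SchemaError("clustering_pass/is_binary must be boolean")
    return df


def write_annotations(panel: GenotypePanel, path: str | Path) -> None:
    out = panel.variants[list(_ANNOT_COLUMNS[1:])].copy()
    out.insert(0, "variant_id", panel.variants.index)
    out.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------


def read_genotypes(
    path: str | Path, fmt: str, annotations: str | Path | None = None
) -> GenotypePanel:
    """Load a genotype panel from ``vcf`` or ``dosage-tsv``.

    VCF GT fields are mapped to alt-allele counts (``./.`` and ``.`` become
    missing); the panel is *unoriented* until
    :func:`gistsig.qc.compute_maf_and_orient` runs.  Multi-allelic records
    are rejected.  ``annotations`` is required for VCF (the VCF carries no
    gene/QC metadata) and optional for dosage-tsv (defaults are synthesized
    when absent).
    """
    if fmt == "vcf":
        return _read_vcf(path, annotations)
    if fmt == "dosage-tsv":
        return _read_dosage_tsv(path, annotations)
    raise ValueError(f"unknown genotype format {fmt!r}; expected 'vcf' or 'dosage-tsv'")


def _read_vcf(path: str | Path, annotations: str | Path | None) -> GenotypePanel:
    if annotations is None:
        raise ValueError("reading VCF requires a variant annotation table")
    annot = read_annotations(annotations)
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    rows = []
    ids = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ParseError(
                f"multi-allelic record {rec.ID or rec.POS} is unsupported (ALT={rec.ALT})"
            )
        vid = rec.ID
        if vid is None or vid == ".":
            raise ParseError(f"record at {rec.CHROM}:{rec.POS} lacks a variant id")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types.astype(float)
        dose = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dose)
        ids.append(vid)
    missing = set(ids) - set(annot.index)
    if missing:
        raise SchemaError(f"variants absent from annotation table: {sorted(missing)[:5]}")
    variants = annot.loc[ids].copy()
    dosages = np.array(rows).T if rows else np.empty((len(subjects), 0))
    # pseudo-binary assays are encoded as 0/1 "alt counts" in VCF already
    return GenotypePanel(subjects=subjects, variants=variants, dosages=dosages)


def _read_dosage_tsv(path: str | Path, annotations: str | Path | None) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    ids = list(df.columns)
    if annotations is not None:
        annot = read_annotations(annotations)
        missing = set(ids) - set(annot.index)
        if missing:
            raise SchemaError(f"variants absent from annotation table: {sorted(missing)[:5]}")
        variants = annot.loc[ids].copy()
    else:
        variants = pd.DataFrame(
            {
                "gene": "unknown",
                "ref": "A",
                "alt": "C",
                "func_class": "unknown",
                "clustering_pass": True,
                "is_binary": False,
            },
            index=pd.Index(ids, name="variant_id"),
        )
    return GenotypePanel(
        subjects=[str(s) for s in df.index],
        variants=variants,
        dosages=df.to_numpy(dtype=float),
    )


def write_genotypes(panel: GenotypePanel, path: str | Path, fmt: str) -> None:
    if fmt == "dosage-tsv":
        df = pd.DataFrame(panel.dosages, index=panel.subjects, columns=panel.variant_ids)
        with pd.option_context("display.float_format", None):
            out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
        out.index.name = "subject_id"
        out.to_csv(path, sep="\t")
        return
    if fmt != "vcf":
        raise ValueError(f"unknown genotype format {fmt!r}")
    _write_vcf(panel, path)


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.subjects),
    ]
    for j, vid in enumerate(panel.variant_ids):
        ref = panel.variants.at[vid, "ref"]
        alt = panel.variants.at[vid, "alt"]
        gts = "\t".join(
            "./." if np.isnan(d) else _GT[d] for d in panel.dosages[:, j]
        )
        lines.append(f"1\t{j + 1}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# subject tables
# ----------------------------------------------------------------------


def read_tables(
    covariates_path: str | Path,
    mutations_path: str | Path,
    reference_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    cov = validate_covariates(pd.read_csv(covariates_path, sep="\t", dtype={"subject_id": str}))
    mut = validate_mutations(pd.read_csv(mutations_path, sep="\t", dtype={"subject_id": str}))
    ref = None
    if reference_path is not None:
        ref = validate_reference(pd.read_csv(reference_path, sep="\t"))
    return cov, mut, ref


def write_tables(
    covariates: pd.DataFrame, mutations: pd.DataFrame, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    covariates.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    mutations.to_csv(outdir / "mutations.tsv", sep="\t", index=False)


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------


def _log10_matrix(df: pd.DataFrame, row: str) -> pd.DataFrame:
    wide = df.pivot(index=row, columns="outcome", values="p")
    return -np.log10(wide)


def write_results(
    assoc: pd.DataFrame,
    skat: pd.DataFrame,
    outdir: str | Path,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write the long-form association table, the -log10 p matrices of both
    analyses, and the run manifest.  Deterministic given identical inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "assoc": outdir / "variant_associations.tsv",
        "skat": outdir / "gene_skat.tsv",
        "assoc_matrix": outdir / "variant_log10p_matrix.tsv",
        "skat_matrix": outdir / "gene_log10p_matrix.tsv",
        "manifest": outdir / "run_manifest.json",
    }
    assoc.to_csv(paths["assoc"], sep="\t", index=False, float_format="%.6g")
    skat.to_csv(paths["skat"], sep="\t", index=False, float_format="%.6g")
    _log10_matrix(assoc, "variant_id").to_csv(paths["assoc_matrix"], sep="\t", float_format="%.4f")
    _log10_matrix(skat, "gene").to_csv(paths["skat_matrix"], sep="\t", float_format="%.4f")
    manifest = dict(metadata or {})
    manifest["n_assoc_rows"] = int(len(assoc))
    manifest["n_skat_rows"] = int(len(skat))
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths


# ----------------------------------------------------------------------
# cohort spec (structured-text config)
# ----------------------------------------------------------------------


def write_spec(spec: CohortSpec, path: str | Path) -> None:
    d = dataclasses.asdict(spec)
    d["strata"] = [
        {"label": s.label, "proportion": s.proportion, "maf": list(map(float, s.maf))}
        for s in spec.strata
    ]
    d["genes"] = [dataclasses.asdict(g) for g in spec.genes]
    d["effects"] = [dataclasses.asdict(e) for e in spec.effects]
    d["binary_variants"] = sorted(spec.binary_variants)
    d["baseline_probs"] = list(map(float, spec.baseline_probs))
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def read_spec(path: str | Path) -> CohortSpec:
    d = json.loads(Path(path).read_text())
    spec = CohortSpec(
        n_subjects=d["n_subjects"],
        strata=[Stratum(s["label"], s["proportion"], np.array(s["maf"])) for s in d["strata"]],
        genes=[GeneSpec(**g) for g in d["genes"]],
        variant_ids=d.get("variant_ids"),
        binary_variants=frozenset(d.get("binary_variants", [])),
        age_mean=d["age_mean"],
        age_sd=d["age_sd"],
        age_bounds=tuple(d["age_bounds"]),
        male_prop=d["male_prop"],
        site_probs=d["site_probs"],
        baseline_probs=np.array(d["baseline_probs"]),
        effects=[PlantedEffect(**e) for e in d.get("effects", [])],
        missing_rate=d["missing_rate"],
        seed=d["seed"],
    )
    spec.validate()
    return spec


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
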