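"""In-memory containers for the case-only GIST cohort.

The analysis operates on three tables plus a genotype panel:

* :class:`GenotypePanel` — samples x variants minor-allele dosage matrix with
  per-variant metadata (gene, alleles, functional class, array QC flag).
* a covariate table (age, sex, race, tumor site), one row per subject.
* a somatic mutation table (gene / exon / mutation type / codon span),
  at most one record per subject; subjects with no record are treated as
  missing mutation data, which is distinct from an explicit wild-type record.
* an optional reference-frequency table for an external comparison population.

Dosages count copies of the *minor* allele (0/1/2) once the panel has been
oriented; ``NaN`` encodes a missing call.  Copy-deletion assays (GSTM1/GSTT1
null genotypes) are pseudo-binary variants with dosage in {0, 1}, where 1 is
the null genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "VARIANT_COLUMNS",
    "COVARIATE_COLUMNS",
    "MUTATION_COLUMNS",
    "SEX_LEVELS",
    "RACE_LEVELS",
    "SITE_LEVELS",
    "MUTATION_GENES",
    "MUTATION_TYPES",
    "validate_covariates",
    "validate_mutations",
    "validate_reference",
    "reconcile_subjects",
]

#: required metadata columns of ``GenotypePanel.variants``
VARIANT_COLUMNS = ("gene", "ref", "alt", "func_class", "clustering_pass", "is_binary")

COVARIATE_COLUMNS = ("subject_id", "age", "sex", "race", "site")
MUTATION_COLUMNS = ("subject_id", "gene", "exon", "mutation_type", "codon_start", "codon_end")

SEX_LEVELS = ("male", "female")
RACE_LEVELS = ("white", "other")
SITE_LEVELS = ("stomach", "small_intestine", "rectum", "other", "missing")
MUTATION_GENES = ("KIT", "PDGFRA", "none")
MUTATION_TYPES = ("deletion", "insertion", "point")


class SchemaError(ValueError):
    """A table does not conform to its documented dialect."""


@dataclass
class GenotypePanel:
    """Samples x variants dosage matrix plus variant metadata.

    Parameters
    ----------
    subjects
        Unique subject identifiers, one per dosage row.
    variants
        Metadata frame indexed by variant id with columns
        ``gene, ref, alt, func_class, clustering_pass, is_binary``.
        After orientation it additionally carries ``minor_allele`` and ``maf``.
    dosages
        ``(n_subjects, n_variants)`` float array with entries in {0, 1, 2}
        ({0, 1} for pseudo-binary variants) and ``NaN`` for missing calls.
    oriented
        Whether :func:`gistsig.qc.compute_maf_and_orient` has fixed the
        minor-allele orientation.
    """

    subjects: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    oriented: bool = False

    def __post_init__(self) -> None:
        self.subjects = [str(s) for s in self.subjects]
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.validate()

    # -- shape -----------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants.index)

    def validate(self) -> None:
        if len(set(self.subjects)) != len(self.subjects):
            raise SchemaError("subject ids must be unique")
        if self.variants.index.has_duplicates:
            raise SchemaError("variant ids must be unique")
        missing_cols = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise SchemaError(f"variant metadata lacks columns: {sorted(missing_cols)}")
        if self.dosages.shape != (len(self.subjects), len(self.variants)):
            raise SchemaError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise SchemaError("dosages must be 0, 1, 2 or NaN")
        is_binary = self.variants["is_binary"].to_numpy(dtype=bool)
        if is_binary.any():
            binary_block = self.dosages[:, is_binary]
            finite = binary_block[~np.isnan(binary_block)]
            if finite.size and finite.max() > 1:
                raise SchemaError("pseudo-binary variants admit dosages {0, 1} only")

    # -- accessors -------------------------------------------------------
    def missing_fraction_per_subject(self) -> np.ndarray:
        """Fraction of missing calls per subject across all panel variants."""
        return np.isnan(self.dosages).mean(axis=1)

    def allele_frequency(self) -> np.ndarray:
        """Coded-allele frequency per variant over non-missing calls.

        Denominator is 2 x (non-missing calls) for SNPs and the number of
        non-missing calls for pseudo-binary variants (whose dosage is a
        single 0/1 state, not an allele count).
        """
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # all-missing variants legitimately yield NaN here
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(self.dosages, axis=0)
        is_binary = self.variants["is_binary"].to_numpy(dtype=bool)
        freq = np.where(is_binary, mean, mean / 2.0)
        return freq

    def subset(
        self,
        subjects: Sequence[str] | None = None,
        variant_ids: Sequence[str] | None = None,
    ) -> "GenotypePanel":
        """Return a new panel restricted to the given subjects / variants."""
        row_idx = np.arange(self.n_subjects)
        col_idx = np.arange(self.n_variants)
        new_subjects = self.subjects
        new_variants = self.variants
        if subjects is not None:
            wanted = [str(s) for s in subjects]
            pos = {s: i for i, s in enumerate(self.subjects)}
            unknown = [s for s in wanted if s not in pos]
            if unknown:
                raise KeyError(f"unknown subjects: {unknown[:5]}")
            row_idx = np.array([pos[s] for s in wanted], dtype=int)
            new_subjects = wanted
        if variant_ids is not None:
            wanted_v = [str(v) for v in variant_ids]
            unknown_v = [v for v in wanted_v if v not in self.variants.index]
            if unknown_v:
                raise KeyError(f"unknown variants: {unknown_v[:5]}")
            col_idx = np.array([self.variants.index.get_loc(v) for v in wanted_v], dtype=int)
            new_variants = self.variants.loc[wanted_v]
        return GenotypePanel(
            subjects=list(new_subjects),
            variants=new_variants.copy(),
            dosages=self.dosages[np.ix_(row_idx, col_idx)].copy(),
            oriented=self.oriented,
        )

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            subjects=list(self.subjects),
            variants=self.variants.copy(),
            dosages=self.dosages.copy(),
            oriented=self.oriented,
        )

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            self.subjects == other.subjects
            and list(self.variants.index) == list(other.variants.index)
            and self.variants[list(VARIANT_COLUMNS)].equals(other.variants[list(VARIANT_COLUMNS)])
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{what} table missing required columns: {sorted(missing)}")


def _check_levels(series: pd.Series, levels: tuple[str, ...], what: str) -> None:
    bad = set(series.dropna().unique()) - set(levels)
    if bad:
        raise SchemaError(f"unknown {what} levels {sorted(bad)}; expected one of {levels}")


def validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a covariate table (one row per subject)."""
    _require_columns(df, COVARIATE_COLUMNS, "covariate")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise SchemaError(f"duplicate subject id in covariate table: {dup}")
    df["age"] = pd.to_numeric(df["age"])
    if ((df["age"] < 0) | (df["age"] > 120)).any():
        raise SchemaError("age outside plausible bounds [0, 120]")
    _check_levels(df["sex"], SEX_LEVELS, "sex")
    _check_levels(df["race"], RACE_LEVELS, "race")
    _check_levels(df["site"], SITE_LEVELS, "site")
    return df.reset_index(drop=True)


def validate_mutations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a somatic mutation table.

    Rows with an empty ``gene`` field (or gene == "none") are explicit
    wild-type records; subjects absent from the table altogether have missing
    mutation data.
    """
    _require_columns(df, MUTATION_COLUMNS, "mutation")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise SchemaError(f"duplicate subject id in mutation table: {dup}")
    df["gene"] = df["gene"].fillna("none").replace("", "none")
    _check_levels(df["gene"], MUTATION_GENES, "mutation gene")
    for col in ("exon", "codon_start", "codon_end"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
    df["mutation_type"] = df["mutation_type"].where(df["mutation_type"].notna(), None)
    typed = df["mutation_type"].notna() & (df["mutation_type"] != "")
    _check_levels(df.loc[typed, "mutation_type"], MUTATION_TYPES, "mutation type")
    wild = df["gene"] == "none"
    bad = wild & (df["exon"].notna() | typed | df["codon_start"].notna() | df["codon_end"].notna())
    if bad.any():
        raise SchemaError(
            f"wild-type records must leave exon/type/codons empty (subject "
            f"{df.loc[bad, 'subject_id'].iloc[0]})"
        )
    indel = df["mutation_type"].isin(("deletion", "insertion"))
    span_missing = indel & (df["codon_start"].isna() | df["codon_end"].isna())
    if span_missing.any():
        raise SchemaError(
            f"deletion/insertion records require a codon span (subject "
            f"{df.loc[span_missing, 'subject_id'].iloc[0]})"
        )
    return df.reset_index(drop=True)


def validate_reference(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a reference-population frequency table.

    Columns: ``variant_id, maf, n_ref_hom, n_het, n_alt_hom`` — genotype-class
    counts in the comparison population, coded on the same minor allele as
    the study panel.
    """
    _require_columns(df, ("variant_id", "maf", "n_ref_hom", "n_het", "n_alt_hom"), "reference")
    df = df.copy()
    df["variant_id"] = df["variant_id"].astype(str)
    if df["variant_id"].duplicated().any():
        raise SchemaError("duplicate variant id in reference table")
    df["maf"] = pd.to_numeric(df["maf"])
    if ((df["maf"] < 0) | (df["maf"] > 1)).any():
        raise SchemaError("reference frequencies must lie in [0, 1]")
    for col in ("n_ref_hom", "n_het", "n_alt_hom"):
        df[col] = pd.to_numeric(df[col]).astype(int)
        if (df[col] < 0).any():
            raise SchemaError("reference genotype counts must be nonnegative")
    return df.reset_index(drop=True)


def reconcile_subjects(
    panel: GenotypePanel,
    covariates: pd.DataFrame,
    mutations: pd.DataFrame,
) -> pd.DataFrame:
    """Cross-table subject reconciliation report.

    One row per subject seen anywhere, with boolean membership flags; used to
    surface subjects present in one input but absent from another before any
    filtering happens.
    """
    geno = set(panel.subjects)
    cov = set(covariates["subject_id"])
    mut = set(mutations["subject_id"])
    everyone = sorted(geno | cov | mut)
    return pd.DataFrame(
        {
            "subject_id": everyone,
            "in_genotypes": [s in geno for s in everyone],
            "in_covariates": [s in cov for s in everyone],
            "in_mutations": [s in mut for s in everyone],
        }
    )
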