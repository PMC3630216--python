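"""Sample- and variant-level QC cascade and descriptive frequency tests.

The cascade mirrors the trial's published exclusion ledger.  Samples: drop
subjects with no somatic mutation record, then subjects with strictly more
than 10% missing genotype calls.  Variants (after minor-allele orientation):
drop, in order, (1) mono-allelic variants, (2) variants with MAF strictly
below 5% in the analysis cohort, (3) variants flagged as poor array
clustering (an intensity-level property consumed here as a boolean flag),
and (4) variants with no minor-allele homozygote at some level of an outcome
dichotomy.  Each variant is attributed to the first rule it violates, so the
per-rule exclusion counts partition the input.

Descriptive checks: duplicate-sample concordance and per-variant
race-stratified (or external-reference) genotype frequency contrasts, with
Pearson chi-square by default and an exact test whenever any observed cell
count falls below 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .cohort import GenotypePanel
from .outcomes import CATEGORIES

__all__ = [
    "QCReport",
    "SampleFilter",
    "VariantFilter",
    "exclude_samples",
    "compute_maf_and_orient",
    "apply_variant_filters",
    "duplicate_concordance",
    "stratified_frequency_test",
    "freeman_halton_2xc",
]


@dataclass
class QCReport:
    """Ledger of one QC stage: per-rule exclusions plus retained count."""

    stage: str
    n_input: int
    rules: list[dict] = field(default_factory=list)  # {"rule", "n_excluded", "excluded"}
    n_retained: int = 0
    tables: dict = field(default_factory=dict)

    def add_rule(self, rule: str, excluded: list[str]) -> None:
        self.rules.append({"rule": rule, "n_excluded": len(excluded), "excluded": list(excluded)})

    def check_conservation(self) -> None:
        total = sum(r["n_excluded"] for r in self.rules) + self.n_retained
        if total != self.n_input:
            raise AssertionError(
                f"{self.stage}: excluded+retained={total} does not partition input={self.n_input}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.stage, r["rule"], r["n_excluded"]) for r in self.rules]
        rows.append((self.stage, "retained", self.n_retained))
        return pd.DataFrame(rows, columns=["stage", "rule", "n"])


# ----------------------------------------------------------------------
# sample filter
# ----------------------------------------------------------------------


class SampleFilter(BaseEstimator):
    """Drop subjects with missing mutation data, then high genotype missingness.

    Parameters
    ----------
    missingness_threshold : float, default 0.10
        Subjects whose fraction of missing genotype calls strictly exceeds
        this are excluded (a subject at exactly the threshold is retained).
    """

    def __init__(self, missingness_threshold: float = 0.10):
        self.missingness_threshold = missingness_threshold

    def fit(self, panel: GenotypePanel, mutations: pd.DataFrame) -> "SampleFilter":
        if not 0 < self.missingness_threshold <= 1:
            raise ValueError("missingness_threshold must lie in (0, 1]")
        with_mutation = set(mutations["subject_id"].astype(str))
        no_record = [s for s in panel.subjects if s not in with_mutation]
        rest = [s for s in panel.subjects if s in with_mutation]
        sub = panel.subset(subjects=rest)
        frac = sub.missing_fraction_per_subject()
        high = [s for s, f in zip(rest, frac) if f > self.missingness_threshold]
        keep = [s for s in rest if s not in set(high)]

        report = QCReport(stage="samples", n_input=panel.n_subjects)
        report.add_rule("missing_mutation_data", no_record)
        report.add_rule(f"genotype_missingness_gt_{self.missingness_threshold:g}", high)
        report.n_retained = len(keep)
        report.check_conservation()
        self.keep_ = keep
        self.report_ = report
        return self

    def transform(self, panel: GenotypePanel) -> GenotypePanel:
        return panel.subset(subjects=self.keep_)

    def fit_transform(self, panel: GenotypePanel, mutations: pd.DataFrame) -> GenotypePanel:
        return self.fit(panel, mutations).transform(panel)


def exclude_samples(
    panel: GenotypePanel, mutations: pd.DataFrame, missingness_threshold: float = 0.10
) -> tuple[GenotypePanel, QCReport]:
    f = SampleFilter(missingness_threshold=missingness_threshold).fit(panel, mutations)
    return f.transform(panel), f.report_


# ----------------------------------------------------------------------
# orientation
# ----------------------------------------------------------------------


def compute_maf_and_orient(panel: GenotypePanel) -> GenotypePanel:
    """Fix the minor-allele orientation and record per-variant MAF.

    Allele frequency is computed over non-missing calls; where the coded
    allele is the more frequent one, dosages are flipped (d -> 2-d) and the
    recorded minor allele switches to the other allele.  An exact 0.5 tie
    keeps the alphabetically-first allele as minor.  Copy-deletion
    pseudo-variants are never flipped (their frequency is the null-genotype
    frequency and may exceed 0.5).  Variants with all calls missing are
    flagged (``maf`` = NaN) and left unoriented.  Idempotent.
    """
    panel = panel.copy()
    freq = panel.allele_frequency()
    is_binary = panel.variants["is_binary"].to_numpy(dtype=bool)
    ref = panel.variants["ref"].to_numpy()
    alt = panel.variants["alt"].to_numpy()
    # the currently-counted allele: alt on a fresh panel, the recorded minor
    # allele on an already-oriented one (keeps the operation idempotent)
    if panel.oriented and "minor_allele" in panel.variants.columns:
        coded = panel.variants["minor_allele"].to_numpy(dtype=object)
    else:
        coded = alt.copy().astype(object)

    minor = coded.copy()
    maf = freq.copy()
    for j in range(panel.n_variants):
        if np.isnan(freq[j]):
            minor[j] = None
            continue
        if is_binary[j]:
            continue  # coded state stays "null genotype"
        other = ref[j] if coded[j] == alt[j] else alt[j]
        flip = freq[j] > 0.5 or (freq[j] == 0.5 and coded[j] != min(coded[j], other))
        if flip:
            panel.dosages[:, j] = 2.0 - panel.dosages[:, j]
            minor[j] = other
            # recompute from the flipped calls (bit-stable under re-runs)
            maf[j] = np.nanmean(panel.dosages[:, j]) / 2.0
    panel.variants["minor_allele"] = minor
    panel.variants["maf"] = maf
    panel.oriented = True
    return panel


# ----------------------------------------------------------------------
# variant filter
# ----------------------------------------------------------------------


def _hom_class(is_binary: np.ndarray) -> np.ndarray:
    return np.where(is_binary, 1.0, 2.0)


class VariantFilter(BaseEstimator):
    """Ordered variant exclusion cascade on an oriented panel.

    Parameters
    ----------
    maf_min : float, default 0.05
        Strict lower frequency bound; variants with MAF < ``maf_min`` are
        excluded (MAF exactly at the bound is retained).  For pseudo-binary
        variants the criterion uses ``min(f, 1-f)`` of the null frequency.
    homozygote_rule : {"any-side", "case-side", "off"}, default "any-side"
        Operationalization of the outcome-homozygote rule: exclude a variant
        when, for at least one of the seven signature dichotomies, the named
        side(s) contain zero minor-allele homozygotes.  The published rule is
        ambiguous about which outcome levels were meant, so the convention is
        configurable and recorded in the report.
    """

    def __init__(self, maf_min: float = 0.05, homozygote_rule: str = "any-side"):
        self.maf_min = maf_min
        self.homozygote_rule = homozygote_rule

    def fit(self, panel: GenotypePanel, outcomes: pd.DataFrame) -> "VariantFilter":
        if not panel.oriented:
            raise ValueError("panel must be oriented (compute_maf_and_orient) before filtering")
        if self.homozygote_rule not in ("any-side", "case-side", "off"):
            raise ValueError(f"unknown homozygote_rule {self.homozygote_rule!r}")
        maf = panel.variants["maf"].to_numpy(dtype=float)
        is_binary = panel.variants["is_binary"].to_numpy(dtype=bool)
        eff_maf = np.where(is_binary, np.minimum(maf, 1.0 - maf), maf)
        clustering = panel.variants["clustering_pass"].to_numpy(dtype=bool)
        ids = np.array(panel.variant_ids)

        mono = (eff_maf == 0) | np.isnan(maf)
        rare = ~mono & (eff_maf < self.maf_min)
        clust = ~mono & ~rare & ~clustering

        hom_fail = np.zeros(panel.n_variants, dtype=bool)
        if self.homozygote_rule != "off":
            ind = outcomes.loc[panel.subjects, list(CATEGORIES)].to_numpy()
            hom = _hom_class(is_binary)
            candidate = ~(mono | rare | clust)
            for j in np.flatnonzero(candidate):
                col = panel.dosages[:, j]
                ok = ~np.isnan(col)
                for k in range(len(CATEGORIES)):
                    cases = ind[:, k] == 1
                    sides = [cases] if self.homozygote_rule == "case-side" else [cases, ~cases]
                    if any(not (col[ok & side] == hom[j]).any() for side in sides):
                        hom_fail[j] = True
                        break

        keep = ~(mono | rare | clust | hom_fail)
        report = QCReport(stage="variants", n_input=panel.n_variants)
        report.add_rule("mono_allelic", list(ids[mono]))
        report.add_rule(f"maf_lt_{self.maf_min:g}", list(ids[rare]))
        report.add_rule("poor_clustering", list(ids[clust]))
        report.add_rule(f"no_outcome_homozygote[{self.homozygote_rule}]", list(ids[hom_fail]))
        report.n_retained = int(keep.sum())
        report.check_conservation()
        report.tables["maf"] = panel.variants[["gene", "maf"]].copy()
        self.keep_ = list(ids[keep])
        self.report_ = report
        return self

    def transform(self, panel: GenotypePanel) -> GenotypePanel:
        return panel.subset(variant_ids=self.keep_)

    def fit_transform(self, panel: GenotypePanel, outcomes: pd.DataFrame) -> GenotypePanel:
        return self.fit(panel, outcomes).transform(panel)


def apply_variant_filters(
    panel: GenotypePanel,
    outcomes: pd.DataFrame,
    maf_min: float = 0.05,
    homozygote_rule: str = "any-side",
) -> tuple[GenotypePanel, QCReport]:
    f = VariantFilter(maf_min=maf_min, homozygote_rule=homozygote_rule).fit(panel, outcomes)
    return f.transform(panel), f.report_


# ----------------------------------------------------------------------
# duplicate concordance
# ----------------------------------------------------------------------


def duplicate_concordance(
    panel: GenotypePanel, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Call-level concordance for duplicate sample pairs.

    Concordance is matching call pairs over call pairs where both members
    are non-missing; a pair with no jointly non-missing call gets NaN and a
    flag.  The last row pools every pair.
    """
    pos = {s: i for i, s in enumerate(panel.subjects)}
    rows = []
    match_total = 0
    joint_total = 0
    for a, b in pairs:
        if a not in pos or b not in pos:
            raise KeyError(f"duplicate pair ({a}, {b}) references unknown subject")
        xa, xb = panel.dosages[pos[a]], panel.dosages[pos[b]]
        joint = ~np.isnan(xa) & ~np.isnan(xb)
        n_joint = int(joint.sum())
        n_match = int((xa[joint] == xb[joint]).sum())
        conc = n_match / n_joint if n_joint else np.nan
        rows.append((a, b, n_joint, n_match, conc, n_joint == 0))
        match_total += n_match
        joint_total += n_joint
    pooled = match_total / joint_total if joint_total else np.nan
    rows.append(("(pooled)", "", joint_total, match_total, pooled, joint_total == 0))
    return pd.DataFrame(
        rows, columns=["subject_a", "subject_b", "n_joint", "n_match", "concordance", "undefined"]
    )


# ----------------------------------------------------------------------
# stratified genotype-frequency tests
# ----------------------------------------------------------------------


def freeman_halton_2xc(table: np.ndarray) -> float:
    """Exact conditional test for a 2 x c contingency table.

    Generalizes Fisher's exact test: enumerate all tables with the observed
    margins, summing the multivariate-hypergeometric probability of every
    table no more probable than the observed one.  Written directly because
    scipy's ``fisher_exact`` only covers 2 x 2; agrees with it there.
    """
    table = np.asarray(table, dtype=int)
    if table.shape[0] != 2:
        raise ValueError("expected a 2 x c table")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)

    def logp(top: np.ndarray) -> float:
        bottom = col - top
        return const - gammaln(top + 1).sum() - gammaln(bottom + 1).sum()

    lp_obs = logp(table[0])
    c = table.shape[1]
    total = 0.0

    def rec(j: int, remaining: int, top: list[int]) -> None:
        nonlocal total
        if j == c - 1:
            if remaining <= col[j]:
                lp = logp(np.array(top + [remaining]))
                if lp <= lp_obs + 1e-9:
                    total += np.exp(lp)
            return
        lo = max(0, remaining - int(col[j + 1 :].sum()))
        hi = min(int(col[j]), remaining)
        for t in range(lo, hi + 1):
            rec(j + 1, remaining - t, top + [t])

    rec(0, int(row[0]), [])
    return min(1.0, float(total))


def _one_frequency_test(counts: np.ndarray) -> tuple[float, float, str]:
    """Chi-square or exact test on a groups x genotype-class count table."""
    counts = np.asarray(counts, dtype=int)
    counts = counts[:, counts.sum(axis=0) > 0]  # drop empty genotype classes
    if counts.shape[0] < 2 or counts.shape[1] < 2 or (counts.sum(axis=1) == 0).any():
        return (np.nan, np.nan, "none")
    if (counts < 5).any():
        if counts.shape == (2, 2):
            _, p = stats.fisher_exact(counts)
        else:
            p = freeman_halton_2xc(counts)
        return (np.nan, float(p), "fisher")
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return (float(chi2), float(p), "chi2")


def _genotype_counts(col: np.ndarray, classes: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(col)
    return np.array([(col[ok] == c).sum() for c in classes])


def stratified_frequency_test(
    panel: GenotypePanel,
    covariates: pd.DataFrame | None = None,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-variant genotype-distribution contrast across race strata or
    against an external reference population.

    Exactly one of ``covariates`` (race stratification within the cohort) or
    ``reference`` (study whites vs. reference genotype counts) must be given.
    Builds the group x genotype-class table (3 classes, or 2 for
    pseudo-binary variants), applies Pearson chi-square, and dispatches to an
    exact test when any observed cell is below 5; the report records which
    test ran.
    """
    if (covariates is None) == (reference is None):
        raise ValueError("give exactly one of covariates (race contrast) or reference")
    is_binary = panel.variants["is_binary"].to_numpy(dtype=bool)
    rows = []
    if covariates is not None:
        cov = covariates.set_index("subject_id").loc[panel.subjects]
        groups = [cov["race"].to_numpy() == "white", cov["race"].to_numpy() != "white"]
        for j, vid in enumerate(panel.variant_ids):
            classes = np.array([0.0, 1.0]) if is_binary[j] else np.array([0.0, 1.0, 2.0])
            counts = np.stack(
                [_genotype_counts(panel.dosages[g, j], classes) for g in groups]
            )
            stat, p, used = _one_frequency_test(counts)
            rows.append((vid, stat, p, used))
    else:
        ref = reference.set_index("variant_id")
        for j, vid in enumerate(panel.variant_ids):
            if vid not in ref.index:
                rows.append((vid, np.nan, np.nan, "none"))
                continue
            classes = np.array([0.0, 1.0]) if is_binary[j] else np.array([0.0, 1.0, 2.0])
            study = _genotype_counts(panel.dosages[:, j], classes)
            r = ref.loc[vid]
            ref_counts = np.array([r["n_ref_hom"], r["n_het"], r["n_alt_hom"]])[: len(classes)]
            stat, p, used = _one_frequency_test(np.stack([study, ref_counts]))
            rows.append((vid, stat, p, used))
    return pd.DataFrame(rows, columns=["variant_id", "statistic", "p", "test"]).set_index(
        "variant_id"
    )
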