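"""Per-variant, per-outcome covariate-adjusted logistic screening.

For each retained variant and each of the seven signature dichotomies the
screen fits a maximum-likelihood logistic regression of the outcome on the
ordinal minor-allele dosage (0/1/2; a per-allele trend coding) adjusted for
race (white vs. other), sex, and age at diagnosis in years.  It reports the
per-allele odds ratio ``exp(beta_dosage)``, its Wald 95% confidence
interval, and the 1-df Wald trend p-value, then controls the false discovery
rate with the Benjamini–Hochberg step-up procedure within each outcome
family (optionally pooled across outcomes).

Subjects with a missing call at a variant are dropped for that variant only
(complete-case per variant).  Quasi-complete separation is detected and
reported as a fit status rather than silently returning an exploded
estimate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import GenotypePanel
from .outcomes import CATEGORIES

__all__ = [
    "VariantAssociationScan",
    "fit_variant_model",
    "bh_adjust",
    "scan",
    "subset_scan",
]

_Z975 = stats.norm.ppf(0.975)
_MAX_ABS_COEF = 15.0  # |log-OR| beyond this is treated as separation


def _design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Adjustment design: intercept + race(white=1) + sex(male=1) + age (years)."""
    X = pd.DataFrame(
        {
            "const": 1.0,
            "race_white": (covariates["race"] == "white").astype(float),
            "sex_male": (covariates["sex"] == "male").astype(float),
            "age": covariates["age"].astype(float),
        },
        index=covariates.index,
    )
    return X


def fit_variant_model(
    dosage: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | None,
) -> dict:
    """One covariate-adjusted per-allele logistic fit.

    Returns a dict with ``or_``, ``ci_low``, ``ci_high``, ``p``, ``n`` and
    ``status`` in {"converged", "separated", "degenerate", "failed"}.
    ``covariates=None`` fits dosage + intercept only.  Adjustment columns
    that are constant among the included subjects are dropped (this happens
    in site-restricted subsets), never the dosage column.
    """
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(dosage) & ~np.isnan(y)
    d, yy = dosage[ok], y[ok]
    n = int(ok.sum())
    out = {"or_": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "n": n}

    if n == 0 or yy.min() == yy.max() or d.min() == d.max():
        out["status"] = "degenerate"
        return out
    # quasi-complete separation on the trend variable itself
    if d[yy == 1].min() > d[yy == 0].max() or d[yy == 1].max() < d[yy == 0].min():
        out["status"] = "separated"
        return out

    cols = {"const": np.ones(n), "dosage": d}
    if covariates is not None:
        Xc = _design(covariates).to_numpy()[ok]
        for name, col in zip(("race_white", "sex_male", "age"), Xc[:, 1:].T):
            if col.min() != col.max():
                cols[name] = col
    X = np.column_stack(list(cols.values()))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            # convergence is checked explicitly below via mle_retvals
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(yy, X).fit(disp=0, maxiter=100, tol=1e-8)
    except (PerfectSeparationError, PerfectSeparationWarning):
        out["status"] = "separated"
        return out
    except np.linalg.LinAlgError:
        out["status"] = "failed"
        return out

    beta = res.params[1]
    se = res.bse[1]
    if not res.mle_retvals.get("converged", False) or not np.isfinite(se):
        out["status"] = "failed"
        return out
    if abs(beta) > _MAX_ABS_COEF:
        out["status"] = "separated"
        return out
    out.update(
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z975 * se)),
        ci_high=float(np.exp(beta + _Z975 * se)),
        p=float(2 * stats.norm.sf(abs(beta / se))),
        status="converged",
    )
    return out


def bh_adjust(p: np.ndarray, q: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up within one family.

    NaN entries (failed fits) are excluded from the family size and come
    back as NaN / not rejected.  Returns ``(adjusted_p, reject)``.
    """
    p = np.asarray(p, dtype=float)
    adj = np.full_like(p, np.nan)
    rej = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.sum():
        rej[ok], adj[ok], _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
    return adj, rej


class VariantAssociationScan(BaseEstimator):
    """Screen every variant against every signature dichotomy.

    Parameters
    ----------
    q : float, default 0.25
        FDR level for the reject flag.
    family : {"per-outcome", "pooled"}, default "per-outcome"
        BH family: one family per outcome dichotomy across variants
        (matching the per-outcome presentation of the results), or a single
        pooled family over all variant x outcome tests.
    site_filter : str or None
        Restrict the analysis to subjects with this tumor site.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per variant x outcome, ordered by (gene, variant, outcome):
        ``variant_id, gene, outcome, or_, ci_low, ci_high, p, p_adj,
        reject, status, n``.
    """

    def __init__(self, q: float = 0.25, family: str = "per-outcome", site_filter: str | None = None):
        self.q = q
        self.family = family
        self.site_filter = site_filter

    def fit(
        self,
        panel: GenotypePanel,
        outcomes: pd.DataFrame,
        covariates: pd.DataFrame,
    ) -> "VariantAssociationScan":
        if self.family not in ("per-outcome", "pooled"):
            raise ValueError(f"unknown family mode {self.family!r}")
        cov = covariates.set_index("subject_id").loc[panel.subjects]
        if self.site_filter is not None:
            keep = [s for s, site in zip(panel.subjects, cov["site"]) if site == self.site_filter]
            if not keep:
                raise ValueError(f"site filter {self.site_filter!r} matches no subjects")
            panel = panel.subset(subjects=keep)
            cov = cov.loc[keep]
        ind = outcomes.loc[panel.subjects, list(CATEGORIES)]

        meta = panel.variants.copy()
        meta["_vid"] = meta.index
        order = meta.sort_values(["gene", "_vid"], kind="stable")
        rows = []
        for vid in order.index:
            j = panel.variants.index.get_loc(vid)
            gene = panel.variants.at[vid, "gene"]
            dose = panel.dosages[:, j]
            for cat in CATEGORIES:
                fit = fit_variant_model(dose, ind[cat].to_numpy(), cov)
                rows.append(
                    (vid, gene, cat, fit["or_"], fit["ci_low"], fit["ci_high"], fit["p"],
                     fit["status"], fit["n"])
                )
        res = pd.DataFrame(
            rows,
            columns=["variant_id", "gene", "outcome", "or_", "ci_low", "ci_high", "p", "status", "n"],
        )
        res["p_adj"] = np.nan
        res["reject"] = False
        if self.family == "pooled":
            adj, rej = bh_adjust(res["p"].to_numpy(), self.q)
            res["p_adj"], res["reject"] = adj, rej
        else:
            for cat in CATEGORIES:
                m = res["outcome"] == cat
                adj, rej = bh_adjust(res.loc[m, "p"].to_numpy(), self.q)
                res.loc[m, "p_adj"] = adj
                res.loc[m, "reject"] = rej
        self.results_ = res[
            ["variant_id", "gene", "outcome", "or_", "ci_low", "ci_high", "p", "p_adj",
             "reject", "status", "n"]
        ]
        self.n_subjects_ = panel.n_subjects
        return self


def scan(
    panel: GenotypePanel,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    q: float = 0.25,
    family: str = "per-outcome",
) -> pd.DataFrame:
    return VariantAssociationScan(q=q, family=family).fit(panel, outcomes, covariates).results_


def subset_scan(
    panel: GenotypePanel,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    site: str,
    q: float = 0.25,
    family: str = "per-outcome",
) -> pd.DataFrame:
    """Identical screen restricted to subjects with the given tumor site."""
    est = VariantAssociationScan(q=q, family=family, site_filter=site)
    return est.fit(panel, outcomes, covariates).results_
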