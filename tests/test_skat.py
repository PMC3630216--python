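"""Kernel-machine score test: null model, IBS kernel, Q, moment matching,
exact mixture, permutation oracle, and their cross-agreements."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gistsig.outcomes import build_outcome_matrix
from gistsig.simulate import PlantedEffect, simulate_cohort
from gistsig.skat import (
    NullModelError,
    build_ibs_kernel,
    build_linear_kernel,
    fit_null,
    gene_scan,
    mixture_p,
    moment_matched_p,
    permutation_p,
    q_statistic,
)

from conftest import null_cohort_spec


def _toy(seed, n=20, p=5, case_frac=0.24, beta=0.5):
    """Seeded toy at the study's typical case fraction."""
    rng = np.random.default_rng(seed)
    Z = rng.integers(0, 3, size=(n, p)).astype(float)
    eta = np.log(case_frac / (1 - case_frac)) + beta * (Z[:, 0] - 1)
    y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
    return Z, y


# ------------------------------------------------------------ null model


def test_intercept_only_null_closed_form():
    y = np.array([1, 1, 0, 0, 0, 0, 0, 1], dtype=float)
    null = fit_null(y, None)
    assert np.allclose(null.mu, 3 / 8)
    assert np.abs(null.P0 @ null.X).max() < 1e-8


def test_null_requires_two_outcome_levels():
    with pytest.raises(NullModelError):
        fit_null(np.ones(10), None)


def test_null_recovers_generating_coefficients():
    rng = np.random.default_rng(3)
    n = 3000
    cov = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "age": rng.uniform(20, 80, n).round(1),
            "sex": rng.choice(["male", "female"], n),
            "race": rng.choice(["white", "other"], n, p=[0.8, 0.2]),
            "site": "stomach",
        }
    )
    # truth: intercept -1.5, race 0.6, sex -0.4, age 0.02
    eta = (-1.5 + 0.6 * (cov["race"] == "white") - 0.4 * (cov["sex"] == "male")
           + 0.02 * cov["age"]).to_numpy()
    y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
    null = fit_null(y, cov)
    se = np.sqrt(np.diag(np.linalg.inv(null.X.T @ (null.X * (null.mu * (1 - null.mu))[:, None]))))
    truth = np.array([-1.5, 0.6, -0.4, 0.02])
    assert (np.abs(null.alpha - truth) < 2 * se).all()


# --------------------------------------------------------------- kernel


def test_ibs_kernel_pointwise_values():
    # single variant: IBS(0,2)=0, IBS(1,2)=1 of max 2
    k = build_ibs_kernel(np.array([[0.0], [1.0], [2.0]]))
    assert k.K[0, 0] == 1.0
    assert k.K[0, 2] == 0.0
    assert k.K[1, 2] == 0.5
    # opposite homozygotes at every one of p variants -> 0
    k2 = build_ibs_kernel(np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]]))
    assert k2.K[0, 1] == 0.0
    # identical genotype vectors -> 1
    k3 = build_ibs_kernel(np.array([[1.0, 2.0], [1.0, 2.0]]))
    assert k3.K[0, 1] == 1.0


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_ibs_kernel_psd_symmetric(seed):
    rng = np.random.default_rng(seed)
    Z = rng.integers(0, 3, size=(15, rng.integers(1, 6))).astype(float)
    Z[rng.random(Z.shape) < 0.1] = np.nan  # mean imputation path
    k = build_ibs_kernel(Z)
    assert np.allclose(k.K, k.K.T)
    assert np.linalg.eigvalsh(k.K).min() > -1e-8
    if not np.isnan(Z).any():
        assert np.allclose(np.diag(k.K), 1.0)


# ------------------------------------------------------------------- Q


def test_q_zero_at_zero_residual():
    Z, y = _toy(0)
    null = fit_null(y, None)
    k = build_ibs_kernel(Z)
    null.y = null.mu.copy()  # force y = mu
    assert q_statistic(k, null) == pytest.approx(0.0)


def test_q_identity_kernel_is_residual_sum_of_squares():
    y = np.array([1, 0, 0, 1, 0, 1], dtype=float)
    null = fit_null(y, None)
    r = y - 0.5
    from gistsig.skat import GeneKernel

    k = GeneKernel(gene="I", variant_ids=[], K=np.eye(6))
    assert q_statistic(k, null) == pytest.approx((r**2).sum())


def test_q_invariant_under_joint_permutation():
    Z, y = _toy(4)
    null = fit_null(y, None)
    k = build_ibs_kernel(Z)
    q1 = q_statistic(k, null)
    perm = np.random.default_rng(0).permutation(len(y))
    null2 = fit_null(y[perm], None)
    k2 = build_ibs_kernel(Z[perm])
    assert q_statistic(k2, null2) == pytest.approx(q1)


def test_q_nonnegative_random_instances():
    for seed in range(20):
        Z, y = _toy(seed, n=30)
        null = fit_null(y, None)
        assert q_statistic(build_ibs_kernel(Z), null) >= 0


# --------------------------------------------------------- p-values


def test_moment_p_trivia():
    Z, y = _toy(1)
    null = fit_null(y, None)
    k = build_ibs_kernel(Z)
    kappa, nu, p0 = moment_matched_p(0.0, k, null)
    assert p0 == pytest.approx(1.0)
    # p strictly decreases in Q at fixed kappa, nu
    qs = [stats.chi2.sf(q / kappa, nu) for q in (0.5, 1.0, 2.0, 4.0)]
    assert all(a > b for a, b in zip(qs, qs[1:]))


def test_moment_identities_against_permutation_moments():
    """tr(P0 K) and 2 tr(P0 K P0 K) track the permutation mean and variance
    of Q at n=300 (small relative slack for the permutation's conditioning
    on the case count and non-Gaussian residuals)."""
    rng = np.random.default_rng(0)
    n = 300
    Z = rng.integers(0, 3, size=(n, 5)).astype(float)
    y = rng.binomial(1, 0.24, n).astype(float)
    null = fit_null(y, None)
    K = build_ibs_kernel(Z).K
    PK = null.P0 @ K
    e_a, v_a = np.trace(PK), 2 * np.sum(PK * PK.T)
    perms = np.stack([rng.permutation(y) for _ in range(20000)]) - null.mu
    Qs = np.einsum("ij,jk,ik->i", perms, K, perms)
    assert abs(Qs.mean() - e_a) / e_a < 0.02
    assert abs(Qs.var() - v_a) / v_a < 0.10


def test_kernel_scale_invariance():
    """Rescaling K by any positive constant leaves the moment-matched and
    exact-mixture p unchanged (kappa absorbs the scale)."""
    Z, y = _toy(7)
    null = fit_null(y, None)
    k = build_ibs_kernel(Z)
    Q = q_statistic(k, null)
    _, _, p1 = moment_matched_p(Q, k, null)
    pe1 = mixture_p(Q, k, null)
    k.K = 7.3 * k.K
    _, _, p2 = moment_matched_p(7.3 * Q, k, null)
    pe2 = mixture_p(7.3 * Q, k, null)
    assert p2 == pytest.approx(p1, rel=1e-9)
    assert pe2 == pytest.approx(pe1, rel=1e-6)


def test_single_variant_linear_kernel_is_squared_score():
    """With one variant and the linear kernel, Q reduces to the squared
    covariate-adjusted logistic score statistic z'(y - mu), up to the fixed
    1/(2p) kernel normalization."""
    rng = np.random.default_rng(11)
    n = 80
    z = rng.integers(0, 3, n).astype(float)
    y = rng.binomial(1, 0.3, n).astype(float)
    null = fit_null(y, None)
    k = build_linear_kernel(z[:, None])
    U = z @ (y - null.mu)
    assert q_statistic(k, null) == pytest.approx(U**2 / 2.0)


def test_exact_mixture_close_to_moment_p_moderate_n():
    Z, y = _toy(5, n=150)
    null = fit_null(y, None)
    k = build_ibs_kernel(Z)
    Q = q_statistic(k, null)
    _, _, p_m = moment_matched_p(Q, k, null)
    p_e = mixture_p(Q, k, null)
    assert p_e == pytest.approx(p_m, abs=0.03)


def test_permutation_p_bounds_and_determinism():
    Z, y = _toy(2)
    null = fit_null(y, None)
    k = build_ibs_kernel(Z)
    p1 = permutation_p(k, null, n_perm=1000, seed=5)
    assert p1 == permutation_p(k, null, n_perm=1000, seed=5)
    assert p1 >= 1 / 1001
    with pytest.raises(ValueError):
        permutation_p(k, null, n_perm=0)


def test_permutation_p_uniform_under_null():
    """Null gene-outcome pairs give uniform permutation p (KS p > 0.001)."""
    rng = np.random.default_rng(9)
    pvals = []
    for _ in range(300):
        n = 40
        Z = rng.integers(0, 3, size=(n, 4)).astype(float)
        y = rng.binomial(1, 0.3, n).astype(float)
        if y.sum() in (0, n):
            continue
        null = fit_null(y, None)
        k = build_ibs_kernel(Z)
        pvals.append(permutation_p(k, null, n_perm=400, seed=int(rng.integers(2**31))))
    assert stats.kstest(pvals, "uniform").pvalue > 0.001


def test_moment_and_permutation_rank_agreement():
    """Across a battery of 100 seeded toys the two p-value routes agree in
    rank (Spearman > 0.95)."""
    pm, pp = [], []
    for seed in range(100):
        Z, y = _toy(seed, n=25, beta=0.4)
        if y.sum() < 2 or y.sum() > 23:
            continue
        null = fit_null(y, None)
        k = build_ibs_kernel(Z)
        Q = q_statistic(k, null)
        _, _, p_m = moment_matched_p(Q, k, null)
        pm.append(p_m)
        pp.append(permutation_p(k, null, n_perm=2000, seed=seed + 1))
    rho = stats.spearmanr(pm, pp).statistic
    assert rho > 0.95


# ------------------------------------------------------------ gene scan


def test_gene_scan_shape_and_causal_ranking():
    """39-gene-style scan structure on a 5-gene panel; the gene holding a
    planted causal variant attains the smallest SKAT p for its outcome in
    most seeds."""
    hits = 0
    n_seeds = 10
    for seed in range(n_seeds):
        spec = null_cohort_spec(seed=700 + seed, n=2000, n_genes=5, p=4)
        spec.effects = [PlantedEffect("var0001", "kit_ex11_557_558_del", np.log(2))]
        cohort = simulate_cohort(spec)
        om = build_outcome_matrix(cohort.mutations)
        res = gene_scan(cohort.panel, om, cohort.covariates)
        assert len(res) == 5 * 7
        tgt = res[res["outcome"] == "kit_ex11_557_558_del"].set_index("gene")
        if tgt["p"].idxmin() == "G0":
            hits += 1
    assert hits >= 8
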