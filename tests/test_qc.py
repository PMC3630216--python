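"""QC cascade: sample/variant exclusion rules, orientation, concordance,
frequency-test dispatch."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gistsig.cohort import GenotypePanel
from gistsig.outcomes import CATEGORIES, build_outcome_matrix
from gistsig.qc import (
    _one_frequency_test,
    apply_variant_filters,
    compute_maf_and_orient,
    duplicate_concordance,
    exclude_samples,
    freeman_halton_2xc,
    stratified_frequency_test,
)


def make_panel(dosages, genes=None, is_binary=None, clustering=None):
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    ids = [f"v{j}" for j in range(p)]
    variants = pd.DataFrame(
        {
            "gene": genes or ["G0"] * p,
            "ref": "A",
            "alt": "C",
            "func_class": "missense",
            "clustering_pass": clustering if clustering is not None else [True] * p,
            "is_binary": is_binary if is_binary is not None else [False] * p,
        },
        index=pd.Index(ids, name="variant_id"),
    )
    return GenotypePanel(subjects=[f"S{i}" for i in range(n)], variants=variants, dosages=dosages)


def _mutations_for(subjects, category_cycle=None):
    cats = category_cycle or ["kit_ex11_557_558_del"]
    templates = {
        "kit_ex11_557_558_del": ("KIT", 11, "deletion", 557, 558),
        "wild_type": ("none", None, None, None, None),
        "pdgfra": ("PDGFRA", 18, "point", 842, 842),
    }
    rows = [(s, *templates[cats[i % len(cats)]]) for i, s in enumerate(subjects)]
    return pd.DataFrame(
        rows, columns=["subject_id", "gene", "exon", "mutation_type", "codon_start", "codon_end"]
    )


# ---------------------------------------------------------------- samples


def test_sample_cascade_on_engineered_cohort(study_fixture):
    """52 subjects without mutation data + 2 with >10% missing calls leave
    279 of 333."""
    c = study_fixture.cohort
    panel, report = exclude_samples(c.panel, c.mutations)
    assert report.n_input == 333
    assert [r["n_excluded"] for r in report.rules] == [52, 2]
    assert panel.n_subjects == 279
    report.check_conservation()


def test_missingness_boundary_is_strict():
    """A subject at exactly 10.0% missing is retained ('more than 10%')."""
    d = np.zeros((3, 10))
    d[0, 0] = np.nan          # 10% exactly -> keep
    d[1, :2] = np.nan         # 20% -> drop
    panel = make_panel(d)
    mut = _mutations_for(panel.subjects)
    kept, report = exclude_samples(panel, mut)
    assert kept.subjects == ["S0", "S2"]
    assert report.rules[1]["excluded"] == ["S1"]


def test_no_op_when_all_complete():
    panel = make_panel(np.ones((4, 3)))
    kept, report = exclude_samples(panel, _mutations_for(panel.subjects))
    assert kept.equals(panel)
    assert report.n_retained == 4


# ------------------------------------------------------------ orientation


def test_orientation_arithmetic_and_tiebreak():
    # [0,1,1,2]: coded frequency 4/8 = 0.5; tie kept on alphabetically-first
    # allele (ref 'A' < alt 'C' -> flip so 'A' is the counted minor allele)
    panel = make_panel(np.array([[0], [1], [1], [2]], dtype=float))
    oriented = compute_maf_and_orient(panel)
    assert oriented.variants["maf"].iloc[0] == 0.5
    assert oriented.variants["minor_allele"].iloc[0] == "A"
    assert oriented.dosages[:, 0].tolist() == [2.0, 1.0, 1.0, 0.0]


def test_orientation_flips_major_coded_variant():
    panel = make_panel(np.array([[2], [2], [2], [1]], dtype=float))
    oriented = compute_maf_and_orient(panel)
    assert oriented.variants["maf"].iloc[0] == pytest.approx(1 / 8)
    assert oriented.dosages[:, 0].tolist() == [0.0, 0.0, 0.0, 1.0]


def test_monoallelic_maf_zero_and_all_missing_flagged():
    panel = make_panel(np.array([[0, np.nan], [0, np.nan], [0, np.nan]]))
    oriented = compute_maf_and_orient(panel)
    assert oriented.variants["maf"].iloc[0] == 0.0
    assert np.isnan(oriented.variants["maf"].iloc[1])
    assert oriented.variants["minor_allele"].iloc[1] is None


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_orientation_idempotent(seed):
    rng = np.random.default_rng(seed)
    d = rng.integers(0, 3, size=(12, 4)).astype(float)
    d[rng.random(d.shape) < 0.1] = np.nan
    once = compute_maf_and_orient(make_panel(d))
    twice = compute_maf_and_orient(once)
    assert np.array_equal(once.dosages, twice.dosages, equal_nan=True)
    assert once.variants["maf"].equals(twice.variants["maf"])


# ------------------------------------------------------------- variants


def test_variant_cascade_on_engineered_panel(study_fixture):
    """3 mono-allelic + 6 below 5% MAF + 7 poor clustering + 1 homozygote-rule
    violation leave 208 of 225."""
    c = study_fixture.cohort
    panel, _ = exclude_samples(c.panel, c.mutations)
    panel = compute_maf_and_orient(panel)
    outcomes = build_outcome_matrix(c.mutations[c.mutations["subject_id"].isin(panel.subjects)])
    kept, report = apply_variant_filters(panel, outcomes)
    assert report.n_input == 225
    assert [r["n_excluded"] for r in report.rules] == [3, 6, 7, 1]
    assert kept.n_variants == 208
    report.check_conservation()


def test_maf_boundary_is_strict():
    """MAF exactly 0.05 survives the 'less than 5%' rule."""
    d = np.zeros((20, 2))
    d[:2, 0] = 1.0  # freq 2/40 = 0.05 -> retained
    d[0, 1] = 1.0   # freq 1/40 = 0.025 -> excluded
    panel = compute_maf_and_orient(make_panel(d))
    outcomes = build_outcome_matrix(_mutations_for(panel.subjects))
    kept, report = apply_variant_filters(panel, outcomes, homozygote_rule="off")
    assert kept.variant_ids == ["v0"]
    assert report.rules[1]["excluded"] == ["v1"]


def test_filter_identity_when_all_pass():
    rng = np.random.default_rng(0)
    d = rng.integers(0, 3, size=(60, 3)).astype(float)
    d[0, :] = 2.0  # guarantee minor homozygotes
    panel = compute_maf_and_orient(make_panel(d))
    outcomes = build_outcome_matrix(
        _mutations_for(panel.subjects, ["kit_ex11_557_558_del", "wild_type"])
    )
    kept, report = apply_variant_filters(panel, outcomes, homozygote_rule="off")
    assert kept.variant_ids == panel.variant_ids
    assert report.n_retained == 3


# ----------------------------------------------------------- concordance


def test_duplicate_concordance_identity_and_arithmetic():
    rng = np.random.default_rng(1)
    row = rng.integers(0, 3, size=1000).astype(float)
    dup = row.copy()
    dup[0] = (dup[0] + 1) % 3  # one discordant call of 1000
    panel = make_panel(np.stack([row, row, dup]).reshape(3, -1))
    res = duplicate_concordance(panel, [("S0", "S1"), ("S0", "S2")])
    assert res.iloc[0]["concordance"] == 1.0
    assert res.iloc[1]["concordance"] == pytest.approx(0.999)


def test_concordance_excludes_missing_from_denominator():
    a = np.array([0.0, 1.0, np.nan, 2.0])
    b = np.array([0.0, np.nan, 1.0, 1.0])
    panel = make_panel(np.stack([a, b]))
    res = duplicate_concordance(panel, [("S0", "S1")])
    assert res.iloc[0]["n_joint"] == 2  # only positions 0 and 3
    assert res.iloc[0]["concordance"] == pytest.approx(0.5)


def test_pair_with_no_joint_calls_flagged():
    a = np.array([np.nan, 1.0])
    b = np.array([0.0, np.nan])
    panel = make_panel(np.stack([a, b]))
    res = duplicate_concordance(panel, [("S0", "S1")])
    assert bool(res.iloc[0]["undefined"])
    assert np.isnan(res.iloc[0]["concordance"])


# ------------------------------------------------- frequency-test dispatch


def test_chi2_matches_textbook_formula():
    table = np.array([[50, 40, 10], [45, 44, 11]])
    stat, p, used = _one_frequency_test(table)
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    expected = np.outer(row, col) / table.sum()
    by_hand = ((table - expected) ** 2 / expected).sum()
    assert used == "chi2"
    assert stat == pytest.approx(by_hand)


def test_proportional_rows_give_zero_statistic():
    stat, p, used = _one_frequency_test(np.array([[20, 20, 10], [40, 40, 20]]))
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_small_cell_dispatches_to_exact_test():
    _, p, used = _one_frequency_test(np.array([[3, 10, 8], [7, 9, 6]]))
    assert used == "fisher"
    assert 0 < p <= 1


def test_freeman_halton_agrees_with_scipy_on_2x2():
    for table in ([[3, 7], [9, 2]], [[1, 9], [8, 3]], [[5, 5], [5, 5]]):
        _, p_scipy = stats.fisher_exact(np.array(table))
        assert freeman_halton_2xc(np.array(table)) == pytest.approx(p_scipy, rel=1e-8)


@given(st.lists(st.integers(0, 30), min_size=6, max_size=6))
@settings(max_examples=60, deadline=None)
def test_dispatch_is_pure_function_of_table(cells):
    table = np.array(cells).reshape(2, 3)
    nonzero = table[:, table.sum(axis=0) > 0]
    _, _, used = _one_frequency_test(table)
    if nonzero.shape[1] < 2 or (nonzero.sum(axis=1) == 0).any():
        assert used == "none"
    elif (nonzero < 5).any():
        assert used == "fisher"
    else:
        assert used == "chi2"


def test_stratified_test_by_race(small_cohort):
    panel = compute_maf_and_orient(small_cohort.panel)
    res = stratified_frequency_test(panel, covariates=small_cohort.covariates)
    assert len(res) == panel.n_variants
    assert set(res["test"].unique()) <= {"chi2", "fisher", "none"}
    valid = res.dropna(subset=["p"])
    assert ((valid["p"] > 0) & (valid["p"] <= 1)).all()
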