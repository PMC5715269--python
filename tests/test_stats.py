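"""Statistical machinery: summary tests, residualization, permutation,
partial correlation."""

import numpy as np
import pytest
from scipy import stats as sps

import wmnet as w


# --- Welch t from summaries -------------------------------------------------


@pytest.mark.parametrize(
    "summ, expected_t",
    [
        ((38.00, 11.85, 30, 37.47, 11.95, 62), 0.201),
        ((14.07, 3.34, 30, 15.42, 2.95, 62), -1.889),
        ((2.93, 1.46, 30, 0.19, 0.51, 62), 9.987),
    ],
)
def test_welch_t_reproduces_group_summaries(summ, expected_t):
    res = w.welch_t_from_summary(*summ)
    assert res.statistic == pytest.approx(expected_t, rel=0.01)


def test_welch_identical_summaries():
    res = w.welch_t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
    assert res.statistic == 0.0 and res.p == 1.0


def test_welch_summary_equals_raw_sample():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 30)
    res = w.welch_t_from_summary(
        a.mean(), a.std(ddof=1), 20, b.mean(), b.std(ddof=1), 30
    )
    t_raw, p_raw = sps.ttest_ind(a, b, equal_var=False)
    assert res.statistic == pytest.approx(t_raw, abs=1e-12)
    assert res.p == pytest.approx(p_raw, abs=1e-12)


def test_welch_errors():
    with pytest.raises(ValueError, match=">= 2"):
        w.welch_t_from_summary(1, 1, 1, 2, 1, 10)
    with pytest.raises(ValueError, match="zero variance"):
        w.welch_t_from_summary(1, 0, 10, 2, 0, 10)


# --- chi-square -------------------------------------------------------------


@pytest.mark.parametrize(
    "table, expected",
    [
        ((15, 15, 26, 36), 0.532),
        ((10, 10, 20, 20), 0.0),
        ((5, 0, 0, 5), 10.0),  # N(ad-bc)^2/(r1 r2 c1 c2) = 10*625/625... closed form
    ],
)
def test_chi_square_values(table, expected):
    res = w.chi_square_2x2(*table)
    assert res.statistic == pytest.approx(expected, rel=0.01, abs=1e-12)
    assert res.df == 1.0


def test_chi_square_matches_scipy():
    obs = np.array([[15, 15], [26, 36]])
    chi2, p, _, _ = sps.chi2_contingency(obs, correction=False)
    res = w.chi_square_2x2(15, 15, 26, 36)
    assert res.statistic == pytest.approx(chi2, abs=1e-12)
    assert res.p == pytest.approx(p, abs=1e-12)


def test_chi_square_zero_marginal():
    with pytest.raises(ValueError, match="marginal"):
        w.chi_square_2x2(0, 0, 5, 5)


# --- residualization --------------------------------------------------------


def test_residualize_exact_linear_combination():
    rng = np.random.default_rng(1)
    covs = rng.normal(size=(40, 3))
    y = 2.0 + covs @ np.array([1.0, -2.0, 0.5])
    assert np.max(np.abs(w.residualize(y, covs))) <= 1e-10


def test_residualize_orthogonal_covariates_center_only():
    rng = np.random.default_rng(2)
    covs = rng.normal(size=(50, 2))
    y = rng.normal(size=50)
    # make y exactly orthogonal to covariates and the intercept
    design = np.column_stack([np.ones(50), covs])
    y = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    y_shift = y + 3.7
    assert np.allclose(w.residualize(y_shift, covs), y_shift - y_shift.mean(), atol=1e-10)


def test_residualize_matches_pinv_oracle_and_orthogonality():
    rng = np.random.default_rng(3)
    covs = rng.normal(size=(30, 4))
    y = rng.normal(size=30)
    design = np.column_stack([np.ones(30), covs])
    oracle = y - design @ (np.linalg.pinv(design.T @ design) @ design.T @ y)
    res = w.residualize(y, covs)
    assert np.allclose(res, oracle, atol=1e-10)
    for k in range(4):
        assert abs(np.corrcoef(res, covs[:, k])[0, 1]) <= 1e-10


def test_residualize_rank_deficiency_named():
    rng = np.random.default_rng(4)
    a = rng.normal(size=30)
    covs = np.column_stack([a, 2 * a])
    with pytest.raises(ValueError, match="collinear"):
        w.residualize(rng.normal(size=30), covs)


def test_covariate_matrix_constant_rejected():
    table = w.generate_cohort(w.CohortSpec(n_is=3, n_nis=3, seed=0)).copy()
    table["age"] = 40.0
    with pytest.raises(ValueError, match="constant"):
        w.covariate_matrix(table)


# --- permutation test -------------------------------------------------------


def test_permutation_identical_values_p_one():
    res = w.permutation_group_test(np.ones(10), np.arange(10) < 5, n_perm=99, seed=0)
    assert res.p == 1.0


def test_permutation_exhaustive_enumeration():
    """{10,10} vs {0,0}: 2 of C(4,2)=6 assignments reach |diff| = 10."""
    vals = np.array([10.0, 10.0, 0.0, 0.0])
    res = w.permutation_group_test(
        vals, np.array([True, True, False, False]), exhaustive=True
    )
    assert res.statistic == 10.0
    assert res.p == pytest.approx(2 / 6)


def test_permutation_exhaustive_invariant_to_subject_order():
    rng = np.random.default_rng(5)
    vals = rng.normal(size=8)
    labels = np.arange(8) < 3
    p0 = w.permutation_group_test(vals, labels, exhaustive=True).p
    perm = rng.permutation(8)
    p1 = w.permutation_group_test(vals[perm], labels[perm], exhaustive=True).p
    assert p0 == p1


def test_permutation_seed_determinism_and_floor():
    rng = np.random.default_rng(6)
    vals = np.concatenate([rng.normal(3, 1, 10), rng.normal(0, 1, 10)])
    labels = np.arange(20) < 10
    a = w.permutation_group_test(vals, labels, n_perm=199, seed=42)
    b = w.permutation_group_test(vals, labels, n_perm=199, seed=42)
    assert a.p == b.p and a.statistic == b.statistic
    assert a.p >= 1 / 200  # smoothing floor
    assert a.direction == 1


def test_permutation_t_statistic_variant():
    rng = np.random.default_rng(7)
    vals = np.concatenate([rng.normal(1, 1, 12), rng.normal(0, 1, 15)])
    labels = np.arange(27) < 12
    res = w.permutation_group_test(vals, labels, n_perm=199, seed=0, statistic="t")
    t_ref, _ = sps.ttest_ind(vals[labels], vals[~labels], equal_var=False)
    assert res.statistic == pytest.approx(t_ref, abs=1e-10)


def test_permutation_empty_group_error():
    with pytest.raises(ValueError, match="non-empty"):
        w.permutation_group_test(np.ones(5), np.zeros(5, dtype=bool))


# --- partial correlation ----------------------------------------------------


def test_partial_correlation_self_is_one():
    x = np.arange(10, dtype=float)
    res = w.partial_correlation(x, x, None)
    assert res.statistic == pytest.approx(1.0)


def test_partial_correlation_reduces_to_pearson():
    rng = np.random.default_rng(8)
    x, y = rng.normal(size=25), rng.normal(size=25)
    res = w.partial_correlation(x, y, None)
    r_ref, p_ref = sps.pearsonr(x, y)
    assert res.statistic == pytest.approx(r_ref, abs=1e-12)
    assert res.p == pytest.approx(p_ref, rel=1e-9)


def test_partial_correlation_double_residual_oracle():
    rng = np.random.default_rng(9)
    covs = rng.normal(size=(30, 3))
    x = covs @ np.array([1.0, 0.5, -1.0]) + rng.normal(size=30)
    y = covs @ np.array([-0.5, 1.0, 0.0]) + 0.5 * x + rng.normal(size=30)
    design = np.column_stack([np.ones(30), covs])
    h = design @ np.linalg.pinv(design.T @ design) @ design.T
    rx, ry = x - h @ x, y - h @ y
    r_oracle = float(rx @ ry / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    res = w.partial_correlation(x, y, covs)
    assert res.statistic == pytest.approx(r_oracle, abs=1e-10)
    assert res.df == 30 - 2 - 3


def test_partial_correlation_zero_variance_error():
    with pytest.raises(ValueError, match="zero variance"):
        w.partial_correlation(np.ones(10), np.arange(10.0), None)


# --- 1/N threshold ----------------------------------------------------------


@pytest.mark.parametrize("n, alpha", [(90, 1 / 90), (1, 1.0), (100, 0.01)])
def test_false_positive_threshold(n, alpha):
    assert w.false_positive_threshold(n) == pytest.approx(alpha)
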