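"""Survival engine vs closed forms, brute-force oracles and lifelines."""

import numpy as np
import pandas as pd
import pytest
from conftest import tiny_instances
from oracles import cox_argmax_oracle, km_oracle, logrank_oracle

from saspsurv.survival import (cox_fit, cv_lambda_min, km_estimate,
                               linear_predictor, logrank_test, ridge_cox_fit,
                               two_group_cox)


# ---------------------------------------------------------------------------
# Kaplan-Meier

def test_km_all_censored_is_flat():
    km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
    assert km.times.size == 0
    assert km.survival_at(10.0) == 1.0


def test_km_closed_form_all_events():
    km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
    assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])


def test_km_matches_exponential_and_oracle():
    rng = np.random.default_rng(3)
    t = rng.exponential(2.0, 200)
    e = np.ones(200, dtype=int)
    km = km_estimate(t, e)
    ts, surv = km_oracle(t, e)
    assert np.allclose(km.times, ts)
    assert np.allclose(km.survival, surv, atol=1e-12)
    sup = max(abs(km.survival_at(x) - np.exp(-0.5 * x))
              for x in np.linspace(0.1, 5, 50))
    assert sup < 0.12  # DKW-style simulation bound at n=200


def test_km_event_precedes_censoring_at_tie():
    # censored subject at t=2 is still at risk for the death at t=2
    km = km_estimate([1, 2, 2, 3], [1, 1, 0, 0])
    assert np.allclose(km.survival, [0.75, 0.75 * (1 - 1 / 3)])


# ---------------------------------------------------------------------------
# Log-rank

def test_logrank_identical_groups_null():
    t = [1, 2, 3, 4.0]
    e = [1, 0, 1, 1]
    chi2, p = logrank_test(t, e, t, e)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_label_symmetry_and_oracle():
    rng = np.random.default_rng(4)
    ta, tb = rng.exponential(1, 30), rng.exponential(2, 40)
    ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 40)
    chi2_ab, _ = logrank_test(ta, ea, tb, eb)
    chi2_ba, _ = logrank_test(tb, eb, ta, ea)
    assert chi2_ab == pytest.approx(chi2_ba, abs=1e-12)
    assert chi2_ab == pytest.approx(logrank_oracle(ta, ea, tb, eb),
                                    abs=1e-10)


def test_logrank_six_patient_hand_instance():
    ta, ea = [1.0, 3.0, 5.0], [1, 1, 0]
    tb, eb = [2.0, 4.0, 6.0], [1, 0, 1]
    chi2, p = logrank_test(ta, ea, tb, eb)
    assert chi2 == pytest.approx(logrank_oracle(ta, ea, tb, eb), abs=1e-10)
    assert 0 <= p <= 1


def test_logrank_no_events_degenerate():
    chi2, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
    assert (chi2, p) == (0.0, 1.0)


# ---------------------------------------------------------------------------
# Cox

def test_cox_constant_covariate_is_null():
    fit = cox_fit([1, 2, 3, 4], [1, 1, 0, 1], np.ones((4, 1)))
    assert fit.beta[0] == pytest.approx(0.0, abs=1e-10)
    assert fit.hr[0] == pytest.approx(1.0)


def test_cox_four_patient_grid_oracle():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([1, 1, 1, 0])
    x = np.array([1.0, 0.0, 1.0, 0.0])
    beta_star, boundary = cox_argmax_oracle(t, e, x)
    assert not boundary
    fit = cox_fit(t, e, x[:, None])
    assert fit.beta[0] == pytest.approx(beta_star, abs=1e-4)


@pytest.mark.parametrize("ties", ["efron", "breslow"])
def test_cox_tiny_instances_match_grid_oracle(ties):
    checked = 0
    for t, e, x in tiny_instances():
        beta_star, boundary = cox_argmax_oracle(t, e, x, ties=ties)
        with np.errstate(all="ignore"):
            fit = cox_fit(t, e, x[:, None], ties=ties)
        if boundary or not fit.converged:
            # both routes must agree the likelihood is monotone
            assert boundary or not fit.converged
            continue
        assert fit.beta[0] == pytest.approx(beta_star, abs=1e-4)
        checked += 1
    assert checked >= 20


def test_cox_monotone_likelihood_flagged():
    with pytest.warns(RuntimeWarning):
        fit = cox_fit([1.0, 2.0], [1, 1], np.array([[1.0], [0.0]]))
    assert not fit.converged


def test_cox_matches_lifelines_multivariate():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(5)
    n = 150
    X = rng.standard_normal((n, 3))
    t = np.round(rng.exponential(1 / (0.3 * np.exp(X @ [0.6, -0.4, 0]))), 1)
    t = np.clip(t, 0.1, None)
    e = (t < 3).astype(int)
    t = np.minimum(t, 3.0)
    fit = cox_fit(t, e, X)
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    df["T"], df["E"] = t, e
    ll = lifelines.CoxPHFitter().fit(df, "T", "E")
    assert np.allclose(fit.beta, ll.params_.to_numpy(), atol=1e-5)
    assert np.allclose(fit.se, ll.standard_errors_.to_numpy(), atol=1e-5)
    assert np.allclose(fit.p, ll.summary["p"].to_numpy(), atol=1e-5)


def test_cox_wald_close_to_logrank_two_group():
    rng = np.random.default_rng(6)
    n = 300
    g = np.repeat([0, 1], n // 2).astype(float)
    t = rng.exponential(1 / (0.4 * np.exp(0.25 * g)))
    e = (t < 4).astype(int)
    t = np.minimum(t, 4.0)
    fit = cox_fit(t, e, g[:, None])
    _, p_lr = logrank_test(t[g == 1], e[g == 1], t[g == 0], e[g == 0])
    assert fit.p[0] == pytest.approx(p_lr, rel=0.2)


# ---------------------------------------------------------------------------
# Ridge Cox

@pytest.fixture(scope="module")
def medium_instance():
    rng = np.random.default_rng(7)
    n = 120
    X = rng.standard_normal((n, 4))
    t = rng.exponential(1 / (0.3 * np.exp(X @ [0.5, 0, -0.3, 0])))
    e = (t < 5).astype(int)
    return np.minimum(t, 5.0), e, X


def test_ridge_zero_lambda_reduces_to_cox(medium_instance):
    t, e, X = medium_instance
    rf = ridge_cox_fit(t, e, X, 0.0)
    Z = (X - X.mean(0)) / X.std(0)
    cf = cox_fit(t, e, Z)
    assert np.allclose(rf.beta, cf.beta, atol=1e-6)


def test_ridge_huge_lambda_shrinks_to_zero(medium_instance):
    t, e, X = medium_instance
    rf = ridge_cox_fit(t, e, X, 1e8)
    assert np.max(np.abs(rf.beta)) < 1e-4


def test_ridge_duplicated_columns_split_equally(medium_instance):
    t, e, X = medium_instance
    XX = np.column_stack([X[:, 0], X[:, 0], X[:, 1]])
    rf = ridge_cox_fit(t, e, XX, 2.0)
    assert rf.beta[0] == pytest.approx(rf.beta[1], abs=1e-6)


@pytest.mark.parametrize("seed", range(5))
def test_ridge_norm_monotone_in_lambda(seed):
    rng = np.random.default_rng(100 + seed)
    n = 80
    X = rng.standard_normal((n, 3))
    t = rng.exponential(1 / (0.3 * np.exp(0.5 * X[:, 0])))
    e = (t < 5).astype(int)
    t = np.minimum(t, 5.0)
    norms = [np.linalg.norm(ridge_cox_fit(t, e, X, lam).beta)
             for lam in np.geomspace(1e-3, 1e3, 8)]
    assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))


def test_linear_predictor_uses_training_standardization(medium_instance):
    t, e, X = medium_instance
    rf = ridge_cox_fit(t, e, X, 1.0)
    scores = linear_predictor(rf, X)
    # duplicated rows score identically (pointwise function)
    assert np.allclose(linear_predictor(rf, np.vstack([X, X]))[:len(X)],
                       scores)
    # shifting a covariate at application time shifts scores: no re-centering
    shifted = X.copy()
    shifted[:, 0] += 10.0
    assert not np.allclose(linear_predictor(rf, shifted), scores)


def test_zero_model_scores_zero(medium_instance):
    t, e, X = medium_instance
    rf = ridge_cox_fit(t, e, X, 1e12)
    assert np.allclose(linear_predictor(rf, X), 0.0, atol=1e-6)


# ---------------------------------------------------------------------------
# Cross-validated penalty

def test_cv_singleton_grid(medium_instance):
    t, e, X = medium_instance
    lam, curve = cv_lambda_min(t, e, X, lambda_grid=[3.3], n_folds=3, seed=0)
    assert lam == 3.3
    assert len(curve) == 1


def test_cv_deterministic(medium_instance):
    t, e, X = medium_instance
    grid = np.geomspace(1e-2, 1e2, 6)
    lam1, _ = cv_lambda_min(t, e, X, lambda_grid=grid, n_folds=5, seed=9)
    lam2, _ = cv_lambda_min(t, e, X, lambda_grid=grid, n_folds=5, seed=9)
    assert lam1 == lam2


def test_cv_shrinks_under_null_and_relaxes_under_signal():
    grid = np.geomspace(1e-3, 1e3, 10)
    upper_null = 0
    lower_signal = 0
    n_seeds = 10
    for seed in range(n_seeds):
        rng = np.random.default_rng(200 + seed)
        # pure noise covariates
        Xn = rng.standard_normal((150, 5))
        tn = rng.exponential(1 / 0.3, 150)
        en = (tn < 5).astype(int)
        lam, _ = cv_lambda_min(np.minimum(tn, 5), en, Xn, lambda_grid=grid,
                               n_folds=5, seed=seed)
        upper_null += lam >= grid[5]
        # strong single-covariate signal
        Xs = rng.standard_normal((300, 5))
        ts = rng.exponential(1 / (0.3 * np.exp(1.5 * Xs[:, 0])))
        es = (ts < 5).astype(int)
        lam, _ = cv_lambda_min(np.minimum(ts, 5), es, Xs, lambda_grid=grid,
                               n_folds=5, seed=seed)
        lower_signal += lam <= grid[4]
    assert upper_null >= 0.8 * n_seeds
    assert lower_signal >= 0.8 * n_seeds


def test_two_group_degenerate_labels_flagged():
    res = two_group_cox([1, 2, 3], [1, 1, 0], [True, True, True])
    assert res["flagged"] and np.isnan(res["hr"])
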