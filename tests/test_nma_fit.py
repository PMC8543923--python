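"""GLS fitting, design matrices, DL and REML heterogeneity estimation.

The two-treatment limit is checked against independent classical
pairwise meta-analysis oracles implemented here from the textbook
formulas (inverse-variance pooling, the DerSimonian-Laird moment
estimator, and a golden-section search on the scalar restricted
likelihood) — never via the package's own GLS code path.
"""

import numpy as np
import pytest

from netdbt.contrasts import build_contrast_set
from netdbt.exceptions import EstimationError
from netdbt.inconsistency import dbt_test
from netdbt.nma_fit import (
    build_design_matrices,
    cochran_q,
    estimate_tau2_dl,
    estimate_tau2_reml,
    fit_consistency,
    gls_fit,
    pairwise_contrasts,
)
from netdbt.synthetic_data import simulate_network, triangle_config

from conftest import make_dataset, manual_contrast_set, random_config


# ---------------------------------------------------------------- oracles

def oracle_pooled(y, v, tau2=0.0):
    w = 1.0 / (v + tau2)
    return float(np.sum(w * y) / np.sum(w)), float(1.0 / np.sum(w))


def oracle_dl(y, v):
    """Classical DerSimonian-Laird: (Q - df) / (sum w - sum w^2 / sum w)."""
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu) ** 2))
    df = len(y) - 1
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(0.0, (q - df) / c)


def oracle_reml(y, v, upper=None, tol=1e-12):
    """Scalar pairwise REML by golden-section search on [0, upper]."""

    def nll(t2):
        s = v + t2
        w = 1.0 / s
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (np.sum(np.log(s)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2))

    if upper is None:
        upper = 10.0 * oracle_dl(y, v) + 1.0
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = 0.0, upper
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = nll(c), nll(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = nll(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = nll(d)
    t2 = (a + b) / 2.0
    return 0.0 if nll(0.0) <= nll(t2) else t2


def pairwise_cs(y, v):
    return manual_contrast_set(
        [(f"s{i}", ("A", "B"), [yi], [[vi]]) for i, (yi, vi) in enumerate(zip(y, v))]
    )


# ------------------------------------------------------- design matrices

class TestDesignMatrices:
    def test_triangle_dimensions_and_rank_gap(self, triangle_designs):
        dm = build_design_matrices(build_contrast_set(make_dataset(triangle_designs)))
        assert dm.X.shape == (6, 2)
        assert dm.X_dbt.shape == (6, 3)
        assert (dm.rank_x, dm.rank_dbt) == (2, 3)
        assert dm.df_inconsistency == 1

    def test_single_design_dbt_equals_consistency(self):
        dm = build_design_matrices(build_contrast_set(make_dataset([("A", "B", "C")])))
        np.testing.assert_allclose(dm.X_dbt, dm.X)
        assert dm.df_inconsistency == 0

    def test_mixed_designs_embedding_shape(self):
        dm = build_design_matrices(
            build_contrast_set(make_dataset([("A", "B", "C"), ("A", "B")]))
        )
        assert dm.X_dbt.shape == (3, 3)
        assert dm.A.shape == (3, 2)
        assert dm.df_inconsistency == 1
        np.testing.assert_allclose(dm.X_dbt @ dm.A, dm.X)

    def test_unknown_reference_errors(self, triangle_designs):
        cs = build_contrast_set(make_dataset(triangle_designs))
        with pytest.raises(Exception, match="reference"):
            build_design_matrices(cs, reference="Z")


# ------------------------------------------------------------------- GLS

class TestGls:
    def test_inverse_variance_average_by_hand(self):
        cs = pairwise_cs([0.5, 1.0], [0.1, 0.1])
        dm = build_design_matrices(cs)
        fit = gls_fit(cs, dm.X, 0.0)
        assert fit.estimates[0] == pytest.approx(0.75, abs=1e-12)
        assert fit.covariance[0, 0] == pytest.approx(0.05, abs=1e-12)

    def test_tau2_shifts_variance_not_estimate(self):
        cs = pairwise_cs([0.5, 1.0], [0.1, 0.1])
        dm = build_design_matrices(cs)
        fit = gls_fit(cs, dm.X, 0.1)
        assert fit.estimates[0] == pytest.approx(0.75, abs=1e-12)
        assert fit.covariance[0, 0] == pytest.approx(0.1, abs=1e-12)

    def test_negative_tau2_rejected(self):
        cs = pairwise_cs([0.5], [0.1])
        dm = build_design_matrices(cs)
        with pytest.raises(ValueError):
            gls_fit(cs, dm.X, -0.5)


class TestCochranQ:
    def test_hand_computed_q_and_i2(self):
        # equal weights w=5: Q = 5*((0-1)^2 + (2-1)^2) = 10, df = 1, I2 = 90%
        cs = pairwise_cs([0.0, 2.0], [0.2, 0.2])
        dm = build_design_matrices(cs)
        q, q_df, i2 = cochran_q(cs, dm.X)
        assert q == pytest.approx(10.0, abs=1e-10)
        assert q_df == 1
        assert i2 == pytest.approx(90.0, abs=1e-8)

    def test_homogeneous_data_zero_q(self):
        cs = pairwise_cs([0.4, 0.4, 0.4], [0.1, 0.1, 0.1])
        dm = build_design_matrices(cs)
        q, q_df, i2 = cochran_q(cs, dm.X)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert i2 == 0.0

    def test_i2_undefined_at_zero_df(self):
        cs = pairwise_cs([0.4], [0.1])
        dm = build_design_matrices(cs)
        _, q_df, i2 = cochran_q(cs, dm.X)
        assert q_df == 0 and i2 is None

    def test_nested_models_q_ordering(self):
        ds = simulate_network(triangle_config(2, 1000, omega_bc=1.0), 9)
        cs = build_contrast_set(ds)
        dm = build_design_matrices(cs)
        q_cons, _, _ = cochran_q(cs, dm.X)
        q_dbt, _, _ = cochran_q(cs, dm.X_dbt)
        assert q_cons >= q_dbt


# ----------------------------------------------------- tau^2 estimators

class TestHeterogeneityEstimators:
    def test_dl_matches_classical_formula_on_five_studies(self):
        y = np.array([0.2, 0.5, -0.1, 0.8, 0.4])
        v = np.array([0.05, 0.1, 0.08, 0.2, 0.12])
        cs = pairwise_cs(y, v)
        dm = build_design_matrices(cs)
        assert estimate_tau2_dl(cs, dm.X) == pytest.approx(oracle_dl(y, v), abs=1e-10)

    def test_homogeneous_data_gives_zero_for_both(self):
        cs = pairwise_cs([0.4, 0.4, 0.4], [0.1, 0.1, 0.1])
        dm = build_design_matrices(cs)
        assert estimate_tau2_dl(cs, dm.X) == 0.0
        assert estimate_tau2_reml(cs, dm.X) == 0.0

    def test_zero_df_raises(self):
        cs = pairwise_cs([0.4], [0.1])
        dm = build_design_matrices(cs)
        with pytest.raises(EstimationError, match="not estimable"):
            estimate_tau2_dl(cs, dm.X)
        with pytest.raises(EstimationError, match="not estimable"):
            estimate_tau2_reml(cs, dm.X)

    def test_pairwise_limit_matches_oracles(self):
        """NMA machinery reduces to classical pairwise DL/REML (20 datasets)."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            k = int(rng.integers(3, 11))
            v = rng.uniform(0.03, 0.3, size=k)
            y = rng.normal(0.3, np.sqrt(v + 0.1))
            cs = pairwise_cs(y, v)
            dm = build_design_matrices(cs)
            t2_dl = estimate_tau2_dl(cs, dm.X)
            t2_reml = estimate_tau2_reml(cs, dm.X)
            assert t2_dl == pytest.approx(oracle_dl(y, v), abs=1e-6)
            assert t2_reml == pytest.approx(oracle_reml(y, v), abs=1e-6)
            fit = gls_fit(cs, dm.X, t2_reml)
            mu, var = oracle_pooled(y, v, t2_reml)
            assert fit.estimates[0] == pytest.approx(mu, abs=1e-8)
            assert fit.covariance[0, 0] == pytest.approx(var, abs=1e-8)

    def test_monte_carlo_tau_recovery_on_large_triangle(self):
        """With 200 studies per design at tau=0.3 both estimators land nearby."""
        cfg = triangle_config(studies_per_design=200, n_per_arm=1000, tau=0.3)
        cs = build_contrast_set(simulate_network(cfg, 123))
        dm = build_design_matrices(cs)
        for est in (estimate_tau2_dl, estimate_tau2_reml):
            assert 0.25 <= np.sqrt(est(cs, dm.X)) <= 0.35


def test_network_reml_matches_multivariate_reference_values():
    """Frozen cross-check against an independent multivariate meta-analysis
    fit (metafor's rma.mv with an i.i.d. study random effect, which is this
    exact model when every study is two-arm): REML tau^2 of both models and
    the consistency-model coefficients on one fixed simulated triangle."""
    cfg = triangle_config(studies_per_design=6, n_per_arm=500, tau=0.25, omega_bc=0.4)
    cs = build_contrast_set(simulate_network(cfg, 77))
    dm = build_design_matrices(cs)
    assert estimate_tau2_reml(cs, dm.X) == pytest.approx(0.1000999909, abs=1e-6)
    assert estimate_tau2_reml(cs, dm.X_dbt) == pytest.approx(0.0899383426, abs=1e-6)
    fit = fit_consistency(cs, estimator="reml", dm=dm)
    np.testing.assert_allclose(
        fit.estimates, [0.1440811210, 0.7063154052], atol=1e-6
    )


# --------------------------------------------------- reference invariance

def test_reference_choice_does_not_change_inference():
    """Pairwise effects, tau^2, Q and the DBT p-value ignore the reference."""
    rng = np.random.default_rng(77)
    cfg = random_config(rng, max_treatments=4, tau=0.1)
    cs = build_contrast_set(simulate_network(cfg, 55))
    fits = {}
    for ref in cfg.treatments[:2]:
        dm = build_design_matrices(cs, reference=ref)
        fits[ref] = fit_consistency(cs, estimator="dl", dm=dm)
    r1, r2 = [fits[r] for r in cfg.treatments[:2]]
    assert r1.tau2 == pytest.approx(r2.tau2, abs=1e-10)
    assert r1.Q == pytest.approx(r2.Q, abs=1e-8)
    pw1 = pairwise_contrasts(r1).set_index(["treat1", "treat2"])
    pw2 = pairwise_contrasts(r2).set_index(["treat1", "treat2"])
    np.testing.assert_allclose(pw1["estimate"], pw2["estimate"], atol=1e-8)
    np.testing.assert_allclose(pw1["se"], pw2["se"], atol=1e-8)
    p1 = dbt_test(cs, estimator="dl", reference=cfg.treatments[0]).p_value
    p2 = dbt_test(cs, estimator="dl", reference=cfg.treatments[1]).p_value
    assert p1 == pytest.approx(p2, abs=1e-10)
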