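"""GLS fitting of consistency and design-by-treatment interaction models.

Both models are weighted linear models for the stacked baseline contrasts
y with covariance Sigma(tau^2) = S + tau^2 * P:

* consistency model  y = X beta + eps, with beta the T-1 basic log odds
  ratios versus a reference treatment, every contrast expressed as a
  difference of treatment effects;
* DBT model          y = X_dbt theta + eps, with a separate set of t_d - 1
  relative effects per design, so each design may disagree with the rest
  of the network.

The consistency model is nested in the DBT model through the embedding
theta = A beta; the number of inconsistency parameters is
rank(X_dbt) - rank(X).  A single heterogeneity variance tau^2 is shared by
all comparisons (compound-symmetry P), estimated either by a matrix
generalisation of the DerSimonian-Laird moment method or by restricted
maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .contrasts import ContrastSet
from .exceptions import EstimationError, NetworkValidationError

__all__ = [
    "DesignMatrices",
    "FitResult",
    "build_design_matrices",
    "gls_fit",
    "cochran_q",
    "estimate_tau2_dl",
    "estimate_tau2_reml",
    "fit_consistency",
    "fit_dbt",
    "pairwise_contrasts",
]

RANK_TOL = 1e-8  # relative to the largest singular value


def _rank(M: np.ndarray) -> int:
    if M.size == 0:
        return 0
    s = np.linalg.svd(M, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > RANK_TOL * s[0]))


def _sym_pinv(G: np.ndarray) -> np.ndarray:
    """Moore-Penrose inverse of a symmetric PSD matrix via eigendecomposition."""
    w, V = np.linalg.eigh((G + G.T) / 2.0)
    tol = RANK_TOL * max(w.max(initial=0.0), 0.0) if w.size else 0.0
    inv = np.where(w > tol, 1.0 / np.where(w > tol, w, 1.0), 0.0)
    return (V * inv) @ V.T


def _log_pdet(G: np.ndarray) -> float:
    """Log pseudo-determinant (product of eigenvalues above tolerance)."""
    w = np.linalg.eigh((G + G.T) / 2.0)[0]
    tol = RANK_TOL * max(w.max(initial=0.0), 0.0) if w.size else 0.0
    keep = w[w > tol]
    return float(np.sum(np.log(keep)))


@dataclass(frozen=True)
class DesignMatrices:
    """Design matrices of the two nested models plus the embedding map.

    ``X`` maps basic parameters (treatments versus ``reference``) to
    contrasts; ``X_dbt`` gives every design its own parameters, labelled by
    ``dbt_params`` as (design, treatment-vs-design-baseline) pairs; ``A``
    satisfies X_dbt @ A == X, i.e. theta = A beta under consistency.
    """

    X: np.ndarray
    X_dbt: np.ndarray
    A: np.ndarray
    treatments: tuple[str, ...]
    reference: str
    basic_params: tuple[str, ...]
    dbt_params: tuple[tuple[str, str], ...]
    rank_x: int
    rank_dbt: int

    @property
    def df_inconsistency(self) -> int:
        return self.rank_dbt - self.rank_x


def build_design_matrices(cs: ContrastSet, reference: str | None = None) -> DesignMatrices:
    """Construct X, X_dbt and A with deterministic column ordering.

    Treatments are sorted; designs are sorted by their canonical label;
    within a design the parameters are the non-baseline treatments in
    sorted order, with the design baseline its smallest treatment label.
    """
    treatments = tuple(cs.treatments)
    if reference is None:
        reference = treatments[0]
    if reference not in treatments:
        raise NetworkValidationError(
            f"reference treatment '{reference}' is not in the network"
        )
    basic = tuple(t for t in treatments if t != reference)
    basic_col = {t: j for j, t in enumerate(basic)}

    designs = sorted(cs.rows["design"].unique())
    dbt_params: list[tuple[str, str]] = []
    for d in designs:
        trts = d.split(":")
        for t in trts[1:]:  # trts[0] is the design baseline (sorted label)
            dbt_params.append((d, t))
    dbt_col = {p: j for j, p in enumerate(dbt_params)}

    n = cs.n_rows
    X = np.zeros((n, len(basic)))
    X_dbt = np.zeros((n, len(dbt_params)))
    for i, row in enumerate(cs.rows.itertuples(index=False)):
        b, k, d = row.baseline, row.comparator, row.design
        if k != reference:
            X[i, basic_col[k]] += 1.0
        if b != reference:
            X[i, basic_col[b]] -= 1.0
        dref = d.split(":", 1)[0]
        if k != dref:
            X_dbt[i, dbt_col[(d, k)]] += 1.0
        if b != dref:
            X_dbt[i, dbt_col[(d, b)]] -= 1.0

    A = np.zeros((len(dbt_params), len(basic)))
    for j, (d, t) in enumerate(dbt_params):
        dref = d.split(":", 1)[0]
        if t != reference:
            A[j, basic_col[t]] += 1.0
        if dref != reference:
            A[j, basic_col[dref]] -= 1.0
    assert np.allclose(X_dbt @ A, X), "embedding map does not reproduce X"

    return DesignMatrices(
        X=X,
        X_dbt=X_dbt,
        A=A,
        treatments=treatments,
        reference=reference,
        basic_params=basic,
        dbt_params=tuple(dbt_params),
        rank_x=_rank(X),
        rank_dbt=_rank(X_dbt),
    )


class _GLS(NamedTuple):
    beta: np.ndarray
    cov: np.ndarray
    rss: float
    logdet_sigma: float
    log_pdet_xwx: float


def _gls(cs: ContrastSet, M: np.ndarray, tau2: float, need_logdet: bool = False) -> _GLS:
    """Blockwise GLS solve with weights (S + tau2 P)^-1 per study."""
    y = cs.y
    logdet = 0.0
    if cs.all_scalar:
        sigma = np.array([b[0, 0] for b in cs.S_blocks]) + tau2
        if np.any(sigma <= 0):
            bad = cs.rows["study"].iloc[int(np.argmin(sigma))]
            raise EstimationError(f"non-positive variance block in study '{bad}'")
        w = 1.0 / sigma
        WM = M * w[:, None]
        Wy = y * w
        if need_logdet:
            logdet = float(np.sum(np.log(sigma)))
    else:
        WM = np.empty_like(M)
        Wy = np.empty_like(y)
        for sl, S_b, P_b in zip(cs.slices, cs.S_blocks, cs.P_blocks):
            sigma_b = S_b + tau2 * P_b
            try:
                c = np.linalg.cholesky(sigma_b)
            except np.linalg.LinAlgError:
                bad = cs.rows["study"].iloc[sl.start]
                raise EstimationError(
                    f"covariance block of study '{bad}' is not positive definite"
                ) from None
            rhs = np.column_stack([M[sl], y[sl]])
            sol = np.linalg.solve(c.T, np.linalg.solve(c, rhs))
            WM[sl] = sol[:, :-1]
            Wy[sl] = sol[:, -1]
            if need_logdet:
                logdet += 2.0 * float(np.sum(np.log(np.diag(c))))
    G = M.T @ WM
    cov = _sym_pinv(G)
    beta = cov @ (M.T @ Wy)
    resid = y - M @ beta
    # rss = resid' W resid; reuse W y and W M to avoid another block solve
    rss = float(resid @ (Wy - WM @ beta))
    lpd = _log_pdet(G) if need_logdet else 0.0
    return _GLS(beta=beta, cov=cov, rss=rss, logdet_sigma=logdet, log_pdet_xwx=lpd)


@dataclass
class FitResult:
    """One fitted model: GLS estimates, heterogeneity and fit statistics.

    ``Q``/``Q_df``/``I2`` always refer to the tau^2 = 0 (fixed-effect)
    residual of the same design matrix; ``rss`` is the generalized residual
    sum of squares at the fitted ``tau2``.
    """

    model: str
    estimates: np.ndarray
    covariance: np.ndarray
    tau2: float
    tau2_estimator: str | None
    rss: float
    Q: float
    Q_df: int
    I2: float | None
    param_labels: tuple
    matrices: DesignMatrices | None = None

    @property
    def tau(self) -> float:
        """Between-study standard deviation (the scale reported in surveys)."""
        return float(np.sqrt(self.tau2))


def cochran_q(cs: ContrastSet, M: np.ndarray) -> tuple[float, int, float | None]:
    """Cochran's Q of the fixed-effect (tau^2 = 0) fit, its df, and I^2.

    I^2 = max(0, 1 - Q_df/Q) * 100; undefined (None) when Q_df = 0.
    """
    res = _gls(cs, M, 0.0)
    q = max(res.rss, 0.0)
    q_df = cs.n_rows - _rank(M)
    if q_df == 0:
        return q, q_df, None
    i2 = 0.0 if q <= q_df else (1.0 - q_df / q) * 100.0
    return q, q_df, i2


def estimate_tau2_dl(cs: ContrastSet, M: np.ndarray) -> float:
    """Matrix method-of-moments (DerSimonian-Laird) heterogeneity estimate.

    tau2 = max(0, (Q - Q_df) / tr[(W0 - W0 M (M' W0 M)^+ M' W0) P]) with
    W0 = S^-1; reduces to the classical DL estimator for a pairwise
    meta-analysis, where P is the identity.
    """
    q, q_df, _ = cochran_q(cs, M)
    if q_df < 1:
        raise EstimationError("heterogeneity not estimable (zero residual df)")
    if cs.all_scalar:
        w = 1.0 / np.array([b[0, 0] for b in cs.S_blocks])
        WM = M * w[:, None]
        W0 = np.diag(w)
    else:
        W0 = np.zeros((cs.n_rows, cs.n_rows))
        for sl, S_b in zip(cs.slices, cs.S_blocks):
            W0[sl, sl] = np.linalg.inv(S_b)
        WM = W0 @ M
    H = W0 - WM @ _sym_pinv(M.T @ WM) @ WM.T
    denom = float(np.trace(H @ cs.P))
    if denom <= 0:
        raise EstimationError("degenerate moment equation for tau^2")
    return max(0.0, (q - q_df) / denom)


def restricted_loglik(cs: ContrastSet, M: np.ndarray, tau2: float) -> float:
    """Restricted log-likelihood (up to a constant) at a given tau^2."""
    res = _gls(cs, M, tau2, need_logdet=True)
    return -0.5 * (res.logdet_sigma + res.log_pdet_xwx + res.rss)


def estimate_tau2_reml(
    cs: ContrastSet, M: np.ndarray, xatol: float = 1e-8
) -> float:
    """REML heterogeneity estimate by bounded scalar optimisation.

    The search interval is [0, 10 * tau2_DL + 1]; the restricted likelihood
    of the estimable subspace uses a pseudo-determinant so rank-deficient
    design matrices are handled.  Deterministic and derivative-free.
    """
    q, q_df, _ = cochran_q(cs, M)
    if q_df < 1:
        raise EstimationError("heterogeneity not estimable (zero residual df)")
    upper = 10.0 * estimate_tau2_dl(cs, M) + 1.0

    def neg(t2: float) -> float:
        return -restricted_loglik(cs, M, t2)

    res = minimize_scalar(neg, bounds=(0.0, upper), method="bounded",
                          options={"xatol": xatol})
    if not res.success:
        raise EstimationError(
            f"REML optimisation failed on [0, {upper:g}]: {res.message}"
        )
    tau2 = float(res.x)
    if neg(0.0) <= res.fun:  # boundary beats the interior optimum
        tau2 = 0.0
    return max(tau2, 0.0)


_ESTIMATORS = {"dl": estimate_tau2_dl, "reml": estimate_tau2_reml}


def gls_fit(
    cs: ContrastSet,
    M: np.ndarray,
    tau2: float,
    model: str = "custom",
    param_labels: tuple = (),
    tau2_estimator: str | None = None,
    matrices: DesignMatrices | None = None,
) -> FitResult:
    """GLS fit of an arbitrary design matrix at a fixed tau^2."""
    if not np.isfinite(tau2) or tau2 < 0:
        raise ValueError(f"tau2 must be finite and >= 0, got {tau2}")
    res = _gls(cs, M, tau2)
    q, q_df, i2 = cochran_q(cs, M)
    return FitResult(
        model=model,
        estimates=res.beta,
        covariance=res.cov,
        tau2=float(tau2),
        tau2_estimator=tau2_estimator,
        rss=res.rss,
        Q=q,
        Q_df=q_df,
        I2=i2,
        param_labels=param_labels or tuple(range(M.shape[1])),
        matrices=matrices,
    )


def _estimate(cs: ContrastSet, M: np.ndarray, estimator: str) -> float:
    est = estimator.lower()
    if est not in _ESTIMATORS:
        raise ValueError(f"unknown tau^2 estimator '{estimator}' (use 'dl' or 'reml')")
    return _ESTIMATORS[est](cs, M)


def fit_consistency(
    cs: ContrastSet,
    estimator: str = "reml",
    reference: str | None = None,
    dm: DesignMatrices | None = None,
    tau2: float | None = None,
) -> FitResult:
    """Random-effects consistency model: estimate tau^2 then GLS-fit X."""
    if dm is None:
        dm = build_design_matrices(cs, reference)
    if tau2 is None:
        tau2 = _estimate(cs, dm.X, estimator)
    return gls_fit(cs, dm.X, tau2, model="consistency",
                   param_labels=dm.basic_params,
                   tau2_estimator=estimator.lower(), matrices=dm)


def fit_dbt(
    cs: ContrastSet,
    estimator: str = "reml",
    reference: str | None = None,
    dm: DesignMatrices | None = None,
    tau2: float | None = None,
) -> FitResult:
    """DBT model fit; its tau^2 is within-design heterogeneity only."""
    if dm is None:
        dm = build_design_matrices(cs, reference)
    if tau2 is None:
        tau2 = _estimate(cs, dm.X_dbt, estimator)
    return gls_fit(cs, dm.X_dbt, tau2, model="dbt",
                   param_labels=dm.dbt_params,
                   tau2_estimator=estimator.lower(), matrices=dm)


def pairwise_contrasts(fit: FitResult) -> pd.DataFrame:
    """All pairwise relative effects implied by a consistency fit.

    Rows are ordered treatment pairs (t1 < t2) with the estimated log odds
    ratio of t2 versus t1 and its standard error.  Invariant to the choice
    of reference treatment.
    """
    if fit.model != "consistency" or fit.matrices is None:
        raise ValueError("pairwise contrasts require a consistency fit with matrices")
    dm = fit.matrices
    full = {dm.reference: 0.0}
    col = {t: j for j, t in enumerate(dm.basic_params)}
    records = []
    T = len(dm.treatments)
    for i in range(T):
        for j in range(i + 1, T):
            t1, t2 = dm.treatments[i], dm.treatments[j]
            c = np.zeros(len(dm.basic_params))
            if t2 != dm.reference:
                c[col[t2]] += 1.0
            if t1 != dm.reference:
                c[col[t1]] -= 1.0
            est = float(c @ fit.estimates)
            var = float(c @ fit.covariance @ c)
            records.append({"treat1": t1, "treat2": t2,
                            "estimate": est, "se": float(np.sqrt(max(var, 0.0)))})
    return pd.DataFrame.from_records(records)
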