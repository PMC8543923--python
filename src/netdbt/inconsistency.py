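"""Global inconsistency assessment via the design-by-treatment interaction model.

The DBT model gives every design its own relative-effect parameters theta;
under consistency theta = A beta, so the inconsistency parameters are the
components of theta orthogonal to the column space of A.  With C an
orthonormal basis of the left null space of A (rank = rank(X_dbt) -
rank(X)), the global Wald statistic

    Q_inc = (C theta_hat)' (C V_theta C')^+ (C theta_hat)

is referred to a chi-squared distribution with that many degrees of
freedom, treating the plugged-in within-design heterogeneity tau^2 as
known.  Algebraically Q_inc equals the drop in generalized residual sum of
squares between the consistency and DBT fits at the same tau^2, which is
computed as an internal cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.linalg import null_space
from scipy.stats import chi2

from .contrasts import BaselineRule, ContrastSet, build_contrast_set
from .exceptions import EstimationError
from .network_data import NetworkDataset
from .nma_fit import (
    DesignMatrices,
    _gls,
    _sym_pinv,
    build_design_matrices,
    cochran_q,
    estimate_tau2_dl,
    estimate_tau2_reml,
)

__all__ = ["InconsistencyTest", "QDecomposition", "dbt_test", "q_decomposition", "classify"]

CROSS_CHECK_TOL = 1e-8


@dataclass
class InconsistencyTest:
    """Result of the global Wald chi-squared test of the DBT model.

    When the network has a single effective design (df = 0) the test is
    not applicable: ``applicable`` is False and ``p_value`` is None, never
    reported as p = 1.
    """

    q_inc: float | None
    df: int
    p_value: float | None
    tau2_within: float | None
    estimator: str
    omega: np.ndarray | None
    omega_cov: np.ndarray | None
    applicable: bool = True
    note: str | None = None

    @property
    def tau_within(self) -> float | None:
        return None if self.tau2_within is None else float(np.sqrt(self.tau2_within))

    def to_dict(self) -> dict:
        return {
            "Q_inc": self.q_inc,
            "df": self.df,
            "p_value": self.p_value,
            "tau_within": self.tau_within,
            "estimator": self.estimator,
            "applicable": self.applicable,
            "classification": classify(self.p_value) if self.applicable else "not-applicable",
            "note": self.note,
        }


def _as_contrast_set(data, baseline_rule: BaselineRule = "min") -> ContrastSet:
    if isinstance(data, NetworkDataset):
        return build_contrast_set(data, baseline_rule=baseline_rule)
    return data


def dbt_test(
    data: NetworkDataset | ContrastSet,
    estimator: str = "reml",
    reference: str | None = None,
    tau2: float | None = None,
    baseline_rule: BaselineRule = "min",
    dm: DesignMatrices | None = None,
) -> InconsistencyTest:
    """Global Wald chi-squared test of the design-by-treatment interaction.

    Parameters
    ----------
    data
        An arm-level dataset or a pre-built contrast set.
    estimator
        'reml' (default) or 'dl' for the within-design tau^2 plugged into
        the DBT fit.
    tau2
        Optional fixed within-design tau^2 overriding estimation (useful
        for oracle comparisons and null-distribution studies).
    """
    cs = _as_contrast_set(data, baseline_rule)
    if dm is None:
        dm = build_design_matrices(cs, reference)
    df = dm.df_inconsistency
    if df == 0:
        return InconsistencyTest(
            q_inc=None, df=0, p_value=None, tau2_within=None,
            estimator=estimator.lower(), omega=None, omega_cov=None,
            applicable=False,
            note="inconsistency not assessable (single effective design)",
        )
    note = None
    if tau2 is None:
        try:
            if estimator.lower() == "dl":
                tau2 = estimate_tau2_dl(cs, dm.X_dbt)
            elif estimator.lower() == "reml":
                tau2 = estimate_tau2_reml(cs, dm.X_dbt)
            else:
                raise ValueError(f"unknown estimator '{estimator}'")
        except EstimationError:
            # saturated DBT model (one study per design): no within-design
            # replication, so the within-design variance is taken as zero
            tau2 = 0.0
            note = "within-design tau^2 not estimable (saturated designs); set to 0"

    dbt = _gls(cs, dm.X_dbt, tau2)
    # rows of C span the left null space of A: the inconsistency directions
    C = null_space(dm.A.T).T
    if C.shape[0] != df:
        raise EstimationError(
            f"null-space dimension {C.shape[0]} does not match df {df}"
        )
    omega = C @ dbt.beta
    omega_cov = C @ dbt.cov @ C.T
    q_wald = float(omega @ _sym_pinv(omega_cov) @ omega)

    cons = _gls(cs, dm.X, tau2)
    q_rss = cons.rss - dbt.rss
    if abs(q_wald - q_rss) > CROSS_CHECK_TOL * max(1.0, abs(q_wald)):
        raise EstimationError(
            f"Wald statistic {q_wald:.10g} disagrees with RSS difference "
            f"{q_rss:.10g}; numerically unstable network"
        )
    q_wald = max(q_wald, 0.0)
    return InconsistencyTest(
        q_inc=q_wald,
        df=df,
        p_value=float(chi2.sf(q_wald, df)),
        tau2_within=float(tau2),
        estimator=estimator.lower(),
        omega=omega,
        omega_cov=omega_cov,
        note=note,
    )


class QDecomposition(NamedTuple):
    q_total: float
    q_within_design: float
    q_between_design: float
    df_total: int
    df_within_design: int
    df_between_design: int


def q_decomposition(
    data: NetworkDataset | ContrastSet, reference: str | None = None
) -> QDecomposition:
    """Split Cochran's Q at tau^2 = 0 into within- and between-design parts.

    Q_total is the consistency-model Q, Q_within the DBT-model Q (the sum
    of per-design homogeneity statistics), and their difference the
    between-design (inconsistency) part, nonnegative by the nesting of the
    two models.
    """
    cs = _as_contrast_set(data)
    dm = build_design_matrices(cs, reference)
    q_total, df_total, _ = cochran_q(cs, dm.X)
    q_within, df_within, _ = cochran_q(cs, dm.X_dbt)
    return QDecomposition(
        q_total=q_total,
        q_within_design=q_within,
        q_between_design=q_total - q_within,
        df_total=df_total,
        df_within_design=df_within,
        df_between_design=df_total - df_within,
    )


def classify(p_value: float | None, thresholds: tuple[float, float] = (0.05, 0.10)) -> str:
    """Three-way classification of a DBT p-value at two cut-offs.

    Below the lower threshold the network is inconsistent at that level;
    between the two it shows weaker evidence of inconsistency; above the
    upper threshold it is labelled consistent.
    """
    if p_value is None:
        return "not-applicable"
    if not (0.0 <= p_value <= 1.0):
        raise ValueError(f"p-value must be in [0, 1], got {p_value}")
    low, high = sorted(thresholds)
    lo_pct, hi_pct = int(round(low * 100)), int(round(high * 100))
    if p_value < low:
        return f"inconsistent@{lo_pct}%"
    if p_value < high:
        return f"inconsistent@{lo_pct}-{hi_pct}%"
    return f"consistent@{hi_pct}%"
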