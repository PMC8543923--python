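"""Study-level log odds-ratio contrasts with exact within-study covariance.

Arm-level dichotomous data are reduced, study by study, to baseline
contrasts: with baseline arm b and comparator k,

    y_k   = logit(e_k / n_k) - logit(e_b / n_b)              (log odds ratio)
    Var   = 1/e_k + 1/(n_k - e_k) + 1/e_b + 1/(n_b - e_b)
    Cov   = 1/e_b + 1/(n_b - e_b)    (shared baseline arm, k != j)

A study with any zero cell receives a +0.5 continuity correction applied to
every cell of every arm of that study (events + 0.5 out of n + 1), so the
correction is study-level and the corrected covariance block stays positive
definite.  The compound-symmetry structure matrix P (1 on the diagonal, 0.5
off) encodes a common heterogeneity variance tau^2 for every pairwise
contrast: under tau^2 * P, Var(delta_AB - delta_AC) = tau^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .exceptions import NetworkValidationError
from .network_data import Arm, NetworkDataset, design_label

__all__ = ["ContrastSet", "study_contrasts", "build_contrast_set"]

BaselineRule = Literal["min", "max"]


@dataclass
class ContrastSet:
    """Baseline contrasts for a whole network, one block per study.

    ``rows`` has columns study, design, baseline, comparator, y; block
    ``i`` of ``S_blocks``/``P_blocks`` covers ``rows[slices[i]]``.
    """

    rows: pd.DataFrame
    S_blocks: list[np.ndarray]
    P_blocks: list[np.ndarray]
    slices: list[slice]
    treatments: list[str]

    @property
    def y(self) -> np.ndarray:
        return self.rows["y"].to_numpy(dtype=float)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def all_scalar(self) -> bool:
        """True when every study is two-arm (all blocks are 1x1)."""
        return all(b.shape == (1, 1) for b in self.S_blocks)

    @property
    def S(self) -> np.ndarray:
        """Dense block-diagonal within-study covariance."""
        return scipy.linalg.block_diag(*self.S_blocks)

    @property
    def P(self) -> np.ndarray:
        """Dense block-diagonal compound-symmetry structure matrix."""
        return scipy.linalg.block_diag(*self.P_blocks)

    @property
    def designs(self) -> list[str]:
        return sorted(self.rows["design"].unique())


def study_contrasts(
    arms: Sequence[Arm],
    correction: float = 0.5,
    baseline: str | None = None,
) -> tuple[str, list[str], np.ndarray, np.ndarray]:
    """Contrasts of one study versus its baseline arm.

    Parameters
    ----------
    arms
        The study's arms (>= 2, distinct treatments).
    correction
        Continuity constant added to every cell of every arm when any cell
        of the study is zero (0.5 by default; 0 disables).
    baseline
        Baseline treatment label; defaults to the lexicographically
        smallest label in the study.  Downstream results are invariant to
        this choice.

    Returns
    -------
    (baseline, comparators, y, S)
        Comparators in sorted order; ``y`` the log odds ratios versus
        baseline; ``S`` the (m x m) within-study covariance block.
    """
    if len(arms) < 2:
        raise NetworkValidationError(
            f"study '{arms[0].study_id if arms else '?'}' has fewer than two arms"
        )
    by_trt = {a.treatment: a for a in arms}
    if len(by_trt) != len(arms):
        raise NetworkValidationError(
            f"study '{arms[0].study_id}' repeats a treatment"
        )
    order = sorted(by_trt)
    if baseline is None:
        baseline = order[0]
    if baseline not in by_trt:
        raise NetworkValidationError(
            f"baseline '{baseline}' not among study treatments {order}"
        )
    comparators = [t for t in order if t != baseline]

    e = np.array([float(by_trt[t].events) for t in order])
    n = np.array([float(by_trt[t].n) for t in order])
    if correction and (np.any(e == 0) or np.any(e == n)):
        e = e + correction
        n = n + 2 * correction
    logit = np.log(e / (n - e))
    var_arm = 1.0 / e + 1.0 / (n - e)
    arm_index = {t: i for i, t in enumerate(order)}

    b = arm_index[baseline]
    idx = [arm_index[t] for t in comparators]
    y = logit[idx] - logit[b]
    m = len(idx)
    S = np.full((m, m), var_arm[b])
    S[np.diag_indices(m)] += var_arm[idx]
    return baseline, comparators, y, S


def _p_block(m: int) -> np.ndarray:
    return 0.5 * np.eye(m) + 0.5 * np.ones((m, m))


def build_contrast_set(
    ds: NetworkDataset,
    correction: float = 0.5,
    baseline_rule: BaselineRule = "min",
) -> ContrastSet:
    """Concatenate per-study contrast blocks in stable study order.

    ``baseline_rule`` picks the baseline arm of every study ("min" or
    "max" lexicographic label); any valid choice yields the same fitted
    network, which is checked by the invariance tests.
    """
    records: list[dict] = []
    S_blocks: list[np.ndarray] = []
    P_blocks: list[np.ndarray] = []
    slices: list[slice] = []
    pos = 0
    for study_id, arms in ds.studies.items():
        trts = sorted({a.treatment for a in arms})
        base = trts[0] if baseline_rule == "min" else trts[-1]
        try:
            base, comparators, y, S = study_contrasts(
                arms, correction=correction, baseline=base
            )
        except NetworkValidationError as err:
            raise NetworkValidationError(f"study '{study_id}': {err}") from err
        design = design_label(trts)
        for t, yv in zip(comparators, y):
            records.append(
                {
                    "study": study_id,
                    "design": design,
                    "baseline": base,
                    "comparator": t,
                    "y": yv,
                }
            )
        m = len(comparators)
        S_blocks.append(S)
        P_blocks.append(_p_block(m))
        slices.append(slice(pos, pos + m))
        pos += m
    rows = pd.DataFrame.from_records(records)
    return ContrastSet(
        rows=rows,
        S_blocks=S_blocks,
        P_blocks=P_blocks,
        slices=slices,
        treatments=sorted({a.treatment for a in ds.arms}),
    )
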