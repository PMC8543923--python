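"""Shared fixtures and builders for the netdbt test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from netdbt.contrasts import ContrastSet
from netdbt.network_data import Arm, NetworkDataset
from netdbt.synthetic_data import DesignSpec, SimConfig


def make_dataset(design_studies, events=10, n=100, network_id="net"):
    """One study per entry of ``design_studies`` (a list of treatment tuples).

    All arms share the same events/n so the resulting contrasts are exactly
    zero — convenient for structural and exact-consistency tests.
    """
    arms = []
    for i, trts in enumerate(design_studies, 1):
        for t in trts:
            arms.append(Arm(f"s{i}", t, events, n))
    return NetworkDataset(network_id, arms)


def manual_contrast_set(studies):
    """Build a ContrastSet directly from (study_id, treatments, y, S) tuples.

    ``treatments`` must be sorted; the first is the baseline.  ``y`` has one
    entry per non-baseline treatment and ``S`` is the matching covariance
    block (a scalar is promoted to 1x1).
    """
    records, S_blocks, P_blocks, slices = [], [], [], []
    pos = 0
    trtset = set()
    for sid, trts, y, S in studies:
        trts = tuple(trts)
        assert list(trts) == sorted(trts), "treatments must be sorted"
        b = trts[0]
        design = ":".join(trts)
        y = np.atleast_1d(np.asarray(y, float))
        for t, yv in zip(trts[1:], y):
            records.append(
                {"study": sid, "design": design, "baseline": b,
                 "comparator": t, "y": float(yv)}
            )
        m = len(trts) - 1
        S_blocks.append(np.atleast_2d(np.asarray(S, float)))
        P_blocks.append(0.5 * np.eye(m) + 0.5 * np.ones((m, m)))
        slices.append(slice(pos, pos + m))
        pos += m
        trtset.update(trts)
    return ContrastSet(
        rows=pd.DataFrame.from_records(records),
        S_blocks=S_blocks,
        P_blocks=P_blocks,
        slices=slices,
        treatments=sorted(trtset),
    )


def random_config(rng: np.random.Generator, max_treatments: int = 5,
                  tau: float = 0.0) -> SimConfig:
    """A random connected network config with at least one closed loop."""
    T = int(rng.integers(3, max_treatments + 1))
    treatments = tuple("ABCDEF"[:T])
    designs = [
        DesignSpec((treatments[i], treatments[i + 1]), int(rng.integers(1, 4)))
        for i in range(T - 1)
    ]
    designs.append(DesignSpec((treatments[0], treatments[-1]), int(rng.integers(1, 4))))
    if T >= 3 and rng.random() < 0.5:
        trio = tuple(sorted(rng.choice(T, size=3, replace=False)))
        designs.append(DesignSpec(tuple(treatments[i] for i in trio),
                                  int(rng.integers(1, 3))))
    effects = {t: float(rng.normal(0, 0.3)) for t in treatments[1:]}
    cfg = SimConfig(
        treatments=treatments,
        designs=tuple(designs),
        n_per_arm=int(rng.integers(300, 1500)),
        true_effects=effects,
        tau=tau,
    )
    cfg.validate()
    return cfg


@pytest.fixture
def triangle_designs():
    """Six two-arm studies: designs AB, AC, BC twice each."""
    return [("A", "B"), ("A", "B"), ("A", "C"), ("A", "C"), ("B", "C"), ("B", "C")]
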