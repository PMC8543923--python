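"""Synthetic networks of randomised trials with known truth.

The generator draws, for each study, a baseline log-odds (fixed or
logit-normal across studies), study-level random effects with common
variance tau^2 and compound-symmetry 0.5 correlation across the study's
contrasts, and binomial event counts per arm.  Inconsistency can be
planted as fixed design-specific shifts omega on a design's contrasts —
exactly the alternative hypothesis of the design-by-treatment interaction
model.  Monte-Carlo harnesses measure type-I error, power and tau
recovery of the global Wald test under these data-generating conditions.

Seeding is stream-based: a root seed spawns one independent substream per
replicate, so results are independent of evaluation order and exactly
reproducible from (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .exceptions import ConfigError
from .inconsistency import dbt_test
from .contrasts import build_contrast_set
from .network_data import Arm, NetworkDataset, design_label
from .nma_fit import build_design_matrices, estimate_tau2_dl, estimate_tau2_reml

__all__ = [
    "DesignSpec",
    "SimConfig",
    "SimResult",
    "simulate_network",
    "type_one_error",
    "power_curve",
    "tau_recovery",
    "triangle_config",
]

#: default per-study baseline spec: logit-normal around a 20% event risk
DEFAULT_BASELINE_LOGIT_MEAN = float(logit(0.2))
DEFAULT_BASELINE_LOGIT_SD = 0.5

#: fraction of replicates allowed to fail fitting before the harness errors
FAILURE_CAP = 0.01


@dataclass(frozen=True)
class DesignSpec:
    """One design: its treatment set, how many studies use it, optional n."""

    treatments: tuple[str, ...]
    studies: int
    n_per_arm: int | None = None


@dataclass(frozen=True)
class SimConfig:
    """Data-generating configuration for one synthetic network.

    ``true_effects`` are log odds ratios of each treatment versus the
    reference (the smallest treatment label); missing entries are 0.
    ``inconsistency`` maps a design label (e.g. ``"B:C"``) to per-treatment
    shifts on that design's contrasts versus its own baseline, on the log
    odds-ratio scale.  ``baseline_risk`` fixes the control-arm risk; when
    None, baselines are drawn logit-normal(``baseline_logit_mean``,
    ``baseline_logit_sd``) per study.
    """

    treatments: tuple[str, ...]
    designs: tuple[DesignSpec, ...]
    n_per_arm: int = 1000
    baseline_risk: float | None = None
    baseline_logit_mean: float = DEFAULT_BASELINE_LOGIT_MEAN
    baseline_logit_sd: float = DEFAULT_BASELINE_LOGIT_SD
    true_effects: Mapping[str, float] = field(default_factory=dict)
    tau: float = 0.0
    inconsistency: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int | None = None

    @property
    def reference(self) -> str:
        return sorted(self.treatments)[0]

    def effect(self, treatment: str) -> float:
        return float(self.true_effects.get(treatment, 0.0))

    def validate(self) -> None:
        if len(self.treatments) < 2:
            raise ConfigError("need at least two treatments")
        if len(set(self.treatments)) != len(self.treatments):
            raise ConfigError("duplicate treatment labels")
        if not self.designs:
            raise ConfigError("need at least one design")
        g = nx.Graph()
        g.add_nodes_from(self.treatments)
        for spec in self.designs:
            if len(spec.treatments) < 2:
                raise ConfigError(f"design {spec.treatments} has fewer than two arms")
            unknown = set(spec.treatments) - set(self.treatments)
            if unknown:
                raise ConfigError(f"design uses unknown treatments {sorted(unknown)}")
            if spec.studies < 1:
                raise ConfigError("each design needs at least one study")
            trts = sorted(spec.treatments)
            for i in range(len(trts) - 1):
                g.add_edge(trts[i], trts[i + 1])
        if not nx.is_connected(g):
            raise ConfigError("designs do not connect all treatments")
        if self.tau < 0:
            raise ConfigError("tau must be >= 0")
        if self.baseline_risk is not None and not (0 < self.baseline_risk < 1):
            raise ConfigError("baseline_risk must lie in (0, 1)")
        for d in self.inconsistency:
            known = {design_label(s.treatments) for s in self.designs}
            if d not in known:
                raise ConfigError(f"inconsistency shift on unknown design '{d}'")
        # margin check: warn if implied risks drift near the boundaries
        mu = (logit(self.baseline_risk) if self.baseline_risk is not None
              else self.baseline_logit_mean)
        spread = (0.0 if self.baseline_risk is not None
                  else 2.0 * self.baseline_logit_sd) + 2.0 * self.tau
        effects = [0.0] + [self.effect(t) for t in self.treatments]
        shifts = [v for m in self.inconsistency.values() for v in m.values()]
        lo = expit(mu - spread + min(effects + shifts, default=0.0))
        hi = expit(mu + spread + max(effects + shifts, default=0.0))
        if lo < 0.005 or hi > 0.995:
            warnings.warn(
                f"implied arm risks range roughly [{lo:.3g}, {hi:.3g}]; "
                "event counts may be sparse or saturated", stacklevel=2,
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        designs = tuple(
            DesignSpec(
                treatments=tuple(spec["treatments"]),
                studies=int(spec.get("studies", 1)),
                n_per_arm=spec.get("n_per_arm"),
            )
            for spec in d["designs"]
        )
        cfg = cls(
            treatments=tuple(d["treatments"]),
            designs=designs,
            n_per_arm=int(d.get("n_per_arm", 1000)),
            baseline_risk=d.get("baseline_risk"),
            baseline_logit_mean=float(
                d.get("baseline_logit_mean", DEFAULT_BASELINE_LOGIT_MEAN)
            ),
            baseline_logit_sd=float(
                d.get("baseline_logit_sd", DEFAULT_BASELINE_LOGIT_SD)
            ),
            true_effects=dict(d.get("true_effects", {})),
            tau=float(d.get("tau", 0.0)),
            inconsistency={k: dict(v) for k, v in d.get("inconsistency", {}).items()},
            seed=d.get("seed"),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def triangle_config(
    studies_per_design: int = 6,
    n_per_arm: int = 1000,
    tau: float = 0.0,
    effects: Mapping[str, float] | None = None,
    omega_bc: float = 0.0,
    baseline_risk: float | None = None,
) -> SimConfig:
    """The canonical ABC triangle: three two-arm designs AB, AC, BC.

    ``omega_bc`` plants an inconsistency shift on the B:C design's contrast
    (C versus B), leaving the other designs at their consistent values.
    """
    inconsistency = {"B:C": {"C": omega_bc}} if omega_bc else {}
    cfg = SimConfig(
        treatments=("A", "B", "C"),
        designs=(
            DesignSpec(("A", "B"), studies_per_design),
            DesignSpec(("A", "C"), studies_per_design),
            DesignSpec(("B", "C"), studies_per_design),
        ),
        n_per_arm=n_per_arm,
        baseline_risk=baseline_risk,
        true_effects=dict(effects or {"B": 0.3, "C": 0.5}),
        tau=tau,
        inconsistency=inconsistency,
    )
    cfg.validate()
    return cfg


def simulate_network(
    cfg: SimConfig, seed: int | np.random.SeedSequence | None = None
) -> NetworkDataset:
    """Draw one arm-level network dataset from the configuration.

    Deterministic given (cfg, seed).  Study random effects are multivariate
    normal with variance tau^2 and 0.5 correlation across the study's
    baseline contrasts; arm event counts are binomial at
    expit(baseline_logit + relative effect + design shift + random effect).
    """
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    ref = cfg.reference
    arms: list[Arm] = []
    sid = 0
    for spec in cfg.designs:
        trts = sorted(spec.treatments)
        b = trts[0]
        d_label = design_label(trts)
        omega = cfg.inconsistency.get(d_label, {})
        n_arm = spec.n_per_arm or cfg.n_per_arm
        m = len(trts) - 1
        cov = cfg.tau**2 * (0.5 * np.eye(m) + 0.5 * np.ones((m, m)))
        for _ in range(spec.studies):
            sid += 1
            study = f"s{sid:04d}"
            if cfg.baseline_risk is not None:
                mu = float(logit(cfg.baseline_risk))
            else:
                mu = rng.normal(cfg.baseline_logit_mean, cfg.baseline_logit_sd)
            delta = (rng.multivariate_normal(np.zeros(m), cov)
                     if cfg.tau > 0 else np.zeros(m))
            e_b = int(rng.binomial(n_arm, expit(mu)))
            arms.append(Arm(study, b, e_b, n_arm))
            for j, t in enumerate(trts[1:]):
                eta = (mu + (cfg.effect(t) - cfg.effect(b))
                       + float(omega.get(t, 0.0)) + delta[j])
                e = int(rng.binomial(n_arm, expit(eta)))
                arms.append(Arm(study, t, e, n_arm))
    label = seed.entropy if isinstance(seed, np.random.SeedSequence) else seed
    return NetworkDataset(network_id=f"sim-{label}", arms=arms)


@dataclass
class SimResult:
    """Summary of a Monte-Carlo run of the DBT test."""

    replicates: int
    n_failures: int
    rejection: dict[tuple[str, float], float]
    mc_se: dict[float, float]
    mean_tau_dbt: dict[str, float]
    mean_q_inc: dict[str, float]
    records: pd.DataFrame | None = None


def _spawn(seed: int | np.random.SeedSequence | None, n: int) -> list[np.random.SeedSequence]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(n)


def _run_replicates(
    cfg: SimConfig,
    reps: int,
    estimators: Sequence[str],
    seed,
    tau2: float | None = None,
) -> tuple[pd.DataFrame, int]:
    """Simulate ``reps`` networks and run the DBT test per estimator."""
    records = []
    failures = 0
    for ss in _spawn(seed, reps):
        try:
            ds = simulate_network(cfg, ss)
            cs = build_contrast_set(ds)
            dm = build_design_matrices(cs)
            rec: dict = {}
            for est in estimators:
                t = dbt_test(cs, estimator=est, tau2=tau2, dm=dm)
                rec[f"p_{est}"] = t.p_value
                rec[f"q_{est}"] = t.q_inc
                rec[f"tau_dbt_{est}"] = t.tau_within
            records.append(rec)
        except Exception:
            failures += 1
            if failures > max(1, FAILURE_CAP * reps):
                raise
    return pd.DataFrame.from_records(records), failures


def type_one_error(
    cfg: SimConfig,
    reps: int = 1000,
    alphas: Sequence[float] = (0.05, 0.10),
    estimators: Sequence[str] = ("reml", "dl"),
    seed: int | np.random.SeedSequence | None = 0,
    tau2: float | None = None,
) -> SimResult:
    """Empirical rejection rate of the DBT test under the configuration.

    With an all-zero ``cfg.inconsistency`` this is the type-I error; the
    Monte-Carlo standard error reported per alpha is sqrt(a(1-a)/reps).
    Replicates whose fit fails are excluded, up to a 1% cap.
    """
    if reps < 100:
        raise ValueError("need at least 100 replicates")
    estimators = [e.lower() for e in estimators]
    df, failures = _run_replicates(cfg, reps, estimators, seed, tau2=tau2)
    n = len(df)
    rejection = {
        (est, float(a)): float((df[f"p_{est}"] < a).mean())
        for est in estimators for a in alphas
    }
    return SimResult(
        replicates=n,
        n_failures=failures,
        rejection=rejection,
        mc_se={float(a): float(np.sqrt(a * (1 - a) / reps)) for a in alphas},
        mean_tau_dbt={est: float(df[f"tau_dbt_{est}"].mean()) for est in estimators},
        mean_q_inc={est: float(df[f"q_{est}"].mean()) for est in estimators},
        records=df,
    )


def power_curve(
    cfg: SimConfig,
    omega_grid: Sequence[float],
    reps: int = 500,
    design: str | None = None,
    treatment: str | None = None,
    alphas: Sequence[float] = (0.05, 0.10),
    estimators: Sequence[str] = ("reml", "dl"),
    seed: int | np.random.SeedSequence | None = 0,
) -> dict[float, SimResult]:
    """Rejection rate as a function of a planted design shift omega.

    The shift is applied to one contrast of one design (by default the
    last design in the configuration and its largest treatment label); the
    omega = 0 point runs the exact type-I-error code path.
    """
    if design is None:
        design = design_label(cfg.designs[-1].treatments)
    if treatment is None:
        treatment = sorted(design.split(":"))[-1]
    out: dict[float, SimResult] = {}
    for ss, omega in zip(_spawn(seed, len(omega_grid)), omega_grid):
        inconsistency = {k: dict(v) for k, v in cfg.inconsistency.items()}
        if omega:
            inconsistency.setdefault(design, {})[treatment] = float(omega)
        shifted = replace(cfg, inconsistency=inconsistency)
        out[float(omega)] = type_one_error(
            shifted, reps=reps, alphas=alphas, estimators=estimators, seed=ss
        )
    return out


def tau_recovery(
    cfg: SimConfig,
    tau_grid: Sequence[float],
    reps: int = 200,
    estimators: Sequence[str] = ("reml", "dl"),
    seed: int | np.random.SeedSequence | None = 0,
) -> pd.DataFrame:
    """Bias and RMSE of the between-study SD estimate across true tau values.

    Both the consistency model (overall heterogeneity) and the DBT model
    (within-design heterogeneity) are estimated; under planted
    inconsistency the consistency-model tau absorbs the between-design
    disagreement and exceeds the DBT-model tau on average.
    """
    if reps < 100:
        raise ValueError("need at least 100 replicates")
    estimators = [e.lower() for e in estimators]
    fns = {"dl": estimate_tau2_dl, "reml": estimate_tau2_reml}
    rows = []
    for ss_tau, tau in zip(_spawn(seed, len(tau_grid)), tau_grid):
        draws: dict[tuple[str, str], list[float]] = {
            (est, model): [] for est in estimators for model in ("consistency", "dbt")
        }
        failures = 0
        for ss in ss_tau.spawn(reps):
            try:
                ds = simulate_network(replace(cfg, tau=float(tau)), ss)
                cs = build_contrast_set(ds)
                dm = build_design_matrices(cs)
                for est in estimators:
                    draws[(est, "consistency")].append(
                        float(np.sqrt(fns[est](cs, dm.X)))
                    )
                    draws[(est, "dbt")].append(
                        float(np.sqrt(fns[est](cs, dm.X_dbt)))
                    )
            except Exception:
                failures += 1
                if failures > max(1, FAILURE_CAP * reps):
                    raise
        for (est, model), vals in draws.items():
            arr = np.asarray(vals)
            rows.append(
                {
                    "tau_true": float(tau),
                    "estimator": est,
                    "model": model,
                    "replicates": len(arr),
                    "failures": failures,
                    "mean_tau_hat": float(arr.mean()),
                    "sd_tau_hat": float(arr.std(ddof=1)),
                    "bias": float(arr.mean() - tau),
                    "rmse": float(np.sqrt(np.mean((arr - tau) ** 2))),
                }
            )
    return pd.DataFrame.from_records(rows)
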