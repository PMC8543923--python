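"""Batch survey of networks: prevalence of inconsistency and its correlates.

This is the empirical pipeline applied to a directory of long-format CSV
networks: each eligible network (>= 4 treatments, >= 1 loop, connected)
yields one record holding its structural metrics, the global DBT test
p-value under both heterogeneity estimators, the between-study SD under
the consistency and DBT models, and I^2.  The records feed cross-tabulated
prevalence at the 0.05/0.10 cut-offs, Pearson correlations of the DBT
p-value against log-scaled structural characteristics, an OLS
multivariable regression on the main counts, rank-based subgroup
comparisons, and a chi-squared trend test over publication years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .contrasts import build_contrast_set
from .exceptions import EstimationError, NetdbtError
from .inconsistency import classify, dbt_test
from .network_data import NetworkDataset, read_long_csv, structure_metrics, validate
from .nma_fit import (
    build_design_matrices,
    cochran_q,
    estimate_tau2_dl,
    estimate_tau2_reml,
)

__all__ = [
    "SurveyRecord",
    "analyze_network",
    "records_frame",
    "prevalence",
    "characteristic_correlations",
    "multivariable_regression",
    "subgroup_distributions",
    "year_trend",
    "run_survey",
]

logger = logging.getLogger("netdbt.survey")

COUNT_CHARACTERISTICS = (
    "n_studies", "n_treatments", "n_edges", "n_designs", "n_loops", "n_multiarm",
)
RATIO_CHARACTERISTICS = (
    "ratio_studies_treatments", "ratio_loops_treatments", "ratio_loops_studies",
    "ratio_designs_studies", "ratio_edges_studies", "ratio_multiarm_studies",
)
REGRESSION_PREDICTORS = ("n_studies", "n_treatments", "n_edges", "n_loops")


@dataclass
class SurveyRecord:
    """One network's row in the survey analysis table."""

    network_id: str
    metrics: dict
    p_dbt: dict[str, float | None] = field(default_factory=dict)
    tau_consistency: dict[str, float | None] = field(default_factory=dict)
    tau_dbt: dict[str, float | None] = field(default_factory=dict)
    i2: float | None = None
    year: int | None = None
    outcome_type: str | None = None
    comparison_type: str | None = None
    complex_interventions: bool | None = None
    notes: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row = {"network_id": self.network_id, **self.metrics, "I2": self.i2,
               "year": self.year, "outcome_type": self.outcome_type,
               "comparison_type": self.comparison_type,
               "complex_interventions": self.complex_interventions}
        for est, p in self.p_dbt.items():
            row[f"p_dbt_{est}"] = p
            row[f"class_{est}"] = classify(p) if p is not None else "not-applicable"
        for est, t in self.tau_consistency.items():
            row[f"tau_consistency_{est}"] = t
        for est, t in self.tau_dbt.items():
            row[f"tau_dbt_{est}"] = t
        row["notes"] = "; ".join(self.notes)
        return row


def analyze_network(
    ds: NetworkDataset,
    estimators: Sequence[str] = ("reml", "dl"),
    require_eligible: bool = False,
) -> SurveyRecord:
    """Full per-network analysis: metrics, heterogeneity, DBT test.

    Statistical degeneracies (inestimable tau^2, singular blocks) are
    recorded as missing values with a note instead of raising, so one bad
    network cannot abort a batch run.
    """
    report = validate(ds)
    if require_eligible and not report.eligible:
        reasons = []
        if not report.connected:
            reasons.append("disconnected")
        if report.n_treatments < 4:
            reasons.append(f"only {report.n_treatments} treatments")
        if not report.has_loop:
            reasons.append("no closed loop")
        raise NetdbtError(
            f"network '{ds.network_id}' ineligible: {', '.join(reasons)}"
        )
    metrics = structure_metrics(ds)
    cs = build_contrast_set(ds)
    dm = build_design_matrices(cs)
    rec = SurveyRecord(
        network_id=ds.network_id,
        metrics=metrics.to_dict(),
        year=ds.year,
        outcome_type=ds.outcome_type,
        comparison_type=ds.comparison_type,
        complex_interventions=ds.complex_interventions,
    )
    _, _, i2 = cochran_q(cs, dm.X)
    rec.i2 = i2
    fns = {"dl": estimate_tau2_dl, "reml": estimate_tau2_reml}
    for est in (e.lower() for e in estimators):
        try:
            rec.tau_consistency[est] = float(np.sqrt(fns[est](cs, dm.X)))
        except (EstimationError, np.linalg.LinAlgError) as err:
            rec.tau_consistency[est] = None
            rec.notes.append(f"tau_consistency[{est}]: {err}")
        try:
            test = dbt_test(cs, estimator=est, dm=dm)
            rec.p_dbt[est] = test.p_value
            rec.tau_dbt[est] = test.tau_within
            if test.note:
                rec.notes.append(f"dbt[{est}]: {test.note}")
        except (EstimationError, np.linalg.LinAlgError) as err:
            rec.p_dbt[est] = None
            rec.tau_dbt[est] = None
            rec.notes.append(f"dbt[{est}]: {err}")
    return rec


def records_frame(records: Iterable[SurveyRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame.from_records([r.to_row() for r in records])


def prevalence(
    records: Iterable[SurveyRecord] | pd.DataFrame,
    thresholds: Sequence[float] = (0.05, 0.10),
    estimators: Sequence[str] = ("reml", "dl"),
) -> pd.DataFrame:
    """Counts and percentages of networks inconsistent at each cut-off.

    Networks with a missing p-value under an estimator are excluded from
    that estimator's denominator; the excluded count is reported.
    """
    df = records_frame(records)
    if df.empty:
        raise ValueError("no survey records")
    rows = []
    for est in (e.lower() for e in estimators):
        col = f"p_dbt_{est}"
        if col not in df:
            continue
        p = pd.to_numeric(df[col], errors="coerce")
        missing = int(p.isna().sum())
        valid = p.dropna()
        for thr in thresholds:
            count = int((valid < thr).sum())
            total = len(valid)
            rows.append(
                {
                    "estimator": est,
                    "threshold": float(thr),
                    "n_inconsistent": count,
                    "n_total": total,
                    "n_missing": missing,
                    "percent": 100.0 * count / total if total else float("nan"),
                }
            )
    return pd.DataFrame.from_records(rows)


def characteristic_correlations(
    records: Iterable[SurveyRecord] | pd.DataFrame,
    estimator: str = "reml",
) -> pd.DataFrame:
    """Pearson correlation of the DBT p-value with log structural features.

    Raw p-values are correlated against the natural log of each count and
    each of the six structural ratios; networks with zero multi-arm
    studies count as one multi-arm study before taking logs, so they are
    not dropped.  Constant characteristics yield a missing correlation.
    """
    df = records_frame(records).copy()
    col = f"p_dbt_{estimator.lower()}"
    df = df.dropna(subset=[col])
    if len(df) < 3:
        raise ValueError("need at least 3 complete records")
    df["n_multiarm"] = df["n_multiarm"].clip(lower=1)
    df["ratio_multiarm_studies"] = df["n_multiarm"] / df["n_studies"]
    p = df[col].astype(float)
    rows = []
    for char in COUNT_CHARACTERISTICS + RATIO_CHARACTERISTICS:
        x = df[char].astype(float)
        mask = x > 0
        xs, ps = np.log(x[mask]), p[mask]
        if len(xs) < 3 or np.ptp(xs) == 0:
            rows.append({"characteristic": char, "n": int(mask.sum()),
                         "r": None, "p_value": None})
            continue
        r, pv = stats.pearsonr(ps, xs)
        rows.append({"characteristic": char, "n": int(mask.sum()),
                     "r": float(r), "p_value": float(pv)})
    return pd.DataFrame.from_records(rows)


def multivariable_regression(
    records: Iterable[SurveyRecord] | pd.DataFrame,
    estimator: str = "reml",
) -> pd.DataFrame:
    """OLS of the raw DBT p-value on studies, treatments, edges and loops.

    Collinear predictors are tolerated: statsmodels falls back to a
    generalized inverse, and the returned table flags the reduced rank.
    """
    df = records_frame(records)
    col = f"p_dbt_{estimator.lower()}"
    sub = df.dropna(subset=[col, *REGRESSION_PREDICTORS])
    if len(sub) < 10:
        raise ValueError("need at least 10 complete records")
    X = sm.add_constant(sub[list(REGRESSION_PREDICTORS)].astype(float))
    model = sm.OLS(sub[col].astype(float), X).fit()
    out = pd.DataFrame(
        {
            "term": model.params.index,
            "coef": model.params.values,
            "se": model.bse.values,
            "p_value": model.pvalues.values,
        }
    )
    out.attrs["rank_deficient"] = np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]
    return out


def subgroup_distributions(
    records: Iterable[SurveyRecord] | pd.DataFrame,
    by: str,
    estimator: str = "reml",
) -> tuple[pd.DataFrame, float]:
    """Per-group quartiles of the DBT p-value and a Kruskal-Wallis test.

    Fourth-root quartiles are reported alongside for plotting parity; they
    carry no statistical weight.  Requires >= 2 groups with >= 2 records.
    """
    df = records_frame(records)
    col = f"p_dbt_{estimator.lower()}"
    sub = df.dropna(subset=[col, by])
    groups = {k: g[col].astype(float).to_numpy() for k, g in sub.groupby(by)}
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError(
            f"need >= 2 groups with >= 2 records each in '{by}', have {len(groups)}"
        )
    rows = []
    for k, v in sorted(groups.items(), key=lambda kv: str(kv[0])):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append(
            {
                by: k, "n": len(v),
                "q1": q1, "median": med, "q3": q3,
                "q1_fourth_root": q1 ** 0.25,
                "median_fourth_root": med ** 0.25,
                "q3_fourth_root": q3 ** 0.25,
            }
        )
    _, p = stats.kruskal(*groups.values())
    return pd.DataFrame.from_records(rows), float(p)


def year_trend(
    records: Iterable[SurveyRecord] | pd.DataFrame,
    estimator: str = "reml",
    threshold: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Chi-squared (Cochran-Armitage) trend of inconsistency rate over years."""
    df = records_frame(records)
    col = f"p_dbt_{estimator.lower()}"
    sub = df.dropna(subset=[col, "year"])
    if sub["year"].nunique() < 2:
        raise ValueError("need at least two distinct publication years")
    table = (
        sub.assign(inconsistent=sub[col].astype(float) < threshold)
        .groupby("year")
        .agg(n=("inconsistent", "size"), r=("inconsistent", "sum"))
        .reset_index()
    )
    x = table["year"].to_numpy(float)
    n = table["n"].to_numpy(float)
    r = table["r"].to_numpy(float)
    pbar = r.sum() / n.sum()
    t = float(np.sum(r * x) - pbar * np.sum(n * x))
    var = pbar * (1 - pbar) * (np.sum(n * x**2) - np.sum(n * x) ** 2 / n.sum())
    if var <= 0:
        return table, float("nan")
    chi2_stat = t**2 / var
    return table, float(stats.chi2.sf(chi2_stat, 1))


def run_survey(
    source: str | Path | Iterable[NetworkDataset],
    estimators: Sequence[str] = ("reml", "dl"),
    require_eligible: bool = True,
) -> tuple[list[SurveyRecord], list[tuple[str, str]]]:
    """Analyse every network in a directory of CSVs (or an iterable).

    Returns the records of analysed networks and a list of
    (network_id, reason) pairs for networks skipped by the eligibility
    screen or by load errors; skips are also logged.
    """
    if isinstance(source, (str, Path)):
        paths = sorted(Path(source).glob("*.csv"))
        datasets: Iterable = (p for p in paths)
    else:
        datasets = source
    records: list[SurveyRecord] = []
    skipped: list[tuple[str, str]] = []
    for item in datasets:
        if isinstance(item, (str, Path)):
            name = Path(item).stem
            try:
                ds = read_long_csv(item)
            except NetdbtError as err:
                logger.warning("skipping %s: %s", name, err)
                skipped.append((name, str(err)))
                continue
        else:
            ds = item
            name = ds.network_id
        try:
            records.append(
                analyze_network(ds, estimators=estimators,
                                require_eligible=require_eligible)
            )
        except NetdbtError as err:
            logger.warning("skipping %s: %s", name, err)
            skipped.append((name, str(err)))
    return records, skipped
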