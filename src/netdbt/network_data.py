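"""Arm-level network datasets: long-format CSV I/O, validation, structural metrics.

The raw unit of analysis is a *network*: a collection of randomised trials,
each contributing two or more arms, where every arm reports a treatment
label, an event count and a sample size for a dichotomous outcome.  Studies
comparing the same set of treatments share a *design*; the structural
quantities computed here (edges with direct evidence, independent loops,
designs, inconsistency degrees of freedom) drive both eligibility screening
and the inconsistency analysis downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .exceptions import (
    DisconnectedNetworkError,
    NetworkFormatError,
    NetworkValidationError,
)

__all__ = [
    "Arm",
    "NetworkDataset",
    "ValidationReport",
    "StructureMetrics",
    "read_long_csv",
    "write_long_csv",
    "validate",
    "comparison_graph",
    "structure_metrics",
    "design_label",
]

REQUIRED_COLUMNS = ("study", "treatment", "events", "n")

#: optional per-network metadata columns recognised in the CSV dialect
METADATA_COLUMNS = ("year", "outcome_type", "comparison_type", "complex")

OUTCOME_TYPES = ("objective", "semi-objective", "subjective")
COMPARISON_TYPES = ("pharm-vs-pharm", "pharm-vs-placebo", "nonpharm-vs-any")


@dataclass(frozen=True)
class Arm:
    """One study arm: a treatment with its event count out of ``n`` patients."""

    study_id: str
    treatment: str
    events: int
    n: int


@dataclass
class NetworkDataset:
    """A network of trials with dichotomous arm-level data.

    Arms are kept in input order.  Per-network metadata (publication year,
    outcome type, comparison type, presence of complex interventions) is
    optional and only used by the survey's subgroup analyses.
    """

    network_id: str
    arms: list[Arm]
    year: int | None = None
    outcome_type: str | None = None
    comparison_type: str | None = None
    complex_interventions: bool | None = None
    extra: dict[str, list] = field(default_factory=dict)

    @property
    def studies(self) -> dict[str, list[Arm]]:
        """Arms grouped by study, preserving first-appearance order."""
        out: dict[str, list[Arm]] = {}
        for arm in self.arms:
            out.setdefault(arm.study_id, []).append(arm)
        return out

    @property
    def treatments(self) -> list[str]:
        return sorted({a.treatment for a in self.arms})

    def design_of(self, study_id: str) -> tuple[str, ...]:
        """The design of a study: its sorted tuple of treatment labels."""
        return tuple(sorted({a.treatment for a in self.arms if a.study_id == study_id}))

    @property
    def designs(self) -> list[tuple[str, ...]]:
        """Unique designs present in the network, sorted."""
        return sorted({tuple(sorted({a.treatment for a in arms}))
                       for arms in self.studies.values()})

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "study": [a.study_id for a in self.arms],
                "treatment": [a.treatment for a in self.arms],
                "events": [a.events for a in self.arms],
                "n": [a.n for a in self.arms],
            }
        )
        return df

    def with_relabelled_treatments(self, mapping: Mapping[str, str]) -> "NetworkDataset":
        """Return a copy with treatment labels renamed (for invariance checks)."""
        arms = [replace(a, treatment=mapping.get(a.treatment, a.treatment))
                for a in self.arms]
        return replace(self, arms=arms)


def design_label(design: Iterable[str]) -> str:
    """Canonical string label of a design (sorted treatments joined by ':')."""
    return ":".join(sorted(design))


def _parse_int(value, column: str, row: int) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise NetworkValidationError(
            f"row {row}: column '{column}' is not a number: {value!r}"
        ) from None
    if not f.is_integer():
        raise NetworkValidationError(
            f"row {row}: column '{column}' must be an integer count, got {value!r}"
        )
    return int(f)


def read_long_csv(path: str | Path, network_id: str | None = None) -> NetworkDataset:
    """Read a network from a long-format CSV (columns study,treatment,events,n).

    Column matching is case-insensitive; surrounding whitespace in study and
    treatment labels is trimmed; extra columns are preserved in ``extra`` and
    the recognised metadata columns (year, outcome_type, comparison_type,
    complex) populate the dataset's per-network fields.

    Raises
    ------
    NetworkFormatError
        If a required column is missing.
    NetworkValidationError
        On non-integer counts, events > n, n <= 0, negative events, or a
        duplicated (study, treatment) pair; the message names the file row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    lower = {c.lower().strip(): c for c in df.columns}
    for col in REQUIRED_COLUMNS:
        if col not in lower:
            raise NetworkFormatError(
                f"{path.name}: required column '{col}' not found "
                f"(have: {', '.join(df.columns)})"
            )

    arms: list[Arm] = []
    seen: set[tuple[str, str]] = set()
    for i, rec in enumerate(df.to_dict("records")):
        row = i + 2  # 1-based, counting the header line
        study = str(rec[lower["study"]]).strip()
        treatment = str(rec[lower["treatment"]]).strip()
        events = _parse_int(rec[lower["events"]], "events", row)
        n = _parse_int(rec[lower["n"]], "n", row)
        if n <= 0:
            raise NetworkValidationError(f"row {row}: n must be positive, got {n}")
        if events < 0:
            raise NetworkValidationError(f"row {row}: events must be >= 0, got {events}")
        if events > n:
            raise NetworkValidationError(
                f"row {row}: events ({events}) exceed sample size ({n})"
            )
        key = (study, treatment)
        if key in seen:
            raise NetworkValidationError(
                f"row {row}: duplicate arm for study '{study}', treatment '{treatment}'"
            )
        seen.add(key)
        arms.append(Arm(study, treatment, events, n))

    extra_cols = [c for c in df.columns
                  if c.lower().strip() not in REQUIRED_COLUMNS]
    extra = {c: df[c].tolist() for c in extra_cols}

    ds = NetworkDataset(
        network_id=network_id or path.stem,
        arms=arms,
        extra=extra,
    )
    meta = {c.lower().strip(): c for c in extra_cols}
    if "year" in meta:
        val = df[meta["year"]].dropna()
        if len(val):
            ds.year = int(float(val.iloc[0]))
    if "outcome_type" in meta:
        val = df[meta["outcome_type"]].dropna()
        if len(val):
            ds.outcome_type = str(val.iloc[0]).strip()
    if "comparison_type" in meta:
        val = df[meta["comparison_type"]].dropna()
        if len(val):
            ds.comparison_type = str(val.iloc[0]).strip()
    if "complex" in meta:
        val = df[meta["complex"]].dropna()
        if len(val):
            ds.complex_interventions = str(val.iloc[0]).strip().lower() in (
                "1", "true", "yes", "y",
            )
    return ds


def write_long_csv(ds: NetworkDataset, path: str | Path) -> None:
    """Write a dataset back to the long-format CSV dialect."""
    df = ds.to_frame()
    if ds.year is not None:
        df["year"] = ds.year
    if ds.outcome_type is not None:
        df["outcome_type"] = ds.outcome_type
    if ds.comparison_type is not None:
        df["comparison_type"] = ds.comparison_type
    if ds.complex_interventions is not None:
        df["complex"] = ds.complex_interventions
    df.to_csv(path, index=False)


def comparison_graph(ds: NetworkDataset) -> nx.Graph:
    """Simple graph of direct comparisons.

    Nodes are treatments; an edge joins two treatments compared within at
    least one study (every pair of arms of a multi-arm study contributes).
    Edge attribute ``n_studies`` counts the supporting studies.
    """
    g = nx.Graph()
    g.add_nodes_from(ds.treatments)
    for study_id, arms in ds.studies.items():
        trts = sorted({a.treatment for a in arms})
        for u, v in itertools.combinations(trts, 2):
            if g.has_edge(u, v):
                g[u][v]["n_studies"] += 1
            else:
                g.add_edge(u, v, n_studies=1)
    return g


@dataclass(frozen=True)
class ValidationReport:
    """Report-only result of dataset validation; never mutates the data."""

    n_components: int
    components: tuple[frozenset[str], ...]
    single_arm_studies: tuple[str, ...]
    all_zero_studies: tuple[str, ...]
    all_events_studies: tuple[str, ...]
    connected: bool
    n_treatments: int
    has_loop: bool
    eligible: bool

    @property
    def problems(self) -> list[str]:
        msgs = []
        if not self.connected:
            msgs.append(f"network is disconnected ({self.n_components} components)")
        for s in self.single_arm_studies:
            msgs.append(f"study '{s}' has a single arm")
        return msgs


def validate(ds: NetworkDataset) -> ValidationReport:
    """Validate a dataset: connectivity, degenerate studies, survey eligibility.

    Eligibility (>= 4 treatment nodes, >= 1 closed loop, connected) mirrors
    the screening applied to published networks; it is reported, not
    enforced, so that small pedagogical networks can still be analysed.
    """
    g = comparison_graph(ds)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    n_comp = len(comps)
    single = tuple(s for s, arms in ds.studies.items() if len(arms) < 2)
    all_zero = tuple(
        s for s, arms in ds.studies.items() if all(a.events == 0 for a in arms)
    )
    all_events = tuple(
        s for s, arms in ds.studies.items() if all(a.events == a.n for a in arms)
    )
    n_trt = len(ds.treatments)
    # cycle-space dimension of the simple comparison graph
    n_loops = g.number_of_edges() - g.number_of_nodes() + n_comp
    connected = n_comp <= 1
    eligible = connected and n_trt >= 4 and n_loops >= 1
    return ValidationReport(
        n_components=n_comp,
        components=tuple(comps),
        single_arm_studies=single,
        all_zero_studies=all_zero,
        all_events_studies=all_events,
        connected=connected,
        n_treatments=n_trt,
        has_loop=n_loops >= 1,
        eligible=eligible,
    )


@dataclass(frozen=True)
class StructureMetrics:
    """Structural summary of a connected network.

    ``n_loops`` is the dimension of the cycle space of the simple graph of
    direct comparisons (edges - nodes + components); multi-edges collapse
    and a three-arm design contributes one triangle.  ``df_inconsistency``
    is the number of design-by-treatment interaction parameters,
    sum_d (t_d - 1) - (T - 1) for a connected network with T treatments and
    designs of t_d treatments each.
    """

    n_studies: int
    n_treatments: int
    n_edges: int
    n_designs: int
    n_multiarm: int
    n_loops: int
    has_single_study_edge: bool
    df_inconsistency: int
    ratio_studies_treatments: float
    ratio_loops_treatments: float
    ratio_loops_studies: float
    ratio_designs_studies: float
    ratio_edges_studies: float
    ratio_multiarm_studies: float

    def to_dict(self) -> dict:
        return {
            "n_studies": self.n_studies,
            "n_treatments": self.n_treatments,
            "n_edges": self.n_edges,
            "n_designs": self.n_designs,
            "n_multiarm": self.n_multiarm,
            "n_loops": self.n_loops,
            "has_single_study_edge": self.has_single_study_edge,
            "df_inconsistency": self.df_inconsistency,
            "ratio_studies_treatments": self.ratio_studies_treatments,
            "ratio_loops_treatments": self.ratio_loops_treatments,
            "ratio_loops_studies": self.ratio_loops_studies,
            "ratio_designs_studies": self.ratio_designs_studies,
            "ratio_edges_studies": self.ratio_edges_studies,
            "ratio_multiarm_studies": self.ratio_multiarm_studies,
        }


def structure_metrics(ds: NetworkDataset) -> StructureMetrics:
    """Compute the structural metrics of a connected network.

    Raises
    ------
    DisconnectedNetworkError
        If the comparison graph has more than one component; analyse the
        largest component separately or fix the data.
    """
    g = comparison_graph(ds)
    n_comp = nx.number_connected_components(g)
    if n_comp > 1:
        raise DisconnectedNetworkError(
            f"network '{ds.network_id}' has {n_comp} components; "
            "analyse the largest connected component or fix the data"
        )
    studies = ds.studies
    designs = ds.designs
    n_studies = len(studies)
    n_trt = g.number_of_nodes()
    n_edges = g.number_of_edges()
    n_multiarm = sum(1 for arms in studies.values()
                     if len({a.treatment for a in arms}) >= 3)
    n_loops = n_edges - n_trt + n_comp
    df_inc = sum(len(d) - 1 for d in designs) - (n_trt - 1)
    single_edge = any(d["n_studies"] == 1 for _, _, d in g.edges(data=True))
    return StructureMetrics(
        n_studies=n_studies,
        n_treatments=n_trt,
        n_edges=n_edges,
        n_designs=len(designs),
        n_multiarm=n_multiarm,
        n_loops=n_loops,
        has_single_study_edge=single_edge,
        df_inconsistency=df_inc,
        ratio_studies_treatments=n_studies / n_trt,
        ratio_loops_treatments=n_loops / n_trt,
        ratio_loops_studies=n_loops / n_studies,
        ratio_designs_studies=len(designs) / n_studies,
        ratio_edges_studies=n_edges / n_studies,
        ratio_multiarm_studies=n_multiarm / n_studies,
    )
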