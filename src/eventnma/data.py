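"""Arm-level trial data: types, validation, readers/writers, network structure.

Randomised trials report severe-event outcomes in one of two aggregate forms:

* **risk** — the number of patients with at least one event (``r``) out of the
  number randomised (``n``), over the trial's follow-up ``T``;
* **rate** — the total number of events (``y``) over the total person-years of
  exposure (``E``), which allows repeat events per patient.

A :class:`Study` may carry both forms (many trials report both), and an
:class:`EvidenceNetwork` collects studies together with the treatment coding
table and the head-to-head comparison structure.

File formats (UTF-8 CSV with a header row):

* risk table: ``study_id, treatment_code, r, n, followup, followup_unit``
* rate table: ``study_id, treatment_code, y, person_years``
* treatments table: ``code, label``

Follow-up is stored internally in years; the reader converts ``weeks``
(52.18 weeks/year) and ``months`` (12 months/year).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import CodingError, DataError, SchemaError

WEEKS_PER_YEAR = 52.18
MONTHS_PER_YEAR = 12.0

RISK_COLUMNS = ["study_id", "treatment_code", "r", "n", "followup", "followup_unit"]
RATE_COLUMNS = ["study_id", "treatment_code", "y", "person_years"]
TREATMENT_COLUMNS = ["code", "label"]

FormatName = Literal["risk", "rate", "mixed"]


@dataclass(frozen=True)
class Treatment:
    """A coded treatment; code 1 is the network reference regimen."""

    code: int
    label: str

    def __post_init__(self) -> None:
        if self.code < 1:
            raise CodingError(f"treatment codes are positive integers, got {self.code}")


@dataclass(frozen=True)
class RiskArm:
    """One arm's risk summary: patients with >=1 event out of those randomised."""

    study_id: str
    treatment_code: int
    events: int  # r: patients with at least one event
    n: int  # patients randomised
    followup: float  # years

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataError(f"{self.study_id}/{self.treatment_code}: n must be >= 1, got {self.n}")
        if not 0 <= self.events <= self.n:
            raise DataError(
                f"{self.study_id}/{self.treatment_code}: need 0 <= r <= n, "
                f"got r={self.events}, n={self.n}"
            )
        if not self.followup > 0:
            raise DataError(
                f"{self.study_id}/{self.treatment_code}: follow-up must be positive, "
                f"got {self.followup}"
            )


@dataclass(frozen=True)
class RateArm:
    """One arm's rate summary: total events over person-years of exposure."""

    study_id: str
    treatment_code: int
    events: int  # y: total event count (repeats included)
    exposure: float  # E: person-years

    def __post_init__(self) -> None:
        if self.events < 0:
            raise DataError(f"{self.study_id}/{self.treatment_code}: y must be >= 0")
        if not self.exposure > 0:
            raise DataError(
                f"{self.study_id}/{self.treatment_code}: exposure must be positive, "
                f"got {self.exposure}"
            )


@dataclass(frozen=True)
class Study:
    """All arms of one randomised study, in whichever formats it reported."""

    study_id: str
    risk_arms: tuple[RiskArm, ...] = ()
    rate_arms: tuple[RateArm, ...] = ()

    def __post_init__(self) -> None:
        if not self.risk_arms and not self.rate_arms:
            raise DataError(f"study {self.study_id} has no arms")
        if len(self.treatments) < 2:
            raise DataError(
                f"study {self.study_id} compares fewer than two distinct treatments"
            )
        followups = {a.followup for a in self.risk_arms}
        if len(followups) > 1:
            raise DataError(
                f"study {self.study_id}: risk arms disagree on follow-up: {sorted(followups)}"
            )
        if self.risk_arms and self.rate_arms:
            risk_t = {a.treatment_code for a in self.risk_arms}
            rate_t = {a.treatment_code for a in self.rate_arms}
            if risk_t != rate_t:
                raise DataError(
                    f"study {self.study_id}: risk and rate records cover different "
                    f"treatment sets {sorted(risk_t)} vs {sorted(rate_t)}"
                )
        for arms in (self.risk_arms, self.rate_arms):
            codes = [a.treatment_code for a in arms]
            if len(codes) != len(set(codes)):
                raise DataError(f"study {self.study_id}: duplicate arm for a treatment")

    @property
    def treatments(self) -> frozenset[int]:
        return frozenset(
            a.treatment_code for a in self.risk_arms + self.rate_arms
        )

    @property
    def reported_formats(self) -> frozenset[str]:
        fmts = set()
        if self.risk_arms:
            fmts.add("risk")
        if self.rate_arms:
            fmts.add("rate")
        return frozenset(fmts)

    @property
    def followup(self) -> float | None:
        """Common follow-up of the risk arms in years (None for rate-only)."""
        return self.risk_arms[0].followup if self.risk_arms else None

    def arms_for(self, fmt: str) -> tuple:
        if fmt == "risk":
            return self.risk_arms
        if fmt == "rate":
            return self.rate_arms
        raise ValueError(f"unknown format {fmt!r}")

    def baseline_code(self, fmt: str) -> int:
        """Study baseline = lowest treatment code among the arms used."""
        return min(a.treatment_code for a in self.arms_for(fmt))


@dataclass
class EvidenceNetwork:
    """Treatment coding plus studies plus the comparison graph they induce."""

    treatments: dict[int, Treatment]
    studies: list[Study] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = sorted(self.treatments)
        if codes != list(range(1, len(codes) + 1)):
            raise CodingError(f"treatment codes must be contiguous from 1, got {codes}")
        for study in self.studies:
            for code in study.treatments:
                if code not in self.treatments:
                    raise CodingError(
                        f"study {study.study_id} uses unknown treatment code {code}"
                    )
        seen = {c for s in self.studies for c in s.treatments}
        missing = set(self.treatments) - seen
        if self.studies and missing:
            raise DataError(
                f"treatments never observed in any study: {sorted(missing)}"
            )

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    def studies_for(self, subset: FormatName = "mixed") -> list[Study]:
        """Studies contributing records to an analysis of the given format.

        ``mixed`` keeps every study (the shared-parameter analysis set).
        """
        if subset == "mixed":
            return list(self.studies)
        if subset in ("risk", "rate"):
            return [s for s in self.studies if subset in s.reported_formats]
        raise ValueError(f"unknown subset {subset!r}")

    def comparison_graph(self, subset: FormatName = "mixed") -> nx.Graph:
        """Nodes = treatment codes; edges = observed head-to-head comparisons.

        Edge attribute ``n_trials`` counts studies making each comparison.
        """
        g = nx.Graph()
        g.add_nodes_from(self.treatments)
        for study in self.studies_for(subset):
            fmt = "rate" if subset == "rate" else ("risk" if subset == "risk" else None)
            if fmt is None:
                codes = sorted(study.treatments)
            else:
                codes = sorted(a.treatment_code for a in study.arms_for(fmt))
            for i, a in enumerate(codes):
                for b in codes[i + 1:]:
                    if g.has_edge(a, b):
                        g[a][b]["n_trials"] += 1
                    else:
                        g.add_edge(a, b, n_trials=1)
        return g


def validate_connectivity(
    network: EvidenceNetwork, subset: FormatName = "mixed"
) -> list[set[int]]:
    """Partition the treatments into connected components for an analysis subset.

    A single component covering all treatments certifies that the NMA basic
    parameters are estimable from the (direct plus indirect) evidence.  This is
    a diagnosis, not a failure: disconnected networks return several components.
    """
    graph = network.comparison_graph(subset)
    return sorted(
        (set(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), min(c)),
    )


def summarize_network(
    network: EvidenceNetwork, subset: FormatName = "mixed"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-treatment totals and per-comparison trial counts.

    Returns ``(nodes, edges)``: nodes carry the number of studies and the total
    randomised/exposure per treatment (the quantities a network plot scales node
    size by); edges carry the number of trials per direct comparison (line
    width).
    """
    rows = []
    for code, t in sorted(network.treatments.items()):
        n_randomised = 0
        exposure = 0.0
        n_studies = 0
        for study in network.studies_for(subset):
            if code not in study.treatments:
                continue
            in_subset = (
                subset == "mixed"
                or any(a.treatment_code == code for a in study.arms_for(subset))
            )
            if not in_subset:
                continue
            n_studies += 1
            for a in study.risk_arms:
                if a.treatment_code == code and subset != "rate":
                    n_randomised += a.n
            for a in study.rate_arms:
                if a.treatment_code == code and subset != "risk":
                    exposure += a.exposure
        rows.append(
            {
                "treatment_code": code,
                "label": t.label,
                "n_studies": n_studies,
                "n_randomised": n_randomised,
                "person_years": exposure,
            }
        )
    nodes = pd.DataFrame(rows).set_index("treatment_code")

    graph = network.comparison_graph(subset)
    edges = pd.DataFrame(
        [
            {"treatment_a": a, "treatment_b": b, "n_trials": d["n_trials"]}
            for a, b, d in sorted(graph.edges(data=True))
        ],
        columns=["treatment_a", "treatment_b", "n_trials"],
    )
    return nodes, edges


# ---------------------------------------------------------------------------
# readers / writers


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns {missing}")


def _followup_to_years(value: float, unit: str, where: str) -> float:
    unit = str(unit).strip().lower()
    if unit in ("year", "years", "y"):
        return float(value)
    if unit in ("month", "months", "m"):
        return float(value) / MONTHS_PER_YEAR
    if unit in ("week", "weeks", "w"):
        return float(value) / WEEKS_PER_YEAR
    raise SchemaError(f"{where}: unknown followup_unit {unit!r} (use weeks/months/years)")


def read_treatments(path: str | os.PathLike) -> dict[int, Treatment]:
    df = pd.read_csv(path)
    _check_columns(df, TREATMENT_COLUMNS, "treatments")
    treatments = {}
    for _, row in df.iterrows():
        code = int(row["code"])
        if code in treatments:
            raise CodingError(f"duplicate treatment code {code}")
        treatments[code] = Treatment(code=code, label=str(row["label"]))
    return treatments


def _read_risk_rows(path: str | os.PathLike) -> list[RiskArm]:
    df = pd.read_csv(path)
    _check_columns(df, RISK_COLUMNS, "risk")
    arms = []
    for idx, row in df.iterrows():
        where = f"risk row {idx} (study {row['study_id']})"
        try:
            arms.append(
                RiskArm(
                    study_id=str(row["study_id"]),
                    treatment_code=int(row["treatment_code"]),
                    events=int(row["r"]),
                    n=int(row["n"]),
                    followup=_followup_to_years(row["followup"], row["followup_unit"], where),
                )
            )
        except DataError as exc:
            raise DataError(f"{where}: {exc}") from exc
    return arms


def _read_rate_rows(path: str | os.PathLike) -> list[RateArm]:
    df = pd.read_csv(path)
    _check_columns(df, RATE_COLUMNS, "rate")
    arms = []
    for idx, row in df.iterrows():
        where = f"rate row {idx} (study {row['study_id']})"
        try:
            arms.append(
                RateArm(
                    study_id=str(row["study_id"]),
                    treatment_code=int(row["treatment_code"]),
                    events=int(row["y"]),
                    exposure=float(row["person_years"]),
                )
            )
        except DataError as exc:
            raise DataError(f"{where}: {exc}") from exc
    return arms


def _assemble(
    risk_arms: Iterable[RiskArm],
    rate_arms: Iterable[RateArm],
    treatments: Mapping[int, Treatment] | None,
) -> EvidenceNetwork:
    studies: dict[str, dict[str, list]] = {}
    for arm in risk_arms:
        studies.setdefault(arm.study_id, {"risk": [], "rate": []})["risk"].append(arm)
    for arm in rate_arms:
        studies.setdefault(arm.study_id, {"risk": [], "rate": []})["rate"].append(arm)
    study_objs = [
        Study(study_id=sid, risk_arms=tuple(d["risk"]), rate_arms=tuple(d["rate"]))
        for sid, d in studies.items()  # insertion order == row order
    ]
    if treatments is None:
        codes = sorted({c for s in study_objs for c in s.treatments})
        treatments = {c: Treatment(c, f"treatment {c}") for c in codes}
    return EvidenceNetwork(treatments=dict(treatments), studies=study_objs)


def read_network(
    path: str | os.PathLike,
    format: FormatName = "mixed",
    treatments_path: str | os.PathLike | None = None,
) -> EvidenceNetwork:
    """Read a validated evidence network from CSV tables.

    ``path`` is either a directory containing ``risk.csv`` / ``rate.csv`` /
    ``treatments.csv`` (whichever the format needs), or — for the single-format
    reads — the table file itself, with ``treatments_path`` naming the coding
    table (optional; codes are then derived from the data).
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        risk_path = os.path.join(path, "risk.csv")
        rate_path = os.path.join(path, "rate.csv")
        t_path = treatments_path or os.path.join(path, "treatments.csv")
    else:
        risk_path = rate_path = path
        t_path = treatments_path

    treatments = read_treatments(t_path) if t_path and os.path.exists(os.fspath(t_path)) else None

    risk_arms: list[RiskArm] = []
    rate_arms: list[RateArm] = []
    if format in ("risk", "mixed"):
        if not os.path.exists(risk_path):
            if format == "risk":
                raise SchemaError(f"risk table not found at {risk_path}")
        else:
            risk_arms = _read_risk_rows(risk_path)
    if format in ("rate", "mixed"):
        if not os.path.exists(rate_path):
            if format == "rate":
                raise SchemaError(f"rate table not found at {rate_path}")
        else:
            rate_arms = _read_rate_rows(rate_path)
    if format not in ("risk", "rate", "mixed"):
        raise ValueError(f"unknown format {format!r}")
    if not risk_arms and not rate_arms:
        raise SchemaError(f"no arm records found under {path}")
    return _assemble(risk_arms, rate_arms, treatments)


def network_to_tables(network: EvidenceNetwork) -> dict[str, pd.DataFrame]:
    """Represent a network as the three CSV-schema DataFrames."""
    risk_rows = []
    rate_rows = []
    for study in network.studies:
        for a in study.risk_arms:
            risk_rows.append(
                {
                    "study_id": a.study_id,
                    "treatment_code": a.treatment_code,
                    "r": a.events,
                    "n": a.n,
                    "followup": a.followup,
                    "followup_unit": "years",
                }
            )
        for a in study.rate_arms:
            rate_rows.append(
                {
                    "study_id": a.study_id,
                    "treatment_code": a.treatment_code,
                    "y": a.events,
                    "person_years": a.exposure,
                }
            )
    return {
        "risk": pd.DataFrame(risk_rows, columns=RISK_COLUMNS),
        "rate": pd.DataFrame(rate_rows, columns=RATE_COLUMNS),
        "treatments": pd.DataFrame(
            [{"code": c, "label": t.label} for c, t in sorted(network.treatments.items())],
            columns=TREATMENT_COLUMNS,
        ),
    }


def write_network(network: EvidenceNetwork, directory: str | os.PathLike) -> None:
    """Write ``risk.csv``, ``rate.csv`` and ``treatments.csv`` under a directory."""
    os.makedirs(directory, exist_ok=True)
    tables = network_to_tables(network)
    tables["treatments"].to_csv(os.path.join(directory, "treatments.csv"), index=False)
    if len(tables["risk"]):
        tables["risk"].to_csv(os.path.join(directory, "risk.csv"), index=False)
    if len(tables["rate"]):
        tables["rate"].to_csv(os.path.join(directory, "rate.csv"), index=False)
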