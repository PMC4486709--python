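"""Reading cohort tables and writing inferred networks.

The pipeline starts from a quantified wide-format concentration table
(rows = serum samples, columns = metabolite concentrations in mM) plus a
sample metadata table carrying animal id, experimental group (FS = fasted,
CPF = carbohydrate pre-fed), timepoint label and survival status.  The
sampling schedule is fixed: a pre-hemorrhage baseline (BS) followed by six
post-hemorrhage draws at 45 min and 3, 5, 9, 17 and 21 h.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .network_assembly import RegulatoryNetwork

logger = logging.getLogger(__name__)

#: Fixed timepoint-label -> hours-after-hemorrhage mapping.
TIMEPOINT_HOURS: dict[str, float] = {
    "BS": 0.0,
    "S45": 0.75,
    "FR2": 3.0,
    "FR4": 5.0,
    "FR8": 9.0,
    "FR16": 17.0,
    "FR20": 21.0,
}

#: Post-hemorrhage labels in schedule order.
POST_BASELINE_TIMEPOINTS: tuple[str, ...] = ("S45", "FR2", "FR4", "FR8", "FR16", "FR20")

GROUPS: tuple[str, ...] = ("FS", "CPF")

_TRUE_STRINGS = {"true", "t", "1", "yes", "y"}
_FALSE_STRINGS = {"false", "f", "0", "no", "n"}


@dataclass(frozen=True)
class SampleRecord:
    """One serum sample draw: who, when, and whether the animal survived."""

    sample_id: str
    animal_id: str
    group: str
    timepoint: str
    survived: bool

    @property
    def hours_post_hemorrhage(self) -> float:
        return TIMEPOINT_HOURS[self.timepoint]


@dataclass
class CohortTimeSeries:
    """Concentrations (mM) indexed animal x timepoint x metabolite.

    ``samples`` is indexed by sample_id with columns ``animal_id``, ``group``,
    ``timepoint``, ``hours``, ``survived``; ``concentrations`` shares the index
    with one column per metabolite.  NaN marks a missing measurement.
    ``is_shifted`` / ``is_normalized`` record preprocessing provenance and
    ``degenerate`` lists metabolites whose pooled variance vanished under
    normalization (left unscaled).
    """

    samples: pd.DataFrame
    concentrations: pd.DataFrame
    is_shifted: bool = False
    is_normalized: bool = False
    degenerate: frozenset = field(default_factory=frozenset)

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.concentrations.columns)

    @property
    def animals(self) -> list[str]:
        return sorted(self.samples["animal_id"].unique())

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def resolve(self, name: str) -> str:
        """Map a metabolite name to its canonical header form.

        Matching is case-insensitive after trimming, so e.g. ``"lactate"``
        resolves to ``"Lactate"`` as spelled in the concentration header.
        """
        key = name.strip().casefold()
        for canonical in self.concentrations.columns:
            if canonical.strip().casefold() == key:
                return canonical
        raise KeyError(f"unknown metabolite {name!r}")

    def subset_group(self, group: str) -> "CohortTimeSeries":
        mask = self.samples["group"] == group
        return replace(
            self,
            samples=self.samples.loc[mask].copy(),
            concentrations=self.concentrations.loc[mask].copy(),
        )

    def post_baseline_mask(self) -> pd.Series:
        return self.samples["timepoint"] != "BS"

    def validate(self) -> None:
        samples, conc = self.samples, self.concentrations
        if not samples.index.equals(conc.index):
            raise ValueError("samples and concentrations must share a sample_id index")
        names = [str(c).strip().casefold() for c in conc.columns]
        if len(set(names)) != len(names):
            raise ValueError("metabolite names must be unique (case-insensitive)")
        unknown = set(samples["timepoint"]) - set(TIMEPOINT_HOURS)
        if unknown:
            bad = samples.index[samples["timepoint"].isin(unknown)][0]
            raise ValueError(
                f"unknown timepoint label(s) {sorted(unknown)} (first offending sample: {bad})"
            )
        bad_group = set(samples["group"]) - set(GROUPS)
        if bad_group:
            raise ValueError(f"unknown group label(s) {sorted(bad_group)}; expected {GROUPS}")
        expected_hours = samples["timepoint"].map(TIMEPOINT_HOURS)
        if not np.allclose(samples["hours"], expected_hours):
            raise ValueError("hours column disagrees with the fixed timepoint schedule")
        dup = samples.duplicated(subset=["animal_id", "timepoint"])
        if dup.any():
            raise ValueError(
                f"duplicate (animal_id, timepoint) pair at sample {samples.index[dup][0]}"
            )
        if not self.is_shifted:
            values = conc.to_numpy(dtype=float)
            neg = np.asarray(values < 0) & np.isfinite(values)
            if neg.any():
                i, j = np.argwhere(neg)[0]
                raise ValueError(
                    f"negative concentration for metabolite {conc.columns[j]!r} "
                    f"in sample {conc.index[i]!r}"
                )

    def to_records(self) -> list[SampleRecord]:
        return [
            SampleRecord(
                sample_id=str(idx),
                animal_id=row["animal_id"],
                group=row["group"],
                timepoint=row["timepoint"],
                survived=bool(row["survived"]),
            )
            for idx, row in self.samples.iterrows()
        ]


def _parse_survived(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float)):
        return bool(value)
    text = str(value).strip().casefold()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise ValueError(f"cannot interpret survived value {value!r}")


def read_cohort(
    concentration_path, metadata_path, sep: str = ",",
) -> CohortTimeSeries:
    """Read and join a concentration table and its sample metadata.

    Both files are delimited text (comma by default, ``sep="\\t"`` for TSV).
    The concentration file's first column is the sample id; every other
    column is one metabolite, in mM.  Missing values may be empty cells or
    ``NA``.  Rows present in only one of the two files are dropped with a
    logged warning.
    """
    conc = pd.read_csv(concentration_path, sep=sep, na_values=["NA"], dtype={0: str})
    meta = pd.read_csv(metadata_path, sep=sep, na_values=["NA"], dtype=str)

    required = {"sample_id", "animal_id", "group", "timepoint", "survived"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing required column(s): {sorted(missing)}")

    conc = conc.rename(columns={conc.columns[0]: "sample_id"})
    for frame, label in ((conc, "concentration"), (meta, "metadata")):
        if frame["sample_id"].isna().any() or (frame["sample_id"].str.strip() == "").any():
            raise ValueError(f"{label} table has a missing sample_id join key")
    conc["sample_id"] = conc["sample_id"].str.strip()
    meta["sample_id"] = meta["sample_id"].str.strip()

    unmatched_conc = set(conc["sample_id"]) - set(meta["sample_id"])
    unmatched_meta = set(meta["sample_id"]) - set(conc["sample_id"])
    for unmatched, label in ((unmatched_conc, "concentration"), (unmatched_meta, "metadata")):
        if unmatched:
            logger.warning(
                "%d %s row(s) had no join partner and were dropped: %s",
                len(unmatched), label, sorted(unmatched)[:5],
            )
    keep = sorted(set(conc["sample_id"]) & set(meta["sample_id"]))
    conc = conc.set_index("sample_id").loc[keep]
    meta = meta.set_index("sample_id").loc[keep]

    metabolites = [str(c).strip() for c in conc.columns]
    conc.columns = metabolites
    conc = conc.astype(float)

    samples = pd.DataFrame(
        {
            "animal_id": meta["animal_id"].str.strip(),
            "group": meta["group"].str.strip(),
            "timepoint": meta["timepoint"].str.strip(),
            "survived": meta["survived"].map(_parse_survived),
        },
        index=meta.index,
    )
    samples["hours"] = samples["timepoint"].map(TIMEPOINT_HOURS)
    if samples["hours"].isna().any():
        bad = samples.index[samples["hours"].isna()][0]
        raise ValueError(
            f"unknown timepoint label {samples.loc[bad, 'timepoint']!r} in metadata row {bad!r}"
        )

    cohort = CohortTimeSeries(samples=samples, concentrations=conc)
    cohort.validate()
    return cohort


def write_network(net: "RegulatoryNetwork", edge_path, graph_path) -> None:
    """Serialize a network as a TSV edge list plus a GraphML graph.

    The TSV has columns ``controlled``, ``controlling``, ``sign``, ``weight``
    (full precision); the GraphML carries a node attribute ``role`` in
    {controlled, controlling, both} and signed edge weights, with edges
    directed controlling -> controlled.
    """
    import networkx as nx

    with open(edge_path, "w") as fh:
        fh.write("controlled\tcontrolling\tsign\tweight\n")
        for e in net.edges:
            fh.write(f"{e.controlled}\t{e.controlling}\t{e.sign}\t{e.weight!r}\n")

    graph = nx.DiGraph()
    controlling = {e.controlling for e in net.edges}
    for node in sorted(net.controlled_nodes | controlling):
        if node in net.controlled_nodes and node in controlling:
            role = "both"
        elif node in net.controlled_nodes:
            role = "controlled"
        else:
            role = "controlling"
        graph.add_node(node, role=role)
    for e in net.edges:
        graph.add_edge(e.controlling, e.controlled, sign=e.sign, weight=float(e.weight))
    graph.graph["group"] = net.group
    nx.write_graphml(graph, graph_path)


def write_cohort(cohort: CohortTimeSeries, concentration_path, metadata_path, sep: str = ",") -> None:
    """Write a cohort as the concentration/metadata file pair ``read_cohort`` accepts."""
    conc = cohort.concentrations.copy()
    conc.index.name = "sample_id"
    conc.to_csv(concentration_path, sep=sep)
    meta = cohort.samples[["animal_id", "group", "timepoint", "survived"]].copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep=sep)


def read_network(edge_path, group: str = "FS") -> "RegulatoryNetwork":
    """Rebuild a network from an edge TSV written by :func:`write_network`."""
    from .network_assembly import Edge, RegulatoryNetwork

    table = pd.read_csv(edge_path, sep="\t", dtype={"controlled": str, "controlling": str})
    edges = [
        Edge(row.controlled, row.controlling, row.sign, float(row.weight))
        for row in table.itertuples(index=False)
    ]
    return RegulatoryNetwork.from_edges(edges, group=group)
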