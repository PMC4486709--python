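"""Assembling signed regulatory networks, surrogates and feedback nodes.

A network is the set of accepted sparse fits read as signed edges
controlling -> controlled, together with *surrogate groups*: for each
controlling node, the other metabolites whose pooled trajectories are so
strongly correlated (R^2 above 0.8 by default) that they could substitute
for it with little loss of predictive power.  A *feedback node* is a
metabolite that is simultaneously controlled and controlling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .io_formats import CohortTimeSeries
from .network_inference import SparseFit
from .preprocessing import RatePanel

logger = logging.getLogger(__name__)


class Edge(NamedTuple):
    controlled: str
    controlling: str
    sign: str  # "+" or "-"
    weight: float


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Signed controlled/controlling network for one experimental group."""

    group: str
    controlled_nodes: frozenset
    edges: tuple
    surrogate_groups: Mapping[str, frozenset] = field(default_factory=dict)

    def __post_init__(self):
        for e in self.edges:
            if e.controlled not in self.controlled_nodes:
                raise ValueError(
                    f"edge {e} has controlled endpoint outside the controlled set"
                )
            if e.sign not in ("+", "-"):
                raise ValueError(f"edge {e} has invalid sign {e.sign!r}")
            if e.weight != 0 and (e.weight > 0) != (e.sign == "+"):
                raise ValueError(f"edge {e} sign disagrees with weight")
        for node, group in self.surrogate_groups.items():
            if node in group:
                raise ValueError(f"{node!r} appears in its own surrogate group")

    @property
    def controlling_nodes(self) -> frozenset:
        return frozenset(e.controlling for e in self.edges)

    @property
    def feedback_nodes(self) -> frozenset:
        """Metabolites that are both controlled and controlling."""
        return self.controlled_nodes & self.controlling_nodes

    @property
    def edge_set(self) -> frozenset:
        """Signed edges without weights, for set-level comparisons."""
        return frozenset((e.controlled, e.controlling, e.sign) for e in self.edges)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Edge],
        group: str = "FS",
        surrogate_groups: Mapping[str, frozenset] | None = None,
        extra_controlled: Iterable[str] = (),
    ) -> "RegulatoryNetwork":
        edges = tuple(edges)
        controlled = frozenset(e.controlled for e in edges) | frozenset(extra_controlled)
        return cls(
            group=group,
            controlled_nodes=controlled,
            edges=edges,
            surrogate_groups=dict(surrogate_groups or {}),
        )


def assemble(
    fits: Iterable[SparseFit],
    panel: RatePanel,
    surrogates: Mapping[str, frozenset] | None = None,
    group: str = "FS",
) -> RegulatoryNetwork:
    """Build the signed network from accepted fits.

    Edge weights are the fitted coefficients; the feedback set falls out of
    the controlled/controlling intersection.  Accepted fits with an empty
    support contribute a controlled node but no edges.
    """
    edges = []
    controlled = set()
    for fit in fits:
        if not fit.accepted:
            continue
        controlled.add(fit.target)
        for name in fit.support:
            w = fit.coefficient_of(name, panel)
            edges.append(Edge(fit.target, name, "+" if w > 0 else "-", w))
    edges.sort(key=lambda e: (e.controlled, e.controlling))
    return RegulatoryNetwork(
        group=group,
        controlled_nodes=frozenset(controlled),
        edges=tuple(edges),
        surrogate_groups=dict(surrogates or {}),
    )


def correlated_signals(
    cohort: CohortTimeSeries, node: str, r2_threshold: float = 0.8
) -> frozenset:
    """Metabolites whose pooled squared correlation with ``node`` exceeds the threshold.

    Pearson correlation is computed on the shifted, normalized post-baseline
    trajectories pooled over all animals, per pair on jointly non-missing
    entries; the comparison is strict (R^2 > threshold) and the node itself
    is never returned.
    """
    if not (cohort.is_shifted and cohort.is_normalized):
        raise ValueError("correlated_signals expects a shifted and normalized cohort")
    canonical = cohort.resolve(node)
    post = cohort.concentrations.loc[cohort.post_baseline_mask()]
    x = post[canonical]
    if x.std(skipna=True) < 1e-12 or x.count() < 3:
        logger.warning("metabolite %s is degenerate; no correlated signals", canonical)
        return frozenset()

    out = set()
    for other in post.columns:
        if other == canonical:
            continue
        pair = post[[canonical, other]].dropna()
        if len(pair) < 3 or pair[other].std() < 1e-12:
            continue
        r = np.corrcoef(pair[canonical], pair[other])[0, 1]
        if r * r > r2_threshold:
            out.add(other)
    return frozenset(out)


def surrogate_map(
    cohort: CohortTimeSeries,
    controlling_nodes: Iterable[str],
    r2_threshold: float = 0.8,
) -> dict:
    """Correlated-signal sets for each controlling node (table-style)."""
    return {
        cohort.resolve(node): correlated_signals(cohort, node, r2_threshold)
        for node in sorted(set(controlling_nodes))
    }


def render_tables(net: RegulatoryNetwork) -> str:
    """Two aligned TSV tables: controlled->controlling and controlling->surrogates.

    Controlling nodes are listed in decreasing coefficient-magnitude order,
    each with its sign; surrogate signals are comma-joined alphabetically.
    Output is deterministic: equal networks render byte-identically.
    """
    lines = ["controlled_node\tcontrolling_nodes"]
    by_controlled: dict[str, list[Edge]] = {}
    for e in net.edges:
        by_controlled.setdefault(e.controlled, []).append(e)
    for controlled in sorted(net.controlled_nodes):
        entries = sorted(
            by_controlled.get(controlled, []),
            key=lambda e: (-abs(e.weight), e.controlling),
        )
        rendered = "; ".join(f"{e.controlling} ({e.sign})" for e in entries)
        lines.append(f"{controlled}\t{rendered}")

    lines.append("")
    lines.append("controlling_node\tcorrelated_signals")
    for node in sorted(net.surrogate_groups):
        joined = ", ".join(sorted(net.surrogate_groups[node]))
        lines.append(f"{node}\t{joined}")
    return "\n".join(lines) + "\n"
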