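"""Example signed networks from a porcine hemorrhagic-shock study.

The printed controlled/controlling relations and correlated-signal tables
for the fasted (FS) and carbohydrate pre-fed (CPF) arms of the porcine
trauma and hemorrhagic-shock serum study this pipeline was designed
around.  The published tables report signs but not coefficient
magnitudes, so every edge carries weight +/-1.  These serve as worked
examples and as realistic topologies for synthetic-recovery fixtures.

Abbreviations follow the printed tables: OPC = O-phosphocholine,
BHB = 3-hydroxybutyrate, PAA = phenylalanine, AHB = 2-hydroxybutyrate,
DMA = dimethylamine.
"""

from __future__ import annotations

from .network_assembly import Edge, RegulatoryNetwork

#: (controlled, controlling, sign) relations for the fasted arm.
FASTED_RELATIONS: tuple = (
    ("Adenosine", "Succinate", "-"),
    ("Adenosine", "OPC", "+"),
    ("Cytidine", "Succinate", "-"),
    ("Cytidine", "OPC", "+"),
    ("Cytidine", "Lactate", "-"),
    ("Cytidine", "Adenosine", "-"),
    ("Glycerol", "Uridine", "+"),
    ("Glycerol", "Lactate", "-"),
    ("Hypoxanthine", "Succinate", "-"),
    ("Lactate", "BHB", "-"),
    ("Lactate", "OPC", "+"),
    ("Lactate", "Citrate", "-"),
    ("Lactate", "Creatine", "-"),
    ("Lactate", "Isobutyrate", "-"),
    ("Uridine", "Succinate", "-"),
    ("Uridine", "OPC", "+"),
    ("Uridine", "Glutamine", "+"),
)

#: (controlled, controlling, sign) relations for the carbohydrate pre-fed arm.
PREFED_RELATIONS: tuple = (
    ("Adenosine", "PAA", "-"),
    ("Adenosine", "AHB", "+"),
    ("Adenosine", "Lactate", "-"),
    ("Cytidine", "PAA", "-"),
    ("Cytidine", "AHB", "+"),
    ("Cytidine", "Formate", "-"),
    ("Glycerol", "Citrate", "-"),
    ("Glycerol", "Acetoacetate", "+"),
    ("Glycerol", "Lactate", "-"),
    ("Hypoxanthine", "Alanine", "-"),
    ("Hypoxanthine", "Glutamate", "+"),
    ("Lactate", "Alanine", "-"),
    ("Lactate", "Glutamate", "+"),
    ("Lactate", "DMA", "+"),
    ("Uridine", "PAA", "-"),
    ("Uridine", "Phenylacetate", "+"),
)

#: Correlated signals (pooled R^2 > 0.8) of the fasted controlling nodes.
FASTED_SURROGATES: dict = {
    "OPC": frozenset({"Glutamate", "Isoleucine", "Leucine", "Valine"}),
    "Lactate": frozenset({"Choline", "Pyruvate"}),
    "Isobutyrate": frozenset({"Pyruvate"}),
    "Glutamine": frozenset(
        {
            "3-hydroxyisovalerate",
            "Glutamate",
            "Glycine",
            "Histidine",
            "Isoleucine",
            "Leucine",
            "Methionine",
            "Serine",
            "Valine",
        }
    ),
}

#: Correlated signals (pooled R^2 > 0.8) of the pre-fed controlling nodes.
PREFED_SURROGATES: dict = {
    "PAA": frozenset({"Tyrosine"}),
    "Lactate": frozenset({"Succinate"}),
    "Alanine": frozenset({"Pyruvate", "Tyrosine"}),
    "Glutamate": frozenset({"Leucine"}),
}


def _network(relations, surrogates, group) -> RegulatoryNetwork:
    edges = [
        Edge(controlled, controlling, sign, 1.0 if sign == "+" else -1.0)
        for controlled, controlling, sign in relations
    ]
    return RegulatoryNetwork.from_edges(edges, group=group, surrogate_groups=surrogates)


def fasted_network() -> RegulatoryNetwork:
    """The published fasted-arm (FS) network as a RegulatoryNetwork."""
    return _network(FASTED_RELATIONS, FASTED_SURROGATES, "FS")


def prefed_network() -> RegulatoryNetwork:
    """The published carbohydrate pre-fed (CPF) network as a RegulatoryNetwork."""
    return _network(PREFED_RELATIONS, PREFED_SURROGATES, "CPF")
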