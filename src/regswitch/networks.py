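"""Per-patient rewiring networks and their export.

Nodes are GO terms colored by state — disease-only (white), healthy-only
(black), both directions across the patient's SNPs (grey) — and sized by
the number of incident switch edges (for shared-only grey nodes, the
number of shared-state records). Edges run healthy term → disease term
and carry the supporting SNP ids, parallel SNPs merged onto one edge with
a multiplicity attribute.
"""

from __future__ import annotations

import networkx as nx

from .switches import PatientSwitchProfile

STATE_TO_COLOR = {"gained": "white", "lost": "black", "both": "grey",
                  "shared": "grey"}


def build_network(profile: PatientSwitchProfile) -> nx.DiGraph:
    """Build a patient's rewiring network from their filtered switch profile."""
    g = nx.DiGraph(patient_id=profile.patient_id, disease=profile.disease)
    edges: dict[tuple[str, str], set[str]] = {}
    for s in profile.switches:
        edges.setdefault((s.healthy_term, s.disease_term), set()).add(s.rsid)
    for term, state in sorted(profile.term_states.items()):
        g.add_node(term, state=state, color=STATE_TO_COLOR[state], size=0)
    for (h, d), rsids in sorted(edges.items()):
        g.add_edge(h, d, rsids=",".join(sorted(rsids)), multiplicity=len(rsids))
    for node in g.nodes:
        incident = g.in_degree(node) + g.out_degree(node)
        if incident == 0 and g.nodes[node]["state"] == "shared":
            incident = 1  # one shared-state record
        g.nodes[node]["size"] = incident
    return g


def export_graph(network: nx.DiGraph, path: str, fmt: str = "GraphML") -> None:
    """Write the network as GraphML (full attributes) or SIF (topology only,
    relation ``switches_to``)."""
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(network, path, named_key_ids=True)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for h, d in sorted(network.edges):
                fh.write(f"{h}\tswitches_to\t{d}\n")
            for node in sorted(network.nodes):
                if network.degree(node) == 0:
                    fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}; use GraphML or SIF")


def read_graphml(path: str) -> nx.DiGraph:
    """Read back an exported GraphML network with integer attributes restored."""
    g = nx.read_graphml(path)
    graph_attrs = {k: v for k, v in g.graph.items()
                   if k not in ("node_default", "edge_default")}
    out = nx.DiGraph(**graph_attrs)
    for node, data in g.nodes(data=True):
        out.add_node(node, state=data["state"], color=data["color"],
                     size=int(data["size"]))
    for u, v, data in g.edges(data=True):
        out.add_edge(u, v, rsids=data["rsids"], multiplicity=int(data["multiplicity"]))
    return out
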