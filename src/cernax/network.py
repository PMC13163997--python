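"""Sign-consistent ceRNA triplet assembly and network construction.

Under the ceRNA hypothesis a lncRNA sponges miRNAs shared with an mRNA, so
in tumor-vs-normal data the lncRNA and mRNA should move in the same
direction and opposite to the miRNA: a downregulated lncRNA pairs with
upregulated miRNAs and their downregulated mRNA targets, and vice versa.
Triplets — not pairs — are the retention unit: an edge with no
sign-consistent third partner never enters the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .interactions import LNC_MIR, MIR_MRNA, InteractionEdge

logger = logging.getLogger(__name__)

EXPORT_FORMATS = ("sif", "graphml", "edge_tsv", "node_tsv")


@dataclass(frozen=True)
class CeRNATriplet:
    """A sign-consistent (lncRNA, miRNA, mRNA) with stored directions."""

    lncrna: str
    mirna: str
    mrna: str
    directions: tuple = ()  # ((id, direction), ...) in lnc, mir, mrna order

    def direction_of(self, node: str) -> str:
        return dict(self.directions)[node]


@dataclass
class CeRNANetwork:
    """Union of triplet nodes and edges, with per-triplet provenance."""

    graph: nx.Graph
    triplets: list[CeRNATriplet] = field(default_factory=list)

    @property
    def nodes(self) -> dict[str, dict]:
        return {n: dict(d) for n, d in self.graph.nodes(data=True)}

    @property
    def edges(self) -> set[tuple[str, str, str]]:
        out = set()
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.add((a, b, d["edge_type"]))
        return out

    def counts_by_type(self) -> dict[str, dict[str, int]]:
        """Node counts per type and direction (e.g. for run logs)."""
        out: dict[str, dict[str, int]] = {}
        for _, d in self.graph.nodes(data=True):
            t = out.setdefault(d["node_type"], {"up": 0, "down": 0})
            t[d["direction"]] += 1
        return out


def assemble_triplets(
    lnc_mir_edges: list[InteractionEdge],
    mir_mrna_edges: list[InteractionEdge],
    directions: dict[str, str],
) -> list[CeRNATriplet]:
    """All (lncRNA, miRNA, mRNA) with both edges present and the sign rule
    direction(lncRNA) = direction(mRNA) != direction(miRNA).

    Many-to-many combinations are allowed; output order is lexicographic.
    """
    for e in list(lnc_mir_edges) + list(mir_mrna_edges):
        for node in (e.source, e.target):
            if node not in directions:
                raise ValueError(f"endpoint {node!r} has no direction")

    by_mir: dict[str, list[str]] = {}
    for e in lnc_mir_edges:
        if e.edge_type != LNC_MIR:
            raise ValueError("first argument must hold lnc_mir edges")
        by_mir.setdefault(e.target, []).append(e.source)

    triplets = []
    for e in mir_mrna_edges:
        if e.edge_type != MIR_MRNA:
            raise ValueError("second argument must hold mir_mrna edges")
        mir, mrna = e.source, e.target
        d_mir, d_mrna = directions[mir], directions[mrna]
        if d_mir == d_mrna:
            continue
        for lnc in by_mir.get(mir, []):
            if directions[lnc] == d_mrna:
                triplets.append(CeRNATriplet(
                    lncrna=lnc, mirna=mir, mrna=mrna,
                    directions=((lnc, directions[lnc]), (mir, d_mir), (mrna, d_mrna)),
                ))
    triplets = sorted(set(triplets), key=lambda t: (t.lncrna, t.mirna, t.mrna))
    return triplets


def build_network(triplets: list[CeRNATriplet]) -> CeRNANetwork:
    """Union the triplets into a typed, direction-annotated graph."""
    g = nx.Graph()
    if not triplets:
        logger.warning("build_network: empty triplet list -> empty network")
        return CeRNANetwork(graph=g, triplets=[])
    for t in triplets:
        dirs = dict(t.directions)
        g.add_node(t.lncrna, node_type="lncRNA", direction=dirs[t.lncrna])
        g.add_node(t.mirna, node_type="miRNA", direction=dirs[t.mirna])
        g.add_node(t.mrna, node_type="mRNA", direction=dirs[t.mrna])
        g.add_edge(t.lncrna, t.mirna, edge_type=LNC_MIR)
        g.add_edge(t.mirna, t.mrna, edge_type=MIR_MRNA)
    net = CeRNANetwork(graph=g, triplets=list(triplets))
    logger.info("ceRNA network: %s", net.counts_by_type())
    return net


def extract_subnetwork(network: CeRNANetwork, center: str, radius: int = 1) -> CeRNANetwork:
    """Induced subgraph of nodes within edge-distance ``radius`` of center."""
    if center not in network.graph:
        raise ValueError(f"unknown center node {center!r}")
    sub = nx.ego_graph(network.graph, center, radius=radius)
    members = set(sub.nodes)
    kept = [t for t in network.triplets
            if {t.lncrna, t.mirna, t.mrna} <= members]
    return CeRNANetwork(graph=sub.copy(), triplets=kept)


# ---------------------------------------------------------------- exports

def export_network(network: CeRNANetwork, path, fmt: str) -> None:
    """Write the network as SIF, GraphML, or node/edge TSV.

    SIF lines are ``source<TAB>edge_type<TAB>target``; the edge TSV carries
    endpoint types and directions so a round-trip read reproduces the
    network exactly.
    """
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; supported: {EXPORT_FORMATS}")
    g = network.graph
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1])):
                fh.write(f"{u}\t{d['edge_type']}\t{v}\n")
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edge_tsv":
        rows = []
        for u, v, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1])):
            rows.append({
                "source": u, "target": v, "edge_type": d["edge_type"],
                "source_type": g.nodes[u]["node_type"],
                "source_direction": g.nodes[u]["direction"],
                "target_type": g.nodes[v]["node_type"],
                "target_direction": g.nodes[v]["direction"],
            })
        pd.DataFrame(rows, columns=["source", "target", "edge_type",
                                    "source_type", "source_direction",
                                    "target_type", "target_direction"]
                     ).to_csv(path, sep="\t", index=False)
    elif fmt == "node_tsv":
        rows = [{"node": n, "node_type": d["node_type"], "direction": d["direction"]}
                for n, d in sorted(g.nodes(data=True))]
        pd.DataFrame(rows, columns=["node", "node_type", "direction"]).to_csv(
            path, sep="\t", index=False)


def read_network_edge_tsv(path) -> CeRNANetwork:
    """Rebuild a network from an ``edge_tsv`` export (triplet provenance is
    not serialized and comes back empty)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_node(row.source, node_type=row.source_type, direction=row.source_direction)
        g.add_node(row.target, node_type=row.target_type, direction=row.target_direction)
        g.add_edge(row.source, row.target, edge_type=row.edge_type)
    return CeRNANetwork(graph=g, triplets=[])
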