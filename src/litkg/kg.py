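"""Knowledge-graph assembly and export.

Nodes are canonical entities (id, preferred name, entity type, optional MeSH
classification, corpus mention count); edges carry the relation type, the
trigger keywords observed, the supporting PMIDs, and the aggregation
confidence/support — the schema a literature-mined biomedical KG serves in a
property-graph store. Parallel edges of *different* relation types between
one pair are retained; same-type duplicates merge with pmid-set union.

Exports: GraphML (round-trip safe), Neo4j bulk-import CSV pair, and a TSV
triple dump for diffing.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx

from .lexicon import Lexicon
from .ner import EntityCensus
from .relations import AggregatedRelation


class GraphIntegrityError(ValueError):
    """An edge references an entity absent from the node set."""


@dataclass(frozen=True)
class KGNode:
    node_id: str
    name: str
    entity_type: str
    mesh_id: str = ""
    mention_count: int = 0


def _join(values: Iterable[str]) -> str:
    return "|".join(sorted(values))


def nodes_from_corpus(
    kept_entities: Mapping[str, str] | Iterable[tuple[str, str]],
    census: EntityCensus | None = None,
    lexicons: Mapping[str, Lexicon] | None = None,
) -> list[KGNode]:
    """Build node records from (canonical id -> entity type) pairs.

    Preferred names come from the lexicons where available, else the census
    example surface, else the id itself; MeSH ids are carried when the
    canonical id itself lives in the MESH namespace.
    """
    items = kept_entities.items() if isinstance(kept_entities, Mapping) else kept_entities
    nodes = []
    for cid, etype in sorted(items):
        name = cid
        if lexicons and etype in lexicons and cid in lexicons[etype].entries:
            name = lexicons[etype].entries[cid].preferred_name
        elif census is not None and cid in census.example_surface:
            name = census.example_surface[cid]
        nodes.append(
            KGNode(
                node_id=cid,
                name=name,
                entity_type=etype,
                mesh_id=cid if cid.startswith("MESH:") else "",
                mention_count=census.mention_counts.get(cid, 0) if census else 0,
            )
        )
    return nodes


def build_graph(
    nodes: Sequence[KGNode],
    relations: Sequence[AggregatedRelation],
) -> nx.MultiGraph:
    """Assemble the KG; referential integrity is enforced.

    Edge keys are relation types, so one pair holds at most one edge per
    type (merged with pmid/keyword union) and parallel edges across types.
    """
    g = nx.MultiGraph()
    for node in nodes:
        if node.node_id in g:
            raise GraphIntegrityError(f"duplicate node id {node.node_id}")
        g.add_node(
            node.node_id,
            name=node.name,
            entity_type=node.entity_type,
            mesh_id=node.mesh_id,
            mention_count=node.mention_count,
        )
    for rel in relations:
        for end in (rel.entity_a, rel.entity_b):
            if end not in g:
                raise GraphIntegrityError(
                    f"edge {rel.entity_a} -- {rel.entity_b} "
                    f"({rel.family_name}) references unknown entity {end}"
                )
        key = rel.majority_type
        if g.has_edge(rel.entity_a, rel.entity_b, key=key):
            data = g.edges[rel.entity_a, rel.entity_b, key]
            pmids = set(data["pmids"].split("|")) | set(rel.pmids)
            kws = set(data["keywords"].split("|")) - {""} | set(rel.keywords)
            data.update(
                pmids=_join(pmids),
                keywords=_join(kws),
                support=data["support"] + rel.support,
                confidence=max(data["confidence"], rel.confidence),
            )
        else:
            g.add_edge(
                rel.entity_a,
                rel.entity_b,
                key=key,
                relation_type=rel.majority_type,
                family=rel.family_name,
                keywords=_join(rel.keywords),
                pmids=_join(rel.pmids),
                confidence=float(rel.confidence),
                support=int(rel.support),
            )
    return g


def _sorted_copy(graph: nx.MultiGraph) -> nx.MultiGraph:
    out = nx.MultiGraph()
    for n in sorted(graph.nodes):
        out.add_node(n, **graph.nodes[n])
    for u, v, k in sorted(
        graph.edges(keys=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]), e[2])
    ):
        out.add_edge(u, v, key=k, **graph.edges[u, v, k])
    return out


def export_graphml(graph: nx.MultiGraph, path_or_stream) -> None:
    """Write GraphML with deterministic element ordering; set-valued fields
    are already pipe-joined strings, so a re-import reproduces the graph."""
    nx.write_graphml(_sorted_copy(graph), path_or_stream)


def read_graphml(path_or_stream) -> nx.MultiGraph:
    g = nx.read_graphml(path_or_stream, force_multigraph=True)
    return nx.MultiGraph(g)


def graph_multisets(graph: nx.MultiGraph):
    """Hashable (nodes, edges) multisets for round-trip comparisons."""
    nodes = sorted(
        (n, tuple(sorted(graph.nodes[n].items()))) for n in graph.nodes
    )
    edges = sorted(
        (min(u, v), max(u, v), k, tuple(sorted(d.items())))
        for u, v, k, d in graph.edges(keys=True, data=True)
    )
    return nodes, edges


_NODE_HEADER = ["id:ID", "name", "entity_type:LABEL", "mesh_id", "mention_count:int"]
_EDGE_HEADER = [
    ":START_ID", ":END_ID", ":TYPE", "family", "keywords", "pmids",
    "confidence:float", "support:int",
]


def export_neo4j_csv(graph: nx.MultiGraph, outdir: str) -> tuple[str, str]:
    """Write ``nodes.csv`` and ``edges.csv`` in Neo4j bulk-import layout."""
    os.makedirs(outdir, exist_ok=True)
    npath = os.path.join(outdir, "nodes.csv")
    epath = os.path.join(outdir, "edges.csv")
    g = _sorted_copy(graph)
    with open(npath, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_NODE_HEADER)
        for n, d in g.nodes(data=True):
            w.writerow(
                [n, d["name"], d["entity_type"], d["mesh_id"], d["mention_count"]]
            )
    with open(epath, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_EDGE_HEADER)
        for u, v, k, d in g.edges(keys=True, data=True):
            w.writerow(
                [u, v, d["relation_type"], d["family"], d["keywords"],
                 d["pmids"], d["confidence"], d["support"]]
            )
    return npath, epath


def export_triples_tsv(graph: nx.MultiGraph, stream: IO[str]) -> None:
    for u, v, k in sorted(
        graph.edges(keys=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]), e[2])
    ):
        a, b = min(u, v), max(u, v)
        stream.write(f"{a}\t{k}\t{b}\n")


def graph_stats(graph: nx.MultiGraph) -> dict:
    """Node/edge/property tallies.

    ``properties`` counts every non-empty attribute value across all nodes
    and edges (the counting rule is stated here because "property count" has
    no single standard definition).
    """
    nodes_by_type: dict[str, int] = {}
    for _, d in graph.nodes(data=True):
        nodes_by_type[d["entity_type"]] = nodes_by_type.get(d["entity_type"], 0) + 1
    edges_by_type: dict[str, int] = {}
    props = 0
    for _, d in graph.nodes(data=True):
        props += sum(1 for v in d.values() if v not in ("", None))
    for _, _, d in graph.edges(data=True):
        edges_by_type[d["relation_type"]] = edges_by_type.get(d["relation_type"], 0) + 1
        props += sum(1 for v in d.values() if v not in ("", None))
    return {
        "nodes": graph.number_of_nodes(),
        "edges": graph.number_of_edges(),
        "nodes_by_type": dict(sorted(nodes_by_type.items())),
        "edges_by_relation_type": dict(sorted(edges_by_type.items())),
        "properties": props,
    }
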