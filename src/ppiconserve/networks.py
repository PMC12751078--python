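"""Conserved-PPI graphs over ortholog groups.

Nodes are ortholog-group IDs; edges are group pairs whose conservation
span meets a threshold (default 5 species), annotated with span, whether a
complex structure exists (solved) and the supporting PDB IDs.  Connected
components ranked by size surface the large conserved machines (ribosome,
proteasome, spliceosome...) and where the structural gaps are.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import networkx as nx

from .conservation import GroupPairSpan
from .core import canonical_pair
from .enrichment import StructureIndex

__all__ = [
    "build_graph",
    "components_ranked",
    "edge_color_summary",
    "export_graph",
    "import_edge_tsv",
]


def build_graph(
    spans: Sequence[GroupPairSpan],
    index: StructureIndex,
    min_span: int = 5,
) -> nx.Graph:
    """Graph of group pairs with span ≥ min_span.

    Edge attributes: ``span`` (int), ``solved`` (bool), ``pdb_ids``
    (sorted tuple).  Self group-pairs become self-loops (homo-oligomers);
    multi-database observations are always collapsed to one edge.
    """
    if min_span < 1:
        raise ValueError("min_span must be >= 1")
    graph = nx.Graph()
    for sp in sorted(spans, key=lambda s: s.group_pair):
        if sp.span < min_span:
            continue
        a, b = sp.group_pair
        graph.add_edge(
            a,
            b,
            span=sp.span,
            solved=index.is_solved(sp.group_pair),
            pdb_ids=tuple(index.pdb_ids(sp.group_pair)),
        )
    return graph


def components_ranked(graph: nx.Graph, k: int = 10) -> list[nx.Graph]:
    """Top-k connected components as subgraph copies.

    Ranked by node count descending, then edge count descending (a
    self-loop counts as one edge), then by smallest node ID.  Self-loops
    never merge components.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    comps = [graph.subgraph(nodes).copy() for nodes in nx.connected_components(graph)]
    comps.sort(
        key=lambda g: (
            -g.number_of_nodes(),
            -g.number_of_edges(),
            min(g.nodes),
        )
    )
    return comps[:k]


def edge_color_summary(component: nx.Graph) -> tuple[int, int]:
    """(n_solved, n_unsolved) edge counts of a component.

    The two classes correspond to structurally solved (with PDB IDs) and
    unsolved interactions; they always sum to the edge count.
    """
    n_solved = sum(1 for _, _, d in component.edges(data=True) if d.get("solved"))
    return n_solved, component.number_of_edges() - n_solved


def export_graph(
    graph: nx.Graph, path: Union[str, Path], fmt: str = "edge-tsv"
) -> None:
    """Export as ``edge-tsv`` (round-trip safe) or ``graphml``.

    TSV columns: group_a, group_b, span, solved{0,1}, pdb_ids
    (semicolon-joined, sorted).  Isolated nodes are not represented in
    edge-tsv; the graphs built here have none.
    """
    if fmt == "edge-tsv":
        with open(path, "wt") as fh:
            fh.write("group_a\tgroup_b\tspan\tsolved\tpdb_ids\n")
            for a, b in sorted(canonical_pair(u, v) for u, v in graph.edges):
                d = graph.edges[a, b]
                pdb = ";".join(d.get("pdb_ids", ()))
                fh.write(
                    f"{a}\t{b}\t{d['span']}\t{1 if d['solved'] else 0}\t{pdb}\n"
                )
    elif fmt == "graphml":
        out = nx.Graph()
        out.add_nodes_from(sorted(graph.nodes))
        for a, b in sorted(canonical_pair(u, v) for u, v in graph.edges):
            d = graph.edges[a, b]
            out.add_edge(
                a,
                b,
                span=int(d["span"]),
                solved=bool(d["solved"]),
                pdb_ids=";".join(d.get("pdb_ids", ())),
            )
        nx.write_graphml(out, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_edge_tsv(path: Union[str, Path]) -> nx.Graph:
    """Re-import an edge-tsv export, restoring attribute types."""
    graph = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("group_a"):
            raise ValueError(f"{path}: missing edge-tsv header")
        for line in fh:
            if not line.strip():
                continue
            a, b, span, solved, pdb = line.rstrip("\n").split("\t")
            graph.add_edge(
                a,
                b,
                span=int(span),
                solved=solved == "1",
                pdb_ids=tuple(p for p in pdb.split(";") if p),
            )
    return graph
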