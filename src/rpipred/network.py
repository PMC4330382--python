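"""Bipartite ncRNA-protein interaction networks from prediction tables.

Each predicted pair becomes an undirected edge between a protein node and an
RNA node (ids are namespaced "P:"/"R:" to prevent collisions). When known
labels are supplied, every edge carries a ``correct`` flag — the basis of
the usual blue/red correct-vs-wrong edge colouring — and hubs (one molecule
interacting with many partners) fall out of node degrees.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

__all__ = ["build_graph", "find_hubs", "export_graph"]


def build_graph(
    predictions: list[dict],
    known: dict[tuple[str, str], int] | None = None,
) -> nx.Graph:
    """Assemble the interaction graph from prediction rows.

    Each row is a dict with keys ``protein_id``, ``rna_id``,
    ``predicted_label`` (0/1) and optionally ``decision_score``. ``known``
    maps (protein_id, rna_id) to the true label; when given, each covered
    edge gets ``correct = (predicted == known)``.
    """
    g = nx.Graph()
    seen: dict[tuple[str, str], int] = {}
    dupes = []
    for row in predictions:
        pid, rid = str(row["protein_id"]), str(row["rna_id"])
        label = int(row["predicted_label"])
        key = (pid, rid)
        if key in seen:
            if seen[key] != label:
                dupes.append(key)
            continue
        seen[key] = label
        pnode, rnode = f"P:{pid}", f"R:{rid}"
        g.add_node(pnode, kind="protein", molecule_id=pid)
        g.add_node(rnode, kind="ncRNA", molecule_id=rid)
        attrs = {"predicted_label": label}
        if "decision_score" in row and row["decision_score"] is not None:
            attrs["decision_score"] = float(row["decision_score"])
        if known is not None and key in known:
            attrs["known_label"] = int(known[key])
            attrs["correct"] = bool(label == int(known[key]))
        g.add_edge(pnode, rnode, **attrs)
    if dupes:
        raise ValueError(f"conflicting duplicate predictions for pairs: {sorted(dupes)}")
    return g


def find_hubs(graph: nx.Graph, min_degree: int = 2) -> list[str]:
    """Nodes of degree >= min_degree, highest degree first, ties by id."""
    if min_degree < 2:
        raise ValueError("a hub needs degree >= 2")
    hubs = [n for n, d in graph.degree() if d >= min_degree]
    return sorted(hubs, key=lambda n: (-graph.degree(n), n))


def export_graph(graph: nx.Graph, fmt: str, path: str | Path) -> None:
    """Write the graph as SIF, GraphML or an edge TSV.

    SIF lines read ``protein pp rna``; GraphML round-trips node and edge
    sets through standard viewers.
    """
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(graph.edges()):
                p, r = (u, v) if u.startswith("P:") else (v, u)
                fh.write(f"{p} pp {r}\n")
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt in ("tsv", "edge-tsv"):
        with open(path, "w") as fh:
            fh.write("protein\trna\tpredicted_label\tdecision_score\tknown_label\tcorrect\n")
            for u, v, data in sorted(graph.edges(data=True)):
                p, r = (u, v) if u.startswith("P:") else (v, u)
                cells = [p, r] + [
                    str(data.get(k, ""))
                    for k in ("predicted_label", "decision_score", "known_label", "correct")
                ]
                fh.write("\t".join(cells) + "\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}; use sif, graphml or tsv")
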