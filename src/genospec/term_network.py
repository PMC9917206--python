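"""Enrichment-map term networks.

Enriched terms become nodes (score and direction as attributes, encoding the
usual size/colour semantics); two terms are connected when they share at
least one differential gene, with edge weight = the number shared.  The
transcript-level map filters on score > 4 with uniformly directed members;
the protein-level variant filters on uniform direction only.
"""

from __future__ import annotations

import math

import networkx as nx
import pandas as pd

from genospec.enrichment import EnrichmentResult


def filter_terms(
    results: list[EnrichmentResult],
    min_score: float = 4.0,
    require_uniform_direction: bool = True,
) -> list[EnrichmentResult]:
    """Keep terms with score strictly above ``min_score`` and, optionally,
    members that are all up- or all down-regulated."""
    out = []
    for r in results:
        if not (r.score > min_score):
            continue
        if require_uniform_direction and r.direction == "mixed":
            continue
        out.append(r)
    return out


def build_network(terms: list[EnrichmentResult]) -> nx.Graph:
    """Undirected term graph; edge weight = |shared differential genes|.

    Terms sharing no gene with any other remain as isolated nodes.  The
    construction is order-independent.
    """
    g = nx.Graph()
    for r in terms:
        g.add_node(
            r.term_id,
            name=r.term_name,
            score=float(r.score),
            direction=r.direction,
            members=",".join(r.members),
        )
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            shared = sorted(set(a.members) & set(b.members))
            if shared:
                g.add_edge(a.term_id, b.term_id, weight=len(shared), shared=",".join(shared))
    return g


def export_network(g: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write GraphML (full attributes) or a 3-column edge TSV (term_a, term_b, weight)."""
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edge_tsv":
        rows = [
            {"term_a": u, "term_b": v, "weight": d["weight"]}
            for u, v, d in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["term_a", "term_b", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_network(path) -> nx.Graph:
    """Read a GraphML network written by :func:`export_network`."""
    g = nx.read_graphml(path)
    for _, d in g.nodes(data=True):
        if "score" in d:
            d["score"] = float(d["score"])
    for _, _, d in g.edges(data=True):
        if "weight" in d:
            d["weight"] = int(d["weight"])
    return g
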