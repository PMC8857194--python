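"""Tripartite network assembly, counting tables, and graph export.

The analytic network has three layers — screened compounds, target
proteins, pathways — with the originating herbs attached as a fourth
annotation layer.  Edges are binary indicators: a compound–target edge
means the interaction survived score screening; a pathway–target edge
means the target belongs to the pathway.  Prediction scores, when known,
ride along on compound–target edges for downstream centrality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from herbnet.catalog import Catalog, TargetInteraction

__all__ = ["TripartiteNetwork", "build_network", "compound_count_per_target",
           "pathway_frequency_table", "network_summary", "export_network",
           "import_network"]


def _id_sort_key(identifier: str) -> tuple[int, object]:
    # numeric ids sort numerically, others lexicographically after them
    return (0, int(identifier)) if identifier.isdigit() else (1, identifier)


@dataclass(frozen=True)
class TripartiteNetwork:
    """Herb-annotated compound–target–pathway network.

    ``compound_target_edges`` and ``pathway_target_edges`` are the binary
    edge-indicator sets; ``n1`` (targets) and ``n2`` (compounds) are the
    layer sizes entering the centrality normalization.  Compounds with no
    surviving interaction stay in ``compound_set`` as isolated nodes —
    the centrality sums only over existing edges, so they cannot affect
    any pathway score.
    """

    herb_set: frozenset[str]
    compound_set: frozenset[str]
    target_set: frozenset[str]
    pathway_set: frozenset[str]
    herb_compound_edges: frozenset[tuple[str, str]]
    compound_target_edges: frozenset[tuple[str, str]]
    pathway_target_edges: frozenset[tuple[str, str]]
    scores: dict[tuple[str, str], float | None] = field(default_factory=dict)
    target_descriptions: dict[str, str] = field(default_factory=dict)

    @property
    def n1(self) -> int:
        """Number of target genes."""
        return len(self.target_set)

    @property
    def n2(self) -> int:
        """Number of compounds (isolated compounds included)."""
        return len(self.compound_set)

    def compounds_of_target(self, target_id: str) -> set[str]:
        return {c for c, t in self.compound_target_edges if t == target_id}

    def targets_of_pathway(self, pathway_name: str) -> set[str]:
        return {t for p, t in self.pathway_target_edges if p == pathway_name}


def build_network(herb_ids: Iterable[str], catalog: Catalog,
                  interactions_kept: Iterable[TargetInteraction],
                  compounds_kept: set[str] | None = None) -> TripartiteNetwork:
    """Assemble the tripartite network for a herb selection.

    ``interactions_kept`` is the score-screened interaction set;
    ``compounds_kept`` optionally restricts each herb's compounds to the
    ADME survivors (default: all of the herb's compounds).  The target
    layer holds the targets of surviving interactions of the selected
    herbs' compounds; the pathway layer holds every pathway with at least
    one member target in the target layer.  Deterministic and
    permutation-invariant in all inputs.

    Raises ``KeyError`` for an unknown herb id.
    """
    herb_set = frozenset(str(h) for h in herb_ids)
    for hid in herb_set:
        if hid not in catalog.herbs:
            raise KeyError(f"unknown herb id {hid!r}")
    compound_set: set[str] = set()
    herb_compound: set[tuple[str, str]] = set()
    for hid in herb_set:
        cids = catalog.herbs[hid].compound_ids
        if compounds_kept is not None:
            cids = cids & compounds_kept
        compound_set |= cids
        herb_compound |= {(hid, c) for c in cids}

    ct_edges: set[tuple[str, str]] = set()
    scores: dict[tuple[str, str], float | None] = {}
    for inter in interactions_kept:
        if inter.compound_id in compound_set:
            ct_edges.add((inter.compound_id, inter.target_id))
            scores[(inter.compound_id, inter.target_id)] = inter.score
    target_set = frozenset(t for _, t in ct_edges)
    pt_edges = frozenset((m.pathway_name, m.target_id)
                         for m in catalog.memberships if m.target_id in target_set)
    pathway_set = frozenset(p for p, _ in pt_edges)
    return TripartiteNetwork(
        herb_set=herb_set,
        compound_set=frozenset(compound_set),
        target_set=target_set,
        pathway_set=pathway_set,
        herb_compound_edges=frozenset(herb_compound),
        compound_target_edges=frozenset(ct_edges),
        pathway_target_edges=pt_edges,
        scores=scores,
        target_descriptions={t: catalog.targets[t].description
                             for t in target_set if t in catalog.targets},
    )


def compound_count_per_target(net: TripartiteNetwork) -> pd.DataFrame:
    """Distinct-compound count per target, ranked.

    Sorted by count descending, ties broken by target id ascending
    (numeric ids compare numerically) so the table is byte-reproducible.
    """
    counts: dict[str, int] = {t: 0 for t in net.target_set}
    for _, t in net.compound_target_edges:
        counts[t] += 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], _id_sort_key(kv[0])))
    return pd.DataFrame(
        [{"target_id": t, "description": net.target_descriptions.get(t, ""),
          "compound_count": n} for t, n in rows])


def pathway_frequency_table(net: TripartiteNetwork) -> pd.DataFrame:
    """Pathway frequency = number of network targets belonging to it.

    Sorted by frequency descending, ties alphabetical by pathway name.
    """
    freq: dict[str, int] = {p: 0 for p in net.pathway_set}
    for p, _ in net.pathway_target_edges:
        freq[p] += 1
    rows = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame([{"pathway_name": p, "frequency": f} for p, f in rows])


def network_summary(net: TripartiteNetwork) -> dict[str, int]:
    """Exact cardinalities of the node sets and edge collections."""
    return {
        "n_herbs": len(net.herb_set),
        "n_compounds": net.n2,
        "n_targets": net.n1,
        "n_pathways": len(net.pathway_set),
        "n_herb_compound_edges": len(net.herb_compound_edges),
        "n_compound_target_edges": len(net.compound_target_edges),
        "n_pathway_target_edges": len(net.pathway_target_edges),
    }


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def _to_graph(net: TripartiteNetwork) -> nx.Graph:
    g = nx.Graph()
    partitions = [("herb", net.herb_set), ("compound", net.compound_set),
                  ("target", net.target_set), ("pathway", net.pathway_set)]
    for part, nodes in partitions:
        for n in sorted(nodes):
            g.add_node(f"{part}:{n}", partition=part, label=n)
    for h, c in sorted(net.herb_compound_edges):
        g.add_edge(f"herb:{h}", f"compound:{c}", layer="herb-compound")
    for c, t in sorted(net.compound_target_edges):
        attrs = {"layer": "compound-target"}
        score = net.scores.get((c, t))
        if score is not None:
            attrs["score"] = float(score)
        g.add_edge(f"compound:{c}", f"target:{t}", **attrs)
    for p, t in sorted(net.pathway_target_edges):
        g.add_edge(f"target:{t}", f"pathway:{p}", layer="target-pathway")
    for n in g.nodes:
        g.nodes[n]["degree"] = g.degree(n)
    return g


def export_network(net: TripartiteNetwork, path: str | Path,
                   format: str = "tsv") -> list[Path]:
    """Write the network as GraphML or a tab-delimited edge list.

    ``tsv`` writes ``<path>/nodes.tsv`` (node, partition, label, degree)
    and ``<path>/edges.tsv`` (source, target, layer, score); ``graphml``
    writes a single file at *path*.  Returns the written paths.

    Raises ``ValueError`` for an unsupported format.
    """
    path = Path(path)
    g = _to_graph(net)
    if format == "graphml":
        path.parent.mkdir(parents=True, exist_ok=True)
        nx.write_graphml(g, path)
        return [path]
    if format == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        nodes = pd.DataFrame(
            [{"node": n, "partition": d["partition"], "label": d["label"],
              "degree": d["degree"]} for n, d in sorted(g.nodes(data=True))])
        if nodes.empty:
            nodes = pd.DataFrame(columns=["node", "partition", "label", "degree"])
        edges = pd.DataFrame(
            [{"source": u, "target": v, "layer": d["layer"],
              "score": d.get("score", "")}
             for u, v, d in sorted(g.edges(data=True))])
        if edges.empty:
            edges = pd.DataFrame(columns=["source", "target", "layer", "score"])
        nodes.to_csv(path / "nodes.tsv", sep="\t", index=False, lineterminator="\n")
        edges.to_csv(path / "edges.tsv", sep="\t", index=False, lineterminator="\n")
        return [path / "nodes.tsv", path / "edges.tsv"]
    raise ValueError(f"unsupported export format {format!r}")


def import_network(path: str | Path, format: str = "tsv") -> TripartiteNetwork:
    """Rebuild a network from :func:`export_network` output."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        nodes = [(n, d["partition"], d["label"]) for n, d in g.nodes(data=True)]
        edges = [(u, v, d["layer"], d.get("score")) for u, v, d in g.edges(data=True)]
    elif format == "tsv":
        ndf = pd.read_csv(path / "nodes.tsv", sep="\t", dtype=str,
                          keep_default_na=False)
        edf = pd.read_csv(path / "edges.tsv", sep="\t", dtype=str,
                          keep_default_na=False)
        nodes = [(r.node, r.partition, r.label) for r in ndf.itertuples(index=False)]
        edges = [(r.source, r.target,
                  getattr(r, "layer"), float(r.score) if str(r.score) else None)
                 for r in edf.itertuples(index=False)]
    else:
        raise ValueError(f"unsupported export format {format!r}")

    sets: dict[str, set[str]] = {"herb": set(), "compound": set(),
                                 "target": set(), "pathway": set()}
    for _, part, label in nodes:
        sets[part].add(label)

    def strip(node: str) -> str:
        return node.split(":", 1)[1]

    hc, ct, pt = set(), set(), set()
    scores: dict[tuple[str, str], float | None] = {}
    for u, v, layer, score in edges:
        a, b = strip(u), strip(v)
        if layer == "herb-compound":
            hc.add((a, b) if u.startswith("herb:") else (b, a))
        elif layer == "compound-target":
            edge = (a, b) if u.startswith("compound:") else (b, a)
            ct.add(edge)
            scores[edge] = score
        elif layer == "target-pathway":
            pt.add((b, a) if u.startswith("target:") else (a, b))
    return TripartiteNetwork(
        herb_set=frozenset(sets["herb"]), compound_set=frozenset(sets["compound"]),
        target_set=frozenset(sets["target"]), pathway_set=frozenset(sets["pathway"]),
        herb_compound_edges=frozenset(hc), compound_target_edges=frozenset(ct),
        pathway_target_edges=frozenset(pt), scores=scores)
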