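"""Dual-evidence functional-interaction networks.

Two knockdowns are connected when their phenotypic similarity is supported
by BOTH readouts: the high-content feature correlation and the
transcriptome (log2FC) correlation must each exceed the threshold
(strictly).  Edges carry both coefficients so that exports can encode one
as edge width and the other as edge colour.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .highcontent import CorrelationMatrix

__all__ = ["Edge", "InteractionNetwork", "dual_evidence_network", "export_network",
           "import_network"]


@dataclass(frozen=True, order=True)
class Edge:
    """Undirected edge in canonical (a < b lexicographic) order."""

    a: str
    b: str
    r_highcontent: float
    r_transcriptome: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-edge on {self.a!r}")
        if self.a > self.b:
            raise ValueError("edge endpoints must be in lexicographic order")


@dataclass(frozen=True)
class InteractionNetwork:
    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        known = set(self.nodes)
        seen = set()
        for e in self.edges:
            if e.a not in known or e.b not in known:
                raise ValueError(f"edge ({e.a}, {e.b}) references unknown node")
            if (e.a, e.b) in seen:
                raise ValueError(f"duplicate edge ({e.a}, {e.b})")
            seen.add((e.a, e.b))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.a, e.b, width=e.r_highcontent, color_value=e.r_transcriptome
            )
        return g

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.a, e.b) for e in self.edges}


def dual_evidence_network(
    corr_hc: CorrelationMatrix,
    corr_rna: CorrelationMatrix,
    threshold: float = 0.4,
    keep_isolated: bool = True,
    use_absolute: bool = False,
) -> InteractionNetwork:
    """Build the network of knockdown pairs correlated in both screens.

    Only knockdowns present in both correlation matrices are considered.
    An edge (a, b) is included iff r_hc(a, b) > threshold AND
    r_rna(a, b) > threshold, both strictly.  With ``use_absolute`` the
    comparison uses |r| instead (off by default: the analysis looks for the
    highest positive similarity scores).  Isolated nodes are retained
    unless ``keep_isolated`` is false.
    """
    common = sorted(set(corr_hc.labels) & set(corr_rna.labels))
    if len(common) < 2:
        raise ValueError(
            "correlation matrices share fewer than 2 knockdown labels"
        )
    edges = []
    for i, a in enumerate(common):
        for b in common[i + 1:]:
            r_hc = corr_hc.get(a, b)
            r_rna = corr_rna.get(a, b)
            v_hc, v_rna = (abs(r_hc), abs(r_rna)) if use_absolute else (r_hc, r_rna)
            if v_hc > threshold and v_rna > threshold:
                edges.append(Edge(a, b, r_hc, r_rna))
    edges = tuple(sorted(edges))
    if keep_isolated:
        nodes = tuple(common)
    else:
        connected = {n for e in edges for n in (e.a, e.b)}
        nodes = tuple(n for n in common if n in connected)
    return InteractionNetwork(nodes, edges)


def export_network(net: InteractionNetwork, path: str | Path, format: str) -> None:
    """Write the network as ``graphml``, ``sif`` or edge-list ``tsv``.

    GraphML and TSV carry both correlation weights (attributes ``width`` =
    high-content r, ``color_value`` = transcriptome r) and round-trip
    exactly through :func:`import_network`; SIF is topology only
    (``A pp B`` per edge, isolated nodes as bare names).
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif format == "sif":
        lines = [f"{e.a}\tpp\t{e.b}" for e in net.edges]
        connected = {n for e in net.edges for n in (e.a, e.b)}
        lines += [n for n in net.nodes if n not in connected]
        path.write_text("".join(s + "\n" for s in lines), encoding="utf-8", newline="\n")
    elif format == "tsv":
        lines = ["a\tb\tr_highcontent\tr_transcriptome"]
        lines += [
            f"{e.a}\t{e.b}\t{e.r_highcontent!r}\t{e.r_transcriptome!r}"
            for e in net.edges
        ]
        connected = {n for e in net.edges for n in (e.a, e.b)}
        lines += [f"{n}\t\t\t" for n in net.nodes if n not in connected]
        path.write_text("".join(s + "\n" for s in lines), encoding="utf-8", newline="\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def import_network(path: str | Path, format: str) -> InteractionNetwork:
    """Read a network written by :func:`export_network` (graphml or tsv)."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        nodes = tuple(sorted(g.nodes))
        edges = tuple(
            sorted(
                Edge(*sorted((a, b)), float(d["width"]), float(d["color_value"]))
                for a, b, d in g.edges(data=True)
            )
        )
        return InteractionNetwork(nodes, edges)
    if format == "tsv":
        nodes: list[str] = []
        edges = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("a\tb"):
                raise ValueError("not a dualscreen network TSV")
            for line in fh:
                a, b, r_hc, r_rna = line.rstrip("\n").split("\t")
                if b == "":
                    nodes.append(a)
                else:
                    edges.append(Edge(a, b, float(r_hc), float(r_rna)))
                    nodes.extend([a, b])
        return InteractionNetwork(tuple(sorted(set(nodes))), tuple(sorted(edges)))
    raise ValueError(f"unknown network format {format!r}")
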