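"""Phenotype-specific signaling networks from constrained shortest paths.

A confidence-weighted directed interactome is combined with gene loadings
from the dominant SVD pattern: loadings become node costs under one of three
schemes (general / non_labor / labor), edge confidences become edge costs
(1 - confidence by default), and Dijkstra's algorithm finds, for every
(source receptor, sink gene) pair, the minimum-cost path whose final edge is
a documented transcription-factor -> target interaction into the sink. The
general network keeps only the cheapest half of all paths; the union of the
retained paths, with typed nodes, is the output network.
"""

from __future__ import annotations

import heapq
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

SCHEMES = ("general", "non_labor", "labor")
ROLES = ("receptor", "signaling", "transcription_factor", "target_gene")


class NetworkValidationError(ValueError):
    pass


def edge_cost_from_confidence(confidence: float, transform: str = "one_minus") -> float:
    """High-confidence edges must be cheap: 1 - c (default) or -log(c)."""
    if transform == "one_minus":
        return 1.0 - confidence
    if transform == "neg_log":
        return -math.log(confidence)
    raise ValueError(f"unknown edge cost transform {transform!r}")


@dataclass
class PathRecord:
    source: str
    sink: str
    nodes: list[str]
    cost: float
    last_edge_is_tf: bool = True


@dataclass
class NetworkResult:
    """Union-of-retained-paths network for one cost scheme."""

    scheme: str
    retained_paths: list[PathRecord]
    discarded_paths: list[PathRecord]
    graph: nx.DiGraph  # union network with role/loading/cost node attributes
    retain_fraction: float
    unreachable: list[tuple] = field(default_factory=list)


class SignalingGraph:
    """Directed interactome with edge confidences, TF-edge flags, node costs."""

    def __init__(self):
        self.graph = nx.DiGraph()
        self.tf_edges: set[tuple] = set()
        self.node_cost: dict[str, float] = {}
        self.loadings: dict[str, float] = {}
        self.sources: list[str] = []
        self.scheme: str | None = None
        self.cost_transform: str = "one_minus"

    @classmethod
    def from_edges(
        cls,
        edges,
        tf_edges,
        sources=None,
        cost_transform: str = "one_minus",
    ) -> "SignalingGraph":
        """Assemble from (tail, head, confidence) records plus TF-edge pairs.

        Self-loops are rejected; duplicate directed edges collapse to the
        highest confidence; every TF edge must appear in the edge list.
        """
        sg = cls()
        sg.cost_transform = cost_transform
        best: dict[tuple, float] = {}
        for tail, head, conf in edges:
            conf = float(conf)
            if tail == head:
                raise NetworkValidationError(f"self-loop on {tail!r}")
            if not 0.0 < conf <= 1.0:
                raise NetworkValidationError(
                    f"edge ({tail},{head}) confidence {conf} outside (0,1]"
                )
            key = (str(tail), str(head))
            best[key] = max(best.get(key, 0.0), conf)
        for (tail, head), conf in best.items():
            sg.graph.add_edge(
                tail, head, confidence=conf, cost=edge_cost_from_confidence(conf, cost_transform)
            )
        for tail, head in tf_edges:
            key = (str(tail), str(head))
            if key not in best:
                raise NetworkValidationError(
                    f"tf edge ({tail},{head}) absent from the edge list"
                )
            sg.tf_edges.add(key)
        sg.sources = list(sources) if sources else []
        return sg

    # -- convenience -------------------------------------------------------
    @property
    def nodes(self):
        return self.graph.nodes

    def cost(self, node: str) -> float:
        return self.node_cost.get(node, 1.0)

    def tf_parents(self, sink: str) -> list[str]:
        return sorted(t for (t, g) in self.tf_edges if g == sink)

    def has_tf_in_edge(self, node: str) -> bool:
        return any(g == node for (_, g) in self.tf_edges)

    def copy(self) -> "SignalingGraph":
        sg = SignalingGraph()
        sg.graph = self.graph.copy()
        sg.tf_edges = set(self.tf_edges)
        sg.node_cost = dict(self.node_cost)
        sg.loadings = dict(self.loadings)
        sg.sources = list(self.sources)
        sg.scheme = self.scheme
        sg.cost_transform = self.cost_transform
        return sg

    def write_edge_lists(self, edges_path, tf_path) -> None:
        rows = [
            (t, h, self.graph.edges[t, h]["confidence"])
            for t, h in sorted(self.graph.edges)
        ]
        # %.17g round-trips IEEE doubles exactly
        pd.DataFrame(rows, columns=["tail", "head", "confidence"]).to_csv(
            edges_path, sep="\t", index=False, float_format="%.17g"
        )
        pd.DataFrame(sorted(self.tf_edges), columns=["tf", "target"]).to_csv(
            tf_path, sep="\t", index=False
        )


def load_signaling_network(
    edge_file, tf_edge_file, cost_transform: str = "one_minus", sources=None
) -> SignalingGraph:
    """Read the edge-list TSV (tail, head, confidence) and TF-edge TSV."""
    edges = pd.read_csv(edge_file, sep="\t", float_precision="round_trip")
    tf = pd.read_csv(tf_edge_file, sep="\t")
    edge_records = list(edges.itertuples(index=False, name=None))
    tf_records = [(str(a), str(b)) for a, b, *_ in tf.itertuples(index=False, name=None)]
    return SignalingGraph.from_edges(
        edge_records, tf_records, sources=sources, cost_transform=cost_transform
    )


def _minmax(values: dict[str, float]) -> dict[str, float]:
    lo, hi = min(values.values()), max(values.values())
    if hi == lo:
        # no spread to rank by: every measured gene sits at the midpoint
        return {k: 0.5 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def assign_node_costs(
    graph: SignalingGraph, loadings: dict[str, float], scheme: str
) -> SignalingGraph:
    """Node costs in [0,1] from SVD gene loadings, per scheme.

    general: 1 - minmax(|loading|), so strongly loaded genes of either sign
    are cheap; non_labor: minmax(loading), so the most NL-associated
    (negative) loadings are cheap; labor: 1 - minmax(loading), the reverse.
    Nodes without a loading get the maximal cost 1.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if not loadings:
        raise ValueError("empty loading vector")
    out = graph.copy()
    out.scheme = scheme
    out.loadings = {str(k): float(v) for k, v in loadings.items()}
    if scheme == "general":
        scaled = _minmax({k: abs(v) for k, v in out.loadings.items()})
        costs = {k: 1.0 - s for k, s in scaled.items()}
    elif scheme == "non_labor":
        costs = _minmax(out.loadings)
    else:  # labor
        scaled = _minmax(out.loadings)
        costs = {k: 1.0 - s for k, s in scaled.items()}
    out.node_cost = {n: costs.get(n, 1.0) for n in out.graph.nodes}
    # keep costs for genes absent from the graph too: sink selection happens
    # on the loading vector, the graph restriction is applied separately
    for k, v in costs.items():
        out.node_cost.setdefault(k, v)
    return out


def select_sink_genes(
    loadings: dict[str, float],
    n_per_side: int = 50,
    scheme: str = "general",
    graph: SignalingGraph | None = None,
) -> tuple[list[str], list[str]]:
    """Top-loading genes to use as path sinks, per scheme.

    general: the ``n_per_side`` most-negative plus most-positive loading
    genes; non_labor: most-negative only; labor: most-positive only. When a
    graph is given, candidates are restricted to nodes with at least one
    incoming TF edge; genes excluded that way are returned as uncoverable.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if not loadings:
        raise ValueError("empty loading vector")
    items = sorted(loadings.items(), key=lambda kv: (kv[1], kv[0]))
    uncoverable: list[str] = []
    if graph is not None:
        covered = [(g, v) for g, v in items if graph.has_tf_in_edge(g)]
        uncoverable = sorted(g for g, _ in items if not graph.has_tf_in_edge(g))
        items = covered
    n = n_per_side
    if n > len(items):
        warnings.warn(
            f"n_per_side={n} exceeds {len(items)} available genes; truncating",
            stacklevel=2,
        )
        n = len(items)
    negative = [g for g, _ in items[:n]]
    positive = [g for g, _ in items[-n:]] if n else []
    if scheme == "general":
        sinks = sorted(set(negative) | set(positive))
    elif scheme == "non_labor":
        sinks = sorted(negative)
    else:
        sinks = sorted(positive)
    return sinks, uncoverable


def _dijkstra_lex(
    graph: SignalingGraph, source: str, exclude: str
) -> dict[str, tuple[float, tuple]]:
    """Min-cost paths from ``source`` avoiding ``exclude``, deterministic.

    Traversal cost of an edge is edge_cost + node_cost(head); the source's
    own node cost is charged once up front. Among equal-cost paths the
    lexicographically smallest node sequence wins (heap entries are
    (cost, path) so ties pop in lexicographic order).
    """
    start = (graph.cost(source), (source,))
    heap = [start]
    done: dict[str, tuple[float, tuple]] = {}
    while heap:
        cost, path = heapq.heappop(heap)
        node = path[-1]
        if node in done:
            continue
        done[node] = (cost, path)
        for _, head, data in graph.graph.out_edges(node, data=True):
            if head == exclude or head in done:
                continue
            heapq.heappush(heap, (cost + data["cost"] + graph.cost(head), path + (head,)))
    return done


def constrained_shortest_path(
    graph: SignalingGraph, source: str, sink: str
) -> PathRecord | None:
    """Cheapest source -> sink path whose final edge is a TF -> sink edge.

    Path cost = sum of node costs along the path (source and sink included)
    plus sum of edge costs. Returns None when the sink has no incoming TF
    edge or no admissible path exists.
    """
    if source not in graph.graph or sink not in graph.graph:
        raise KeyError(f"source or sink not in graph: {source!r}, {sink!r}")
    if source == sink:
        raise ValueError("source and sink must differ")
    tf_parents = graph.tf_parents(sink)
    if not tf_parents:
        return None
    dist = _dijkstra_lex(graph, source, exclude=sink)
    best: tuple[float, tuple] | None = None
    for t in tf_parents:
        if t not in dist:
            continue
        d, path = dist[t]
        cand_cost = d + graph.graph.edges[t, sink]["cost"] + graph.cost(sink)
        cand = (cand_cost, path + (sink,))
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    cost, nodes = best
    return PathRecord(source=source, sink=sink, nodes=list(nodes), cost=cost)


def build_parturition_network(
    graph: SignalingGraph,
    sources: list[str],
    sinks: list[str],
    scheme: str,
    retain_fraction: float = 0.5,
) -> NetworkResult:
    """One constrained shortest path per reachable (source, sink) pair, with
    cost-based retention and union assembly.

    For the general scheme, paths are ranked by cost and only the cheapest
    ``ceil(retain_fraction * count)`` are kept; the phenotype-specific
    schemes keep every path. The union network contains exactly the nodes
    and edges on retained paths, with roles receptor / signaling /
    transcription_factor / target_gene.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    paths: list[PathRecord] = []
    unreachable: list[tuple] = []
    for source in sources:
        for sink in sinks:
            if sink == source:
                continue
            record = constrained_shortest_path(graph, source, sink)
            if record is None:
                unreachable.append((source, sink))
            else:
                paths.append(record)
    if not paths:
        raise NetworkValidationError("no reachable (source, sink) pair")

    paths.sort(key=lambda p: (p.cost, tuple(p.nodes)))
    if scheme == "general":
        keep = math.ceil(retain_fraction * len(paths))
        retained, discarded = paths[:keep], paths[keep:]
    else:
        retained, discarded = paths, []

    union = nx.DiGraph()
    tf_tails = {t for p in retained for t in [p.nodes[-2]]}
    source_set, sink_set = set(sources), set(sinks)
    for p in retained:
        for a, b in zip(p.nodes, p.nodes[1:]):
            data = graph.graph.edges[a, b]
            union.add_edge(
                a,
                b,
                confidence=data["confidence"],
                cost=data["cost"],
                is_tf_edge=(a, b) in graph.tf_edges,
            )
    for node in union.nodes:
        if node in source_set:
            role = "receptor"
        elif node in sink_set:
            role = "target_gene"
        elif node in tf_tails:
            role = "transcription_factor"
        else:
            role = "signaling"
        union.nodes[node]["role"] = role
        union.nodes[node]["loading"] = float(graph.loadings.get(node, 0.0))
        union.nodes[node]["cost"] = graph.cost(node)
    return NetworkResult(
        scheme=scheme,
        retained_paths=retained,
        discarded_paths=discarded,
        graph=union,
        retain_fraction=retain_fraction,
        unreachable=unreachable,
    )


def export_network(result: NetworkResult, out_dir) -> dict:
    """Write SIF, node/edge attribute TSVs, GraphML, and a path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = result.scheme
    files = {}

    sif = out / f"network_{tag}.sif"
    with open(sif, "w") as fh:
        for a, b, data in sorted(result.graph.edges(data=True)):
            rel = "tf_regulates" if data.get("is_tf_edge") else "signals"
            fh.write(f"{a}\t{rel}\t{b}\n")
    files["sif"] = str(sif)

    nodes = pd.DataFrame(
        [
            (n, d["role"], d["loading"], d["cost"])
            for n, d in sorted(result.graph.nodes(data=True))
        ],
        columns=["node", "role", "loading", "cost"],
    )
    node_path = out / f"network_{tag}_nodes.tsv"
    nodes.to_csv(node_path, sep="\t", index=False, float_format="%.10g")
    files["nodes"] = str(node_path)

    edges = pd.DataFrame(
        [
            (a, b, d["confidence"], d["cost"], bool(d.get("is_tf_edge")))
            for a, b, d in sorted(result.graph.edges(data=True))
        ],
        columns=["tail", "head", "confidence", "cost", "is_tf_edge"],
    )
    edge_path = out / f"network_{tag}_edges.tsv"
    edges.to_csv(edge_path, sep="\t", index=False, float_format="%.10g")
    files["edges"] = str(edge_path)

    graphml = out / f"network_{tag}.graphml"
    nx.write_graphml(result.graph, graphml)
    files["graphml"] = str(graphml)

    manifest = out / f"network_{tag}_paths.json"
    with open(manifest, "w") as fh:
        json.dump(
            {
                "scheme": result.scheme,
                "retain_fraction": result.retain_fraction,
                "n_retained": len(result.retained_paths),
                "n_discarded": len(result.discarded_paths),
                "unreachable": [list(p) for p in result.unreachable],
                "retained_paths": [
                    {"source": p.source, "sink": p.sink, "nodes": p.nodes, "cost": p.cost}
                    for p in result.retained_paths
                ],
            },
            fh,
            indent=1,
        )
    files["paths"] = str(manifest)
    return files
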