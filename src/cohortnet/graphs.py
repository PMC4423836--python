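"""Spanning trees, stability filtering and graph-complexity indices.

From the trained similarity matrix the pipeline builds three undirected
views of the variable-association structure:

* the **MST** — the spanning tree of minimal total distance ``1 - S``
  (equivalently maximal total similarity), the simplest loop-free view of
  the strongest associations;
* the **Meta-MST** — the edges stable under record resampling: those that
  recur in at least ``support_threshold`` of ``k`` MSTs rebuilt after
  randomly excluding a fraction of the records;
* the **MRG** (maximally regular graph) — the MST with the strongest
  previously removed links re-introduced, chosen as the graph of maximal
  hubness along the greedy re-insertion sequence, exposing the cyclic
  microstructures the tree view suppresses.

Complexity is summarized by two indices.  The hubness

    H = sum_i max(0, deg_i - 2) / (2A - N)

measures how much connectivity is concentrated in high-degree nodes; the
denominator equals ``N - 2`` on trees (so a path scores 0 and a star
``(N-3)/(N-2)``) and bounds the numerator on every connected graph, keeping
``H`` in [0, 1].  The topological entropy

    E_G = (A / P) * H_S,    H_S = -sum_i p_i log2 p_i,  p_i = deg_i / sum deg

combines edge density per pruning cycle (``P`` = waves of minimal-degree
node deletion needed to empty the graph) with the Shannon information of
the degree distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .autocm import (
    NOISE_FLOOR,
    SimilarityMatrix,
    saturating_C,
    similarity_matrix,
    to_distances,
    train_autocm,
)


class GraphError(ValueError):
    pass


@dataclass
class ComplexityReport:
    """Complexity indices of one graph."""

    H: float
    E_G: float
    A: int
    P: int
    degree_histogram: dict[int, int]

    def to_dict(self) -> dict:
        return {
            "H": self.H,
            "E_G": self.E_G,
            "A": self.A,
            "P": self.P,
            "degree_histogram": {str(k): v for k, v in sorted(self.degree_histogram.items())},
        }


def complexity_report(G: nx.Graph) -> ComplexityReport:
    degs = [d for _, d in G.degree()]
    hist: dict[int, int] = {}
    for d in degs:
        hist[d] = hist.get(d, 0) + 1
    return ComplexityReport(
        H=h_index(G),
        E_G=topological_entropy(G),
        A=G.number_of_edges(),
        P=pruning_cycles(G),
        degree_histogram=hist,
    )


# ---------------------------------------------------------------------------
# spanning trees
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def minimum_spanning_tree(D: np.ndarray, labels: list[str] | None = None) -> nx.Graph:
    """Kruskal's algorithm with deterministic lexicographic tie-breaking.

    Edges are sorted by (distance, label pair); among equal-distance edges
    the lexicographically first node-label pair wins.  The result has
    exactly ``N - 1`` edges, is connected and acyclic, and carries both
    ``distance`` and ``similarity`` (``1 - distance``) edge attributes.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise GraphError("distance matrix must be square")
    if not np.isfinite(D).all():
        raise GraphError("distance matrix must be finite")
    if not np.allclose(D, D.T):
        raise GraphError("distance matrix must be symmetric")
    labels = labels or [f"n{i}" for i in range(n)]
    edges = sorted(
        (D[i, j], *sorted((labels[i], labels[j])))
        for i in range(n)
        for j in range(i + 1, n)
    )
    G = nx.Graph()
    G.add_nodes_from(labels)
    uf = _UnionFind(labels)
    for d, a, b in edges:
        if uf.union(a, b):
            G.add_edge(a, b, distance=float(d), similarity=float(1.0 - d))
            if G.number_of_edges() == n - 1:
                break
    if G.number_of_edges() != n - 1:
        raise GraphError("input does not admit a spanning tree")
    return G


def mst_from_similarity(sim: SimilarityMatrix) -> nx.Graph:
    return minimum_spanning_tree(to_distances(sim), sim.labels)


def meta_mst(
    indicators,
    k: int = 10,
    drop_fraction: float = 0.1,
    support_threshold: int = 9,
    seed: int = 0,
    autocm_kwargs: dict | None = None,
) -> nx.Graph:
    """Edge-stability filter over resampled MSTs.

    The similarity network and its MST are retrained on each of ``k``
    record subsamples (each excluding ``drop_fraction`` of the rows,
    drawn without replacement); the Meta-MST keeps the edges present in at
    least ``support_threshold`` of the ``k`` trees, with a ``support``
    edge attribute.  It may be disconnected.  Columns that become constant
    within a subsample are dropped for that resample only.
    """
    import pandas as pd

    if isinstance(indicators, pd.DataFrame):
        X = indicators.to_numpy(dtype=float)
        labels = [str(c) for c in indicators.columns]
    else:
        X = np.asarray(indicators, dtype=float)
        labels = [f"col{i}" for i in range(X.shape[1])]
    if not 1 <= support_threshold <= k:
        raise GraphError("support_threshold must lie in [1, k]")
    n = X.shape[0]
    n_drop = int(round(drop_fraction * n))
    if n - n_drop < 3:
        raise GraphError("subsamples too small to build a tree")
    rng = np.random.default_rng(seed)
    kwargs = dict(autocm_kwargs or {})

    support: dict[tuple[str, str], int] = {}
    sim_sum: dict[tuple[str, str], float] = {}
    for _ in range(k):
        keep = np.sort(rng.choice(n, size=n - n_drop, replace=False)) if n_drop else np.arange(n)
        Xs = X[keep]
        live = np.flatnonzero(Xs.max(axis=0) > Xs.min(axis=0))
        if live.size < 2:
            raise GraphError("subsample left fewer than 2 varying columns")
        sub_labels = [labels[i] for i in live]
        sub_kwargs = dict(kwargs)
        if sub_kwargs.get("C") == "auto":
            sub_kwargs["C"] = saturating_C(Xs[:, live])
        model = train_autocm(Xs[:, live], labels=sub_labels, **sub_kwargs)
        tree = mst_from_similarity(similarity_matrix(model))
        for a, b, attrs in tree.edges(data=True):
            key = tuple(sorted((a, b)))
            support[key] = support.get(key, 0) + 1
            sim_sum[key] = sim_sum.get(key, 0.0) + attrs["similarity"]

    G = nx.Graph()
    G.add_nodes_from(labels)
    for (a, b), count in sorted(support.items()):
        if count >= support_threshold:
            G.add_edge(
                a,
                b,
                support=count,
                similarity=sim_sum[(a, b)] / count,
                distance=1.0 - sim_sum[(a, b)] / count,
            )
    return G


# ---------------------------------------------------------------------------
# complexity indices
# ---------------------------------------------------------------------------


def h_index(G: nx.Graph) -> float:
    """Hubness in [0, 1]: excess degree beyond 2 per unit of available
    excess, ``sum(max(0, deg-2)) / (2A - N)``.  Paths and cycles score 0;
    a star scores ``(N-3)/(N-2)``."""
    N = G.number_of_nodes()
    if N < 3:
        raise GraphError("hubness needs at least 3 nodes")
    if not nx.is_connected(G):
        raise GraphError("hubness is defined for connected graphs")
    A = G.number_of_edges()
    denom = 2 * A - N
    if denom <= 0:
        return 0.0
    excess = sum(max(0, d - 2) for _, d in G.degree())
    return excess / denom


def pruning_cycles(G: nx.Graph) -> int:
    """Waves of minimal-degree deletion needed to empty the graph.

    Each wave removes every node of degree <= 1 if any exist (leaf
    stripping), otherwise every node of the current minimum degree
    (cycle collapse).  Returns the number of waves.
    """
    if G.number_of_nodes() == 0:
        raise GraphError("pruning_cycles of an empty graph")
    H = G.copy()
    waves = 0
    while H.number_of_nodes():
        degs = dict(H.degree())
        lo = min(degs.values())
        cut = 1 if lo <= 1 else lo
        H.remove_nodes_from([v for v, d in degs.items() if d <= cut])
        waves += 1
    return waves


def topological_entropy(G: nx.Graph) -> float:
    """``E_G = (A / P) * H_S`` with ``H_S`` the Shannon entropy (bits) of
    the degree distribution ``p_i = deg_i / sum_j deg_j``."""
    if G.number_of_nodes() < 2:
        raise GraphError("topological entropy needs at least 2 nodes")
    if not nx.is_connected(G):
        raise GraphError("topological entropy is defined for connected graphs")
    A = G.number_of_edges()
    P = pruning_cycles(G)
    degs = np.array([d for _, d in G.degree()], dtype=float)
    p = degs / degs.sum()
    H_S = float(-(p * np.log2(p)).sum())
    return A / P * H_S


def hub_nodes(G: nx.Graph, top_k: int | None = None) -> list[tuple[str, int]]:
    """Nodes ranked by degree (descending), ties broken by label."""
    if G.number_of_nodes() == 0:
        raise GraphError("empty graph")
    ranked = sorted(G.degree(), key=lambda nd: (-nd[1], str(nd[0])))
    return ranked[:top_k] if top_k else ranked


# ---------------------------------------------------------------------------
# maximally regular graph
# ---------------------------------------------------------------------------


def maximally_regular_graph(
    sim: SimilarityMatrix,
    mst: nx.Graph | None = None,
    floor: float = NOISE_FLOOR,
) -> tuple[nx.Graph, ComplexityReport]:
    """Re-introduce the strongest non-tree links and keep the hubbiest graph.

    Candidate edges are the non-tree pairs with similarity above ``floor``
    (by default the noise bound below which a link is "null or very low"),
    sorted by descending similarity with lexicographic tie-breaks.  They
    are added to a copy of the MST one at a time, recording the hubness H
    after each addition; the graph of maximal H along this sequence is
    returned, taking the *last* graph attaining the maximum so that ties
    keep the largest number of re-introduced connections (with no usable
    candidate the MRG is the MST itself), together with its
    :class:`ComplexityReport`.
    """
    if mst is None:
        mst = mst_from_similarity(sim)
    S = sim.S
    labels = sim.labels
    n = len(labels)
    cands = []
    for i in range(n):
        for j in range(i + 1, n):
            if S[i, j] > floor and not mst.has_edge(labels[i], labels[j]):
                a, b = sorted((labels[i], labels[j]))
                cands.append((-S[i, j], a, b))
    cands.sort()
    G = mst.copy()
    best_graph = mst.copy()
    best_h = h_index(mst)
    for negs, a, b in cands:
        G.add_edge(a, b, similarity=float(-negs), distance=float(1.0 + negs))
        h = h_index(G)
        if h >= best_h - 1e-12:
            best_h = max(best_h, h)
            best_graph = G.copy()
    return best_graph, complexity_report(best_graph)


# ---------------------------------------------------------------------------
# per-group complexity contrast
# ---------------------------------------------------------------------------


@dataclass
class GroupContrast:
    """Complexity of the case-only and control-only association networks.

    Deltas are control minus case, so a positive ``delta_E_G`` means the
    event-free group carries the more complex network.
    """

    case: ComplexityReport
    control: ComplexityReport
    delta_H: float
    delta_E_G: float
    case_graph: nx.Graph = field(repr=False, default=None)
    control_graph: nx.Graph = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "case": self.case.to_dict(),
            "control": self.control.to_dict(),
            "delta_H": self.delta_H,
            "delta_E_G": self.delta_E_G,
        }


def group_complexity_contrast(
    indicators,
    outcome: np.ndarray,
    floor: float = NOISE_FLOOR,
    autocm_kwargs: dict | None = None,
    min_rows: int = 20,
) -> GroupContrast:
    """Auto-CM -> MST -> MRG separately on case rows and control rows.

    ``indicators`` is a 0/1 DataFrame or array of *feature* columns
    (outcome indicator columns must not be included — they are constant
    within a group).  Columns constant within one group are dropped from
    that group's network.  ``autocm_kwargs`` may set ``C="auto"`` to use
    the saturating contraction (the default here, so similarities populate
    the interpretable scale the MRG floor assumes).
    """
    import pandas as pd

    if isinstance(indicators, pd.DataFrame):
        X = indicators.to_numpy(dtype=float)
        labels = [str(c) for c in indicators.columns]
    else:
        X = np.asarray(indicators, dtype=float)
        labels = [f"col{i}" for i in range(X.shape[1])]
    outcome = np.asarray(outcome, dtype=int)
    kwargs = dict(autocm_kwargs or {})
    kwargs.setdefault("C", "auto")

    reports = {}
    graphs = {}
    for name, mask in (("case", outcome == 1), ("control", outcome == 0)):
        if mask.sum() < min_rows:
            raise GraphError(f"{name} group has fewer than {min_rows} rows")
        Xg = X[mask]
        live = np.flatnonzero(Xg.max(axis=0) > Xg.min(axis=0))
        sub_kwargs = dict(kwargs)
        if sub_kwargs.get("C") == "auto":
            sub_kwargs["C"] = saturating_C(Xg[:, live])
        model = train_autocm(Xg[:, live], labels=[labels[i] for i in live], **sub_kwargs)
        sim = similarity_matrix(model)
        graphs[name], reports[name] = maximally_regular_graph(sim, floor=floor)
    return GroupContrast(
        case=reports["case"],
        control=reports["control"],
        delta_H=reports["control"].H - reports["case"].H,
        delta_E_G=reports["control"].E_G - reports["case"].E_G,
        case_graph=graphs["case"],
        control_graph=graphs["control"],
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_edge_list(G: nx.Graph, path: str | Path) -> Path:
    """Deterministic TSV edge list (lexicographic edge order)."""
    path = Path(path)
    attrs = sorted({k for _, _, d in G.edges(data=True) for k in d})
    lines = ["\t".join(["source", "target"] + attrs)]
    for a, b in sorted(tuple(sorted(e)) for e in G.edges()):
        d = G.edges[a, b]
        lines.append(
            "\t".join([a, b] + [f"{d[k]:.6f}" if isinstance(d.get(k), float) else str(d.get(k, "")) for k in attrs])
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_graphml(G: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(G, path)
    return path


def write_dot(G: nx.Graph, path: str | Path) -> Path:
    """Minimal DOT writer (undirected), edge similarity as label."""
    path = Path(path)
    lines = ["graph cohortnet {"]
    for node in sorted(G.nodes()):
        lines.append(f'  "{node}";')
    for a, b in sorted(tuple(sorted(e)) for e in G.edges()):
        d = G.edges[a, b]
        sim = d.get("similarity")
        label = f' [label="{sim:.2f}"]' if isinstance(sim, float) else ""
        lines.append(f'  "{a}" -- "{b}"{label};')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_complexity(report: ComplexityReport, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=1))
    return path
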