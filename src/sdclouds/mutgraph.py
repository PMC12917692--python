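"""Mutational connectivity of SD cores and activity clouds.

The design space is modeled as the Hamming-1 graph: nodes are observed
cores (annotated with their ETR and cloud label), edges join pairs that
differ at exactly one position, so a node has at most ``6 * 3 = 18``
neighbors and the complete 4096-core graph is 18-regular with 36 864
edges.  On top of it the module computes

* intracloud robustness — component structure, giant-component fraction,
  degree/clustering/path-length statistics of every cloud-induced
  subgraph (a large giant component means many single-base mutations
  preserve the coarse expression class);
* the intercloud meta-graph — one edge per cloud pair joined by at least
  one Hamming-1 bridge, carrying the bridge count and the mean absolute
  ETR jump across the boundary;
* evolutionary accessibility — a row-stochastic transition matrix
  ``P(C_i -> C_j)`` under a uniform random single-base step (diagonal =
  P(stay)), beneficial-move fractions (share of directed moves with
  strictly increasing ETR), and monotone (selectively accessible) paths
  on the subgraph of non-decreasing-ETR edges.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Hashable, Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .etr_data import ALPHABET, CORE_LENGTH, EtrMap
from .clouds import CloudTable

MAX_DEGREE = CORE_LENGTH * (len(ALPHABET) - 1)  # 18


class GraphError(ValueError):
    """Invalid mutational-graph input."""


def hamming_neighbors(core: str) -> Iterable[str]:
    """The up-to-18 sequences at Hamming distance 1 from ``core``."""
    for pos, base in enumerate(core):
        for alt in ALPHABET:
            if alt != base:
                yield core[:pos] + alt + core[pos + 1:]


def build_hamming_graph(
    etr_map: EtrMap, cloud_table: CloudTable | None = None
) -> nx.Graph:
    """Hamming-1 graph over the landscape's cores.

    Every node carries ``etr`` and ``cloud`` attributes (``cloud`` is
    ``None`` for cores missing from ``cloud_table``; such nodes are
    excluded from cloud-level analyses).
    """
    G = nx.Graph()
    for core, etr in etr_map.items():
        cloud = None
        if cloud_table is not None and core in cloud_table:
            cloud = cloud_table.label_of(core)
        G.add_node(core, etr=etr, cloud=cloud)
    for core in G.nodes:
        for nb in hamming_neighbors(core):
            if nb > core and nb in G:
                G.add_edge(core, nb)
    return G


def intracloud_metrics(
    G: nx.Graph, max_path_nodes: int | None = None
) -> pd.DataFrame:
    """Robustness metrics of every cloud-induced subgraph.

    One row per cloud: node/edge counts, number of connected components,
    giant-component size and fraction, average degree, average
    clustering coefficient and average shortest-path length on the giant
    component (0 for a single-node giant).  The all-pairs path average is
    quadratic in the giant size; ``max_path_nodes`` caps the giant size
    for which it is computed (NaN beyond the cap, ``None`` = no cap).
    """
    rows = []
    for label, nodes in sorted(_cloud_nodes(G).items()):
        sub = G.subgraph(nodes)
        comps = sorted(nx.connected_components(sub), key=len, reverse=True)
        giant = sub.subgraph(comps[0])
        n = sub.number_of_nodes()
        rows.append(
            {
                "label": label,
                "n_nodes": n,
                "n_edges": sub.number_of_edges(),
                "n_components": len(comps),
                "giant_size": giant.number_of_nodes(),
                "giant_fraction": giant.number_of_nodes() / n,
                "avg_degree": 2 * sub.number_of_edges() / n,
                "avg_clustering": nx.average_clustering(sub),
                "avg_shortest_path_giant": _avg_shortest_path(
                    giant, max_path_nodes
                ),
            }
        )
    return pd.DataFrame(rows)


def _avg_shortest_path(giant: nx.Graph, max_path_nodes: int | None) -> float:
    n = giant.number_of_nodes()
    if n == 1:
        return 0.0
    if max_path_nodes is not None and n > max_path_nodes:
        return float("nan")
    return float(nx.average_shortest_path_length(giant))


def _cloud_nodes(G: nx.Graph) -> dict[Hashable, list[str]]:
    out: dict[Hashable, list[str]] = {}
    for node, data in G.nodes(data=True):
        if data.get("cloud") is None:
            continue
        out.setdefault(data["cloud"], []).append(node)
    if not out:
        raise GraphError("no cloud-labeled node in the graph")
    return out


def build_meta_graph(G: nx.Graph) -> nx.Graph:
    """Cloud meta-graph: one undirected edge per bridged cloud pair.

    Edge attributes: ``bridge_count`` and ``mean_abs_detr`` (mean
    absolute ETR difference over bridges with finite ETR at both ends).
    Nodes are cloud labels, each annotated with its member count.
    """
    meta = nx.Graph()
    for label, nodes in sorted(_cloud_nodes(G).items()):
        meta.add_node(label, n_cores=len(nodes))
    for u, v in G.edges:
        cu, cv = G.nodes[u].get("cloud"), G.nodes[v].get("cloud")
        if cu is None or cv is None or cu == cv:
            continue
        detr = abs(G.nodes[u]["etr"] - G.nodes[v]["etr"])
        if meta.has_edge(cu, cv):
            e = meta.edges[cu, cv]
            e["bridge_count"] += 1
            if np.isfinite(detr):
                e["_detr_sum"] += detr
                e["_detr_n"] += 1
        else:
            meta.add_edge(
                cu,
                cv,
                bridge_count=1,
                _detr_sum=detr if np.isfinite(detr) else 0.0,
                _detr_n=1 if np.isfinite(detr) else 0,
            )
    for _, _, e in meta.edges(data=True):
        n = e.pop("_detr_n")
        s = e.pop("_detr_sum")
        e["mean_abs_detr"] = s / n if n else np.nan
    return meta


def _cloud_order(G: nx.Graph, order: str) -> list[Hashable]:
    clouds = _cloud_nodes(G)
    if order == "label":
        return sorted(clouds)
    if order == "mean_etr":
        means = {
            label: float(np.mean([G.nodes[n]["etr"] for n in nodes]))
            for label, nodes in clouds.items()
        }
        return sorted(clouds, key=lambda c: (means[c], c))
    raise GraphError(f"unknown cloud order {order!r}")


def meta_matrices(
    G: nx.Graph, order: str = "mean_etr"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bridge-count and mean-|dETR| cloud x cloud matrices.

    ``order`` is ``"mean_etr"`` (ascending mean cloud ETR, the default
    export ordering) or ``"label"``.
    """
    meta = build_meta_graph(G)
    labels = _cloud_order(G, order)
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    detr = pd.DataFrame(np.nan, index=labels, columns=labels)
    for u, v, e in meta.edges(data=True):
        counts.loc[u, v] = counts.loc[v, u] = e["bridge_count"]
        detr.loc[u, v] = detr.loc[v, u] = e["mean_abs_detr"]
    return counts, detr


def _directed_moves(G: nx.Graph):
    """Yield (cloud_u, cloud_v, detr) once per directed adjacent pair."""
    for u, v in G.edges:
        cu, cv = G.nodes[u].get("cloud"), G.nodes[v].get("cloud")
        if cu is None or cv is None:
            continue
        d = G.nodes[v]["etr"] - G.nodes[u]["etr"]
        yield cu, cv, d
        yield cv, cu, -d


def transition_matrix(G: nx.Graph, order: str = "label") -> pd.DataFrame:
    """Row-stochastic cloud transition matrix under a random 1-base step.

    ``P[i, j]`` is the probability that a uniform random single-base
    step from a core of cloud ``i`` lands in cloud ``j``; the diagonal is
    P(stay).  Every directed adjacent core pair counts as one move.
    """
    labels = _cloud_order(G, order)
    idx = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))
    for cu, cv, _ in _directed_moves(G):
        counts[idx[cu], idx[cv]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        bad = [labels[i] for i in np.where(row_sums.ravel() == 0)[0]]
        raise GraphError(f"cloud(s) with zero outgoing moves: {bad}")
    return pd.DataFrame(counts / row_sums, index=labels, columns=labels)


def beneficial_fractions(G: nx.Graph, order: str = "label") -> pd.DataFrame:
    """Fraction of directed i->j moves with strictly positive ΔETR.

    Entries for ordered cloud pairs with zero moves are NaN.
    """
    labels = _cloud_order(G, order)
    idx = {c: i for i, c in enumerate(labels)}
    total = np.zeros((len(labels), len(labels)))
    up = np.zeros_like(total)
    for cu, cv, d in _directed_moves(G):
        total[idx[cu], idx[cv]] += 1
        if d > 0:
            up[idx[cu], idx[cv]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, up / np.where(total > 0, total, 1), np.nan)
    return pd.DataFrame(frac, index=labels, columns=labels)


@dataclass(frozen=True)
class MonotonePathResult:
    reachable: bool
    shortest_length: int | None
    witness_path: tuple[str, ...] | None


def monotone_paths(
    G: nx.Graph,
    source_cloud: Hashable,
    target_cloud: Hashable,
    strict: bool = False,
) -> MonotonePathResult:
    """Selective accessibility between two clouds.

    On the directed subgraph keeping only steps with ΔETR >= 0 (> 0 if
    ``strict``), reports whether any core of the target cloud is
    reachable from any core of the source cloud, the minimum number of
    steps, and one witness path (deterministic: breadth-first search with
    sources and neighbors visited in lexicographic order).  ETR is
    non-decreasing (increasing if strict) along the witness.
    """
    clouds = _cloud_nodes(G)
    for c in (source_cloud, target_cloud):
        if c not in clouds:
            raise GraphError(f"unknown cloud {c!r}")
    sources = sorted(clouds[source_cloud])
    targets = set(clouds[target_cloud])
    if source_cloud == target_cloud:
        return MonotonePathResult(True, 0, (sources[0],))

    def admissible(u: str, v: str) -> bool:
        d = G.nodes[v]["etr"] - G.nodes[u]["etr"]
        return d > 0 if strict else d >= 0

    parent: dict[str, str | None] = {s: None for s in sources}
    frontier = deque(sources)
    hits: list[str] = []
    depth = 0
    while frontier and not hits:
        depth += 1
        for _ in range(len(frontier)):
            u = frontier.popleft()
            for v in sorted(G.neighbors(u)):
                if v in parent or not admissible(u, v):
                    continue
                parent[v] = u
                if v in targets:
                    hits.append(v)
                frontier.append(v)
    if not hits:
        return MonotonePathResult(False, None, None)
    end = min(hits)
    path = [end]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    path.reverse()
    return MonotonePathResult(True, len(path) - 1, tuple(path))


def giant_fraction_histogram(
    metrics: pd.DataFrame, bins: int = 20
) -> pd.DataFrame:
    """Plot-ready histogram of per-cloud giant-component fractions."""
    counts, edges = np.histogram(
        metrics["giant_fraction"], bins=bins, range=(0.0, 1.0)
    )
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
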