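"""Protein-protein interaction network analysis.

Centrality is always computed on the *full* network and carried unchanged
onto the subnetwork of experimentally detected proteins, so subnetwork
values stay numerically calibrated to the whole-proteome centrality scale.
Community structure is found by Louvain modularity optimization on the
largest connected component of the subnetwork.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CentralityMap",
    "CommunityPartition",
    "load_network",
    "write_network",
    "eigenvector_centrality",
    "calibrated_subnetwork",
    "louvain_partition",
    "community_centrality_profile",
    "membership_upset",
]


@dataclass(frozen=True)
class CentralityMap:
    """Eigenvector centralities with the scale they were computed on.

    ``scope`` is ``"full-network"`` when the values come from the whole
    interaction network, or ``"subnetwork-calibrated"`` when a subnetwork
    carries the full-network values unchanged.
    """

    values: dict[str, float]
    scope: str = "full-network"

    def __getitem__(self, node: str) -> float:
        return self.values[node]

    def __len__(self) -> int:
        return len(self.values)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name="eigenvector_centrality")


@dataclass(frozen=True)
class CommunityPartition:
    """Louvain community labels over the largest connected component."""

    labels: dict[str, int]
    modularity: float
    seed: int
    resolution: float

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, label in self.labels.items():
            out.setdefault(label, set()).add(node)
        return out


def load_network(path: str | Path, min_score: float = 400.0) -> nx.Graph:
    """Load a STRING-style edge list ``protein1 protein2 combined_score``.

    Scores are on the 0-1000 STRING scale.  Edges below ``min_score`` are
    dropped, self-loops removed, and duplicate undirected edges merged
    keeping the maximum score.
    """
    graph = nx.Graph()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("protein1"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw_score = parts
            try:
                score = float(raw_score)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad score {raw_score!r}") from exc
            if a == b:
                continue
            if score < min_score:
                continue
            if graph.has_edge(a, b):
                graph[a][b]["score"] = max(graph[a][b]["score"], score)
            else:
                graph.add_edge(a, b, score=score)
    if graph.number_of_edges() == 0:
        warnings.warn(f"no edges retained from {path} at min_score={min_score}", stacklevel=2)
    return graph


def write_network(graph: nx.Graph, path: str | Path) -> None:
    """Write a STRING-style three-column edge list."""
    with open(path, "w") as handle:
        handle.write("protein1\tprotein2\tcombined_score\n")
        for a, b, data in sorted(graph.edges(data=True)):
            handle.write(f"{a}\t{b}\t{int(round(data.get('score', 1000)))}\n")


def eigenvector_centrality(
    graph: nx.Graph, tol: float = 1e-10, max_iter: int = 1000
) -> CentralityMap:
    """Eigenvector centrality of every node, unit Euclidean norm.

    Power iteration on the unweighted adjacency of the full graph, shifted
    by the identity (x <- (A + I) x) so the iteration converges on
    bipartite components too.  On a disconnected graph the dominant
    component carries essentially all of the mass, which matches computing
    centrality on the full graph at once.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = list(graph.nodes())
    adjacency = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight=None, dtype=float)
    n = len(nodes)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        x_new = adjacency @ x + x
        norm = np.linalg.norm(x_new)
        if norm == 0:
            break  # edgeless graph: uniform vector is already the answer
        x_new /= norm
        if np.abs(x_new - x).sum() < n * tol:
            x = x_new
            break
        x = x_new
    else:
        raise RuntimeError(
            f"eigenvector centrality did not converge in {max_iter} iterations; "
            "increase max_iter"
        )
    x = np.abs(x)
    x /= np.linalg.norm(x)
    return CentralityMap(dict(zip(nodes, x.tolist())), scope="full-network")


def calibrated_subnetwork(
    graph: nx.Graph, centrality: CentralityMap, detected_ids: Iterable[str]
) -> tuple[nx.Graph, CentralityMap]:
    """Induced subgraph on detected proteins, keeping full-network centrality.

    The returned centrality values are exactly the full-network values for
    the retained ids — no recomputation — so the subnetwork stays on the
    whole-proteome centrality scale.  Ids absent from the network are
    reported via a warning and dropped.
    """
    detected = list(dict.fromkeys(detected_ids))
    present = [pid for pid in detected if pid in graph]
    missing = sorted(set(detected) - set(present))
    if missing:
        warnings.warn(
            f"{len(missing)} detected ids absent from network (e.g. {missing[:5]})",
            stacklevel=2,
        )
    if not present:
        raise ValueError("no detected ids present in the network")
    sub = graph.subgraph(present).copy()
    sub_values = {pid: centrality.values[pid] for pid in present}
    return sub, CentralityMap(sub_values, scope="subnetwork-calibrated")


def louvain_partition(
    subnetwork: nx.Graph, seed: int = 0, resolution: float = 1.0
) -> CommunityPartition:
    """Louvain partition of the largest connected component.

    Edges are treated as unweighted; modularity of the returned partition
    is reported.  Deterministic for a fixed seed.
    """
    if subnetwork.number_of_edges() == 0:
        raise ValueError("cannot partition an edgeless network")
    component = max(nx.connected_components(subnetwork), key=len)
    lcc = subnetwork.subgraph(component)
    communities = nx.community.louvain_communities(
        lcc, weight=None, resolution=resolution, seed=seed
    )
    # stable labels: communities ordered by (size desc, smallest member)
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = {node: idx for idx, comm in enumerate(ordered) for node in comm}
    modularity = nx.community.modularity(lcc, ordered, weight=None, resolution=resolution)
    return CommunityPartition(labels=labels, modularity=modularity, seed=seed,
                              resolution=resolution)


def community_centrality_profile(
    partition: CommunityPartition, centrality: CentralityMap
) -> pd.DataFrame:
    """Per-community summary of the centrality distribution.

    Returns count, quartiles and max of eigenvector centrality for each
    community label, indexed by label.
    """
    rows = {}
    for label, members in sorted(partition.communities().items()):
        vals = np.array([centrality.values[m] for m in members if m in centrality.values])
        if vals.size == 0:
            continue
        rows[label] = {
            "count": int(vals.size),
            "q25": float(np.quantile(vals, 0.25)),
            "median": float(np.quantile(vals, 0.5)),
            "q75": float(np.quantile(vals, 0.75)),
            "max": float(vals.max()),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("community")


def membership_upset(
    partition: Mapping[str, int | str],
    old_signs: Mapping[str, int],
    young_signs: Mapping[str, int],
) -> pd.DataFrame:
    """Set-membership counts of community x age x PTM-change sign.

    Signs are -1 (loss), +1 (gain) or 0 (no change); zero-sign proteins
    contribute only to the ``no_change`` margin column.
    """
    records = []
    for protein, community in partition.items():
        for age, signs in (("old", old_signs), ("young", young_signs)):
            sign = signs.get(protein, 0)
            records.append({"community": community, "age": age, "sign": int(sign)})
    df = pd.DataFrame(records)
    counts = (
        df[df["sign"] != 0]
        .groupby(["community", "age", "sign"])
        .size()
        .rename("count")
        .reset_index()
    )
    no_change = int((df["sign"] == 0).sum())
    counts.attrs["no_change"] = no_change
    return counts
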