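"""Markov Cluster Algorithm (MCL) on weighted similarity graphs.

MCL simulates random walks on a graph by alternating *expansion* (matrix
power, letting flow spread) and *inflation* (entrywise power followed by
column renormalization, strengthening strong currents and weakening weak
ones). The process converges to a sparse "attractor" structure whose
connected components are the clusters. Inflation controls granularity;
the pipeline runs it at 1.5 at both the sequence and the profile level,
deliberately low because secretory-peptide families are held together by
weak similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import MclConfig


@dataclass
class Clustering:
    """Disjoint clusters (each >= 2 members, labelled c1, c2, ... by
    decreasing size, ties by smallest member id) plus singletons."""

    clusters: list[list[str]]
    singletons: list[str]
    diagnostics: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        seen: set[str] = set()
        for c in self.clusters:
            if len(c) < 2:
                raise ValueError("clusters must have >= 2 members")
            if seen & set(c):
                raise ValueError("clusters must be pairwise disjoint")
            seen |= set(c)
        if seen & set(self.singletons):
            raise ValueError("singletons must be disjoint from clusters")

    @property
    def nodes(self) -> set[str]:
        out = set(self.singletons)
        for c in self.clusters:
            out |= set(c)
        return out

    def labels(self) -> dict[str, str]:
        """node id -> "c<k>" or "singleton"."""
        out = {n: "singleton" for n in self.singletons}
        for k, members in enumerate(self.clusters, start=1):
            for n in members:
                out[n] = f"c{k}"
        return out

    def to_frame(self) -> pd.DataFrame:
        lab = self.labels()
        return pd.DataFrame(
            sorted(lab.items()), columns=["node_id", "cluster_id"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _order_clusters(groups: list[list[str]]) -> list[list[str]]:
    groups = [sorted(g) for g in groups]
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


def mcl_cluster(
    graph: nx.Graph | np.ndarray,
    inflation: float = 1.5,
    expansion: int = 2,
    prune_below: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
    node_ids: Sequence[str] | None = None,
    config: MclConfig | None = None,
) -> Clustering:
    """Run MCL and read clusters off the attractor structure.

    Accepts an undirected weighted ``networkx`` graph (node order is the
    sorted node ids, making the result deterministic) or a symmetric
    non-negative adjacency matrix with ``node_ids``. Self-loops are set to
    each node's maximum incident weight (1 for isolated nodes) before
    column normalization. Iteration stops when the matrix changes by less
    than ``tol`` (max absolute entry) or after ``max_iter`` rounds (with a
    warning recorded in ``diagnostics``).

    A node attracted by several attractor systems joins the cluster
    containing the smallest member id. Single-node components become
    singletons.
    """
    if config is not None:
        inflation = config.inflation
        expansion = config.expansion
        prune_below = config.prune_below
        max_iter = config.max_iter
        tol = config.tol
    if inflation <= 1:
        raise ValueError("inflation must be > 1")

    if isinstance(graph, nx.Graph):
        ids = sorted(graph.nodes)
        a = nx.to_numpy_array(graph, nodelist=ids, weight="weight")
    else:
        a = np.asarray(graph, dtype=float)
        if node_ids is None:
            raise ValueError("node_ids required with a matrix input")
        ids = list(node_ids)
    n = a.shape[0]
    if a.shape != (n, n) or n != len(ids):
        raise ValueError("adjacency must be square and match node_ids")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if (a < 0).any():
        raise ValueError("edge weights must be non-negative")
    if n == 0:
        return Clustering(clusters=[], singletons=[])

    m = a.copy()
    np.fill_diagonal(m, 0.0)
    loops = m.max(axis=0)
    loops[loops <= 0] = 1.0  # isolated nodes
    np.fill_diagonal(m, loops)
    m /= m.sum(axis=0, keepdims=True)

    colsum_dev = 0.0
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m ** inflation
        m /= m.sum(axis=0, keepdims=True)
        m[m < prune_below] = 0.0
        m /= m.sum(axis=0, keepdims=True)
        colsum_dev = max(colsum_dev, float(np.abs(m.sum(axis=0) - 1.0).max()))
        if np.abs(m - prev).max() < tol:
            converged = True
            break

    eps = prune_below
    attractors = [i for i in range(n) if m[i, i] > eps]
    # attractor systems: attractors linked by mutual/one-way flow
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (m[i, j] > eps or m[j, i] > eps):
                sys_graph.add_edge(i, j)
    systems = [sorted(c) for c in nx.connected_components(sys_graph)]
    system_of = {}
    for s_idx, syst in enumerate(systems):
        for i in syst:
            system_of[i] = s_idx

    members: dict[int, set[int]] = {s: set(syst) for s, syst in enumerate(systems)}
    for j in range(n):
        if j in system_of:
            continue
        pulls = sorted({system_of[i] for i in attractors if m[i, j] > eps})
        if not pulls:
            continue  # will fall out as a singleton below
        if len(pulls) > 1:
            # join the system containing the smallest member id
            pulls.sort(key=lambda s: min(ids[i] for i in members[s]))
        members[pulls[0]].add(j)

    assigned = set()
    groups = []
    for s in sorted(members):
        grp = members[s]
        assigned |= grp
        groups.append([ids[i] for i in grp])
    leftovers = [ids[j] for j in range(n) if j not in assigned]

    clusters = _order_clusters([g for g in groups if len(g) >= 2])
    singletons = sorted(leftovers + [g[0] for g in groups if len(g) == 1])
    diag = {
        "iterations": iterations,
        "converged": converged,
        "max_colsum_deviation": colsum_dev,
    }
    if not converged:
        diag["warning"] = f"MCL did not converge within {max_iter} iterations"
    return Clustering(clusters=clusters, singletons=singletons, diagnostics=diag)
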