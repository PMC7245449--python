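"""District adjacency structure and Moran's I spatial autocorrelation.

The adjacency graph encodes which districts share a common boundary.  For
Moran's I the neighbour matrix is row-standardized (each row with at least
one neighbour sums to one); isolated nodes stay in the graph but drop out of
the statistic's sums.  Inference is by random permutation of the values over
nodes, giving a two-sided pseudo p-value on |I|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AdjacencyGraph",
    "build_adjacency",
    "read_edge_list",
    "morans_i",
    "bivariate_morans_i",
    "permutation_pvalue",
]


class GraphFormatError(ValueError):
    pass


class UndefinedStatisticError(ValueError):
    pass


@dataclass
class AdjacencyGraph:
    """Symmetric neighbourhood structure on nodes 1..n (1-based ids)."""

    n_nodes: int
    neighbours: dict[int, set[int]] = field(repr=False)

    def __post_init__(self) -> None:
        for i, nb in self.neighbours.items():
            for j in nb:
                if i == j:
                    raise GraphFormatError(f"self-loop at node {i}")
                if i not in self.neighbours.get(j, set()):
                    raise GraphFormatError(f"asymmetric edge ({i}, {j})")

    @property
    def isolated_nodes(self) -> list[int]:
        return [i for i in range(1, self.n_nodes + 1) if not self.neighbours.get(i)]

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.neighbours.values()) // 2

    def degree(self, i: int) -> int:
        return len(self.neighbours.get(i, set()))

    def binary_matrix(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix (nodes in id order)."""
        A = np.zeros((self.n_nodes, self.n_nodes))
        for i, nb in self.neighbours.items():
            for j in nb:
                A[i - 1, j - 1] = 1.0
        return A

    def row_standardized(self) -> np.ndarray:
        """Row-standardized weight matrix; all-zero rows stay all-zero."""
        A = self.binary_matrix()
        rs = A.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            W = np.where(rs > 0, A / rs, 0.0)
        return W

    def edge_list(self) -> list[tuple[int, int]]:
        return sorted(
            (i, j) for i, nb in self.neighbours.items() for j in nb if i < j
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(1, self.n_nodes + 1))
        g.add_edges_from(self.edge_list())
        return g


def build_adjacency(edges, n_nodes: int) -> AdjacencyGraph:
    """Build a deduplicated symmetric graph from 1-based node-pair edges."""
    neighbours: dict[int, set[int]] = {i: set() for i in range(1, n_nodes + 1)}
    for a, b in edges:
        a, b = int(a), int(b)
        if a == b:
            raise GraphFormatError(f"self-loop ({a}, {b}) not allowed")
        if not (1 <= a <= n_nodes and 1 <= b <= n_nodes):
            raise GraphFormatError(f"edge ({a}, {b}) out of range 1..{n_nodes}")
        neighbours[a].add(b)
        neighbours[b].add(a)
    return AdjacencyGraph(n_nodes=n_nodes, neighbours=neighbours)


def read_edge_list(path, n_nodes: int) -> AdjacencyGraph:
    """Read a two-column CSV (node_a, node_b) of 1-based district indices."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise GraphFormatError("edge list needs two columns (node_a, node_b)")
    return build_adjacency(df.iloc[:, :2].to_numpy(), n_nodes)


def write_edge_list(graph: AdjacencyGraph, path) -> None:
    pd.DataFrame(graph.edge_list(), columns=["node_a", "node_b"]).to_csv(
        path, index=False
    )


def _active(graph: AdjacencyGraph) -> np.ndarray:
    deg = np.array([graph.degree(i) for i in range(1, graph.n_nodes + 1)])
    return deg > 0


def morans_i(values, graph: AdjacencyGraph) -> float:
    """Moran's I with row-standardized weights:
    I = (n / sum W) * sum_ij w_ij z_i z_j / sum_i z_i^2, z the centred values.

    Isolated nodes are excluded from all sums (including the centring).
    """
    x = np.asarray(values, dtype=float)
    if len(x) != graph.n_nodes:
        raise ValueError("values length must equal the number of nodes")
    act = _active(graph)
    xa = x[act]
    if np.ptp(xa) == 0:
        raise UndefinedStatisticError("Moran's I undefined for a constant vector")
    W = graph.row_standardized()[np.ix_(act, act)]
    z = xa - xa.mean()
    n = act.sum()
    S0 = W.sum()
    return float((n / S0) * (z @ W @ z) / (z @ z))


def bivariate_morans_i(x, y, graph: AdjacencyGraph) -> float:
    """Bivariate Moran's I between two variables on the same graph:
    I_xy = (n / sum W) * sum_ij w_ij zx_i zy_j / sqrt(sum zx^2 * sum zy^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != graph.n_nodes or len(y) != graph.n_nodes:
        raise ValueError("value vectors must match the number of nodes")
    act = _active(graph)
    xa, ya = x[act], y[act]
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedStatisticError("bivariate Moran's I undefined for constants")
    W = graph.row_standardized()[np.ix_(act, act)]
    zx = xa - xa.mean()
    zy = ya - ya.mean()
    n = act.sum()
    S0 = W.sum()
    return float((n / S0) * (zx @ W @ zy) / np.sqrt((zx @ zx) * (zy @ zy)))


def permutation_pvalue(
    stat_fn, values, graph: AdjacencyGraph, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Two-sided permutation pseudo p-value for a spatial statistic.

    pseudo-p = (1 + #{permutations with |I*| >= |I_obs|}) / (n_perm + 1).
    Returns (observed statistic, pseudo-p); fully determined by ``seed``.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    x = np.asarray(values, dtype=float)
    obs = stat_fn(x, graph)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(x)
        if abs(stat_fn(perm, graph)) >= abs(obs):
            count += 1
    return float(obs), (1 + count) / (n_perm + 1)
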