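"""Graph-theory characterization of binary brain networks.

For an undirected, unweighted network with adjacency a(i, j) on N nodes:

* degree centrality              D(i) = sum_j a(i, j)
* nodal efficiency               E_nodal(i) = 1/(N-1) * sum_{j != i} 1/d(i, j)
* clustering coefficient         C(i) = 2 L_i / (Z_i (Z_i - 1))
* global efficiency              E_glob = 1/(N(N-1)) * sum_{i != j} 1/d(i, j)
* local efficiency               E_loc = 1/N * sum_i E_glob(G_i)
* small-worldness                sigma = (K / C_rand) / (L / L_rand)

with d(i, j) the shortest path length, L_i the edge count among node i's
neighbors, Z_i its neighbor count, G_i the subgraph induced by those
neighbors, K the mean clustering coefficient, and L the characteristic
path length on the largest connected component.  C_rand and L_rand come
from degree-preserving (Maslov-Sneppen) rewired null networks.  Unreachable
pairs contribute 1/inf = 0 to efficiencies.

Because the raw sigma index is >= 1 for small-world networks while some
toolchains report a 0-1 bounded variant, the normalized value
sigma / (1 + sigma) is emitted alongside the raw index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, shortest_path

from .connectivity import ConnectivityMatrix, binarize_sparsity

DEFAULT_SPARSITY_GRID = np.round(np.arange(0.50, 0.901, 0.05), 10)


@dataclass
class BinaryNetwork:
    """Undirected, unweighted network: symmetric 0/1 adjacency, no self-loops."""

    adjacency: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.all(np.isin(a, (0.0, 1.0))):
            raise ValueError("adjacency must be binary")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not self.labels:
            self.labels = [f"CH{i + 1:02d}" for i in range(a.shape[0])]
        self.adjacency = a

    @classmethod
    def from_connectivity(cls, matrix: ConnectivityMatrix) -> "BinaryNetwork":
        if matrix.kind != "binary":
            raise ValueError("expected a binary-kind connectivity matrix")
        return cls(adjacency=matrix.values, labels=list(matrix.labels))

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() / 2)

    def edges(self) -> list[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(iu.tolist(), ju.tolist()))


def shortest_path_lengths(net: BinaryNetwork) -> np.ndarray:
    """BFS hop-count distances; unreachable pairs are infinite."""
    if net.n == 0:
        return np.zeros((0, 0))
    return shortest_path(net.adjacency, method="D", unweighted=True, directed=False)


def degree_centrality(net: BinaryNetwork) -> np.ndarray:
    return net.adjacency.sum(axis=1)


def _inverse_distances(dist: np.ndarray) -> np.ndarray:
    inv = np.zeros_like(dist)
    finite = np.isfinite(dist) & (dist > 0)
    inv[finite] = 1.0 / dist[finite]
    return inv


def nodal_efficiency(net: BinaryNetwork, dist: np.ndarray | None = None) -> np.ndarray:
    if dist is None:
        dist = shortest_path_lengths(net)
    n = net.n
    if n < 2:
        return np.zeros(n)
    return _inverse_distances(dist).sum(axis=1) / (n - 1)


def clustering_coefficient(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering C(i) and its network mean K; C(i) = 0 when the
    node has fewer than 2 neighbors."""
    a = net.adjacency
    c = np.zeros(net.n)
    for i in range(net.n):
        nb = np.flatnonzero(a[i])
        z = nb.size
        if z < 2:
            continue
        l_i = a[np.ix_(nb, nb)].sum() / 2.0
        c[i] = 2.0 * l_i / (z * (z - 1))
    return c, float(c.mean()) if net.n else 0.0


def global_efficiency(net: BinaryNetwork, dist: np.ndarray | None = None) -> float:
    n = net.n
    if n < 2:
        return 0.0
    if dist is None:
        dist = shortest_path_lengths(net)
    return float(_inverse_distances(dist).sum() / (n * (n - 1)))


def local_efficiency(net: BinaryNetwork) -> float:
    """Mean global efficiency of each node's neighbor-induced subgraph."""
    a = net.adjacency
    if net.n == 0:
        return 0.0
    total = 0.0
    for i in range(net.n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        sub = BinaryNetwork(adjacency=a[np.ix_(nb, nb)])
        total += global_efficiency(sub)
    return total / net.n


def characteristic_path_length(
    net: BinaryNetwork, dist: np.ndarray | None = None
) -> float:
    """Mean shortest path length over pairs in the largest connected component."""
    if dist is None:
        dist = shortest_path_lengths(net)
    n_comp, memb = connected_components(net.adjacency, directed=False)
    sizes = np.bincount(memb)
    giant = np.flatnonzero(memb == sizes.argmax())
    if giant.size < 2:
        return np.nan
    sub = dist[np.ix_(giant, giant)]
    mask = ~np.eye(giant.size, dtype=bool)
    return float(sub[mask].mean())


def rewire_degree_preserving(
    net: BinaryNetwork, rng: np.random.Generator, n_attempts: int | None = None
) -> BinaryNetwork:
    """Maslov-Sneppen double-edge swaps: each attempt picks two edges
    (a, b), (c, d) and rewires to (a, d), (c, b) when no self-loop or
    duplicate edge would result.  Every node degree is preserved exactly."""
    a = net.adjacency.copy()
    edges = net.edges()
    m = len(edges)
    if n_attempts is None:
        n_attempts = 10 * m
    if m < 2:
        return BinaryNetwork(adjacency=a, labels=list(net.labels))
    for _ in range(n_attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        (u, v), (x, y) = edges[i], edges[j]
        if rng.random() < 0.5:
            x, y = y, x
        # propose (u, y) and (x, v)
        if u == y or x == v:
            continue
        if a[u, y] or a[x, v]:
            continue
        a[u, v] = a[v, u] = 0.0
        a[x, y] = a[y, x] = 0.0
        a[u, y] = a[y, u] = 1.0
        a[x, v] = a[v, x] = 1.0
        edges[i] = (min(u, y), max(u, y))
        edges[j] = (min(x, v), max(x, v))
    return BinaryNetwork(adjacency=a, labels=list(net.labels))


@dataclass
class SmallWorldResult:
    sigma: float
    sigma_normalized: float  # sigma / (1 + sigma), bounded in (0, 1)
    K: float
    L: float
    C_rand: float
    L_rand: float
    n_nulls: int
    seed: int | None
    defined: bool = True


def small_worldness(
    net: BinaryNetwork, n_nulls: int = 100, seed: int | None = None
) -> SmallWorldResult:
    """Small-world index sigma = (K / C_rand) / (L / L_rand) against
    degree-preserving rewired nulls."""
    if n_nulls < 10:
        raise ValueError("need at least 10 null networks")
    if net.n_edges < 2:
        return SmallWorldResult(
            sigma=np.nan, sigma_normalized=np.nan, K=np.nan, L=np.nan,
            C_rand=np.nan, L_rand=np.nan, n_nulls=0, seed=seed, defined=False,
        )
    _, K = clustering_coefficient(net)
    L = characteristic_path_length(net)
    rng = np.random.default_rng(seed)
    ks, ls = [], []
    for _ in range(n_nulls):
        null = rewire_degree_preserving(net, rng)
        _, k_null = clustering_coefficient(null)
        ks.append(k_null)
        ls.append(characteristic_path_length(null))
    C_rand = float(np.mean(ks))
    L_rand = float(np.nanmean(ls))
    defined = C_rand > 0 and L > 0 and np.isfinite(L) and np.isfinite(L_rand)
    sigma = (K / C_rand) / (L / L_rand) if defined else np.nan
    return SmallWorldResult(
        sigma=sigma,
        sigma_normalized=sigma / (1.0 + sigma) if defined else np.nan,
        K=K, L=L, C_rand=C_rand, L_rand=L_rand, n_nulls=n_nulls, seed=seed,
        defined=defined,
    )


@dataclass
class GraphMetricSet:
    """All nodal and network metrics of one binary network."""

    degree: np.ndarray
    nodal_efficiency: np.ndarray
    clustering: np.ndarray
    global_efficiency: float
    local_efficiency: float
    char_path_length: float
    mean_clustering: float
    small_world: SmallWorldResult | None = None
    sparsity: float | None = None
    labels: list[str] = field(default_factory=list)

    def network_summary(self) -> dict[str, float]:
        d = {
            "global_efficiency": self.global_efficiency,
            "local_efficiency": self.local_efficiency,
            "char_path_length": self.char_path_length,
            "mean_clustering": self.mean_clustering,
        }
        if self.small_world is not None:
            d["small_worldness"] = self.small_world.sigma
            d["small_worldness_normalized"] = self.small_world.sigma_normalized
        return d


def compute_metrics(
    net: BinaryNetwork,
    n_nulls: int = 0,
    seed: int | None = None,
    sparsity: float | None = None,
) -> GraphMetricSet:
    """Full metric set; small-worldness only when ``n_nulls`` > 0."""
    dist = shortest_path_lengths(net)
    c, K = clustering_coefficient(net)
    sw = small_worldness(net, n_nulls=n_nulls, seed=seed) if n_nulls else None
    return GraphMetricSet(
        degree=degree_centrality(net),
        nodal_efficiency=nodal_efficiency(net, dist),
        clustering=c,
        global_efficiency=global_efficiency(net, dist),
        local_efficiency=local_efficiency(net),
        char_path_length=characteristic_path_length(net, dist),
        mean_clustering=K,
        small_world=sw,
        sparsity=sparsity,
        labels=list(net.labels),
    )


@dataclass
class SparsitySweep:
    """Metric sets over a strictly increasing sparsity grid, with
    mean +/- SD summaries across levels."""

    grid: np.ndarray
    metrics: list[GraphMetricSet]

    def summary(self) -> pd.DataFrame:
        rows = []
        for s, m in zip(self.grid, self.metrics):
            row = {"sparsity": s, **m.network_summary()}
            rows.append(row)
        return pd.DataFrame(rows)

    def mean_sd(self) -> pd.DataFrame:
        df = self.summary().drop(columns="sparsity")
        return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})

    def nodal_long(self) -> pd.DataFrame:
        rows = []
        for s, m in zip(self.grid, self.metrics):
            for i, label in enumerate(m.labels):
                rows.append(
                    {
                        "sparsity": s,
                        "node": label,
                        "degree": m.degree[i],
                        "nodal_efficiency": m.nodal_efficiency[i],
                        "clustering": m.clustering[i],
                    }
                )
        return pd.DataFrame(rows)


def sparsity_sweep(
    matrix: ConnectivityMatrix,
    grid: np.ndarray | None = None,
    n_nulls: int = 100,
    seed: int | None = None,
) -> SparsitySweep:
    """Binarize an r-kind matrix at each sparsity level and compute the full
    metric set per level (default grid 0.50-0.90, step 0.05)."""
    if grid is None:
        grid = DEFAULT_SPARSITY_GRID
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sparsity grid must be strictly increasing")
    if np.any(grid <= 0) or np.any(grid > 1):
        raise ValueError("sparsity grid must lie within (0, 1]")
    metrics = []
    for k, s in enumerate(grid):
        net = BinaryNetwork.from_connectivity(binarize_sparsity(matrix, float(s)))
        level_seed = None if seed is None else seed + k
        metrics.append(
            compute_metrics(net, n_nulls=n_nulls, seed=level_seed, sparsity=float(s))
        )
    return SparsitySweep(grid=grid, metrics=metrics)
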