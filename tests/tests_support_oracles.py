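"""Independent brute-force oracles used by the acceptance suite."""

import numpy as np


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    """O(n^3) all-pairs shortest paths, written independently of the
    package's BFS-based implementation."""
    n = a.shape[0]
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_clustering(a: np.ndarray) -> np.ndarray:
    """Clustering coefficients by explicit triangle counting over all
    neighbor pairs."""
    n = a.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        z = nb.size
        if z < 2:
            continue
        links = sum(
            a[nb[u], nb[v]] for u in range(z) for v in range(u + 1, z)
        )
        c[i] = 2.0 * links / (z * (z - 1))
    return c
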