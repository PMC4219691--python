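"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths (and libraries) they are checking:
betweenness is counted by explicit BFS shortest-path enumeration, not by
Brandes' algorithm.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_betweenness(adjacency: np.ndarray) -> np.ndarray:
    """Unnormalised betweenness by explicit shortest-path counting.

    For every node pair (s, t) the number of shortest paths sigma_st and,
    for every intermediate v, sigma_sv * sigma_vt when v lies on a shortest
    s-t path. Suitable for small graphs only.
    """
    a = np.asarray(adjacency) != 0
    p = a.shape[0]
    dist = np.full((p, p), np.inf)
    sigma = np.zeros((p, p))
    for s in range(p):
        dist[s, s] = 0.0
        sigma[s, s] = 1.0
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in np.nonzero(a[u])[0]:
                if np.isinf(dist[s, v]):
                    dist[s, v] = dist[s, u] + 1
                    queue.append(v)
                if dist[s, v] == dist[s, u] + 1:
                    sigma[s, v] += sigma[s, u]
    betweenness = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            if np.isinf(dist[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(p):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    betweenness[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return betweenness


def random_directed_adjacency(rng: np.random.Generator, p: int, density: float = 0.3) -> np.ndarray:
    """Random binary directed adjacency with zero diagonal."""
    a = (rng.random((p, p)) < density).astype(int)
    np.fill_diagonal(a, 0)
    return a
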