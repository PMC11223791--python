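"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (dense linear algebra, O(n^2) loops,
direct textbook formulas) and shares no code with the package
implementations it cross-checks.
"""

import numpy as np


# -- graph metrics ----------------------------------------------------------


def pagerank_power_iteration(adjacency: np.ndarray, alpha: float = 0.85,
                             tol: float = 1e-13, max_iter: int = 100000) -> np.ndarray:
    n = adjacency.shape[0]
    out_degree = adjacency.sum(axis=1)
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        dangling = p[out_degree == 0].sum()
        new = np.zeros(n)
        for i in range(n):
            if out_degree[i] > 0:
                new += alpha * p[i] * adjacency[i] / out_degree[i]
        new += alpha * dangling / n + (1 - alpha) / n
        if np.abs(new - p).sum() < tol:
            return new
        p = new
    return p


def authority_power_iteration(adjacency: np.ndarray, iters: int = 5000) -> np.ndarray:
    ata = adjacency.T @ adjacency
    v = np.full(adjacency.shape[0], 1.0)
    v /= np.linalg.norm(v)
    for _ in range(iters):
        nv = ata @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            return np.zeros_like(v)
        v = nv / norm
    return v


def graph_energy(adjacency: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(adjacency).real).sum())


def clustering_brute_force(adjacency: np.ndarray) -> np.ndarray:
    n = adjacency.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(adjacency[i])[0]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            adjacency[u, v] > 0
            for ai, u in enumerate(nbrs) for v in nbrs[ai + 1:]
        )
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def shortest_paths_floyd(adjacency: np.ndarray) -> np.ndarray:
    n = adjacency.shape[0]
    d = np.where(adjacency > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def eccentricity_diameter_radius(adjacency: np.ndarray):
    """Per-component eccentricities; graph diameter/radius over components."""
    d = shortest_paths_floyd(adjacency)
    n = adjacency.shape[0]
    finite = np.isfinite(d)
    ecc = np.array([d[i][finite[i]].max() for i in range(n)])
    seen = set()
    diameters, radii = [], []
    for i in range(n):
        if i in seen:
            continue
        comp = np.nonzero(finite[i])[0]
        seen.update(comp.tolist())
        diameters.append(ecc[comp].max())
        radii.append(ecc[comp].min())
    return ecc, max(diameters), min(radii)


def random_connected_adjacency(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random simple connected graph: random spanning tree + random extra edges."""
    a = np.zeros((n, n))
    order = rng.permutation(n)
    for idx in range(1, n):
        j = order[idx]
        i = order[rng.integers(idx)]
        a[i, j] = a[j, i] = 1.0
    p = rng.uniform(0.1, 0.6)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                a[i, j] = a[j, i] = 1.0
    return a


# -- signatures -------------------------------------------------------------


def signature_brute_force(atom_positions, atom_class_sets, cutoffs,
                          pair_index, n_pairs) -> np.ndarray:
    """O(n^2) cumulative class-pair counting over all atom pairs."""
    n = len(atom_positions)
    sig = np.zeros((len(cutoffs), n_pairs), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(np.asarray(atom_positions[i])
                                     - np.asarray(atom_positions[j])))
            for ci in atom_class_sets[i]:
                for cj in atom_class_sets[j]:
                    col = pair_index(ci, cj)
                    for k, cut in enumerate(cutoffs):
                        if d <= cut:
                            sig[k, col] += 1
    return sig.reshape(-1)


# -- regression metrics ------------------------------------------------------


def pearson_naive(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def average_ranks(x):
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_naive(x, y):
    return pearson_naive(average_ranks(x), average_ranks(y))


def kendall_tau_b_naive(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2.0
    denom = np.sqrt((n0 - ties_x) * (n0 - ties_y))
    return float((concordant - discordant) / denom)


def r_squared_naive(y_true, y_pred):
    y_true, y_pred = np.asarray(y_true, float), np.asarray(y_pred, float)
    ss_res = ((y_pred - y_true) ** 2).sum()
    ss_tot = ((y_true - y_true.mean()) ** 2).sum()
    return float(1.0 - ss_res / ss_tot)
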