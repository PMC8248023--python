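"""Graph-theory metrics for weighted structural connectomes.

Degree, density, clustering and degree-preserving rewiring operate on the
binary support of the matrix; path-based metrics (efficiencies,
characteristic path length) use weighted shortest paths with edge cost equal
to the inverse connection weight, the standard convention for
connection-probability matrices.  Disconnected pairs contribute 1/inf = 0 to
efficiencies; the characteristic path length of a disconnected graph is
computed on its largest connected component and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "MetricSet",
    "degree_and_density",
    "shortest_path_lengths",
    "efficiencies",
    "characteristic_path_length",
    "clustering_coefficient",
    "randomized_ensemble",
    "small_world_sigma",
    "compute_metric_set",
]


@dataclass
class MetricSet:
    """All scalar/nodal metrics for one connectome."""

    degree: np.ndarray
    mean_degree: float
    density: float
    e_glob: float
    e_nodal: np.ndarray
    e_local: float
    char_path_length: float
    path_on_largest_component: bool
    clustering: float
    sigma: float | None = None
    cl_rand: float | None = None
    l_rand: float | None = None

    def as_row(self) -> dict:
        row = {
            "mean_degree": self.mean_degree, "density": self.density,
            "e_glob": self.e_glob, "e_local": self.e_local,
            "char_path_length": self.char_path_length,
            "clustering": self.clustering,
        }
        if self.sigma is not None:
            row["sigma"] = self.sigma
        return row


def _check_square(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("connectome must be a square matrix")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    return w


def degree_and_density(weights: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Binary degree per node, mean degree, and connection density 2E/(N(N-1))."""
    w = _check_square(weights)
    a = (w > 0).astype(int)
    np.fill_diagonal(a, 0)
    k = a.sum(axis=1)
    n = a.shape[0]
    e = a.sum() / 2
    return k, float(k.mean()), float(2 * e / (n * (n - 1)))


def shortest_path_lengths(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths with edge cost = 1 / weight.

    Disconnected pairs are +inf; the diagonal is 0.
    """
    w = _check_square(weights)
    with np.errstate(divide="ignore"):
        cost = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return shortest_path(csr_array(cost), method="D", directed=False)


def efficiencies(lengths: np.ndarray) -> tuple[float, np.ndarray, float]:
    """(E_glob, E_nodal vector, E_local) from a shortest-path-length matrix."""
    l = np.asarray(lengths, dtype=float)
    n = l.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / l
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    e_nodal = inv.sum(axis=0) / (n - 1)
    e_glob = inv.sum() / (n * (n - 1))
    return float(e_glob), e_nodal, float(e_nodal.mean())


def characteristic_path_length(lengths: np.ndarray) -> tuple[float, bool]:
    """Mean shortest path length over all ordered pairs.

    On a disconnected graph the mean is taken over the largest connected
    component and the second return value is True.
    """
    l = np.asarray(lengths, dtype=float)
    n = l.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.isfinite(l[off]).all():
        return float(l[off].mean()), False
    finite_adj = np.isfinite(l) & off
    n_comp, labels = connected_components(csr_array(finite_adj.astype(int)),
                                          directed=False)
    sizes = np.bincount(labels)
    comp = np.flatnonzero(labels == sizes.argmax())
    if comp.size < 2:
        warnings.warn("largest component has a single node; L undefined, returning inf",
                      stacklevel=2)
        return float("inf"), True
    sub = l[np.ix_(comp, comp)]
    m = comp.size
    return float(sub[~np.eye(m, dtype=bool)].mean()), True


def clustering_coefficient(weights: np.ndarray, per_node: bool = False):
    """Mean binary clustering coefficient 2 t_i / (k_i (k_i - 1)).

    Nodes with degree < 2 contribute 0.
    """
    w = _check_square(weights)
    a = (w > 0).astype(float)
    np.fill_diagonal(a, 0)
    k = a.sum(axis=1)
    t = np.diag(a @ a @ a) / 2.0            # closed triangles per node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2 * t / denom, 0.0)
    return c if per_node else float(c.mean())


def randomized_ensemble(weights: np.ndarray, n_nets: int = 100,
                        seed: int | np.random.Generator = 0,
                        swaps_per_edge: int = 10) -> list[np.ndarray]:
    """Degree-preserving rewired null networks, weights carried with edges.

    Each member is produced by attempted double-edge swaps
    (u,v),(x,y) -> (u,x),(v,y), rejecting self-loops, multi-edges and swaps
    that touch fewer than four distinct nodes.  The binary degree sequence is
    exactly preserved and each surviving edge keeps its original weight.
    """
    if n_nets < 1:
        raise ValueError("need n_nets >= 1")
    w = _check_square(weights)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu, ju = np.nonzero(np.triu(w, k=1))
    m = iu.size
    if m < 2:
        warnings.warn("too few edges to rewire; returning copies", stacklevel=2)
        return [w.copy() for _ in range(n_nets)]

    out = []
    base_edges = list(zip(iu.tolist(), ju.tolist()))
    base_wts = [w[i, j] for i, j in base_edges]
    for _ in range(n_nets):
        edges = list(base_edges)
        wts = list(base_wts)
        edge_set = set(edges)
        attempts = swaps_per_edge * m
        picks = rng.integers(0, m, size=(attempts, 2))
        flips = rng.random(attempts) < 0.5
        for (a, b), flip in zip(picks, flips):
            if a == b:
                continue
            u, v = edges[a]
            x, y = edges[b]
            if flip:
                x, y = y, x
            if len({u, v, x, y}) < 4:
                continue
            e1 = (min(u, x), max(u, x))
            e2 = (min(v, y), max(v, y))
            if e1 in edge_set or e2 in edge_set:
                continue
            edge_set.discard(edges[a])
            edge_set.discard(edges[b])
            edges[a], edges[b] = e1, e2
            edge_set.add(e1)
            edge_set.add(e2)
        r = np.zeros_like(w)
        for (i, j), wt in zip(edges, wts):
            r[i, j] = r[j, i] = wt
        out.append(r)
    return out


def small_world_sigma(weights: np.ndarray,
                      ensemble: list[np.ndarray]) -> tuple[float, float, float]:
    """Small-world index sigma = (Cl/Cl_rand) / (L/L_rand).

    Returns (sigma, Cl_rand, L_rand) where the rand terms are ensemble means.
    sigma > 1 indicates small-world organization.
    """
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    cl = clustering_coefficient(weights)
    l, _ = characteristic_path_length(shortest_path_lengths(weights))
    cl_rand = float(np.mean([clustering_coefficient(r) for r in ensemble]))
    l_rand = float(np.mean([characteristic_path_length(shortest_path_lengths(r))[0]
                            for r in ensemble]))
    if cl_rand == 0 or l_rand == 0:
        raise ValueError("degenerate ensemble: Cl_rand or L_rand is zero")
    return (cl / cl_rand) / (l / l_rand), cl_rand, l_rand


def compute_metric_set(weights: np.ndarray, n_rand: int = 0,
                       seed: int = 0) -> MetricSet:
    """All metrics for one connectome; sigma only when ``n_rand`` > 0."""
    k, mean_k, dens = degree_and_density(weights)
    l_mat = shortest_path_lengths(weights)
    e_glob, e_nodal, e_local = efficiencies(l_mat)
    cpl, flagged = characteristic_path_length(l_mat)
    cl = clustering_coefficient(weights)
    sigma = cl_rand = l_rand = None
    if n_rand > 0:
        ens = randomized_ensemble(weights, n_rand, seed)
        sigma, cl_rand, l_rand = small_world_sigma(weights, ens)
    return MetricSet(degree=k, mean_degree=mean_k, density=dens,
                     e_glob=e_glob, e_nodal=e_nodal, e_local=e_local,
                     char_path_length=cpl, path_on_largest_component=flagged,
                     clustering=cl, sigma=sigma, cl_rand=cl_rand, l_rand=l_rand)
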