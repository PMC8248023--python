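"""Modularity, hub classification and modular-connectivity fingerprints.

Community structure is found by running weighted Louvain many times with
distinct sub-seeds and keeping the modal partition (ties broken by higher
modularity Q, then lexicographically), which sidesteps the degeneracy of
single Louvain runs.  Hubs come in three flavours: global hubs by normalized
nodal efficiency, and provincial/connector hubs by within-module degree
z-score combined with the participation coefficient.  Degree quantities in
the role and fingerprint computations are binary connection counts.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Partition",
    "louvain_consensus",
    "modularity_q",
    "partition_similarity",
    "classify_global_hubs",
    "node_roles",
    "rsn_overlap",
    "Fingerprints",
    "modular_fingerprints",
    "select_reference_partition",
]


@dataclass
class Partition:
    """Node -> module assignment (module ids contiguous from 1)."""

    assignment: np.ndarray
    q: float
    n_runs: int = 1
    mode_frequency: float = 1.0

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max())

    def members(self, module: int) -> np.ndarray:
        """0-based node indices of a 1-based module id."""
        return np.flatnonzero(self.assignment == module)

    def modules(self) -> list[set[int]]:
        return [set(self.members(m).tolist()) for m in range(1, self.n_modules + 1)]


def _canonical(assignment: np.ndarray) -> tuple[int, ...]:
    """Relabel modules by first node occurrence -> comparable canonical form."""
    relabel: dict[int, int] = {}
    out = []
    for a in assignment:
        if a not in relabel:
            relabel[a] = len(relabel) + 1
        out.append(relabel[a])
    return tuple(out)


def modularity_q(weights: np.ndarray, assignment) -> float:
    """Weighted Newman modularity of an assignment.

    Q = sum_ij (w_ij - s_i s_j / 2m) delta(c_i, c_j) / 2m with s the node
    strengths and 2m the total weight.
    """
    w = np.asarray(weights, dtype=float)
    c = np.asarray(assignment)
    s = w.sum(axis=1)
    two_m = s.sum()
    if two_m == 0:
        raise ValueError("graph has zero total weight")
    same = c[:, None] == c[None, :]
    return float(((w - np.outer(s, s) / two_m) * same).sum() / two_m)


def louvain_consensus(weights: np.ndarray, n_runs: int = 100,
                      seed: int = 0, resolution: float = 1.0) -> Partition:
    """Modal partition over repeated weighted Louvain runs.

    Each run uses a distinct sub-seed; partitions are canonicalized before
    counting so label permutations collapse.  Ties in occurrence count are
    broken by higher Q, then by lexicographic canonical form.
    """
    w = np.asarray(weights, dtype=float)
    if w.sum() == 0:
        raise ValueError("empty graph")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    g = nx.from_numpy_array(w)
    rng = np.random.default_rng(seed)
    counter: Counter[tuple[int, ...]] = Counter()
    for _ in range(n_runs):
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution,
            seed=int(rng.integers(2 ** 31)))
        assignment = np.empty(w.shape[0], dtype=int)
        for label, nodes in enumerate(comms, start=1):
            assignment[list(nodes)] = label
        counter[_canonical(assignment)] += 1
    best = max(counter.items(),
               key=lambda kv: (kv[1], modularity_q(w, np.array(kv[0])),
                               tuple(-x for x in kv[0])))
    assignment = np.array(best[0])
    return Partition(assignment=assignment, q=modularity_q(w, assignment),
                     n_runs=n_runs, mode_frequency=best[1] / n_runs)


def partition_similarity(p1: Partition, p2: Partition,
                         symmetrize: bool = False) -> float:
    """Mean best-match module overlap between two partitions, in (0, 1].

    For each module of ``p1`` the best Jaccard overlap (shared regions over
    the union of the two modules) with any module of ``p2`` is found; the
    similarity is the mean of these maxima.  ``symmetrize`` averages both
    directions.  Identical partitions score 1.
    """
    if len(p1.assignment) != len(p2.assignment):
        raise ValueError("partitions must share a node set")
    if p1.n_modules == 0 or p2.n_modules == 0:
        raise ValueError("empty partition")

    def directed(a: Partition, b: Partition) -> float:
        mods_b = b.modules()
        best = [max(len(m & mb) / len(m | mb) for mb in mods_b) for m in a.modules()]
        return float(np.mean(best))

    if symmetrize:
        return 0.5 * (directed(p1, p2) + directed(p2, p1))
    return directed(p1, p2)


def classify_global_hubs(e_nodal: np.ndarray) -> pd.DataFrame:
    """Global hubs by normalized nodal efficiency.

    Efficiency is normalized by its mean; a node is a hub when its normalized
    value strictly exceeds 1 + SD of the normalized values (sample SD).
    Returns a table sorted by descending normalized efficiency with a
    boolean ``is_hub`` column (nodes are 1-based).
    """
    e = np.asarray(e_nodal, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two nodes")
    if np.any(e < 0) or e.sum() == 0:
        raise ValueError("nodal efficiencies must be non-negative and not all zero")
    norm = e / e.mean()
    cut = 1.0 + norm.std(ddof=1)
    df = pd.DataFrame({"node": np.arange(1, e.size + 1),
                       "e_nodal": e, "normalized": norm,
                       "is_hub": norm > cut})
    return df.sort_values("normalized", ascending=False, ignore_index=True)


def node_roles(weights: np.ndarray, partition: Partition) -> pd.DataFrame:
    """Within-module degree z-score, participation coefficient and hub role.

    z uses binary within-module degree standardized within each module
    (sample SD; singleton or degenerate modules give z = 0).  PC is
    1 - sum_m (k_im / k_i)^2 on binary degrees.  A node with z above
    mean(z) + SD(z) of all nodes is a provincial hub when PC <= 0.3 and a
    connector hub when PC > 0.3.
    """
    w = np.asarray(weights, dtype=float)
    a = (w > 0).astype(int)
    np.fill_diagonal(a, 0)
    c = partition.assignment
    n = a.shape[0]
    k = a.sum(axis=1)

    k_within = np.zeros(n)
    per_module = np.zeros((n, partition.n_modules))
    for m in range(1, partition.n_modules + 1):
        members = c == m
        per_module[:, m - 1] = a[:, members].sum(axis=1)
        k_within[members] = per_module[members, m - 1]

    z = np.zeros(n)
    for m in range(1, partition.n_modules + 1):
        members = c == m
        if members.sum() < 2:
            continue
        mu, sd = k_within[members].mean(), k_within[members].std(ddof=1)
        if sd > 0:
            z[members] = (k_within[members] - mu) / sd

    with np.errstate(divide="ignore", invalid="ignore"):
        pc = np.where(k > 0, 1.0 - ((per_module / np.where(k, k, 1)[:, None]) ** 2).sum(axis=1), 0.0)

    cut = z.mean() + z.std(ddof=1)
    role = np.where(z > cut, np.where(pc > 0.3, "connector hub", "provincial hub"), "none")
    return pd.DataFrame({"node": np.arange(1, n + 1), "module": c,
                         "z_within": z, "pc": pc, "role": role})


def rsn_overlap(partition: Partition, region_volumes: pd.DataFrame) -> pd.DataFrame:
    """Module x RSN percentage-overlap matrix.

    ``region_volumes`` is a region x RSN table of intersection volumes (rows
    ordered like the partition's nodes).  Entry (m, r) is 100 times the
    volume of module m's regions intersecting RSN r over the total volume of
    all regions intersecting r, so columns sum to 100 when every region is
    assigned.
    """
    vols = np.asarray(region_volumes, dtype=float)
    if vols.shape[0] != len(partition.assignment):
        raise ValueError("region rows must match partition nodes")
    if np.any(vols < 0):
        raise ValueError("volumes must be non-negative")
    totals = vols.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("an RSN has zero total intersection volume")
    rows = []
    for m in range(1, partition.n_modules + 1):
        rows.append(100.0 * vols[partition.members(m)].sum(axis=0) / totals)
    cols = (region_volumes.columns if isinstance(region_volumes, pd.DataFrame)
            else [f"RSN_{r + 1}" for r in range(vols.shape[1])])
    return pd.DataFrame(rows, index=range(1, partition.n_modules + 1), columns=cols)


@dataclass
class Fingerprints:
    """Modular-connectivity fingerprints under a reference partition.

    ``inter`` counts binary edges between module pairs (symmetric, zero
    diagonal); ``intra`` the edge count within each module; ``hub_driven``
    counts edges from connector hubs of the row module toward nodes of the
    column module (off-diagonal only).
    """

    inter: np.ndarray
    intra: np.ndarray
    hub_driven: np.ndarray
    no_connector_hubs: bool

    @property
    def overall_hub_connectivity(self) -> int:
        return int(self.hub_driven.sum())


def modular_fingerprints(weights: np.ndarray, reference: Partition,
                         connector_hubs) -> Fingerprints:
    """Inter/intra-modular and connector-hub-driven connectivity counts.

    ``connector_hubs`` is an iterable of 1-based node indices (e.g. from
    ``node_roles``).  With no connector hubs the hub-driven matrix is all
    zero and flagged.
    """
    a = (np.asarray(weights) > 0).astype(int)
    np.fill_diagonal(a, 0)
    c = reference.assignment
    nm = reference.n_modules
    onehot = np.zeros((a.shape[0], nm), dtype=int)
    onehot[np.arange(a.shape[0]), c - 1] = 1
    block = onehot.T @ a @ onehot            # (m, m') degree-sum blocks
    inter = block.copy()
    np.fill_diagonal(inter, 0)
    intra = np.diag(block) // 2              # within-module edge counts

    hubs = sorted(set(int(h) for h in connector_hubs))
    hub_driven = np.zeros((nm, nm), dtype=int)
    for h in hubs:
        hm = c[h - 1] - 1
        targets = a[h - 1] @ onehot
        for m2 in range(nm):
            if m2 != hm:
                hub_driven[hm, m2] += targets[m2]
    no_hubs = not hubs
    if no_hubs:
        warnings.warn("no connector hubs: hub-driven fingerprint is all zero",
                      stacklevel=2)
    return Fingerprints(inter=inter, intra=np.asarray(intra),
                        hub_driven=hub_driven, no_connector_hubs=no_hubs)


def select_reference_partition(subject_matrices, candidates: list[Partition]) -> Partition:
    """Candidate with the highest mean modularity across subject matrices.

    The goodness-of-fit of a candidate partition is its mean Q over all
    subject matrices; ties keep the first candidate.
    """
    if not candidates:
        raise ValueError("need at least one candidate partition")
    scores = [float(np.mean([modularity_q(m, cand.assignment) for m in subject_matrices]))
              for cand in candidates]
    return candidates[int(np.argmax(scores))]
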