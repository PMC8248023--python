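"""From raw streamline counts to analysis-ready structural connectomes.

The construction chain is fixed: divide each row of the raw count matrix by
its seed region's waytotal, divide by the individual's maximum value so
entries lie in [0, 1], average the two directed estimates into a symmetric
connection-probability matrix, zero entries below 1% of the subject's
strongest connection, and finally apply a group consistency mask that keeps
the 30% (by default) most consistent edges across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import hemisphere_of, node_table

__all__ = [
    "SubjectConnectome",
    "ConsistencyMask",
    "CohortPair",
    "normalize_sc",
    "apply_weight_threshold",
    "consistency_mask",
    "apply_mask",
    "threshold_diagnostics",
    "classify_edge_hemisphere",
    "build_cohort_pair",
]


@dataclass
class SubjectConnectome:
    """One subject/timepoint symmetric connectivity-probability matrix."""

    weights: np.ndarray
    subject_id: str = ""
    timepoint: int = 1
    labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class ConsistencyMask:
    """Group consistency mask at a target edge density."""

    mask: np.ndarray                 # (n, n) bool, symmetric, zero diagonal
    target_density: float
    achieved_density: float
    scores: np.ndarray               # (n, n) per-edge consistency (mean/SD)

    @property
    def n_edges(self) -> int:
        return int(self.mask[np.triu_indices_from(self.mask, k=1)].sum())


@dataclass
class CohortPair:
    """Aligned cohort across two timepoints — the paired-analysis unit."""

    sc_t1: np.ndarray                # (n_subjects, n, n)
    sc_t2: np.ndarray                # (n_subjects, n, n)
    subject_ids: list[str]
    mask: np.ndarray                 # common group mask, (n, n) bool
    labels: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sc_t1.shape != self.sc_t2.shape:
            raise ValueError("timepoint stacks must have identical shape")
        if len(self.subject_ids) != self.sc_t1.shape[0]:
            raise ValueError("subject_ids length mismatch")
        if self.labels is None:
            self.labels = node_table(self.sc_t1.shape[1])

    @property
    def n_subjects(self) -> int:
        return self.sc_t1.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.sc_t1.shape[1]

    #: stacks under each timepoint's own mask (falls back to the common-mask
    #: stacks when masks were pooled); topology stages use these so the two
    #: timepoints keep their own edge support
    sc_t1_own: np.ndarray | None = None
    sc_t2_own: np.ndarray | None = None

    def differences(self) -> np.ndarray:
        """Per-subject difference matrices (timepoint 2 - timepoint 1)."""
        return self.sc_t2 - self.sc_t1

    def own_mask_stacks(self) -> tuple[np.ndarray, np.ndarray]:
        if self.sc_t1_own is None or self.sc_t2_own is None:
            return self.sc_t1, self.sc_t2
        return self.sc_t1_own, self.sc_t2_own


def normalize_sc(raw_counts: np.ndarray, waytotals: np.ndarray) -> np.ndarray:
    """Waytotal-normalize, scale to [0, 1], and symmetrize raw counts.

    Each row i is divided by waytotal_i, the whole matrix by its maximum, and
    the directed estimates P_ij, P_ji are averaged.  Scale-invariant in the
    raw counts.  A zero matrix (individual max = 0) is returned as all zeros
    with a warning rather than dividing by zero.
    """
    counts = np.asarray(raw_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("raw counts must be a square matrix")
    if np.any(counts < 0):
        raise ValueError("raw counts must be non-negative")
    waytotals = np.asarray(waytotals, dtype=float)
    if waytotals.shape != (counts.shape[0],):
        raise ValueError("waytotals must be a vector of length n_nodes")
    if np.any(waytotals <= 0):
        raise ValueError("waytotals must be strictly positive")

    p = counts / waytotals[:, None]
    top = p.max()
    if top == 0:
        warnings.warn("all-zero count matrix: individual maximum is 0", stacklevel=2)
        return np.zeros_like(p)
    p /= top
    sym = 0.5 * (p + p.T)
    np.fill_diagonal(sym, 0.0)
    return sym


def apply_weight_threshold(weights: np.ndarray, fraction: float = 0.01) -> np.ndarray:
    """Zero entries below ``fraction`` of the subject's strongest connection."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    w = np.asarray(weights, dtype=float)
    if fraction == 0 or w.max() == 0:
        return w.copy()
    out = w.copy()
    out[out < fraction * w.max()] = 0.0
    return out


def consistency_mask(cohort: list[np.ndarray] | np.ndarray,
                     target_density: float = 0.30) -> ConsistencyMask:
    """Keep the most consistent edges across subjects at a target density.

    Consistency of an edge is the inverse coefficient of variation of its
    weight across subjects (mean / SD, absent edges counted as weight 0).
    Edges are ranked most-consistent first — ties broken by higher mean
    weight, then lower (i, j) order — and the top round(density * N(N-1)/2)
    are kept.  If fewer edges than that are present in any subject, all
    present edges are kept and the achieved density reported.
    """
    stack = np.asarray(cohort, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack of >= 2 same-shape subject matrices")
    n = stack.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    vals = stack[:, iu, ju]                       # (subjects, edges)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(sd > 0, mean / sd, np.where(mean > 0, np.inf, -np.inf))

    n_pairs = iu.size
    k = int(round(target_density * n_pairs))
    present = mean > 0
    if k > present.sum():
        warnings.warn(
            f"target density {target_density:.2f} exceeds available edge density "
            f"{present.sum() / n_pairs:.3f}; keeping all present edges",
            stacklevel=2,
        )
        k = int(present.sum())

    # rank: score desc, mean desc, (i, j) asc
    order = np.lexsort((ju, iu, -mean, -np.nan_to_num(score, posinf=np.finfo(float).max,
                                                      neginf=-np.finfo(float).max)))
    keep = order[:k]
    mask = np.zeros((n, n), dtype=bool)
    mask[iu[keep], ju[keep]] = True
    mask |= mask.T

    scores = np.zeros((n, n))
    scores[iu, ju] = np.nan_to_num(score, posinf=np.finfo(float).max, neginf=0.0)
    scores += scores.T
    return ConsistencyMask(mask=mask, target_density=target_density,
                           achieved_density=k / n_pairs, scores=scores)


def apply_mask(weights: np.ndarray, mask: np.ndarray | ConsistencyMask) -> np.ndarray:
    """Elementwise product of a connectome with a binary mask."""
    m = mask.mask if isinstance(mask, ConsistencyMask) else np.asarray(mask)
    w = np.asarray(weights, dtype=float)
    if m.shape != w.shape:
        raise ValueError("mask and connectome shapes differ")
    return w * m


def threshold_diagnostics(cohort: list[np.ndarray] | np.ndarray,
                          mask: ConsistencyMask,
                          bins: int = 20) -> pd.DataFrame:
    """Per-subject report of what the consistency mask removed.

    For each subject: the fraction of its present connections removed by the
    mask, a histogram of the removed connection strengths, the fraction of
    mask edges absent (zero weight) in the subject, and a histogram of the
    strengths of mask edges across the group where the subject lacks them
    counts as zero.  Mirrors the standard validation that the mask removes
    few, weak connections and that no subject lacks more than half the mask.
    """
    stack = np.asarray(cohort, dtype=float)
    n = stack.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    m = mask.mask[iu, ju]
    rows = []
    edges = np.linspace(0, 1, bins + 1)
    for s in range(stack.shape[0]):
        w = stack[s, iu, ju]
        present = w > 0
        removed = present & ~m
        absent = m & ~present
        rows.append({
            "subject": s,
            "fraction_removed": removed.sum() / present.sum() if present.any() else 0.0,
            "removed_strength_hist": np.histogram(w[removed], bins=edges)[0],
            "fraction_mask_absent": absent.sum() / max(m.sum(), 1),
            "absent_strength_hist": np.histogram(
                stack[:, iu, ju].mean(axis=0)[absent], bins=edges)[0],
        })
    return pd.DataFrame(rows)


def classify_edge_hemisphere(i: int, j: int, n_nodes: int = 90) -> str:
    """Classify a 1-based edge as intra-left, intra-right or inter-hemispheric.

    Uses the AAL convention: odd index = left hemisphere, even = right.
    """
    for idx in (i, j):
        if not 1 <= idx <= n_nodes:
            raise ValueError(f"node index {idx} outside 1..{n_nodes}")
    hi, hj = hemisphere_of(i), hemisphere_of(j)
    if hi == hj:
        return "intra-left" if hi == "L" else "intra-right"
    return "inter-hemispheric"


def build_cohort_pair(counts: np.ndarray, waytotals: np.ndarray,
                      subject_ids: list[str] | None = None,
                      weight_fraction: float = 0.01,
                      mask_density: float = 0.30,
                      mask_pooling: str = "per-timepoint") -> tuple[CohortPair, ConsistencyMask]:
    """Run the full construction chain on a raw cohort.

    Parameters
    ----------
    counts, waytotals : arrays shaped (n_subjects, 2, n, n) and (n_subjects, 2, n)
    mask_pooling : "per-timepoint" (default: one consistency mask per
        timepoint, the pair receives their intersection as the common support
        for paired tests) or "pooled" (one mask from all subject-timepoints).
        Pooling across timepoints inflates the cross-observation coefficient
        of variation of genuinely changing edges and therefore biases the
        mask against exactly the connections a longitudinal analysis is
        after; the per-timepoint intersection leaves within-timepoint
        consistency to decide membership.
    """
    if mask_pooling not in ("pooled", "per-timepoint"):
        raise ValueError("mask_pooling must be 'pooled' or 'per-timepoint'")
    s = counts.shape[0]
    thresholded = np.empty_like(counts, dtype=float)
    for sub in range(s):
        for t in range(2):
            sym = normalize_sc(counts[sub, t], waytotals[sub, t])
            thresholded[sub, t] = apply_weight_threshold(sym, weight_fraction)

    own1 = own2 = None
    if mask_pooling == "pooled":
        cmask = consistency_mask(thresholded.reshape(-1, *counts.shape[2:]), mask_density)
        common = cmask.mask
    else:
        m1 = consistency_mask(thresholded[:, 0], mask_density)
        m2 = consistency_mask(thresholded[:, 1], mask_density)
        cmask = m1
        common = m1.mask & m2.mask
        own1 = thresholded[:, 0] * m1.mask
        own2 = thresholded[:, 1] * m2.mask

    sc_t1 = thresholded[:, 0] * common
    sc_t2 = thresholded[:, 1] * common
    ids = subject_ids or [f"sub-{k + 1:03d}" for k in range(s)]
    pair = CohortPair(sc_t1=sc_t1, sc_t2=sc_t2, subject_ids=list(ids), mask=common,
                      sc_t1_own=own1, sc_t2_own=own2)
    return pair, cmask
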