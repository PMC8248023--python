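"""Intra- and inter-timepoint consistency of structural-connectivity signatures.

TC-I: each subject's upper-triangle SC vector is correlated (Pearson) with the
timepoint-mean SC vector; the per-subject r values are averaged on the
Fisher-Z scale and transformed back.  TC-II: the distribution of Pearson
correlations between all subject pairs, optionally pooling both timepoints as
if they were one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["fisher_z_mean", "tc_within", "tc_pairwise", "ConsistencyReport"]

_CLIP = 1 - 1e-12


def fisher_z_mean(rs, on_perfect: str = "clip") -> float:
    """Average correlations on the Fisher-Z (atanh) scale.

    Returns tanh(mean(atanh(r))).  |r| = 1 has infinite z; by default such
    values are clipped to 1 - 1e-12 with a warning (``on_perfect="raise"``
    rejects them instead).
    """
    rs = np.asarray(list(rs), dtype=float)
    if rs.size == 0:
        raise ValueError("cannot average an empty list of correlations")
    if np.any(np.abs(rs) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(rs) >= 1):
        if on_perfect == "raise":
            raise ValueError("|r| = 1 has infinite Fisher-Z")
        warnings.warn("perfect correlation clipped before Fisher-Z", stacklevel=2)
        rs = np.clip(rs, -_CLIP, _CLIP)
    return float(np.tanh(np.mean(np.arctanh(rs))))


def _upper_vectors(stack: np.ndarray) -> np.ndarray:
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack of >= 2 subject matrices")
    iu, ju = np.triu_indices(stack.shape[1], k=1)
    return stack[:, iu, ju]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance connectivity vector")
    return float(np.corrcoef(a, b)[0, 1])


def tc_within(stack: np.ndarray) -> tuple[float, np.ndarray]:
    """TC-I for one timepoint: pooled subject-vs-mean correlation.

    Returns (Fisher-Z pooled value, per-subject r vector).
    """
    vecs = _upper_vectors(stack)
    mean_vec = vecs.mean(axis=0)
    rs = np.array([_pearson(v, mean_vec) for v in vecs])
    return fisher_z_mean(rs), rs


def tc_pairwise(stack: np.ndarray, other: np.ndarray | None = None) -> np.ndarray:
    """TC-II: Pearson correlations between all pairs of subject vectors.

    With ``other`` given, the two stacks are pooled and treated as one
    timepoint (the inter-timepoint variant); otherwise all m(m-1)/2 pairs
    within ``stack`` are returned.
    """
    vecs = _upper_vectors(stack)
    if other is not None:
        vecs = np.vstack([vecs, _upper_vectors(other)])
    if np.any(vecs.std(axis=1) == 0):
        raise ValueError("zero-variance connectivity vector")
    corr = np.corrcoef(vecs)
    iu, ju = np.triu_indices(vecs.shape[0], k=1)
    return corr[iu, ju]


@dataclass
class ConsistencyReport:
    """Summary of TC-I/TC-II for a two-timepoint cohort."""

    tc1_t1: float
    tc1_t2: float
    tc2_t1: list[float]
    tc2_t2: list[float]
    tc2_pooled: list[float]
    n_pairs_within: int
    n_pairs_pooled: int

    @classmethod
    def from_cohort(cls, stack_t1: np.ndarray, stack_t2: np.ndarray) -> "ConsistencyReport":
        r1, _ = tc_within(stack_t1)
        r2, _ = tc_within(stack_t2)
        p1 = tc_pairwise(stack_t1)
        p2 = tc_pairwise(stack_t2)
        pooled = tc_pairwise(stack_t1, stack_t2)
        return cls(tc1_t1=r1, tc1_t2=r2,
                   tc2_t1=p1.tolist(), tc2_t2=p2.tolist(), tc2_pooled=pooled.tolist(),
                   n_pairs_within=p1.size, n_pairs_pooled=pooled.size)

    def histogram(self, which: str = "pooled", bins: int = 50,
                  lo: float = 0.5, hi: float = 1.0):
        data = {"t1": self.tc2_t1, "t2": self.tc2_t2, "pooled": self.tc2_pooled}[which]
        return np.histogram(data, bins=bins, range=(lo, hi))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
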