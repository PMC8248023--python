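"""Monte-Carlo validation of the paired NBS procedure.

Two simulations: the empirical family-wise error rate on null cohorts with no
planted effect (the permutation test's headline guarantee), and
power/recovery of a planted connected component.  Both run the *full*
pipeline on every simulated cohort — Poisson counts, waytotal and maximum
normalization, 1% weight threshold, 30% consistency mask, then NBS — so the
guarantee is checked for the procedure actually used, not an idealization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .build import build_cohort_pair
from .nbs import nbs_paired
from .synthetic import CohortConfig, generate_cohort

__all__ = ["default_primary_threshold", "empirical_fwer", "component_recovery"]


def default_primary_threshold(n_subjects: int, edge_p: float = 0.01) -> float:
    """Primary F threshold at a fixed edge-level tail probability.

    F = t^2 for a paired t with n-1 degrees of freedom is F(1, n-1); the
    threshold is its upper ``edge_p`` quantile.  An edge-level p of 0.01
    leaves enough supra-threshold edges under the null for components to
    form, so the component-level FWER bound is exercised non-trivially.
    """
    return float(sps.f.isf(edge_p, 1, n_subjects - 1))


def _base_config(n_subjects: int, seed: int, **overrides) -> CohortConfig:
    cfg = CohortConfig(n_subjects=n_subjects, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class FwerReport:
    rate: float
    n_datasets: int
    n_rejections: int
    alpha: float
    primary_threshold: float

    @property
    def monte_carlo_se(self) -> float:
        return float(np.sqrt(self.alpha * (1 - self.alpha) / self.n_datasets))


def empirical_fwer(n_datasets: int = 200, n_subjects: int = 30,
                   n_perm: int = 500, alpha: float = 0.05,
                   seed: int = 1, primary_threshold: float | None = None,
                   config: CohortConfig | None = None) -> FwerReport:
    """Fraction of null cohorts yielding any FWER-significant component.

    Each dataset is an independent null cohort (no planted effect) generated
    with seeds ``seed .. seed + n_datasets - 1``, pushed through the full
    construction chain and tested with sign-flip NBS.  With the +1-corrected
    permutation p-value the rate should not exceed ``alpha`` beyond
    Monte-Carlo error.
    """
    thr = primary_threshold if primary_threshold is not None \
        else default_primary_threshold(n_subjects)
    hits = 0
    for k in range(n_datasets):
        cfg = (replace(config, seed=seed + k) if config is not None
               else _base_config(n_subjects, seed + k))
        cohort = generate_cohort(cfg)
        pair, _ = build_cohort_pair(cohort.counts, cohort.waytotals)
        result = nbs_paired(pair, thr, n_perm=n_perm, alpha=alpha, seed=seed + k)
        if result.significant:
            hits += 1
    return FwerReport(rate=hits / n_datasets, n_datasets=n_datasets,
                      n_rejections=hits, alpha=alpha, primary_threshold=thr)


@dataclass
class RecoveryReport:
    recall: float           # planted edges recovered / planted, mean over replicates
    false_discovery: float  # spurious edges / detected edges, mean over replicates
    detection_rate: float   # replicates with a significant component
    n_replicates: int


def component_recovery(config: CohortConfig, n_replicates: int = 20,
                       n_perm: int = 500, alpha: float = 0.05,
                       seed: int = 1,
                       primary_threshold: float | None = None) -> RecoveryReport:
    """Recovery of a planted component over independent cohort replicates.

    For each replicate the largest significant component is compared with the
    planted edge set: recall is the fraction of planted edges it contains,
    false discovery the fraction of its edges that were not planted.

    When ``primary_threshold`` is None a strict edge-level cutoff is used
    (the upper 1e-4 quantile of F(1, n-1)): power analysis of a planted
    component asks which edges individually carry a strong effect, so the
    primary threshold is set where individually-null edges are vanishingly
    rare.
    """
    planted = {(min(i, j), max(i, j)) for i, j, _ in config.planted_edges()}
    if not planted:
        raise ValueError("config has no planted edges")
    thr = primary_threshold if primary_threshold is not None \
        else default_primary_threshold(config.n_subjects, edge_p=1e-4)
    recalls, fds, detected = [], [], 0
    for k in range(n_replicates):
        cohort = generate_cohort(replace(config, seed=seed + k))
        pair, _ = build_cohort_pair(cohort.counts, cohort.waytotals)
        result = nbs_paired(pair, thr, n_perm=n_perm, alpha=alpha, seed=seed + k)
        sig = result.significant
        if not sig:
            recalls.append(0.0)
            fds.append(0.0)
            continue
        detected += 1
        comp = max(sig, key=lambda c: c.size)
        found = {(min(i, j), max(i, j)) for i, j, _ in comp.edges}
        recalls.append(len(found & planted) / len(planted))
        fds.append(len(found - planted) / len(found))
    return RecoveryReport(recall=float(np.mean(recalls)),
                          false_discovery=float(np.mean(fds)),
                          detection_rate=detected / n_replicates,
                          n_replicates=n_replicates)
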