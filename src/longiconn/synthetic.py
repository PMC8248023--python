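"""Synthetic two-timepoint streamline-count cohorts with planted effects.

This module generates the raw material every downstream stage consumes:
per-subject, per-timepoint integer streamline-count matrices with the
statistical character of probabilistic-tractography output, plus waytotal
vectors, cognitive scores coupled to a designated sub-network, and
region-by-tract overlap fixtures for the tract-attribution stage.

Generative model
----------------
Nodes receive 3-D coordinates mirrored across the midline so that the
1-based odd/even = left/right convention holds and homotopic edges have
identical expected weight.  A fraction ``base_density`` of node pairs is
connected (sampled by mirror-orbit so the support is itself symmetric).
The expected streamline count of a present edge decays exponentially with
Euclidean inter-node distance.  On top of that expectation:

* a per-subject log-normal multiplier, shared across timepoints, creates the
  within-subject correlation paired tests and rmcorr rely on;
* per-subject x edge x timepoint log-normal noise with coefficient of
  variation ``noise_cv``;
* the two directions (i->j and j->i) are jittered independently by +/-5% so
  the symmetrization step downstream is non-trivial;
* planted edges have their timepoint-2 expectation multiplied by (1 + delta);
* observed counts are Poisson draws around the resulting mean, giving
  overdispersed integers.

Waytotals are row sums inflated by a per-region factor in [1, 2], so the
waytotal normalization downstream is not a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CohortConfig",
    "CognitionCoupling",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_cognition",
    "generate_tract_fixtures",
    "mirror_node",
]

_JHU_TRACTS = (
    "ATR_L", "ATR_R", "CGC_L", "CGC_R", "CST_L", "CST_R", "FMI", "FMA",
    "IFOF_L", "IFOF_R", "SLF_L", "SLF_R", "UF_L", "UF_R",
)


def mirror_node(i: int) -> int:
    """Homotopic partner of a 1-based node index (odd <-> even pair)."""
    return i + 1 if i % 2 == 1 else i - 1


@dataclass(frozen=True)
class CognitionCoupling:
    """Linear coupling between sub-network mean SC and a cognitive score.

    score = subject intercept + slope * (sub-network mean SC) + residual,
    with subject intercepts ~ N(0, subject_sd) and residuals
    ~ N(0, residual_sd), independent across observations.
    """

    slope: float = -1.0
    subject_sd: float = 1.0
    residual_sd: float = 0.1


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Planted edge lists use 1-based node indices; ``delta`` is the fractional
    change of the edge's expected count from timepoint 1 to timepoint 2
    (delta > -1).
    """

    n_subjects: int = 51
    n_nodes: int = 90
    base_density: float = 0.35
    weight_decay: float = 0.7
    noise_cv: float = 0.1
    subject_cv: float = 0.2
    base_count: float = 2000.0
    spurious_count: float = 3.0
    planted_noise_factor: float = 0.5
    asym_jitter: float = 0.05
    planted_increase_edges: tuple[tuple[int, int, float], ...] = ()
    planted_decrease_edges: tuple[tuple[int, int, float], ...] = ()
    cognition: CognitionCoupling = field(default_factory=CognitionCoupling)
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.base_density <= 1:
            raise ValueError("base_density must be in (0, 1]")
        if self.n_subjects < 1 or self.n_nodes < 2 or self.n_nodes % 2:
            raise ValueError("need >= 1 subject and an even number >= 2 of nodes")
        seen: set[tuple[int, int]] = set()
        for i, j, delta in self.planted_edges():
            if not (1 <= i <= self.n_nodes and 1 <= j <= self.n_nodes) or i == j:
                raise ValueError(f"planted edge ({i}, {j}) outside node range")
            if delta <= -1:
                raise ValueError(f"planted delta must be > -1, got {delta}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"planted edge lists overlap at {key}")
            seen.add(key)

    def planted_edges(self) -> tuple[tuple[int, int, float], ...]:
        return tuple(self.planted_increase_edges) + tuple(self.planted_decrease_edges)


@dataclass
class GroundTruth:
    """What was planted: reproducible from (CohortConfig, seed)."""

    increase_edges: tuple[tuple[int, int, float], ...]
    decrease_edges: tuple[tuple[int, int, float], ...]
    cognition_slope: float
    subject_intercepts: np.ndarray          # (n_subjects,)
    expected_counts_t1: np.ndarray          # (n, n) expectation at timepoint 1
    delta_matrix: np.ndarray                # (n, n) fractional change, 0 off-plant
    coordinates: np.ndarray                 # (n, 3) mirrored node coordinates

    @property
    def planted_edges(self) -> tuple[tuple[int, int, float], ...]:
        return self.increase_edges + self.decrease_edges


@dataclass
class SyntheticCohort:
    """A generated two-timepoint cohort of raw streamline counts."""

    config: CohortConfig
    counts: np.ndarray      # (n_subjects, 2, n, n) non-negative integers
    waytotals: np.ndarray   # (n_subjects, 2, n) strictly positive
    truth: GroundTruth

    @property
    def subject_ids(self) -> list[str]:
        return [f"sub-{s + 1:03d}" for s in range(self.config.n_subjects)]


def _mirrored_coordinates(n_nodes: int, rng: np.random.Generator) -> np.ndarray:
    """Coordinates in a unit box, pairs (2k+1, 2k+2) mirrored across x = 0."""
    half = n_nodes // 2
    x = rng.uniform(0.05, 0.5, size=half)
    yz = rng.uniform(0.0, 1.0, size=(half, 2))
    coords = np.empty((n_nodes, 3))
    coords[0::2, 0] = -x     # odd 1-based index -> left, negative x
    coords[1::2, 0] = x
    coords[0::2, 1:] = yz
    coords[1::2, 1:] = yz
    return coords


def _mirrored_support(n_nodes: int, density: float, rng: np.random.Generator,
                      forced: list[tuple[int, int]]) -> np.ndarray:
    """Boolean upper support sampled by mirror-orbit to the target density.

    ``forced`` pairs (0-based, i < j) are always present (planted edges must
    exist in the support).
    """
    def mirror0(i: int) -> int:
        return i + 1 if i % 2 == 0 else i - 1

    iu, ju = np.triu_indices(n_nodes, k=1)
    orbit_of: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for i, j in zip(iu.tolist(), ju.tolist()):
        mi, mj = sorted((mirror0(i), mirror0(j)))
        rep = min((i, j), (mi, mj))
        orbit_of.setdefault(rep, []).append((i, j))

    support = np.zeros((n_nodes, n_nodes), dtype=bool)
    target = int(round(density * len(iu)))
    count = 0
    for i, j in forced:
        mi, mj = sorted((mirror0(i), mirror0(j)))
        rep = min((i, j), (mi, mj))
        for a, b in orbit_of.pop(rep, []):
            if not support[a, b]:
                support[a, b] = True
                count += 1
    reps = list(orbit_of)
    rng.shuffle(reps)
    for rep in reps:
        if count >= target:
            break
        for a, b in orbit_of[rep]:
            support[a, b] = True
            count += 1
    return support | support.T


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate raw counts, waytotals and ground truth for a cohort.

    Deterministic given ``config`` (including its seed).  The timepoint-2
    expectation of a planted edge equals the timepoint-1 expectation times
    (1 + delta); all other edges are stationary in expectation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, s = config.n_nodes, config.n_subjects

    coords = _mirrored_coordinates(n, rng)
    forced = [(min(i, j) - 1, max(i, j) - 1) for i, j, _ in config.planted_edges()]
    support = _mirrored_support(n, config.base_density, rng, forced)

    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    lam0 = config.base_count * np.exp(-dist / config.weight_decay)
    # absent node pairs still receive a trickle of spurious streamlines, the
    # false positives the 1% weight and consistency thresholds exist to remove
    lam0 = np.where(support, lam0, config.spurious_count)
    np.fill_diagonal(lam0, 0.0)

    delta = np.zeros((n, n))
    for i, j, d in config.planted_edges():
        delta[i - 1, j - 1] = delta[j - 1, i - 1] = d

    # log-normal multipliers with unit mean
    def lognormal_unit(sigma: float, size) -> np.ndarray:
        if sigma <= 0:
            return np.ones(size)
        return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)

    sig_subj = np.sqrt(np.log1p(config.subject_cv ** 2))
    sig_edge = np.sqrt(np.log1p(config.noise_cv ** 2))
    subj_mult = lognormal_unit(sig_subj, s)

    counts = np.zeros((s, 2, n, n), dtype=np.int64)
    iu, ju = np.triu_indices(n, k=1)
    # planted edges emulate robust, reliably reconstructed pathways: their
    # edge-level tractography noise is scaled by planted_noise_factor
    sig_planted = sig_edge * config.planted_noise_factor
    planted_idx = [(min(i, j) - 1, max(i, j) - 1) for i, j, _ in config.planted_edges()]
    for sub in range(s):
        for t in range(2):
            edge_noise = np.ones((n, n))
            noise_u = lognormal_unit(sig_edge, iu.size)
            edge_noise[iu, ju] = noise_u
            edge_noise[ju, iu] = noise_u            # shared by both directions
            if planted_idx:
                pn = lognormal_unit(sig_planted, len(planted_idx))
                for (a, b), v in zip(planted_idx, np.atleast_1d(pn)):
                    edge_noise[a, b] = edge_noise[b, a] = v
            lam = lam0 * subj_mult[sub] * edge_noise
            if t == 1:
                lam = lam * (1.0 + delta)
            jitter = rng.uniform(1 - config.asym_jitter, 1 + config.asym_jitter,
                                 size=(n, n))      # independent per direction
            lam = lam * jitter
            c = rng.poisson(lam)
            np.fill_diagonal(c, 0)
            counts[sub, t] = c

    row_sums = counts.sum(axis=-1)
    # the inflation factor reflects streamlines rejected by masks; it is a
    # property of the seed region, stable within subject across timepoints
    factors = rng.uniform(1.0, 2.0, size=(s, 1, n))
    waytotals = np.maximum(row_sums, 1) * factors

    truth = GroundTruth(
        increase_edges=tuple(config.planted_increase_edges),
        decrease_edges=tuple(config.planted_decrease_edges),
        cognition_slope=config.cognition.slope,
        subject_intercepts=rng.normal(0.0, config.cognition.subject_sd, size=s),
        expected_counts_t1=lam0,
        delta_matrix=delta,
        coordinates=coords,
    )
    return SyntheticCohort(config=config, counts=counts, waytotals=waytotals, truth=truth)


def subnetwork_mean(weights: np.ndarray, edges) -> float:
    """Mean weight over a 1-based edge list of a single symmetric matrix."""
    edges = list(edges)
    if not edges:
        raise ValueError("designated edge set is empty")
    return float(np.mean([weights[e[0] - 1, e[1] - 1] for e in edges]))


def generate_cognition(subnet_means: np.ndarray, config: CohortConfig,
                       truth: GroundTruth) -> np.ndarray:
    """Two-timepoint cognitive scores linearly coupled to sub-network SC.

    Parameters
    ----------
    subnet_means : (n_subjects, 2) array
        Per-subject, per-timepoint mean connectivity of the designated edge
        set (normally computed on the analysis-ready matrices).

    Returns
    -------
    (n_subjects, 2) array of scores:
    intercept_subject + slope * mean + N(0, residual_sd).
    """
    subnet_means = np.asarray(subnet_means, dtype=float)
    if subnet_means.ndim != 2 or subnet_means.shape[1] != 2:
        raise ValueError("subnet_means must have shape (n_subjects, 2)")
    coup = config.cognition
    if not np.isfinite(coup.slope):
        raise ValueError("coupling slope must be finite")
    rng = np.random.default_rng((config.seed, 0x5C0E))
    resid = (rng.normal(0.0, coup.residual_sd, size=subnet_means.shape)
             if coup.residual_sd > 0 else np.zeros_like(subnet_means))
    return truth.subject_intercepts[:, None] + coup.slope * subnet_means + resid


def generate_tract_fixtures(config: CohortConfig, n_tracts: int, seed: int):
    """Region x tract overlap matrices at both timepoints plus the true map.

    Each planted edge is assigned one true tract; the overlap entries of both
    endpoint regions in that tract's column change between timepoints by the
    edge's fractional delta, so the change has the planted sign at both
    endpoints.  Distractor entries are identical at both timepoints (exactly
    zero change), which guarantees unique recovery by sign-matching
    attribution.

    Returns
    -------
    (overlap_t1, overlap_t2, edge_to_tract)
        Two (n_nodes, n_tracts) arrays of non-negative mean streamline
        intensities and a dict mapping (i, j) 1-based sorted edge tuples to
        the true tract column name.
    """
    if n_tracts < 1:
        raise ValueError("need at least one tract")
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_nodes
    names = [(_JHU_TRACTS[k] if k < len(_JHU_TRACTS) else f"TRACT_{k + 1}")
             for k in range(n_tracts)]

    background = rng.uniform(5.0, 50.0, size=(n, n_tracts))
    t1 = background.copy()
    t2 = background.copy()

    edge_to_tract: dict[tuple[int, int], str] = {}
    for k, (i, j, delta) in enumerate(config.planted_edges()):
        col = k % n_tracts
        base = 100.0 + 10.0 * k
        for node in (i, j):
            t1[node - 1, col] = base
            t2[node - 1, col] = base * (1.0 + delta)
        edge_to_tract[(min(i, j), max(i, j))] = names[col]
    return t1, t2, {"tract_names": names, "edge_to_tract": edge_to_tract}
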