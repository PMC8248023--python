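# Methods

This note records the models, conventions and numerical choices behind
`longiconn`, in the order the pipeline applies them, together with the
reasoning for the choices that were genuinely open.

## Network construction

A subject/timepoint connectome starts as a raw streamline-count matrix C
(seed region × target region) and a waytotal vector w (total streamlines
generated from each seed that were not rejected by masking). The chain is
fixed:

1. **Waytotal normalization** — row i of C is divided by w_i, making each
   entry the probability that a streamline from seed i reaches region j.
2. **Individual-maximum scaling** — division by the subject's largest entry
   maps the matrix into [0, 1]. Normalization is therefore scale-invariant:
   multiplying all counts and waytotals by a constant changes nothing.
3. **Symmetrization** — tractography is seed-dependent, so P_ij ≠ P_ji; the
   undirected weight is their average.
4. **Absolute threshold** — entries below 1% of the subject's strongest
   connection are zeroed. This removes the trickle of spurious streamlines
   that probabilistic tractography produces between unconnected regions.
   The 1% reference maximum is taken after symmetrization (the order is a
   convention; the two choices differ only through the averaging of nearly
   equal directed maxima).
5. **Consistency mask** — per edge, consistency = mean/SD of the weight
   across subjects (inverse coefficient of variation; absent edges count as
   zero-weight observations, which penalizes inconsistent presence). Edges
   are ranked most-consistent first, ties broken by higher mean weight and
   then lexicographic edge order so the mask is deterministic, and the top
   round(0.30 · N(N−1)/2) edges are kept. Diagnostics report, per subject,
   how many and how strong the removed connections were, and what fraction
   of mask edges the subject lacks.

**Mask pooling.** Whether the consistency mask should be computed from all
subject-timepoints at once or per timepoint is an open design point; both
modes exist. The default is *per-timepoint*, with the paired analysis
receiving the intersection of the two masks as its common edge support. The
reason is statistical, not cosmetic: consistency is an inverse CV, and for
an edge whose weight genuinely changes by a fraction δ between timepoints,
pooling both timepoints inflates the cross-observation CV by ≈ |δ|/2 in
quadrature. A pooled mask therefore systematically ranks *changing* edges
as inconsistent and removes exactly the connections a longitudinal analysis
is looking for. With per-timepoint masks, membership is decided by
within-timepoint reproducibility only, and the intersection still
guarantees a common support for paired tests. Topology stages (group-mean
hubs, modularity, fingerprints) use each timepoint's own mask so the two
timepoints keep their own edge support — under the intersection the binary
degree structure of the two timepoints would be identical by construction
and fingerprint comparisons degenerate.

**Hemisphere convention.** 1-based odd atlas indices are left-hemisphere,
even are right; an edge is intra-left, intra-right, or inter-hemispheric
accordingly. This matches the AAL-90 ordering in which homotopic pairs are
interleaved.

## Timepoint consistency

TC-I correlates each subject's upper-triangle weight vector (post-mask,
i.e. the matrices the analysis actually uses) with the timepoint mean
vector and pools the r values via Fisher-Z: tanh(mean(atanh r)). Perfect
correlations (identical-subject fixtures) are clipped to 1 − 1e−12 with a
warning rather than crashing on an infinite z. TC-II is the distribution
of all m(m−1)/2 pairwise subject correlations; the inter-timepoint variant
pools both timepoints into one set of subjects.

## Paired NBS

Edge-wise statistic: for within-subject differences d_s on an edge,
t = mean(d)/(SD(d)/√n) and F = t². Zero-variance edges give F = 0 when the
mean is also zero and a capped sentinel (10¹²) with a warning otherwise —
a finite stand-in for an infinite t that keeps the component machinery
total. Components are connected subgraphs (union-find) of edges with
F above the primary threshold, sized by edge count (extent).

The permutation null flips the sign of each subject's whole difference
matrix independently (2ⁿ patterns), which is exact under exchangeability of
the two timepoints within subject. Monte-Carlo p-values carry the +1
correction, p = (1 + #{null max ≥ size})/(1 + n_perm), so p > 0 always and
the test errs conservative. The implementation exploits that Σd² per edge
is sign-invariant, so each permutation costs one matrix-vector product.

**Primary thresholds.** The threshold trades sensitivity profile for
nothing else — FWER control holds at any value. Defaults by purpose:

* *General runs*: the upper 1% quantile of F(1, n−1), i.e. an edge-level
  p = 0.01 cutoff. Under the null this leaves enough supra-threshold edges
  for components to form, so the permutation machinery is exercised rather
  than trivially silent.
* *FWER validation*: same threshold, for the same reason — a bound that is
  never tested is not evidence.
* *Power/recovery analysis of a planted component*: the upper 1e−4 quantile
  (F ≈ 19 at n = 40). Recovery asks which edges individually carry a strong
  effect, so the threshold sits where individually-null edges are
  vanishingly rare; this keeps spurious admixture in the detected component
  near zero without touching the planted edges, whose F values are an order
  of magnitude higher under the study conditions.
* The sweep utility reproduces the published-style selection rule (maximal
  F with a unique component of more than two edges). It is available and
  tested, but not used for recovery scoring: pushed to its maximum the rule
  prunes a detected component to its strongest core, which under-reports
  recall of the full planted edge set.

Component summaries stratify per-subject mean connectivity by sign of
change × hemisphere class (12 series) and report group percent change
100·(m₂ − m₁)/m₁; empty strata are flagged, not zero-filled.

## Graph metrics

Degree, density, clustering and rewiring operate on the binary support;
path-based quantities use weighted shortest paths with cost 1/w (Dijkstra).
Efficiencies use 1/∞ = 0 for disconnected pairs; the characteristic path
length of a disconnected graph is computed on the largest component and
flagged. The randomized ensemble applies 10·E attempted double-edge swaps
per network — a standard mixing heuristic — with weights carried along with
the swapped edges, preserving both the degree sequence and the weight
multiset. σ = (Cl/Cl_rand)/(L/L_rand) with ensemble-mean normalizers;
σ > 1 indicates small-world organization, and on Erdős–Rényi inputs (their
own null) σ ≈ 1.

Brute-force oracles (explicit Floyd–Warshall, exhaustive triangle
enumeration) live in the test suite and pin every metric to 1e−10 on random
small graphs.

## Community structure, hubs, fingerprints

Louvain is stochastic and degenerate; the consensus partition is the modal
canonicalized partition over many runs (10,000 by default in full runs),
ties broken by higher Q then lexicographically. Q is the standard weighted
Newman modularity. Partition similarity takes, for each module of the first
partition, the best Jaccard overlap (shared regions over the union) with
any module of the second, and averages; the union reading — rather than the
sum of the two module sizes — is required for identical partitions to score
1. A symmetrized variant averages both directions.

Global hubs: nodal efficiency normalized by its mean; hub iff the
normalized value strictly exceeds 1 + SD (sample SD). Node roles: binary
within-module degree standardized within each module (z = 0 for singleton
or degenerate modules), participation coefficient on binary degrees; a node
with z above the all-node mean + SD is a provincial hub when PC ≤ 0.3 and a
connector hub when PC > 0.3. Pooling z across modules for the cutoff, and
binary rather than strength-weighted PC, are the two ambiguous points; both
choices keep the role table invariant to module relabeling and to global
weight rescaling.

Fingerprints count binary edges between module pairs (inter), within
modules (intra; the degree-sum convention is exactly twice these counts),
and from connector hubs of a module toward other modules (hub-driven,
off-diagonal). A reference partition — the candidate with the highest mean
Q across all subject matrices — fixes the module frame across timepoints.
RSN overlap percentages normalize each column (RSN) by the total
intersected volume so columns sum to 100 when every region is assigned.

## Tract attribution

Region×tract overlap matrices (mean streamline intensity of each region's
density map over each tract mask, after a 1% per-map threshold) are
thresholded at 5% of their global maximum; the proportion-of-change matrix
(M₂ − M₁)/M₁ masks baseline-zero entries as undefined. For a component edge
with sign s, candidate tracts are those whose change has sign s in *both*
endpoint rows; among candidates the one with the highest mean intensity
over {t1, t2} × {both endpoints} is selected (averaging endpoints rather
than maximizing is an interpretation, chosen for symmetry and determinism;
all sign-matching candidates are reported ranked). An edge with no
sign-matching tract falls back to the highest-mean-intensity tract and is
flagged. Attribution is invariant to rescaling both overlap matrices by a
common constant, and the 5% threshold can only remove candidates, never
create them.

## Longitudinal statistics

Paired t-tests are two-sided with Cohen's d = mean(diff)/SD(diff) and
BH-FDR across metrics. The repeated-measures correlation centers both
variables within subject; r_rm is the Pearson correlation of the centered
variables — algebraically identical to the subject-intercept ANCOVA form
sign(slope)·√(SS_measure/(SS_measure + SS_error)) — with
df = n_obs − n_subjects − 1 (= N(k−1)−1 for balanced designs). Subjects
with a single observation carry no within-subject information and are
dropped with a warning. Bootstrap intervals are percentile (not BCa — the
simplest interval consistent with "10,000 draws"), resampling whole
subjects so both timepoints travel together.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the statistical character of tractography-derived
connectomes, not their anatomy:

* **Geometry** — nodes get random coordinates in a unit box with exact
  mirror symmetry across the midline, so homotopic edges have identical
  expected weight and the odd/even hemisphere convention holds.
* **Expected counts** — present edges (a mirror-symmetric random support at
  `base_density` = 0.35 of all pairs) decay exponentially with distance
  (length constant 0.7 box units from a base of 2,000 expected streamlines).
  The dynamic range is chosen so genuine connections sit well above the 1%
  absolute threshold; *spurious* connections are modeled explicitly as a
  ~3-streamline Poisson trickle on absent pairs, giving the 1% threshold
  and the consistency mask their real jobs.
* **Noise** — a per-subject log-normal multiplier (CV 0.2) shared across
  timepoints creates within-subject correlation; per-edge log-normal noise
  (CV 0.1) per timepoint; independent ±5% directed jitter exercises
  symmetrization; Poisson counting noise on top. Waytotals are row sums
  inflated by a per-region factor in [1, 2], stable within subject across
  timepoints (it models seed-dependent mask rejection, a property of the
  region).
* **Planted effects** — listed edges have their timepoint-2 expectation
  multiplied by (1 + δ). Planted edges carry half the edge-level noise CV
  of background edges: they stand for the robust, reliably reconstructed
  pathways on which longitudinal effects are reported, and the recovery
  analysis asks whether the pipeline finds a real signal, not whether
  marginal edges survive a 30%-density lottery.
* **Cognition** — score = subject intercept + slope × sub-network mean SC +
  Gaussian residual; defaults slope −1, intercept SD 1, residual SD 0.1.
* **Tract fixtures** — each planted edge is assigned one true tract whose
  overlap entries at both endpoints change by exactly (1 + δ); distractor
  entries are identical at both timepoints, so exact recovery is the
  correct answer, not luck.

Default cohort size is 51 subjects (a realistic longitudinal aging cohort);
the bundled demo plants a connected 16-edge component (9 decreases:
3 intra-left / 5 intra-right / 1 inter-hemispheric; 7 increases:
2 intra-left / 5 inter-hemispheric) at δ = ±0.4 in 40 subjects.

What passing tests on this generator shows: the statistics are correctly
implemented, FWER is controlled under the null for the *full* pipeline
(normalization and masking included), planted effects of realistic
magnitude are recovered with few false edges, and every stage is
deterministic under its seed. What it does not show: robustness to motion
artifacts, registration error, scanner drift, anatomically realistic
geometry or distance-dependent false-positive structure — none of which
are modeled.

## Problem sizes and numerical conventions

Simulation-based checks run at deliberately desk-scale sizes chosen as
adequate for their Monte-Carlo error, and these sizes are part of the
study conditions: 200 null cohorts × 500 permutations for the FWER
estimate (binomial SE ≈ 0.015 at 0.05), 20 replicates for recovery,
100-network ensembles for σ. SDs in hub rules use the sample convention
(ddof = 1). All random stages accept explicit seeds; the pipeline derives
per-stage seeds from a single global seed via CRC-tagged generators, so a
re-run with the same config reproduces every output. Known limitations:
the double-edge-swap rewiring is a heuristic sampler of the fixed-degree
ensemble, not an exact uniform sampler; Louvain consensus is the modal
partition, which for highly degenerate modularity landscapes can itself be
unstable at small run counts; and the FWER simulation's +1-corrected
p-values make the test slightly conservative at 500 permutations.
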