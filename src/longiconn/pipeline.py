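"""End-to-end orchestration: manifest + config in, staged results out.

Stages run in the order of the analysis: construction (normalize, threshold,
consistency mask), timepoint consistency, paired NBS, graph metrics with
paired tests, community structure and fingerprints, optional tract
attribution, and the brain-cognition repeated-measures correlation.  A
single global seed deterministically spawns per-stage seeds so a re-run with
the same config reproduces every output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import DEMO_COMPONENT
from .build import build_cohort_pair, threshold_diagnostics
from .community import (classify_global_hubs, louvain_consensus,
                        modular_fingerprints, node_roles, partition_similarity,
                        select_reference_partition)
from .consistency import ConsistencyReport
from .io import read_cohort, write_cohort, write_matrix
from .metrics import compute_metric_set, efficiencies, shortest_path_lengths
from .nbs import component_summaries, nbs_paired, threshold_sweep, select_primary_threshold
from .stats import bootstrap_ci, fdr_bh, paired_t_with_d, rmcorr
from .synthetic import (CohortConfig, CognitionCoupling, generate_cognition,
                        generate_cohort, generate_tract_fixtures, subnetwork_mean)
from .tracts import TractOverlap, attribute_tracts, proportion_change, threshold_overlap
from .validation import default_primary_threshold

__all__ = ["RunConfig", "run_pipeline", "make_demo"]

log = logging.getLogger("longiconn")


@dataclass
class RunConfig:
    """Everything a full run needs; defaults follow the standard recipe."""

    manifest: str
    out_dir: str = "results"
    weight_fraction: float = 0.01
    mask_density: float = 0.30
    mask_pooling: str = "per-timepoint"
    primary_threshold: float | None = None      # None -> edge-p-based default
    sweep_thresholds: list[float] = field(default_factory=list)
    n_perm: int = 5000
    alpha: float = 0.05
    louvain_runs: int = 10_000
    n_random_networks: int = 100
    bootstrap_draws: int = 10_000
    seed: int = 0
    cognition_file: str | None = None           # TSV: subject, score_t1, score_t2
    tract_overlap_t1: str | None = None         # region x tract TSVs for attribution
    tract_overlap_t2: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_perm", "louvain_runs", "n_random_networks", "bootstrap_draws"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("weight_fraction", "mask_density"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        tag = zlib.crc32(stage.encode())
        return int(np.random.default_rng((self.seed, tag)).integers(2 ** 31))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    counts, ways, ids, labels, manifest = read_cohort(config.manifest)
    if manifest.get("excluded"):
        log.warning("excluded subjects missing a timepoint: %s", manifest["excluded"])
    log.info("loaded %d paired subjects, %d nodes", len(ids), counts.shape[-1])

    # --- construction -----------------------------------------------------
    pair, cmask = build_cohort_pair(counts, ways, ids,
                                    weight_fraction=config.weight_fraction,
                                    mask_density=config.mask_density,
                                    mask_pooling=config.mask_pooling)
    pair.labels = labels
    write_matrix(out / "consistency_mask.tsv", cmask.mask.astype(int), labels["name"])
    diag = threshold_diagnostics(np.concatenate([pair.sc_t1, pair.sc_t2]), cmask)
    _write_tsv(diag.drop(columns=[c for c in diag.columns if c.endswith("hist")]),
               out / "threshold_diagnostics.tsv")
    log.info("mask: %d edges (density %.3f)", cmask.n_edges, cmask.achieved_density)

    # --- timepoint consistency -------------------------------------------
    report = ConsistencyReport.from_cohort(pair.sc_t1, pair.sc_t2)
    report.to_json(out / "timepoint_consistency.json")
    log.info("TC-I: t1 %.4f, t2 %.4f", report.tc1_t1, report.tc1_t2)

    # --- NBS --------------------------------------------------------------
    if config.sweep_thresholds:
        sweep = threshold_sweep(pair, sorted(config.sweep_thresholds))
        _write_tsv(sweep, out / "threshold_sweep.tsv")
        thr = select_primary_threshold(sweep)
        if thr is None:
            thr = config.primary_threshold or default_primary_threshold(pair.n_subjects)
    else:
        thr = config.primary_threshold or default_primary_threshold(pair.n_subjects)
    result = nbs_paired(pair, thr, n_perm=config.n_perm, alpha=config.alpha,
                        seed=config.stage_seed("nbs"))
    comp_rows = []
    for rank, comp in enumerate(result.components):
        table = comp.edge_table(labels)
        table.insert(0, "component", rank + 1)
        table["p_fwer"] = comp.p_fwer
        comp_rows.append(table)
    if comp_rows:
        _write_tsv(pd.concat(comp_rows, ignore_index=True), out / "nbs_components.tsv")
    significant = result.significant
    log.info("NBS at F=%.2f: %d components, %d significant",
             thr, len(result.components), len(significant))

    subnet_means = None
    if significant:
        comp = max(significant, key=lambda c: c.size)
        per_subject, changes = component_summaries(pair, comp)
        _write_tsv(per_subject, out / "component_mean_sc.tsv")
        _write_tsv(changes, out / "component_percent_change.tsv")
        edges = [(i, j) for i, j, _ in comp.edges]
        subnet_means = np.array([
            [subnetwork_mean(pair.sc_t1[s], edges), subnetwork_mean(pair.sc_t2[s], edges)]
            for s in range(pair.n_subjects)])

    # --- graph metrics + paired tests ------------------------------------
    seed_m = config.stage_seed("metrics")
    rows = []
    for t, stack in ((1, pair.sc_t1), (2, pair.sc_t2)):
        for s, sid in enumerate(pair.subject_ids):
            ms = compute_metric_set(stack[s], n_rand=config.n_random_networks,
                                    seed=seed_m + s)
            row = {"subject": sid, "timepoint": t}
            row.update(ms.as_row())
            rows.append(row)
    metric_table = pd.DataFrame(rows)
    _write_tsv(metric_table, out / "graph_metrics.tsv")

    tests = []
    metrics = [c for c in metric_table.columns if c not in ("subject", "timepoint")]
    wide = metric_table.pivot(index="subject", columns="timepoint")
    for m in metrics:
        res = paired_t_with_d(wide[(m, 1)], wide[(m, 2)])
        tests.append({"metric": m, "t": res.t, "df": res.df, "p": res.p, "d": res.d})
    tests_df = pd.DataFrame(tests)
    tests_df["q"] = fdr_bh(tests_df["p"])
    _write_tsv(tests_df, out / "graph_metric_tests.tsv")

    # --- community structure ----------------------------------------------
    seed_c = config.stage_seed("community")
    own1, own2 = pair.own_mask_stacks()
    group = {1: own1.mean(axis=0), 2: own2.mean(axis=0)}
    partitions = {}
    for t, mat in group.items():
        part = louvain_consensus(mat, n_runs=config.louvain_runs, seed=seed_c + t)
        partitions[t] = part
        pd.DataFrame({"node": labels["index"], "module": part.assignment}) \
            .to_csv(out / f"partition_t{t}.tsv", sep="\t", index=False)
        e_nodal = efficiencies(shortest_path_lengths(mat))[1]
        hubs = classify_global_hubs(e_nodal)
        hubs["name"] = labels.set_index("index")["name"].reindex(hubs["node"]).values
        _write_tsv(hubs, out / f"global_hubs_t{t}.tsv")
        roles = node_roles(mat, part)
        roles["name"] = labels["name"]
        _write_tsv(roles, out / f"node_roles_t{t}.tsv")
    sim = partition_similarity(partitions[1], partitions[2])
    reference = select_reference_partition(
        list(pair.sc_t1) + list(pair.sc_t2), [partitions[1], partitions[2]])
    finger = {}
    for t, mat in group.items():
        roles = node_roles(mat, reference)
        hubs = roles.loc[roles.role == "connector hub", "node"].tolist()
        fp = modular_fingerprints(mat, reference, hubs)
        finger[t] = fp
        write_matrix(out / f"fingerprint_inter_t{t}.tsv", fp.inter)
        write_matrix(out / f"fingerprint_hub_t{t}.tsv", fp.hub_driven)
        np.savetxt(out / f"fingerprint_intra_t{t}.tsv", fp.intra, fmt="%d")
    hub1 = finger[1].overall_hub_connectivity
    hub_change = (100.0 * (finger[2].overall_hub_connectivity - hub1) / hub1
                  if hub1 else float("nan"))
    log.info("partition similarity %.3f; hub-driven connectivity change %.1f%%",
             sim, hub_change)

    # --- tract attribution ------------------------------------------------
    if config.tract_overlap_t1 and config.tract_overlap_t2 and significant:
        comp = max(significant, key=lambda c: c.size)
        t1 = _load_overlap(config.tract_overlap_t1, 1)
        t2 = _load_overlap(config.tract_overlap_t2, 2)
        t1s, t2s = threshold_overlap(t1), threshold_overlap(t2)
        assignment = attribute_tracts(comp.edges, proportion_change(t1s, t2s), t1s, t2s)
        assignment["candidates"] = assignment["candidates"].map(";".join)
        _write_tsv(assignment.drop(columns="candidate_mean_intensity"),
                   out / "tract_assignment.tsv")
        log.info("tract attribution: %d edges, %d fallback(s)", len(assignment),
                 int((assignment.rule != "common-sign").sum()))

    # --- brain-cognition --------------------------------------------------
    cognition_results = None
    if config.cognition_file and subnet_means is not None:
        cog = pd.read_csv(config.cognition_file, sep="\t")
        scores = cog[["score_t1", "score_t2"]].to_numpy()
        ids_long = np.repeat(np.arange(pair.n_subjects), 2)
        x = subnet_means.ravel()
        y = scores.ravel()
        res = rmcorr(ids_long, x, y)
        records = list(zip(subnet_means, scores))

        def stat(recs):
            sm = np.array([r[0] for r in recs])
            sc = np.array([r[1] for r in recs])
            n = len(recs)
            return rmcorr(np.repeat(np.arange(n), 2), sm.ravel(), sc.ravel()).r

        lo, hi = bootstrap_ci(records, stat, n_draws=config.bootstrap_draws,
                              alpha=config.alpha, seed=config.stage_seed("bootstrap"))
        cognition_results = {"r_rm": res.r, "df": res.df, "p": res.p,
                             "q": float(fdr_bh([res.p])[0]),
                             "ci": [lo, hi]}
        with open(out / "cognition_rmcorr.json", "w") as fh:
            json.dump(cognition_results, fh, indent=2)
        log.info("rmcorr r=%.3f (df=%d, p=%.3g, CI [%.3f, %.3f])",
                 res.r, res.df, res.p, lo, hi)

    # --- provenance -------------------------------------------------------
    provenance = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "n_subjects": pair.n_subjects,
        "n_nodes": pair.n_nodes,
        "mask_edges": cmask.n_edges,
        "primary_threshold": thr,
        "n_significant_components": len(significant),
        "partition_similarity": sim,
        "hub_driven_change_percent": hub_change,
        "wall_time_s": time.time() - t0,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    log.info("pipeline finished in %.1f s", provenance["wall_time_s"])
    return out


def demo_config(seed: int = 0, n_subjects: int = 40, delta: float = 0.4) -> CohortConfig:
    """Cohort config planting the 16-edge demo component at +/- delta."""
    inc = tuple((i, j, delta) for i, j, d in DEMO_COMPONENT if d > 0)
    dec = tuple((i, j, -delta) for i, j, d in DEMO_COMPONENT if d < 0)
    return CohortConfig(n_subjects=n_subjects, seed=seed,
                        planted_increase_edges=inc, planted_decrease_edges=dec,
                        cognition=CognitionCoupling(slope=-1.0, subject_sd=1.0,
                                                    residual_sd=0.1))


def make_demo(seed: int, out_dir, n_subjects: int = 40,
              delta: float = 0.4, n_tracts: int = 16,
              fast: bool = False) -> tuple[Path, RunConfig]:
    """Write a bundled synthetic demo cohort and a matching run config.

    The planted sub-network is a connected 16-edge fronto-subcortical
    component (9 decreases: 3 intra-left / 5 intra-right / 1 inter;
    7 increases: 2 intra-left / 5 inter-hemispheric).  ``fast=True`` scales
    the stochastic stage sizes down for quick smoke runs.
    """
    out = Path(out_dir)
    cfg = demo_config(seed, n_subjects, delta)
    cohort = generate_cohort(cfg)
    manifest_path = write_cohort(out / "cohort", cohort)

    pair, _ = build_cohort_pair(cohort.counts, cohort.waytotals)
    edges = [(i, j) for i, j, _ in cfg.planted_edges()]
    means = np.array([[subnetwork_mean(pair.sc_t1[s], edges),
                       subnetwork_mean(pair.sc_t2[s], edges)]
                      for s in range(cfg.n_subjects)])
    scores = generate_cognition(means, cfg, cohort.truth)
    cog_path = out / "cognition.tsv"
    pd.DataFrame({"subject": cohort.subject_ids,
                  "score_t1": scores[:, 0], "score_t2": scores[:, 1]}) \
        .to_csv(cog_path, sep="\t", index=False)

    t1, t2, tract_truth = generate_tract_fixtures(cfg, n_tracts, seed)
    names = tract_truth["tract_names"]
    pd.DataFrame(t1, columns=names).to_csv(out / "tract_overlap_t1.tsv", sep="\t", index=False)
    pd.DataFrame(t2, columns=names).to_csv(out / "tract_overlap_t2.tsv", sep="\t", index=False)

    run = RunConfig(manifest=str(manifest_path), out_dir=str(out / "results"),
                    seed=seed, cognition_file=str(cog_path),
                    tract_overlap_t1=str(out / "tract_overlap_t1.tsv"),
                    tract_overlap_t2=str(out / "tract_overlap_t2.tsv"))
    if fast:
        run.n_perm, run.louvain_runs = 500, 100
        run.n_random_networks, run.bootstrap_draws = 20, 1000
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(run), fh)
    return manifest_path, run


def _load_overlap(path, timepoint: int) -> TractOverlap:
    df = pd.read_csv(path, sep="\t")
    df.index = pd.RangeIndex(1, len(df) + 1)    # rows are 1-based region indices
    return TractOverlap(df, timepoint)


def attribute_demo_tracts(demo_dir, component_edges) -> pd.DataFrame:
    """Tract attribution on a demo directory's overlap fixtures."""
    demo_dir = Path(demo_dir)
    t1 = _load_overlap(demo_dir / "tract_overlap_t1.tsv", 1)
    t2 = _load_overlap(demo_dir / "tract_overlap_t2.tsv", 2)
    t1s, t2s = threshold_overlap(t1), threshold_overlap(t2)
    change = proportion_change(t1s, t2s)
    return attribute_tracts(component_edges, change, t1s, t2s)
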