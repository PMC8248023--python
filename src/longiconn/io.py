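"""Delimited-text I/O for matrices, node tables and cohort manifests.

Everything on disk is plain text: square matrices as TSV with node-label
headers, node tables as three-column TSV, masks as {0,1} matrices in the
same dialect, and a JSON manifest tying a cohort's files together.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_matrix", "read_matrix",
    "write_node_table", "read_node_table",
    "write_manifest", "read_manifest",
    "write_cohort",
]


def write_matrix(path, matrix: np.ndarray, labels=None) -> None:
    """Write a square matrix as TSV with a node-label header row."""
    m = np.asarray(matrix)
    cols = list(labels) if labels is not None else [str(i + 1) for i in range(m.shape[1])]
    pd.DataFrame(m, columns=cols).to_csv(path, sep="\t", index=False)


def read_matrix(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    m = df.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {m.shape}")
    return m


def write_node_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_node_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"index", "name", "hemisphere"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: node table needs columns {sorted(required)}")
    return df


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_cohort(out_dir, cohort, labels: pd.DataFrame | None = None) -> Path:
    """Write a synthetic cohort as per-subject matrix/waytotal files + manifest.

    Returns the manifest path.  Ground truth (planted edges, slope) is stored
    in the manifest so downstream checks can recover it.
    """
    from .atlas import node_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = labels if labels is not None else node_table(cohort.config.n_nodes)
    names = labels["name"].tolist()
    write_node_table(out / "nodes.tsv", labels)

    subjects = []
    for s, sid in enumerate(cohort.subject_ids):
        entry = {"id": sid}
        for t in (0, 1):
            mat = out / f"{sid}_t{t + 1}_counts.tsv"
            way = out / f"{sid}_t{t + 1}_waytotal.tsv"
            write_matrix(mat, cohort.counts[s, t], names)
            np.savetxt(way, cohort.waytotals[s, t], fmt="%.10g")
            entry[f"t{t + 1}_counts"] = mat.name
            entry[f"t{t + 1}_waytotal"] = way.name
        subjects.append(entry)

    manifest = {
        "n_nodes": cohort.config.n_nodes,
        "seed": cohort.config.seed,
        "node_table": "nodes.tsv",
        "timepoints": [1, 2],
        "subjects": subjects,
        "ground_truth": {
            "increase_edges": [list(e) for e in cohort.truth.increase_edges],
            "decrease_edges": [list(e) for e in cohort.truth.decrease_edges],
            "cognition_slope": cohort.truth.cognition_slope,
        },
    }
    path = out / "manifest.json"
    write_manifest(path, manifest)
    return path


def read_cohort(manifest_path) -> tuple[np.ndarray, np.ndarray, list[str], pd.DataFrame, dict]:
    """Load a cohort written by :func:`write_cohort`.

    Subjects missing a file at either timepoint are excluded (their ids
    reported in the returned manifest dict under ``"excluded"``).
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    root = manifest_path.parent
    labels = read_node_table(root / manifest["node_table"])
    counts, ways, ids, excluded = [], [], [], []
    for entry in manifest["subjects"]:
        paths = [root / entry[k] for k in
                 ("t1_counts", "t1_waytotal", "t2_counts", "t2_waytotal")]
        if not all(p.exists() for p in paths):
            excluded.append(entry["id"])
            continue
        counts.append([read_matrix(paths[0]), read_matrix(paths[2])])
        ways.append([np.loadtxt(paths[1]), np.loadtxt(paths[3])])
        ids.append(entry["id"])
    manifest["excluded"] = excluded
    return (np.asarray(counts), np.asarray(ways), ids, labels, manifest)
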