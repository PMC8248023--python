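"""White-matter tract attribution for significant component edges.

Given region x tract mean-streamline overlap matrices at both timepoints,
each component edge is attributed to the tract(s) whose overlap with *both*
endpoint regions changed in the same direction as the edge's connectivity
change.  When several tracts qualify, the one with the highest mean overlap
intensity across both timepoints and both endpoints wins; when none does,
the highest-mean-intensity tract is chosen regardless of sign and the edge
is flagged as a fallback assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TractOverlap",
    "density_to_overlap",
    "threshold_overlap",
    "proportion_change",
    "attribute_tracts",
]


@dataclass
class TractOverlap:
    """Region x tract mean streamline intensities at one timepoint."""

    values: pd.DataFrame        # rows = regions, columns = tract names
    timepoint: int = 1

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            v = pd.DataFrame(np.asarray(v, dtype=float))
            v.columns = [f"TRACT_{k + 1}" for k in range(v.shape[1])]
            self.values = v
        if (self.values.to_numpy() < 0).any():
            raise ValueError("overlap intensities must be non-negative")


def density_to_overlap(densities: dict, tract_masks: dict,
                       max_fraction: float = 0.01, timepoint: int = 1) -> TractOverlap:
    """Mean streamline intensity of each region's density map over each tract.

    ``densities`` maps region id -> streamline-density array; ``tract_masks``
    maps tract name -> boolean array on the same grid.  Each density array is
    first thresholded at ``max_fraction`` of its own maximum to suppress
    spurious streamlines, then averaged over each tract mask's support.
    """
    rows = {}
    for region, dens in densities.items():
        d = np.asarray(dens, dtype=float)
        if d.max() > 0:
            d = np.where(d >= max_fraction * d.max(), d, 0.0)
        row = {}
        for tract, mask in tract_masks.items():
            m = np.asarray(mask, dtype=bool)
            if m.shape != d.shape:
                raise ValueError(f"grid mismatch for tract {tract!r}")
            if not m.any():
                raise ValueError(f"empty mask for tract {tract!r}")
            row[tract] = float(d[m].mean())
        rows[region] = row
    return TractOverlap(values=pd.DataFrame.from_dict(rows, orient="index"),
                        timepoint=timepoint)


def threshold_overlap(overlap: TractOverlap, fraction: float = 0.05) -> TractOverlap:
    """Zero entries below ``fraction`` of the matrix's global maximum."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    v = overlap.values.to_numpy(dtype=float)
    out = np.where(v >= fraction * v.max(), v, 0.0) if v.max() > 0 else v.copy()
    return TractOverlap(values=pd.DataFrame(out, index=overlap.values.index,
                                            columns=overlap.values.columns),
                        timepoint=overlap.timepoint)


def proportion_change(overlap_t1: TractOverlap, overlap_t2: TractOverlap) -> pd.DataFrame:
    """(M2 - M1) / M1 elementwise; entries with M1 = 0 are NaN-masked."""
    v1 = overlap_t1.values
    v2 = overlap_t2.values
    if v1.shape != v2.shape:
        raise ValueError("overlap matrices must share a shape")
    a1 = v1.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        change = np.where(a1 > 0, (v2.to_numpy(dtype=float) - a1) / np.where(a1, a1, 1),
                          np.nan)
    return pd.DataFrame(change, index=v1.index, columns=v1.columns)


def attribute_tracts(component_edges, change: pd.DataFrame,
                     overlap_t1: TractOverlap, overlap_t2: TractOverlap) -> pd.DataFrame:
    """Attribute each signed component edge to responsible tract(s).

    ``component_edges`` is an iterable of (i, j, difference); i and j must be
    row labels of the overlap matrices.  Candidate tracts are those whose
    masked proportion change has the edge's sign in both endpoint rows; they
    are ranked by mean overlap intensity over {t1, t2} x {i, j}, the top one
    marked selected.  Edges without any sign-matching tract fall back to the
    highest-mean-intensity tract and are flagged.

    Returns a table with one row per edge: selected tract, rule used, the
    ranked candidate list and their mean intensities.
    """
    v1, v2 = overlap_t1.values, overlap_t2.values
    rows = []
    for i, j, diff in component_edges:
        for endpoint in (i, j):
            if endpoint not in v1.index:
                raise KeyError(f"region {endpoint!r} missing from overlap matrices")
        sign = np.sign(diff)
        ch_i = change.loc[i]
        ch_j = change.loc[j]
        mean_intensity = 0.25 * (v1.loc[i] + v1.loc[j] + v2.loc[i] + v2.loc[j])
        matching = change.columns[
            (np.sign(ch_i) == sign) & (np.sign(ch_j) == sign)
            & ch_i.notna() & ch_j.notna()
        ] if sign != 0 else change.columns[:0]
        if len(matching):
            ranked = mean_intensity[matching].sort_values(ascending=False)
            rule = "common-sign"
        else:
            ranked = mean_intensity.sort_values(ascending=False).head(1)
            rule = "highest-mean fallback"
        rows.append({
            "area_1": i, "area_2": j, "difference": diff,
            "selected_tract": ranked.index[0],
            "rule": rule,
            "candidates": list(ranked.index),
            "candidate_mean_intensity": ranked.to_list(),
        })
    return pd.DataFrame(rows)
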