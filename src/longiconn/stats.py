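"""Longitudinal statistics: paired tests, FDR, rmcorr, cluster bootstrap.

The repeated-measures correlation (rmcorr) is the common within-subject
association between two variables measured repeatedly: an ANCOVA with a
subject factor and a shared slope, equivalent to the correlation of the
within-subject-centered variables, with N(k-1)-1 degrees of freedom for N
subjects and k measurements each.  Bootstrap intervals resample whole
subjects (both timepoints together) so the repeated-measures structure is
preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedTestResult",
    "RmcorrResult",
    "paired_t_with_d",
    "fdr_bh",
    "rmcorr",
    "bootstrap_ci",
]


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    d: float        # Cohen's d for paired data: mean(diff) / SD(diff)
    q: float | None = None


@dataclass
class RmcorrResult:
    r: float
    df: int
    p: float
    slope: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_subjects: int = 0


def paired_t_with_d(values_t1, values_t2) -> PairedTestResult:
    """Two-sided paired t-test with Cohen's d on the differences."""
    x1 = np.asarray(values_t1, dtype=float)
    x2 = np.asarray(values_t2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1 or x1.size < 3:
        raise ValueError("need two aligned vectors of length >= 3")
    diff = x2 - x1
    sd = diff.std(ddof=1)
    n = diff.size
    if sd == 0:
        if np.allclose(diff, 0):
            return PairedTestResult(t=0.0, df=n - 1, p=1.0, d=0.0)
        raise ValueError("zero-variance, nonzero differences: t undefined")
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return PairedTestResult(t=float(t), df=n - 1, p=float(p), d=float(diff.mean() / sd))


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rmcorr(subject_ids, x, y) -> RmcorrResult:
    """Repeated-measures correlation via subject-intercept ANCOVA.

    Both variables are centered within subject; the rmcorr coefficient is the
    Pearson correlation of the centered variables (equivalently
    sign(slope) * sqrt(SS_measure / (SS_measure + SS_error)) from the ANCOVA)
    with df = n_observations - n_subjects - 1.  Subjects contributing a
    single observation carry no within-subject information and are dropped
    with a warning.
    """
    ids = np.asarray(subject_ids)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (ids.shape == x.shape == y.shape) or x.ndim != 1:
        raise ValueError("subject_ids, x and y must be aligned 1-D arrays")

    df_in = pd.DataFrame({"id": ids, "x": x, "y": y})
    counts = df_in.groupby("id")["x"].transform("size")
    if (counts < 2).any():
        warnings.warn("dropping subject(s) with a single observation", stacklevel=2)
        df_in = df_in[counts >= 2]
    n_sub = df_in["id"].nunique()
    if n_sub < 3:
        raise ValueError("rmcorr needs >= 3 subjects with repeated observations")

    g = df_in.groupby("id")
    xc = (df_in["x"] - g["x"].transform("mean")).to_numpy()
    yc = (df_in["y"] - g["y"].transform("mean")).to_numpy()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0 or syy == 0:
        raise ValueError("no within-subject variance in x or y")
    sxy = float(xc @ yc)
    r = sxy / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    dof = len(df_in) - n_sub - 1
    if dof < 1:
        raise ValueError("non-positive degrees of freedom")
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1 - r ** 2))
        p = float(2 * sps.t.sf(abs(t), df=dof))
    return RmcorrResult(r=r, df=dof, p=p, slope=sxy / sxx, n_subjects=n_sub)


def bootstrap_ci(subject_records, statistic, n_draws: int = 10_000,
                 alpha: float = 0.05, seed: int = 0,
                 max_redraws: int = 1000) -> tuple[float, float]:
    """Percentile bootstrap interval resampling subjects with replacement.

    ``subject_records`` is a sequence of per-subject records (each record
    carries everything the statistic needs for that subject, e.g. both
    timepoints); ``statistic`` maps a list of records to a float.  Resamples
    on which the statistic raises are redrawn (count capped and reported).
    """
    records = list(subject_records)
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    rng = np.random.default_rng(seed)
    n = len(records)
    values = np.empty(n_draws)
    redraws = 0
    for b in range(n_draws):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                values[b] = statistic([records[i] for i in idx])
                break
            except (ValueError, ZeroDivisionError, FloatingPointError):
                redraws += 1
                if redraws > max_redraws:
                    raise RuntimeError("statistic undefined on too many resamples")
    if redraws:
        warnings.warn(f"{redraws} resample(s) redrawn", stacklevel=2)
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
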