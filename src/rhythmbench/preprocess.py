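"""Pre-processing of expression time series.

Filters (probe mapping, missing values, all-zero rows), the dataset-level
Z-score shift normalization, probe-level p-value combination (empirical
Brown / Fisher), expression summaries and quartile subsets, and
time-design transformations (regularization, restriction, replicate
reshaping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, SampleDesign


@dataclass(frozen=True)
class GeneAnnotation:
    """probe_id -> gene_id mapping plus a protein-coding flag per gene."""

    probe_to_gene: pd.DataFrame  # columns: probe_id, gene_id
    coding: dict  # gene_id -> bool

    def __post_init__(self) -> None:
        if self.probe_to_gene.duplicated().any():
            raise ValueError("annotation mapping rows must be unique")

    @classmethod
    def identity(cls, gene_ids, coding: bool = True) -> "GeneAnnotation":
        df = pd.DataFrame({"probe_id": list(gene_ids), "gene_id": list(gene_ids)})
        return cls(df, {g: coding for g in gene_ids})


def filter_dataset(m: ExpressionMatrix, ann: GeneAnnotation):
    """Keep rows mapped to exactly one protein-coding gene, with no missing
    value, and not all-zero. Returns ``(filtered, tally)`` with a tally of
    removals per rule; raises if nothing survives.
    """
    counts = ann.probe_to_gene.groupby("probe_id")["gene_id"].nunique()
    gene_of = ann.probe_to_gene.drop_duplicates("probe_id").set_index("probe_id")["gene_id"]

    tally = {"unmapped": 0, "multi": 0, "noncoding": 0, "missing": 0, "allzero": 0}
    keep = []
    for pid, row in zip(m.values.index, m.array()):
        if pid not in counts.index:
            tally["unmapped"] += 1
        elif counts[pid] > 1:
            tally["multi"] += 1
        elif not ann.coding.get(gene_of[pid], False):
            tally["noncoding"] += 1
        elif np.any(~np.isfinite(row)):
            tally["missing"] += 1
        elif np.all(row == 0):
            tally["allzero"] += 1
        else:
            keep.append(pid)
    if not keep:
        raise ValueError(f"no rows survive filtering (tally: {tally})")
    return m.copy_with(values=m.values.loc[keep]), tally


def zscore_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Shift each gene so its mean equals its dataset-level Z-score.

    With gene mean ``m_i`` and dataset mean/sd ``m``/``sd``, each series is
    shifted by the constant ``x_i = m_i - Z_i`` where ``Z_i = (m_i - m)/sd``.
    Within-gene shape (all pairwise differences over time) is unchanged.
    """
    vals = m.array()
    mu, sd = float(np.mean(vals)), float(np.std(vals))
    if sd == 0:
        raise ValueError("degenerate dataset: standard deviation is zero")
    gene_means = vals.mean(axis=1)
    z = (gene_means - mu) / sd
    shifted = vals - gene_means[:, None] + z[:, None]
    return m.copy_with(values=pd.DataFrame(shifted, index=m.values.index,
                                           columns=m.values.columns))


def _brown_scale_df(probe_series: np.ndarray) -> tuple[float, float]:
    """Scale c and effective df for Brown's combination of k probe p-values.

    Each probe's data vector is ecdf-uniformized, transformed to
    ``w = -2 ln u``, and the empirical covariance of the w variables across
    samples rescales Fisher's chi-square statistic.
    """
    k, n = probe_series.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, probe_series)
    u = ranks / (n + 1)
    w = -2.0 * np.log(u)
    expected = 2.0 * k
    var = 4.0 * k
    if k > 1:
        cov = np.cov(w)
        var += 2.0 * np.sum(np.triu(cov, 1))
    var = max(var, 1e-12)
    c = var / (2.0 * expected)
    df = 2.0 * expected ** 2 / var
    return c, df


def combine_probe_pvalues(p, probe_series=None, mode: str = "brown") -> float:
    """Combine per-probe p-values of one gene into a single p-value.

    ``fisher`` assumes independent probes; ``brown`` estimates the
    dependence among probes from their raw data vectors (required) and
    reduces to Fisher when the probes are uncorrelated. A single p-value is
    returned unchanged.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return float(p[0])
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    x = -2.0 * np.sum(np.log(p))
    if mode == "fisher":
        return float(stats.chi2.sf(x, 2 * p.size))
    if mode == "brown":
        if probe_series is None:
            raise ValueError("brown mode requires the probes' data vectors")
        series = np.asarray(probe_series, dtype=float)
        if series.shape[0] != p.size:
            raise ValueError("probe_series rows must match p-values")
        c, df = _brown_scale_df(series)
        return float(stats.chi2.sf(x / c, df))
    raise ValueError(f"unknown mode {mode!r}")


def summarize_expression(m: ExpressionMatrix, stat: str = "median") -> pd.Series:
    """One expression level per gene: median, mean, or min of time-points."""
    if not np.all(np.isfinite(m.array())):
        raise ValueError("missing values present; filter first")
    if stat == "median":
        return m.values.median(axis=1)
    if stat == "mean":
        return m.values.mean(axis=1)
    if stat == "min":
        return m.values.min(axis=1)
    raise ValueError(f"unknown stat {stat!r}")


def quartile_subset(m: ExpressionMatrix, levels: pd.Series, which: str) -> ExpressionMatrix:
    """Rows in the bottom (Q1) or top (Q4) expression quarter.

    Each quartile holds ``floor(n/4)`` genes; ties are broken by stable
    rank (input order), so the subsetting is reproducible.
    """
    n = m.n_genes
    if n < 4:
        raise ValueError("need at least 4 genes for quartile subsetting")
    k = n // 4
    lv = levels.reindex(m.values.index)
    order = np.argsort(lv.to_numpy(), kind="stable")
    if which == "Q1":
        pick = order[:k]
    elif which == "Q4":
        pick = order[n - k:]
    else:
        raise ValueError(f"unknown quartile {which!r}; expected 'Q1' or 'Q4'")
    pick = np.sort(pick)  # preserve original row order
    return m.copy_with(values=m.values.iloc[pick])


def regularize_timepoints(m: ExpressionMatrix, grid_step: float) -> ExpressionMatrix:
    """Bin samples to the nearest regular grid time and average within bins.

    Values in the same (gene, grid time, replicate) bin are averaged; the
    output design is regular. Idempotent on already-regular input.
    """
    if not (grid_step > 0):
        raise ValueError("grid_step must be > 0")
    d = m.design
    grid_time = np.round(d.times / grid_step) * grid_step
    frame = pd.DataFrame({"time": grid_time, "cycle": d.cycle, "replicate": d.replicate})
    groups = frame.groupby(["time", "replicate"], sort=True)
    cols, times, cycles, reps = [], [], [], []
    vals = m.array()
    out = []
    for (t, r), idx in groups.indices.items():
        out.append(vals[:, idx].mean(axis=1))
        times.append(float(t))
        cycles.append(int(frame.loc[idx[0], "cycle"]))
        reps.append(int(r))
    full = np.arange(min(times), max(times) + grid_step / 2, grid_step)
    missing = sorted(set(np.round(full, 9)) - set(np.round(times, 9)))
    if missing:
        raise ValueError(f"empty bins at grid times {missing}")
    order = np.lexsort((reps, times))
    design = SampleDesign(tuple(np.asarray(times)[order]),
                          tuple(np.asarray(cycles)[order]),
                          tuple(np.asarray(reps)[order]))
    arr = np.column_stack([out[i] for i in order])
    df = pd.DataFrame(arr, index=m.values.index, columns=design.labels())
    return ExpressionMatrix(df, design)


def restrict_timepoints(m: ExpressionMatrix, keep) -> ExpressionMatrix:
    """Column subset by a predicate on (time, cycle); design updated."""
    d = m.design
    mask = [bool(keep(t, c)) for t, c in zip(d.time, d.cycle)]
    if sum(mask) < 3:
        raise ValueError("predicate keeps fewer than 3 samples")
    idx = [i for i, k in enumerate(mask) if k]
    design = SampleDesign(tuple(d.time[i] for i in idx), tuple(d.cycle[i] for i in idx),
                          tuple(d.replicate[i] for i in idx))
    df = m.values.iloc[:, idx].copy()
    df.columns = design.labels()
    return ExpressionMatrix(df, design)


def reshape_replicates(m: ExpressionMatrix, mode: str,
                       cycle_length: float = 24.0) -> ExpressionMatrix:
    """Treat replicates as new cycles, or average them.

    ``as_cycles``: replicate r at within-cycle time t becomes a sample of
    cycle r at absolute time ``t + (r-1)*cycle_length`` with a single
    replicate — the recommended way to feed replicated designs to methods
    that assume one value per time. ``average``: replicates are averaged per
    (gene, time, cycle).
    """
    d = m.design
    frame = pd.DataFrame({"time": d.time, "cycle": d.cycle, "replicate": d.replicate})
    if mode == "as_cycles":
        per_time = frame.groupby("time")["replicate"].nunique()
        if per_time.nunique() != 1:
            raise ValueError("as_cycles requires a balanced replicate count per time")
        new_time = frame["time"] + (frame["replicate"] - 1) * cycle_length
        design = SampleDesign(tuple(new_time), tuple(frame["replicate"].astype(int)),
                              tuple(1 for _ in range(len(frame))))
        order = np.argsort(new_time.to_numpy(), kind="stable")
        design = SampleDesign(tuple(new_time.iloc[order]),
                              tuple(frame["replicate"].iloc[order].astype(int)),
                              tuple(1 for _ in order))
        df = m.values.iloc[:, order].copy()
        df.columns = design.labels()
        return ExpressionMatrix(df, design)
    if mode == "average":
        groups = frame.groupby(["time", "cycle"], sort=True)
        vals = m.array()
        times, cycles, cols = [], [], []
        for (t, c), idx in groups.indices.items():
            cols.append(vals[:, idx].mean(axis=1))
            times.append(float(t))
            cycles.append(int(c))
        design = SampleDesign(tuple(times), tuple(cycles), tuple(1 for _ in times))
        df = pd.DataFrame(np.column_stack(cols), index=m.values.index,
                          columns=design.labels())
        return ExpressionMatrix(df, design)
    raise ValueError(f"unknown mode {mode!r}")
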