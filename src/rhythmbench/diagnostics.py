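"""P-value behaviour diagnostics.

Distribution profiles (histogram + uniformity KS + tail fractions),
multiple-testing adjustments, exclusive method-overlap summaries with a
Jaccard matrix, cross-run p-value concordance, and the expression-
enrichment t-test contrasting rhythmic and non-rhythmic genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PValueProfile:
    method: str
    subset: str
    bin_edges: np.ndarray
    densities: np.ndarray
    ks_d: float
    ks_p: float
    frac_below: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.densities < 0):
            raise ValueError("densities must be non-negative")


def pvalue_profile(p, subset: str = "full", bins: int = 20,
                   method: str = "") -> PValueProfile:
    """Normalized histogram over [0, 1], KS-vs-Uniform, and tail fractions."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, bins + 1)
    dens, _ = np.histogram(p, bins=edges, density=True)
    d, ks_p = stats.kstest(p, "uniform")
    frac = {c: float(np.mean(p < c)) for c in (0.05, 0.01)}
    return PValueProfile(method=method, subset=subset, bin_edges=edges,
                         densities=dens, ks_d=float(d), ks_p=float(ks_p),
                         frac_below=frac)


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Bonferroni (min(1, n*p)) or Benjamini-Hochberg step-up adjustment.

    Order of the input is preserved; BH enforces monotonicity of the
    adjusted values from the largest p downwards.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if method == "bonferroni":
        return np.minimum(1.0, n * p)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.minimum(1.0, adj)
        return out
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class OverlapSummary:
    exclusive: dict  # frozenset of method names -> count
    jaccard: pd.DataFrame
    union_size: int


def _calls_from_results(results: dict, mode: str, cutoff) -> dict:
    calls = {}
    for name, frame in results.items():
        if mode == "threshold":
            calls[name] = set(frame.index[frame["default_p"] <= cutoff])
        elif mode == "topN":
            ordered = frame.rename_axis(None).sort_values(
                ["default_p", "raw_p", "gene_id"], kind="stable")
            calls[name] = set(ordered.index[: int(cutoff)])
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return calls


def method_overlap(calls: dict | None = None, mode: str = "threshold",
                   results: dict | None = None, cutoff=0.05) -> OverlapSummary:
    """Exclusive intersection counts (upset-style) and Jaccard matrix.

    Either pass ``calls`` (method -> set of gene ids) directly, or
    ``results`` (method -> results frame indexed by gene id) with a mode:
    ``threshold`` keeps genes at default_p <= cutoff, ``topN`` the cutoff
    smallest default_p (ties by raw_p then id). Exclusive counts partition
    the union of called genes.
    """
    if calls is None:
        if results is None:
            raise ValueError("need calls or results")
        calls = _calls_from_results(results, mode, cutoff)
    if not calls:
        raise ValueError("no method call sets given")
    methods = sorted(calls)
    union = set().union(*calls.values())
    membership = {}
    for g in union:
        key = frozenset(m for m in methods if g in calls[m])
        membership[key] = membership.get(key, 0) + 1
    jac = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            sa, sb = calls[a], calls[b]
            u = len(sa | sb)
            val = len(sa & sb) / u if u else 1.0
            jac.loc[a, b] = jac.loc[b, a] = val
    return OverlapSummary(exclusive=membership, jaccard=jac, union_size=len(union))


def pvalue_concordance(pA: pd.Series, pB: pd.Series,
                       log_transform: bool = False):
    """Pearson r of paired p-values shared by id, plus the paired table.

    The correlation is computed on the untransformed p-values by default
    (a -log10 variant is available but non-default).
    """
    shared = pA.index.intersection(pB.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared ids")
    a = pA.loc[shared].astype(float)
    b = pB.loc[shared].astype(float)
    if np.ptp(a.to_numpy()) == 0 or np.ptp(b.to_numpy()) == 0:
        raise ValueError("zero variance in a p-value vector")
    if log_transform:
        a = -np.log10(np.maximum(a, np.finfo(float).tiny))
        b = -np.log10(np.maximum(b, np.finfo(float).tiny))
    r, _ = stats.pearsonr(a, b)
    table = pd.DataFrame({"pA": a, "pB": b})
    return float(r), table


def rhythmic_expression_ttest(levels: pd.Series, results: pd.DataFrame,
                              rhythmic_cutoff: float = 0.005,
                              nonrhythmic_floor: float = 0.01,
                              seed: int = 0,
                              p_column: str = "default_p") -> dict:
    """Welch t-test of expression levels, rhythmic vs non-rhythmic genes.

    Rhythmic genes have ``p <= rhythmic_cutoff``; the non-rhythmic pool
    (``p > nonrhythmic_floor``) is down-sampled without replacement to the
    same size using ``seed``. Returns n, group means, t, Welch df and p.
    """
    p = results[p_column]
    rhythmic_ids = results.index[p <= rhythmic_cutoff]
    pool_ids = results.index[p > nonrhythmic_floor]
    if len(rhythmic_ids) == 0 or len(pool_ids) == 0:
        raise ValueError("a group is empty; adjust cutoffs")
    n = min(len(rhythmic_ids), len(pool_ids))
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(pool_ids), size=n, replace=False)
    rhythmic_ids = rhythmic_ids[:n]
    x = levels.loc[rhythmic_ids].to_numpy(dtype=float)
    y = levels.loc[pool_ids[np.sort(pick)]].to_numpy(dtype=float)
    t, pval = stats.ttest_ind(x, y, equal_var=False)
    vx, vy = x.var(ddof=1) / n, y.var(ddof=1) / n
    df = (vx + vy) ** 2 / (vx ** 2 / (n - 1) + vy ** 2 / (n - 1)) if vx + vy > 0 else n - 1
    return {"n": int(n), "mean_rhythmic": float(x.mean()),
            "mean_nonrhythmic": float(y.mean()), "t": float(t),
            "df": float(df), "p": float(pval)}
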