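"""Ortholog-conservation benchmark of rhythm-detection output.

The benchmark set is the species-2 side of the one-to-one ortholog map
that a chosen method calls rhythmic ("rhythmic orthologs"). Species-1
orthologs are then ranked — by a method's p-values, or by median
expression for the Naive baseline — and the cumulative proportion of
top-N genes whose partner is in the benchmark set traces a proportion
curve. A good method's curve rises above the Naive curve for genes with a
strong rhythmic signal; a Kolmogorov-Smirnov contrast of species-1
p-values (partner rhythmic vs not) quantifies the conservation signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diagnostics import adjust_pvalues
from .simulate import OrthologMap


@dataclass(frozen=True)
class BenchmarkSet:
    method: str
    kind: str  # "p" or "FDR"
    cutoff: float
    members: frozenset  # species2 gene ids called rhythmic
    universe_size: int  # number of ortholog pairs with data

    @property
    def base_rate(self) -> float:
        return len(self.members) / self.universe_size


@dataclass(frozen=True)
class ProportionCurve:
    gene_ids: list
    ordering_values: np.ndarray
    in_benchmark: np.ndarray  # partner-in-benchmark flags, ordered
    proportions: np.ndarray  # cumulative top-N proportions
    marker_rank: int | None  # largest N with ordering statistic <= 0.01

    def __post_init__(self) -> None:
        if np.any((self.proportions < 0) | (self.proportions > 1)):
            raise ValueError("proportions must lie in [0, 1]")


def build_benchmark_set(resultsB: pd.DataFrame, omap: OrthologMap, method: str,
                        kind: str = "p", cutoff: float = 0.01) -> BenchmarkSet:
    """Species-2 orthologs called rhythmic at the cutoff.

    ``kind='p'`` thresholds default_p directly; ``kind='FDR'`` applies a
    Benjamini-Hochberg adjustment to default_p first. Orthologs without
    species-2 results are dropped from the universe.
    """
    ids2 = [g for g in omap.species2_ids() if g in resultsB.index]
    if not ids2:
        raise ValueError("no species2 orthologs covered by the results")
    sub = resultsB.loc[ids2]
    if kind == "p":
        score = sub["default_p"].to_numpy(dtype=float)
    elif kind == "FDR":
        score = adjust_pvalues(sub["default_p"].to_numpy(dtype=float), "bh")
    else:
        raise ValueError(f"unknown threshold kind {kind!r}")
    members = frozenset(np.asarray(ids2)[score <= cutoff])
    if not members:
        raise ValueError("empty benchmark set: no species2 ortholog passes the cutoff")
    return BenchmarkSet(method=method, kind=kind, cutoff=cutoff,
                        members=members, universe_size=len(ids2))


def _paired_table(resultsA: pd.DataFrame, omap: OrthologMap,
                  bench: BenchmarkSet) -> pd.DataFrame:
    rows = []
    for a, b in omap.pairs:
        if a in resultsA.index:
            rows.append((a, b, b in bench.members))
    if not rows:
        raise ValueError("no species1 orthologs covered by the results")
    df = pd.DataFrame(rows, columns=["species1", "species2", "in_bench"])
    return df.set_index("species1")


def ks_conserved_vs_not(resultsA: pd.DataFrame, omap: OrthologMap,
                        bench: BenchmarkSet, p_column: str = "raw_p"):
    """Two-sample KS of species-1 p-values: conserved vs non-conserved.

    Returns (D, p, direction); direction -1 means the conserved group
    (partner in the benchmark set) is enriched in small p-values.
    """
    table = _paired_table(resultsA, omap, bench)
    p = resultsA.loc[table.index, p_column].to_numpy(dtype=float)
    grp = table["in_bench"].to_numpy()
    x, y = p[grp], p[~grp]
    if x.size == 0 or y.size == 0:
        raise ValueError("a conservation group is empty")
    d, pval = stats.ks_2samp(x, y)
    ranks = stats.rankdata(p)
    direction = int(np.sign(ranks[grp].mean() - ranks[~grp].mean()))
    return float(d), float(pval), direction


def _curve_from_flags(ids: list, values: np.ndarray, flags: np.ndarray,
                      marker_rank) -> ProportionCurve:
    cum = np.cumsum(flags) / np.arange(1, flags.size + 1)
    return ProportionCurve(gene_ids=ids, ordering_values=values,
                           in_benchmark=flags.astype(bool), proportions=cum,
                           marker_rank=marker_rank)


def proportion_curve(resultsA: pd.DataFrame, omap: OrthologMap,
                     bench: BenchmarkSet, marker_cutoff: float = 0.01) -> ProportionCurve:
    """Cumulative rhythmic-ortholog proportion, genes ordered by p-value.

    Orthologs are ordered by ascending default_p (ties: raw_p, then id);
    the marker is the largest rank whose ordering p-value is still at or
    below ``marker_cutoff`` (the threshold diamond).
    """
    table = _paired_table(resultsA, omap, bench)
    sub = resultsA.loc[table.index].rename_axis(None)
    ordered = sub.sort_values(["default_p", "raw_p", "gene_id"], kind="stable")
    flags = table.loc[ordered.index, "in_bench"].to_numpy()
    pvals = ordered["default_p"].to_numpy(dtype=float)
    below = np.flatnonzero(pvals <= marker_cutoff)
    marker = int(below[-1] + 1) if below.size else None
    return _curve_from_flags(list(ordered.index), pvals, flags, marker)


def naive_curve(levels: pd.Series, omap: OrthologMap,
                bench: BenchmarkSet) -> ProportionCurve:
    """Proportion curve of the Naive method: order by median expression.

    Genes are ordered from highest to lowest expression (ties by id);
    the cumulative construction is identical but carries no p-threshold
    marker — the ranking knows nothing about rhythmicity.
    """
    pairs = [(a, b) for a, b in omap.pairs if a in levels.index]
    if not pairs:
        raise ValueError("no species1 orthologs covered by the levels")
    frame = pd.DataFrame(pairs, columns=["species1", "species2"]).set_index("species1")
    lv = levels.loc[frame.index]
    order = sorted(frame.index, key=lambda g: (-lv[g], g))
    flags = np.array([frame.loc[g, "species2"] in bench.members for g in order])
    values = lv.loc[order].to_numpy(dtype=float)
    return _curve_from_flags(order, values, flags, None)


def compare_curves(method_curves: dict, naive: ProportionCurve,
                   run_length: int = 10) -> pd.DataFrame:
    """Rank at which the Naive curve overtakes each method's curve.

    For each method: the smallest N where the naive proportion is >= the
    method's and stays >= for at least ``run_length`` consecutive ranks
    (suppressing noise-level flickering). ``n + 1`` is the sentinel for
    "never". Also reports whether the method's p = 0.01 marker lies beyond
    that crossing — the regime where a plain expression ranking already
    outperforms the rhythm test.
    """
    n = naive.proportions.size
    need = min(run_length, n)
    rows = []
    for name, curve in method_curves.items():
        if curve.proportions.size != n:
            raise ValueError("curves must share the ortholog universe")
        ge = naive.proportions >= curve.proportions
        crossing = n + 1  # sentinel: naive never takes over
        run = 0
        for i in range(n):
            run = run + 1 if ge[i] else 0
            if run >= need:
                crossing = i - run + 2  # 1-based rank where the run started
                break
        marker = curve.marker_rank
        rows.append({"method": name, "crossing_rank": int(crossing),
                     "marker_rank": marker,
                     "marker_beyond_crossing": (marker is not None
                                                and marker >= crossing)})
    return pd.DataFrame(rows).set_index("method")
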