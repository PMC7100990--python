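"""Rhythm-detection tests for gene-expression time series.

Four native methods, each returning a raw and a default (software-style)
p-value per gene:

* ``jtk_cycle`` — Kendall-tau scan against cosine references on a
  period/phase grid. The per-reference tau null is exact (inversion-count
  DP); the gene-level raw p is the tail of the *scan minimum p* under the
  permutation null (exhaustive for short series, otherwise a design-level
  Monte-Carlo null with an analytic proportional tail), so it is calibrated
  despite the scan. The default correction is a Bonferroni across the gene
  set, applied by ``run_method_on_matrix``.
* ``lomb_scargle`` — floating-mean Lomb-Scargle periodogram on a
  Fourier-spaced frequency grid restricted to the period band; exact
  single-frequency beta null, Sidak-combined over the grid size.
* ``empirical_jtk`` — extends the cosine scan with asymmetric
  (linear-sawtooth) references at the 24 h period; raw p is the
  *uncorrected* best-reference tail (left-skewed under the null by
  construction), and the default p is min(empirical permutation p,
  Bonferroni over references) — the correction that restores calibration.
* ``robust_g_periodogram`` — rank-based periodogram at the Fourier
  frequencies with Fisher's exact g test.

``fisher_integration`` combines p-values chi-square style (meta analogue).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kendall import ReferenceScan, pair_signs
from .matrix import ExpressionMatrix, SampleDesign
from .waveforms import WaveformSpec, generate_waveform

logger = logging.getLogger(__name__)

_EXHAUSTIVE_MAX_N = 8


@dataclass(frozen=True)
class MethodConfig:
    min_period: float = 20.0
    max_period: float = 28.0
    phase_step: float = 2.0
    asymmetry_step: float = 2.0
    n_permutations: int = 2000
    seed: int = 0
    null_size: int = 100_000  # design-level Monte-Carlo null draws (jtk scan)

    def __post_init__(self) -> None:
        if not (0 < self.min_period <= self.max_period):
            raise ValueError("need 0 < min_period <= max_period")
        if self.phase_step <= 0 or self.asymmetry_step <= 0:
            raise ValueError("steps must be positive")
        if self.phase_step > self.min_period:
            raise ValueError("phase_step larger than the period range makes no grid")


@dataclass(frozen=True)
class RhythmResult:
    gene_id: str
    statistic: float
    best_period: float
    best_phase: float
    best_asymmetry: float | None
    raw_p: float
    default_p: float

    def __post_init__(self) -> None:
        for name in ("raw_p", "default_p"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} outside [0, 1]: {v}")


def results_frame(results: list[RhythmResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "statistic": [r.statistic for r in results],
            "best_period": [r.best_period for r in results],
            "best_phase": [r.best_phase for r in results],
            "best_asymmetry": [r.best_asymmetry for r in results],
            "raw_p": [r.raw_p for r in results],
            "default_p": [r.default_p for r in results],
        }
    ).set_index("gene_id", drop=False).rename_axis(None)


# ---------------------------------------------------------------------------
# reference grids


def _period_grid(cfg: MethodConfig) -> list[float]:
    """Integer-hour periods from min_period to max_period."""
    lo = int(math.ceil(cfg.min_period))
    hi = int(math.floor(cfg.max_period))
    return [float(p) for p in range(lo, hi + 1)] or [cfg.min_period]

def _cosine_refs_period(times: np.ndarray, period: float, phase_step: float):
    values, meta = [], []
    for phase in np.arange(0.0, period, phase_step):
        spec = WaveformSpec("cosine", period=period, phase=float(phase))
        values.append(generate_waveform(spec, times))
        meta.append({"period": period, "phase": float(phase), "asymmetry": None})
    return np.array(values), meta


def _cosine_refs(cfg: MethodConfig, times: np.ndarray):
    values, meta = [], []
    for period in _period_grid(cfg):
        v, m = _cosine_refs_period(times, period, cfg.phase_step)
        values.extend(v)
        meta.extend(m)
    return np.array(values), meta


def _sawtooth_refs(cfg: MethodConfig, times: np.ndarray, period: float = 24.0):
    values, meta = [], []
    asyms = np.arange(cfg.asymmetry_step, period, cfg.asymmetry_step)
    for phase in np.arange(0.0, period, cfg.phase_step):
        for asym_h in asyms:
            spec = WaveformSpec("ramp", period=period, phase=float(phase),
                                asymmetry=float(asym_h / period))
            values.append(generate_waveform(spec, times))
            meta.append({"period": period, "phase": float(phase),
                         "asymmetry": float(asym_h)})
    return np.array(values), meta


# ---------------------------------------------------------------------------
# scan contexts (cached per design + config)

_scan_cache: dict = {}


class _ScanContext:
    """Reference scan plus its design-level null of the scan statistic."""

    def __init__(self, times: np.ndarray, cfg: MethodConfig, kind: str):
        self.times = times
        self.cfg = cfg
        self.kind = kind
        if kind == "jtk":
            vals, meta = _cosine_refs(cfg, times)
        elif kind == "ejtk":
            # the empirical variant scans a fixed 24 h period: cosine phases
            # every phase_step plus asymmetric sawtooths on the asymmetry grid
            v1, m1 = _cosine_refs_period(times, 24.0, cfg.phase_step)
            v2, m2 = _sawtooth_refs(cfg, times)
            vals, meta = np.vstack([v1, v2]), m1 + m2
        else:
            raise ValueError(kind)
        self.scan = ReferenceScan(vals, meta)
        self._null_pmin: np.ndarray | None = None
        self._null_exhaustive = False

    @property
    def n(self) -> int:
        return self.times.size

    def null_pmin(self) -> tuple[np.ndarray, bool]:
        """Sorted scan-minimum p-values under the permutation null.

        Exhaustive over all n! rank orderings for short series, otherwise
        ``cfg.null_size`` Monte-Carlo rank permutations (seeded from the
        config), shared by every distinct-valued gene on this design.
        """
        if self._null_pmin is not None:
            return self._null_pmin, self._null_exhaustive
        n = self.n
        if n <= _EXHAUSTIVE_MAX_N:
            perms = np.array(list(itertools.permutations(range(n))), dtype=float)
            self._null_exhaustive = True
        else:
            rng = np.random.default_rng((self.cfg.seed, 0xC0FFEE, n))
            base = np.tile(np.arange(n, dtype=float), (self.cfg.null_size, 1))
            perms = rng.permuted(base, axis=1)
        pmins = []
        for start in range(0, perms.shape[0], 20000):
            chunk = perms[start:start + 20000]
            p, _, _ = self.scan.best(pair_signs(chunk))
            pmins.append(p)
        self._null_pmin = np.sort(np.concatenate(pmins))
        return self._null_pmin, self._null_exhaustive

    def calibrated_tail(self, p_obs: np.ndarray) -> np.ndarray:
        """P(scan min-p <= p_obs) under the permutation null.

        Exhaustive counts are exact tails. Monte-Carlo tails use the
        (1 + count)/(B + 1) estimator with a proportional-in-p analytic
        continuation below the smallest draw, keeping resolution for very
        strong signals.
        """
        null, exhaustive = self.null_pmin()
        B = null.size
        p_obs = np.atleast_1d(np.asarray(p_obs, dtype=float))
        counts = np.searchsorted(null, p_obs, side="right")
        if exhaustive:
            return counts / B
        out = (1.0 + counts) / (B + 1.0)
        # below the k-th smallest draw the tail is linear in the scan
        # minimum p (near-disjoint reference exceedances): use the chord
        # through the k-th order statistic for resolution beyond 1/B
        k = min(10, B)
        lo = counts < k
        if np.any(lo):
            c_hat = (k / (B + 1.0)) / max(null[k - 1], 1e-300)
            out[lo] = np.minimum(out[lo], c_hat * p_obs[lo])
        return np.clip(out, 0.0, 1.0)


def _get_context(design: SampleDesign, cfg: MethodConfig, kind: str) -> _ScanContext:
    key = (tuple(np.round(design.times, 9)), cfg, kind)
    ctx = _scan_cache.get(key)
    if ctx is None:
        ctx = _ScanContext(design.times, cfg, kind)
        _scan_cache[key] = ctx
    return ctx


def _check_series(series, min_samples: int) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def _result_from_scan(gene_id, ctx: _ScanContext, tau, meta_idx, raw_p, default_p):
    meta = ctx.scan.meta[int(meta_idx)]
    return RhythmResult(gene_id=gene_id, statistic=float(tau),
                        best_period=float(meta["period"]),
                        best_phase=float(meta["phase"]),
                        best_asymmetry=meta["asymmetry"],
                        raw_p=float(raw_p), default_p=float(default_p))


def _tie_permutation_pmin(ctx: _ScanContext, x: np.ndarray,
                          rng: np.random.Generator, B: int) -> float:
    """Permutation tail of the scan statistic for a tied series."""
    p_obs, _, _ = ctx.scan.best(pair_signs(x))
    perms = rng.permuted(np.tile(x, (B, 1)), axis=1)
    p_null, _, _ = ctx.scan.best(pair_signs(perms))
    return float((1 + np.sum(p_null <= p_obs[0])) / (B + 1))


# ---------------------------------------------------------------------------
# jtk_cycle


def jtk_cycle(series, design: SampleDesign, cfg: MethodConfig | None = None,
              gene_id: str = "gene") -> RhythmResult:
    """Kendall-tau cosine scan with a calibrated scan-level raw p.

    ``default_p`` equals ``raw_p`` here; the Bonferroni across the gene set
    (the software-style default) is applied by ``run_method_on_matrix``.
    """
    cfg = cfg or MethodConfig()
    x = _check_series(series, 6)
    if np.all(x == x[0]):
        return RhythmResult(gene_id, 0.0, float("nan"), float("nan"), None, 1.0, 1.0)
    ctx = _get_context(design, cfg, "jtk")
    p_min, tau, idx = ctx.scan.best(pair_signs(x))
    if np.unique(x).size < x.size:
        rng = np.random.default_rng((cfg.seed, zlib.crc32(gene_id.encode())))
        raw = _tie_permutation_pmin(ctx, x, rng, max(cfg.n_permutations, 200))
    else:
        raw = float(ctx.calibrated_tail(p_min)[0])
    return _result_from_scan(gene_id, ctx, tau[0], idx[0], raw, raw)


# ---------------------------------------------------------------------------
# empirical JTK


def empirical_jtk(series, design: SampleDesign, cfg: MethodConfig | None = None,
                  gene_id: str = "gene") -> RhythmResult:
    cfg = cfg or MethodConfig()
    if cfg.n_permutations < 100:
        warnings.warn("empirical_jtk with fewer than 100 permutations is unreliable")
    x = _check_series(series, 6)
    if np.all(x == x[0]):
        return RhythmResult(gene_id, 0.0, float("nan"), float("nan"), None, 1.0, 1.0)
    ctx = _get_context(design, cfg, "ejtk")
    p_min, tau, idx = ctx.scan.best(pair_signs(x))
    raw = float(p_min[0])
    emp = _ejtk_empirical_p(ctx, x, np.array([raw]), cfg)[0]
    default = min(emp, min(1.0, raw * ctx.scan.n_refs))
    return _result_from_scan(gene_id, ctx, tau[0], idx[0], raw, default)


def _ejtk_empirical_batch(ctx: _ScanContext, rows: np.ndarray, raw: np.ndarray,
                          cfg: MethodConfig, rng: np.random.Generator,
                          chunk_genes: int = 32) -> np.ndarray:
    """Per-gene permutation empirical p-values for a block of series.

    Each gene's time labels are permuted ``n_permutations`` times
    independently; the empirical p is the +1-corrected rank of the gene's
    raw p among the permuted raw p's. Gene chunks are batched through one
    pair-sign/ reference matmul for speed.
    """
    B = cfg.n_permutations
    G = rows.shape[0]
    emp = np.empty(G)
    for start in range(0, G, chunk_genes):
        block = rows[start:start + chunk_genes]
        g = block.shape[0]
        perms = rng.permuted(np.repeat(block, B, axis=0), axis=1)
        p_null, _, _ = ctx.scan.best(pair_signs(perms))
        p_null = p_null.reshape(g, B)
        counts = (p_null <= raw[start:start + g, None]).sum(axis=1)
        emp[start:start + g] = (1.0 + counts) / (B + 1.0)
    return emp


def _ejtk_empirical_p(ctx: _ScanContext, x: np.ndarray, raw: np.ndarray,
                      cfg: MethodConfig) -> np.ndarray:
    rng = np.random.default_rng((cfg.seed, 0xE17C, zlib.crc32(x.tobytes())))
    return _ejtk_empirical_batch(ctx, x[None, :], raw, cfg, rng)


# ---------------------------------------------------------------------------
# Lomb-Scargle


def _ls_grid(times: np.ndarray, cfg: MethodConfig) -> np.ndarray:
    """Fourier-spaced frequencies k/T inside [1/max_period, 1/min_period]."""
    span = float(times.max() - times.min())
    if span <= 0:
        raise ValueError("degenerate time span")
    steps = np.diff(np.sort(np.unique(times)))
    T = span + (float(np.median(steps)) if steps.size else 0.0)
    f_lo, f_hi = 1.0 / cfg.max_period, 1.0 / cfg.min_period
    ks = np.arange(max(1, math.ceil(f_lo * T - 1e-9)), math.floor(f_hi * T + 1e-9) + 1)
    freqs = ks / T
    freqs = freqs[(freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)]
    if freqs.size == 0:
        freqs = np.array([2.0 / (cfg.min_period + cfg.max_period)])
    return freqs


def _ls_power(x: np.ndarray, times: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Floating-mean (generalized) Lomb-Scargle, standard normalization.

    power(f) = 1 - SS_resid(f)/SS_total from the least-squares fit of
    ``a + b cos(2 pi f t) + c sin(2 pi f t)``; lies in [0, 1].
    """
    y = x - x.mean()
    ss_tot = float(y @ y)
    power = np.empty(freqs.size)
    for k, f in enumerate(freqs):
        w = 2 * np.pi * f * times
        X = np.column_stack([np.ones_like(times), np.cos(w), np.sin(w)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        power[k] = 1.0 - float(resid @ resid) / ss_tot
    return power


def lomb_scargle(series, design: SampleDesign, cfg: MethodConfig | None = None,
                 gene_id: str = "gene") -> RhythmResult:
    """Lomb-Scargle periodogram test; tolerates irregular times natively.

    The single-frequency null of the standardized power is exact
    (``p = (1-z)^((N-3)/2)``); the grid peak is corrected with the Sidak
    factor for M = grid size. The default p is the raw p (uncorrected).
    """
    cfg = cfg or MethodConfig()
    x = _check_series(series, 6)
    times = design.times
    if np.all(x == x[0]):
        return RhythmResult(gene_id, 0.0, float("nan"), float("nan"), None, 1.0, 1.0)
    freqs = _ls_grid(times, cfg)
    power = _ls_power(x, times, freqs)
    k = int(np.argmax(power))
    z = float(np.clip(power[k], 0.0, 1.0))
    n = x.size
    p_single = (1.0 - z) ** ((n - 3) / 2.0)
    raw = float(-np.expm1(freqs.size * np.log1p(-min(p_single, 1.0 - 1e-16))))
    raw = min(max(raw, 0.0), 1.0)
    # best phase of the fitted sinusoid, in hours
    w = 2 * np.pi * freqs[k] * times
    X = np.column_stack([np.ones_like(times), np.cos(w), np.sin(w)])
    beta, *_ = np.linalg.lstsq(X, x - x.mean(), rcond=None)
    phase = float((math.atan2(beta[2], beta[1]) / (2 * np.pi)) % 1.0 / freqs[k])
    return RhythmResult(gene_id, z, float(1.0 / freqs[k]), phase, None, raw, raw)


# ---------------------------------------------------------------------------
# rank-based periodogram with Fisher's g


def fisher_g_sf(g: float, m: int) -> float:
    """Exact tail P(G > g) of Fisher's g with m periodogram ordinates."""
    if g <= 0:
        return 1.0
    if g >= 1:
        return 0.0
    terms = []
    for j in range(1, min(m, int(1.0 / g)) + 1):
        terms.append((-1.0) ** (j - 1) * math.comb(m, j) * (1.0 - j * g) ** (m - 1))
    return float(min(1.0, max(0.0, math.fsum(terms))))


def _rank_periodogram(x: np.ndarray) -> np.ndarray:
    """Periodogram ordinates of the rank-transformed series, k=1..floor((n-1)/2).

    ``x`` may be (..., n); midranks are used under ties.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    r = np.apply_along_axis(stats.rankdata, 1, x)
    r = r - r.mean(axis=1, keepdims=True)
    n = r.shape[1]
    m = (n - 1) // 2
    ft = np.fft.rfft(r, axis=1)
    return (np.abs(ft[:, 1:m + 1]) ** 2) / n


_g_null_cache: dict = {}


def _g_null(n: int, cfg: MethodConfig, values: np.ndarray | None = None) -> np.ndarray:
    """Sorted null g-statistics from seeded permutations.

    For distinct values the rank vector is a permutation of 1..n, so the
    null depends only on n and is shared across genes; a tied series passes
    its own midrank ``values`` and gets a dedicated (smaller) draw.
    """
    if values is None:
        key = (n, cfg.seed, cfg.null_size)
        cached = _g_null_cache.get(key)
        if cached is not None:
            return cached
        B, base = cfg.null_size, np.arange(1.0, n + 1.0)
    else:
        B, base = max(cfg.n_permutations, 1000), np.asarray(values, dtype=float)
    rng = np.random.default_rng((cfg.seed, 0x9C, n))
    out = []
    for start in range(0, B, 20000):
        b = min(20000, B - start)
        perms = rng.permuted(np.tile(base, (b, 1)), axis=1)
        spec = _rank_periodogram(perms)
        out.append(spec.max(axis=1) / spec.sum(axis=1))
    null = np.sort(np.concatenate(out))
    if values is None:
        _g_null_cache[key] = null
    return null


def _g_tail(g: float, m: int, null: np.ndarray) -> float:
    """P(G >= g) from the permutation null, Fisher-tail continuation beyond it."""
    B = null.size
    count = B - np.searchsorted(null, g, side="left")  # draws >= g
    if count == 0:
        g_top = null[-1]
        anchor = fisher_g_sf(g_top, m)
        scale = (1.0 / (B + 1.0)) / max(anchor, 1e-300)
        return float(min(1.0, fisher_g_sf(g, m) * scale))
    return float((1.0 + count) / (B + 1.0))


def robust_g_periodogram(series, design: SampleDesign, cfg: MethodConfig | None = None,
                         gene_id: str = "gene") -> RhythmResult:
    """Rank-based spectral test: Fisher's g on the rank periodogram.

    Requires a regular design (one replicate, even spacing). The null of g
    on ranks is distribution-free, so the p-value comes from a seeded
    permutation null shared by every distinct-valued gene (Fisher's exact
    tail formula continues it beyond the permutation resolution); tied
    series get their own midrank permutation null. Raw and default p
    coincide (the software default is uncorrected).
    """
    cfg = cfg or MethodConfig()
    x = _check_series(series, 6)
    if not design.is_regular():
        raise ValueError("robust_g_periodogram needs a regular design; "
                         "use regularize_timepoints / reshape_replicates first")
    if np.all(x == x[0]):
        return RhythmResult(gene_id, 0.0, float("nan"), float("nan"), None, 1.0, 1.0)
    spec = _rank_periodogram(x)[0]
    m = spec.size
    total = float(spec.sum())
    g = float(spec.max() / total) if total > 0 else 0.0
    k = int(np.argmax(spec)) + 1
    order = np.argsort(design.times)
    step = float(np.median(np.diff(design.times[order])))
    period = x.size * step / k
    if np.unique(x).size < x.size:
        null = _g_null(x.size, cfg, values=stats.rankdata(x))
    else:
        null = _g_null(x.size, cfg)
    p = _g_tail(g, m, null)
    return RhythmResult(gene_id, g, period, float("nan"), None, p, p)


# ---------------------------------------------------------------------------
# meta integration


def fisher_integration(p) -> float:
    """Fisher's chi-square combination of k p-values (meta2d analogue)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to the smallest positive float")
        p = np.maximum(p, np.finfo(float).tiny)
    if p.size == 1:
        return float(p[0])
    x = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x, 2 * p.size))


# ---------------------------------------------------------------------------
# matrix-level driver

METHODS = ("jtk", "ls", "ejtk", "rgc", "meta")


def _run_scan_matrix(m: ExpressionMatrix, cfg: MethodConfig, kind: str):
    """Vectorized scan over all rows; returns (p_min, tau, ref_idx, tied_rows)."""
    ctx = _get_context(m.design, cfg, kind)
    vals = m.array()
    p_min = np.ones(m.n_genes)
    tau = np.zeros(m.n_genes)
    idx = np.zeros(m.n_genes, dtype=int)
    tied = np.array([np.unique(row).size < row.size for row in vals])
    constant = np.array([np.all(row == row[0]) for row in vals])
    todo = ~constant
    if np.any(todo):
        signs = pair_signs(vals[todo])
        p, t, i = ctx.scan.best(signs)
        p_min[todo], tau[todo], idx[todo] = p, t, i
    return ctx, p_min, tau, idx, tied, constant


def run_method_on_matrix(m: ExpressionMatrix, method: str,
                         cfg: MethodConfig | None = None) -> list[RhythmResult]:
    """Apply one method to every row; gene-set-level default corrections.

    The JTK default p is the Bonferroni of its raw p across the gene set;
    the other methods' defaults are per-gene. Deterministic given
    ``cfg.seed``.
    """
    cfg = cfg or MethodConfig()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    logger.info("running %s on %d genes x %d samples", method, m.n_genes, m.n_samples)
    ids = m.gene_ids
    G = m.n_genes

    if method in ("jtk", "ejtk"):
        ctx, p_min, tau, idx, tied, constant = _run_scan_matrix(m, cfg, method)
        results = []
        if method == "jtk":
            raw = ctx.calibrated_tail(p_min)
            for i in range(G):
                if constant[i]:
                    results.append(RhythmResult(ids[i], 0.0, float("nan"),
                                                float("nan"), None, 1.0, 1.0))
                    continue
                if tied[i]:
                    rng = np.random.default_rng((cfg.seed, zlib.crc32(ids[i].encode())))
                    r = _tie_permutation_pmin(ctx, m.array()[i], rng,
                                              max(cfg.n_permutations, 200))
                else:
                    r = float(raw[i])
                # software-style default: Bonferroni across the gene set of
                # the uncorrected best-reference tail (the software's "raw"),
                # floored at the calibrated scan p so default >= raw always
                default = min(1.0, max(r, float(p_min[i]) * G))
                results.append(_result_from_scan(ids[i], ctx, tau[i], idx[i],
                                                 r, default))
            return results
        # ejtk: per-gene permutation empirical p, batched in gene order
        vals = m.array()
        emp = np.ones(G)
        todo = np.flatnonzero(~constant)
        if todo.size:
            rng = np.random.default_rng((cfg.seed, 0xE17C))
            emp[todo] = _ejtk_empirical_batch(ctx, vals[todo], p_min[todo], cfg, rng)
        for i in range(G):
            if constant[i]:
                results.append(RhythmResult(ids[i], 0.0, float("nan"), float("nan"),
                                            None, 1.0, 1.0))
            else:
                default = min(float(emp[i]), min(1.0, float(p_min[i]) * ctx.scan.n_refs))
                results.append(_result_from_scan(ids[i], ctx, tau[i], idx[i],
                                                 float(p_min[i]), default))
        return results

    if method == "ls":
        return [lomb_scargle(row, m.design, cfg, gene_id=g)
                for g, row in zip(ids, m.array())]
    if method == "rgc":
        return [robust_g_periodogram(row, m.design, cfg, gene_id=g)
                for g, row in zip(ids, m.array())]

    # meta: Fisher integration of jtk + ls + rgc raw p-values
    parts = [run_method_on_matrix(m, name, cfg) for name in ("jtk", "ls", "rgc")]
    out = []
    for i, gid in enumerate(ids):
        ps = [part[i].raw_p for part in parts]
        combined = fisher_integration(ps)
        base = parts[0][i]
        out.append(RhythmResult(gid, float(-2.0 * np.sum(np.log(np.maximum(ps, 1e-300)))),
                                base.best_period, base.best_phase, base.best_asymmetry,
                                combined, combined))
    return out
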