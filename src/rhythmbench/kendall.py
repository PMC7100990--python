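"""Exact null distributions for Kendall-tau reference scans.

JTK-style tests score a series against phase-shifted reference waveforms
with Kendall's tau. For a fixed reference with tie groups of sizes
``(g_1, ..., g_k)`` the concordance count U (pairs ordered the same way in
series and reference, among pairs the reference can order) is a
Jonckheere-Terpstra statistic. Its exact permutation null is built here by
convolving Mann-Whitney null distributions over the tie groups — the
inversion-count dynamic programme — giving tail probabilities to full
floating-point depth without enumeration.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=4096)
def mann_whitney_pmf(m: int, n: int) -> np.ndarray:
    """Null pmf of the Mann-Whitney U statistic for group sizes (m, n).

    Classic count recurrence ``c(u; m, n) = c(u - n; m - 1, n) +
    c(u; m, n - 1)``; counts stay exact in float64 for the sizes used here
    (binomials up to C(48, 24) < 2^53).
    """
    if m == 0 or n == 0:
        return np.array([1.0])
    table = [[None] * (n + 1) for _ in range(m + 1)]
    for mm in range(m + 1):
        for nn in range(n + 1):
            if mm == 0 or nn == 0:
                table[mm][nn] = np.array([1.0])
                continue
            a = table[mm - 1][nn]  # c(u; m-1, n), shifted by n
            b = table[mm][nn - 1]  # c(u; m, n-1)
            size = mm * nn + 1
            out = np.zeros(size)
            out[nn:nn + a.size] += a
            out[:b.size] += b
            table[mm][nn] = out
    c = table[m][n]
    return c / c.sum()


@lru_cache(maxsize=4096)
def jt_null_sf(group_sizes: tuple[int, ...]) -> np.ndarray:
    """Survival function P(U >= u) of the Jonckheere-Terpstra statistic.

    ``group_sizes`` are the reference's tie-group sizes in reference order
    (the distribution depends only on the multiset). Index u runs from 0 to
    ``T = sum_{i<j} g_i g_j``. The tail is accumulated from the top so deep
    tail probabilities keep full relative precision.
    """
    pmf = np.array([1.0])
    placed = 0
    for g in group_sizes:
        if g <= 0:
            raise ValueError("group sizes must be positive")
        if placed > 0:
            pmf = np.convolve(pmf, mann_whitney_pmf(placed, g))
        placed += g
    sf = np.cumsum(pmf[::-1])[::-1]
    return np.minimum(sf, 1.0)


def pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Ordered sample pairs (i < j) as two index arrays."""
    return np.triu_indices(n, 1)


def pair_signs(x: np.ndarray) -> np.ndarray:
    """sign(x_j - x_i) over pairs i < j; x is (..., n)."""
    x = np.asarray(x, dtype=float)
    i, j = pair_indices(x.shape[-1])
    return np.sign(x[..., j] - x[..., i]).astype(np.int8)


class ReferenceScan:
    """A set of reference waveforms with their exact per-reference nulls.

    ``ref_values`` is (n_refs, n_samples). For each reference the pair
    weight vector (sign of the reference difference over sample pairs), the
    number of comparable pairs T, and the exact JT survival function are
    precomputed. ``scores(series_signs)`` maps pair-sign rows to the
    per-reference exact one-sided p-values and tau statistics.
    """

    def __init__(self, ref_values: np.ndarray, meta: list[dict] | None = None,
                 tol: float = 1e-9):
        ref_values = np.asarray(ref_values, dtype=float)
        if ref_values.ndim != 2:
            raise ValueError("ref_values must be 2-D")
        self.n_refs, self.n_samples = ref_values.shape
        self.meta = meta if meta is not None else [{} for _ in range(self.n_refs)]
        # quantize so analytically tied reference values group together
        q = np.round(ref_values / tol) * tol
        self.weights = pair_signs(q).T.astype(np.float32)  # (n_pairs, n_refs)
        self.T = np.abs(self.weights).sum(axis=0)  # comparable pairs per ref
        self.sfs = []
        for r in range(self.n_refs):
            _, counts = np.unique(q[r], return_counts=True)
            self.sfs.append(jt_null_sf(tuple(int(c) for c in sorted(counts))))

    def scores(self, signs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-reference (p, tau) for pair-sign rows ``signs`` (G, n_pairs).

        p is the exact one-sided tail P(U >= u) of the reference's JT null;
        tau = S / T with S the concordant-minus-discordant count. Rows with
        within-series ties get fractional U; the tail at ``ceil(U)`` is used
        (callers needing exactness under ties use a permutation null).
        """
        signs = np.asarray(signs, dtype=np.float32)
        if signs.ndim == 1:
            signs = signs[None, :]
        S = signs @ self.weights  # (G, n_refs)
        with np.errstate(invalid="ignore", divide="ignore"):
            tau = np.where(self.T > 0, S / self.T, 0.0)
        p = np.ones_like(S, dtype=float)
        for r in range(self.n_refs):
            sf = self.sfs[r]
            u = np.ceil((S[:, r] + self.T[r]) / 2.0).astype(int)
            u = np.clip(u, 0, sf.size - 1)
            p[:, r] = sf[u]
        return p, tau

    def best(self, signs: np.ndarray):
        """Scan statistic per row: (min per-ref p, tau/meta of the best ref)."""
        p, tau = self.scores(signs)
        idx = np.argmin(p, axis=1)
        rows = np.arange(p.shape[0])
        return p[rows, idx], tau[rows, idx], idx
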