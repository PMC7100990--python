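"""Synthetic one- and two-species nycthemeral transcriptomes.

The generator emulates the statistical regimes of real circadian
time-series compendia: a bimodal log-expression baseline, a rhythmic
fraction with mixed waveforms at a 24 h period, an optional logistic
coupling between expression level and the probability of being rhythmic,
multiplicative log-normal measurement noise, and — for species pairs —
conservation of rhythmicity among one-to-one orthologs with phase jitter
and correlated baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .matrix import ExpressionMatrix, SampleDesign
from .waveforms import SHAPES, WaveformSpec, generate_waveform

DEFAULT_WAVEFORM_MIX = {"cosine": 0.5, "ramp": 0.2, "peak": 0.15, "box": 0.15}


@dataclass(frozen=True)
class BaselineMixture:
    """Two-component normal mixture on the log2 expression scale."""

    loc_low: float = 4.0
    scale_low: float = 1.0
    loc_high: float = 8.0
    scale_high: float = 1.0
    weight_low: float = 0.45

    def __post_init__(self) -> None:
        if not (0 <= self.weight_low <= 1):
            raise ValueError("mixing weight must lie in [0, 1]")
        if self.scale_low < 0 or self.scale_high < 0:
            raise ValueError("mixture scales must be non-negative")

    def ppf(self, q: np.ndarray) -> np.ndarray:
        """Numeric quantile function of the mixture (monotone interpolation)."""
        lo = min(self.loc_low - 8 * self.scale_low, self.loc_high - 8 * self.scale_high)
        hi = max(self.loc_low + 8 * self.scale_low, self.loc_high + 8 * self.scale_high)
        grid = np.linspace(lo, hi, 4097)
        cdf = (self.weight_low * stats.norm.cdf(grid, self.loc_low, self.scale_low)
               + (1 - self.weight_low) * stats.norm.cdf(grid, self.loc_high, self.scale_high))
        return np.interp(np.clip(q, cdf[0], cdf[-1]), cdf, grid)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.random(n) < self.weight_low
        x = np.where(comp,
                     rng.normal(self.loc_low, self.scale_low, n),
                     rng.normal(self.loc_high, self.scale_high, n))
        return x


@dataclass(frozen=True)
class SpeciesSimConfig:
    n_genes: int = 2000
    frac_rhythmic: float = 0.3
    baseline_mixture: BaselineMixture = field(default_factory=BaselineMixture)
    expression_rhythm_coupling: float = 0.0
    waveform_mix: dict = field(default_factory=lambda: dict(DEFAULT_WAVEFORM_MIX))
    amplitude_range: tuple[float, float] = (0.1, 0.8)
    asymmetry_range: tuple[float, float] = (0.2, 0.8)
    noise_cv: float = 0.25
    period: float = 24.0
    design: SampleDesign = field(default_factory=lambda: SampleDesign.regular(24, 2.0))
    seed: int = 0
    gene_prefix: str = "g"

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not (0 <= self.frac_rhythmic <= 1):
            raise ValueError("frac_rhythmic must lie in [0, 1]")
        total = sum(self.waveform_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("waveform_mix probabilities must sum to 1")
        if any(k not in SHAPES for k in self.waveform_mix):
            raise ValueError("waveform_mix keys must be valid shapes")
        if any(p < 0 for p in self.waveform_mix.values()):
            raise ValueError("waveform_mix probabilities must be non-negative")
        a0, a1 = self.amplitude_range
        if a0 < 0 or a1 < a0:
            raise ValueError("amplitude_range must be non-negative and ordered")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    is_rhythmic: bool
    waveform: WaveformSpec | None
    baseline: float

    def __post_init__(self) -> None:
        if self.is_rhythmic != (self.waveform is not None):
            raise ValueError("waveform must be present iff is_rhythmic")
        if not (self.baseline > 0):
            raise ValueError("baseline must be positive")


@dataclass(frozen=True)
class ConservationConfig:
    n_orthologs: int = 1000
    p_conserved: float = 0.8
    phase_jitter_sd: float = 1.0
    baseline_log_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_orthologs <= 0:
            raise ValueError("n_orthologs must be positive")
        if not (0 <= self.p_conserved <= 1):
            raise ValueError("p_conserved must lie in [0, 1]")
        if self.phase_jitter_sd < 0:
            raise ValueError("phase_jitter_sd must be non-negative")
        if not (-1 <= self.baseline_log_correlation <= 1):
            raise ValueError("baseline_log_correlation must lie in [-1, 1]")


def _solve_intercept(f: float, coupling: float, logb_c: np.ndarray) -> float:
    """Intercept of the logistic link so the marginal rhythmic fraction is f."""
    if f <= 0:
        return -np.inf
    if f >= 1:
        return np.inf
    if coupling == 0:
        return float(np.log(f / (1 - f)))

    def mean_prob(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + coupling * logb_c))))) - f

    lo, hi = -50.0, 50.0
    return float(optimize.brentq(mean_prob, lo, hi, xtol=1e-12))


def _rhythmic_flags(cfg: SpeciesSimConfig, log_baseline: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    logb_c = log_baseline - log_baseline.mean()
    alpha = _solve_intercept(cfg.frac_rhythmic, cfg.expression_rhythm_coupling, logb_c)
    with np.errstate(over="ignore"):
        prob = 1.0 / (1.0 + np.exp(-(alpha + cfg.expression_rhythm_coupling * logb_c)))
    return rng.random(cfg.n_genes) < prob


def _draw_waveform(cfg: SpeciesSimConfig, rng: np.random.Generator) -> WaveformSpec:
    shapes = list(cfg.waveform_mix.keys())
    probs = np.array([cfg.waveform_mix[s] for s in shapes], dtype=float)
    shape = shapes[rng.choice(len(shapes), p=probs / probs.sum())]
    phase = float(rng.uniform(0, cfg.period))
    asym = float(rng.uniform(*cfg.asymmetry_range))
    amp = float(rng.uniform(*cfg.amplitude_range))
    return WaveformSpec(shape=shape, period=cfg.period, phase=phase,
                        asymmetry=asym, rel_amplitude=amp)


def _noise_factor(cv: float, shape: tuple, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and CV ``cv``."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), shape))


def _assemble(cfg: SpeciesSimConfig, log_baseline: np.ndarray, rhythmic: np.ndarray,
              waveforms: list, rng: np.random.Generator) -> tuple[ExpressionMatrix, list]:
    times = cfg.design.times
    baseline = np.exp2(log_baseline)
    signal = np.ones((cfg.n_genes, cfg.design.n_samples))
    truths: list[GeneTruth] = []
    ids = [f"{cfg.gene_prefix}{i:05d}" for i in range(cfg.n_genes)]
    for i in range(cfg.n_genes):
        wf = waveforms[i] if rhythmic[i] else None
        if wf is not None:
            signal[i] += wf.rel_amplitude * generate_waveform(wf, times)
        truths.append(GeneTruth(ids[i], bool(rhythmic[i]), wf, float(baseline[i])))
    values = baseline[:, None] * signal * _noise_factor(cfg.noise_cv, signal.shape, rng)
    df = pd.DataFrame(values, index=ids, columns=cfg.design.labels())
    return ExpressionMatrix(df, cfg.design), truths


def simulate_species(config: SpeciesSimConfig) -> tuple[ExpressionMatrix, list[GeneTruth]]:
    """Simulate one species' expression matrix plus per-gene ground truth.

    ``expression(g, t) = baseline_g * (1 + amp_g * template_g(t)) * noise``
    with multiplicative log-normal noise of coefficient of variation
    ``noise_cv``. Rhythmic flags follow a logistic link on the centred log
    baseline whose intercept is solved so the marginal rhythmic fraction
    equals ``frac_rhythmic``. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    log_baseline = config.baseline_mixture.rvs(config.n_genes, rng)
    rhythmic = _rhythmic_flags(config, log_baseline, rng)
    waveforms = [_draw_waveform(config, rng) for _ in range(config.n_genes)]
    return _assemble(config, log_baseline, rhythmic, waveforms, rng)


class OrthologMap:
    """Strictly one-to-one pairs of (species1 gene id, species2 gene id)."""

    def __init__(self, pairs: list[tuple[str, str]]):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        if len(set(a)) != len(a) or len(set(b)) != len(b):
            raise ValueError("ortholog map must be one-to-one (duplicate ids found)")
        self.pairs = list(pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def partner_of(self) -> dict[str, str]:
        """species1 id -> species2 id."""
        return dict(self.pairs)

    def species1_ids(self) -> list[str]:
        return [p[0] for p in self.pairs]

    def species2_ids(self) -> list[str]:
        return [p[1] for p in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["species1_gene_id", "species2_gene_id"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OrthologMap":
        return cls(list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))


def _copula_input_correlation(mix_a: BaselineMixture, mix_b: BaselineMixture,
                              target: float) -> float:
    """Latent-normal correlation whose Gaussian copula yields Pearson ``target``.

    The attenuation of a Gaussian copula pushed through the mixture quantile
    maps is computed from the Hermite expansions of both maps; the implied
    Pearson correlation is a polynomial in the latent correlation, inverted
    with a bracketed root search.
    """
    if target == 0:
        return 0.0
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    w = weights / weights.sum()

    def coeffs(mix: BaselineMixture) -> np.ndarray:
        g = mix.ppf(stats.norm.cdf(nodes))
        herm = np.ones((12, nodes.size))
        if herm.shape[0] > 1:
            herm[1] = nodes
        for k in range(2, herm.shape[0]):
            herm[k] = nodes * herm[k - 1] - (k - 1) * herm[k - 2]
        fact = np.cumprod(np.concatenate([[1.0], np.arange(1, herm.shape[0])]))
        return np.array([(w * g * herm[k]).sum() / fact[k] for k in range(herm.shape[0])])

    ca, cb = coeffs(mix_a), coeffs(mix_b)
    fact = np.cumprod(np.concatenate([[1.0], np.arange(1, ca.size)]))
    sd_a = np.sqrt(np.sum(ca[1:] ** 2 * fact[1:]))
    sd_b = np.sqrt(np.sum(cb[1:] ** 2 * fact[1:]))

    def implied(rho: float) -> float:
        return float(np.sum(ca[1:] * cb[1:] * fact[1:] * rho ** np.arange(1, ca.size))
                     / (sd_a * sd_b))

    lo, hi = (-1.0, 0.0) if target < 0 else (0.0, 1.0)
    if abs(target) >= abs(implied(np.sign(target) * 1.0)):
        return float(np.sign(target))
    return float(optimize.brentq(lambda r: implied(r) - target, lo, hi, xtol=1e-10))


def simulate_ortholog_pair(configA: SpeciesSimConfig, configB: SpeciesSimConfig,
                           cons: ConservationConfig):
    """Simulate a two-species study with conserved rhythmicity.

    The first ``cons.n_orthologs`` genes of each species are paired
    one-to-one. Paired log baselines follow a Gaussian copula calibrated so
    their Pearson correlation (log scale) matches
    ``cons.baseline_log_correlation``. For a rhythmic species-A ortholog the
    species-B partner inherits rhythmicity with probability
    ``cons.p_conserved`` (phase shifted by N(0, phase_jitter_sd)); otherwise
    the partner's rhythmicity is drawn independently from the species-B
    model, so with ``p_conserved = 0`` partners of rhythmic genes are
    rhythmic at the species-B background rate.

    Returns ``(matrixA, matrixB, ortholog_map, (truthsA, truthsB))``.
    """
    n_orth = cons.n_orthologs
    if n_orth > configA.n_genes or n_orth > configB.n_genes:
        raise ValueError("n_orthologs exceeds a species' gene count")
    if configA.gene_prefix == configB.gene_prefix:
        configB = replace(configB, gene_prefix=configB.gene_prefix + "b")

    rngA = np.random.default_rng(configA.seed)
    rngB = np.random.default_rng(configB.seed)
    rngC = np.random.default_rng(cons.seed)

    # --- baselines: copula-correlated for ortholog pairs, independent rest
    rho_in = _copula_input_correlation(configA.baseline_mixture, configB.baseline_mixture,
                                       cons.baseline_log_correlation)
    zA = rngC.standard_normal(n_orth)
    zB = rho_in * zA + np.sqrt(max(0.0, 1 - rho_in ** 2)) * rngC.standard_normal(n_orth)
    logbA = np.empty(configA.n_genes)
    logbB = np.empty(configB.n_genes)
    logbA[:n_orth] = configA.baseline_mixture.ppf(stats.norm.cdf(zA))
    logbB[:n_orth] = configB.baseline_mixture.ppf(stats.norm.cdf(zB))
    logbA[n_orth:] = configA.baseline_mixture.rvs(configA.n_genes - n_orth, rngA)
    logbB[n_orth:] = configB.baseline_mixture.rvs(configB.n_genes - n_orth, rngB)

    rhythmicA = _rhythmic_flags(configA, logbA, rngA)
    waveA = [_draw_waveform(configA, rngA) for _ in range(configA.n_genes)]

    # --- species B rhythmicity: background draw, then conservation overwrite
    rhythmicB = _rhythmic_flags(configB, logbB, rngB)
    waveB = [_draw_waveform(configB, rngB) for _ in range(configB.n_genes)]
    inherit = (rngC.random(n_orth) < cons.p_conserved) & rhythmicA[:n_orth]
    for i in np.flatnonzero(inherit):
        rhythmicB[i] = True
        wfA = waveA[i]
        jitter = float(rngC.normal(0.0, cons.phase_jitter_sd)) if cons.phase_jitter_sd > 0 else 0.0
        waveB[i] = replace(wfA, period=configB.period,
                           phase=float((wfA.phase + jitter) % configB.period))

    mA, truthsA = _assemble(configA, logbA, rhythmicA, waveA, rngA)
    mB, truthsB = _assemble(configB, logbB, rhythmicB, waveB, rngB)
    omap = OrthologMap(list(zip(mA.gene_ids[:n_orth], mB.gene_ids[:n_orth])))
    return mA, mB, omap, (truthsA, truthsB)


def randomize_time_labels(m: ExpressionMatrix, seed: int,
                          scope: str = "per_gene") -> ExpressionMatrix:
    """Destroy temporal structure by permuting sample values.

    ``per_gene``: each gene's values are permuted across samples
    independently. ``global``: one shared permutation of the sample labels
    is applied to every gene. The per-gene multiset of values is preserved
    and the same seed reproduces identical output.
    """
    if m.n_genes == 0 or m.n_samples == 0:
        raise ValueError("cannot randomize an empty matrix")
    rng = np.random.default_rng(seed)
    vals = m.array()
    if scope == "per_gene":
        idx = np.argsort(rng.random(vals.shape), axis=1)
        shuffled = np.take_along_axis(vals, idx, axis=1)
    elif scope == "global":
        perm = rng.permutation(vals.shape[1])
        shuffled = vals[:, perm]
    else:
        raise ValueError(f"unknown scope {scope!r}; expected 'per_gene' or 'global'")
    df = pd.DataFrame(shuffled, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(df, m.design)
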