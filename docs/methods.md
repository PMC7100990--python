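# Methods

## The problem and the model

A gene is called rhythmic when its mRNA abundance varies with a ~24 h
period. Detectors for this signal differ in the waveforms they assume,
how they treat replicates and irregular sampling, and — critically — in
the meaning of the p-values they report. This package implements four
detectors with carefully constructed nulls, a diagnostics layer for
p-value behaviour, and a benchmark that scores detectors by how well
their top-ranked genes are enriched in orthologs independently called
rhythmic in a second species. Because real compendia (microarray and
RNA-seq time courses across tissues and species) cannot be shipped or
regenerated deterministically, every experiment runs on a synthetic
generator whose statistical structure mimics those data.

## The synthetic generator

A gene's observed expression is

    x_g(t) = b_g · (1 + a_g · w_g(t)) · ε_{g,t}

* **Baseline** b_g = 2^z with z drawn from a two-component normal
  mixture on the log2 scale (modes 4.0 and 8.0, both sd 1.0, low-mode
  weight 0.45) — the bimodal expression density typical of expression
  compendia. The modes and weight are fixed package defaults; nothing
  downstream is sensitive to their exact placement.
* **Waveform** w_g: a unit template (mean 0, peak-to-trough 1 over one
  period) of shape cosine, ramp (rise fraction = asymmetry), raised-
  cosine peak (width = asymmetry·period) or box (duty = asymmetry),
  period 24 h, phase uniform on [0, 24). Default shape mix: cosine 0.50,
  ramp 0.20, peak 0.15, box 0.15 — mostly sinusoidal with a substantial
  non-sinusoidal minority, as seen among known cycling genes. Relative
  amplitude a_g ~ Uniform(0.1, 0.8), asymmetry ~ Uniform(0.2, 0.8).
* **Rhythmic flags**: P(rhythmic | b) = logistic(α + κ·(log b − mean)),
  with the intercept α solved numerically so the marginal rhythmic
  fraction equals its target (default 0.30) for any coupling κ. κ > 0
  encodes the observed enrichment of rhythmicity among highly expressed
  genes while leaving the marginal fraction fixed.
* **Noise** ε is multiplicative log-normal with unit mean and
  coefficient of variation 0.25 (σ_log2 ≈ 0.35) — a realistic residual
  noise level for normalized array intensities; multiplicativity keeps
  values positive and reproduces the mean–variance coupling of
  expression data.
* **Design**: 24 samples every 2 h over two 24 h cycles by default;
  helpers generate thinned or replicated designs, and replicates can be
  reshaped into extra cycles (the recommended arrangement) or averaged.
* **Species pairs**: the first n_orthologs genes of two simulations are
  paired one-to-one. A rhythmic species-A ortholog passes its rhythmicity
  (same shape and amplitude, phase jittered by N(0, 1 h)) to its partner
  with probability p_conserved; otherwise the partner's state is redrawn
  independently from the species-B model, so unconserved partners sit at
  the species-B background rate. Paired log-baselines follow a Gaussian
  copula whose latent correlation is solved (via the Hermite expansion of
  the mixture quantile map) so their *Pearson* correlation matches the
  requested value.
* **Nulls**: per-gene (default) or global permutation of time labels.
  Whether a real randomization should permute per gene or globally is
  ambiguous; per-gene is the cleaner null and both are exposed.

What the generator does **not** emulate: probe-level artifacts, batch
effects, integer read-count sampling, inter-cycle drift, light-dark vs
dark-dark condition differences, and non-stationary noise. Passing
tests therefore demonstrate correct statistical behaviour under a
faithful stochastic caricature of such data, not performance on any
particular real dataset.

## Method nulls and numerical choices

**Kendall-tau scan (jtk).** For a reference with tie-group sizes
(g_1,…,g_k) the concordance count U is Jonckheere–Terpstra distributed;
its exact pmf is the convolution of Mann–Whitney nulls built by the
classic count recurrence (exact in float64 up to the binomials used
here) and tails are accumulated from the top to preserve deep-tail
precision. Reference values are quantized at 1e-9 before grouping so
analytically tied cosine values are treated as ties. The scan statistic
is the minimum per-reference exact p over the grid (integer periods
20–28 h, phases every 2 h). Because a minimum over ~110 correlated
references is not a p-value, the reported raw p is the tail of that
minimum under the permutation null: exhaustive over all n! rank
orderings for n ≤ 8; otherwise 100 000 seeded rank permutations shared
by every distinct-valued gene (the null is distribution-free given the
design), with a linear-in-p chord through the 10th order statistic
below the Monte-Carlo resolution. Series with ties fall back to a
per-gene permutation null with midrank scoring. The default p follows
the original software's semantics — a Bonferroni across the gene set of
the *uncorrected* best-reference tail — floored at the raw p.

**Empirical scan (ejtk).** References are the 24 h cosine phases plus
linear sawtooths (asymmetries 2–22 h every 2 h, phases every 2 h) —
the grid the published empirical variant scans; the interpolation is
linear since the original's is unspecified. Raw p is the uncorrected
best-reference tail. The empirical p is the +1-corrected rank of the
raw p among n_permutations per-gene time permutations (batched through
one reference matmul per gene block); the default p is
min(empirical p, Bonferroni over references). Sharing one permutation
draw across genes was rejected: it leaks a common Monte-Carlo error
into every gene and visibly distorts the ensemble p-value distribution.

**Lomb–Scargle (ls).** Floating-mean (generalized) periodogram,
standard normalization, computed by least squares per frequency.
The frequency grid is the Fourier set k/T inside [1/max_period,
1/min_period] (T = span + median step) — typically one or two
frequencies for circadian designs — falling back to the band midpoint
if empty. Single-frequency null p = (1−z)^((N−3)/2) (exact for Gaussian
noise), Šidák-combined over the grid size M; with M this small the test
is essentially exact, so no attempt is made to reproduce the null
pathology real LS implementations show near p = 1. The pipeline feeds
methods log2 intensities, on which the generator's noise is Gaussian.

**Rank periodogram (rgc).** Ranks replace values; the periodogram at
the Fourier frequencies k = 1…⌊(n−1)/2⌋ gives Fisher's g. On ranks the
null of g depends only on n, so the p-value uses a seeded permutation
null (100 000 draws, shared across genes; per-gene draws under ties),
continued beyond its resolution by the analytic Fisher tail ratio. The
analytic Fisher formula alone is mildly anti-conservative on ranks
(it assumes Gaussian ordinates), which is why the permutation null is
the default. Requires a regular design with ≥ 6 samples; irregular
designs must be regularized or replicate-averaged first, as the guard
message says.

**Meta integration.** Fisher's −2Σln p over jtk+ls+rgc raw p-values.
The three statistics come from the same series, so the chi-square
reference is anti-conservative under the null — the known behaviour of
such combined methods; meta is therefore excluded from the calibration
experiment but included in power and benchmark comparisons.

**Brown's combination.** Probe-level p-values are combined with the
empirical Brown procedure: each probe vector is ecdf-uniformized
(ranks/(n+1)), transformed to −2 ln u, and the empirical covariance of
those variables rescales Fisher's statistic to a scaled chi-square
(c = Var/2E, df = 2E²/Var). Uncorrelated probes reduce to Fisher;
duplicated probes are not double-counted (c → 2, df → 2).

**Z-score normalization.** Each gene is shifted by the constant that
makes its mean equal its dataset-level Z-score ((m_i − m)/sd). The
published description of this transform has garbled subscripts; the
shift-only reading is the one consistent with its stated form and with
shape preservation, and rank-based statistics are invariant to it
(property-tested).

**Adjustments.** Bonferroni is min(1, n·p); BH is the step-up with
enforced monotonicity, tested against a literal brute-force definition
and against statsmodels.

## The benchmark

The benchmark set B is the species-2 side of the ortholog map called
rhythmic at default p ≤ 0.01 by a chosen method (the rank periodogram
by default, mirroring the practice of defining the set with a
well-calibrated detector). Proportion curves are computed per rank
(ties broken by raw p then gene id, so curves are deterministic), carry
the p ≤ 0.01 marker rank, and end exactly at the base rate |B|/n.
The Naive curve orders by descending median expression (ties by id).
The "crossing" where the Naive curve overtakes a method is the first
rank opening a run of ≥ 10 consecutive ranks with naive ≥ method — the
run-length rule is this package's convention for reading crossings off
noisy curves, with n+1 as the "never" sentinel and a crossing at rank 1
for identical curves. Under no conservation and no coupling, every
curve must stay inside the ±3 SD hypergeometric band of the base rate,
checked at deciles.

## Experiment sizes and determinism

The packaged experiments use 2000 genes for null calibration, 500
rhythmic genes per design for power, 2000 orthologs for the KS
contrast, and 1000 orthologs for the curve benchmark — sizes at which
the binomial/KS resolutions called for by the checks are comfortably
met while a full run stays within a few minutes on one CPU. Every
random stream (simulation, permutation nulls, shuffled controls,
down-sampling in the t-test) derives from a single seed via SHA-256
stage hashing, and the pipeline writes content-hashed manifests; two
runs with the same config produce byte-identical summaries.

## Known limitations

* The jtk scan null is Monte-Carlo beyond n = 8 samples; its deep tail
  relies on a linear continuation that is approximate (conservative in
  the union-bound regime) below ~1e-5.
* The empirical variant's default p mixes a discrete permutation rank
  (resolution 1/(B+1)) with a references-Bonferroni; with few
  permutations its power at stringent thresholds is resolution-limited.
* The generator's conservation model inherits shape and amplitude
  unchanged; real orthologs diverge in both.
* Detector comparisons concern detection only — amplitude, phase and
  precise period accuracy are out of scope.
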