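# rhythmbench

Statistics for detecting 24-hour (nycthemeral) rhythms in gene-expression
time series, and a benchmark that scores rhythm-detection methods by the
evolutionary conservation of the genes they call rhythmic — all exercised
end to end on a synthetic two-species transcriptome generator with known
ground truth.

## Who this is for

Chronobiologists and method developers who need to know how much to trust
a list of "rhythmic genes": how a detector's p-values behave under a true
null, how fast power is lost as time points or cycles are dropped, and
whether a detector finds *biologically relevant* rhythmicity — proxied
here, as in comparative transcriptomics, by one-to-one orthologs that are
rhythmic in the homologous tissue of a second species.

## What is implemented

Four native rhythm detectors, each returning a raw and a default
(software-style) p-value per gene:

* **jtk** — a Kendall-tau scan: the series is scored against cosine
  references cos(2π(t−φ)/T) on a period grid T = 20…28 h and phase grid
  φ every 2 h. Per reference, the concordance count is a
  Jonckheere–Terpstra statistic whose exact permutation null is built by
  an inversion-count dynamic programme (convolved Mann–Whitney nulls over
  the reference's tie groups). The gene-level raw p is the tail of the
  *scan minimum p* under the permutation null — exhaustive over all n!
  orderings for n ≤ 8 — so it stays uniform under the null despite the
  scan. The default p is the Bonferroni across the gene set of the
  uncorrected best-reference tail.
* **ls** — a floating-mean Lomb–Scargle periodogram with the standard
  normalization z = 1 − SS_res/SS_tot, evaluated at Fourier-spaced
  frequencies inside [1/28, 1/20] h⁻¹; single-frequency null
  p = (1−z)^((N−3)/2), Šidák-combined over the grid.
* **ejtk** — the empirical variant: the cosine scan is extended with
  asymmetric sawtooth references (rise fraction 2–22 h every 2 h at the
  24 h period). Its raw p is the *uncorrected* best-reference tail
  (left-skewed under the null by construction); the default p is
  min(empirical permutation p, Bonferroni over references), which
  restores calibration.
* **rgc** — a robust rank-based periodogram: Fisher's
  g = max_k I(ω_k)/Σ_k I(ω_k) on the periodogram of the ranks, with a
  distribution-free permutation null (Fisher's exact g tail continues it
  beyond the permutation resolution).

Plus a Fisher chi-square integration of jtk+ls+rgc (**meta**), the
pre-processing used around such methods (probe filters, the Z-score shift
normalization, empirical Brown combination of probe-level p-values,
quartile subsets, time-grid regularization, replicate reshaping),
p-value diagnostics (uniformity profiles, BH/Bonferroni, exclusive
upset-style overlaps, concordance, the rhythmic-vs-nonrhythmic expression
t-test), and the conservation benchmark:

* a **benchmark set** B of "rhythmic orthologs" — species-2 sides of the
  one-to-one ortholog map called rhythmic at default p ≤ 0.01;
* **proportion curves** — species-1 orthologs ranked by a method's
  p-values (or by median expression for the **Naive** baseline, which
  knows nothing about rhythm); at each rank N the curve is the fraction
  of the top N whose partner is in B;
* a two-sample **Kolmogorov–Smirnov** contrast of species-1 p-values
  between conserved and non-conserved orthologs.

The synthetic generator produces bimodal log-normal baselines, a
configurable rhythmic fraction with mixed waveforms (cosine / ramp /
peak / box) at 24 h, an optional logistic coupling of rhythmicity to
expression level, multiplicative log-normal noise, per-gene or global
time-label randomization for nulls, and two-species studies with
conserved rhythmicity (inheritance probability, phase jitter, correlated
baselines via a calibrated Gaussian copula).

## Worked example

```sh
python analysis/05_conservation_signal.py --seed 1 --n-orthologs 500
```

prints

```
benchmark set: 46 rhythmic orthologs (base rate 0.092)
conserved vs rest: D = 0.418, p = 4.14e-07, direction -1 (conserved enriched in small p)
label-shuffled control: D = 0.169, p = 0.162 (no signal)
```

Read: of 500 one-to-one orthologs, 46 are called rhythmic in species 2
by the rank periodogram at default p ≤ 0.01. Species-1 orthologs whose
partner is in that set have clearly smaller species-1 p-values than the
rest (KS D = 0.42, p ≈ 4e−7, shifted toward small p), while assigning
benchmark membership at random erases the signal — rhythmicity that is
conserved between species carries a real, detectable statistical signal.

The other drivers follow the same pattern: `02` checks p-value
uniformity on time-randomized data, `03` tabulates power loss across
sampling designs, `04` the between-method overlap of rhythmic calls,
and `06` the proportion-curve benchmark, where every method beats the
Naive expression ranking near the top of its ranking but is caught by it
at a finite rank — only genes with a strong rhythmic signal are called
better than by expression level alone.

There is also a one-shot pipeline CLI:

```sh
rhythmbench all --out out/ --seed 1
```

which simulates a species pair, runs the methods, and writes every
table, a content-hashed manifest, and a summary JSON.

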