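# Methods

This note documents the models implemented in plexquant, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Impurity correction

Isotopic impurities of an isobaric tag shift a known fraction of its
reporter signal into other channels. We model this with a row-stochastic
mixing matrix A: entry A[i, j] is the fraction of channel i's *true* signal
observed in channel j, rows summing to 1. The observed vector is therefore
y = Aᵀx, and correction solves for x.

Conventions and numerical choices:

- **Templates carry percentages** (matching vendor certificates of
  analysis); all internal arithmetic uses fractions. Destinations are named
  channels rather than ±1 mass offsets, so C-type vs N-type leakage
  (TMTpro 126 → 127C *and* 127N) is unambiguous.
- **Zero-channel reduction.** Channels with exactly zero observed intensity
  are deleted from y and from the rows and columns of A before solving;
  deleted channels are reported as zero. Only exact zeros trigger removal —
  tiny positive intensities are kept. The reduced sub-matrix is solved
  as-is, without re-normalizing its rows.
- **Solver.** The reduced Aᵀ is factorized by LU decomposition
  (`scipy.linalg.lu_factor`). Negative solution elements are clamped to 0.
  The batch API groups spectra by zero pattern so each pattern is factorized
  once.
- **Singular systems.** A singular reduced matrix (detected by a non-finite
  solution, since the LU routine does not raise) passes the raw values
  through unchanged with a logged warning. Spectra are never silently
  dropped: quantification completeness is preferred over data loss.

On diagonally dominant matrices (every realistic impurity certificate) the
round trip x → Aᵀx → correction recovers x to ≤1e-8 relative error; the
test suite checks this on random systems up to n = 16 against an
independent dense solve.

## Weighted-median normalization

For protein group g and sample channel c, collect over the group's PSMs in
that plex the ratios r_i = s_ic / ρ_i where ρ_i is the reference intensity
of PSM i, and report the weighted median of {r_i} with weights
w_i = (precursor intensity × fill time)^α.

- **Reference intensity.** `reference` mode: sum of the plex's reference
  channels. `all_sample_sum` mode: sum of the PSM's sample channels.
  Carrier and empty channels are excluded in both modes.
- **Isobaric weight exponent α** defaults to 1.0. No authoritative default
  exists for this parameter, so the natural choice (weights proportional to
  estimated ion counts) is used; α = 0 reproduces the unweighted median. A
  missing precursor intensity or fill time contributes a factor of 1 rather
  than discarding the PSM (logged).
- **Zero handling.** A PSM contributes to a cell only when both the sample
  intensity and the reference intensity are positive: ratios with zero
  denominators are undefined, and zero numerators would collapse the median
  to 0 under sparse channels.
- **Weighted-median tie rule.** The result is the smallest value whose
  cumulative weight reaches half the total; when the cumulative weight hits
  exactly half, the midpoint with the next order statistic is returned.
  This reduces to the ordinary even-count median convention whenever
  weights are equal, duplicated values included.
- **Output scale.** Cells are the weighted-median ratios themselves — the
  quantity the method defines. `min_psms` (default 1) ratios must survive
  for a cell to be reported; otherwise it is missing, not zero.
- **Summed roll-up.** The unnormalized alternative sums reporter
  intensities over all PSMs of a group per sample channel; fractions
  sharing an experiment name are summed together. Groups with no surviving
  PSMs are missing, not zero.

Because every cell is a within-spectrum ratio, multiplying all intensities
of one plex by any constant leaves the WM output unchanged — this is the
mechanism by which per-plex batch effects are removed.

## Batch-effect evaluation

- **PCA.** Complete protein rows only (imputation is deliberately out of
  scope), optional log2 transform, per-protein centering across samples,
  thin SVD. The sign of each component is fixed by making its
  largest-magnitude loading positive, so the embedding is deterministic.
  PCA is the only built-in embedder; t-SNE/UMAP coordinates computed
  elsewhere can be supplied as `sample/dim1/dim2` TSV files.
- **Wilks' lambda.** Λ = det(W)/det(W+B) from the pooled within-group (W)
  and between-group (B) scatter of the 2-D coordinates. The p-value uses
  Bartlett's chi-square approximation: −(N−1−(d+g)/2)·ln Λ ~ χ² with
  d(g−1) degrees of freedom (d = 2). Rao's F transformation would be an
  alternative; Bartlett was chosen for its simplicity at d = 2, and the
  approximation is accurate for the sample sizes involved (the null test in
  the suite draws 10,000 independent 60-sample clouds and checks p-value
  uniformity by Kolmogorov–Smirnov). A singular W is regularized with a
  ridge of 1e-12 × trace(W+B) and flagged in the result.
- **PC1 ANOVA score.** −log10 of the one-way fixed-effects ANOVA p-value of
  a grouping on the first principal coordinate; p-values that underflow to
  zero are reported as the cap 320 (the double-precision limit of
  −log10).

## The synthetic generator

The generator emulates three benchmark designs — a single-cell carrier
plex, a two-proteome spike-in series, and a two-species ratio-compression
design — with complete ground truth, so correctness can be asserted against
configured values rather than eyeballed.

Forward model per PSM:

1. protein abundance a ~ LogNormal(0, σ_ab) per protein, σ_ab = 2 natural-log
   units (a standard stand-in for proteome dynamic range);
2. true channel intensity x_c = a × (mixing amount of the protein's species
   in channel c's sample) × (per-plex batch factor);
3. co-isolation: with contamination fraction f, add f/(1−f) × a
   background-proteome reporter pattern scaled to the PSM's own total, and
   set the PSM's PIF to 1−f — so the precursor contributes exactly the PIF
   share of the isolation window. The background pattern follows the
   constant (human) species profile, which is what compresses species
   ratios toward zero;
4. impurity mixing y = Aᵀx with the configured correction factors;
5. multiplicative LogNormal(0, σ) noise per channel (reporter noise is
   treated as intensity-proportional; counting noise is out of scope);
6. precursor intensity ~ LogNormal(ln 1e6, 1), fill time ~ Uniform(5, 50) ms.

PSM counts per protein and plex are Poisson. Carrier channels carry
carrier_amount = carrier ratio × the single-sample amount; empty channels
carry nothing and receive only leakage (plus an optional additive noise
floor, default 0). A fixed seed reproduces every table byte-identically.

### Preset conditions

- **ds1_carrier** (TMTpro 16-plex, 1 plex): channel 126 carries a bulk human
  proteome at 434× the single-cell amount, 127C is empty, 14 equal
  single-cell sample channels; 300 proteins, Poisson-3 PSMs/protein,
  σ = 0.1. Impurities: same-type +1 leakage 4%, −1 leakage 1%, plus
  126 → 127N at 1% (the cross-type carrier-neighbor effect). At 434× even
  1% leakage multiplies the neighbor's signal several-fold; correction
  removes it, at the cost of amplified noise in the small remainder.
- **ds3_two_proteome** (TMT 11-plex, 2 plexes): constant 50-unit human
  background, yeast at 1/1.75/3/5.2/9 units (two replicates per plex),
  reference channel at 50 human + 3.9 yeast; 200 proteins/species,
  Poisson-5 PSMs/protein, σ = 0.1, per-plex batch factors drawn
  Uniform(0.25, 4).
- **ds5_phospho_ratios** (TMTpro 16-plex, 1 plex): human:yeast at
  100:0/100:6/100:9/100:12 in triplicate; the first channel and the three
  unused high channels are empty. Contamination: 30% of PSMs are clean,
  the rest draw f ~ Uniform(0, 0.6); background = human; 400
  proteins/species, Poisson-8 PSMs/protein, σ = 0.1. The sizes are a
  desk-scale stand-in for a phosphosite-level data set: large enough that
  the median yeast−human log2 difference moves smoothly with the PIF
  threshold.

### What the generator does not emulate

No peptide sequences, spectra, peaks, retention-time profiles, missed
identifications, FDR, FAIMS or MS3 paths; no protein-level missingness
structure beyond Poisson PSM sampling; noise is purely multiplicative
lognormal (no additive electronic noise, no detector saturation).
Consequently, passing tests demonstrate that the *algorithms* behave as
specified under their own model assumptions — exact inversion, exact
ratio cancellation, monotone filter response — not that real instrument
data meet those assumptions.

## Scale of the shipped analyses

The acceptance script and test suite run sub-minute analyses: 1,000 random
mixing systems (n up to 16), simulations of 2–16 thousand PSMs, and
10,000-draw null calibrations. These sizes were chosen as the smallest at
which the qualitative contrasts (batch dominance before normalization,
biology dominance after; leakage before correction, not after; ratio
compression easing with the PIF threshold) are stable across seeds.

## Known limitations

- Impurity correction after zero-channel reduction solves the sub-matrix
  as-is; whether re-normalizing the reduced rows would be preferable is
  design-dependent and was decided against to keep the reduced system
  faithful to the certificate.
- The Bartlett p-value is asymptotic; for very small sample counts
  (N ≲ 15) it is mildly anti-conservative.
- `all_sample_sum` normalization presumes each plex holds a roughly
  representative sample subset; with very few samples per plex the
  sum-of-samples reference becomes composition-sensitive and a pooled
  reference channel is the safer design.
- Corrected intensities are clamped at zero, which biases near-zero
  channels slightly upward relative to an unconstrained estimator; this is
  the price of non-negative reported intensities.
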