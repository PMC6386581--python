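# Methods

This note documents the models and estimators implemented in dilutionlab,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical choices that matter.

## Growth regimes and dilution arithmetic

**Model.** Cell volume in a prolonged G1 arrest follows a continuous
two-regime law: exponential growth dV/dt = k·V (specific rate k, units 1/h)
until the volume reaches a ceiling V\*·ploidy, then linear growth at the
constant rate the exponential had at the transition, dV/dt = k·V\*·ploidy.
The ceiling scales with genome copy number because biosynthetic capacity is
ultimately template-limited; the haploid default V\* = 200 fL and
k = 0.46/h describe newborn cells (V₀ = 30 fL) arrested for ~7 h.

**Fitting** (`fit_growth_regimes`) is a breakpoint grid search over interior
time points (leaving ≥ 3 points per segment). For each candidate t\*, the
exponential segment is fitted log-linearly on t ≤ t\* — log space stabilizes
the small-volume points — and the linear segment on t ≥ t\* is constrained
through the exponential's value at t\*, keeping the model continuous and
identifiable. Candidates are scored by total sum of squared error in *raw*
volume space, where the data live; the minimizer wins. Degenerate inputs
behave sensibly: a pure exponential selects the last candidate breakpoint, a
pure linear series the first. The fit is exactly invariant under rescaling
volume units (t\* unchanged, rates scale linearly).

**Dilution index** = content fold-change ÷ volume fold-change between two
times; 1 means content kept pace with volume, values below 1 quantify
dilution. Fold changes interpolate linearly between sampled time points.
Where a vacuole track is present, the caller chooses between total and
vacuole-excluded volume folds; both are exposed because the appropriate
denominator depends on whether the question is about total density or
cytoplasmic concentration.

**Density prediction** (`predict_density_drop`). The excess of cell density
over water is proportional to dry-mass concentration, so the relative
density decrease is the dry-mass-fraction-weighted sum of per-component
concentration drops: Σ_c fraction(c)·drop(c). Default fractions are protein
0.50, carbohydrate 0.30, RNA 0.10, other (lipids + inorganic) 0.07 — kept
as printed, deliberately *not* renormalized to 1, so the canonical worked
example (protein −53%, RNA −68%, rest unchanged) yields exactly
0.50·0.53 + 0.10·0.68 = 0.333, a 33% predicted drop. Components absent from
the drops map contribute zero.

## GEM nanoparticle rheology

**Model.** 40 nm GEM particles in cytoplasm are subdiffusive:
MSD(τ) = 4Kτ^α in 2-D with α < 1 and K in μm²/s^α. At short timescales
(< 100 ms) the curve is summarized by MSD(τ) = 4·D_eff·τ.

**Estimators.**
- `time_averaged_msd` uses all overlapping start frames (the standard
  time-average definition); pair counts per lag are recorded.
- `ensemble_msd` is an unweighted mean across tracks; curves of unequal
  length are averaged over the tracks that reach each lag.
- `fit_anomalous`: unweighted OLS of log₁₀MSD on log₁₀τ; α is the slope,
  K = 10^intercept/4.
- `fit_deff`: least squares through the origin on the first 10 lags
  (D_eff = Σmsd·τ / 4Στ²). The quoted linear relationship has no intercept,
  so the origin-constrained form is the default; an optional free intercept
  is exposed but off. A warning fires if the lags used extend past 0.1 s.
- `compare_deff`: group medians, percent change 100·(med_B/med_A − 1), and
  a two-sample Kolmogorov–Smirnov test (scipy).

**Presets.** `control` (K = 0.010 μm²/s^α, α = 0.9) and `treated`
(K = 0.013, α = 0.9) plant a D_eff ratio of exactly 1.3 — the ~30% diffusion
increase seen when an oversized senescent cytoplasm dilutes — for
self-contained end-to-end recovery tests. With 500 tracks × 100 frames per
condition the recovered median percent change lands within a few points of
30%.

**Frame interval.** The default dt = 0.01 s is an assumption (typical for
GEM imaging); set it explicitly when the acquisition rate is known.

## SMR density inference

Weighing one cell in two fluids gives m_b,i = V·(ρ − ρ_f,i), hence
V = (m_b1 − m_b2)/(ρ_f2 − ρ_f1), ρ = ρ_f1 + m_b1/V, m = ρV
(1 pg = 1 fL·g/mL). The inversion is exact and symmetric under swapping the
two measurements; because it is a linear map, Gaussian measurement noise
propagates without bias into volume. Equal buoyant masses leave V undefined
and raise; inferred V ≤ 0 is *flagged* (`CellPhysical.valid`), never
silently dropped — filtering is a caller decision. Excess-density
normalization (ρ − ρ_baseline)/(ρ_ref − ρ_baseline) uses a configurable
water baseline of 1.000 g/mL (no temperature correction applied).
`density_volume_profile` reports per-volume-bin median densities normalized
to the first (smallest-volume) bin, matching the convention of normalizing
to cells below a size cutoff.

## Spike-in transcriptomics

**fpkmCa** = count / (gene length in kb) / (spike reads in millions).
Because every sample contains the same number of spike (*C. albicans*)
cells, this unit is proportional to per-cell transcript abundance and makes
transcriptome *size* comparable across differently sized cells.

**Gene filter** (three steps, each count reported): protein-coding only;
expression floor log₂(fpkmCa + pseudocount) > 2; coefficient of variation
(sd/mean of the log₂ values) ≤ 0.5 across samples. Open choices made here:

- The expression floor is aggregated across samples by the **mean** by
  default; `min` (every sample) and `any` (at least one) are available as
  `expression_rule`, since which aggregation the canonical filter used is
  not stated and gene counts on real data are sensitive to it.
- CV is computed on log₂-transformed values (the scale annotation attaches
  to the CV step); genes whose mean log₂ ≤ 0 have an undefined CV and are
  excluded and counted separately.
- Default pseudocount 1 fpkmCa-unit before log₂; the worked three-gene
  example in the tests uses pseudocount 0 to match hand arithmetic.

**Scaling analysis**: per gene, fold = expression ratio to a reference
sample, expected fold = volume ratio, scaling ratio = fold/expected;
a gene "scales" when |log₂ scaling ratio| ≤ log₂(1 + tolerance)
(default tolerance 0.3). Volumes are vacuole-excluded cell volumes supplied
per sample.

## Enrichment

**Preranked GSEA.** Genes ranked by log₂ pooled ratio (early vs late sample
pools) or signal-to-noise ((μA−μB)/(σA+σB), σ floored at 0.2·|μ| per the
standard convention). The ES is the maximum signed deviation of the
weighted running sum: hits add |metric|^p normalized to sum 1 (p = 1
default), misses subtract 1/(N − n_set); |ES| ≤ 1 by construction, and
p = 0 reduces to the unweighted Kolmogorov–Smirnov statistic.
Significance is by **gene-set permutation**: n_perm random same-size sets
drawn uniformly from the universe. NES = ES / mean(|ES_perm| of the same
sign); the nominal p is the same-sign tail fraction; FDR q compares the
pooled normalized null tail with the observed NES tail (positive and
negative scores separately), clipped to [0, 1]. Ties in the ranking are
broken by gene id for determinism.

**ssGSEA.** Per sample, genes are rank-normalized (top gene → 1, bottom →
1/N) and the score integrates the difference between the weighted ECDF of
set members (rank^0.25 weighting, the convention of the single-sample
projection method; the exponent is configurable) and the uniform ECDF of
non-members over the whole list. Row-centering subtracts the across-sample
mean, turning scores into relative deviations along a time course.

## Induction kinetics

Two-step correction: subtract the per-frame field background (measured in
empty positions), then the mean of the cell's first 3 (configurable)
corrected frames — the pre-induction window — which removes per-cell
autofluorescence. The correction is idempotent and affects neither rates
nor amplitudes, only baselines. Induction rate is the OLS slope over the
linear rise; because choosing that window by eye is not reproducible, the
`auto` mode scans every contiguous window of length ≥ max(3, 20% of frames)
with positive slope and returns the R²-maximizing one (ties: longest, then
earliest). A trace with no positive-slope window reports rate 0 with an
explicit flag. Amplitude = max − min of the corrected trace; the induced
fraction is the share of cells with amplitude above a threshold.

## Synthetic generators

All generators are pure functions of their parameter record (seed
included), so every simulated dataset is exactly reproducible.

- **Growth**: closed-form piecewise trajectories; protein and RNA content
  follow the same law with their ceiling multiplied by
  `content_cap_factor` — a factor < 1 is the smallest parameterization that
  produces content–volume divergence (dilution) without committing to a
  mechanistic transcription model. Noise is multiplicative lognormal with
  the requested CV, mean-corrected so it is bias-free.
- **GEM tracks**: exact fractional Gaussian noise per coordinate via
  Davies–Harte circulant embedding (full-covariance Cholesky fallback for
  embeddings that are not non-negative definite), cumulated so a noiseless
  track has per-coordinate MSD 2Kτ^α; optional i.i.d. Gaussian localization
  error per frame, which adds ≈ 4σ² to every lag of the 2-D MSD.
- **Spike-in counts**: per-gene baseline abundances lognormal (median 20
  fpkmCa, log-sd 1, spanning the realistic expression range); a
  `frac_scaling` fraction of genes has expected abundance proportional to
  the sample volume factor, the rest constant; ESR-induced/-repressed
  member genes shift ×4 / ×¼ (log₂ ± 2) in the late half of the samples;
  gene lengths uniform on 0.5–5 kb (typical ORF range); counts negative
  binomial with variance μ + dispersion·μ² (Poisson at dispersion 0); spike
  totals constant per sample by design.
- **Buoyant pairs** and **induction traces**: direct forward models of the
  equations above, with Gaussian measurement noise, a deterministic slow
  background drift, and per-cell autofluorescence drawn uniformly ±50%
  around the nominal level.

What the generators do **not** emulate: imaging artifacts (motion blur,
tracking errors, track fragmentation), mappability and GC bias in counts,
library-preparation batch effects, correlated gene programs beyond the
planted ESR shift, cell-to-cell growth-parameter variability, and fluid
exchange artifacts in the SMR. Passing recovery tests therefore shows the
estimators are correct for data satisfying the stated models, not that they
are robust to every failure mode of real instruments.

## Problem sizes and numerical choices

End-to-end stochastic checks use 500 tracks × 100 frames per condition for
the GEM pipeline, 50 replicate trajectories for growth-transition recovery,
2000 genes for count simulations, and 10⁴ draws for the SMR inversion
property — sizes at which the Monte-Carlo error of the checked medians is
several times smaller than the tolerances asserted. OLS fits use closed
forms or `numpy.polyfit`; the KS test comes from scipy. The breakpoint grid
search is O(n²) in time points and exact within its grid (resolution = the
sampling interval); no continuous breakpoint refinement is attempted.

## Known limitations

- `fit_deff` does not correct for static/dynamic localization error; with
  localization noise present, the intercept it ignores biases D_eff
  upward. The optional free-intercept fit is a partial mitigation.
- The regime fitter assumes a single transition; trajectories with more
  than two regimes will be forced into the nearest two-regime description.
- FDR estimates from gene-set permutation are anti-conservative when gene
  sets are strongly internally correlated, an intrinsic property of the
  random-set null.
- The ssGSEA exponent and the GSEA weight are conventions, not fitted
  quantities; scores are comparable only within a fixed choice.
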