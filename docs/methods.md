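# Methods

This note records the models, algorithms and numerical choices behind
`specselect`, the defaults that matter, and what the synthetic benchmark
does and does not demonstrate.

## PLS1 core

The calibration model is single-response partial least squares: the
centered spectra matrix is decomposed as `X = T P' + E` with scores `T`
chosen to maximise covariance with the response, and predictions follow
the regression form `ŷ = (X − x̄) B + ȳ`. Components are extracted by
NIPALS with deflation of `X` only. For one response the NIPALS inner loop
converges in a single pass — the weight vector is `X'y` up to
normalisation — so each component is computed directly; there is no
iteration tolerance to tune. Coefficients for every nested model
(1..c components) come from the rotation `r_a = w_a − Σ_{b<a}(p_b'w_a) r_b`,
`B_c = R_{:,1..c} q_{1..c}`, which the cross-validation loops exploit to
evaluate all component counts from one fit.

Degenerate cases: a response with zero covariance against every column
yields the zero-coefficient model (predict the mean) rather than an error;
a rank-deficient `X` raises a fit error in `fit_pls`, while the
cross-validation helpers (`press_curve`, `mwpls`) cap the component count
at the effective rank of each calibration subset and repeat the last
attainable coefficient vector — past the rank the model cannot change, so
the recorded curve is flat rather than missing.

Mean-centering is always on. Unit-variance scaling is applied only where a
method requires comparable coefficient magnitudes: the β score is computed
from standardized refits. EUV refits are centered-only: the reliability
ratio mean/sd is invariant to column scale, and autoscaling would inflate
the deliberately tiny artificial columns to unit variance, letting them
perturb the very fit they are meant to leave untouched.

## Validation

All resampling uses the block-stratified scheme: samples sorted by
concentration (ties broken by original index), split into `n_v` contiguous
blocks whose sizes differ by at most one (larger blocks first), one sample
drawn uniformly per block. The pooled Monte Carlo RMSECV is
`sqrt(SSE_val / (N·n_v))`; per-iteration mean squared calibration and
validation errors are retained. Every refit re-centers (and, if scaling,
re-scales) on its own calibration subset, so no statistics leak from
held-out samples. The latent-variable count is the first point on a PRESS
curve whose relative improvement to the next count falls strictly below
`rel_tol` (default 0.02); the curve is evaluated on splits shared across
component counts so it is comparable point to point.

In the comparison workflow the test set (default 8 samples) is split off
first and never enters selection. For the RMSECV stage the default scope
is the full dataset (calibration size `n − n_v`), with
`mccv_scope="train"` available to confine cross-validation to the training
samples as well; the default matches the convention of validating reduced
models on all available non-test mechanics while the stricter scope suits
leakage audits.

## Selection methods

**β** (`beta_importance`) — score `|b′ᵢ|` from one standardized fit
(`N=1`, the plain method) or the mean over `N` MCCV refits; mask = scores
at or above the 0.8 quantile (top 20 %), the quantile being configurable
because no absolute coefficient threshold generalises across datasets.

**EUV** (`euv_select`) — append `min(p, 300)` uniform random columns with
amplitude `1e−3 × median |X|` (small enough not to perturb the fit, present
in every resample), estimate reliabilities over leave-one-out refits
(or MCCV), and keep real wavelengths with `|cᵢ| > max |c_artif|`. The
cutoff construction guarantees artificial columns are never selected; by
design the method reports, rather than formally tests, significance.

**iPLS / FS-iPLS** (`ipls`, `fs_ipls`) — `k` equidistant intervals (sizes
differ by ≤ 1, larger first), each scored by RMSECV on splits shared
across intervals; ties break to the lower start index. Forward selection
adds the interval minimising combined-model RMSECV and stops when the
relative improvement drops below 0.5 % (a stop rule needed because chance
improvements at finite `N` would otherwise grow the model indefinitely) or
at `max_intervals`. Micro-optimisation hill-climbs interval edges — moves
in the order expand-left, expand-right, truncate-left, truncate-right,
first improving move accepted — on the same fixed splits, so the returned
interval is never worse than the input; `one_sided` mode locks onto the
edge of the first accepted move.

**MWPLS** (`mwpls`) — an odd-length window (default 31 wavelengths) slides
one position at a time; training SSR is recorded for 1..c_max components.
The informative-region criterion is qualitative in origin, so region
extraction is a separate deterministic helper (`mwpls_select`): centers
whose SSR at a reference component count falls below a fraction (default
0.5) of the median across windows.

**GA** (`run_ga`, `ensemble_ga`) — bit-string chromosomes over
wavelengths; unfitness = mean calibration MSE over `fitness_mccv_iters`
(default 100) block-stratified splits of the evolution set. Three
anti-overfitting layers: a per-run block-stratified holdout (default 5
samples) whose RMSEV is used exactly once to accept or discard the run
(threshold 1.5× the all-wavelength model's holdout RMSEV, same component
count); resampled fitness; and an ensemble of (default) 100 runs from
`SeedSequence`-spawned child seeds, so results are independent of
execution order. Operators: tournament selection of size 2, uniform
crossover at rate 0.9, per-bit mutation 1/p (elites exempt), elitism 1,
population 64. Fitness splits are drawn once per run and shared by every
chromosome and generation: fitness values are then directly comparable
within a run, the run is deterministic, and caching makes elites free to
re-evaluate. The per-generation holdout-RMSEV history is recorded for
diagnostics only; it never influences evolution, preserving the
use-once semantics of the holdout.

Initialisation density is 0.05. With an MSEC-only objective (parsimony
terms are deliberately out of scope) the pressure to drop useless
wavelengths is a weak per-bit gradient; a population initialised at half
density stays near half density within realistic generation budgets, and
the ensemble selection probability then cannot separate informative bands
from background. Sparse initialisation — the standard GA-PLS remedy —
starts chromosomes at ~5 % density (≈ 150 of 3151 wavelengths at full
scale, the order of the final selected sets this method class reports) and
lets the fitness decide which additions survive.

`H = GᵀG` is computed in integer arithmetic from accepted runs only;
`P_GA = diag(H) / n_accepted` by default, with the total-run denominator
available because discarded-run handling is a genuine ambiguity — both
counts are recorded in every result. The synchronous 2D correlation
spectrum `Φ = X̃'X̃/(n−1)` is provided as the model-free comparison surface
for `H`.

## Synthetic data

`generate` produces `absorbance = background + concentration × analyte +
drift + noise`: Gaussian bands for both background (solvent/buffer, fixed)
and analyte (amplitude exactly linear in concentration, per Beer-Lambert),
a smooth random cubic baseline per sample, and iid Gaussian noise. The
default full-scale design mirrors a 47-sample aqueous calibration series:
the 0–18 mmol/L grid (0.25 steps to 5, then 0.5 steps), 850–4000 cm⁻¹ at
1 cm⁻¹ (p = 3151), analyte bands in the fingerprint region
(1125, 1215 cm⁻¹) plus a weak high-wavenumber band (3505 cm⁻¹), dominant
water/buffer bands (≈ 0.9–1.2 AU), noise 2e−4 AU and drift 5e−4 AU —
instrument-plausible magnitudes for ATR-FTIR of dilute aqueous solutes.
The ground-truth mask marks wavelengths within 2 Gaussian widths of an
analyte band center (≈ 95 % of band energy, ~5 % of the axis).

The reduced benchmark (`reduced_benchmark_config`) keeps two fingerprint
bands on a p = 301 axis and raises the noise to 2e−3 AU (peak SNR ≈ 13).
That choice makes the truth mask self-consistent: at instrument-level
noise the Gaussian shoulders at 2–3 widths still carry recoverable signal,
so selection methods legitimately pick wavelengths just outside the mask
and any precision measured against it is biased low; at SNR ≈ 13 the band
tails meet the noise floor right at the mask boundary.

What the generator does not emulate: ATR penetration-depth dispersion,
water-vapor lines, band-shape asymmetry, correlated (pink) noise,
matrix effects or interfering absorbers. Passing recovery tests therefore
show that the estimators find concentration-correlated bands under clean
Beer-Lambert structure — not that they survive the confounders of serum
or whole-blood spectra.

## Benchmark scales and determinism

Test-suite and acceptance-script runs use reduced problem sizes chosen as
the smallest that still exercise the full mechanics: p = 301 spectra
axis, GA ensembles of 10 runs × 30 generations × 20 fitness-MCCV
iterations, comparison MCCV at 500–2000 iterations. Full-scale defaults
(100 runs, 100 generations, 100 fitness iterations, 10 000-iteration
MCCV) remain the package defaults. Every stochastic step takes an explicit
seed; ensembles spawn child seeds with `numpy.random.SeedSequence`, so
identical configurations are bit-identical regardless of evaluation
order. A 10-run ensemble's precision against ground truth fluctuates
noticeably across seeds (roughly 0.5–0.9 on the benchmark) — the 100-run
default exists precisely to stabilise `P_GA`.

## Known limitations

- Single analyte only (PLS1); multi-response calibration is out of scope.
- The GA objective is mean MSEC alone; parsimony- or MSEV-augmented
  objectives are not implemented.
- MWPLS region extraction is a thresholding convenience, not a calibrated
  statistic.
- `micro_optimize` is a local hill-climb; it inherits the usual local-
  minimum caveats.
- CSV is the only supported spectra format (no instrument formats), with
  values printed at 10 significant digits.
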