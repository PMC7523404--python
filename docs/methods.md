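# Methods

## Model

A qPCR assay with per-cycle amplification factor E that crosses the
detection threshold at cycle Cq started from an amount of template
proportional to E^−Cq.  Taking base-10 logs gives the efficiency-weighted
cycle value Cq⁽ʷ⁾ = log₁₀(E)·Cq, which places assays with different
efficiencies on one common log scale.  The base is fixed at 10 throughout
the package and is not configurable: a mixed-base pipeline silently corrupts
every downstream ratio, and a single fixed base makes Cq⁽ʷ⁾, ΔCq⁽ʷ⁾ and
log-transformed covariates directly comparable.

Normalization subtracts the arithmetic mean of the reference genes'
weighted values within the same sample (arithmetic, not geometric: the
values are already logs).  The result, ΔCq⁽ʷ⁾, is an ordinary per-sample
real number: higher means lower expression of the gene of interest.  A
difference of two ΔCq⁽ʷ⁾ values back-transforms to a relative expression
ratio R = 10^(−ΔΔCq⁽ʷ⁾).

Technical replicates are assumed to be collapsed (averaged) into one
(sample, gene) record before import; the package does not impose a
replicate-averaging policy.

## Regression and CI propagation

`fit_ols` is simple least squares (delegating to `scipy.stats.linregress`)
with the textbook slope inference: se(m) from the unbiased residual
variance (divisor n−2), t-based CI on n−2 df, two-sided p for m = 0.  The
slope SE is recomputed from the residual sum of squares directly so that
exactly collinear or constant responses yield se = 0 (and a degenerate CI)
rather than NaN.  The fit records the observed x range and mean so that
baseline selection and extrapolation guards never re-read the raw data.

The central design decision is that **all prediction intervals are
propagated from the slope CI alone**.  Once the baseline x₀ is fixed, a
predicted ΔΔCq⁽ʷ⁾ = m(x − x₀) has the slope as its only random element;
intercept and prediction variance are deliberately not added.  The
resulting band is a confidence band for the *relative* prediction anchored
at the baseline, which is why it collapses to a point exactly at x₀.  The
two candidate endpoints (from L and U) swap order as the input crosses the
baseline; the implementation orders them pointwise with min/max, which
handles all five cases uniformly.

### Baseline

The baseline is the fixed comparison point: R(x₀) = 1 by construction.
Policies: `mean` (default — smallest and most symmetric bands, since band
width grows with |x − x₀|), `min`, `max`, or `custom` (must lie inside the
observed range; comparing against a never-observed point is
extrapolation).  For case D the baseline lives on the raw scale while the
fit lives on log₁₀(x), so `choose_baseline` accepts the raw values
explicitly.  Baseline statistics are kept at full float precision; the
bundled worked datasets print baselines rounded to 3 decimals, which is why
table-comparison tests carry a ±0.01 tolerance on ratio columns.

### Extrapolation and null slopes

Evaluation outside the observed x range raises by default and warns under
an explicit `allow_extrapolation=True`.  A slope not significantly
different from zero does *not* silently flatten the curve: the fitted curve
is returned with `null_slope=True`, and `null_as_unity=True` opts into
reporting the constant R̂ = 1 (the convention for "no evidence of an
effect").  Destroying the fitted curve by default would hide information;
the flag keeps the choice explicit and auditable.

### Log-transformed cases

Cases D and E log-transform x or y internally from the raw values at full
precision.  Re-deriving the fit from a rounded printed log column shifts
the slope in the third decimal (e.g. 7.882 vs 7.878 on the larval-length
data), so raw-scale input is the only supported interface.

## ANCOVA

One-way ANCOVA on ΔCq⁽ʷ⁾ with a quantitative covariate, k ≥ 2 groups:

1. **Separate slopes** per group (screen: if no slope differs from zero,
   the covariate can be dropped and plain ANOVA used — reported as a note).
2. **Homogeneity of slopes** as an extra-sum-of-squares F test between the
   separate-slopes model (2k parameters) and the common-slope model (k+1
   parameters), F on (k−1, n−2k) df.  This generalizes the
   coefficient-wise interaction test to any k and is verified against the
   statsmodels GLM in the test suite.  When the full model is saturated
   (noise-free groups), the test degenerates gracefully: F = 0/p = 1 for
   perfectly parallel lines, F = ∞/p = 0 otherwise, with the zero-RSS
   threshold taken relative to the response's own scale.
3. **Common slope** by pooling: m = Σ_g Sxy_g / Σ_g Sxx_g (equivalently the
   Sxx-weighted mean of per-group slopes); b_g = ȳ_g − m·x̄_g; MSE on
   n−(k+1) df.  If step 2 rejects at α (default 0.05) the fit *refuses*
   with the interaction test attached; `force=True` overrides with a
   warning, mainly so heterogeneous fixtures remain analyzable.

A contrast between groups i and j is diff = b_i − b_j, a ΔΔCq⁽ʷ⁾, with the
standard adjusted-means variance

    SE² = MSE·(1/n_i + 1/n_j + (x̄_i − x̄_j)²/Sxx_pooled)

which collapses to MSE·(1/n_i + 1/n_j) for shared covariate designs.  The
t interval (L, U) back-transforms to the ratio interval
(10^−U, 10^−L) — the endpoint order flips under the negative exponent.
Pairwise comparisons are unadjusted by default (Fisher-LSD style), with
Bonferroni and Sidak corrections (of both the interval level and the
p-value, for k(k−1)/2 comparisons) as options.  Tukey HSD is out of scope:
it needs studentized-range quantiles and the choice of contrast family is
left to the analyst.  The covariate is used as supplied — centering is
unnecessary because contrasts depend only on intercept differences of
parallel lines.

## Synthetic data

`SyntheticSpec`/`generate` draw datasets of the same shapes as the bundled
worked examples, with known parameters, from numpy's PCG64
(`default_rng(seed)`); the same spec always yields the same dataset.
Defaults emulate the hormone study: n = 10 samples on an even grid over
8.7–10.9 pg/mL, slope −0.139 ΔCq⁽ʷ⁾ per pg/mL, intercept 1.83, Gaussian
noise with SD 0.021 (the residual scatter implied by that dataset's slope
CI).  Coverage batteries instead use SD 0.064, which puts r² near 0.7 —
a deliberately noisy regime where interval calibration is informative.
ANCOVA simulations use the diet-study conditions: 3 groups × 8 points over
22–36 °C, slope 0.033, residual SD 0.0275.

What the generator emulates: a single linear (or log-linear) trend with
homoscedastic Gaussian noise and a fixed covariate grid — exactly the
assumptions of the model.  What it does not emulate: plate/batch effects,
heteroscedastic Cq noise, efficiency mis-estimation, or non-linear trends.
Passing coverage tests therefore demonstrates that the interval arithmetic
is calibrated *under the model's own assumptions*, not that real qPCR data
meet those assumptions.

## Numerical and interface choices

- Validation: Cq must be positive; efficiency ≤ 1.2 is rejected with a
  percentage-conversion hint (E = 1 + pct/100), since amplification factors
  below 1.2 are almost always percentage-style input, and E ≤ 1 is
  physically meaningless.  E > 2.2 (beyond perfect doubling plus margin)
  warns at the API level; the strict file reader turns it into a
  row-naming error, on the principle that files are imported unattended
  while API callers can inspect warnings.
- Full float precision everywhere in memory; rounding (default 3 decimals)
  happens only in writers.
- Range checks use a 1e−9 relative slack so observed endpoints never trip
  the extrapolation guard through round-off.
- Output tables are deterministic: identical inputs and configuration give
  byte-identical files (timestamps appear only in logs).
- Test problem sizes: coverage batteries run 2000 replicates per setting
  at n = 10 (slope CIs) and 3×8 (contrast CIs), enough to resolve the
  0.95 ± 0.02 acceptance band with binomial SE ≈ 0.005.

## Known limitations

- Single covariate, one-way designs only; no multi-way ANCOVA, random
  effects, or multi-plate batch modeling.
- No efficiency estimation from raw fluorescence curves; E is an input.
- Doubly-exponential/doubly-logarithmic response shapes (log-transforming
  ΔCq⁽ʷ⁾ itself) are not implemented.
- OLS assumptions (linearity, homoscedasticity, independence, normality)
  are the caller's responsibility; the package reports r² and the slope
  test but performs no diagnostics.
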