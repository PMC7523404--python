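# commonbase

Relative-expression analysis for qPCR experiments under the general linear
model: efficiency-weighted ΔCq computation, regression→expression transforms
with confidence intervals, and ANCOVA with pairwise expression contrasts.

## The problem

Classical qPCR analyses (2^−ΔΔCq and its efficiency-corrected variants) were
built for *paired* designs: treatment A vs treatment B, before vs after.
Many experiments are not paired — expression varies along a measured
covariate (hormone level, cell density, temperature), or is itself the
manipulated variable, or must be compared between groups while controlling
for a covariate.  The common base method handles these designs by keeping
every measurement on a single base-10 log scale:

    Cq⁽ʷ⁾ = log₁₀(E) · Cq                       (efficiency weighting)
    ΔCq⁽ʷ⁾ = Cq⁽ʷ⁾_GOI − mean(Cq⁽ʷ⁾_REF_i)      (reference normalization)
    R = 10^(−ΔΔCq⁽ʷ⁾)                           (expression ratio)

where E is the per-cycle amplification factor (perfect doubling = 2.0), GOI
the gene of interest and REF the reference gene(s).  Because ΔCq⁽ʷ⁾ values
are ordinary per-sample numbers, they drop straight into linear regression
and ANCOVA; this package supplies the back-transformations that turn a
fitted line y = mx + b into expression ratios with confidence intervals.

Five functional configurations are covered:

| case | fitted relationship            | back-transform                 |
|------|--------------------------------|--------------------------------|
| A    | ΔCq⁽ʷ⁾ = m·x + b               | R̂(x) = 10^{m(x₀−x)}            |
| B    | y = m·ΔCq⁽ʷ⁾ + b               | ŷ(R) = ŷ₀ − m·log₁₀R           |
| C    | ΔCq⁽ʷ⁾_B = m·ΔCq⁽ʷ⁾_A + b      | R̂_B = R_A^m                    |
| D    | ΔCq⁽ʷ⁾ = m·log₁₀(x) + b        | R̂(x) = (x₀/x)^m                |
| E    | log₁₀(y) = m·ΔCq⁽ʷ⁾ + b        | ŷ(R) = ŷ₀·R^{−m}               |

All confidence intervals are propagated from the slope CI (L, U) alone —
after fixing the baseline x₀, the slope is the only random element in a
predicted ΔΔCq⁽ʷ⁾.  For grouped designs, a one-way ANCOVA tests homogeneity
of slopes (treatment×covariate interaction), enforces a common slope, and
converts intercept differences b_i − b_j into between-group expression
ratios R̂ = 10^{−(b_i−b_j)} with t-based intervals.

## Worked example

Ten plants with measured hormone concentration and ΔCq⁽ʷ⁾ of a gene
(embedded dataset 1):

```python
from commonbase import case_a_curve, choose_baseline, fit_ols, example_table

data = example_table(1)
fit = fit_ols(data["hormone_pg_ml"], data["delta_cq_w"])
baseline = choose_baseline(fit)          # mean hormone concentration
curve = case_a_curve(fit, baseline, [8.85, baseline.x0, 10.5])
```

Running `python examples/expression_from_hormone.py` prints:

```
slope m = -0.1394 dCq(w) per pg/mL, 95% CI (-0.1617, -0.1171), r2 = 0.963
baseline x0 = 9.85 pg/mL (policy: mean)
x =  8.85 pg/mL  R = 0.725  95% CI (0.689, 0.764)
x =  9.85 pg/mL  R = 1.000  95% CI (1.000, 1.000)
x = 10.50 pg/mL  R = 1.232  95% CI (1.192, 1.274)
```

A plant at 8.85 pg/mL is predicted to express the gene at 73% of the level
of a plant at the average concentration (95% CI 69–76%); at the baseline
itself the ratio is exactly 1 with a degenerate interval, as it must be.
The other examples (`response_from_expression.py`,
`ancova_diet_contrasts.py`, `weighting_wells.py`) walk through cases B/E,
the ANCOVA pipeline, and raw-well weighting.

## Command line

The same pipeline is exposed as a thin CLI:

```sh
commonbase tables --id 1 --out t1.csv          # emit an embedded dataset
commonbase regress --mode A --in t1.csv --baseline mean --at 8.85
commonbase ancova --in t8.csv                  # exit 2 if slopes differ
commonbase weight --in wells.csv               # wells -> per-sample dCq(w)
commonbase simulate --mode A --seed 42 --n 10  # synthetic dataset
```

Input is comma-separated with a header; output is tab-separated with a
`#`-prefixed metadata header.  Exit codes: 0 success, 1 validation error,
2 statistical refusal (heterogeneous slopes without `--force`).

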