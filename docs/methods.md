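# Methods

## The measurement problem

Histological sections of lung read as a web of dark alveolar walls on a
bright field. Pathologies such as hemorrhage, edema or interstitial
pneumonia simplify that web: hemorrhage floods alveolar lumens, edema
levels wall contours. `fractmorph` quantifies this as a change in the
*scaling structure* of the binary contour pattern, via two complementary
statistics: lacunarity (gappiness as a function of scale) and the
box-counting singularity spectrum f(α) (the distribution of local scaling
exponents). Both are computed on a preprocessed contour image, never on the
raw micrograph, because staining artifacts dominate raw-pixel statistics.

## Preprocessing model

1. **Luminance.** RGB input is reduced with BT.601 weights
   (0.299, 0.587, 0.114); a pure red pixel maps to 76. The weights are
   pinned by a regression test so results are stable across releases.
2. **Binarization.** Foreground = intensity ≤ threshold, default **220**.
   The inclusive "≤" and the dark-is-foreground polarity ensure the
   near-white field (≈255) never enters the measure.
3. **Outline.** A foreground pixel survives iff one of its 4-neighbours is
   background; the image border counts as background. A ring-shaped
   alveolus therefore yields two closed curves — the "double linear
   contour".
4. **Skeletonization.** scikit-image 2-D thinning iterated to a fixed
   point, so the operation is idempotent and the result is a unit-width,
   topology-preserving curve set.

Any stage can be the analysis endpoint (`stop_stage`); the default is the
skeleton. Whether the outline or the skeleton is the better spectrum
substrate for real sections is an open measurement question — on the
synthetic patterns below the two give nearly identical spectra, and the
pipeline exposes both.

## Lacunarity

For grid cell side `s` (default ladder 1–60 px), a single grid anchored at
the top-left corner tiles the binary image; partial cells at the right and
bottom edges are discarded. With per-cell foreground counts having mean μ
and *population* standard deviation σ (empty cells included),

    L(s) = (σ/μ)² + 1.

The `+1` is a plotting convention that makes homogeneous patterns read
exactly 1; the raw (σ/μ)² is exposed as `cv2`. Cell sizes are normalized
as ε = s / max(H, W). The curve is summarized over the window
ε ∈ [0.01, 0.6] by the OLS slope of log₁₀ L on log₁₀ ε and by min/max L.
Log–log axes are the standard choice for a scaling exponent; the summary
records the fit R² so a non-power-law curve is visible as such.

Closed-form check: for i.i.d. Bernoulli(p) pixels, per-cell counts are
Binomial(s², p), so E[L(s)] ≈ 1 + (1−p)/(p s²); the suite verifies this
within three standard errors over 20 seeds for p ∈ {0.2, 0.5, 0.8},
s ∈ {2, 4, 8}.

## Multifractal estimators

The contour lifts to a measure with unit mass per foreground pixel (any
nonnegative 2-D field is accepted; all estimates are invariant to a global
mass rescaling). For each box side `s` in a ladder (default: powers of 2
from 2 to min(H, W)/4), a fixed grid anchored at (0, 0) partitions the
field; partial edge boxes are discarded, the retained mass is renormalized,
and empty boxes dropped, giving fractions p_i(ε) with ε = s / max(H, W).

* **Mass exponents.** τ(q) is the OLS slope of log Z(q, ε) on log ε with
  Z = Σ p_i^q, per q on the default grid −5…+5 step 0.25. τ(1) = 0 is an
  algebraic identity of any normalized partition and is set exactly; the
  per-q fit R² is recorded.
* **Generalized dimensions.** D(q) = τ(q)/(q−1) for q ≠ 1; D(1) comes from
  the entropy scaling Σ p_i log p_i ~ D(1) log ε (the L'Hôpital limit),
  never from the generic ratio.
* **Singularity spectrum.** The direct moment-weighted (Chhabra–Jensen)
  method: with μ_i(q, ε) = p_i^q / Z, α(q) is the slope of Σ μ_i log p_i
  and f(q) the slope of Σ μ_i log μ_i against log ε. This avoids
  numerically differentiating a noisy τ(q); the Legendre relation
  f = qα − τ is kept as a cross-check invariant. All partition sums are
  evaluated in log space (logsumexp), so q = −5 on fields with box masses
  down to 10⁻⁷ stays finite.

Optionally the partition statistics are averaged over G random grid
origins (seeded) before the regressions; the default is a single (0, 0)
grid — determinism first, offset averaging as documented variance
reduction.

**Monofractality test.** A field is called monofractal iff a single global
line fits τ(q) with R² ≥ 0.999 *and* the spectrum width α_max − α_min over
the q-grid is ≤ 0.15. Both thresholds are exposed; the defaults separate
the exactly-linear oracles (uniform field, Sierpinski carpet, widths
≈ 10⁻¹⁵) from the test cascade (width ≈ 1.86) by orders of magnitude, so
classification is not threshold-sensitive for the validated cases.

## Spectrum descriptors

With α₀ = α(0) and the branch ends read at the q-grid extremes
(q = −5 → α_max, rarefied regions; q = +5 → α_min, dense regions):

| descriptor | definition |
|---|---|
| width | α_max − α_min |
| height | f(α₀) (= capacity dimension of the support) |
| right width / height | α_max − α₀, f(α₀) − f(α_max) |
| left width / height | α₀ − α_min, f(α₀) − f(α_min) |

`width = left_width + right_width` holds exactly by construction. Because
the ends are grid values, not q → ±∞ extrapolations, descriptors are
comparable only across runs with identical q-grids; the comparison API
enforces this. A comparison reports signed deltas (test − reference) and a
`left_shifted` flag (α₀ decreased); no statistical inference is attempted.

## Synthetic ground truth

* **Binomial cascade** (weights w, default (0.4, 0.3, 0.2, 0.1), depth 7 →
  128²): recursive quadrant mass multiplication. On dyadic ladders the
  partition function is exactly (Σ w_i^q)^k, so the estimators must
  reproduce τ(q) = −log₂ Σ w_i^q, D(1) = Σ w_i log₂(1/w_i) ≈ 1.846 and
  α(q) = Σ w_i^q log₂(1/w_i)/Σ w_i^q to numerical precision — and do.
  `shuffle` permutes quadrant placement per subdivision without changing
  the mass multiset (hence τ), giving seeded spatially random replicates.
* **Sierpinski carpet** (depth 5 → 243²): monofractal oracle with
  dimension log 8/log 3 ≈ 1.8928 on triadic ladders.
* **Bernoulli noise**: lacunarity oracle (closed form above).
* **Alveolar pattern** (512², 120 cells, 3 px walls): a nearest-seed
  (Voronoi) tessellation drawn as dark walls (intensity 30) on a bright
  field (245). One `degradation` dial in [0, 1] couples two pathology
  mechanisms: `round(degradation × hemorrhage_fill × n_cells)` compartments
  are flooded dark (hemorrhage; `hemorrhage_fill` = 0.5 by default) and the
  foreground is closed with a disk of radius
  `round(degradation × smoothing_max_radius)` px (edema-like contour
  leveling; max radius 5 px ≈ 1% of the raster). Defaults were fixed once:
  ~120 alveolar cross-sections at 512² gives a mean compartment diameter of
  ~50 px, comparable to an alveolus at ×200; walls of 3 px survive both
  outlining and thinning. The generator claims *directional* agreement
  only — rising degradation lowers spectrum height and width and shifts α₀
  left (verified over seeds) — and models no specific diagnosis, staining
  color, nuclei or 3-D structure. Passing tests on it show the pipeline
  detects contour simplification, not that it diagnoses real tissue.

## Numerical choices and degenerate inputs

* Regressions use plain OLS; a perfectly flat response reports R² = 1
  (the fit is exact), not NaN.
* q-grid values landing on integers are snapped so the q = 0 and q = 1
  special cases trigger exactly.
* A box ladder needs ≥ 2 distinct sizes; an all-background image raises an
  empty-measure error; fewer than 2 lacunarity points in the ε window
  raises an insufficient-data error; a q-grid without 0 is a config error
  (α₀ anchors the descriptors).
* Single-pixel and single-box cases degrade gracefully: a point mass has
  p = (1,), a degenerate spectrum has all widths/heights 0.

## Known limitations

* **Negative-moment bias on sparse contours.** With a fixed grid, boxes
  that barely graze a thin curve hold near-constant minimal mass across
  scales, biasing α(q) low for strongly negative q. On heavily degraded
  alveolar patterns this can invert the rarefied branch so the
  grid-extreme descriptor width goes negative. The effect is reported as
  measured (it is itself a strong "simplified pattern" signal, and the
  healthy-vs-degraded contrasts keep their direction); grid-offset
  averaging reduces but does not remove it.
* Grid-extreme descriptor ends are estimator-configuration dependent, as
  are all box-counting spectra; compare only at fixed q-grid and ladder.
* Lacunarity uses a single anchored grid, not gliding boxes; values at
  large ε rest on few cells and are noisy.

## Problem sizes

The test suite and the acceptance script run the oracles at the sizes
stated above (256² uniform field, depth-7 cascade, depth-5 carpet, 512²
Bernoulli and alveolar rasters; 10–20 seeds where averaging is needed);
the full suite completes in well under a minute on one CPU.
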