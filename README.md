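# fractmorph

Multifractal and lacunarity morphometry of binary-contour histological
images.

Histological texture — the motivating case is the alveolar pattern of lung
sections — often cannot be summarized by a single fractal dimension: the
pattern is a superposition of structures with different local scaling. This
package reduces a micrograph to a thin binary contour and measures its
scaling structure, for researchers who want calculable, comparable numbers
out of tissue images: quantitative-pathology and bio-image-analysis groups,
and anyone validating box-counting estimators against analytic ground
truth.

## What it computes

Given a nonnegative measure (a binary contour lifts to unit mass per
foreground pixel), box counting over a ladder of grid scales ε yields

* mass exponents τ(q) from Z(q, ε) = Σᵢ pᵢ(ε)^q ~ ε^τ(q), q ∈ [−5, 5];
* generalized dimensions D(q) = τ(q)/(q−1), with the information dimension
  D(1) from the entropy scaling Σ pᵢ log pᵢ ~ D(1) log ε;
* the singularity spectrum f(α) by the direct moment-weighted
  (Chhabra–Jensen) method — α(q) and f(q) as scaling slopes of the
  q-weighted partition statistics;
* spectrum descriptors: width α_max − α_min, height f(α₀), the right/left
  branch widths and heights, and the apex position α₀ — the quantities
  whose decrease and leftward shift separate degraded from healthy contour
  patterns;
* grid-scan lacunarity L(ε) = (σ/μ)² + 1 with its log–log slope and range
  over ε ∈ [0.01, 0.6];
* a monofractality test (linear τ(q) and near-zero spectrum width).

Preprocessing (grayscale → threshold-220 binarization → outline →
skeleton) and synthetic generators with known answers (multiplicative
cascades, the Sierpinski carpet, Bernoulli noise, and a degradable
alveolar-pattern generator) are included. See `docs/methods.md` for the
estimators, defaults and limitations.

## Worked example

Analytic oracle — a depth-7 multiplicative cascade with quadrant weights
(0.4, 0.3, 0.2, 0.1), whose exact exponents are
τ(q) = −log₂ Σ wᵢ^q:

```python
import numpy as np
from fractmorph import (CascadeSpec, binomial_cascade_2d, tau_function,
                        generalized_dimensions, singularity_spectrum,
                        extract_descriptors, is_monofractal, analytic_cascade_tau)

field = binomial_cascade_2d(CascadeSpec(weights=(0.4, 0.3, 0.2, 0.1), depth=7))
tau = tau_function(field)
D = generalized_dimensions(tau)
sp = singularity_spectrum(field)
d = extract_descriptors(sp)
print(f"tau(2)  = {tau.tau[np.isclose(tau.q_grid, 2)][0]:.4f}"
      f"   (closed form {analytic_cascade_tau((0.4, 0.3, 0.2, 0.1), 2):.4f})")
print(f"D(0)    = {D.D[np.isclose(D.q_grid, 0)][0]:.4f}")
print(f"D(1)    = {tau.info_dimension:.4f}")
print(f"alpha0  = {d.alpha0:.4f}  width = {d.width:.4f}  height = {d.height:.4f}")
print(f"monofractal: {is_monofractal(tau, sp).monofractal}")
```

prints

```
tau(2)  = 1.7370   (closed form 1.7370)
D(0)    = 2.0000
D(1)    = 1.8464
alpha0  = 2.1757  width = 1.8579  height = 2.0000
monofractal: False
```

The estimate matches −log₂(0.4²+0.3²+0.2²+0.1²) = 1.7370 exactly (dyadic
grids resolve the cascade without regression error); the support fills the
square (D(0) = 2), D(1) equals the weight entropy 1.8464, and the wide
spectrum correctly fails the monofractality test.

The same pipeline from the shell, on synthetic "healthy" vs "degraded"
alveolar micrographs:

```bash
fractmorph synth-alveolar --degradation 0 --seed 1 -o healthy.png
fractmorph synth-alveolar --degradation 1 --seed 1 -o degraded.png
fractmorph analyze healthy.png  -o out_healthy
fractmorph analyze degraded.png -o out_degraded
fractmorph compare out_healthy/report.json out_degraded/report.json
```

```
{
 "delta_alpha0": -0.158,
 "delta_height": -0.134,
 "delta_width": -0.437,
 "left_shifted": true,
 "collapsed_to_monofractal": false
}
```

The degraded pattern's spectrum is lower (simpler contour), narrower (more
uniform structure) and shifted left — the signature that distinguishes
pathological from healthy alveolar patterns. Each `analyze` output
directory also contains the binarized/contour PNGs, per-image lacunarity
and spectrum CSVs, and a JSON report that re-runs bit-identically from its
embedded config.

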