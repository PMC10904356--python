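"""Least-squares helpers shared by the scaling-exponent estimators."""

from __future__ import annotations

import numpy as np


def ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least-squares line fit.

    Returns ``(slope, intercept, r2)``.  A perfectly flat response
    (zero total sum of squares) is reported with R^2 = 1.0 — the line
    explains all of the (zero) variance — rather than NaN, so downstream
    linearity checks treat exact fits as linear.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired points for a line fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all x values equal")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(r2)
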