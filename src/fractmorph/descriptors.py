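"""Scalar descriptors of a singularity spectrum and pairwise comparison.

A singularity spectrum f(alpha) is summarized by six quantities used for
healthy-vs-pathology contrasts, plus the apex abscissa alpha_0 = alpha(0):

* width            alpha_max - alpha_min
* height           f(alpha_0) (the apex value, equal to the capacity
                   dimension of the support)
* right width      alpha_max - alpha_0   (rarefied branch, q < 0)
* right height     f(alpha_0) - f(alpha_max)
* left width       alpha_0 - alpha_min   (dense branch, q > 0)
* left height      f(alpha_0) - f(alpha_min)

``alpha_max``/``alpha_min`` and the branch-end f values are taken at the
q-grid extremes (q_min and q_max respectively), not extrapolated to true
q -> +/- infinity limits, so descriptors are comparable across runs only at
a fixed q-grid.  ``width == left_width + right_width`` holds exactly by
construction.

A comparison of a test spectrum against a reference reports signed deltas
only (no statistical inference); a negative delta alpha_0 means the test
spectrum is shifted toward the origin ("to the left").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, GridMismatchError
from .multifractal import DEFAULT_WIDTH_MAX, SingularitySpectrum

__all__ = ["SpectrumDescriptors", "SpectrumComparison", "extract_descriptors", "compare_descriptors"]


@dataclass
class SpectrumDescriptors:
    """The six spectrum-shape quantities plus alpha_0 (all dimensionless)."""

    width: float
    height: float
    right_width: float
    right_height: float
    left_width: float
    left_height: float
    alpha0: float
    q_grid: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class SpectrumComparison:
    """Signed descriptor deltas, test minus reference."""

    delta_alpha0: float
    delta_height: float
    delta_width: float
    left_shifted: bool
    collapsed_to_monofractal: bool


def extract_descriptors(spec: SingularitySpectrum) -> SpectrumDescriptors:
    """Reduce a spectrum to its shape descriptors.

    Branch ends are read at the q-grid extremes: the most negative q probes
    the most rarefied boxes (alpha_max), the most positive q the densest
    (alpha_min).  A single-point (degenerate monofractal) spectrum yields
    all-zero widths and heights.
    """
    q = np.asarray(spec.q_grid, dtype=float)
    if not np.isclose(q, 0.0, atol=1e-12).any():
        raise ConfigError("spectrum q-grid must contain q = 0")
    i0 = int(np.argmin(np.abs(q)))
    imin, imax = int(np.argmin(q)), int(np.argmax(q))
    alpha0 = float(spec.alpha[i0])
    f0 = float(spec.f[i0])
    alpha_max, f_at_alpha_max = float(spec.alpha[imin]), float(spec.f[imin])
    alpha_min, f_at_alpha_min = float(spec.alpha[imax]), float(spec.f[imax])
    right_width = alpha_max - alpha0
    left_width = alpha0 - alpha_min
    return SpectrumDescriptors(
        width=right_width + left_width,
        height=f0,
        right_width=right_width,
        right_height=f0 - f_at_alpha_max,
        left_width=left_width,
        left_height=f0 - f_at_alpha_min,
        alpha0=alpha0,
        q_grid=q.copy(),
    )


def compare_descriptors(
    reference: SpectrumDescriptors,
    test: SpectrumDescriptors,
    width_max: float = DEFAULT_WIDTH_MAX,
) -> SpectrumComparison:
    """Signed descriptor deltas of ``test`` relative to ``reference``.

    Both descriptor sets must come from the same q-grid.  The
    ``collapsed_to_monofractal`` flag marks a test spectrum whose width has
    dropped to ``width_max`` or below while the reference's had not.
    """
    if reference.q_grid.size and test.q_grid.size:
        if reference.q_grid.shape != test.q_grid.shape or not np.allclose(
            reference.q_grid, test.q_grid
        ):
            raise GridMismatchError("descriptors were extracted on different q-grids")
    delta_alpha0 = test.alpha0 - reference.alpha0
    return SpectrumComparison(
        delta_alpha0=float(delta_alpha0),
        delta_height=float(test.height - reference.height),
        delta_width=float(test.width - reference.width),
        left_shifted=bool(delta_alpha0 < 0),
        collapsed_to_monofractal=bool(
            test.width <= width_max < reference.width
        ),
    )
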