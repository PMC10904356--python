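"""Grid-scan lacunarity of binary patterns.

Lacunarity quantifies the heterogeneity of space filling: the image is
scanned with a fixed grid of square cells of side ``s`` and the statistic

    L(s) = (sigma / mu)^2 + 1

is computed from the per-cell foreground pixel counts, where ``mu`` is the
mean count and ``sigma`` the population standard deviation over all cells
(empty cells included — they are exactly the "chaotic dips" the statistic
is sensitive to).  The ``+1`` plotting convention makes homogeneous
patterns (sigma = 0) read exactly 1; the raw coefficient-of-variation form
``(sigma/mu)^2`` is exposed alongside.

Cell sizes are also reported as relative sizes ``eps = s / max(H, W)``, and
the curve is summarized by the ordinary-least-squares slope of
log10 L against log10 eps inside an eps window (default 0.01–0.6) together
with the L range over that window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, EmptyMeasureError, InsufficientDataError
from ._regression import ols_fit

__all__ = [
    "DEFAULT_BOX_SIZES",
    "DEFAULT_EPS_WINDOW",
    "LacunarityCurve",
    "LacunaritySummary",
    "lacunarity_curve",
    "lacunarity_summary",
]

#: Grid cell sides used by default: 1..60 px.
DEFAULT_BOX_SIZES = tuple(range(1, 61))

#: Relative-size window over which the slope and L range are summarized.
DEFAULT_EPS_WINDOW = (0.01, 0.6)


@dataclass
class LacunarityCurve:
    """L(eps) samples for one binary image.

    Attributes
    ----------
    box_sizes : strictly increasing grid cell sides, px.
    eps : relative cell sizes, ``box_size / max(H, W)``.
    L : lacunarity under the plotting convention, ``(sigma/mu)^2 + 1`` (>= 1).
    cv2 : the base statistic ``(sigma/mu)^2`` (>= 0).
    """

    box_sizes: np.ndarray
    eps: np.ndarray
    L: np.ndarray
    cv2: np.ndarray

    def __post_init__(self) -> None:
        self.box_sizes = np.asarray(self.box_sizes, dtype=int)
        self.eps = np.asarray(self.eps, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        self.cv2 = np.asarray(self.cv2, dtype=float)
        if not (len(self.box_sizes) == len(self.eps) == len(self.L) == len(self.cv2)):
            raise ValueError("curve arrays must have equal length")
        if np.any(np.diff(self.box_sizes) <= 0):
            raise ValueError("box_sizes must be strictly increasing")


@dataclass
class LacunaritySummary:
    """Slope and L range of a lacunarity curve over an eps window."""

    slope: float
    L_min: float
    L_max: float
    eps_window: tuple = field(default=DEFAULT_EPS_WINDOW)
    n_points: int = 0
    fit_r2: float = float("nan")


def _grid_counts(fg: np.ndarray, s: int) -> np.ndarray:
    """Per-cell foreground counts for a fixed grid anchored at (0, 0).

    Partial cells at the right/bottom edges are discarded.
    """
    h, w = fg.shape[0] // s, fg.shape[1] // s
    if h == 0 or w == 0:
        return np.empty(0)
    return (
        fg[: h * s, : w * s]
        .reshape(h, s, w, s)
        .sum(axis=(1, 3))
        .ravel()
        .astype(np.float64)
    )


def lacunarity_curve(img: np.ndarray, box_sizes=DEFAULT_BOX_SIZES) -> LacunarityCurve:
    """Lacunarity L(s) of a binary image over a ladder of grid cell sizes.

    Cell sizes whose retained grid holds no foreground (mu = 0) are skipped.

    Raises
    ------
    EmptyMeasureError
        If the image has no foreground pixel at all.
    ConfigError
        If a requested cell size exceeds the smaller image dimension.
    """
    fg = np.asarray(img, dtype=bool)
    if fg.ndim != 2:
        raise ConfigError(f"expected a 2-D binary image, got shape {fg.shape}")
    if not fg.any():
        raise EmptyMeasureError("image has no foreground pixels")
    sizes = sorted(set(int(s) for s in box_sizes))
    if sizes[0] < 1:
        raise ConfigError("box sizes must be >= 1")
    if sizes[-1] > min(fg.shape):
        raise ConfigError(
            f"max box size {sizes[-1]} exceeds min image dimension {min(fg.shape)}"
        )
    denom = max(fg.shape)
    out_s, out_eps, out_L, out_cv2 = [], [], [], []
    for s in sizes:
        counts = _grid_counts(fg, s)
        mu = counts.mean() if counts.size else 0.0
        if mu == 0.0:
            continue
        cv2 = counts.var() / mu**2  # population variance
        out_s.append(s)
        out_eps.append(s / denom)
        out_cv2.append(cv2)
        out_L.append(cv2 + 1.0)
    return LacunarityCurve(
        box_sizes=np.array(out_s),
        eps=np.array(out_eps),
        L=np.array(out_L),
        cv2=np.array(out_cv2),
    )


def lacunarity_summary(
    curve: LacunarityCurve, eps_window: tuple = DEFAULT_EPS_WINDOW
) -> LacunaritySummary:
    """Summarize a curve by its log-log slope and L range inside ``eps_window``.

    The slope is the OLS slope of log10(L) on log10(eps) restricted to
    eps_window (bounds inclusive); L_min/L_max are the curve extremes there.
    """
    lo, hi = eps_window
    if not lo < hi:
        raise ConfigError(f"eps_window must satisfy lo < hi, got {eps_window}")
    sel = (curve.eps >= lo) & (curve.eps <= hi)
    if sel.sum() < 2:
        raise InsufficientDataError(
            f"only {int(sel.sum())} curve points fall inside eps window {eps_window}"
        )
    eps, L = curve.eps[sel], curve.L[sel]
    slope, _, r2 = ols_fit(np.log10(eps), np.log10(L))
    return LacunaritySummary(
        slope=float(slope),
        L_min=float(L.min()),
        L_max=float(L.max()),
        eps_window=tuple(eps_window),
        n_points=int(sel.sum()),
        fit_r2=float(r2),
    )
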