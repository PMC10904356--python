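"""Synthetic inputs with known ground truth.

Three families of oracles make every estimator testable without any image
download:

* 2-D binomial multiplicative cascades, whose mass exponents have the closed
  form ``tau(q) = -log2(sum_i w_i^q)`` on dyadic box ladders
  (:func:`analytic_cascade_tau`, :func:`analytic_cascade_alpha`);
* the Sierpinski carpet, a monofractal set of known box dimension
  log 8 / log 3;
* i.i.d. Bernoulli noise, whose lacunarity has the binomial closed form
  ``L(s) = 1 + (1 - p) / (p s^2)``.

A fourth generator draws a cartoon of a lung histology section: a nearest-
seed (Voronoi) tessellation of "alveolar" compartments with dark walls on a
bright field.  A ``degradation`` parameter in [0, 1] emulates two pathology
mechanisms seen in hemorrhagic/edematous tissue: a fraction of compartments
is flooded with dark mass (erythrocyte-filled areas), and wall contours are
leveled by morphological closing with a radius that grows with degradation
(edema-like smoothing).  Rising degradation simplifies the contour pattern,
so spectrum height and width fall and the spectrum shifts left — the
qualitative healthy-vs-pathology signature the pipeline is meant to detect.
The generator claims only this directional agreement, not a quantitative
mapping onto any named pathology.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree
from skimage.morphology import closing, dilation, disk

from .exceptions import ConfigError, ImageInputError

__all__ = [
    "CascadeSpec",
    "AlveolarSpec",
    "binomial_cascade_2d",
    "analytic_cascade_tau",
    "analytic_cascade_alpha",
    "sierpinski_carpet",
    "random_binary",
    "alveolar_pattern",
]

#: Cascade weights used throughout the test oracles.
DEFAULT_CASCADE_WEIGHTS = (0.4, 0.3, 0.2, 0.1)

_WALL_INTENSITY = 30  # well below the 220 threshold
_BACKGROUND_INTENSITY = 245  # bright field, above the threshold


@dataclass(frozen=True)
class CascadeSpec:
    """Parameters of a 2-D binomial multiplicative cascade.

    ``weights`` are the four quadrant mass multipliers (must sum to 1); the
    final raster is ``2**depth`` pixels on a side.  With ``shuffle`` the
    quadrant placement is permuted independently at every subdivision (the
    mass multiset, hence tau(q), is unchanged; only the spatial arrangement
    randomizes).
    """

    weights: tuple = DEFAULT_CASCADE_WEIGHTS
    depth: int = 7
    shuffle: bool = False
    seed: int = 0


@dataclass(frozen=True)
class AlveolarSpec:
    """Parameters of the synthetic alveolar-pattern micrograph.

    degradation : float in [0, 1]
        0 = healthy (open compartments, crisp walls); 1 = fully degraded.
        The number of flooded compartments is
        ``round(degradation * hemorrhage_fill * n_cells)`` and the closing
        radius is ``round(degradation * smoothing_max_radius)``, coupling
        the hemorrhage and smoothing mechanisms to one dial.
    hemorrhage_fill : float in [0, 1]
        Fraction of compartments flooded at full degradation.
    smoothing_max_radius : int
        Closing radius (px) at full degradation; sets the relative strength
        of contour leveling versus flooding.
    """

    n_cells: int = 120
    raster_size: int = 512
    wall_thickness: int = 3
    degradation: float = 0.0
    hemorrhage_fill: float = 0.5
    seed: int = 0
    smoothing_max_radius: int = 5


def binomial_cascade_2d(spec: CascadeSpec) -> np.ndarray:
    """Generate the cascade measure as a ``2**depth`` square mass field.

    Each recursion splits every cell into four quadrants carrying fractions
    ``weights`` of the parent mass (row-major placement
    ``[[w0, w1], [w2, w3]]`` when ``shuffle`` is off), so total mass is 1 at
    every depth.
    """
    w = np.asarray(spec.weights, dtype=float)
    if w.shape != (4,) or np.any(w < 0):
        raise ConfigError("cascade needs 4 nonnegative weights")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ConfigError(f"cascade weights must sum to 1 (got {w.sum()!r})")
    if spec.depth < 1:
        raise ConfigError("cascade depth must be >= 1")
    rng = np.random.default_rng(spec.seed)
    field = np.ones((1, 1))
    for _ in range(spec.depth):
        n = field.shape[0]
        if spec.shuffle:
            blocks = rng.permuted(np.tile(w, (n * n, 1)), axis=1)
        else:
            blocks = np.tile(w, (n * n, 1))
        blocks = blocks.reshape(n, n, 2, 2)
        field = (field[:, :, None, None] * blocks).transpose(0, 2, 1, 3).reshape(2 * n, 2 * n)
    return field


def analytic_cascade_tau(weights, q: float) -> float:
    """Closed-form mass exponent ``tau(q) = -log2(sum_i w_i^q)`` of a cascade.

    Zero weights carry no mass: they are excluded for q > 0 and make
    negative moments divergent (an error) for q < 0.  At q = 0 the sum
    counts the nonempty quadrants.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ConfigError("weights must be nonnegative and sum to 1")
    nz = w[w > 0]
    if q < 0 and len(nz) < len(w):
        raise ConfigError("negative moments diverge for cascades with zero weights")
    return float(-np.log2(np.sum(nz**q)))


def analytic_cascade_alpha(weights, q: float) -> float:
    """Closed-form Holder exponent ``alpha(q)`` of a cascade.

    alpha(q) = sum_i w_i^q log2(1/w_i) / sum_i w_i^q — the q-weighted mean
    of the quadrant singularity strengths; the independent check for the
    direct spectrum estimator's abscissas.
    """
    w = np.asarray(weights, dtype=float)
    nz = w[w > 0]
    if q < 0 and len(nz) < len(w):
        raise ConfigError("negative moments diverge for cascades with zero weights")
    wq = nz**q
    return float(np.sum(wq * np.log2(1.0 / nz)) / np.sum(wq))


def sierpinski_carpet(depth: int) -> np.ndarray:
    """Sierpinski carpet of the given depth as a ``3**depth`` square bool image.

    Standard center-removal construction; the foreground count is
    ``8**depth`` and the box dimension is log 8 / log 3 ≈ 1.8928.
    """
    if depth < 1:
        raise ConfigError("carpet depth must be >= 1")
    cell = np.ones((3, 3), dtype=bool)
    cell[1, 1] = False
    carpet = cell
    for _ in range(depth - 1):
        carpet = np.kron(carpet, cell)
    return carpet


def random_binary(p: float, size: int | tuple[int, int], seed: int = 0) -> np.ndarray:
    """I.i.d. Bernoulli(p) binary image, reproducible by seed."""
    if not 0.0 < p <= 1.0:
        raise ConfigError(f"p must be in (0, 1], got {p}")
    shape = (size, size) if np.isscalar(size) else tuple(size)
    rng = np.random.default_rng(seed)
    return rng.random(shape) < p


def _voronoi_labels(points: np.ndarray, size: int) -> np.ndarray:
    """Nearest-seed label for every pixel center of a ``size`` square raster."""
    yy, xx = np.mgrid[0:size, 0:size]
    pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(float) + 0.5
    _, labels = cKDTree(points).query(pix)
    return labels.reshape(size, size)


def alveolar_pattern(spec: AlveolarSpec) -> np.ndarray:
    """Render a synthetic alveolar-pattern micrograph as a grayscale image.

    ``spec.n_cells`` seed points are scattered uniformly over the raster and
    their nearest-seed tessellation is drawn: inter-compartment boundaries
    become dark walls of ``wall_thickness`` pixels on a bright background.
    Degradation floods randomly chosen compartments with dark mass and
    smooths the foreground by morphological closing (see
    :class:`AlveolarSpec`).  Identical specs produce bit-identical rasters.
    """
    if not 0.0 <= spec.degradation <= 1.0:
        raise ConfigError("degradation must be in [0, 1]")
    if not 0.0 <= spec.hemorrhage_fill <= 1.0:
        raise ConfigError("hemorrhage_fill must be in [0, 1]")
    if spec.n_cells < 2:
        raise ConfigError("need at least 2 alveolar compartments")
    if spec.wall_thickness < 1:
        raise ConfigError("wall_thickness must be >= 1")
    # each compartment must have room for its walls
    min_area = (4 * spec.wall_thickness) ** 2
    if spec.n_cells * min_area > spec.raster_size**2:
        raise ImageInputError(
            f"{spec.n_cells} compartments do not fit a {spec.raster_size}px raster "
            f"at wall thickness {spec.wall_thickness}"
        )
    rng = np.random.default_rng(spec.seed)
    size = spec.raster_size
    points = rng.uniform(0.0, size, size=(spec.n_cells, 2))
    labels = _voronoi_labels(points, size)

    wall = np.zeros((size, size), dtype=bool)
    wall[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    wall[:-1, :] |= labels[:-1, :] != labels[1:, :]
    if spec.wall_thickness > 1:
        wall = dilation(wall, disk((spec.wall_thickness - 1) / 2))

    n_flooded = int(round(spec.degradation * spec.hemorrhage_fill * spec.n_cells))
    fg = wall
    if n_flooded > 0:
        flooded = rng.choice(spec.n_cells, size=n_flooded, replace=False)
        fg = fg | np.isin(labels, flooded)

    radius = int(round(spec.degradation * spec.smoothing_max_radius))
    if radius > 0:
        fg = closing(fg, disk(radius))

    return np.where(fg, _WALL_INTENSITY, _BACKGROUND_INTENSITY).astype(np.uint8)


def spec_to_dict(spec) -> dict:
    """JSON-ready dict of a generator spec (sidecar metadata)."""
    d = asdict(spec)
    if "weights" in d:
        d["weights"] = list(d["weights"])
    return d
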