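"""Topological shape descriptors: Euler-characteristic curves on annuli.

A fruit silhouette is summarized by a 120-value signature built in four
steps:

1. a pixel-density function on the silhouette — a Gaussian kernel sum
   over its pixels (all foreground pixels by default; contour pixels as an
   option), bandwidth proportional to the object radius, min–max
   normalized to [0, 1] over the foreground;
2. a partition of the silhouette into four concentric annuli of equal
   radial width emanating from the centroid;
3. per annulus, an Euler characteristic curve (ECC): the Euler
   characteristic of the density superlevel set, evaluated at 30 evenly
   spaced thresholds on [0, 1];
4. concatenation of the four 30-point curves (innermost annulus first).

The signature is translation invariant by construction and approximately
rotation invariant (up to rasterization).  PCA over a panel of such
signatures yields the PC1/PC2 shape traits used downstream; the principal
component sign is fixed by requiring the largest-magnitude loading of each
component to be positive, so scores are reproducible across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .mask import BinaryMask, DegenerateShapeError, euler_characteristic


@dataclass
class PHConfig:
    """Parameters of the descriptor.

    ``bandwidth_frac`` scales the Gaussian bandwidth as a fraction of the
    centroid-to-farthest-pixel radius; ``density_source`` selects kernel
    sums over all foreground pixels (default; angularly smooth) or over
    contour pixels only (emphasizes boundary curvature but carries
    rasterization anisotropy); ``direction`` selects superlevel (>= t,
    default) or sublevel (<= t) filtration.
    """

    n_annuli: int = 4
    n_levels: int = 30
    bandwidth_frac: float = 0.2
    density_source: str = "foreground"  # or "contour"
    direction: str = "super"  # or "sub"


@dataclass
class DensityMap:
    """Per-pixel density on a mask's foreground, normalized to [0, 1]."""

    values: np.ndarray  # full-grid float array, 0 outside the foreground
    foreground: np.ndarray
    bandwidth_px: float


@dataclass
class AnnulusPartition:
    """Integer annulus label (1..n, 0 = background) per pixel."""

    labels: np.ndarray
    n_annuli: int
    center: tuple[float, float]
    r_max: float


@dataclass
class ECCCurve:
    values: np.ndarray  # n_levels integers
    thresholds: np.ndarray


def density_map(
    mask: BinaryMask,
    bandwidth_frac: float = 0.2,
    density_source: str = "foreground",
) -> DensityMap:
    """Gaussian-kernel pixel density over the silhouette.

    Density at pixel p is the kernel sum over source pixels (all
    foreground pixels by default) with sigma = ``bandwidth_frac`` x r_max,
    computed by Gaussian filtering of the source indicator (mathematically
    the same sum up to a constant factor, which the normalization
    removes).
    """
    grid = mask.grid
    if density_source == "contour":
        src = mask.boundary()
    elif density_source == "foreground":
        src = grid
    else:
        raise ValueError(f"unknown density source {density_source!r}")
    if src.sum() < 4:
        raise DegenerateShapeError("mask has fewer than 4 source pixels")
    cy, cx = mask.centroid()
    rows, cols = np.nonzero(grid)
    r_max = float(np.sqrt((rows - cy) ** 2 + (cols - cx) ** 2).max())
    if r_max <= 0:
        raise DegenerateShapeError("mask has zero radius")
    sigma = bandwidth_frac * r_max
    dens = ndimage.gaussian_filter(src.astype(float), sigma, mode="constant", truncate=6.0)
    vals = dens[grid]
    lo, hi = vals.min(), vals.max()
    out = np.zeros_like(dens)
    if hi > lo:
        out[grid] = (dens[grid] - lo) / (hi - lo)
    return DensityMap(out, grid, sigma)


def annulus_partition(mask: BinaryMask, n_annuli: int = 4) -> AnnulusPartition:
    """Equal-radial-width concentric annuli around the centroid.

    Annulus i (1-based) holds foreground pixels whose normalized distance
    from the centroid lies in [(i-1)/n, i/n); the last bin is closed so the
    farthest pixel belongs to annulus n.
    """
    grid = mask.grid
    cy, cx = mask.centroid()
    rr, cc = np.indices(grid.shape)
    dist = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
    r_max = float(dist[grid].max())
    labels = np.zeros(grid.shape, dtype=np.int32)
    if r_max == 0:
        labels[grid] = 1
    else:
        idx = np.minimum((dist / r_max * n_annuli).astype(int), n_annuli - 1) + 1
        labels[grid] = idx[grid]
    return AnnulusPartition(labels, n_annuli, (cy, cx), r_max)


def ecc_curve(
    density: DensityMap,
    annulus: np.ndarray,
    n_levels: int = 30,
    direction: str = "super",
) -> ECCCurve:
    """Euler characteristic curve of one annulus along the density filtration.

    ``annulus`` is a boolean pixel set (one annulus of the partition);
    value j is the Euler characteristic of {p in annulus : density(p) >= t_j}
    (or <= t_j for sublevel) with t evenly spaced on [0, 1].
    """
    thresholds = np.linspace(0.0, 1.0, n_levels)
    rows, cols = np.nonzero(annulus)
    vals = np.zeros(n_levels, dtype=int)
    if rows.size:
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        sub_ann = annulus[r0:r1, c0:c1]
        sub_den = density.values[r0:r1, c0:c1]
        for j, t in enumerate(thresholds):
            if direction == "super":
                level = sub_ann & (sub_den >= t)
            else:
                level = sub_ann & (sub_den <= t)
            vals[j] = euler_characteristic(level)
    return ECCCurve(vals, thresholds)


def ph_descriptor(mask: BinaryMask, cfg: PHConfig | None = None) -> np.ndarray:
    """The concatenated topological signature of one mask.

    Returns a vector of length ``n_annuli * n_levels`` (120 by default):
    the ECCs of annuli 1..n (innermost first), each discretized into
    ``n_levels`` values.
    """
    cfg = cfg or PHConfig()
    m = mask.cropped(pad=2)
    dens = density_map(m, cfg.bandwidth_frac, cfg.density_source)
    part = annulus_partition(m, cfg.n_annuli)
    pieces = []
    for i in range(1, cfg.n_annuli + 1):
        curve = ecc_curve(dens, part.labels == i, cfg.n_levels, cfg.direction)
        pieces.append(curve.values)
    return np.concatenate(pieces).astype(float)


@dataclass
class PCAModel:
    """PCA of a descriptor matrix with a deterministic sign convention."""

    mean: np.ndarray
    loadings: np.ndarray  # p x k, orthonormal columns
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # n x k

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.loadings


def fit_pca(X: np.ndarray, n_components: int | None = None) -> PCAModel:
    """Column-centred PCA via SVD.

    The sign of each component is fixed so that its largest-|loading|
    entry is positive, making PC1/PC2 reproducible across panels.  A
    constant input matrix yields all-zero scores with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 observations")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(np.abs(Xc) > 1e-12):
        warnings.warn("descriptor matrix is constant; all scores are 0", stacklevel=2)
        k = n_components or 1
        load = np.zeros((X.shape[1], k))
        load[np.arange(min(k, X.shape[1])), np.arange(min(k, X.shape[1]))] = 1.0
        return PCAModel(mean, load, np.zeros(k), np.zeros((X.shape[0], k)))
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    ratio = var / var.sum()
    k = n_components or int(np.sum(s > s[0] * 1e-12))
    load = Vt[:k].T
    scores = U[:, :k] * s[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
            scores[:, j] = -scores[:, j]
    return PCAModel(mean, load, ratio[:k], scores)
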