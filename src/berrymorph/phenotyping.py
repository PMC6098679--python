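"""Scene segmentation, size calibration, and basic fruit descriptors.

The measurement convention follows the photographic protocol this package
emulates: fruit are photographed on a light background with reference
circles of known physical diameter; after global thresholding and
connected-component labelling, each fruit silhouette is measured for

* length — the longest chord through the object centroid (mm),
* width — the shortest chord through the centroid (mm),
* LW ratio — length / width,
* projected area — foreground pixel count scaled to mm^2,
* eccentricity — of the second-central-moment (best fit) ellipse,
  0 for a circle, approaching 1 for a line segment.

Chords are evaluated at 360 angles over [0, pi); both extremes therefore
pass through the centroid, which for non-convex (e.g. strongly bell-shaped)
silhouettes can differ from Feret diameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu

from .mask import BinaryMask


class CalibrationError(ValueError):
    """Reference circles missing or mutually inconsistent."""


class SegmentationWarning(UserWarning):
    """Suspicious component (e.g. probable touching objects)."""


@dataclass
class SegmentationConfig:
    """Knobs for scene segmentation.

    ``expected_ref_diameter_px`` enables reference-circle identification:
    components whose area is within ``ref_area_rel_tol`` of the expected
    circle area *and* whose eccentricity is at most ``ref_ecc_max`` are
    treated as references.  ``threshold`` overrides Otsu; ``invert`` flips
    the dark-on-light assumption.
    """

    min_area_px: int = 25
    max_area_px: int | None = None
    expected_ref_diameter_px: float | None = None
    ref_area_rel_tol: float = 0.25
    ref_ecc_max: float = 0.3
    threshold: float | None = None
    invert: bool = False


@dataclass
class ScaleCalibration:
    mm_per_px: float
    n_references_used: int
    cv: float


@dataclass
class BasicDescriptors:
    """The five basic size/shape traits of one fruit, in physical units."""

    length: float
    width: float
    lw_ratio: float
    area: float
    eccentricity: float


def segment_scene(
    image: np.ndarray, cfg: SegmentationConfig | None = None, scene_id: str = ""
) -> tuple[list[BinaryMask], list[BinaryMask]]:
    """Split a scene into fruit masks and reference-circle masks.

    Global threshold (Otsu unless overridden) + 8-connected labelling;
    components below ``min_area_px`` are dropped.  Returns masks with a
    placeholder scale of 1 mm/px; apply :func:`calibrate_scale` and set
    ``mm_per_px`` afterwards (see :func:`phenotype_scene`).
    """
    cfg = cfg or SegmentationConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() == img.min():
        return [], []
    thr = cfg.threshold if cfg.threshold is not None else threshold_otsu(img)
    fg = img > thr if cfg.invert else img < thr
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), int))
    fruit: list[BinaryMask] = []
    refs: list[BinaryMask] = []
    exp_area = (
        np.pi * (cfg.expected_ref_diameter_px / 2.0) ** 2
        if cfg.expected_ref_diameter_px
        else None
    )
    for prop in skmeasure.regionprops(labels):
        if prop.area < cfg.min_area_px:
            continue
        if cfg.max_area_px is not None and prop.area > cfg.max_area_px:
            warnings.warn(
                f"component {prop.label} in scene {scene_id!r} has area "
                f"{prop.area} px (> {cfg.max_area_px}); possible touching objects",
                SegmentationWarning,
                stacklevel=2,
            )
        grid = labels == prop.label
        mask = BinaryMask(grid, 1.0, f"{scene_id}:{prop.label}").cropped(pad=2)
        is_ref = (
            exp_area is not None
            and abs(prop.area - exp_area) <= cfg.ref_area_rel_tol * exp_area
            and prop.eccentricity <= cfg.ref_ecc_max
        )
        (refs if is_ref else fruit).append(mask)
    return fruit, refs


def calibrate_scale(
    ref_masks: list[BinaryMask], known_diameter_mm: float, cv_tol: float = 0.05
) -> ScaleCalibration:
    """Physical scale from reference circles of known diameter.

    Per-reference pixel diameter is the equivalent-area-circle diameter;
    the scale is the known diameter over the mean pixel diameter.  A
    coefficient of variation above ``cv_tol`` means the references are
    inconsistent (mis-segmentation) and raises :class:`CalibrationError`.
    """
    if not ref_masks:
        raise CalibrationError("no reference circles found")
    diam_px = np.array([2.0 * np.sqrt(m.area_px / np.pi) for m in ref_masks])
    cv = float(diam_px.std() / diam_px.mean())
    if cv > cv_tol:
        raise CalibrationError(
            f"reference diameters inconsistent (cv={cv:.3f} > {cv_tol})"
        )
    return ScaleCalibration(known_diameter_mm / float(diam_px.mean()), len(ref_masks), cv)


def _centroid_chords(grid: np.ndarray, n_angles: int, step: float = 0.5) -> np.ndarray:
    """Chord length (px) of the mask through its centroid at each angle.

    The chord at angle theta is the contiguous run of foreground samples
    containing the centroid; if the centroid itself falls outside the
    foreground (non-convex mask), the longest intersection run is used.
    """
    rows, cols = np.nonzero(grid)
    cy, cx = rows.mean(), cols.mean()
    h, w = grid.shape
    r_max = np.sqrt(h**2 + w**2) / 2.0 + 2
    t = np.arange(-r_max, r_max + step, step)
    ic = int(np.argmin(np.abs(t)))
    theta = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    sample_c = cx + np.cos(theta)[:, None] * t[None, :]
    sample_r = cy + np.sin(theta)[:, None] * t[None, :]
    rr = np.rint(sample_r).astype(int)
    cc = np.rint(sample_c).astype(int)
    inb = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    member = np.zeros(rr.shape, dtype=bool)
    member[inb] = grid[rr[inb], cc[inb]]
    chords = np.empty(n_angles)
    center_in = member[:, ic]
    # contiguous run around the centre sample, vectorized
    right = member[:, ic:]
    left = member[:, ic::-1]
    ext_r = np.where(right.all(axis=1), right.shape[1], np.argmin(right, axis=1))
    ext_l = np.where(left.all(axis=1), left.shape[1], np.argmin(left, axis=1))
    chords = (ext_r + ext_l - 1).astype(float) * step
    for i in np.nonzero(~center_in)[0]:
        m = member[i]
        # longest run of True
        best = cur = 0
        for v in m:
            cur = cur + 1 if v else 0
            best = max(best, cur)
        chords[i] = best * step
    return chords


def measure_basic(mask: BinaryMask, n_angles: int = 360) -> BasicDescriptors:
    """Compute the five basic descriptors of a single-fruit mask."""
    grid = mask.grid
    if not grid.any():
        raise ValueError("empty mask")
    chords = _centroid_chords(grid, n_angles)
    length = float(chords.max()) * mask.mm_per_px
    width = float(chords.min()) * mask.mm_per_px
    area = float(grid.sum()) * mask.mm_per_px**2
    props = skmeasure.regionprops(grid.astype(np.uint8))[0]
    ecc = float(np.clip(props.eccentricity, 0.0, 1.0))
    width = max(width, mask.mm_per_px)  # a 1-px-wide mask still has one pixel of width
    return BasicDescriptors(length, width, length / width, area, ecc)


def phenotype_scene(
    image: np.ndarray,
    ref_diameter_mm: float | None,
    cfg: SegmentationConfig | None = None,
    scene_id: str = "",
    n_angles: int = 360,
) -> tuple["pd.DataFrame", list[BinaryMask]]:
    """Segment, calibrate and measure one scene.

    Returns a per-fruit trait table (scene_id, fruit_id, length_mm,
    width_mm, lw_ratio, area_mm2, eccentricity) and the calibrated fruit
    masks for the topological stage.  With ``ref_diameter_mm`` None no
    calibration is attempted and measurements are in pixel units.
    """
    import pandas as pd

    fruit, refs = segment_scene(image, cfg, scene_id)
    mm_per_px = 1.0
    if ref_diameter_mm is not None:
        cal = calibrate_scale(refs, ref_diameter_mm)
        mm_per_px = cal.mm_per_px
    for m in fruit:
        m.mm_per_px = mm_per_px
    rows = []
    for i, m in enumerate(fruit):
        d = measure_basic(m, n_angles)
        rows.append(
            {
                "scene_id": scene_id,
                "fruit_id": i,
                "length_mm": d.length,
                "width_mm": d.width,
                "lw_ratio": d.lw_ratio,
                "area_mm2": d.area,
                "eccentricity": d.eccentricity,
            }
        )
    return pd.DataFrame(rows), fruit
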