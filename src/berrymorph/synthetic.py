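"""Synthetic fruit scenes and a simulated four-way cross with planted QTL.

This module fabricates the whole study design end to end: superellipse /
piriform fruit silhouettes spanning the round -> elongated -> bell-shaped
continuum, photographic-protocol scenes (25 fruit per genotype, six size
reference circles along the top and bottom edges), an outbred four-way
cross (genotype classes ac, ad, bc, bd) simulated under the Haldane
no-interference model, and repeated-year phenotypes with planted QTL plus a
polygenic background.  Every downstream stage (segmentation, topology,
BLUP, QTL scans) is tested against the ground truth produced here.

All randomness flows through ``numpy.random.default_rng(seed)``; a fixed
seed reproduces every artifact bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mask import BinaryMask, DegenerateShapeError

SHAPE_CLASSES = ("round", "elongated", "bell")
#: genotype code -> (maternal allele index, paternal allele index)
#: 1=ac, 2=ad, 3=bc, 4=bd, 0=missing
CLASS_LABELS = ("ac", "ad", "bc", "bd")


class PackingError(RuntimeError):
    """Scene objects could not be placed without overlap."""


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


# ---------------------------------------------------------------------------
# fruit silhouettes


@dataclass
class ShapeParams:
    """Ground-truth geometry of one fruit silhouette.

    ``a``/``b`` are the semi-axes along the length/width in mm (a >= b).
    ``n_exp`` is the superellipse exponent (2 = ellipse, larger = boxier).
    ``bell_k`` in [0, 1) skews the half-width profile along the long axis,
    giving one blunt and one tapered end; 0 means symmetric.  ``rotation``
    is the angle of the long axis in radians, ``center`` the (x, y) pixel
    position in a scene (None until placed).
    """

    shape_class: str
    a: float
    b: float
    n_exp: float = 2.0
    bell_k: float = 0.0
    rotation: float = 0.0
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ConfigError(f"unknown shape class {self.shape_class!r}")
        if not (self.a >= self.b > 0):
            raise ConfigError("require a >= b > 0")
        if self.n_exp < 1:
            raise ConfigError("superellipse exponent must be >= 1")
        if not (0 <= self.bell_k < 1):
            raise ConfigError("bell_k must lie in [0, 1)")
        if self.shape_class == "round" and abs(self.a / self.b - 1) > 0.05:
            raise ConfigError("round fruit must have a/b within 5% of 1")
        if self.shape_class == "bell" and self.bell_k <= 0:
            raise ConfigError("bell fruit needs bell_k > 0")


def _inside(params: ShapeParams, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
    """Membership test in the fruit's local frame (x along the length)."""
    a, b, n = params.a, params.b, params.n_exp
    if params.shape_class == "bell":
        t = x_mm / a
        with np.errstate(invalid="ignore"):
            half_w = b * (1.0 - params.bell_k * t) * np.clip(1.0 - t**2, 0.0, None) ** (1.0 / n)
        return (np.abs(t) <= 1.0) & (np.abs(y_mm) <= half_w)
    return np.abs(x_mm / a) ** n + np.abs(y_mm / b) ** n <= 1.0


def make_fruit_mask(params: ShapeParams, px_per_mm: float) -> BinaryMask:
    """Rasterize a fruit silhouette onto its own pixel grid.

    The boundary for round/elongated fruit is the superellipse
    ``|x/a|^n + |y/b|^n = 1``; for bell fruit the half-width at axial
    coordinate t in [-1, 1] is ``b (1 - bell_k t) (1 - t^2)^(1/n)``.
    Pixels are classified at their centres.
    """
    if px_per_mm <= 0:
        raise ConfigError("px_per_mm must be positive")
    half = max(params.a, params.b) * px_per_mm + 2
    n_half = int(np.ceil(half))
    coords = (np.arange(-n_half, n_half + 1) + 0.0) / px_per_mm
    xs, ys = np.meshgrid(coords, coords, indexing="xy")
    c, s = np.cos(params.rotation), np.sin(params.rotation)
    # rotate scene coords back into the fruit frame
    x_loc = c * xs + s * ys
    y_loc = -s * xs + c * ys
    grid = _inside(params, x_loc, y_loc)
    mask = BinaryMask(grid, mm_per_px=1.0 / px_per_mm)
    if mask.area_px < 25:
        raise DegenerateShapeError(
            f"rasterized fruit covers only {mask.area_px} px (< 25)"
        )
    return mask.cropped(pad=2)


# ---------------------------------------------------------------------------
# scenes


@dataclass
class SceneSpec:
    """Layout of one photographed scene.

    Defaults follow the acquisition protocol emulated here: 25 fruit per
    scene with six reference circles of known diameter along each of the
    top and bottom edges, dark objects on a light background.
    """

    fruits: list[ShapeParams] = field(default_factory=list)
    n_ref_circles_per_side: int = 6
    ref_diameter_mm: float = 25.4
    px_per_mm: float = 5.0
    image_size: tuple[int, int] = (1200, 1600)
    background: int = 255
    foreground: int = 40
    margin_px: int = 6
    pixel_noise_sd: float = 0.0


def _disk(radius_px: float) -> np.ndarray:
    n = int(np.ceil(radius_px)) + 1
    c = np.arange(-n, n + 1)
    xs, ys = np.meshgrid(c, c)
    return xs**2 + ys**2 <= radius_px**2


def _stamp(img: np.ndarray, obj: np.ndarray, center_rc: tuple[int, int], value: int) -> None:
    h, w = obj.shape
    r0 = center_rc[0] - h // 2
    c0 = center_rc[1] - w // 2
    if r0 < 0 or c0 < 0 or r0 + h > img.shape[0] or c0 + w > img.shape[1]:
        raise PackingError(
            f"object of size {h}x{w} does not fit at ({center_rc[0]}, {center_rc[1]})"
        )
    img[r0 : r0 + h, c0 : c0 + w][obj] = value


def compose_scene(
    spec: SceneSpec, seed: int, max_tries: int = 400
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a scene image and return it with its ground-truth table.

    Reference circles are laid out deterministically in a top and a bottom
    band; fruit are placed uniformly at random in the interior with
    rejection sampling on bounding-box overlap (objects never touch).
    Returns ``(image uint8 HxW, truth DataFrame)`` where the truth table
    carries one row per placed object (kind, centre, shape parameters).
    """
    rng = np.random.default_rng(seed)
    H, W = spec.image_size
    img = np.full((H, W), spec.background, dtype=np.uint8)
    rows: list[dict] = []

    ref_r_px = spec.ref_diameter_mm * spec.px_per_mm / 2.0
    band = int(np.ceil(ref_r_px)) + spec.margin_px
    disk = _disk(ref_r_px)
    for side, row_c in (("top", band), ("bottom", H - band)):
        for i in range(spec.n_ref_circles_per_side):
            col = int((i + 0.5) * W / spec.n_ref_circles_per_side)
            _stamp(img, disk, (row_c, col), spec.foreground)
            rows.append(
                {
                    "object_id": f"ref_{side}_{i}",
                    "kind": "reference",
                    "row": row_c,
                    "col": col,
                    "diameter_mm": spec.ref_diameter_mm,
                }
            )

    # interior region available to fruit
    top = 2 * band + spec.margin_px
    bottom = H - 2 * band - spec.margin_px
    placed: list[tuple[int, int, int, int]] = []  # r0, r1, c0, c1 occupied boxes
    for idx, fruit in enumerate(spec.fruits):
        fmask = make_fruit_mask(fruit, spec.px_per_mm)
        fh, fw = fmask.grid.shape
        if bottom - top < fh or W - 2 * spec.margin_px < fw:
            raise PackingError("fruit larger than the available interior")
        for _ in range(max_tries):
            r = int(rng.integers(top + fh // 2, bottom - (fh - fh // 2)))
            c = int(rng.integers(spec.margin_px + fw // 2, W - spec.margin_px - (fw - fw // 2)))
            box = (r - fh // 2 - spec.margin_px, r + fh - fh // 2 + spec.margin_px,
                   c - fw // 2 - spec.margin_px, c + fw - fw // 2 + spec.margin_px)
            if all(box[1] <= p[0] or box[0] >= p[1] or box[3] <= p[2] or box[2] >= p[3]
                   for p in placed):
                placed.append(box)
                _stamp(img, fmask.grid, (r, c), spec.foreground)
                rec = {
                    "object_id": f"fruit_{idx}",
                    "kind": "fruit",
                    "row": r,
                    "col": c,
                    "shape_class": fruit.shape_class,
                    "a_mm": fruit.a,
                    "b_mm": fruit.b,
                    "n_exp": fruit.n_exp,
                    "bell_k": fruit.bell_k,
                    "rotation": fruit.rotation,
                }
                rows.append(rec)
                break
        else:
            raise PackingError(
                f"could not place fruit {idx} after {max_tries} tries"
            )
    if spec.pixel_noise_sd > 0:
        noise = rng.normal(0.0, spec.pixel_noise_sd, img.shape)
        img = np.clip(img.astype(float) + noise, 0, 255).astype(np.uint8)
    return img, pd.DataFrame(rows)


def random_shape_params(
    rng: np.random.Generator,
    shape_class: str,
    mean_radius_mm: float = 8.0,
    cv: float = 0.06,
) -> ShapeParams:
    """Draw one fruit's parameters around class-typical values."""
    g = mean_radius_mm * float(np.exp(rng.normal(0, cv)))
    rot = float(rng.uniform(0, np.pi))
    if shape_class == "round":
        ratio = float(np.exp(rng.normal(0, 0.01)))
        ratio = min(max(ratio, 1.0), 1.04)
        return ShapeParams("round", g * ratio, g, 2.0, 0.0, rot)
    if shape_class == "elongated":
        ratio = float(np.exp(rng.normal(0.45, 0.08)))
        return ShapeParams("elongated", g * np.sqrt(ratio), g / np.sqrt(ratio), 2.0, 0.0, rot)
    ratio = float(np.exp(rng.normal(0.45, 0.08)))
    k = float(np.clip(rng.normal(0.45, 0.08), 0.1, 0.8))
    return ShapeParams("bell", g * np.sqrt(ratio), g / np.sqrt(ratio), 2.0, k, rot)


# ---------------------------------------------------------------------------
# four-way cross


@dataclass
class SimCross:
    """A simulated four-way cross.

    ``gmap`` has columns (marker, lg, cm); ``geno`` is an n x m int array of
    genotype codes 1=ac, 2=ad, 3=bc, 4=bd, 0=missing; ``qtl_geno`` maps a
    planted (lg, cm) locus to the true class vector of the offspring.
    """

    gmap: pd.DataFrame
    geno: np.ndarray
    ids: list[str]
    qtl_geno: dict[tuple, np.ndarray] = field(default_factory=dict)
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.geno.shape[0]


def make_linkage_map(
    n_markers: int = 976, n_lg: int = 12, lg_length_cm: float = 100.0
) -> pd.DataFrame:
    """Evenly spaced marker map: ``n_markers`` spread over ``n_lg`` groups."""
    per = [n_markers // n_lg + (1 if i < n_markers % n_lg else 0) for i in range(n_lg)]
    rows = []
    for lg_i, m in enumerate(per, start=1):
        pos = np.linspace(0.0, lg_length_cm, m)
        for j, p in enumerate(pos):
            rows.append({"marker": f"LG{lg_i}_M{j + 1}", "lg": lg_i, "cm": float(p)})
    return pd.DataFrame(rows)


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for distance d in cM (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def _simulate_gametes(rng: np.random.Generator, n: int, cm: np.ndarray) -> np.ndarray:
    """n haplotypes over loci at positions cm (one LG): 0/1 allele indices."""
    L = len(cm)
    out = np.empty((n, L), dtype=np.int8)
    out[:, 0] = rng.random(n) < 0.5
    if L > 1:
        r = haldane_r(np.diff(cm))
        switches = rng.random((n, L - 1)) < r[None, :]
        parity = np.cumsum(switches, axis=1) % 2
        out[:, 1:] = out[:, :1] ^ parity.astype(np.int8)
    return out


def simulate_cross(
    gmap: pd.DataFrame,
    n: int = 351,
    seed: int = 0,
    extra_loci: list[tuple] | None = None,
    missing_rate: float = 0.0,
) -> SimCross:
    """Simulate offspring genotypes of a four-way cross along a linkage map.

    Each offspring receives one maternal (a/b) and one paternal (c/d)
    gamete per linkage group, with crossovers following the Haldane model.
    ``extra_loci`` are additional (lg, cm) positions — typically planted
    QTL — whose true genotype classes are recorded in ``qtl_geno`` but not
    emitted as markers.
    """
    if gmap.empty:
        raise ConfigError("linkage map is empty")
    rng = np.random.default_rng(seed)
    extra = list(extra_loci or [])
    geno_cols: list[np.ndarray] = []
    marker_order: list[str] = []
    qtl_geno: dict[tuple, np.ndarray] = {}
    for lg, sub in gmap.groupby("lg", sort=False):
        cm = sub["cm"].to_numpy(dtype=float)
        if np.any(np.diff(cm) < 0):
            raise ConfigError(f"marker positions decrease within LG {lg}")
        lg_extra = sorted({float(c) for (l, c) in extra if l == lg})
        all_pos = np.concatenate([cm, np.asarray(lg_extra)])
        order = np.argsort(all_pos, kind="stable")
        pos_sorted = all_pos[order]
        mat = _simulate_gametes(rng, n, pos_sorted)
        pat = _simulate_gametes(rng, n, pos_sorted)
        codes_sorted = (2 * mat + pat + 1).astype(np.int8)
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        codes = codes_sorted[:, inv]  # back to [markers..., extras...] order
        geno_cols.append(codes[:, : len(cm)])
        marker_order.extend(sub["marker"].tolist())
        for k, c in enumerate(lg_extra):
            qtl_geno[(lg, c)] = codes[:, len(cm) + k].astype(int)
    geno = np.concatenate(geno_cols, axis=1)
    # restore the input marker ordering (groupby preserved appearance order)
    if marker_order != gmap["marker"].tolist():
        idx = [marker_order.index(m) for m in gmap["marker"]]
        geno = geno[:, idx]
    if missing_rate > 0:
        miss = rng.random(geno.shape) < missing_rate
        geno = np.where(miss, 0, geno)
    ids = [f"G{i + 1:04d}" for i in range(n)]
    return SimCross(gmap.reset_index(drop=True), geno.astype(int), ids, qtl_geno, seed)


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class PlantedQTL:
    """One planted QTL: position plus a class-effect pattern.

    ``effects`` gives the relative effect of the four genotype classes
    (ac, ad, bc, bd); the pattern is rescaled so that the QTL explains
    ``var_frac`` of the genotype-mean phenotypic variance.
    """

    lg: int
    cm: float
    effects: tuple[float, float, float, float] = (1.0, 0.0, 0.0, -1.0)
    var_frac: float = 0.1


@dataclass
class TraitModel:
    """Genetic architecture of one simulated trait on the genotype-mean scale.

    Variance fractions refer to the per-year genotype-mean phenotype with
    total variance 1: planted QTL fractions + ``polygenic_h2`` + residual
    (of the 25-fruit mean) sum to 1.  ``sigma_fruit`` (SD of single fruit
    around the genotype-year latent) is derived from that residual unless
    given explicitly.
    """

    name: str
    qtls: list[PlantedQTL] = field(default_factory=list)
    polygenic_h2: float = 0.0
    mean: float = 0.0
    sigma_fruit: float | None = None

    @property
    def h2_total(self) -> float:
        return self.polygenic_h2 + sum(q.var_frac for q in self.qtls)


def _standardize(x: np.ndarray, target_var: float) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ConfigError("degenerate (constant) genetic component")
    return x / sd * np.sqrt(target_var)


def _polygenic_values(
    cross: SimCross, rng: np.random.Generator, target_var: float
) -> np.ndarray:
    """Sum of small random effects over maternal/paternal marker indicators,
    standardized to the requested variance."""
    mat_is_a = np.isin(cross.geno, (1, 2)).astype(float)
    pat_is_c = np.isin(cross.geno, (1, 3)).astype(float)
    w = np.concatenate([mat_is_a, pat_is_c], axis=1)
    w -= w.mean(axis=0, keepdims=True)
    beta = rng.normal(0.0, 1.0, w.shape[1])
    return _standardize(w @ beta, target_var)


def genetic_values(cross: SimCross, model: TraitModel, rng: np.random.Generator) -> np.ndarray:
    """Per-genotype total genetic value (QTL + polygenic), variance-scaled."""
    if model.h2_total >= 1.0:
        raise ConfigError(
            f"trait {model.name!r}: genetic variance {model.h2_total} >= total"
        )
    g = np.zeros(cross.n)
    qtl_onehots = [np.ones((cross.n, 1))]
    for q in model.qtls:
        key = (q.lg, q.cm)
        if key not in cross.qtl_geno:
            raise ConfigError(f"no simulated genotypes at QTL {key}; "
                              "pass it via extra_loci when simulating the cross")
        classes = cross.qtl_geno[key]
        vals = np.asarray(q.effects, dtype=float)[classes - 1]
        g += _standardize(vals, q.var_frac)
        qtl_onehots.append((classes[:, None] == np.arange(1, 5)[None, :]).astype(float))
    if model.polygenic_h2 > 0:
        poly = _polygenic_values(cross, rng, model.polygenic_h2)
        if model.qtls:
            # orthogonalize against the planted QTL classes so the variance
            # fractions compose additively (markers linked to a planted QTL
            # otherwise correlate the two components by chance)
            D = np.hstack(qtl_onehots)
            coef, *_ = np.linalg.lstsq(D, poly, rcond=None)
            poly = _standardize(poly - D @ coef, model.polygenic_h2)
        g += poly
    return g


def simulate_phenotypes(
    cross: SimCross,
    traits: list[TraitModel],
    n_years: int = 3,
    n_fruit: int = 25,
    year_effect_sd: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-fruit and per-genotype-year trait tables.

    Model per trait: genotype value g (constant over years) + additive year
    shift + per-fruit noise.  Fruit noise SD is chosen so the residual
    variance of the 25-fruit genotype mean equals 1 - h2_total, making the
    planted variance fractions hold on the genotype-mean scale.

    Returns ``(per_fruit, per_genotype)`` tables; the per-genotype table
    contains the arithmetic means of the fruit draws.
    """
    rng = np.random.default_rng(seed)
    year_labels = [2014 + k for k in range(n_years)]
    fruit_rows = {"genotype": np.repeat(cross.ids, n_years * n_fruit),
                  "year": np.tile(np.repeat(year_labels, n_fruit), cross.n),
                  "fruit": np.tile(np.arange(1, n_fruit + 1), cross.n * n_years)}
    per_fruit = pd.DataFrame(fruit_rows)
    for model in traits:
        g = genetic_values(cross, model, rng)
        resid_mean_var = 1.0 - model.h2_total
        sigma_fruit = (model.sigma_fruit if model.sigma_fruit is not None
                       else np.sqrt(resid_mean_var * n_fruit))
        year_shift = rng.normal(0.0, year_effect_sd, n_years)
        vals = (model.mean
                + np.repeat(g, n_years * n_fruit)
                + np.tile(np.repeat(year_shift, n_fruit), cross.n)
                + rng.normal(0.0, sigma_fruit, cross.n * n_years * n_fruit))
        per_fruit[model.name] = vals
    names = [m.name for m in traits]
    per_geno = (per_fruit.groupby(["genotype", "year"], sort=True)[names]
                .agg(["mean", "count"]))
    per_geno.columns = [f"{t}_{s}" if s == "count" else t for t, s in per_geno.columns]
    count_cols = [c for c in per_geno.columns if c.endswith("_count")]
    per_geno["n_fruit"] = per_geno[count_cols[0]] if count_cols else 0
    per_geno = per_geno.drop(columns=count_cols).reset_index()
    return per_fruit, per_geno


# ---------------------------------------------------------------------------
# latent shape traits -> fruit geometry (for the image pipeline)


@dataclass
class ShapeArchitecture:
    """Genetic architecture of the latent size and elongation traits that
    drive fruit geometry in image simulations.

    ``size`` controls log mean radius, ``elong`` the log length/width
    ratio, ``bell`` the bell asymmetry.  Each is an independent
    :class:`TraitModel`, so size and shape can be made genetically
    orthogonal (the default).
    """

    size: TraitModel
    elong: TraitModel
    bell: TraitModel | None = None
    base_radius_mm: float = 8.0
    size_scale: float = 0.10   # SD of log-radius per unit latent
    elong_base: float = 0.25   # baseline log(a/b)
    elong_scale: float = 0.20
    fruit_cv: float = 0.04     # within-genotype fruit-to-fruit variability


def simulate_fruit_geometry(
    cross: SimCross,
    arch: ShapeArchitecture,
    n_years: int = 1,
    n_fruit: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-fruit :class:`ShapeParams` inheriting the genetic signal.

    Returns a long table (genotype, year, fruit, latent values and the
    realized a/b/bell_k/rotation) from which masks or whole scenes can be
    rendered via :func:`make_fruit_mask` / :func:`compose_scene`.
    """
    rng = np.random.default_rng(seed)
    traits = [arch.size, arch.elong] + ([arch.bell] if arch.bell else [])
    per_fruit, _ = simulate_phenotypes(
        cross, traits, n_years=n_years, n_fruit=n_fruit,
        year_effect_sd=0.0, seed=int(rng.integers(2**31 - 1)),
    )
    size_l = per_fruit[arch.size.name].to_numpy()
    elong_l = per_fruit[arch.elong.name].to_numpy()
    n_rows = len(per_fruit)
    g_mm = arch.base_radius_mm * np.exp(arch.size_scale * size_l
                                        + rng.normal(0, arch.fruit_cv, n_rows))
    log_ratio = np.clip(arch.elong_base + arch.elong_scale * elong_l, 0.0, 1.2)
    ratio = np.exp(log_ratio)
    out = per_fruit[["genotype", "year", "fruit"]].copy()
    out["a_mm"] = g_mm * np.sqrt(ratio)
    out["b_mm"] = g_mm / np.sqrt(ratio)
    if arch.bell is not None:
        bell_l = per_fruit[arch.bell.name].to_numpy()
        out["bell_k"] = np.clip(0.3 + 0.15 * bell_l, 0.0, 0.8)
    else:
        out["bell_k"] = 0.0
    out["rotation"] = rng.uniform(0, np.pi, n_rows)
    for t in traits:
        out[f"latent_{t.name}"] = per_fruit[t.name]
    return out


def shape_params_from_row(row: pd.Series) -> ShapeParams:
    """Build :class:`ShapeParams` from one row of the geometry table."""
    k = float(row["bell_k"])
    a, b = float(row["a_mm"]), float(row["b_mm"])
    if k > 1e-9:
        cls = "bell"
    elif a / b > 1.05:
        cls = "elongated"
    else:
        cls = "round"
        a = min(a, b * 1.05)
    return ShapeParams(cls, a, b, 2.0, k if cls == "bell" else 0.0,
                       float(row["rotation"]))
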