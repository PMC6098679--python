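"""QTL mapping in a four-way cross: Haley-Knott scans and stepwise models.

The chain implemented here mirrors standard multiple-QTL practice for an
outbred full-sib family with four distinguishable founder alleles per
locus (offspring classes ac, ad, bc, bd):

* hidden-Markov genotype probabilities on a pseudomarker grid, with
  Haldane (no-interference) transitions applied independently to the
  maternal and paternal meioses and a small genotyping-error emission;
* single-QTL Haley-Knott regression of the phenotype on the three
  genotype-probability contrasts, LOD = (n/2) log10(RSS0 / RSS1),
  optionally with trait covariates;
* genome-wide significance by permutation: the main-effect penalty T_m is
  the empirical (1 - alpha) quantile of the genome-wide maximum LOD under
  phenotype permutation (covariates travel with the phenotype);
* additive stepwise model selection maximizing the penalized LOD
  pLOD = LOD(model) - T_m * (#QTL), with forward search, backward
  deletion, and one round of local position refinement;
* 1.5-LOD support intervals, drop-one explained variance, and cross-year
  collocation of peaks within an 8 cM window.

Only additive (main-effect) models are fitted; two-dimensional two-QTL
scans and interaction penalties are out of scope by design.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .synthetic import SimCross, haldane_r

CLASS_LABELS = ("ac", "ad", "bc", "bd")


@dataclass
class GenoProbs:
    """Posterior genotype-class probabilities on a position grid.

    ``positions`` has columns (lg, cm, name, is_marker); ``probs`` is an
    n x P x 4 array over classes (ac, ad, bc, bd), each row summing to 1.
    """

    positions: pd.DataFrame
    probs: np.ndarray
    ids: list[str]
    error_rate: float
    step_cm: float

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    def lg_slices(self) -> dict:
        out = {}
        for lg in self.positions["lg"].unique():
            idx = np.nonzero((self.positions["lg"] == lg).to_numpy())[0]
            out[lg] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out


@dataclass
class ScanCurve:
    """LOD per grid position for one trait / covariate combination."""

    table: pd.DataFrame  # columns lg, cm, name, lod
    df: int = 3
    trait: str = ""
    year: object = None
    covariates: tuple = ()

    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    def peak(self) -> pd.Series:
        return self.table.loc[self.table["lod"].idxmax()]


@dataclass
class Penalty:
    T_m: float
    alpha: float
    n_perm: int
    seed: int


@dataclass
class QTL:
    lg: object
    cm: float
    lod: float  # drop-one LOD
    effects: np.ndarray  # per-class effect estimates, mean-centred
    pct_var: float  # drop-one explained variance, percent
    ci_lo: float
    ci_hi: float


@dataclass
class QTLModel:
    qtls: list[QTL] = field(default_factory=list)
    full_model_pct_var: float = 0.0
    plod: float = 0.0
    trait: str = ""
    year: object = None
    covariates: tuple = ()

    @property
    def size(self) -> int:
        return len(self.qtls)


# ---------------------------------------------------------------------------
# genotype probabilities


def _transition(d_cm: float) -> np.ndarray:
    r = float(haldane_r(d_cm))
    t2 = np.array([[1.0 - r, r], [r, 1.0 - r]])
    return np.kron(t2, t2)  # state = 2*maternal + paternal


def _emissions(obs: np.ndarray, error_rate: float) -> np.ndarray:
    """n x 4 emission weights for one typed position (0 = missing)."""
    n = obs.shape[0]
    E = np.ones((n, 4))
    typed = obs > 0
    if typed.any():
        E[typed] = error_rate / 3.0
        E[typed, obs[typed] - 1] = 1.0 - error_rate
    return E


def _grid_positions(cm: np.ndarray, step_cm: float) -> tuple[np.ndarray, np.ndarray]:
    """Marker positions merged with a pseudomarker grid.

    Returns (positions, marker_index) where marker_index[j] gives the
    marker column for grid point j, or -1 for a pseudomarker.
    """
    lo, hi = float(cm.min()), float(cm.max())
    grid = np.arange(lo, hi + step_cm / 2.0, step_cm) if step_cm > 0 else np.array([])
    pos = list(cm)
    src = list(range(len(cm)))
    for g in grid:
        if np.min(np.abs(cm - g)) > 1e-9:
            pos.append(float(g))
            src.append(-1)
    order = np.argsort(pos, kind="stable")
    return np.asarray(pos)[order], np.asarray(src)[order]


def calc_genoprob(
    cross: SimCross, step_cm: float = 1.0, error_rate: float = 1e-4
) -> GenoProbs:
    """Forward-backward genotype-class probabilities for every individual.

    Transitions between positions d cM apart use the Haldane recombination
    fraction independently per parent (4x4 = Kronecker square of the 2x2
    chain); emissions give weight 1 - error_rate to the observed class and
    error_rate/3 to the others, and are uniform at missing genotypes and
    pseudomarkers.
    """
    pos_rows = []
    prob_blocks = []
    for lg, sub in cross.gmap.groupby("lg", sort=False):
        cm = sub["cm"].to_numpy(dtype=float)
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"marker positions decrease within LG {lg}")
        cols = [cross.gmap.index.get_loc(i) for i in sub.index]
        obs = cross.geno[:, cols].astype(int)
        if obs.min() < 0 or obs.max() > 4:
            raise ValueError("genotype codes must lie in {0..4}")
        pos, src = _grid_positions(cm, step_cm)
        P = len(pos)
        n = obs.shape[0]
        E = np.ones((n, P, 4))
        for j in range(P):
            if src[j] >= 0:
                E[:, j, :] = _emissions(obs[:, src[j]], error_rate)
        trans = [_transition(pos[j + 1] - pos[j]) for j in range(P - 1)]
        fwd = np.empty((n, P, 4))
        f = 0.25 * E[:, 0, :]
        fwd[:, 0, :] = f / f.sum(axis=1, keepdims=True)
        for j in range(1, P):
            f = (fwd[:, j - 1, :] @ trans[j - 1]) * E[:, j, :]
            fwd[:, j, :] = f / f.sum(axis=1, keepdims=True)
        post = np.empty((n, P, 4))
        b = np.ones((n, 4))
        post[:, P - 1, :] = fwd[:, P - 1, :]
        for j in range(P - 2, -1, -1):
            b = (b * E[:, j + 1, :]) @ trans[j].T
            b /= b.sum(axis=1, keepdims=True)
            p = fwd[:, j, :] * b
            post[:, j, :] = p / p.sum(axis=1, keepdims=True)
        prob_blocks.append(post)
        markers = sub["marker"].tolist()
        for j in range(P):
            pos_rows.append(
                {
                    "lg": lg,
                    "cm": float(pos[j]),
                    "name": markers[src[j]] if src[j] >= 0 else f"LG{lg}_c{pos[j]:g}",
                    "is_marker": src[j] >= 0,
                }
            )
    probs = np.concatenate(prob_blocks, axis=1)
    return GenoProbs(pd.DataFrame(pos_rows), probs, list(cross.ids), error_rate, step_cm)


# ---------------------------------------------------------------------------
# Haley-Knott regression


def _design_null(n: int, C: np.ndarray | None) -> np.ndarray:
    ones = np.ones((n, 1))
    return ones if C is None else np.hstack([ones, C])


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0])
    return float(np.sum((y - X @ coef) ** 2))


def _check_covariates(trait: str, covariate_names: tuple) -> None:
    if trait and trait in covariate_names:
        raise ValueError(f"trait {trait!r} cannot be its own covariate")


def _prep(y: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    y = np.asarray(y, dtype=float)
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    obs = ~np.isnan(y)
    if C is not None:
        obs &= ~np.isnan(C).any(axis=1)
        C = C[obs]
    return y[obs], C, obs


def hk_scan(
    probs: GenoProbs,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    trait: str = "",
    year: object = None,
    covariate_names: tuple = (),
) -> ScanCurve:
    """Single-QTL Haley-Knott genome scan.

    At each grid position the phenotype is regressed on [1, covariates,
    three genotype-probability contrasts]; the LOD compares that fit to
    the covariate-only null.
    """
    _check_covariates(trait, covariate_names)
    yo, C, obs = _prep(y, covariates)
    n = len(yo)
    X0 = _design_null(n, C)
    if n <= X0.shape[1] + 3:
        raise ValueError("too few individuals for the scan design")
    rss0 = _rss(X0, yo)
    P = probs.probs[obs][:, :, 1:]  # drop the ac column: 3 contrasts
    lods = np.zeros(P.shape[1])
    tol = 1e-12 * max(1.0, float(np.sum(yo**2)))
    if rss0 > tol:
        for j in range(P.shape[1]):
            X1 = np.hstack([X0, P[:, j, :]])
            lods[j] = 0.5 * n * np.log10(rss0 / max(_rss(X1, yo), tol * 1e-3))
    table = probs.positions.copy()
    table["lod"] = np.clip(lods, 0.0, None)
    return ScanCurve(table, 3, trait, year, tuple(covariate_names))


def hk_scan_batch(probs: GenoProbs, Y: np.ndarray) -> np.ndarray:
    """LOD matrix (positions x phenotype columns) without covariates.

    Shares the per-position QR factorization across many phenotypes, which
    makes permutation thresholds and replicate studies cheap.  Rows of
    ``Y`` must be complete (no NaN).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0, keepdims=True)
    rss0 = np.sum(Yc**2, axis=0)
    P = probs.probs.shape[1]
    lods = np.empty((P, Y.shape[1]))
    ones = np.ones((n, 1))
    for j in range(P):
        X = np.hstack([ones, probs.probs[:, j, 1:]])
        Q, _ = np.linalg.qr(X)
        proj = Q.T @ Y
        rss1 = np.sum(Y**2, axis=0) - np.sum(proj**2, axis=0)
        lods[j] = 0.5 * n * np.log10(np.maximum(rss0, 1e-300) / np.maximum(rss1, 1e-300))
    return np.clip(lods, 0.0, None)


def perm_threshold(
    probs: GenoProbs,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> Penalty:
    """Genome-wide LOD threshold by phenotype permutation.

    Phenotype rows are shuffled against genotype rows; covariate rows
    travel with the phenotype, preserving the trait-covariate correlation
    under the genome-wide null.  T_m is the empirical (1 - alpha) quantile
    (linear / type-7 interpolation) of the genome-wide maximum LOD.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    yo, C, obs = _prep(y, covariates)
    n = len(yo)
    sub = GenoProbs(probs.positions, probs.probs[obs], [], probs.error_rate, probs.step_cm)
    if C is None:
        perms = np.stack([rng.permutation(n) for _ in range(n_perm)], axis=1)
        maxlod = hk_scan_batch(sub, yo[perms]).max(axis=0)
    else:
        maxlod = np.empty(n_perm)
        for k in range(n_perm):
            perm = rng.permutation(n)
            inv = np.empty(n, dtype=int)
            inv[perm] = np.arange(n)
            # permuting (y, C) jointly == inverse-permuting the genotypes
            shuf = GenoProbs(sub.positions, sub.probs[inv], [], sub.error_rate, sub.step_cm)
            maxlod[k] = hk_scan(shuf, yo, C).max_lod()
    T_m = float(np.quantile(maxlod, 1.0 - alpha, method="linear"))
    return Penalty(T_m, alpha, n_perm, seed)


# ---------------------------------------------------------------------------
# stepwise additive model selection


def _model_design(probs_obs: np.ndarray, qtl_idx: list[int], C: np.ndarray | None) -> np.ndarray:
    n = probs_obs.shape[0]
    cols = [np.ones((n, 1))]
    if C is not None:
        cols.append(C)
    for j in qtl_idx:
        cols.append(probs_obs[:, j, 1:])
    return np.hstack(cols)


def _model_lod(probs_obs, qtl_idx, yo, C, rss0) -> float:
    tol = 1e-12 * max(1.0, float(np.sum(yo**2)))
    if not qtl_idx or rss0 <= tol:
        return 0.0
    rss = _rss(_model_design(probs_obs, qtl_idx, C), yo)
    return 0.5 * len(yo) * np.log10(rss0 / max(rss, tol * 1e-3))


def _conditional_scan(probs_obs, qtl_idx, yo, C, rss0, candidates) -> np.ndarray:
    """LOD of (model + one candidate position) for each candidate."""
    lods = np.zeros(len(candidates))
    tol = 1e-12 * max(1.0, float(np.sum(yo**2)))
    if rss0 <= tol:
        return lods
    base = _model_design(probs_obs, qtl_idx, C)
    for k, j in enumerate(candidates):
        X = np.hstack([base, probs_obs[:, j, 1:]])
        rss = _rss(X, yo)
        lods[k] = 0.5 * len(yo) * np.log10(rss0 / max(rss, tol * 1e-3))
    return lods


def stepwise_additive(
    probs: GenoProbs,
    y: np.ndarray,
    penalty: Penalty,
    covariates: np.ndarray | None = None,
    max_qtl: int = 6,
    refine_window_cm: float = 10.0,
    drop: float = 1.5,
    trait: str = "",
    year: object = None,
    covariate_names: tuple = (),
) -> QTLModel:
    """Forward/backward additive multi-QTL selection under pLOD.

    pLOD(model) = LOD(model vs covariate-only null) - T_m * (#QTL).  The
    forward step adds the position that maximizes pLOD as long as it
    increases; backward deletion then removes QTL whose loss raises pLOD;
    finally each QTL is locally rescanned within ``refine_window_cm``.
    Returns drop-one LODs, class-effect estimates, drop-one explained
    variance and 1.5-LOD support intervals for every retained QTL.
    """
    _check_covariates(trait, covariate_names)
    yo, C, obs = _prep(y, covariates)
    n = len(yo)
    probs_obs = probs.probs[obs]
    rss0 = _rss(_design_null(n, C), yo)
    pos = probs.positions
    all_idx = np.arange(len(pos))
    lg_of = pos["lg"].to_numpy()
    cm_of = pos["cm"].to_numpy(dtype=float)

    model: list[int] = []
    cur_plod = 0.0
    for _ in range(max_qtl):
        cands = [j for j in all_idx if all(
            lg_of[j] != lg_of[q] or abs(cm_of[j] - cm_of[q]) > 1e-9 for q in model)]
        lods = _conditional_scan(probs_obs, model, yo, C, rss0, cands)
        k = int(np.argmax(lods))
        new_plod = lods[k] - penalty.T_m * (len(model) + 1)
        if new_plod <= cur_plod + 1e-9:
            break
        model.append(cands[k])
        cur_plod = new_plod
        # backward deletion
        improved = True
        while improved and len(model) > 1:
            improved = False
            for q in list(model):
                rest = [m for m in model if m != q]
                plod = _model_lod(probs_obs, rest, yo, C, rss0) - penalty.T_m * len(rest)
                if plod > cur_plod + 1e-9:
                    model = rest
                    cur_plod = plod
                    improved = True
                    break

    # one round of local position refinement
    for i, q in enumerate(list(model)):
        near = [int(j) for j in all_idx
                if lg_of[j] == lg_of[q] and abs(cm_of[j] - cm_of[q]) <= refine_window_cm
                and j not in model]
        near.append(q)
        others = [m for m in model if m != q]
        lods = _conditional_scan(probs_obs, others, yo, C, rss0, near)
        best = near[int(np.argmax(lods))]
        model[i] = best
    cur_plod = _model_lod(probs_obs, model, yo, C, rss0) - penalty.T_m * len(model)

    # summaries
    qtls: list[QTL] = []
    full_rss = _rss(_model_design(probs_obs, model, C), yo) if model else rss0
    tss = float(np.sum((yo - yo.mean()) ** 2))
    full_lod = _model_lod(probs_obs, model, yo, C, rss0)
    for q in model:
        others = [m for m in model if m != q]
        rss_wo = _rss(_model_design(probs_obs, others, C), yo) if others else rss0
        lod_q = 0.5 * n * np.log10(max(rss_wo, 1e-300) / max(full_rss, 1e-300))
        pct_q = 100.0 * (rss_wo - full_rss) / tss
        # conditional scan over the QTL's LG for the support interval
        lg_idx = [int(j) for j in all_idx if lg_of[j] == lg_of[q]]
        cond = _conditional_scan(probs_obs, others, yo, C, rss0, lg_idx)
        curve = pd.DataFrame({"lg": lg_of[lg_idx], "cm": cm_of[lg_idx], "lod": cond})
        lo, hi = support_interval(curve, float(cm_of[q]), drop=drop)
        coef, *_ = np.linalg.lstsq(_model_design(probs_obs, model, C), yo, rcond=None)
        off = 1 + (0 if C is None else C.shape[1]) + 3 * model.index(q)
        eff = np.concatenate([[0.0], coef[off : off + 3]])
        eff -= eff.mean()
        qtls.append(QTL(lg_of[q], float(cm_of[q]), float(lod_q), eff,
                        float(pct_q), lo, hi))
    full_pct = 100.0 * (1.0 - full_rss / tss) if model else 0.0
    qtls.sort(key=lambda q: (str(q.lg), q.cm))
    return QTLModel(qtls, float(full_pct), float(cur_plod), trait, year,
                    tuple(covariate_names))


def support_interval(curve: pd.DataFrame, peak_cm: float, drop: float = 1.5) -> tuple[float, float]:
    """1.5-LOD support interval on one linkage group's scan curve.

    The contiguous run of grid positions around the peak with LOD within
    ``drop`` of the peak LOD, expanded by one grid point beyond each
    crossing (one-sided at LG boundaries).
    """
    sub = curve.sort_values("cm").reset_index(drop=True)
    cm = sub["cm"].to_numpy(dtype=float)
    lod = sub["lod"].to_numpy(dtype=float)
    k = int(np.argmin(np.abs(cm - peak_cm)))
    thr = lod[k] - drop
    lo = k
    while lo > 0 and lod[lo - 1] >= thr:
        lo -= 1
    hi = k
    while hi < len(cm) - 1 and lod[hi + 1] >= thr:
        hi += 1
    lo = max(lo - 1, 0)
    hi = min(hi + 1, len(cm) - 1)
    return float(cm[lo]), float(cm[hi])


def explained_variance(
    model: QTLModel, probs: GenoProbs, y: np.ndarray, covariates: np.ndarray | None = None
) -> QTLModel:
    """Recompute full-model and drop-one explained variance for a model.

    full = 100 (1 - RSS_full / TSS); per-QTL = 100 (RSS_without - RSS_full) / TSS.
    """
    yo, C, obs = _prep(y, covariates)
    probs_obs = probs.probs[obs]
    pos = probs.positions
    idx = []
    for q in model.qtls:
        match = np.nonzero((pos["lg"].to_numpy() == q.lg)
                           & (np.abs(pos["cm"].to_numpy(dtype=float) - q.cm) < 1e-9))[0]
        idx.append(int(match[0]))
    tss = float(np.sum((yo - yo.mean()) ** 2))
    rss0 = _rss(_design_null(len(yo), C), yo)
    full_rss = _rss(_model_design(probs_obs, idx, C), yo) if idx else rss0
    for q, j in zip(model.qtls, idx):
        others = [m for m in idx if m != j]
        rss_wo = _rss(_model_design(probs_obs, others, C), yo) if others else rss0
        q.pct_var = float(100.0 * (rss_wo - full_rss) / tss)
    model.full_model_pct_var = float(100.0 * (1.0 - full_rss / tss)) if idx else 0.0
    return model


# ---------------------------------------------------------------------------
# collocation across years and the covariate diallel


def models_to_table(models: list[QTLModel]) -> pd.DataFrame:
    rows = []
    for m in models:
        for q in m.qtls:
            rows.append(
                {
                    "trait": m.trait,
                    "year": m.year,
                    "covariate": "+".join(m.covariates) if m.covariates else "",
                    "lg": q.lg,
                    "peak_cm": q.cm,
                    "lod": q.lod,
                    "pct_var": q.pct_var,
                    "ci_lo": q.ci_lo,
                    "ci_hi": q.ci_hi,
                }
            )
    cols = ["trait", "year", "covariate", "lg", "peak_cm", "lod", "pct_var", "ci_lo", "ci_hi"]
    return pd.DataFrame(rows, columns=cols)


def collocate(
    qtl_table: pd.DataFrame,
    window_cm: float = 8.0,
    min_years: int = 2,
    mode: str = "peak",
) -> pd.DataFrame:
    """Group same-trait QTL recurring across years on the same LG.

    ``mode='peak'`` groups peaks whose pairwise distance is at most
    ``window_cm`` (complete linkage, strict <=); ``mode='interval'``
    instead requires every pair of support intervals to overlap.  Groups
    spanning at least ``min_years`` distinct years are reported.
    """
    rows = []
    gid = 0
    if qtl_table.empty or qtl_table["year"].nunique() < 2:
        return pd.DataFrame(
            columns=["group", "trait", "lg", "n_years", "years", "mean_cm", "peaks"])
    for (trait, lg), sub in qtl_table.groupby(["trait", "lg"], sort=True):
        sub = sub.reset_index(drop=True)
        if len(sub) == 1:
            clusters = np.array([1])
        else:
            if mode == "peak":
                d = np.abs(sub["peak_cm"].to_numpy()[:, None]
                           - sub["peak_cm"].to_numpy()[None, :])
            elif mode == "interval":
                lo = sub["ci_lo"].to_numpy()
                hi = sub["ci_hi"].to_numpy()
                gap = np.maximum(lo[:, None], lo[None, :]) - np.minimum(hi[:, None], hi[None, :])
                d = np.where(gap <= 0, 0.0, gap)
            else:
                raise ValueError(f"unknown collocation mode {mode!r}")
            cond = d[np.triu_indices(len(sub), 1)]
            thr = window_cm if mode == "peak" else 0.0
            clusters = fcluster(linkage(cond, method="complete"), thr, criterion="distance")
        for c in np.unique(clusters):
            grp = sub[clusters == c]
            years = sorted(grp["year"].unique())
            if len(years) < min_years:
                continue
            gid += 1
            rows.append(
                {
                    "group": gid,
                    "trait": trait,
                    "lg": lg,
                    "n_years": len(years),
                    "years": ",".join(str(y) for y in years),
                    "mean_cm": float(grp["peak_cm"].mean()),
                    "peaks": ";".join(f"{y}:{p:.1f}" for y, p in
                                      zip(grp["year"], grp["peak_cm"])),
                }
            )
    return pd.DataFrame(rows, columns=["group", "trait", "lg", "n_years", "years",
                                       "mean_cm", "peaks"])


def covariate_diallel(
    probs: GenoProbs,
    traits: pd.DataFrame,
    trait_names: list[str],
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    window_cm: float = 8.0,
    max_qtl: int = 6,
) -> pd.DataFrame:
    """Stepwise scans for every ordered (trait, covariate) pair.

    ``traits`` is a genotype x year table (columns: genotype, year, one
    column per trait) aligned to ``probs.ids`` within each year.  For each
    pair with trait != covariate a per-year stepwise model is fitted with
    the covariate included, QTL collocated across all years are reported,
    and those absent from the matching univariate results are flagged
    ``novel``.  Using a trait as its own covariate raises ``ValueError``.
    """
    years = sorted(traits["year"].unique())
    by_year = {}
    for yr in years:
        sub = traits[traits["year"] == yr].set_index("genotype").reindex(probs.ids)
        by_year[yr] = sub

    def fit_models(trait: str, cov: str | None) -> list[QTLModel]:
        if cov == trait:
            raise ValueError(f"trait {trait!r} cannot be its own covariate")
        models = []
        for yr in years:
            y = by_year[yr][trait].to_numpy(dtype=float)
            C = None if cov is None else by_year[yr][cov].to_numpy(dtype=float)
            child = zlib.crc32(f"{trait}|{cov}|{yr}".encode()) % 100000
            pen = perm_threshold(probs, y, C, n_perm=n_perm, alpha=alpha,
                                 seed=seed + child)
            models.append(
                stepwise_additive(probs, y, pen, C, max_qtl=max_qtl, trait=trait,
                                  year=yr, covariate_names=() if cov is None else (cov,))
            )
        return models

    uni_groups: dict[str, pd.DataFrame] = {}
    for trait in trait_names:
        tab = models_to_table(fit_models(trait, None))
        uni_groups[trait] = collocate(tab, window_cm, min_years=len(years))
    rows = []
    for trait in trait_names:
        for cov in trait_names:
            if cov == trait:
                continue
            tab = models_to_table(fit_models(trait, cov))
            grp = collocate(tab, window_cm, min_years=len(years))
            for _, g in grp.iterrows():
                uni = uni_groups[trait]
                novel = True
                if not uni.empty:
                    same = uni[(uni["lg"] == g["lg"])
                               & (np.abs(uni["mean_cm"] - g["mean_cm"]) <= window_cm)]
                    novel = same.empty
                rows.append(
                    {
                        "trait": trait,
                        "covariate": cov,
                        "lg": g["lg"],
                        "mean_cm": g["mean_cm"],
                        "n_years": g["n_years"],
                        "novel": novel,
                    }
                )
    return pd.DataFrame(rows, columns=["trait", "covariate", "lg", "mean_cm",
                                       "n_years", "novel"])
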