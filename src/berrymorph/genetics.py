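"""Kinship-BLUP and genomic heritability for the four-way cross.

Repeated fruit measurements are first averaged per genotype and year.  A
marker-based additive relationship matrix is then built from the four-way
genotype codes, and for each trait-year the one-random-effect mixed model

    y = 1 mu + u + e,   u ~ N(0, A sigma_u^2),   e ~ N(0, I sigma_e^2)

is fitted by REML, profiled down to a one-dimensional search over the
variance ratio lambda = sigma_u^2 / sigma_e^2 on the spectral decomposition
of A.  Genomic heritability is reported on the genotype-mean scale,
h^2 = sigma_u^2 / (sigma_u^2 + sigma_e^2).

Kinship encoding: each four-way marker (classes ac, ad, bc, bd) is split
into two biallelic indicator loci — "maternal allele is a" and "paternal
allele is c" — which preserves both parental segregations.  Indicators are
centred by their observed frequency and the cross-product is scaled by the
summed indicator variances (VanRaden-style), giving a mean diagonal near 1
and mean off-diagonal near 0.5 for full sibs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

TRAITS = ("length", "width", "area", "lw_ratio", "eccentricity", "pc1", "pc2")


@dataclass
class KinshipMatrix:
    A: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape[0] != self.A.shape[1] or self.A.shape[0] != len(self.ids):
            raise ValueError("kinship matrix / id length mismatch")


@dataclass
class MixedModelFit:
    sigma2_u: float
    sigma2_e: float
    mu: float
    u: np.ndarray
    h2: float
    loglik_reml: float


def genotype_means(per_fruit: pd.DataFrame, trait_cols: list[str] | None = None) -> pd.DataFrame:
    """Average repeated fruit measurements per genotype and year.

    Expects a long table with ``genotype`` and ``year`` columns plus one
    column per trait; returns one row per genotype-year with arithmetic
    means and an ``n_fruit`` count.  Genotype-years absent from the input
    simply have no row; callers that need a complete design should reindex
    and will see missing values there.
    """
    if trait_cols is None:
        drop = {"genotype", "year", "fruit", "scene_id", "fruit_id"}
        trait_cols = [c for c in per_fruit.columns
                      if c not in drop and np.issubdtype(per_fruit[c].dtype, np.number)]
    g = per_fruit.groupby(["genotype", "year"], sort=True)
    out = g[trait_cols].mean()
    out["n_fruit"] = g.size()
    return out.reset_index()


def fourway_indicators(geno: np.ndarray) -> np.ndarray:
    """Two indicator dosages per marker: maternal allele = a, paternal = c.

    Codes are 1=ac, 2=ad, 3=bc, 4=bd, 0=missing; missing entries are
    imputed to the observed column mean of each indicator.
    """
    geno = np.asarray(geno)
    mat_a = np.isin(geno, (1, 2)).astype(float)
    pat_c = np.isin(geno, (1, 3)).astype(float)
    miss = geno == 0
    out = np.concatenate([mat_a, pat_c], axis=1)
    miss2 = np.concatenate([miss, miss], axis=1)
    if miss2.any():
        masked = np.where(miss2, np.nan, out)
        col_mean = np.nanmean(masked, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.5, col_mean)
        out = np.where(miss2, col_mean[None, :], out)
    return out


def kinship(
    geno: np.ndarray, ids: list[str], center: str = "observed", ridge: float = 1e-8
) -> KinshipMatrix:
    """Marker-based additive relationship matrix from four-way codes.

    A = W W' / sum_k p_k (1 - p_k) over all (non-monomorphic) indicator
    columns, with W the centred indicators.  Within a single full-sib
    family every offspring draws its parental alleles independently, so
    this matrix captures Mendelian-sampling covariance around the family
    mean: the diagonal averages ~1 and the off-diagonal averages ~0 (it is
    the deviation from the family expectation, not the pedigree value of
    0.5, that carries information for within-family BLUP).
    ``center='expected'`` centres at the theoretical segregation frequency
    p = 1/2 instead of the observed one.  A small ridge is added to the
    diagonal to guarantee positive semidefiniteness.
    """
    geno = np.asarray(geno)
    if geno.shape[0] < 2 or geno.shape[1] < 10:
        raise ValueError("kinship needs >= 2 individuals and >= 10 markers")
    if np.any((geno == 0).all(axis=1)):
        raise ValueError("individual with all genotypes missing")
    W = fourway_indicators(geno)
    p_obs = W.mean(axis=0)
    keep = (p_obs > 0) & (p_obs < 1)
    if not keep.any():
        raise ValueError("all indicator columns are monomorphic")
    if center == "observed":
        p = p_obs[keep]
    elif center == "expected":
        p = np.full(int(keep.sum()), 0.5)
    else:
        raise ValueError(f"unknown centering {center!r}")
    Wc = W[:, keep] - p[None, :]
    denom = float(np.sum(p * (1.0 - p)))
    A = Wc @ Wc.T / denom
    A[np.diag_indices_from(A)] += ridge
    return KinshipMatrix(A, list(ids))


def _reml_neg_loglik(log_lam: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> float:
    """Negative restricted log-likelihood profiled over mu and sigma_e^2.

    d are eigenvalues of A, yt/xt the rotated response and intercept.
    """
    lam = np.exp(log_lam)
    v = lam * d + 1.0  # V / sigma_e^2, diagonal in the eigenbasis
    w = 1.0 / v
    xtwx = float(np.sum(w * xt * xt))
    xtwy = float(np.sum(w * xt * yt))
    beta = xtwy / xtwx
    r = yt - xt * beta
    n = len(yt)
    rss = float(np.sum(w * r * r))
    sigma2e = rss / (n - 1)
    ll = -0.5 * (
        np.sum(np.log(v))
        + (n - 1) * np.log(sigma2e)
        + np.log(xtwx)
        + (n - 1)
    )
    return -ll


def reml_fit(
    y: np.ndarray,
    K: KinshipMatrix,
    log_lambda_bounds: tuple[float, float] = (-10.0, 10.0),
    tol: float = 1e-6,
) -> MixedModelFit:
    """REML fit of the kinship mixed model for one trait-year.

    Missing phenotypes are dropped casewise (with the matching rows and
    columns of A).  The restricted likelihood is maximized over
    log(lambda) by bounded scalar minimization on the eigenbasis of A;
    BLUPs come from the mixed-model equations at the optimum and are
    reported for all individuals, with dropped ones set to NaN.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(K.ids):
        raise ValueError("phenotype / kinship dimension mismatch")
    obs = ~np.isnan(y)
    if obs.sum() < 10:
        raise ValueError("need >= 10 non-missing phenotypes")
    yo = y[obs]
    A = K.A[np.ix_(obs, obs)]
    n = len(yo)
    if np.var(yo) == 0:
        u = np.full(len(y), np.nan)
        u[obs] = 0.0
        return MixedModelFit(0.0, 0.0, float(yo[0]), u, 0.0, np.nan)
    d, U = np.linalg.eigh(A)
    if d.min() < -1e-6:
        raise ValueError("kinship matrix not PSD even after ridge")
    d = np.clip(d, 0.0, None)
    yt = U.T @ yo
    xt = U.T @ np.ones(n)
    res = minimize_scalar(
        _reml_neg_loglik,
        bounds=log_lambda_bounds,
        args=(d, yt, xt),
        method="bounded",
        options={"xatol": tol},
    )
    lam = float(np.exp(res.x))
    v = lam * d + 1.0
    w = 1.0 / v
    beta = float(np.sum(w * xt * yt) / np.sum(w * xt * xt))
    r = yt - xt * beta
    sigma2e = float(np.sum(w * r * r) / (n - 1))
    sigma2u = lam * sigma2e
    # BLUP: u = lam * A (lam A + I)^{-1} (y - mu), in the eigenbasis
    u_rot = lam * d * w * r
    u_obs = U @ u_rot
    u = np.full(len(y), np.nan)
    u[obs] = u_obs
    h2 = sigma2u / (sigma2u + sigma2e) if (sigma2u + sigma2e) > 0 else 0.0
    return MixedModelFit(sigma2u, sigma2e, beta, u, float(h2), float(-res.fun))


def reml_profile(
    y: np.ndarray, K: KinshipMatrix, log_lambda_grid: np.ndarray
) -> np.ndarray:
    """Restricted log-likelihood along a grid of log(lambda).

    Exposed so the 1-D optimizer can be cross-checked against an
    exhaustive grid search on small fixtures.
    """
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(y)
    yo = y[obs]
    A = K.A[np.ix_(obs, obs)]
    d, U = np.linalg.eigh(A)
    d = np.clip(d, 0.0, None)
    yt = U.T @ yo
    xt = U.T @ np.ones(len(yo))
    return np.array([-_reml_neg_loglik(g, d, yt, xt) for g in log_lambda_grid])


def fit_all_traits(
    means: pd.DataFrame, K: KinshipMatrix, trait_cols: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per trait-year REML fits over a genotype-mean table.

    Returns ``(blups, h2)``: a long BLUP table (genotype, year, trait,
    mean, blup) and a variance-component table (trait, year, h2, sigma2_u,
    sigma2_e).
    """
    blup_rows = []
    h2_rows = []
    for year, sub in means.groupby("year", sort=True):
        sub = sub.set_index("genotype").reindex(K.ids)
        for trait in trait_cols:
            yv = sub[trait].to_numpy(dtype=float)
            fit = reml_fit(yv, K)
            h2_rows.append(
                {"trait": trait, "year": year, "h2": fit.h2,
                 "sigma2_u": fit.sigma2_u, "sigma2_e": fit.sigma2_e}
            )
            for gid, raw, b in zip(K.ids, yv, fit.u):
                blup_rows.append(
                    {"genotype": gid, "year": year, "trait": trait,
                     "mean": raw, "blup": b}
                )
    return pd.DataFrame(blup_rows), pd.DataFrame(h2_rows)
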