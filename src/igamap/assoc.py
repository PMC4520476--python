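"""Mixed-model association and combination of per-run p-values.

Cryptic relatedness and subpopulation structure are controlled by a two-stage
strategy: a polygenic model y = Xb + g + e with cov(g) = s2_g * K (K an
allele-sharing kinship matrix) is fitted once per phenotype run by REML, and
each marker is then tested with a 1-df score test against the variance-adjusted
residuals.  P-values are left uncorrected (no genomic control).  The four runs
(3-, 4-, 5-percentile groups and extreme case/control) are merged per marker by
the geometric mean

    p_hat = (prod_i p_i) ** (1/n),

whose significance is interpreted only against permutation thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import GenotypeMatrix, PhenotypeTable, logger
from .phenotype import (
    CASE,
    EXCLUDED,
    _ibs_matrix,
    extreme_case_control,
    percentile_groups,
)

RUN_LABELS = ("groups3", "groups4", "groups5", "extremes")


@dataclass
class KinshipMatrix:
    samples: list[str]
    values: np.ndarray  # symmetric allele-sharing similarity

    def subset(self, idx: np.ndarray) -> "KinshipMatrix":
        idx = np.flatnonzero(idx) if np.asarray(idx).dtype == bool else np.asarray(idx)
        return KinshipMatrix([self.samples[i] for i in idx],
                             self.values[np.ix_(idx, idx)])


def kinship_matrix(g: GenotypeMatrix) -> KinshipMatrix:
    """IBS-style allele-sharing similarity over pairwise-complete markers."""
    if g.n_samples < 2 or g.n_markers < 10:
        raise ValueError("kinship needs >= 2 samples and >= 10 markers")
    return KinshipMatrix(list(g.samples), _ibs_matrix(g.dosage))


@dataclass
class PolygenicFit:
    """REML fit of the polygenic null model for one phenotype run."""

    beta: np.ndarray
    sigma_g: float
    sigma_e: float
    heritability: float
    residuals: np.ndarray            # y - X beta, original scale
    reml_loglik: float
    # cached rotated-space quantities for fast score tests
    _U: np.ndarray = field(repr=False, default=None)
    _w: np.ndarray = field(repr=False, default=None)          # 1/(s2_g*lam + s2_e)
    _Xr: np.ndarray = field(repr=False, default=None)
    _Pyr: np.ndarray = field(repr=False, default=None)        # P y, rotated
    _XtWX_inv: np.ndarray = field(repr=False, default=None)


def _normalized_kinship(K: np.ndarray) -> np.ndarray:
    """Rescale raw allele-sharing to a relationship scale: background
    (mean off-diagonal) sharing maps to 0 and self-similarity to 1.  Under
    REML with an intercept this changes only the scale on which the variance
    components are reported, not the fit (the all-ones component is absorbed
    by the fixed effects)."""
    n = K.shape[0]
    off = ~np.eye(n, dtype=bool)
    background = K[off].mean() if n > 1 else 0.0
    denom = K.diagonal().mean() - background
    if denom <= 0:
        return np.eye(n)
    return (K - background) / denom


def _reml_neg_loglik(h2: float, lam: np.ndarray, Xr: np.ndarray, yr: np.ndarray) -> float:
    n, p = Xr.shape
    w = 1.0 / (h2 * lam + (1 - h2))
    XtWX = (Xr * w[:, None]).T @ Xr
    XtWy = (Xr * w[:, None]).T @ yr
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    r = yr - Xr @ beta
    rss = float(r @ (w * r))
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    ll = -0.5 * ((n - p) * np.log(sigma2) - np.log(w).sum() + logdet_XtWX + (n - p))
    return -ll


def polygenic_fit(y: np.ndarray, covariates: np.ndarray, K: KinshipMatrix) -> PolygenicFit:
    """REML variance components for y = Xb + g + e with cov(g) prop. to K.

    ``covariates`` is the fixed-effect design without intercept (one is added).
    Negative kinship eigenvalues (possible for IBS similarity) are clipped at
    zero.  Raises on optimizer failure.
    """
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.atleast_2d(np.asarray(covariates, float).T).T]) \
        if covariates is not None and np.size(covariates) else np.ones((len(y), 1))
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("covariates and trait must be complete")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear fixed-effect design")

    lam, U = np.linalg.eigh(_normalized_kinship(K.values))
    lam = np.clip(lam, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X

    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(1e-6, 1 - 1e-6), args=(lam, Xr, yr), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"REML optimizer failed: {res}")
    h2 = float(res.x)
    # at an interior optimum barely distinguishable from h2=0, prefer the
    # boundary (identity-covariance) solution for stability
    if _reml_neg_loglik(1e-9, lam, Xr, yr) <= res.fun:
        h2 = 1e-9

    n, p = Xr.shape
    w = 1.0 / (h2 * lam + (1 - h2))
    XtWX = (Xr * w[:, None]).T @ Xr
    XtWX_inv = np.linalg.inv(XtWX)
    beta = XtWX_inv @ ((Xr * w[:, None]).T @ yr)
    r = yr - Xr @ beta
    sigma2 = float(r @ (w * r)) / (n - p)
    # P y in rotated space is W r - W X (X'WX)^-1 X' W r; the GLS normal
    # equations give X' W r = 0, so P y = W r exactly.
    Pyr = w * r
    return PolygenicFit(
        beta=beta,
        sigma_g=h2 * sigma2,
        sigma_e=(1 - h2) * sigma2,
        heritability=h2,
        residuals=np.asarray(y - X @ beta),
        reml_loglik=-float(res.fun),
        _U=U, _w=w, _Xr=Xr, _Pyr=Pyr, _XtWX_inv=XtWX_inv,
    )


def _score_from_rotated(fit: PolygenicFit, Gr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 1-df score test for rotated marker columns (n x m).

    The squared standardized score T2 = (g'Py)^2 / (g'Pg * s2) satisfies
    T2/(n-p) ~ Beta(1/2, (n-p-1)/2) under the null with known variance ratio
    (the residual variance estimate is part of the statistic), so p-values are
    taken from the equivalent F(1, n-p-1) transform rather than the asymptotic
    chi-square, which is visibly non-uniform at cohort scale.
    """
    w, Xr, Pyr, XtWX_inv = fit._w, fit._Xr, fit._Pyr, fit._XtWX_inv
    sigma2 = fit.sigma_g + fit.sigma_e
    n, p = Xr.shape
    score = Gr.T @ Pyr                                      # g' P y (up to sigma2)
    GW = Gr * w[:, None]
    gWg = np.einsum("ij,ij->j", Gr, GW)
    gWX = GW.T @ Xr                                          # m x p
    var = gWg - np.einsum("ij,ij->i", gWX @ XtWX_inv, gWX)
    # markers (near-)constant after covariate projection carry no information
    informative = var > 1e-9 * np.maximum(gWg, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(informative, score**2 / (var * sigma2), 0.0)
    t2 = np.clip(t2, 0.0, (n - p) * (1 - 1e-12))
    f_stat = t2 * (n - p - 1) / (n - p - t2)
    pvals = stats.f.sf(f_stat, 1, n - p - 1)
    pvals = np.where(informative, pvals, 1.0)
    return pvals, np.sign(score)


def score_test(fit: PolygenicFit, dosage: np.ndarray) -> tuple[float, float]:
    """Score test for one marker; missing dosages are mean-imputed.

    Returns (two-sided p, effect sign).  A marker monomorphic among the
    non-missing samples gives p = 1 with a warning.
    """
    d = np.asarray(dosage, dtype=float).copy()
    obs = ~np.isnan(d)
    if obs.sum() == 0 or np.nanstd(d) == 0:
        warnings.warn("monomorphic marker tested; p set to 1")
        return 1.0, 0.0
    d[~obs] = d[obs].mean()
    Gr = fit._U.T @ d[:, None]
    p, sign = _score_from_rotated(fit, Gr)
    return float(p[0]), float(sign[0])


@dataclass
class AssocRun:
    """One GWAS run: per-marker p-values (the 1-df P1df) and effect signs."""

    label: str
    marker_ids: np.ndarray
    p: np.ndarray
    sign: np.ndarray
    n_samples: int
    fit: PolygenicFit | None = None


@dataclass
class CombinedResult:
    """Per-marker geometric-mean p_hat across runs."""

    marker_ids: np.ndarray
    p_hat: np.ndarray
    n_runs: int
    run_labels: tuple[str, ...]

    def as_frame(self, markers=None) -> pd.DataFrame:
        df = pd.DataFrame({"marker_id": self.marker_ids, "p_hat": self.p_hat})
        if markers is not None:
            ann = markers.table[["marker_id", "chrom", "pos"]]
            df = df.merge(ann, on="marker_id", how="left")
        return df


def combine_pvalues(runs: list[AssocRun]) -> CombinedResult:
    """Geometric mean of run p-values per marker; markers missing from any
    run are dropped with a warning."""
    if not runs:
        raise ValueError("empty run list")
    shared = runs[0].marker_ids
    for r in runs[1:]:
        shared = shared[np.isin(shared, r.marker_ids)]
    if any(len(shared) < len(r.marker_ids) for r in runs):
        warnings.warn("markers absent from some runs were dropped from the combination")
    logs = np.zeros(len(shared))
    for r in runs:
        idx = {m: i for i, m in enumerate(r.marker_ids)}
        order = np.fromiter((idx[m] for m in shared), dtype=int, count=len(shared))
        logs += np.log(r.p[order])
    p_hat = np.exp(logs / len(runs))
    return CombinedResult(shared, p_hat, len(runs), tuple(r.label for r in runs))


# ---------------------------------------------------------------------------
# the four-run pipeline
# ---------------------------------------------------------------------------


class MixedModelEngine:
    """Pre-rotated genotypes + kinship shared across runs and permutations."""

    def __init__(self, g: GenotypeMatrix, K: KinshipMatrix | None = None):
        self.g = g
        self.K = K if K is not None else kinship_matrix(g)
        lam, U = np.linalg.eigh(_normalized_kinship(self.K.values))
        self.lam = np.clip(lam, 0.0, None)
        self.U = U
        D = g.dosage.copy()
        mu = np.nanmean(D, axis=0)
        nan_mask = np.isnan(D)
        D[nan_mask] = np.take(mu, np.where(nan_mask)[1])
        self._D = D
        self.Gr = U.T @ D

    def run(self, y: np.ndarray, covariates: np.ndarray | None,
            sample_mask: np.ndarray | None = None,
            label: str = "run") -> AssocRun:
        """One association run; ``sample_mask`` restricts to a subset (the
        extremes design), in which case kinship and markers are re-rotated."""
        if sample_mask is not None and not sample_mask.all():
            idx = np.flatnonzero(sample_mask)
            Ksub = self.K.subset(idx)
            fit = polygenic_fit(y[idx],
                                covariates[idx] if covariates is not None else None,
                                Ksub)
            Gr = fit._U.T @ self._D[idx]
            pvals, signs = _score_from_rotated(fit, Gr)
            n_used = len(idx)
        else:
            fit = self._fit_prerotated(y, covariates)
            pvals, signs = _score_from_rotated(fit, self.Gr)
            n_used = self.g.n_samples
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
        return AssocRun(label, self.g.markers.marker_ids.copy(), pvals, signs, n_used, fit)

    def _fit_prerotated(self, y: np.ndarray, covariates: np.ndarray | None) -> PolygenicFit:
        y = np.asarray(y, float)
        X = np.column_stack([np.ones(len(y)),
                             np.atleast_2d(np.asarray(covariates, float).T).T]) \
            if covariates is not None and np.size(covariates) else np.ones((len(y), 1))
        yr = self.U.T @ y
        Xr = self.U.T @ X
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=(1e-6, 1 - 1e-6), args=(self.lam, Xr, yr),
            method="bounded", options={"xatol": 1e-8})
        h2 = float(res.x)
        if _reml_neg_loglik(1e-9, self.lam, Xr, yr) <= res.fun:
            h2 = 1e-9
        n, p = Xr.shape
        w = 1.0 / (h2 * self.lam + (1 - h2))
        XtWX_inv = np.linalg.inv((Xr * w[:, None]).T @ Xr)
        beta = XtWX_inv @ ((Xr * w[:, None]).T @ yr)
        r = yr - Xr @ beta
        sigma2 = float(r @ (w * r)) / (n - p)
        return PolygenicFit(beta=beta, sigma_g=h2 * sigma2, sigma_e=(1 - h2) * sigma2,
                            heritability=h2, residuals=y - X @ beta,
                            reml_loglik=-float(res.fun),
                            _U=self.U, _w=w, _Xr=Xr, _Pyr=w * r, _XtWX_inv=XtWX_inv)


def _covariate_design(pheno: pd.DataFrame) -> np.ndarray:
    """Age plus dummy-coded subpopulation (when present and non-constant)."""
    cols = [pheno["age"].to_numpy(float)]
    if "subpop" in pheno.columns and pheno["subpop"].notna().all():
        levels = sorted(pheno["subpop"].unique())
        for lev in levels[1:]:
            cols.append((pheno["subpop"] == lev).to_numpy(float))
    return np.column_stack(cols)


def run_multirun_gwas(
    g: GenotypeMatrix, p: PhenotypeTable, covariates: np.ndarray | None = None,
) -> tuple[CombinedResult, dict[str, AssocRun]]:
    """The four-run percentile-group GWAS on QC'd data, combined per marker.

    Runs groups3/4/5 with the group number as a numeric trait and the extreme
    case/control run on the reduced sample, then merges p-values by geometric
    mean.  ``covariates`` defaults to age (+ subpopulation dummies if present).
    """
    pheno = p.aligned_to(g.samples)
    iga = pheno["iga"].to_numpy(float)
    X = covariates if covariates is not None else _covariate_design(pheno)
    engine = MixedModelEngine(g)

    runs: dict[str, AssocRun] = {}
    for k, label in ((3, "groups3"), (4, "groups4"), (5, "groups5")):
        ga = percentile_groups(iga, k)
        try:
            runs[label] = engine.run(ga.group.astype(float), X, label=label)
        except Exception as exc:  # noqa: BLE001 - re-raise naming the run
            raise RuntimeError(f"GWAS run {label!r} failed: {exc}") from exc
        logger.info("run %s: n=%d", label, runs[label].n_samples)

    ecc = extreme_case_control(iga)
    mask = ecc.group != EXCLUDED
    try:
        runs["extremes"] = engine.run(
            (ecc.group == CASE).astype(float), X, sample_mask=mask, label="extremes")
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"GWAS run 'extremes' failed: {exc}") from exc
    logger.info("run extremes: n=%d (middle 50%% excluded)", runs["extremes"].n_samples)

    combined = combine_pvalues([runs[l] for l in RUN_LABELS])
    return combined, runs
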