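"""Precision-weighted linear modelling of paired DNA/RNA reporter counts.

Per 600-bp window the model on normalized log2-CPM abundance is

    y_i = mu + m_i*b1 + s_i*b2*I(m_i=0) + s_i*b3*I(m_i=1) + e_i

with m_i the methylation condition (0 = unmethylated, 1 = methylated) and
s_i the molecule label (0 = DNA input, 1 = RNA output). b2 and b3 are the
RNA-vs-DNA enrichments in the unmethylated and methylated states; a window
is enhancer-like when either is significantly positive, and
methylation-dependent when b2 and b3 differ (contrast b2 - b3).

Counts are converted to log2-CPM, library sizes rescaled by trimmed-mean
(TMM) normalization factors, and observations weighted by the inverse of a
lowess mean-variance trend (voom-style precision weights), optionally
combined with per-sample quality weights. Per-window variances are
moderated by empirical-Bayes shrinkage toward a scaled-inverse-chi-square
prior fit by method of moments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datamodel import SampleMeta

log = logging.getLogger("mstarr")

DESIGN_COLUMNS = ("intercept", "methylation", "rna_unmeth", "rna_meth")


def build_design(samples: Sequence[SampleMeta]) -> np.ndarray:
    """Samples x 4 design: [1, m, s*(1-m), s*m]; entries in {0,1}."""
    m = np.array([1.0 if s.methylation == "methylated" else 0.0 for s in samples])
    s_ = np.array([1.0 if s.molecule == "RNA" else 0.0 for s in samples])
    X = np.column_stack([np.ones_like(m), m, s_ * (1.0 - m), s_ * m])
    return X


def log_cpm(
    counts: np.ndarray, library_sizes: np.ndarray, prior_count: float = 0.5
) -> np.ndarray:
    """log2((count + prior) / (library_size + 1) * 1e6)."""
    lib = np.asarray(library_sizes, dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return np.log2((np.asarray(counts, float) + prior_count) / (lib + 1.0) * 1e6)


def normalization_factors(counts: np.ndarray, library_sizes: np.ndarray | None = None) -> np.ndarray:
    """Trimmed-mean-of-M-values scale factors, geometric mean 1.

    Per sample, the weighted trimmed mean of log2 ratios to a reference
    sample (trimming the extreme 30% of ratios and 5% of abundances) gives
    the factor; effective library size = library_size * factor.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a windows x samples matrix with >= 2 samples")
    lib = counts.sum(axis=0) if library_sizes is None else np.asarray(library_sizes, float)
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample column")

    # reference: sample whose upper-quartile CPM is closest to the mean UQ
    uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(counts.shape[1])
    yr, nr = counts[:, ref], lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        y, n = counts[:, j], lib[j]
        keep = (y > 0) & (yr > 0)
        if keep.sum() == 0:
            continue
        p, pr = y[keep] / n, yr[keep] / nr
        M = np.log2(p / pr)
        A = 0.5 * np.log2(p * pr)
        w = (n - y[keep]) / (n * y[keep]) + (nr - yr[keep]) / (nr * yr[keep])
        finite = np.isfinite(M) & np.isfinite(A)
        M, A, w = M[finite], A[finite], w[finite]
        if M.size == 0 or np.allclose(M, M[0]):
            factors[j] = 2 ** (M[0] if M.size else 0.0)
            continue
        lM = np.floor(M.size * 0.30) + 1
        lA = np.floor(M.size * 0.05) + 1
        keep_trim = (
            (stats.rankdata(M) >= lM)
            & (stats.rankdata(M) <= M.size + 1 - lM)
            & (stats.rankdata(A) >= lA)
            & (stats.rankdata(A) <= A.size + 1 - lA)
        )
        if keep_trim.sum() == 0:
            keep_trim = np.ones_like(keep_trim)
        factors[j] = 2 ** (np.sum(M[keep_trim] / w[keep_trim]) / np.sum(1.0 / w[keep_trim]))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _ols_residual_sd(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched OLS of each row of y on X; returns (residual sd, fitted)."""
    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T
    fitted = beta @ X.T
    resid = y - fitted
    df = y.shape[1] - np.linalg.matrix_rank(X)
    sd = np.sqrt((resid**2).sum(axis=1) / max(df, 1))
    return sd, fitted


def precision_weights(
    logcpm: np.ndarray,
    design: np.ndarray,
    library_sizes: np.ndarray | None = None,
    span: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Voom-style inverse-variance observation weights.

    Fits each window by OLS, pairs sqrt(residual SD) with mean log2 count,
    smooths the trend by lowess, and assigns every observation the inverse
    of the trend's predicted variance at its fitted count scale.

    Returns (weights matrix, trend curve as an (x, sqrt-sd) array).
    """
    y = np.asarray(logcpm, float)
    if y.ndim != 2:
        raise ValueError("logcpm must be windows x samples")
    n_windows = y.shape[0]
    sd, fitted = _ols_residual_sd(y, design)

    if library_sizes is not None:
        lib_offset = np.log2(np.asarray(library_sizes, float) + 1.0) - np.log2(1e6)
        sx = y.mean(axis=1) + np.mean(lib_offset)
        eval_x = fitted + lib_offset[None, :]
    else:
        sx = y.mean(axis=1)
        eval_x = fitted
    sy = np.sqrt(sd)

    if n_windows < 8 or np.allclose(sd, 0):
        if np.allclose(sd, 0):
            log.warning("degenerate mean-variance trend; using uniform weights")
        trend = np.column_stack([sx, np.full_like(sx, max(sy.mean(), 1e-8))])
        return np.ones_like(y), trend

    delta = 0.01 * (sx.max() - sx.min())
    trend = lowess(sy, sx, frac=span, it=2, delta=delta)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-8)
    pred = np.interp(eval_x, tx, ty)  # constant extrapolation at ends
    weights = pred**-4
    return weights, trend


def sample_quality_weights(
    logcpm: np.ndarray, design: np.ndarray, iterations: int = 2
) -> np.ndarray:
    """Per-sample variance-inflation weights, geometric mean 1.

    Each sample's variance factor is the mean of its leverage-adjusted
    standardized squared residuals across windows; weights are the inverse
    factors, refined over a small number of re-weighted fits.
    """
    y = np.asarray(logcpm, float)
    n = y.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples")
    w = np.ones(n)
    for _ in range(max(iterations, 1)):
        Xw = design * np.sqrt(w)[:, None]
        yw = y * np.sqrt(w)[None, :]
        pinv = np.linalg.pinv(Xw)
        beta = yw @ pinv.T
        resid = yw - beta @ Xw.T
        H = Xw @ pinv
        h = np.clip(np.diag(H), 0.0, 0.99)
        df = n - np.linalg.matrix_rank(design)
        s2 = (resid**2).sum(axis=1) / max(df, 1)
        s2 = np.maximum(s2, 1e-12)
        z2 = resid**2 / s2[:, None] / (1.0 - h)[None, :]
        v = z2.mean(axis=0)
        w = w / v
        w /= np.exp(np.mean(np.log(w)))
    return w


@dataclass
class ModelFits:
    """Batched per-window weighted least-squares fits."""

    beta: np.ndarray  # windows x 4 (mu, b1, b2, b3)
    unscaled_cov: np.ndarray  # windows x 4 x 4, (X'WX)^-1
    sigma2: np.ndarray  # residual variance per window
    df_resid: int
    ok: np.ndarray  # windows passing rank/df checks
    sigma2_post: np.ndarray | None = None
    df_prior: float = 0.0
    p_unmeth: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    p_meth: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    p_int: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def se(self) -> np.ndarray:
        s2 = self.sigma2_post if self.sigma2_post is not None else self.sigma2
        return np.sqrt(s2[:, None] * np.diagonal(self.unscaled_cov, axis1=1, axis2=2))

    @property
    def positive_beta(self) -> np.ndarray:
        """b2 > 0 or b3 > 0: more RNA than DNA in at least one condition."""
        return ((self.beta[:, 2] > 0) | (self.beta[:, 3] > 0)) & self.ok


def fit_windows(
    logcpm: np.ndarray, weights: np.ndarray, design: np.ndarray
) -> ModelFits:
    """Weighted least squares for every window at once.

    beta = (X'WX)^-1 X'W y per window; windows whose weighted design is
    rank-deficient or with no residual degrees of freedom are flagged
    not-ok and excluded downstream.
    """
    y = np.asarray(logcpm, float)
    w = np.asarray(weights, float)
    X = np.asarray(design, float)
    n, p = X.shape
    if y.shape[1] != n or w.shape != y.shape:
        raise ValueError("shape mismatch between logcpm, weights, design")

    XtWX = np.einsum("nj,wn,nk->wjk", X, w, X)
    XtWy = np.einsum("nj,wn,wn->wj", X, w, y)
    ok = np.ones(y.shape[0], dtype=bool)
    # rank check via condition of the 4x4 normal matrix
    with np.errstate(all="ignore"):
        det = np.linalg.det(XtWX)
        scale = np.trace(XtWX, axis1=1, axis2=2) / p
        ok &= np.isfinite(det) & (det > (1e-10 * np.maximum(scale, 1e-300) ** p))
    cov = np.full_like(XtWX, np.nan)
    beta = np.full((y.shape[0], p), np.nan)
    if ok.any():
        cov[ok] = np.linalg.inv(XtWX[ok])
        beta[ok] = np.einsum("wjk,wk->wj", cov[ok], XtWy[ok])
    resid = y - beta @ X.T
    df = n - p
    if df <= 0:
        ok &= False
    rss = np.einsum("wn,wn->w", w, np.nan_to_num(resid) ** 2)
    sigma2 = rss / max(df, 1)
    return ModelFits(beta=beta, unscaled_cov=cov, sigma2=sigma2, df_resid=max(df, 0), ok=ok)


@dataclass
class WindowFit:
    """Single-window view of a fit (convenience over the batched form)."""

    beta: np.ndarray
    se: np.ndarray
    sigma2: float
    df_resid: int
    p_unmeth: float
    p_meth: float
    p_int: float
    ok: bool

    @property
    def max_pos_beta(self) -> bool:
        return bool(self.beta[2] > 0 or self.beta[3] > 0)


def fit_window_model(
    logcpm_row: np.ndarray, weights_row: np.ndarray, design: np.ndarray
) -> WindowFit:
    """Fit one window; unmoderated two-sided t-tests on b2, b3 and b2-b3."""
    fits = fit_windows(
        np.atleast_2d(logcpm_row), np.atleast_2d(weights_row), design
    )
    compute_pvalues(fits, moderate=False)
    return WindowFit(
        beta=fits.beta[0],
        se=fits.se[0],
        sigma2=float(fits.sigma2[0]),
        df_resid=fits.df_resid,
        p_unmeth=float(fits.p_unmeth[0]),
        p_meth=float(fits.p_meth[0]),
        p_int=float(fits.p_int[0]),
        ok=bool(fits.ok[0]),
    )


def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    f = lambda x: special.polygamma(1, x) - y
    lo, hi = 1e-8, 1e8
    if f(lo) < 0 or f(hi) > 0:
        return np.inf if f(hi) > 0 else lo
    return optimize.brentq(f, lo, hi)


def moderate_variances(fits: ModelFits, enabled: bool = True) -> ModelFits:
    """Empirical-Bayes shrinkage of per-window variances.

    Fits a scaled inverse-chi-square prior (s0^2, d0) to the observed
    residual variances by method of moments on the log scale, then shrinks:
    sigma2_post = (d0*s0^2 + df*s2) / (d0 + df). t-tests downstream use
    df_resid + d0 degrees of freedom.
    """
    if not enabled:
        fits.sigma2_post = None
        fits.df_prior = 0.0
        return fits
    s2 = fits.sigma2[fits.ok & (fits.sigma2 > 0)]
    if s2.size < 10 or np.allclose(s2, s2[0]):
        # degenerate: no spread to estimate a prior from; leave unmoderated
        fits.sigma2_post = fits.sigma2.copy()
        fits.df_prior = 0.0
        return fits
    df1 = fits.df_resid
    z = np.log(s2)
    e = z - special.digamma(df1 / 2.0) + np.log(df1 / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, df1 / 2.0)
    if evar > 0:
        df0 = 2.0 * _trigamma_inverse(evar)
        if np.isfinite(df0):
            s20 = np.exp(np.mean(e) + special.digamma(df0 / 2.0) - np.log(df0 / 2.0))
        else:
            df0, s20 = np.inf, np.exp(np.mean(e))
    else:
        df0, s20 = np.inf, np.exp(np.mean(e))
    if np.isinf(df0):
        post = np.full_like(fits.sigma2, s20)
        fits.df_prior = 1e6  # effectively pooled
    else:
        post = (df0 * s20 + df1 * fits.sigma2) / (df0 + df1)
        fits.df_prior = float(df0)
    fits.sigma2_post = post
    return fits


def compute_pvalues(fits: ModelFits, moderate: bool = True) -> ModelFits:
    """Two-sided t-tests for b2, b3 and the contrast b2 - b3."""
    if moderate and fits.sigma2_post is None:
        moderate_variances(fits, enabled=True)
    s2 = fits.sigma2_post if (moderate and fits.sigma2_post is not None) else fits.sigma2
    df = fits.df_resid + (fits.df_prior if moderate else 0.0)
    df = min(df, 1e6)

    with np.errstate(all="ignore"):
        var2 = s2 * fits.unscaled_cov[:, 2, 2]
        var3 = s2 * fits.unscaled_cov[:, 3, 3]
        cov23 = s2 * fits.unscaled_cov[:, 2, 3]
        t2 = fits.beta[:, 2] / np.sqrt(var2)
        t3 = fits.beta[:, 3] / np.sqrt(var3)
        var_c = var2 + var3 - 2.0 * cov23
        tc = (fits.beta[:, 2] - fits.beta[:, 3]) / np.sqrt(np.maximum(var_c, 0))

    def two_sided(t: np.ndarray) -> np.ndarray:
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p[~np.isfinite(t)] = np.nan
        return p

    fits.p_unmeth = two_sided(t2)
    fits.p_meth = two_sided(t3)
    fits.p_int = two_sided(tc)
    for arr in (fits.p_unmeth, fits.p_meth, fits.p_int):
        arr[~fits.ok] = np.nan
    return fits


def activity_pvalue(fits: ModelFits) -> np.ndarray:
    """Combined activity p per window: min p over conditions with a
    positive RNA-vs-DNA coefficient; 1 when neither is positive (the window
    is excluded from the FDR analysis set)."""
    if fits.p_unmeth is None:
        raise ValueError("compute_pvalues first")
    p_act = np.ones(fits.beta.shape[0])
    pos2 = (fits.beta[:, 2] > 0) & fits.ok
    pos3 = (fits.beta[:, 3] > 0) & fits.ok
    cand = np.full((fits.beta.shape[0], 2), np.inf)
    cand[pos2, 0] = fits.p_unmeth[pos2]
    cand[pos3, 1] = fits.p_meth[pos3]
    has = pos2 | pos3
    p_act[has] = cand.min(axis=1)[has]
    return p_act
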