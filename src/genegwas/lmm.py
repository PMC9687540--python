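"""The spectrally transformed LMM engine.

Model: y = 1*mu + X*beta + a + eps with a ~ N(0, K sigma_a^2),
eps ~ N(0, I sigma_e^2). Writing h2 = sigma_a^2 / (sigma_a^2 + sigma_e^2)
and K = U diag(S) U^T, rotating by U^T and rescaling by
W = (h2/(1-h2)) diag(S) + I turns the mixed model into an ordinary
regression on the whitened scale:

    y* = W^{-1/2} U^T y,   X* = W^{-1/2} U^T [1 X],   y* = X* b + e*,
    e* ~ N(0, I sigma_e^2).

A single eigendecomposition therefore serves every gene and every value of
h2. The per-gene fit is a barebones weighted least squares: an
intercept-only fit gives the whitened total sum of squares, the full fit
gives the residual sum, and the gene's F statistic is the usual
mean-square ratio with (df_beta, n - df_beta - 1) degrees of freedom.
The profile -2 log-likelihood in h2 is n*log(sigma_e^2-hat) + log|W|,
minimized by a bounded one-dimensional search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DegeneratePhenotypeError, GeneGwasError
from .kinship import SpectralKinship

logger = logging.getLogger(__name__)

#: Lower end of the h2 search interval (open interval (0, 1)).
H2_FLOOR = 1e-6
#: Profile ranges below this are treated as flat (tie -> lower bound).
FLAT_TOL = 1e-8


@dataclass
class BarebonesFit:
    """Result of the whitened weighted-least-squares fit for one design."""

    h2: float
    beta: np.ndarray          # k+1 coefficients, intercept first
    sigma2e: float            # residual variance on the whitened scale
    ssy: float                # whitened total SS (about the intercept fit)
    sse: float                # whitened residual SS
    ssr: float                # ssy - sse
    df_beta: int
    df_eps: int
    F: float
    p: float
    neg2logL: float           # n*log(sigma2e) + log|W|


def _with_intercept(X: np.ndarray | None, n: int) -> np.ndarray:
    one = np.ones((n, 1))
    if X is None or X.size == 0:
        return one
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] != n:
        raise GeneGwasError(f"design has {X.shape[0]} rows, expected {n}")
    return np.hstack([one, X])


def weights(S: np.ndarray, h2: float) -> np.ndarray:
    """Diagonal of W = (h2/(1-h2)) S + I."""
    if not 0.0 <= h2 < 1.0:
        raise ValueError(f"h2 must lie in [0, 1), got {h2}")
    return (h2 / (1.0 - h2)) * S + 1.0


def whiten(y: np.ndarray, X: np.ndarray | None, spectral: SpectralKinship,
           h2: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotate and rescale (y, [1 X]) into the whitened regression problem.

    Returns (ystar, xstar, wdiag); the first xstar column is the
    transformed intercept.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    A = _with_intercept(X, n)
    wdiag = weights(spectral.S, h2)
    sw = np.sqrt(wdiag)
    ystar = (spectral.U.T @ y) / sw
    xstar = (spectral.U.T @ A) / sw[:, None]
    return ystar, xstar, wdiag


def barebones_fit(ystar: np.ndarray, xstar: np.ndarray, wdiag: np.ndarray,
                  h2: float = np.nan) -> BarebonesFit:
    """Barebones regression on whitened data.

    (i) intercept-only fit -> whitened total SS; (ii) full fit -> residual
    SS; (iii) F = (ssr/df_beta) / (sse/df_eps); (iv) upper-tail F p-value;
    (v) -2 log L = log|W| + n log(sse/df_eps).
    """
    n, kp1 = xstar.shape
    k = kp1 - 1
    df_eps = n - kp1
    if df_eps <= 0:
        raise GeneGwasError(
            f"residual df {df_eps} <= 0: design too large for n={n}"
        )
    x0 = xstar[:, 0]
    mu = float(x0 @ ystar) / float(x0 @ x0)
    r0 = ystar - x0 * mu
    ssy = float(r0 @ r0)
    if k == 0:
        beta = np.array([mu])
        sse = ssy
    else:
        beta, *_ = np.linalg.lstsq(xstar, ystar, rcond=None)
        resid = ystar - xstar @ beta
        sse = float(resid @ resid)
    ssr = max(ssy - sse, 0.0)
    ve = sse / df_eps
    if ve <= 0:
        raise DegeneratePhenotypeError("zero residual variance in whitened fit")
    if k == 0:
        F, p = 0.0, 1.0
    else:
        F = (ssr / k) / ve
        p = f_pvalue(F, k, df_eps)
    neg2logL = float(np.sum(np.log(wdiag))) + n * float(np.log(ve))
    return BarebonesFit(
        h2=h2, beta=np.asarray(beta), sigma2e=ve, ssy=ssy, sse=sse, ssr=ssr,
        df_beta=k, df_eps=df_eps, F=F, p=p, neg2logL=neg2logL,
    )


def f_pvalue(F: float, df_beta: int, df_eps: int) -> float:
    """Upper-tail probability of the F(df_beta, df_eps) distribution."""
    if df_beta < 1 or df_eps < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got "
                         f"({df_beta}, {df_eps})")
    if F < 0:
        raise ValueError(f"F must be >= 0, got {F}")
    return float(stats.f.sf(F, df_beta, df_eps))


class _ProfileObjective:
    """Profile -2logL as a function of h2, with the rotation precomputed."""

    def __init__(self, y: np.ndarray, X: np.ndarray | None,
                 spectral: SpectralKinship):
        y = np.asarray(y, dtype=np.float64)
        self.n = len(y)
        A = _with_intercept(X, self.n)
        self.yt = spectral.U.T @ y
        self.xt = spectral.U.T @ A
        self.S = spectral.S

    def fit(self, h2: float) -> BarebonesFit:
        wdiag = weights(self.S, h2)
        sw = np.sqrt(wdiag)
        return barebones_fit(self.yt / sw, self.xt / sw[:, None], wdiag, h2)

    def __call__(self, h2: float) -> float:
        val = self.fit(h2).neg2logL
        if not np.isfinite(val):
            raise GeneGwasError(f"non-finite profile likelihood at h2={h2}")
        return val


def profile_neg2loglik(h2: float, y: np.ndarray, X: np.ndarray | None,
                       spectral: SpectralKinship) -> float:
    """-2 log profile likelihood of the whitened fit at a fixed h2."""
    if not 0.0 <= h2 < 1.0:
        raise ValueError(f"h2 must lie in [0, 1), got {h2}")
    return _ProfileObjective(y, X, spectral)(h2)


def optimize_h2(y: np.ndarray, X: np.ndarray | None,
                spectral: SpectralKinship, upper_bound: float | None = None,
                tol: float = 1e-6) -> float:
    """ML estimate of h2 by bounded one-dimensional search.

    A coarse grid locates the basin; Brent refinement (absolute tolerance
    ``tol``) polishes it. On a flat profile (range < 1e-8) the lower search
    bound is returned — the most parsimonious polygenic signal.
    ``upper_bound`` defaults to just below 1; per-gene scans pass the
    trait's genomic heritability estimate (search-down strategy).
    """
    upper = 1.0 - 1e-6 if upper_bound is None else float(upper_bound)
    if not 0.0 < upper < 1.0:
        raise ValueError(f"upper_bound must lie in (0, 1), got {upper}")
    lower = min(H2_FLOOR, upper)
    obj = _ProfileObjective(y, X, spectral)

    grid = np.linspace(lower, upper, 25)
    vals = np.array([obj(g) for g in grid])
    if vals.max() - vals.min() < FLAT_TOL:
        logger.debug("flat h2 profile (range %.2e); returning lower bound",
                     vals.max() - vals.min())
        return lower
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                   options={"xatol": tol})
    candidates = [(vals[i], grid[i]), (float(res.fun), float(res.x)),
                  (vals[0], grid[0])]
    best = min(candidates, key=lambda t: t[0])[1]
    return float(min(best, upper))


def estimate_genomic_h2(y: np.ndarray, spectral: SpectralKinship) -> float:
    """Genomic heritability from the null (intercept-only) mixed model."""
    y = np.asarray(y, dtype=np.float64)
    if np.std(y) == 0:
        raise DegeneratePhenotypeError("phenotype is constant")
    return optimize_h2(y, None, spectral, upper_bound=1.0 - 1e-6)
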