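"""G-BLUP with profile-REML variance components and back-solved marker effects.

The mixed model is y = 1 mu + g + e with g ~ N(0, sigma_g^2 G) and
e ~ N(0, sigma_e^2 I), where G = M_c M_c' / k is the genomic relationship
built from markers centered at observed (training) allele frequencies and
k = sum_j 4 p_j (1 - p_j) so that the diagonal is ~1 for inbred lines.

REML is a one-dimensional profile likelihood over the heritability
h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2): after an eigendecomposition of G
the likelihood is evaluated on a grid and refined by bounded scalar
minimization.  Marker effects are recovered as

    beta_hat = (sigma_g^2 / k) M_c' (sigma_g^2 G + sigma_e^2 I)^-1 (y - mu),

which reproduces the training GEBVs exactly (M_c beta_hat = g_hat) because G
is the exact cross-product of the centered markers.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize

from .genome import validate_genotypes

__all__ = [
    "genomic_relationship",
    "GBLUPFit",
    "fit_gblup",
    "backsolve_effects",
    "predict_gebv",
]


def _center_markers(M):
    M = validate_genotypes(np.asarray(M)).astype(float)
    p = (M == 1).mean(axis=0)  # +1-allele frequency
    k = float((4.0 * p * (1.0 - p)).sum())
    if k == 0.0:
        raise ValueError("all markers are monomorphic")
    Mc = M - (2.0 * p - 1.0)
    return Mc, p, k


def genomic_relationship(M, blend: float = 0.01) -> np.ndarray:
    """Genomic relationship G = M_c M_c' / k, blended (1-b) G + b I.

    The default blend of 0.01 guarantees positive definiteness when a
    standalone invertible relationship matrix is needed; pass ``blend=0`` for
    the raw cross-product form.
    """
    Mc, _, k = _center_markers(M)
    if Mc.shape[0] < 2:
        raise ValueError("need at least two individuals")
    G = Mc @ Mc.T / k
    if blend:
        G = (1.0 - blend) * G + blend * np.eye(G.shape[0])
    return G


@dataclasses.dataclass
class GBLUPFit:
    """Fitted G-BLUP: variance components, GEBVs and back-solved effects."""

    mu: float
    h2: float
    sigma2_g: float
    sigma2_e: float
    gebv: np.ndarray
    beta: np.ndarray | None
    freqs: np.ndarray | None
    k: float | None
    loglik: float

    def predict(self, X_new) -> np.ndarray:
        """GEBVs for new +-1 genotypes on the training marker panel."""
        if self.beta is None:
            raise ValueError("fit has no marker effects (no marker matrix given)")
        return predict_gebv(self.beta, self.mu, X_new, self.freqs)


def _reml_profile(h2, s, y_rot, x_rot):
    """Negative REML log-likelihood profiled over mu and total variance."""
    n = len(y_rot)
    d = h2 * s + (1.0 - h2)
    xtx = float((x_rot**2 / d).sum())
    mu = float((x_rot * y_rot / d).sum()) / xtx
    r = y_rot - x_rot * mu
    rss = float((r**2 / d).sum())
    sigma2 = rss / (n - 1)
    ll = -0.5 * ((n - 1) * (np.log(sigma2) + 1.0) + np.log(d).sum() + np.log(xtx))
    return -ll, mu, sigma2


def fit_gblup(y, G=None, M=None, h2_grid: int = 99) -> GBLUPFit:
    """Fit the G-BLUP mixed model by profile REML.

    Provide either the marker matrix ``M`` (preferred: enables exact
    back-solving of marker effects) or a precomputed relationship ``G``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be finite")
    Mc = p = None
    k = None
    if M is not None:
        Mc, p, k = _center_markers(M)
        if Mc.shape[0] != len(y):
            raise ValueError("phenotypes and genotypes are not aligned")
        G = Mc @ Mc.T / k
    if G is None:
        raise ValueError("either G or M must be given")
    G = np.asarray(G, dtype=float)
    if G.shape[0] != len(y):
        raise ValueError("phenotypes and relationship matrix are not aligned")
    s, U = np.linalg.eigh(G)
    s = np.maximum(s, 0.0)
    y_rot = U.T @ y
    x_rot = U.T @ np.ones_like(y)
    grid = np.linspace(0.001, 0.999, h2_grid)
    nll = np.array([_reml_profile(h, s, y_rot, x_rot)[0] for h in grid])
    j = int(np.argmin(nll))
    lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda h: _reml_profile(h, s, y_rot, x_rot)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    h2 = float(res.x)
    nll_best, mu, sigma2 = _reml_profile(h2, s, y_rot, x_rot)
    d = h2 * s + (1.0 - h2)
    shrink = h2 * s / d
    g_rot = shrink * (y_rot - x_rot * mu)
    gebv = U @ g_rot
    beta = None
    if Mc is not None:
        # (sigma_g^2 G + sigma_e^2 I)^-1 (y - mu) in the rotated basis
        w = U @ ((y_rot - x_rot * mu) / (sigma2 * d))
        beta = (h2 * sigma2 / k) * (Mc.T @ w)
    return GBLUPFit(
        mu=mu,
        h2=h2,
        sigma2_g=h2 * sigma2,
        sigma2_e=(1.0 - h2) * sigma2,
        gebv=gebv,
        beta=beta,
        freqs=p,
        k=k,
        loglik=-nll_best,
    )


def backsolve_effects(fit: GBLUPFit, M) -> np.ndarray:
    """Marker effects beta_hat = (1/k) M_c' G^-1 GEBV for the training markers.

    Solved through the shifted system used at fit time so no explicit G
    inverse (and no diagonal blending) is required; reproduces the training
    GEBVs via M_c beta_hat = GEBV.
    """
    if fit.beta is not None:
        return fit.beta
    Mc, _, k = _center_markers(M)
    G = Mc @ Mc.T / k
    # GEBV lies in the range of G, so the minimum-norm solve recovers G^-1 GEBV
    # even when G is only positive semidefinite
    w = np.linalg.lstsq(G, fit.gebv, rcond=None)[0]
    return (Mc.T @ w) / k


def predict_gebv(beta, intercept: float, X_new, train_freqs) -> np.ndarray:
    """Linear predictor mu + (X_new - training column means) beta."""
    X_new = validate_genotypes(np.asarray(X_new)).astype(float)
    beta = np.asarray(beta, dtype=float)
    if X_new.shape[-1] != len(beta):
        raise ValueError("genotypes do not match the marker panel")
    center = 2.0 * np.asarray(train_freqs, dtype=float) - 1.0
    return intercept + (X_new - center) @ beta
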