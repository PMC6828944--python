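"""Usefulness criterion and parental contributions (UCPC) for two-way DH crosses.

For a cross P1 x P2 of fully homozygous lines, the DH progeny breeding value
and the P1 genome contribution are treated as a bivariate normal whose moments
follow from the progeny genotype covariance under linkage:

    Sigma_jk = (1 - 2 r_jk) (x1_j - x2_j)(x1_k - x2_k) / 4,

with r_jk the Haldane recombination fraction within a chromosome and 0.5
across chromosomes (so 1 - 2 r_jk = exp(-0.02 |d_jk|) within and 0 across).
Then

    mu_T      = (x1 + x2)' beta_T / 2          progeny mean
    sigma_T^2 = beta_T' Sigma beta_T           progeny variance
    beta_C1   = (x1 - x2) / ((x1 - x2)'(x1 - x2))   IBS contribution "effects"
    mu_C1     = (x1' beta_C1 + x2' beta_C1 + 1) / 2
    sigma_T,C1 = beta_T' Sigma beta_C1

and truncation selection of the best fraction q (intensity i = phi(z)/q,
accuracy h) gives the selected-progeny mean UC = mu_T + i h sigma_T and the
post-selection P1 contribution c1 = mu_C1 + i sigma_T,C1 / sigma_T (clamped to
[0, 1]; its complement is c2 = 1 - c1).

Contributions are identity-by-state over the loci polymorphic between the two
parents; for such loci x1 + x2 = 0, hence mu_C1 = 1/2 exactly for every
non-degenerate two-way cross.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneticMap, validate_genotypes

__all__ = [
    "SelectionRegime",
    "CrossPrediction",
    "selection_intensity",
    "SigmaDH",
    "dh_progeny_covariance",
    "predict_cross",
    "predict_crosses_batch",
]


def selection_intensity(q: float) -> float:
    """Standardized truncation-selection intensity for a selected fraction ``q``.

    i = phi(Phi^-1(1 - q)) / q for the standard normal; i(1) = 0 (no
    selection) and i(0.05) = 2.063.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("selected fraction must be in (0, 1]")
    if q == 1.0:
        return 0.0
    z = stats.norm.ppf(1.0 - q)
    return float(stats.norm.pdf(z) / q)


@dataclasses.dataclass(frozen=True)
class SelectionRegime:
    """Within-family truncation selection: fraction ``q``, intensity ``i``, accuracy ``h``."""

    q: float = 0.05
    i: float | None = None
    h: float = 1.0

    def __post_init__(self):
        if self.i is None:
            object.__setattr__(self, "i", selection_intensity(self.q))
        if self.i < 0:
            raise ValueError("selection intensity must be non-negative")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("selection accuracy must be in [0, 1]")

    @classmethod
    def none(cls) -> "SelectionRegime":
        """No within-family selection (i = 0)."""
        return cls(q=1.0)


@dataclasses.dataclass(frozen=True)
class CrossPrediction:
    """Predicted progeny moments and selection response of one two-way cross."""

    p1: int
    p2: int
    mu_T: float
    sigma_T: float
    mu_C1: float
    sigma2_C1: float
    sigma_T_C1: float
    uc: float
    c1: float
    n_polymorphic: int

    @property
    def c2(self) -> float:
        return 1.0 - self.c1


def _chrom_kernels(gmap: GeneticMap) -> list[tuple[slice, np.ndarray]]:
    """Per-chromosome matrices of 1 - 2 r_jk = exp(-0.02 |pos_j - pos_k|)."""
    out = []
    for sl in gmap.chrom_slices():
        pos = gmap.pos[sl]
        out.append((sl, np.exp(-0.02 * np.abs(pos[:, None] - pos[None, :]))))
    return out


class SigmaDH:
    """Progeny genotype covariance of one cross, as a quadratic-form evaluator.

    ``quad(u, v)`` returns u' Sigma v without materializing the m x m matrix;
    ``matrix()`` materializes it (small problems / tests only).
    """

    def __init__(self, x1, x2, gmap: GeneticMap, kernels=None):
        x1 = validate_genotypes(np.asarray(x1).ravel())
        x2 = validate_genotypes(np.asarray(x2).ravel())
        if x1.shape[0] != gmap.n_loci or x2.shape[0] != gmap.n_loci:
            raise ValueError("parent genotypes do not match the map")
        self.gmap = gmap
        self.g = ((x1.astype(np.int64) - x2.astype(np.int64)) // 2).astype(float)  # (x1-x2)/2 in {-1,0,1}
        self._kernels = kernels if kernels is not None else _chrom_kernels(gmap)

    def quad(self, u, v) -> float:
        u = np.asarray(u, dtype=float) * self.g
        v = np.asarray(v, dtype=float) * self.g
        total = 0.0
        for sl, E in self._kernels:
            total += u[sl] @ E @ v[sl]
        return float(total)

    def matrix(self) -> np.ndarray:
        m = self.gmap.n_loci
        S = np.zeros((m, m))
        for sl, E in self._kernels:
            S[sl, sl] = E
        return S * np.outer(self.g, self.g)


def dh_progeny_covariance(x1, x2, gmap: GeneticMap) -> SigmaDH:
    """Covariance of QTL genotypes among DH progeny of ``x1`` x ``x2``."""
    return SigmaDH(x1, x2, gmap)


def predict_cross(x1, x2, beta, gmap: GeneticMap, regime: SelectionRegime,
                  p1: int = 0, p2: int = 1, _sigma: SigmaDH | None = None) -> CrossPrediction:
    """UCPC prediction for a single cross, through the generic algebra.

    Degenerate crosses (identical parents, no polymorphic locus, or zero
    progeny variance) fall back to UC = mu_T and c1 = 1/2 by convention.
    """
    beta = np.asarray(beta, dtype=float)
    sig = _sigma if _sigma is not None else SigmaDH(x1, x2, gmap)
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    mu_T = 0.5 * (x1 @ beta + x2 @ beta)
    d = x1 - x2
    dd = float(d @ d)
    n_poly = int(round(dd / 4.0))
    if n_poly == 0:
        return CrossPrediction(p1, p2, float(mu_T), 0.0, 0.5, 0.0, 0.0, float(mu_T), 0.5, 0)
    beta_c1 = d / dd
    mu_C1 = 0.5 * (x1 @ beta_c1 + x2 @ beta_c1 + 1.0)
    s2_T = max(sig.quad(beta, beta), 0.0)
    s2_C1 = max(sig.quad(beta_c1, beta_c1), 0.0)
    s_TC1 = sig.quad(beta, beta_c1)
    sigma_T = float(np.sqrt(s2_T))
    if sigma_T == 0.0:
        uc, c1 = float(mu_T), float(mu_C1)
    else:
        uc = float(mu_T + regime.i * regime.h * sigma_T)
        c1 = float(np.clip(mu_C1 + regime.i * s_TC1 / sigma_T, 0.0, 1.0))
    return CrossPrediction(p1, p2, float(mu_T), sigma_T, float(mu_C1),
                           float(s2_C1), float(s_TC1), uc, c1, n_poly)


def predict_crosses_batch(X, pairs, beta, gmap: GeneticMap, regime: SelectionRegime,
                          chunk: int = 1024) -> pd.DataFrame:
    """Vectorized UCPC predictions for many crosses from one candidate pool.

    Exploits the factorization Sigma_jk = g_j g_k exp(-0.02 d_jk) with
    g = (x1 - x2)/2 in {-1, 0, 1}: all three quadratic forms reduce, per
    chromosome, to products with a shared distance kernel, amortized over
    crosses.  Restriction to polymorphic loci is implicit (g = 0 elsewhere).

    Parameters
    ----------
    X : (N, m) +-1 matrix of candidate parents aligned to ``gmap``.
    pairs : (n_cross, 2) integer array of parent indices.
    beta : (m,) additive effects aligned to ``gmap``.

    Returns a DataFrame with one row per pair, element-wise identical to
    :func:`predict_cross`.
    """
    X = validate_genotypes(np.asarray(X, dtype=np.int8))
    if X.shape[1] != gmap.n_loci:
        raise ValueError("genotype matrix does not match the map")
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if pairs.size and (pairs.min() < 0 or pairs.max() >= X.shape[0]):
        raise IndexError("pair index outside the candidate pool")
    beta = np.asarray(beta, dtype=float)
    kernels = _chrom_kernels(gmap)
    a = X @ beta
    n = len(pairs)
    s2T = np.zeros(n)
    sTC = np.zeros(n)
    s2C = np.zeros(n)
    n_poly = np.zeros(n, dtype=np.int64)
    for lo in range(0, n, chunk):
        sel = slice(lo, min(lo + chunk, n))
        p1, p2 = pairs[sel, 0], pairs[sel, 1]
        G = (X[p1].astype(np.int64) - X[p2].astype(np.int64)) // 2
        G = G.astype(float)
        U = G * beta
        P = np.abs(G)
        n_poly[sel] = P.sum(axis=1).astype(np.int64)
        for sl, E in kernels:
            PE = P[:, sl] @ E
            s2T[sel] += ((U[:, sl] @ E) * U[:, sl]).sum(axis=1)
            sTC[sel] += (PE * U[:, sl]).sum(axis=1)
            s2C[sel] += (PE * P[:, sl]).sum(axis=1)
    poly = n_poly > 0
    mu_T = 0.5 * (a[pairs[:, 0]] + a[pairs[:, 1]])
    s2T = np.maximum(s2T, 0.0)
    sigma_T = np.sqrt(s2T)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_T_C1 = np.where(poly, sTC / (2.0 * n_poly), 0.0)
        sigma2_C1 = np.where(poly, s2C / (4.0 * n_poly.astype(float) ** 2), 0.0)
        ratio = np.where(sigma_T > 0, sigma_T_C1 / np.where(sigma_T > 0, sigma_T, 1.0), 0.0)
    mu_C1 = np.full(n, 0.5)
    uc = mu_T + regime.i * regime.h * sigma_T
    c1 = np.clip(mu_C1 + regime.i * ratio, 0.0, 1.0)
    deg = ~poly | (sigma_T == 0.0)
    uc = np.where(deg, mu_T, uc)
    c1 = np.where(deg, 0.5, c1)
    return pd.DataFrame(
        {
            "p1": pairs[:, 0],
            "p2": pairs[:, 1],
            "mu_T": mu_T,
            "sigma_T": np.where(poly, sigma_T, 0.0),
            "mu_C1": mu_C1,
            "sigma2_C1": sigma2_C1,
            "sigma_T_C1": sigma_T_C1,
            "uc": uc,
            "c1": c1,
            "c2": 1.0 - c1,
            "n_polymorphic": n_poly,
        }
    )
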