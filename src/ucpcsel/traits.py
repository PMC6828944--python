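"""Trait architecture, true breeding values and phenotypes.

The simulated trait is purely additive: ``m`` biallelic QTLs with effects
drawn from N(0, effect_var) and the favorable allele oriented at random.
True breeding values are TBV = X beta over the QTL columns; phenotypes add
the mean of ``n_env`` independent normal plot errors, calibrated so that the
single-plot repeatability in the founder population takes a target value.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genome import FounderSet, GeneticMap

__all__ = [
    "TraitArchitecture",
    "sample_qtls",
    "tbv",
    "error_variance",
    "simulate_phenotype",
]


@dataclasses.dataclass
class TraitArchitecture:
    """QTL positions and additive effects on a shared genetic map.

    Attributes
    ----------
    qtl_idx : array of int
        Indices of the QTLs into the full map, in map order.
    beta : array of float
        Signed additive effect per QTL; the favorable allele of QTL j is the
        homozygote whose +-1 code has the sign of ``beta[j]``.
    gmap : GeneticMap
        The full map the indices refer to.
    """

    qtl_idx: np.ndarray
    beta: np.ndarray
    gmap: GeneticMap

    def __post_init__(self):
        idx = np.asarray(self.qtl_idx, dtype=np.int64)
        beta = np.asarray(self.beta, dtype=float)
        if len(idx) != len(beta):
            raise ValueError("one effect per QTL required")
        order = np.argsort(idx, kind="stable")
        self.qtl_idx, self.beta = idx[order], beta[order]
        if len(self.qtl_idx) and self.qtl_idx[-1] >= self.gmap.n_loci:
            raise ValueError("QTL index outside the map")

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_idx)

    def qtl_map(self) -> GeneticMap:
        """Map restricted to the QTLs (exact under Haldane/Markov meiosis)."""
        return self.gmap.subset(self.qtl_idx)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.gmap.ids[self.qtl_idx],
                "chrom": self.gmap.chrom[self.qtl_idx],
                "pos_cM": self.gmap.pos[self.qtl_idx],
                "beta": self.beta,
            }
        )


def sample_qtls(
    founders: FounderSet,
    m: int = 1000,
    maf_min: float = 0.2,
    spacing_min: float = 0.2,
    effect_var: float = 0.05,
    rng=None,
) -> TraitArchitecture:
    """Sample a QTL architecture from the segregating founder loci.

    Loci are eligible when their founder MAF is >= ``maf_min``; eligible loci
    are shuffled and accepted greedily subject to a minimum within-chromosome
    spacing of ``spacing_min`` cM (deterministic given the generator state).
    Effects are i.i.d. N(0, effect_var), with an extra random sign flip that
    assigns the favorable allele to +1 or -1 with probability 1/2.
    """
    if rng is None:
        rng = np.random.default_rng()
    gmap = founders.gmap
    eligible = np.flatnonzero(founders.maf() >= maf_min)
    order = rng.permutation(eligible)
    chosen: list[int] = []
    by_chrom: dict[int, list[float]] = {}
    for j in order:
        c, p = int(gmap.chrom[j]), float(gmap.pos[j])
        placed = by_chrom.get(c)
        if placed and min(abs(p - q) for q in placed) < spacing_min:
            continue
        chosen.append(int(j))
        by_chrom.setdefault(c, []).append(p)
        if len(chosen) == m:
            break
    if len(chosen) < m:
        raise ValueError(
            f"only {len(chosen)} loci satisfy MAF >= {maf_min} and spacing >= "
            f"{spacing_min} cM; cannot place {m} QTLs"
        )
    beta = rng.normal(0.0, np.sqrt(effect_var), size=m)
    beta *= rng.choice((-1.0, 1.0), size=m)
    return TraitArchitecture(np.array(chosen), beta, gmap)


def tbv(X, arch: TraitArchitecture, columns: str = "full") -> np.ndarray:
    """True breeding values a = X beta summed over QTLs.

    ``columns='full'`` expects ``X`` over the full map (QTL columns are
    picked out); ``columns='qtl'`` expects ``X`` already restricted to the
    QTLs in map order.
    """
    X = np.asarray(X)
    one = X.ndim == 1
    X = np.atleast_2d(X)
    if columns == "full":
        if X.shape[1] != arch.gmap.n_loci:
            raise ValueError("genotype matrix does not cover the full map")
        Xq = X[:, arch.qtl_idx]
    elif columns == "qtl":
        if X.shape[1] != arch.n_qtl:
            raise ValueError("genotype matrix does not cover all QTLs")
        Xq = X
    else:
        raise ValueError("columns must be 'full' or 'qtl'")
    a = Xq @ arch.beta
    return a[0] if one else a


def error_variance(founder_additive_var: float, repeatability: float) -> float:
    """Per-environment (plot) error variance for a target founder repeatability.

    Solves repeatability = V_A / (V_A + sigma_e^2) for sigma_e^2.
    """
    if not 0.0 < repeatability <= 1.0:
        raise ValueError("repeatability must be in (0, 1]")
    return founder_additive_var * (1.0 / repeatability - 1.0)


def simulate_phenotype(tbv_values, sigma2_e: float, n_env: int, rng) -> np.ndarray:
    """Phenotype = TBV + mean of ``n_env`` i.i.d. N(0, sigma2_e) plot errors."""
    if sigma2_e < 0:
        raise ValueError("error variance must be non-negative")
    if n_env < 1:
        raise ValueError("need at least one environment")
    a = np.asarray(tbv_values, dtype=float)
    err = rng.normal(0.0, np.sqrt(sigma2_e), size=(n_env,) + a.shape).mean(axis=0)
    return a + err
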