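"""Genetic maps, meiosis of doubled-haploid (DH) material and synthetic founders.

All genotypes are fully homozygous inbred lines coded ``+1`` / ``-1`` for the
two homozygote classes at each biallelic locus.  A DH line is obtained from the
F1 of two such parents by sampling one recombinant gamete and doubling it, so a
single meiosis separates a DH from its F1.  Recombination follows the Haldane
map function (no crossover interference): the crossover process is Markov along
each chromosome, which is what makes restriction of a map to a subset of loci
(e.g. QTLs only) exact.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "FounderSet",
    "haldane_recomb",
    "sample_gamete",
    "sample_gametes",
    "make_dh",
    "make_dh_population",
    "default_map",
    "generate_founders",
    "read_map",
    "write_map",
    "read_genotypes",
    "write_genotypes",
    "read_vcf",
    "validate_genotypes",
]


def haldane_recomb(d):
    """Recombination fraction between loci ``d`` centimorgan apart (Haldane).

    r = (1 - exp(-2 d / 100)) / 2, i.e. r(0) = 0 and r -> 0.5 as d -> inf.

    Parameters
    ----------
    d : float or array-like
        Map distance in cM, must be non-negative.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-0.02 * d))
    return r.item() if r.ndim == 0 else r


class GeneticMap:
    """Ordered biallelic loci with chromosome assignment and cM positions.

    Parameters
    ----------
    chrom : array of int
        Chromosome id per locus; loci of one chromosome must be contiguous.
    ids : sequence of str
        Unique locus identifiers.
    pos : array of float
        Genetic position in cM, non-decreasing within each chromosome.
    """

    def __init__(self, chrom, ids, pos):
        self.chrom = np.asarray(chrom, dtype=np.int64)
        self.ids = np.asarray(ids, dtype=object)
        self.pos = np.asarray(pos, dtype=float)
        if not (len(self.chrom) == len(self.ids) == len(self.pos)):
            raise ValueError("chrom, ids and pos must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("locus ids must be unique")
        if np.any(self.pos < 0):
            raise ValueError("cM positions must be non-negative")
        # contiguity + sortedness within chromosome
        change = np.flatnonzero(np.diff(self.chrom) != 0)
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [len(self.chrom)]))
        if len(set(self.chrom[starts])) != len(starts):
            raise ValueError("loci of one chromosome must be contiguous")
        for s, e in zip(starts, ends):
            if np.any(np.diff(self.pos[s:e]) < 0):
                raise ValueError(
                    f"positions must be non-decreasing within chromosome {self.chrom[s]}"
                )
        self._starts = starts
        self._ends = ends

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    @property
    def n_chrom(self) -> int:
        return len(self._starts)

    def chrom_slices(self):
        """Yield one ``slice`` per chromosome, in map order."""
        return [slice(int(s), int(e)) for s, e in zip(self._starts, self._ends)]

    def switch_probs(self) -> np.ndarray:
        """Per-locus probability that gamete origin switches from the previous locus.

        The first locus of each chromosome gets 0.5 (independent 50/50 start,
        expressed as a symmetric switch from the previous chromosome's end),
        every other locus gets the Haldane recombination fraction for the
        distance to its left neighbour.
        """
        p = np.empty(self.n_loci)
        p[1:] = haldane_recomb(np.maximum(np.diff(self.pos), 0.0))
        p[self._starts] = 0.5
        return p

    def subset(self, indices) -> "GeneticMap":
        """Map restricted to ``indices`` (kept in map order)."""
        idx = np.sort(np.asarray(indices, dtype=np.int64))
        return GeneticMap(self.chrom[idx], self.ids[idx], self.pos[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "id": self.ids, "pos_cM": self.pos})

    def __len__(self) -> int:
        return self.n_loci

    def __repr__(self) -> str:
        return f"GeneticMap({self.n_loci} loci, {self.n_chrom} chromosomes)"


@dataclasses.dataclass
class FounderSet:
    """A set of >= 2 fully homozygous founder lines sharing one genetic map."""

    X: np.ndarray  # (n_founders, n_loci) in {-1, +1}
    gmap: GeneticMap
    ids: list

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.int8)
        if self.X.ndim != 2 or self.X.shape[0] < 2:
            raise ValueError("FounderSet needs a 2-D matrix with >= 2 lines")
        if self.X.shape[1] != self.gmap.n_loci:
            raise ValueError("genotype width does not match map")
        validate_genotypes(self.X)
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("one id per founder required")

    @property
    def n_founders(self) -> int:
        return self.X.shape[0]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the +1-coded allele per locus."""
        return (self.X == 1).mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


def validate_genotypes(X) -> np.ndarray:
    X = np.asarray(X)
    if not np.isin(X, (-1, 1)).all():
        raise ValueError("genotypes must be coded +1/-1 (fully homozygous DH lines)")
    return X


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def sample_gametes(x1, x2, gmap: GeneticMap, n: int, rng) -> np.ndarray:
    """Sample ``n`` gametes of the F1 of two DH parents.

    Origin of each locus follows a Markov switch process along every
    chromosome: switch probability between adjacent loci is the Haldane
    recombination fraction of their distance, origin at each chromosome start
    is uniform, chromosomes assort independently.

    Returns an ``(n, m)`` matrix coded +1/-1.
    """
    x1 = np.asarray(x1, dtype=np.int8).ravel()
    x2 = np.asarray(x2, dtype=np.int8).ravel()
    if x1.shape[0] != gmap.n_loci or x2.shape[0] != gmap.n_loci:
        raise ValueError("parent genotype length does not match the map")
    p = gmap.switch_probs()
    switch = rng.random((n, gmap.n_loci)) < p
    # cumulative XOR of switches gives the origin; chromosome boundaries use a
    # symmetric 0.5 switch so running the cumsum straight through is exact
    origin = np.cumsum(switch, axis=1) & 1
    return np.where(origin == 0, x1, x2).astype(np.int8)


def sample_gamete(x1, x2, gmap: GeneticMap, rng) -> np.ndarray:
    """A single F1 gamete (see :func:`sample_gametes`)."""
    return sample_gametes(x1, x2, gmap, 1, rng)[0]


def make_dh(x1, x2, gmap: GeneticMap, rng) -> np.ndarray:
    """One doubled-haploid progeny of the cross ``x1`` x ``x2``.

    Doubling a gamete makes it fully homozygous, so in +-1 coding the DH
    genotype equals the gamete.
    """
    return sample_gamete(x1, x2, gmap, rng)


def make_dh_population(x1, x2, gmap: GeneticMap, n: int, rng) -> np.ndarray:
    """``n`` independent DH progeny of a cross, as an ``(n, m)`` matrix."""
    return sample_gametes(x1, x2, gmap, n, rng)


# ---------------------------------------------------------------------------
# synthetic founders
# ---------------------------------------------------------------------------

def default_map(n_chrom: int = 10, chrom_len_cm: float = 160.0, n_loci: int = 4000) -> GeneticMap:
    """Maize-like synthetic map: evenly spaced loci on equal-length chromosomes."""
    per = n_loci // n_chrom
    counts = [per + (1 if c < n_loci % n_chrom else 0) for c in range(n_chrom)]
    chrom, ids, pos = [], [], []
    for c, k in enumerate(counts, start=1):
        chrom.extend([c] * k)
        pos.extend(np.linspace(0.0, chrom_len_cm, k))
        ids.extend([f"c{c}_l{j}" for j in range(k)])
    return GeneticMap(chrom, ids, pos)


def generate_founders(
    n_founders: int,
    gmap: GeneticMap | None = None,
    rng=None,
    *,
    pool_size: int = 100,
    n_generations: int = 10,
    freq_low: float = 0.2,
    freq_high: float = 0.8,
    min_qtl: int | None = None,
    maf_min: float = 0.2,
) -> FounderSet:
    """Synthetic elite founder pool with within-pool LD.

    An ancestral pool of ``pool_size`` DH lines is drawn in linkage
    equilibrium with per-locus allele frequencies ~ Uniform(freq_low,
    freq_high), then evolved for ``n_generations`` of random mating with DH
    extraction inside the bottlenecked pool.  Drift through the bottleneck
    builds linkage disequilibrium and an elite-pool-like MAF spectrum;
    ``n_founders`` lines are then sampled without replacement.

    If ``min_qtl`` is given, the founders are required to segregate at
    ``min_qtl`` loci with MAF >= ``maf_min``; a shortfall raises ``ValueError``
    naming the achieved count.
    """
    if n_founders < 2:
        raise ValueError("need at least two founders")
    if rng is None:
        rng = np.random.default_rng()
    if gmap is None:
        gmap = default_map()
    m = gmap.n_loci
    freqs = rng.uniform(freq_low, freq_high, size=m)
    pool = np.where(rng.random((pool_size, m)) < freqs, 1, -1).astype(np.int8)
    for _ in range(n_generations):
        dams = rng.integers(pool_size, size=pool_size)
        sires = rng.integers(pool_size, size=pool_size)
        sires = np.where(sires == dams, (sires + 1) % pool_size, sires)
        nxt = np.empty_like(pool)
        for i in range(pool_size):
            nxt[i] = sample_gamete(pool[dams[i]], pool[sires[i]], gmap, rng)
        pool = nxt
    take = rng.choice(pool_size, size=n_founders, replace=False)
    founders = FounderSet(pool[take], gmap, [f"F{i:03d}" for i in range(n_founders)])
    if min_qtl is not None:
        n_ok = int((founders.maf() >= maf_min).sum())
        if n_ok < min_qtl:
            raise ValueError(
                f"founder pool segregates at only {n_ok} loci with MAF >= {maf_min}, "
                f"fewer than the {min_qtl} requested"
            )
    return founders


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_map(path) -> GeneticMap:
    """Read a tab-delimited map with header columns chrom, id, pos_cM."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "id", "pos_cM"} - set(df.columns)
    if missing:
        raise ValueError(f"map file missing columns: {sorted(missing)}")
    return GeneticMap(df["chrom"].to_numpy(), df["id"].to_numpy(), df["pos_cM"].to_numpy())


def write_map(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(path, sep="\t") -> pd.DataFrame:
    """Delimited genotype matrix: rows = individuals, columns = loci, entries +-1."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    validate_genotypes(df.to_numpy())
    return df.astype(np.int8)


def write_genotypes(X, ids, locus_ids, path, sep="\t") -> None:
    pd.DataFrame(np.asarray(X, dtype=np.int8), index=ids, columns=locus_ids).to_csv(path, sep=sep)


def read_vcf(path) -> pd.DataFrame:
    """Import fully homozygous lines from a VCF.

    Only 0/0 and 1/1 genotypes are accepted (REF homozygote -> -1, ALT
    homozygote -> +1); any heterozygous or missing call raises.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids = [], []
    for var in vcf:
        gt = np.asarray(var.gt_types)  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        if np.any((gt == 1) | (gt == 2)):
            raise ValueError(
                f"variant {var.CHROM}:{var.POS} has heterozygous or missing calls; "
                "only fully homozygous lines can be imported"
            )
        rows.append(np.where(gt == 3, 1, -1).astype(np.int8))
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
    if not rows:
        raise ValueError("no variants in VCF")
    return pd.DataFrame(np.column_stack(rows), index=samples, columns=ids)
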