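"""Recurrent DH breeding-program simulation with overlapping cohorts.

The program runs a burn-in of recurrent phenotypic selection to build up
linkage disequilibrium, then a campaign of recurrent selection in which each
year's crossing plan is chosen by a configurable cross-selection index (PM,
UC, OCS or UCPC) under one of three evaluation scenarios:

* ``TRUE`` — QTL positions and effects are known; progeny are selected on
  their true breeding values.
* ``GS``   — effects are re-estimated every year by G-BLUP on a noncausal SNP
  panel and back-solved to marker effects; progeny are selected on GEBVs.
* ``PS``   — no marker information; progeny are selected on phenotypic means
  and crosses on parental phenotypic means (PM only).

Candidate parents of cohort T are the within-family-selected DH lines of the
three cohorts T-3, T-4 and T-5 (DH derivation plus testing takes three
years), which makes cohorts overlapping and connected.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import yaml

from . import ocs
from .gblup import fit_gblup, predict_gebv
from .genome import FounderSet, default_map, generate_founders, make_dh_population
from .traits import TraitArchitecture, error_variance, sample_qtls, simulate_phenotype, tbv
from .ucpc import SelectionRegime, predict_crosses_batch, selection_intensity

__all__ = [
    "ProgramConfig",
    "Cohort",
    "BreedingProgram",
    "CampaignResult",
    "run_campaign",
    "within_family_select",
    "genic_variance",
    "expected_het",
    "count_fixed_lost",
    "discounted_gain",
]

_SCENARIOS = ("TRUE", "GS", "PS")


@dataclasses.dataclass
class ProgramConfig:
    """Every knob of the simulated breeding program (defaults: full scale)."""

    # genome / founders
    n_founders: int = 40
    n_chrom: int = 10
    chrom_len_cm: float = 160.0
    n_map_loci: int = 4000
    founder_pool_size: int = 100
    founder_generations: int = 10
    # trait
    n_qtl: int = 1000
    maf_min: float = 0.2
    spacing_min_cm: float = 0.2
    effect_var: float = 0.05
    repeatability: float = 0.4
    n_env: int = 4
    # program structure
    burnin_years: int = 20
    campaign_years: int = 60
    lags: tuple = (3, 4, 5)
    n_crosses: int = 20
    n_prog: int = 80
    selected_fraction: float = 0.05
    n_burnin_parents: int = 50
    # cross selection
    scenario: str = "TRUE"
    csi: str = "UCPC"
    he_star: float = 0.01
    t_star: int = 60
    traj_shape: float = 1.0
    he0: float | None = None  # None: measured on cohort 0 at campaign start
    accuracy_h: float = 1.0
    # GS scenario
    n_snp: int = 2000
    train_cap: int = 4800
    # differential evolution
    de_pop: int = 7170
    de_iters: int = 1000
    de_p_mut: float = 0.1
    de_p_cross: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}")
        if self.csi.upper() not in ("PM", "UC", "OCS", "UCPC"):
            raise ValueError("csi must be PM, UC, OCS or UCPC")
        if self.scenario == "PS" and self.csi.upper() != "PM":
            raise ValueError("the PS scenario supports only the PM index")
        for name in ("n_founders", "n_crosses", "n_prog", "burnin_years", "campaign_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.lags) < 1:
            raise ValueError("cohort lags must be >= 1")

    @property
    def n_selected_per_family(self) -> int:
        return math.ceil(self.selected_fraction * self.n_prog)

    @property
    def intensity(self) -> float:
        return selection_intensity(self.selected_fraction)

    @classmethod
    def scaled(cls, **overrides) -> "ProgramConfig":
        """Reduced-size profile for tests and desk-scale experiments.

        500 QTLs on a 2,000-locus map, 10 crosses of 40 DH progeny, a 25-line
        burn-in parent pool, a 1,000-SNP panel and a 200 x 100 differential
        evolution, with 20 campaign years; everything else at the defaults.
        """
        base = dict(
            n_map_loci=2000, n_qtl=500, n_crosses=10, n_prog=40,
            n_burnin_parents=25, n_snp=1000, train_cap=1200,
            de_pop=200, de_iters=100, campaign_years=20,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "ProgramConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "lags" in raw:
            raw["lags"] = tuple(raw["lags"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["lags"] = list(d["lags"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclasses.dataclass
class Cohort:
    """One year's 20 x 80 DH progeny with their values and selection flags."""

    year: int                      # absolute year (burn-in years are 1..burnin_years)
    X: np.ndarray | None           # (n_prog * n_crosses, m_work) or None once pruned
    family: np.ndarray             # family index per progeny
    parents: np.ndarray            # (n_crosses, 2) global candidate ids (informative only)
    tbv: np.ndarray
    phen: np.ndarray
    gebv: np.ndarray | None = None
    selected: np.ndarray | None = None

    @property
    def n_progeny(self) -> int:
        return len(self.family)


def within_family_select(values, family, fraction: float) -> np.ndarray:
    """Boolean flags for the top ``fraction`` per family, ties by stable order."""
    values = np.asarray(values, dtype=float)
    family = np.asarray(family)
    if not np.all(np.isfinite(values)):
        raise ValueError("selection criterion contains non-finite values")
    flags = np.zeros(len(values), dtype=bool)
    for f in np.unique(family):
        idx = np.flatnonzero(family == f)
        k = math.ceil(fraction * len(idx))
        order = idx[np.argsort(-values[idx], kind="stable")]
        flags[order[:k]] = True
    return flags


# ---------------------------------------------------------------------------
# per-cohort metrics
# ---------------------------------------------------------------------------

def genic_variance(p, beta) -> float:
    """Additive genic variance sum_j 4 p_j (1-p_j) beta_j^2 at the QTLs."""
    p = np.asarray(p, dtype=float)
    beta = np.asarray(beta, dtype=float)
    return float((4.0 * p * (1.0 - p) * beta**2).sum())


def expected_het(p) -> float:
    """Mean expected heterozygosity (1/m) sum_j 2 p_j (1-p_j)."""
    p = np.asarray(p, dtype=float)
    return float((2.0 * p * (1.0 - p)).mean())


def count_fixed_lost(p, beta) -> tuple[int, int]:
    """QTLs whose favorable allele (sign of beta) is fixed, respectively lost."""
    p = np.asarray(p, dtype=float)
    fav_freq = np.where(np.asarray(beta) >= 0, p, 1.0 - p)
    return int((fav_freq == 1.0).sum()), int((fav_freq == 0.0).sum())


def discounted_gain(g10_series, rho: float) -> float:
    """Discounted cumulative commercial gain sum_T w_T G10(T), w_T ~ (1+rho)^-T."""
    g = np.asarray(g10_series, dtype=float)
    if g.size == 0:
        raise ValueError("empty gain series")
    if rho < 0:
        raise ValueError("interest rate must be non-negative")
    t = np.arange(1, g.size + 1)
    w = (1.0 + rho) ** (-t.astype(float))
    w /= w.sum()
    return float(w @ g)


# ---------------------------------------------------------------------------
# the program
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CampaignResult:
    """Per-cohort metrics, per-year plan records and the final program state."""

    metrics: pd.DataFrame
    plans: list
    config: ProgramConfig
    program: "BreedingProgram"

    def discounted(self, rho: float) -> float:
        g10 = self.metrics.loc[self.metrics["year"] >= 1, "G10"].to_numpy()
        return discounted_gain(g10, rho)


class BreedingProgram:
    """Mutable program state: founders, architecture and overlapping cohorts.

    All randomness flows from the single generator seeded by the config, so a
    (config, seed) pair fully determines every trajectory.
    """

    def __init__(self, config: ProgramConfig, founders: FounderSet | None = None,
                 arch: TraitArchitecture | None = None):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        cfg = config
        if founders is None:
            gmap = default_map(cfg.n_chrom, cfg.chrom_len_cm, cfg.n_map_loci)
            founders = generate_founders(
                cfg.n_founders, gmap, self.rng,
                pool_size=cfg.founder_pool_size,
                n_generations=cfg.founder_generations,
                min_qtl=cfg.n_qtl, maf_min=cfg.maf_min,
            )
        self.founders = founders
        if arch is None:
            arch = sample_qtls(founders, cfg.n_qtl, cfg.maf_min, cfg.spacing_min_cm,
                               cfg.effect_var, self.rng)
        self.arch = arch
        # working loci: QTLs plus (in GS) the noncausal SNP panel
        if cfg.scenario == "GS":
            non_qtl = np.setdiff1d(np.arange(founders.gmap.n_loci), arch.qtl_idx)
            if len(non_qtl) < cfg.n_snp:
                raise ValueError("map too small for the requested SNP panel")
            panel = np.sort(self.rng.choice(non_qtl, size=cfg.n_snp, replace=False))
        else:
            panel = np.array([], dtype=np.int64)
        self.work_idx = np.union1d(arch.qtl_idx, panel)
        self.wmap = founders.gmap.subset(self.work_idx)
        self.qtl_cols = np.searchsorted(self.work_idx, arch.qtl_idx)
        self.snp_cols = np.searchsorted(self.work_idx, panel)
        self.beta_q = arch.beta
        founder_tbv = tbv(founders.X, arch)
        self.sigma2_e = error_variance(float(np.var(founder_tbv, ddof=1)), cfg.repeatability)
        self.cohorts: dict[int, Cohort] = {}
        self.year = 0
        self.mu0: float | None = None
        self.sigmaA0: float | None = None
        self.trajectory: ocs.DiversityTrajectory | None = None
        self._gs_fit = None

    # -- small helpers ------------------------------------------------------

    def _tbv_work(self, X_work) -> np.ndarray:
        return X_work[:, self.qtl_cols] @ self.beta_q

    def _qtl_freq(self, X_work) -> np.ndarray:
        return (X_work[:, self.qtl_cols] == 1).mean(axis=0)

    def _random_pairs(self, n: int, k: int) -> np.ndarray:
        pairs = ocs.all_pairs(n)
        take = self.rng.choice(len(pairs), size=k, replace=False)
        return pairs[take]

    def _phenotype(self, a) -> np.ndarray:
        return simulate_phenotype(a, self.sigma2_e, self.config.n_env, self.rng)

    def _make_cohort(self, year: int, pairs: np.ndarray, parent_X: np.ndarray,
                     parent_ids: np.ndarray | None = None) -> Cohort:
        cfg = self.config
        blocks, fam = [], []
        for f, (i, j) in enumerate(pairs):
            blocks.append(make_dh_population(parent_X[i], parent_X[j], self.wmap,
                                             cfg.n_prog, self.rng))
            fam.extend([f] * cfg.n_prog)
        X = np.vstack(blocks)
        a = self._tbv_work(X)
        phen = self._phenotype(a)
        gids = pairs if parent_ids is None else parent_ids[pairs]
        cohort = Cohort(year, X, np.asarray(fam), np.asarray(gids), a, phen)
        self.cohorts[year] = cohort
        self._prune()
        return cohort

    def _prune(self) -> None:
        """Free genotype matrices no longer reachable as candidate parents."""
        horizon = self.year - max(self.config.lags)
        for y, c in self.cohorts.items():
            if y < horizon and c.X is not None and c.selected is not None:
                c.X = c.X[c.selected]
                c.family = c.family[c.selected]
                c.tbv = c.tbv[c.selected]
                c.phen = c.phen[c.selected]
                if c.gebv is not None:
                    c.gebv = c.gebv[c.selected]
                c.selected = np.ones(c.X.shape[0], dtype=bool)
                # keep only the selected lines; metrics were recorded at creation

    # -- burn-in ------------------------------------------------------------

    def run_burn_in(self) -> None:
        """Recurrent phenotypic selection for ``burnin_years`` years."""
        cfg = self.config
        founder_work = self.founders.X[:, self.work_idx]
        for year in range(1, cfg.burnin_years + 1):
            self.year = year
            if year <= min(cfg.lags):
                pairs = self._random_pairs(cfg.n_founders, cfg.n_crosses)
                cohort = self._make_cohort(year, pairs, founder_work)
            else:
                pool_X, pool_phen = self._burnin_pool(year)
                order = np.argsort(-pool_phen, kind="stable")[: cfg.n_burnin_parents]
                pool_X = pool_X[order]
                pairs = self._random_pairs(len(pool_X), cfg.n_crosses)
                cohort = self._make_cohort(year, pairs, pool_X)
            cohort.selected = within_family_select(cohort.phen, cohort.family,
                                                   cfg.selected_fraction)

    def _burnin_pool(self, year: int):
        avail = sorted(y for y in self.cohorts if y <= year - min(self.config.lags))
        avail = avail[-len(self.config.lags):]
        if not avail:
            raise RuntimeError("no available cohort to draw burn-in parents from")
        Xs, ph = [], []
        for y in avail:
            c = self.cohorts[y]
            Xs.append(c.X[c.selected])
            ph.append(c.phen[c.selected])
        return np.vstack(Xs), np.concatenate(ph)

    # -- campaign -----------------------------------------------------------

    def start_campaign(self) -> None:
        """Freeze cohort-0 references and the diversity trajectory."""
        cfg = self.config
        c0 = self.cohorts[cfg.burnin_years]
        self.mu0 = float(c0.tbv.mean())
        self.sigmaA0 = float(np.std(c0.tbv, ddof=0))
        if self.sigmaA0 == 0.0:
            raise RuntimeError("cohort 0 has zero genetic variance; gains undefined")
        he0 = cfg.he0
        if he0 is None:
            cols = self.snp_cols if cfg.scenario == "GS" else self.qtl_cols
            p0 = (c0.X[:, cols] == 1).mean(axis=0)
            he0 = expected_het(p0)
        self.trajectory = ocs.DiversityTrajectory(he0, cfg.he_star, cfg.t_star, cfg.traj_shape)

    def candidate_pool(self, year: int):
        """Selected DH of cohorts year-3, year-4, year-5: X, values, source index."""
        cfg = self.config
        Xs, tb, ph, ge, src = [], [], [], [], []
        for lag in sorted(cfg.lags):
            y = year - lag
            if y not in self.cohorts:
                raise KeyError(f"cohort {y} required for year {year} does not exist")
            c = self.cohorts[y]
            if c.selected is None:
                raise RuntimeError(f"cohort {y} has no selection flags yet")
            sel = np.flatnonzero(c.selected)
            Xs.append(c.X[sel])
            tb.append(c.tbv[sel])
            ph.append(c.phen[sel])
            ge.append(c.gebv[sel] if c.gebv is not None else np.full(len(sel), np.nan))
            src.extend((y, int(s)) for s in sel)
        return (np.vstack(Xs), np.concatenate(tb), np.concatenate(ph),
                np.concatenate(ge), src)

    def _gs_refit(self, year: int):
        """Annual G-BLUP refit on the three contributing cohorts; flag the
        newly available cohort on predicted GEBVs."""
        cfg = self.config
        ys = [year - lag for lag in sorted(cfg.lags)]
        Xs = np.vstack([self.cohorts[y].X for y in ys])
        phen = np.concatenate([self.cohorts[y].phen for y in ys])
        if len(phen) > cfg.train_cap:
            take = np.sort(self.rng.choice(len(phen), size=cfg.train_cap, replace=False))
            Xs, phen = Xs[take], phen[take]
        fit = fit_gblup(phen, M=Xs[:, self.snp_cols])
        self._gs_fit = fit
        for y in ys:
            c = self.cohorts[y]
            gebv = predict_gebv(fit.beta, fit.mu, c.X[:, self.snp_cols], fit.freqs)
            c.gebv = gebv
            if c.selected is None:
                c.selected = within_family_select(gebv, c.family, cfg.selected_fraction)
        return fit

    def advance_one_year(self, t: int) -> dict:
        """Run campaign year ``t`` (t = 1 is the first post-burn-in cohort)."""
        cfg = self.config
        year = cfg.burnin_years + t
        self.year = year
        fit = self._gs_refit(year) if cfg.scenario == "GS" else None
        pool_X, pool_tbv, pool_phen, pool_gebv, src = self.candidate_pool(year)
        n_pool = pool_X.shape[0]
        pairs = ocs.all_pairs(n_pool)
        regime = SelectionRegime(q=cfg.selected_fraction, h=cfg.accuracy_h)
        csi = ocs.CSISpec.from_label(cfg.csi, regime.i * regime.h)
        if cfg.scenario == "TRUE":
            marker_cols, beta = self.qtl_cols, self.beta_q
        elif cfg.scenario == "GS":
            marker_cols, beta = self.snp_cols, fit.beta
        else:  # PS: parental phenotypic means only
            marker_cols, beta = None, None
        if marker_cols is not None:
            M = pool_X[:, marker_cols]
            gmap_m = self.wmap.subset(marker_cols)
            preds = predict_crosses_batch(M, pairs, beta, gmap_m, regime)
            K = ocs.ibs_coancestry(M) if csi.constrained else None
        else:
            mu = 0.5 * (pool_phen[pairs[:, 0]] + pool_phen[pairs[:, 1]])
            preds = pd.DataFrame(
                {"p1": pairs[:, 0], "p2": pairs[:, 1], "mu_T": mu,
                 "sigma_T": 0.0, "uc": mu, "c1": 0.5}
            )
            K = None
        constraint = ocs.he_target(t, self.trajectory) if csi.constrained else None
        de = ocs.DEConfig(cfg.de_pop, cfg.de_iters, cfg.de_p_mut, cfg.de_p_cross)
        result = ocs.optimize_plan(preds, K, csi, cfg.n_crosses, constraint, de, self.rng)
        chosen = pairs[result.plan]
        cohort = self._make_cohort(year, chosen, pool_X)
        if cfg.scenario == "TRUE":
            cohort.selected = within_family_select(cohort.tbv, cohort.family,
                                                   cfg.selected_fraction)
        elif cfg.scenario == "PS":
            cohort.selected = within_family_select(cohort.phen, cohort.family,
                                                   cfg.selected_fraction)
        # GS cohorts are flagged on GEBVs when they first enter a candidate pool
        return {
            "t": t, "year": year, "n_pool": n_pool, "n_candidate_crosses": len(pairs),
            "V": result.V, "D": result.D, "feasible": result.feasible,
            "constraint": constraint, "plan": chosen,
        }

    def metrics_row(self, t: int) -> dict:
        cohort = self.cohorts[self.config.burnin_years + t]
        p = self._qtl_freq(cohort.X) if cohort.X is not None else None
        if p is None:
            raise RuntimeError("cohort genotypes already pruned")
        s2A = float(np.var(cohort.tbv, ddof=0))
        s2a = genic_variance(p, self.beta_q)
        n_fixed, n_lost = count_fixed_lost(p, self.beta_q)
        mu = float(cohort.tbv.mean())
        mu10 = float(np.sort(cohort.tbv)[-10:].mean())
        return {
            "year": t,
            "sigma2_A": s2A,
            "sigma2_a": s2a,
            "ratio": s2A / s2a if s2a > 0 else np.nan,
            "He": expected_het(p),
            "n_fixed": n_fixed,
            "n_lost": n_lost,
            "G": (mu - self.mu0) / self.sigmaA0,
            "G10": (mu10 - self.mu0) / self.sigmaA0,
        }


def run_campaign(config: ProgramConfig, founders: FounderSet | None = None,
                 arch: TraitArchitecture | None = None) -> CampaignResult:
    """Burn-in plus a full campaign under the configured scenario and CSI."""
    prog = BreedingProgram(config, founders, arch)
    prog.run_burn_in()
    prog.start_campaign()
    rows = [prog.metrics_row(0)]
    plans = []
    for t in range(1, config.campaign_years + 1):
        plans.append(prog.advance_one_year(t))
        rows.append(prog.metrics_row(t))
    return CampaignResult(pd.DataFrame(rows), plans, config, prog)
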