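"""Crossing-plan evaluation and epsilon-constraint differential-evolution search.

A crossing plan is a set of ``nc`` distinct two-way crosses drawn from the
candidate crosses of a parent pool.  Its gain term V is the mean expected
progeny performance (parental-mean at intensity i = 0, usefulness criterion at
i > 0); its diversity term D = 1 - c'Kc is the expected heterozygosity of the
(selected) progeny implied by the parental contributions c and the IBS
coancestry K among candidates.  The optimizer maximizes V subject to
D >= He(t), where He(t) is a scheduled diversity trajectory, using a
differential-evolution search over integer cross-index vectors with
lexicographic feasibility handling.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .genome import validate_genotypes

__all__ = [
    "ibs_coancestry",
    "progeny_allele_freq",
    "plan_contributions",
    "gain_V",
    "diversity_D",
    "DiversityTrajectory",
    "he_target",
    "DEConfig",
    "CSISpec",
    "PlanResult",
    "optimize_plan",
    "exhaustive_plan_search",
    "all_pairs",
]


def ibs_coancestry(X) -> np.ndarray:
    """Identity-by-state coancestry K = (XX'/m + 1)/2 for +-1-coded lines.

    Diagonal entries are 1 for fully homozygous lines; off-diagonals equal the
    probability that a random locus carries the same allele in both lines.
    """
    X = validate_genotypes(np.asarray(X, dtype=np.int8)).astype(float)
    m = X.shape[1]
    return 0.5 * (X @ X.T / m + 1.0)


def all_pairs(n: int) -> np.ndarray:
    """All n(n-1)/2 unordered parent pairs (no selfing), lexicographic order."""
    i, j = np.triu_indices(n, k=1)
    return np.column_stack((i, j))


def progeny_allele_freq(c, X) -> np.ndarray:
    """Expected +1-allele frequency in progeny under parental contributions c."""
    c = np.asarray(c, dtype=float)
    X = np.asarray(X, dtype=float)
    return 0.5 * (c @ X + 1.0)


def _contrib_weights(predictions: pd.DataFrame, plan, intensity: float):
    plan = np.asarray(plan, dtype=np.int64)
    if intensity == 0.0:
        w1 = np.full(len(plan), 0.5)
    else:
        w1 = predictions["c1"].to_numpy()[plan]
    return plan, w1


def plan_contributions(plan, predictions: pd.DataFrame, intensity: float,
                       n_candidates: int) -> np.ndarray:
    """Per-candidate contributions c = (Z1 c1 + Z2 c2) / nc for one plan.

    At intensity 0 both parents of a cross contribute 1/2; at intensity > 0
    the post-selection contributions c1, c2 from the predictions table are
    used.  The result is non-negative and sums to 1.
    """
    plan, w1 = _contrib_weights(predictions, plan, intensity)
    p1 = predictions["p1"].to_numpy()[plan]
    p2 = predictions["p2"].to_numpy()[plan]
    c = np.zeros(n_candidates)
    np.add.at(c, p1, w1 / len(plan))
    np.add.at(c, p2, (1.0 - w1) / len(plan))
    return c


def gain_V(plan, predictions: pd.DataFrame, intensity: float) -> float:
    """Expected mean performance of the (selected) progeny of a plan."""
    plan = np.asarray(plan, dtype=np.int64)
    col = "mu_T" if intensity == 0.0 else "uc"
    return float(predictions[col].to_numpy()[plan].mean())


def diversity_D(plan, predictions: pd.DataFrame, K: np.ndarray, intensity: float) -> float:
    """Expected heterozygosity D = 1 - c'Kc of the (selected) progeny of a plan."""
    c = plan_contributions(plan, predictions, intensity, K.shape[0])
    return float(1.0 - c @ K @ c)


# ---------------------------------------------------------------------------
# diversity trajectory
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DiversityTrajectory:
    """Scheduled lower bound on progeny diversity.

    He(t) moves from ``he0`` at t = 0 to ``he_star`` at the horizon ``t_star``
    (and stays there) with shape ``s`` (s = 1: linear, s = 2: quadratic,
    s = 0.5: inverse-quadratic).
    """

    he0: float
    he_star: float
    t_star: int
    s: float = 1.0

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("shape parameter must be positive")
        if self.t_star <= 0:
            raise ValueError("horizon must be positive")

    def __call__(self, t: float) -> float:
        return he_target(t, self)


def he_target(t: float, traj: DiversityTrajectory) -> float:
    """He(t) = He0 + (t/t*)^s (He* - He0) for t <= t*, else He*."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if t >= traj.t_star:
        return float(traj.he_star)
    return float(traj.he0 + (t / traj.t_star) ** traj.s * (traj.he_star - traj.he0))


# ---------------------------------------------------------------------------
# cross-selection indices
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CSISpec:
    """Cross-selection index: which intensities enter V and D, and whether the
    diversity constraint is active.

    PM:       V at i = 0, no constraint (mean parental breeding value).
    UC:       V at i, no constraint (mean usefulness criterion).
    OCS:      V and D at i = 0, constraint on (classical optimal cross-selection).
    UCPC:     V and D at i, constraint on (accounts for within-family selection).
    """

    label: str
    i_V: float
    i_D: float
    constrained: bool

    @classmethod
    def pm(cls) -> "CSISpec":
        return cls("PM", 0.0, 0.0, False)

    @classmethod
    def uc(cls, intensity: float) -> "CSISpec":
        return cls("UC", intensity, 0.0, False)

    @classmethod
    def ocs(cls) -> "CSISpec":
        return cls("OCS", 0.0, 0.0, True)

    @classmethod
    def ucpc(cls, intensity: float) -> "CSISpec":
        return cls("UCPC", intensity, intensity, True)

    @classmethod
    def from_label(cls, label: str, intensity: float) -> "CSISpec":
        key = label.upper()
        if key == "PM":
            return cls.pm()
        if key == "UC":
            return cls.uc(intensity)
        if key == "OCS":
            return cls.ocs()
        if key == "UCPC":
            return cls.ucpc(intensity)
        raise ValueError(f"unknown CSI label {label!r}")


@dataclasses.dataclass(frozen=True)
class DEConfig:
    """Differential-evolution settings (population, iterations, operator rates)."""

    pop_size: int = 7170
    iterations: int = 1000
    p_mut: float = 0.1
    p_cross: float = 0.5

    def __post_init__(self):
        if self.pop_size < 2 or self.iterations < 1:
            raise ValueError("population must be >= 2 and iterations >= 1")


@dataclasses.dataclass
class PlanResult:
    """Outcome of a plan search: the plan, its (V, D) and feasibility."""

    plan: np.ndarray
    V: float
    D: float
    feasible: bool
    violation: float
    history: list


# ---------------------------------------------------------------------------
# batch plan evaluation
# ---------------------------------------------------------------------------

class _PlanEvaluator:
    def __init__(self, predictions: pd.DataFrame, K, csi: CSISpec, constraint):
        self.p1 = predictions["p1"].to_numpy(dtype=np.int64)
        self.p2 = predictions["p2"].to_numpy(dtype=np.int64)
        self.mu = predictions["mu_T"].to_numpy(dtype=float)
        self.uc = predictions["uc"].to_numpy(dtype=float)
        self.c1 = predictions["c1"].to_numpy(dtype=float)
        self.K = None if K is None else np.asarray(K, dtype=float)
        self.csi = csi
        self.constraint = constraint if csi.constrained else None
        self.n_crosses = len(predictions)

    def __call__(self, plans: np.ndarray):
        """V, D, violation for a (pop, nc) array of plans."""
        plans = np.atleast_2d(plans)
        pop, nc = plans.shape
        gain = self.mu if self.csi.i_V == 0.0 else self.uc
        V = gain[plans].mean(axis=1)
        if self.K is None:
            D = np.full(pop, np.nan)
        else:
            w1 = np.full((pop, nc), 0.5) if self.csi.i_D == 0.0 else self.c1[plans]
            C = np.zeros((pop, self.K.shape[0]))
            rows = np.broadcast_to(np.arange(pop)[:, None], (pop, nc))
            np.add.at(C, (rows, self.p1[plans]), w1 / nc)
            np.add.at(C, (rows, self.p2[plans]), (1.0 - w1) / nc)
            D = 1.0 - np.einsum("ij,ij->i", C @ self.K, C)
        if self.constraint is None:
            viol = np.zeros(pop)
        else:
            viol = np.maximum(self.constraint - D, 0.0)
        return V, D, viol


def _better(Va, viola, Vb, violb):
    """Lexicographic superiority of a over b: feasibility first, then V,
    then smaller violation among infeasible."""
    fa, fb = viola == 0.0, violb == 0.0
    return (fa & ~fb) | (fa & fb & (Va > Vb)) | (~fa & ~fb & (viola < violb))


def _repair_row(row: np.ndarray, n_crosses: int, rng) -> None:
    """Redraw duplicate crosses within one plan, in place."""
    seen = set()
    for k, v in enumerate(row):
        while v in seen:
            v = int(rng.integers(n_crosses))
        row[k] = v
        seen.add(v)


def optimize_plan(
    predictions: pd.DataFrame,
    K,
    csi: CSISpec,
    nc: int,
    constraint: float | None = None,
    de: DEConfig = DEConfig(),
    rng=None,
    track_history: bool = False,
) -> PlanResult:
    """Differential-evolution search for the best crossing plan.

    Candidate solutions are integer vectors of ``nc`` distinct cross indices
    into ``predictions``.  Each iteration mutates every solution (each gene
    replaced by a random cross index with probability ``p_mut``), applies
    uniform crossover with a random partner (``p_cross`` per gene), repairs
    duplicate crosses by redraw, and keeps the offspring only if superior
    (elitist one-for-one replacement), so the best objective value is
    non-decreasing.  Feasibility is lexicographic: any feasible plan beats any
    infeasible one; among infeasible plans smaller constraint violation wins.

    If the constraint cannot be satisfied by any explored plan, the
    least-violating plan is returned with ``feasible=False``.
    """
    if rng is None:
        rng = np.random.default_rng()
    n_crosses = len(predictions)
    if n_crosses < nc:
        raise ValueError("fewer candidate crosses than plan size")
    evaluate = _PlanEvaluator(predictions, K, csi, constraint)
    pop = np.empty((de.pop_size, nc), dtype=np.int64)
    for r in range(de.pop_size):
        pop[r] = rng.choice(n_crosses, size=nc, replace=False)
    V, D, viol = evaluate(pop)
    history = []
    for _ in range(de.iterations):
        off = pop.copy()
        mut = rng.random(off.shape) < de.p_mut
        off[mut] = rng.integers(n_crosses, size=int(mut.sum()))
        partner = (np.arange(de.pop_size) + rng.integers(1, de.pop_size, size=de.pop_size)) % de.pop_size
        cx = rng.random(off.shape) < de.p_cross
        off[cx] = pop[partner][cx]
        bad = np.flatnonzero([len(set(row)) < nc for row in off])
        for r in bad:
            _repair_row(off[r], n_crosses, rng)
        Vo, Do, violo = evaluate(off)
        repl = _better(Vo, violo, V, viol)
        pop[repl] = off[repl]
        V[repl], D[repl], viol[repl] = Vo[repl], Do[repl], violo[repl]
        if track_history:
            b = _best_index(V, viol)
            history.append((float(V[b]), float(D[b])))
    b = _best_index(V, viol)
    return PlanResult(np.sort(pop[b]), float(V[b]), float(D[b]),
                      bool(viol[b] == 0.0), float(viol[b]), history)


def _best_index(V, viol) -> int:
    feas = viol == 0.0
    if feas.any():
        idx = np.flatnonzero(feas)
        return int(idx[np.argmax(V[idx])])
    return int(np.argmin(viol))


def exhaustive_plan_search(
    predictions: pd.DataFrame,
    K,
    csi: CSISpec,
    nc: int,
    constraint: float | None = None,
    max_plans: int = 1_000_000,
    batch: int = 4096,
) -> PlanResult:
    """True optimum by enumerating every plan (test oracle for small instances)."""
    from math import comb

    n_crosses = len(predictions)
    total = comb(n_crosses, nc)
    if total > max_plans:
        raise ValueError(f"{total} plans exceed the enumeration limit {max_plans}")
    evaluate = _PlanEvaluator(predictions, K, csi, constraint)
    best = None
    buf = []
    for combo in itertools.combinations(range(n_crosses), nc):
        buf.append(combo)
        if len(buf) == batch:
            best = _fold_best(best, np.array(buf, dtype=np.int64), evaluate)
            buf = []
    if buf:
        best = _fold_best(best, np.array(buf, dtype=np.int64), evaluate)
    plan, V, D, viol = best
    return PlanResult(np.sort(plan), V, D, bool(viol == 0.0), viol, [])


def _fold_best(best, plans, evaluate):
    V, D, viol = evaluate(plans)
    b = _best_index(V, viol)
    cand = (plans[b], float(V[b]), float(D[b]), float(viol[b]))
    if best is None:
        return cand
    if _better(np.array([cand[1]]), np.array([cand[3]]),
               np.array([best[1]]), np.array([best[3]]))[0]:
        return cand
    return best


def export_plan(result: PlanResult, predictions: pd.DataFrame, path, ids=None) -> None:
    """Write a plan as a delimited table (rank, parents, UC, c1)."""
    sub = predictions.iloc[result.plan].copy()
    sub = sub.sort_values("uc", ascending=False).reset_index(drop=True)
    out = pd.DataFrame(
        {
            "rank": np.arange(1, len(sub) + 1),
            "p1": sub["p1"] if ids is None else [ids[i] for i in sub["p1"]],
            "p2": sub["p2"] if ids is None else [ids[i] for i in sub["p2"]],
            "uc": sub["uc"],
            "c1": sub["c1"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
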