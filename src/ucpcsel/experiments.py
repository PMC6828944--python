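"""Replications of the two simulation experiments on synthetic founders.

``simulation1`` evaluates how well parental-contribution-based predictions
anticipate the genetic diversity (expected heterozygosity, He) of the selected
fraction of progeny of random crossing plans, comparing ante-selection
contributions (both parents 1/2) with post-selection UCPC contributions.  Two
reference pools are extracted from a seeded parental-mean campaign: E1 (the
candidate parents of the first post-burn-in cohort, diverse) and E2 (those of
a late cohort, improved and narrower), and random sets of crosses are drawn
within E1, within E2, and across the combined pool.

Head-to-head campaign comparisons (the second experiment) are plain
:func:`ucpcsel.program.run_campaign` calls with different ``csi`` settings.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import ocs
from .genome import make_dh_population
from .program import BreedingProgram, ProgramConfig, expected_het, within_family_select
from .ucpc import SelectionRegime, predict_crosses_batch

__all__ = ["Sim1Result", "simulation1"]

SET_TYPES = ("E1xE1", "E2xE2", "mixed")


@dataclasses.dataclass
class Sim1Result:
    """Per-set predictions and empirical diversities, plus summary statistics."""

    per_set: pd.DataFrame
    summary: dict
    config: ProgramConfig

    def __repr__(self):
        s = self.summary
        return (
            f"Sim1Result({len(self.per_set)} sets; pre-selection: "
            f"R2={s['r2_ante_pre']:.3f}, mean error={s['mean_err_ante_pre']:.4f})"
        )


def _r2(x, y) -> float:
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def simulation1(
    config: ProgramConfig | None = None,
    n_sets_per_type: int = 100,
    crosses_per_set: int = 20,
    n_prog: int = 80,
    late_year: int = 20,
) -> Sim1Result:
    """Predicted vs empirical He of the selected progeny of random cross sets.

    For each of ``3 * n_sets_per_type`` random sets of ``crosses_per_set``
    two-way crosses, ``n_prog`` DH per cross are simulated and the best 5% per
    family selected on TBV.  He is predicted as 1 - c'Kc from ante-selection
    (i = 0) and post-selection (i = i_5%) contributions, and measured
    empirically before and after selection on QTL allele frequencies.
    """
    if config is None:
        config = ProgramConfig.scaled()
    cfg = dataclasses.replace(config, csi="PM", scenario="TRUE",
                              campaign_years=max(late_year, 1))
    prog = BreedingProgram(cfg)
    prog.run_burn_in()
    prog.start_campaign()
    X1 = prog.candidate_pool(cfg.burnin_years + 1)[0]
    for t in range(1, late_year + 1):
        prog.advance_one_year(t)
    X2 = prog.candidate_pool(cfg.burnin_years + late_year)[0]
    qcols = prog.qtl_cols
    Xc = np.vstack((X1, X2))[:, qcols]
    n1 = X1.shape[0]
    n_all = Xc.shape[0]
    qmap = prog.wmap.subset(qcols)
    beta = prog.beta_q
    K = ocs.ibs_coancestry(Xc)
    regime = SelectionRegime(q=cfg.selected_fraction, h=1.0)
    rng = np.random.default_rng((cfg.seed, 20_001))
    fam = np.repeat(np.arange(crosses_per_set), n_prog)
    rows = []
    for set_type in SET_TYPES:
        if set_type == "E1xE1":
            members = np.arange(n1)
        elif set_type == "E2xE2":
            members = np.arange(n1, n_all)
        else:
            members = np.arange(n_all)
        all_p = ocs.all_pairs(len(members))
        for _ in range(n_sets_per_type):
            take = rng.choice(len(all_p), size=crosses_per_set, replace=False)
            pairs = members[all_p[take]]
            preds = predict_crosses_batch(Xc, pairs, beta, qmap, regime)
            plan = np.arange(crosses_per_set)
            pred_ante = ocs.diversity_D(plan, preds, K, 0.0)
            pred_post = ocs.diversity_D(plan, preds, K, regime.i)
            prog_X = np.vstack([
                make_dh_population(Xc[i], Xc[j], qmap, n_prog, rng)
                for i, j in pairs
            ])
            a = prog_X @ beta
            sel = within_family_select(a, fam, cfg.selected_fraction)
            emp_pre = expected_het((prog_X == 1).mean(axis=0))
            emp_post = expected_het((prog_X[sel] == 1).mean(axis=0))
            delta_tbv = float(np.abs(
                Xc[pairs[:, 0]] @ beta - Xc[pairs[:, 1]] @ beta
            ).mean())
            rows.append({
                "set_type": set_type, "pred_ante": pred_ante,
                "pred_post": pred_post, "emp_pre": emp_pre,
                "emp_post": emp_post, "delta_tbv": delta_tbv,
                "n_selected": int(sel.sum()),
            })
    per_set = pd.DataFrame(rows)
    summary = {
        "r2_ante_pre": _r2(per_set["pred_ante"], per_set["emp_pre"]),
        "mean_err_ante_pre": float((per_set["pred_ante"] - per_set["emp_pre"]).mean()),
    }
    for st in SET_TYPES:
        sub = per_set[per_set["set_type"] == st]
        summary[f"r2_ante_post_{st}"] = _r2(sub["pred_ante"], sub["emp_post"])
        summary[f"r2_post_post_{st}"] = _r2(sub["pred_post"], sub["emp_post"])
        summary[f"mean_err_ante_post_{st}"] = float((sub["pred_ante"] - sub["emp_post"]).mean())
        summary[f"mean_err_post_post_{st}"] = float((sub["pred_post"] - sub["emp_post"]).mean())
    summary["mean_err_ante_post"] = float((per_set["pred_ante"] - per_set["emp_post"]).mean())
    summary["mean_err_post_post"] = float((per_set["pred_post"] - per_set["emp_post"]).mean())
    return Sim1Result(per_set, summary, cfg)
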