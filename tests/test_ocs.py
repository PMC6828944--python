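"""Crossing-plan evaluation, diversity identity and the DE search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ucpcsel as u
from ucpcsel.ucpc import SelectionRegime, predict_crosses_batch


def _preds(founders, beta, regime=None):
    regime = regime or SelectionRegime(q=0.05)
    pairs = u.all_pairs(founders.n_founders)
    return predict_crosses_batch(founders.X, pairs, beta, founders.gmap, regime)


class TestCoancestry:
    def test_examples(self):
        X = np.array([[1, 1, -1, -1], [-1, -1, 1, 1], [1, 1, 1, 1]], dtype=np.int8)
        K = u.ibs_coancestry(X)
        assert np.allclose(np.diag(K), 1.0)
        assert K[0, 1] == pytest.approx(0.0)      # opposite at every locus
        assert K[0, 2] == pytest.approx(0.5)      # agree at half the loci
        with pytest.raises(ValueError):
            u.ibs_coancestry(np.array([[0, 1]]))


class TestContributionsAndGain:
    def test_halves_and_conservation(self, founders12, arch50):
        preds = _preds(founders12, np.zeros(founders12.gmap.n_loci))
        plan = np.arange(20)
        c = u.plan_contributions(plan, preds, 0.0, founders12.n_founders)
        assert c.sum() == pytest.approx(1.0)
        # parent appearing in k crosses contributes k / (2 nc)
        counts = np.bincount(
            np.concatenate([preds["p1"][plan], preds["p2"][plan]]),
            minlength=founders12.n_founders,
        )
        assert np.allclose(c, counts / 40)

    def test_single_cross_post_selection_split(self):
        preds = pd.DataFrame({"p1": [0], "p2": [1], "mu_T": [0.0],
                              "sigma_T": [1.0], "uc": [2.06], "c1": [0.946]})
        c = u.plan_contributions([0], preds, 2.06, 2)
        assert np.allclose(c, [0.946, 0.054])

    def test_gain_identity_and_uc_dominance(self, founders12, arch50):
        beta = np.zeros(founders12.gmap.n_loci)
        beta[arch50.qtl_idx] = arch50.beta
        preds = _preds(founders12, beta)
        a = founders12.X @ beta
        rng = np.random.default_rng(0)
        plan = rng.choice(len(preds), 10, replace=False)
        v0 = u.gain_V(plan, preds, 0.0)
        c = u.plan_contributions(plan, preds, 0.0, founders12.n_founders)
        assert v0 == pytest.approx(float(c @ a))          # V(0) = c'a
        assert u.gain_V(plan, preds, 2.06) >= v0          # UC >= mu_T

    def test_single_cross_uc_value(self):
        mu, sigma = 0.0, np.sqrt(3.0)
        preds = pd.DataFrame({"p1": [0], "p2": [1], "mu_T": [mu],
                              "sigma_T": [sigma], "uc": [mu + 2.06 * sigma],
                              "c1": [0.5]})
        assert u.gain_V([0], preds, 2.06) == pytest.approx(3.568, abs=5e-4)


class TestDiversity:
    def test_extremes(self):
        X = np.array([[1, -1], [-1, 1]], dtype=np.int8)
        K = u.ibs_coancestry(X)
        preds = pd.DataFrame({"p1": [0], "p2": [1], "mu_T": [0.0],
                              "sigma_T": [0.0], "uc": [0.0], "c1": [1.0]})
        # all contribution on one line -> no diversity
        assert u.diversity_D([0], preds, K, 2.06) == pytest.approx(0.0)
        # everywhere-opposite parents at i=0 -> maximal diversity 0.5
        assert u.diversity_D([0], preds, K, 0.0) == pytest.approx(0.5)

    def test_identity_with_frequency_oracle(self, founders12, arch50):
        """1 - c'Kc equals the expected heterozygosity implied by the
        contribution-weighted progeny allele frequencies, exactly."""
        beta = np.zeros(founders12.gmap.n_loci)
        beta[arch50.qtl_idx] = arch50.beta
        preds = _preds(founders12, beta)
        K = u.ibs_coancestry(founders12.X)
        rng = np.random.default_rng(1)
        for intensity in (0.0, 2.06):
            for _ in range(5):
                plan = rng.choice(len(preds), 8, replace=False)
                c = u.plan_contributions(plan, preds, intensity,
                                         founders12.n_founders)
                p = u.progeny_allele_freq(c, founders12.X)
                he = float((2 * p * (1 - p)).mean())
                assert u.diversity_D(plan, preds, K, intensity) == pytest.approx(
                    he, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12))
    def test_identity_for_arbitrary_contributions(self, raw):
        """The coancestry identity holds for any contribution vector summing to 1."""
        c = np.asarray(raw) + 1e-9
        c = c / c.sum()
        rng = np.random.default_rng(len(raw))
        X = rng.choice([-1, 1], size=(len(c), 40)).astype(np.int8)
        K = u.ibs_coancestry(X)
        p = u.progeny_allele_freq(c, X)
        assert 1 - c @ K @ c == pytest.approx(float((2 * p * (1 - p)).mean()),
                                              abs=1e-12)


class TestTrajectory:
    def test_values(self):
        traj = u.DiversityTrajectory(0.3, 0.01, 60, s=1.0)
        assert u.he_target(0, traj) == pytest.approx(0.3)
        assert u.he_target(60, traj) == pytest.approx(0.01)
        assert u.he_target(90, traj) == pytest.approx(0.01)
        assert u.he_target(30, traj) == pytest.approx(0.155)
        with pytest.raises(ValueError):
            u.he_target(-1, traj)

    def test_monotone_decline(self):
        traj = u.DiversityTrajectory(0.3, 0.01, 60, s=2.0)
        vals = [u.he_target(t, traj) for t in range(61)]
        assert np.all(np.diff(vals) <= 0)


class TestOptimizer:
    def _small_problem(self, founders, arch, n_cand=6, seed=0):
        rng = np.random.default_rng(seed)
        take = rng.choice(founders.n_founders, n_cand, replace=False)
        X = founders.X[take]
        beta = np.zeros(founders.gmap.n_loci)
        beta[arch.qtl_idx] = arch.beta
        preds = predict_crosses_batch(X, u.all_pairs(n_cand), beta,
                                      founders.gmap, SelectionRegime(q=0.05))
        return preds, u.ibs_coancestry(X)

    def test_unconstrained_pm_equals_exhaustive(self, founders12, arch50):
        preds, K = self._small_problem(founders12, arch50)
        csi = u.CSISpec.pm()
        ex = u.exhaustive_plan_search(preds, K, csi, nc=2)
        de = u.optimize_plan(preds, K, csi, nc=2,
                             de=u.DEConfig(60, 60), rng=np.random.default_rng(1))
        assert de.V == pytest.approx(ex.V)

    def test_determinism(self, founders12, arch50):
        preds, K = self._small_problem(founders12, arch50)
        csi = u.CSISpec.ucpc(2.06)
        kw = dict(nc=3, constraint=0.2, de=u.DEConfig(40, 40))
        r1 = u.optimize_plan(preds, K, csi, rng=np.random.default_rng(3), **kw)
        r2 = u.optimize_plan(preds, K, csi, rng=np.random.default_rng(3), **kw)
        assert np.array_equal(r1.plan, r2.plan) and r1.V == r2.V

    def test_elitist_best_is_monotone(self, founders12, arch50):
        preds, K = self._small_problem(founders12, arch50, n_cand=8, seed=2)
        res = u.optimize_plan(preds, K, u.CSISpec.uc(2.06), nc=3,
                              de=u.DEConfig(30, 50),
                              rng=np.random.default_rng(4), track_history=True)
        vs = [v for v, _ in res.history]
        assert np.all(np.diff(vs) >= -1e-12)

    def test_infeasible_constraint_flagged(self, founders12, arch50):
        preds, K = self._small_problem(founders12, arch50)
        res = u.optimize_plan(preds, K, u.CSISpec.ocs(), nc=2, constraint=0.9,
                              de=u.DEConfig(30, 30), rng=np.random.default_rng(5))
        assert not res.feasible and res.violation > 0
        ex = u.exhaustive_plan_search(preds, K, u.CSISpec.ocs(), nc=2, constraint=0.9)
        assert not ex.feasible

    def test_plan_sizes_validated(self, founders12, arch50):
        preds, K = self._small_problem(founders12, arch50, n_cand=3)
        with pytest.raises(ValueError):
            u.optimize_plan(preds, K, u.CSISpec.pm(), nc=10,
                            de=u.DEConfig(10, 5), rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="enumeration limit"):
            u.exhaustive_plan_search(preds, K, u.CSISpec.pm(), nc=2, max_plans=1)

    def test_uc_plans_carry_more_variance_than_pm(self, founders12, arch50):
        """Selecting on UC favors crosses with larger progeny SD than PM."""
        diffs = []
        for seed in range(20):
            preds, K = self._small_problem(founders12, arch50, n_cand=8, seed=seed)
            rng = np.random.default_rng(100 + seed)
            pm = u.optimize_plan(preds, None, u.CSISpec.pm(), nc=3,
                                 de=u.DEConfig(40, 40), rng=rng)
            uc = u.optimize_plan(preds, None, u.CSISpec.uc(2.06), nc=3,
                                 de=u.DEConfig(40, 40), rng=rng)
            diffs.append(preds["sigma_T"][uc.plan].mean()
                         - preds["sigma_T"][pm.plan].mean())
        assert np.mean(diffs) >= 0
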