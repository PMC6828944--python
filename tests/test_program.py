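"""Breeding-program orchestration, metrics and configuration."""

import dataclasses

import numpy as np
import pytest

import ucpcsel as u
from ucpcsel.program import within_family_select


class TestWithinFamilySelect:
    def test_five_percent_of_eighty_is_four(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=160)
        fam = np.repeat([0, 1], 80)
        flags = within_family_select(vals, fam, 0.05)
        assert flags[fam == 0].sum() == 4 and flags[fam == 1].sum() == 4
        top = np.argsort(-vals[:80])[:4]
        assert set(np.flatnonzero(flags[:80])) == set(top)

    def test_ties_broken_by_stable_order(self):
        flags = within_family_select(np.zeros(10), np.zeros(10), 0.3)
        assert np.array_equal(np.flatnonzero(flags), [0, 1, 2])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            within_family_select([np.nan, 1.0], [0, 0], 0.5)


class TestMetricOps:
    def test_genic_variance(self):
        assert u.genic_variance([0.5], [1.0]) == pytest.approx(1.0)
        assert u.genic_variance([1.0, 0.0], [2.0, 3.0]) == 0.0
        assert u.genic_variance([0.5, 0.5], [1.0, 1.0]) == pytest.approx(2.0)

    def test_expected_het(self):
        assert u.expected_het([0.5, 0.5]) == pytest.approx(0.5)
        assert u.expected_het([0.0, 1.0]) == 0.0
        p = np.array([0.1, 0.3, 0.7])
        assert u.expected_het(p) == pytest.approx(u.expected_het(1 - p))

    def test_count_fixed_lost(self):
        n_fixed, n_lost = u.count_fixed_lost([1.0, 0.0, 0.5], [0.2, 0.3, 0.4])
        assert (n_fixed, n_lost) == (1, 1)
        # favorable allele is the sign of beta: p=1 with beta<0 means lost
        assert u.count_fixed_lost([1.0], [-0.5]) == (0, 1)
        assert u.count_fixed_lost([0.0], [-0.5]) == (1, 0)

    def test_discounted_gain(self):
        g = np.full(60, 3.0)
        for rho in (0.0, 0.04, 0.2):
            assert u.discounted_gain(g, rho) == pytest.approx(3.0)
        series = np.arange(1, 61, dtype=float)
        assert u.discounted_gain(series, 0.0) == pytest.approx(series.mean())
        with pytest.raises(ValueError):
            u.discounted_gain([], 0.0)


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = u.ProgramConfig.scaled(csi="OCS", seed=42)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = u.ProgramConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg

    def test_unknown_keys_rejected(self, tmp_path):
        (tmp_path / "bad.yaml").write_text("n_founders: 10\nbogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            u.ProgramConfig.from_yaml(tmp_path / "bad.yaml")

    def test_invalid_combinations(self):
        with pytest.raises(ValueError):
            u.ProgramConfig(scenario="PS", csi="UCPC")
        with pytest.raises(ValueError):
            u.ProgramConfig(scenario="FOO")
        with pytest.raises(ValueError):
            u.ProgramConfig(csi="OHV")


class TestBurnIn:
    def test_structure_and_direction(self, mini_cfg):
        """Burn-in fills every cohort, loses diversity and gains performance."""
        dhe, dg = [], []
        for seed in range(3):
            cfg = mini_cfg(seed=seed)
            prog = u.BreedingProgram(cfg)
            prog.run_burn_in()
            assert len(prog.cohorts) == cfg.burnin_years
            last = prog.cohorts[cfg.burnin_years]
            assert last.n_progeny == cfg.n_crosses * cfg.n_prog
            he_f = u.expected_het((prog.founders.X[:, prog.arch.qtl_idx] == 1).mean(0))
            he_l = u.expected_het((last.X[:, prog.qtl_cols] == 1).mean(0))
            dhe.append(he_f - he_l)
            dg.append(last.tbv.mean() - prog.cohorts[1].tbv.mean())
        assert np.mean(dhe) > 0        # diversity declines under selection
        assert np.mean(dg) > 0         # phenotypic selection gains merit

    def test_candidate_pool_size_and_flags(self, mini_cfg):
        cfg = mini_cfg()
        prog = u.BreedingProgram(cfg)
        prog.run_burn_in()
        X, tb, ph, ge, src = prog.candidate_pool(cfg.burnin_years + 1)
        n_sel = cfg.n_selected_per_family
        assert X.shape[0] == n_sel * cfg.n_crosses * len(cfg.lags)
        for y, i in src:
            assert prog.cohorts[y].selected[i]

    def test_single_lag_pool(self, mini_cfg):
        cfg = mini_cfg(lags=(3,))
        prog = u.BreedingProgram(cfg)
        prog.run_burn_in()
        X = prog.candidate_pool(cfg.burnin_years + 1)[0]
        assert X.shape[0] == cfg.n_selected_per_family * cfg.n_crosses


class TestCampaign:
    def test_determinism(self, mini_cfg):
        cfg = mini_cfg(csi="UCPC", campaign_years=2, seed=5)
        m1 = u.run_campaign(cfg).metrics
        m2 = u.run_campaign(cfg).metrics
        assert m1.equals(m2)

    def test_metrics_invariants(self, mini_cfg):
        cfg = mini_cfg(csi="UC", campaign_years=3, seed=6)
        res = u.run_campaign(cfg)
        m = res.metrics
        assert m["year"].tolist() == [0, 1, 2, 3]
        assert m.loc[0, "G"] == 0.0
        assert (m["G10"] >= m["G"]).all()
        assert (m["He"] >= 0).all() and (m["sigma2_a"] >= 0).all()
        # gains match direct arithmetic on the stored cohorts
        prog = res.program
        c3 = prog.cohorts[cfg.burnin_years + 3]
        g3 = (c3.tbv.mean() - prog.mu0) / prog.sigmaA0
        assert m.loc[3, "G"] == pytest.approx(g3)
        g10 = (np.sort(c3.tbv)[-10:].mean() - prog.mu0) / prog.sigmaA0
        assert m.loc[3, "G10"] == pytest.approx(g10)

    def test_candidate_cross_count(self, mini_cfg):
        cfg = mini_cfg(csi="PM", campaign_years=1, seed=7)
        res = u.run_campaign(cfg)
        n_pool = res.plans[0]["n_pool"]
        assert res.plans[0]["n_candidate_crosses"] == n_pool * (n_pool - 1) // 2

    def test_constrained_plan_respects_prediction(self, mini_cfg):
        """Accepted UCPC plans honor the diversity constraint in prediction."""
        cfg = mini_cfg(csi="UCPC", campaign_years=3, he_star=0.05, seed=8)
        res = u.run_campaign(cfg)
        for p in res.plans:
            if p["feasible"]:
                assert p["D"] >= p["constraint"] - 1e-9

    def test_gs_scenario_runs_and_fits(self, mini_cfg):
        cfg = mini_cfg(scenario="GS", csi="UC", campaign_years=2, seed=9)
        res = u.run_campaign(cfg)
        prog = res.program
        assert prog._gs_fit is not None and 0 < prog._gs_fit.h2 < 1
        pool_gebv = prog.candidate_pool(cfg.burnin_years + 2)[3]
        assert np.isfinite(res.metrics.to_numpy()[:, 1:].astype(float)).all()

    def test_ps_scenario_runs(self, mini_cfg):
        cfg = mini_cfg(scenario="PS", csi="PM", campaign_years=2, seed=10)
        res = u.run_campaign(cfg)
        assert len(res.metrics) == 3
        assert res.metrics["G"].iloc[-1] > -5  # finite, sane
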