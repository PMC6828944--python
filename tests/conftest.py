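import numpy as np
import pytest

import ucpcsel as u


@pytest.fixture(scope="session")
def founders12():
    """Small founder pool: 12 lines, 3 chromosomes x 120 cM, 300 loci."""
    rng = np.random.default_rng(7)
    gmap = u.default_map(n_chrom=3, chrom_len_cm=120.0, n_loci=300)
    return u.generate_founders(12, gmap, rng, pool_size=30, n_generations=5)


@pytest.fixture(scope="session")
def arch50(founders12):
    rng = np.random.default_rng(8)
    return u.sample_qtls(founders12, m=50, rng=rng)


@pytest.fixture(scope="session")
def founders_scaled():
    """Scaled-profile founders: 40 lines on a 2,000-locus, 10-chromosome map."""
    rng = np.random.default_rng(11)
    gmap = u.default_map(n_chrom=10, chrom_len_cm=160.0, n_loci=2000)
    return u.generate_founders(40, gmap, rng, pool_size=100, n_generations=10)


def mini_config(**overrides):
    """Very small program profile for fast orchestration tests."""
    base = dict(
        n_map_loci=600, n_qtl=150, n_crosses=6, n_prog=20,
        n_burnin_parents=12, burnin_years=8, campaign_years=3,
        n_snp=200, train_cap=400, de_pop=40, de_iters=30, seed=0,
    )
    base.update(overrides)
    return u.ProgramConfig(**base)


@pytest.fixture()
def mini_cfg():
    return mini_config
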