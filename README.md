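# ucpcsel

**UCPC-based optimal cross selection and recurrent genomic-selection
breeding-program simulation for doubled-haploid crops.**

`ucpcsel` is for plant-breeding researchers and quantitative geneticists who
design crossing plans for inbred-line (doubled-haploid, DH) programs and want
to study how different cross-selection indices trade short-term genetic gain
against genetic diversity over decades of recurrent selection.

## The problem and the method

In a biparental DH program only a small selected fraction of each family
(typically the best 5%) becomes candidate parents of the next generation.
Classical optimal cross-selection scores a crossing plan *nc* of |nc| crosses
by the expected progeny mean V = **c′a** under a diversity constraint
D = 1 − **c′Kc** ≥ He(t), with **c** the parental contributions, **a** the
parental breeding values, **K** = ½(XX′/m + 1) the identity-by-state
coancestry of the ±1-coded parents, and He(t) a scheduled diversity
trajectory. This ignores within-family selection entirely.

`ucpcsel` implements the *usefulness criterion parental contribution* (UCPC)
treatment: for a cross P1 × P2 the progeny breeding value T and the P1 genome
contribution C1 are bivariate normal with moments computed under linkage from
the DH progeny genotype covariance

    Σ_jk = (1 − 2 r_jk) (x1_j − x2_j)(x1_k − x2_k) / 4,

where r_jk is the Haldane recombination fraction (r_jk = ½ across
chromosomes). With within-family selection intensity *i* (2.06 at 5%) and
accuracy *h*,

    UC^(i) = μ_T + i·h·σ_T,          σ_T² = β_T′ Σ β_T,
    c1^(i) = μ_C1 + i·σ_{T,C1}/σ_T,  σ_{T,C1} = β_T′ Σ β_C1,

so the plan's gain term becomes the mean UC of its crosses and the diversity
term uses the *post-selection* contributions c1^(i), c2^(i) in **c**. The
optimal plan under the ε-constraint formulation max V^(i) s.t. D^(i) ≥ He(t)
is found by an elitist differential-evolution search over sets of distinct
cross indices.

Around this core the package provides: Haldane-model meiosis and DH
simulation, synthetic elite founder pools with within-pool LD, additive QTL
architectures and phenotypes, IBS coancestry and diversity trajectories,
G-BLUP with profile-REML variance components and exactly back-solved marker
effects, and a breeding-program simulator with overlapping cohorts
(candidates of cohort T come from cohorts T−3, T−4, T−5) run under three
evaluation scenarios (known QTL effects, genomic selection on a noncausal SNP
panel, phenotypic selection).

## Worked example

Predict one cross, then run a scaled 20-year campaign with UCPC-based optimal
cross-selection targeting He* = 0.01 at year 60:

```python
import numpy as np
import ucpcsel as u

rng = np.random.default_rng(0)
founders = u.generate_founders(8, u.default_map(10, 160.0, 2000), rng)
arch = u.sample_qtls(founders, m=300, rng=rng)
Xq = founders.X[:, arch.qtl_idx]

regime = u.SelectionRegime(q=0.05)          # i = 2.06, h = 1
pred = u.predict_cross(Xq[0], Xq[1], arch.beta, arch.qtl_map(), regime)
print(f"mu_T = {pred.mu_T:.3f}   sigma_T = {pred.sigma_T:.3f}")
print(f"UC(5%) = {pred.uc:.3f}   c1 = {pred.c1:.3f}")
```

```
mu_T = 3.262   sigma_T = 2.318
UC(5%) = 8.043   c1 = 0.494
```

The cross's selected fraction is expected to average 8.04 trait units (versus
a progeny mean of 3.26), and selection barely distorts the parental
contributions (c1 ≈ 0.5) because trait and contribution are nearly
uncorrelated here.

```python
res = u.run_campaign(u.ProgramConfig.scaled(csi="UCPC", he_star=0.01, seed=0))
print(res.metrics.tail(3).round(3).to_string(index=False))
print("discounted gain (rho=0.04):", round(res.discounted(0.04), 3))
```

```
 year  sigma2_A  sigma2_a  ratio    He  n_fixed  n_lost     G    G10
   18     3.577     6.215  0.575 0.209      163      28 8.486  9.915
   19     2.932     5.743  0.510 0.203      172      29 8.674  9.928
   20     3.803     5.313  0.716 0.199      173      28 9.150 10.611
```

```
discounted gain (rho=0.04): 6.686
```

Per cohort the simulator reports the additive genetic variance σ²_A of the
1,600 (here 400) progeny TBVs, the genic variance σ²_a = Σ 4p(1−p)β², their
ratio (< 1 under directional selection: the Bulmer effect), the expected
heterozygosity He at QTLs, counts of QTLs with the favorable allele fixed or
lost, and the cumulative gains G (whole-progeny mean) and G10 (mean of the 10
best progeny) in units of the cohort-0 genetic standard deviation. Realized
He (0.199 at year 20) tracks the scheduled constraint He(20) ≈ 0.2.

A CLI mirrors the library: `ucpcsel simulate`, `ucpcsel predict-cross`,
`ucpcsel optimize`, `ucpcsel sim1` (see `--help`).

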