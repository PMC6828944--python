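# Methods

This note records the models implemented in `ucpcsel`, the defaults and why,
the numerical choices, and what the synthetic data do and do not emulate.

## Genome and meiosis

Loci live on a genetic map (chromosome, id, position in cM). Meiosis follows
the Haldane map function with no crossover interference: the gamete-origin
process is Markov along each chromosome, switching between the two parental
origins between adjacent loci with probability r = ½(1 − e^(−2d/100)) and
starting each chromosome at an independent 50/50 draw. Two consequences are
used throughout:

* restricting a simulation to any subset of loci (e.g. QTLs only) is exact,
  because the restriction of a Markov switch process is again Markov with the
  recombination fractions of the larger distances — campaigns therefore track
  genotypes only at the loci that matter (QTLs, plus the SNP panel in the GS
  scenario);
* the two-locus covariance algebra below holds with 1 − 2r_jk = e^(−0.02 d_jk).

All lines are fully homozygous DH material coded ±1, so a DH progeny equals
one recombinant gamete of the F1 and "doubling" is the identity in this
coding. Heterozygous parents, sex-specific maps and interference models are
out of scope.

## Synthetic founders

Real elite germplasm is not shipped; founders are synthetic. An ancestral
pool of 100 DH lines is drawn in linkage equilibrium with per-locus allele
frequencies ~ U(0.2, 0.8), then evolved through 10 generations of random
mating with DH extraction inside the closed pool of 100. Drift through this
bottleneck generates within-pool LD and a realistic elite-pool MAF spectrum;
founders are sampled from the final generation. Under the default map (10
chromosomes × 160 cM, 4,000 evenly spaced loci) the 40 founders comfortably
segregate at ≥ 1,500 loci with MAF ≥ 0.2, enough to place 1,000 QTLs at
MAF ≥ 0.2 with ≥ 0.2 cM spacing. The generator raises a descriptive error if
a configuration cannot host the requested QTL count.

This bottleneck-and-mate scheme was chosen over coalescent machinery because
the downstream experiments only need *some* realistic LD and frequency
spectrum — the burn-in (below) then produces the selection-structured LD that
actually matters. The synthetic pool is a stand-in, not a calibration: no
quantitative claim about any specific germplasm follows from it.

## Trait, phenotypes

The trait is purely additive: m QTLs (default 1,000) sampled from the
segregating founder loci (MAF ≥ 0.2, within-chromosome spacing ≥ 0.2 cM,
greedy acceptance over a shuffled eligible list — deterministic given the
seed), effects i.i.d. N(0, 0.05) with a random sign flip so the favorable
allele is +1 or −1 with probability ½. TBV = Xβ. Phenotypes add the mean of
n_env = 4 i.i.d. plot errors whose variance is calibrated so that
*single-plot* repeatability in the founders equals 0.4:
σ²_e = V_A,founders (1/0.4 − 1). "Repeatability" is interpreted per plot
(the conventional reading); the four-environment mean then has error
σ²_e/4. σ²_e is frozen at its founder calibration for the whole program
rather than recomputed per cohort.

## UCPC for two-way crosses

For cross P1 × P2, the DH progeny genotype covariance is
Σ_jk = (1 − 2r_jk)(x1_j − x2_j)(x1_k − x2_k)/4 (zero across chromosomes,
zero rows for loci monomorphic in the cross). Progeny mean and variance are
μ_T = ½(x1 + x2)′β and σ²_T = β′Σβ. P1's genome contribution is followed as
a normally distributed trait with IBS "effects" β_C1 = (x1 − x2)/((x1 −
x2)′(x1 − x2)) over polymorphic loci; since x1 + x2 = 0 at those loci,
μ_C1 = ½ exactly for every non-degenerate two-way cross. Truncation
selection of the top fraction q (intensity i = φ(Φ⁻¹(1−q))/q from the
infinite-population normal formula, accuracy h, default h = 1) gives

    UC^(i) = μ_T + i·h·σ_T,
    c1^(i) = μ_C1 + i·σ_{T,C1}/σ_T,  c2^(i) = 1 − c1^(i).

Numerical conventions: c1^(i) is clamped to [0, 1] (the normal approximation
can overshoot when trait and contribution are strongly correlated, and the
contribution enters downstream as a probability mass); identical parents, no
polymorphic loci, or σ_T = 0 fall back to UC = μ_T and c1 = ½.

The batch evaluator exploits Σ_jk = g_j g_k e^(−0.02 d_jk) with
g = (x1 − x2)/2 ∈ {−1, 0, 1}: all three quadratic forms reduce per
chromosome to products with one precomputed distance kernel shared across
all crosses of a pool, which is what makes the 28,680-cross annual
evaluation cheap. The batch path is verified element-wise against the
straightforward single-cross algebra, and both against Monte-Carlo moments
of 10⁵ simulated progeny.

## Crossing plans, diversity, optimization

A plan is a set of |nc| *distinct* crosses (default 20); a parent may appear
in several crosses (contributions and the diversity term regulate reuse; no
selfing). Contributions are c = (Z1c1 + Z2c2)/|nc| with c1 = c2 = ½ at
i = 0 and the post-selection values at i > 0. Gain is V = mean μ_T (i = 0)
or mean UC^(i); diversity is D = 1 − c′Kc with K = ½(XX′/m + 1). The
identity D = (1/m) Σ 2p_j(1−p_j), with p_j the contribution-weighted progeny
allele frequency, is exact for any c summing to one and is asserted to
1e−12 in the tests.

The scheduled constraint He(t) = He⁰ + (t/t*)^s (He* − He⁰) (linear s = 1 by
default, horizon t* = 60) uses He⁰ measured on cohort 0 at the scenario's
marker set unless configured explicitly. The ε-constraint problem
max V^(i) s.t. D^(i) ≥ He(t) is solved by differential evolution over
integer vectors of distinct cross indices: per iteration each solution is
mutated (gene-wise replacement probability 0.1), crossed uniformly with a
random partner (0.5 per gene), repaired (duplicate crosses redrawn) and
replaced one-for-one only if superior, so the incumbent never worsens.
Superiority is lexicographic — feasible beats infeasible, larger V among
feasible, smaller violation among infeasible — which avoids penalty-weight
tuning; if nothing feasible is found the least-violating plan is returned
and flagged. Operator rates are package choices (the underlying DE
literature leaves them open); population 7,170 × 1,000 iterations are the
full-scale defaults, 200 × 100 in the scaled profile. An exhaustive
enumerator under the same ordering serves as the optimizer's oracle on
small instances.

## G-BLUP (GS scenario)

y = 1μ + g + e with g ~ N(0, σ²_g G), G = M_cM_c′/k, markers centered at
observed training frequencies, k = Σ 4p(1−p). REML is a 1-D profile
likelihood in h²: after one eigendecomposition of G, a 99-point grid scan is
refined by bounded scalar minimization (xatol 1e−6). This is deliberately
not an AI-REML clone; one parameter, no convergence tuning. Marker effects
are back-solved through the shifted system β̂ = (σ²_g/k) M_c′(σ²_g G +
σ²_e I)⁻¹(y − μ̂), which is PD for h² < 1 and reproduces the training GEBVs
exactly (M_cβ̂ = ĝ). A standalone blended relationship (0.99G + 0.01I) is
available where an invertible G is needed on its own; the fit path does not
blend, precisely so the back-solving identity is exact.

Each campaign year the model is refit on all phenotyped progeny of the three
cohorts currently contributing candidates (selected and unselected sibs,
capped at 4,800 by random subsampling), and cohorts are flagged on predicted
GEBVs when they first enter a candidate pool.

## Program structure

Burn-in (20 years) mimics recurrent phenotypic selection: three initial
years of 20 random founder crosses initiate the overlapping-cohort
structure; thereafter the selected DH (top 5% per family, i.e. 4/80) of the
three available cohorts are pooled, the 50 with the best phenotypic means
are randomly mated into 20 distinct crosses of 80 DH each. The "three
available cohorts" reading mirrors the campaign's T−3/T−4/T−5 lag structure.
Campaign years replace random mating with the configured CSI (PM, UC,
OCS-He*, UCPC-He*) and scenario; the PS scenario runs PM on phenotypic
family means only. Reported per cohort: σ²_A (variance of progeny TBVs),
σ²_a = Σ 4p(1−p)β², their ratio (Bulmer effect), He at QTLs, favorable-allele
fixed/lost counts, G and G10 (progeny-mean and top-10-mean gains in units of
the cohort-0 genetic SD), and discounted cumulative gains Σ w_T G10(T) with
w_T ∝ (1+ρ)^(−T).

Ties in within-family selection break by stable individual order; all
randomness flows from the single generator seeded by the config, so runs are
bit-reproducible.

## Problem sizes

Full scale (defaults) is 40 founders, 1,000 QTLs on 4,000 loci, 20 × 80
progeny, 240-parent pools, 28,680 candidate crosses, DE 7,170 × 1,000, 60
campaign years. The scaled profile used by the test suite and the
reproduction script — a package choice documented here — is 500 QTLs on
2,000 loci, 10 × 40 progeny, 60-parent pools, a 1,000-SNP panel, DE
200 × 100 and 20 campaign years; the diversity-prediction experiment keeps
the full 300 sets × 20 crosses × 80 DH design. Directional campaign
comparisons at this size reproduce the qualitative ordering (UC > PM in
G10; UCPC-He* > OCS-He* early G10; realized He tracking He(t) within 0.05),
not the full-scale magnitudes.

## Known limitations

* The normal approximation behind UC and c1^(i) slightly overestimates
  post-selection diversity: genome-wide contributions stand in for per-QTL
  contributions, shrinking predicted extreme frequencies toward the mean.
  The experiment reproduces this signature (positive mean error that
  post-selection contributions reduce but do not eliminate).
* Single additive trait; no dominance, epistasis, G×E, multi-trait indices,
  hybrid/testcross extensions, or four-way crosses.
* IBS (not IBD) contributions and coancestry, per the two-way biallelic
  simplification.
* The synthetic founder pool emulates an elite pool's LD and MAF spectrum
  generically; passing tests say nothing about any particular real
  germplasm, and full-scale economic conclusions require full-scale runs.
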