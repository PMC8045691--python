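# Methods

## Genetic model

Breed groups are `D` (diploid *Ae. tauschii*, one subgenome), `T`
(tetraploid *T. turgidum*, two), `V` (hexaploid *T. aestivum*, three), `S`
(doubled D×T synthetic) and `SD` (synthetic derivatives from S×V and
successive backcrosses to V).  All polyploids here are allopolyploids:
subgenomes pair independently at meiosis, so each subgenome is treated as an
independent diploid and inbreeding is defined per subgenome.  The trait is
assumed to be controlled by many unlinked, purely additive loci.

Additive variances are defined on the ploidy scale, `σ²_Q = ploidy_Q ·
Var(α_Q)` for one allele effect α, so a non-inbred pure individual of breed
Q has genotypic variance `(1 + F) σ²_Q` and the doubled synthetic has
`(1+F_D) σ²_D + (1+F_T) σ²_T`.  Crossbred (SD) variance splits into
pure-breed parts weighted by the breed fractions `f_i` (parental averages,
with `f_D = f_T = 1` at the S node) and two segregation parts, `DV` and
`TV`, capturing the extra variance a segregating backcross shows over the
F1 when allele frequencies differ between the source populations.

### Partial relationship matrices

Each component matrix `A_Q` is built by the tabular method in topological
pedigree order.  Off-diagonals use the purebred recursion
`a_Q(i,j) = [a_Q(s,j) + a_Q(d,j)]/2` with unknown parents contributing
zero.  Diagonals: pure founders are 1 on their own component;
`a_Q(i,i) = f_i^Q + a_Q(s,d)/2` for Q ∈ {D,T,V}; segregation diagonals
`a_DV(i,i) = 2(f_s^D f_s^V + f_d^D f_d^V) + a_DV(s,d)/2` and the analogous
`4(·)` rule for TV.  Two deliberate generalisations of the standard
single-parent presentation:

* the segregation diagonal sums over **both** parents.  In the usual
  breeding scheme the second parent is pure V and the extra term is zero,
  so the symmetric form reduces exactly to the familiar one while removing
  any dependence on which parent is listed first;
* the segregation recursion carries `a_seg(s,d)/2` so the covariance
  recursion holds component-wise; it vanishes whenever the parents are
  unrelated, as in all the standard cross types.

A one-breed numerator matrix (labels ignored) is built alongside for the
homogeneous comparison model.

### The S-doubling question

Chromosome doubling makes the two homologs of an S line *identical copies*
of one gamete.  The breed-group variance rules nevertheless treat the S
diagonal like an ordinary inbred genotype, `a_D(S,S) = 1 + F_D` with `F_D`
from the standard recursion (hence 1 for non-inbred parents).  Taken
literally, doubling implies `a_D(S,S) = 2` and unhalved covariances through
the doubling step.  `build_partial_matrices(..., s_doubling="literal")`
implements that variant (S rows are the sum of the parent rows; S diagonals
2 on the two pure components).  The gene-dropping oracle (below) matches
the literal rule everywhere and the default "printed" rule on every pair
whose shared ancestry does not pass through an S doubling; the affected
pairs — an S line with itself, with its pure parents, and between
descendants that share an S ancestor — differ by a factor of 2 and are
reported both ways rather than reconciled.  The default remains the printed
rule, which is what the published variance tables are built on.

## The Bayesian mixed model

`y = Xb + Σ_Q Z_Q a_Q + Z_GE ge + e` with fixed location×cycle environment
effects b, breed-of-origin breeding values `a_Q ~ N(0, A_Q σ²_Q)` on each
component's support, iid genotype-by-environment effects and iid Gaussian
errors.  b keeps the intercept and **all** environment columns; the
resulting singularity is regularised by the proper prior `b ~ N(0, K)`,
K diagonal with entries 1e8 (> 1e7), rather than by dropping a column.
Every variance has a scaled inverse chi-square prior; defaults use ν = 5
and a scale S² chosen so the prior mode ν S²/(ν+2) equals an equal share of
the phenotypic variance across all variance components (the historical
analysis delegated this to its fitting package's internal defaults, which
are not fully reconstructable; priors are user-overridable).  Chain
defaults are 10,000 burn-in plus 10,000 retained draws, thin 1.

### Sampler

All full conditionals are conjugate.  Effects are updated in blocks, and
the genetic blocks are drawn **jointly** each iteration: the likelihood
involves them only through the total genetic value `u = Σ_Q a_Q` of each
phenotyped genotype, so the sampler first draws u from its Gaussian
conditional under the collapsed prior `u ~ N(0, G)`, `G = Σ_Q σ²_Q A_Q`
(via Matheron's conditioning rule: a prior draw corrected by the kriging
regression), then decomposes u into the component effects from their
conditional distribution given u.  This matters because the SAWYT-type
crossing grammar makes some components nearly or exactly collinear on the
phenotyped genotypes (see "Identifiability" below); a one-block-per-term
sampler then mixes extremely slowly (effective sample sizes of ~5–40 per
2,000 iterations for D and T), while the joint draw resolves the trade-off
within each iteration.

Unphenotyped relatives (founders, intermediate crosses) are integrated out
of the likelihood — the marginal of `N(0, A_Q σ²_Q)` on the phenotyped
subset is `N(0, A_phen σ²_Q)` — which leaves every variance posterior
unchanged while shrinking the per-iteration linear algebra to the
phenotyped dimension.  Their breeding values are recovered afterwards as
exact MVN conditional means, `â_anc = A_anc,phen A_phen⁻¹ â_phen`, a
regression that does not depend on the variance scale.  Variance updates
are the standard scaled inverse chi-square conditionals, e.g.
`σ²_Q | · ~ ScInvχ²(ν + q_Q, (a'A⁻¹a + νS²)/(ν + q_Q))`.

Numerical choices: matrices restricted to their support are Cholesky
factorised; if factorisation fails a ridge of `1e-8 · mean(diag)` is added
with a logged warning.  A variance draw that is non-finite or exceeds 1e14
aborts the chain with diagnostics.  Chains are reproducible given the seed
(one `numpy` Generator, fixed draw order).  HPD95 intervals are the
shortest empirical interval containing 95 % of draws (cross-checked against
arviz in the tests); effective sample sizes are reported via arviz.

### Identifiability of the segregation components

In the standard crossing grammar every derivative has `f_D = f_T`, which
makes `A_TV = 2 A_DV` **exactly** on the phenotyped genotypes: the
likelihood identifies only the combination `σ²_DV + 2 σ²_TV`, and the split
between the two segregation variances is driven by their priors.  (The
historical estimates show the same signature: their DV:TV posterior-mean
ratio mirrors the 1:2 ratio of their prior scales.)  The sampler handles
the degeneracy exactly; users should interpret the individual DV and TV
posteriors with this in mind.  Separating them would require crosses in
which the D and T fractions differ, e.g. backcrosses to T. 

## Derived summaries

Group variances evaluate the Table-style rules for a canonical non-inbred
representative of each cross type with unrelated parents (F1, BC1, BC2,
BC3).  Narrow-sense heritability is computed on the **plot basis**,
`σ²_A/(σ²_A + σ²_GE + σ²_e)`: that reading reproduces the published
per-group values (0.47/0.52/0.44/0.35; one-breed 0.13), whereas the
replication divisors `yl = n_GYL/n_G` and `b = n/n_GYL` enter only the
line-mean repeatability `σ²_A/(σ²_A + σ²_GE/yl + σ²_e/(yl·b))`.  BLUP
columns are compared by Pearson correlation on the shared genotype set.

## Synthetic data

`SimScheme` defaults mirror the published trial database: 10 D, 21 T,
105 V founders, 16 synthetics and (12, 45, 24, 7) crosses at the
F1/BC1/BC2/BC3 levels (152 parents + 88 crosses), over 5 locations ×
4 cycles with 2 replicates.  Deeper crosses reuse randomly chosen shallower
crosses as parents, reproducing the sharing of synthetics across lines.
Phenotypes are drawn from the model itself: environment means from
N(4, 1) t/ha (the scale of semi-arid yield trials), breeding values from
`N(0, A_Q σ²_Q)` on the full supports, iid G×E and errors.  An
`env_presence` parameter can thin genotype×environment cells; the default
is complete presence, which is milder than the severe temporal
discontinuity of the real trial network — parameter-recovery results here
therefore say nothing about confounding caused by real-world
disconnectedness, only about the model's internal consistency.

The gene-dropping oracle samples founder alleles at unlinked biallelic loci
from breed-specific frequencies (a shared base frequency plus per-breed
deviations scaled by a `divergence` knob; divergence 0 removes all
segregation variance), transmits them by independent meiosis per subgenome,
doubles literally at S nodes and accumulates empirical covariances of
genotypic values.  Its analytic counterparts are
`σ²_B = ploidy_B Σ e² p_B(1−p_B)` and
`σ²_BV = ½ Σ e² (p_B − p_V)²` for B ∈ {D, T}.

## Problem sizes used in the checks

The closed-form variance-table regeneration runs on the 11-individual
canonical chain in well under a second.  The oracle check uses an
11-individual pedigree (two F1 lines sharing one synthetic, two further
backcrosses), 12 loci and 10⁶ replicates, comparing every pair at 3
Monte-Carlo standard errors.  The recovery experiment simulates 20
replicates of 300 crosses × 20 environments × 2 replicates (12,000 records)
and fits 2,000-iteration chains with 500 burn-in; aggregate HPD95 coverage
of the seven true components across the 140 intervals is required to reach
90 %.  Per-component coverage is near nominal except TV (~80 %), the direct
consequence of the prior-driven DV/TV split discussed above.

## Known limitations

* No dominance or epistasis; no marker data; relationship matrices are
  pedigree-based only.
* G×E is iid; no factor-analytic or multi-trait structure.
* Residual variance is homogeneous across environments.
* Non-founders must have both parents known; single-known-parent records
  are rejected rather than guessed.
* REML is not provided; estimation is MCMC only.
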