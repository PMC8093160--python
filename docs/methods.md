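# Methods

`pgsnurture` studies how much of a trait's parent–offspring resemblance is
environmental (vertical transmission, VT) versus genetic, using the
information carried by transmitted and nontransmitted polygenic scores in
parent–offspring trios. It has three layers: a forward-time generative
simulator, a deterministic moment recursion that yields model-implied
covariances, and maximum-likelihood fitting of seven causal models plus a
Monte Carlo harness. This note records the model, the conventions, and
the design decisions a maintainer would need.

## The generative model

Each individual carries two haplotypes over `m` unlinked causal variants
(CVs), half contributing to a measured polygenic score (PGS) and half to
a latent genetic score (LGS) that is orthogonal to the PGS in the base
population. The phenotype is

    Y = delta*(s_P + s_M) + a*(l_P + l_M) + F + eps,

with `s`/`l` the haplotypic PGS/LGS, `F = f*Y_father + f*Y_mother` the
familial score produced by VT, and `eps` residual environment. Primary
phenotypic assortative mating (AM) is parameterized by a copath
coefficient `mu` on the covariance scale: mate phenotypic covariance is
`mu*V_Y^2`, and for any father-trait A and mother-trait B,
`cov(A,B) = mu*cov(A,Y)*cov(B,Y)`. The mate correlation is `mu*V_Y`.

In the simulator the truth scale has `delta = a = 1`: allele frequencies
are iid U(.1,.5), raw effects are N(0, h2_t0/(2 m p (1-p))), and scaling
coefficients are frozen in the base generation so that *empirically*
var(Y)=1 exactly, var(PGS)=r2_pgs_t0 and var(LGS)=h2_t0-r2_pgs_t0 exactly
(the environmental score is residualized on the genetic score and scaled
to the exact remainder; its variance therefore equals 1-h2_t0 up to the
empirical PGS–LGS covariance it absorbs). Every later generation reuses
those scalings, so variances inflate above base values as VT and AM act.

Mates are paired by splitting each generation randomly into two pools
(no sex effects), giving pool A a latent score `r*z(Y) + sqrt(1-r^2)*eta`
and pairing the pools by rank; realized mate correlations target
`r_mate` up to Monte Carlo error, and because pairing depends on
phenotype alone the cross-mate covariances follow the copath rule. Each
couple has exactly two offspring (constant population size `2*n_fam`);
gametes form by choosing one parental allele per CV independently (free
recombination, valid for unlinked CVs). Trio extraction takes every
couple once with one randomly chosen offspring, so no siblings appear.

The nontransmitted haplotypic score is computed as the parental diploid
PGS minus the transmitted score. At the allele level the partition is
exact; on the score scale the identity `T + NT = diploid` holds to
machine precision (last-ulp float grouping aside), which is what the
partition tests assert.

## The moment recursion

All second moments of a generation follow deterministically from the
parents' moments. The state is nine numbers: cis (within-haplotype,
cross-locus) covariances `g, h, i` for PGS/LGS/cross; their within-person
cross-haplotype counterparts `g_x, h_x, i_x`; per-haplotype nurture
covariances `w = cov(s,F)` and `v = cov(l,F)`; and `V_F = var(F)`. One
generation maps

    g'   = (g + g_x)/2          g_x' = mu * cov(s,Y)^2
    h'   = (h + h_x)/2          h_x' = mu * cov(l,Y)^2
    i'   = (i + i_x)/2          i_x' = mu * cov(s,Y) * cov(l,Y)
    w'   = f * (1 + mu*V_Y) * cov(s,Y)
    v'   = f * (1 + mu*V_Y) * cov(l,Y)
    V_F' = 2 f^2 (V_Y + mu*V_Y^2)

with `cov(s,Y) = delta*(v_t+g+g_x) + a*(i+i_x) + w` and the analogous
`cov(l,Y)`; `v_t` is the base haplotypic score variance and V_Y is
assembled from the state. The halving rule is free recombination: a
gamete's cis covariance averages the parental cis and cross-haplotype
values, while mating refreshes the cross-haplotype ("trans") terms
through the copath. At the fixed point cis equals trans, the equilibrium
signature of AM. One iteration from a parental state gives the
disequilibrium expectations.

The recursion is infinitesimal in one respect: the same-locus component
of the between-haplotype covariance (an O(1/m) share of the total) is
lumped with the cross-locus part. At m=100 the resulting error in implied
covariances is roughly 50-fold below the Monte Carlo resolution of a
200K-family simulation, as the oracle-equivalence test confirms.

Observable moments follow by path tracing; notably
`theta_T - theta_NT = 2*delta*v_t` exactly — the cis terms cancel because
cov(T, NT) carries the same cis inflation as var(T) — so the contrast
isolates the direct PGS effect in every regime.

## The seven models and their regimes

All models are covariance-structure ML models for the observed vector
(T_p, NT_p, T_m, NT_m, Y_o) plus, for Models 2e/2d, (Y_p, Y_m). Free
parameters are `delta, f, v_eps, v_t` everywhere; `mu` is added by every
AM-aware model and `a` by Models 2e/2d. Models 0/1e/1d assume the PGS
captures all genetic variance (`a = 0`); Models 2e-NP/2d-NP replace the
parental phenotypes with an assumed base-population heritability, from
which `a` is derived: with base variance `V_Y0 = v_eps/(1-h2)`, the
latent effect supplies `h2*V_Y0` minus the PGS share (clipped at zero).

Regimes map onto the recursion as follows:

* Model 0: fixed point with `mu = 0` (VT at equilibrium, random mating).
* Equilibrium models (1e, 2e, 2e-NP): fixed point with the model's `mu`.
* Disequilibrium models (1d, 2d, 2d-NP): the `mu = 0` fixed point as the
  parental generation, then a single assortative mating.

Treating VT as equilibrated while AM is the disequilibrium process is a
deliberate design choice, and the simulator's disequilibrium condition
matches it (`vt_burnin=19, generations=1`: random-mating VT burn-in,
then one assortative generation). The rationale: V_F reaches its
equilibrium relation after a single generation whereas AM's consequences
take several, so "one generation of AM" is the natural disequilibrium
scenario for a trait whose VT has been operating all along; it is also
the only structure under which the no-AM condition leaves all seven
models simultaneously well-specified, which the unbiasedness results
require.

### Scale conventions

The latent haplotypic LGS base variance is tied to the PGS's `v_t`, with
`a` carrying its effect. Under this convention the identification
constraint `w/delta = v/a` (equal nurture-to-direct-effect ratio for
observed and latent scores) holds automatically at every fixed point and
after one assortative step, so no explicit nonlinear constraint is
needed in the optimizer. `w = cov(s, F)` is on the observed score scale
(`theta_NT = 2w` with no AM, the convention of the nontransmitted-allele
literature); `v = cov(l, F)` is on the latent scale implied by the tie,
and the generative truth for `v` is accordingly the simulator's
`cov(LGS_hap, F)` divided by the true `a`.

`v_t` is profiled as a free auxiliary parameter in every fit: observed
var(T) equals `v_t` plus the AM-induced cis covariance, so it cannot be
fixed from data a priori without already knowing `mu`.

## Estimation

The discrepancy is the Wishart ML fit function
`(n-1)[ln det Sigma + tr(S Sigma^-1) - ln det S - p]` on the unbiased
sample covariance — equivalent to full-information normal ML with
saturated means. Optimization is L-BFGS-B (bounded: `f >= 0` to resolve
the VT reflection, variances `>= 0`, `|mu|` capped with an admissibility
guard that rejects implied mate correlations of 1 or more) from a
moment-based start plus jittered restarts, followed by a Nelder-Mead
polish that also serves as the convergence criterion; infeasible starts
(explosive VT/AM feedback) are repaired by shrinking `f`, `mu`, `v_eps`.
Parameter points where the recursion diverges receive a large penalty.
Standard errors come from the inverse central-finite-difference Hessian
of half the fit function, propagated to derived quantities (V_F, w, v,
V_PGS, V_LGS, thetas) by a finite-difference delta method. Standardized
estimates divide variance-scale quantities by the fitted V_Y, report
`mu*V_Y` (the implied mate correlation) for `mu`, and rescale the paths
`delta, a` by `sqrt(v_t/V_Y)`; `f`, a phenotype-to-phenotype path, is
unchanged.

Equilibrium solving uses plain fixed-point iteration (tolerance 1e-10 on
the maximum absolute moment change, 200 iterations maximum; convergence
is geometric at rate ~max(1/2, f, mate correlation) so 30–60 iterations
are typical). Non-convergence raises an error carrying the last state;
inside fitting it is flagged, never raised.

## Monte Carlo harness

Replicate seeds derive from the root seed via `SeedSequence(root,
spawn_key=(cell, replicate))`, so results are byte-identical regardless
of worker count (joblib parallelism is optional and off by default).
Summaries report mean, bias, quartiles and 2.5%/97.5% quantiles per
parameter; the empirical standard error is the root-mean-square
deviation of standardized estimates about the true standardized value
(an RMSE about truth, not a dispersion about the mean). Non-converged
replicates are excluded from summaries with a reported count; in the
shipped test designs convergence is complete.

Generative truths come from running the recursion exactly as the
simulator does: the simulator targets a constant mate *correlation*, so
the truth recursion applies a per-generation copath `mu_t = r_mate /
V_Y(t)`; the reported true `mu` is the final-mating value, which at
equilibrium is `r_mate / V_Y*`.

## Problem sizes and what the tests show

The full study design (1K replicates, samples up to 64K families) is
summarized at desk scale in the test suite: bias cells run 200
replicates at 4K families, precision cells 100 replicates at 8K and 16K,
and the oracle-equivalence check one 200K-family simulation per AM
regime, with Monte Carlo tolerance bands sized accordingly (3 MC SEs for
bias means, 4 for covariance entries). These sizes were chosen so the
entire suite completes on a single CPU while leaving the tested claims
at the same Monte Carlo resolution the full-scale design would give.

Two caveats delimit what passing tests show. First, maximum-likelihood
point estimates of the nonlinear derived quantities carry O(1/n)
finite-sample (Jensen-type) bias — at 4K families about +3% on V̂_F and
−3% on v̂, halving by 8K and a quarter by 16K, with the optimizer
verified to sit at the global optimum and the truth verified against a
mega-simulation. A fixed-seed 3-MC-SE unbiasedness check on those two
quantities at 200×4K is therefore near its detection edge; "unbiased"
throughout means consistent, with vanishing relative bias at study-scale
samples. Second, the simulator realizes the same structural assumptions
as the models (primary phenotypic AM via rank matching, equal maternal
and paternal VT paths, purely additive unlinked CVs, no shared
environment beyond F); passing tests validate the estimators under this
generative family, not robustness to realistic linkage disequilibrium,
GWAS-estimated weights, or other mating/transmission mechanisms. For
unequal parental VT paths the expected estimation deficit
`(f_p-f_m)^2/2*(V_Y+V_Y^2*mu)` is provided as a closed form
(`predicted_vf_underestimate`); the simulator supports `f_p != f_m` but
the truth recursion intentionally does not.

## Known limitations

* No linkage disequilibrium, genotyping error, or GWAS-based score
  construction; CVs are the score.
* No sibling/twin structures, no bivariate traits, no missing-data FIML
  (incomplete rows are dropped), no shared-environment component.
* Social/genetic homogamy, gene-age interaction, dominance and epistasis
  are outside the generative family and the model set.
* The Hessian standard errors assume an interior optimum; boundary hits
  are flagged and the SEs then deserve suspicion.
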