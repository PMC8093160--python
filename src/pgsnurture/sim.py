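"""Forward-time polygenic trio simulator with VT and assortative mating.

The generative process: ``m`` unlinked causal variants (CVs) in linkage
equilibrium in the base population, half contributing to a measured
polygenic score (PGS) and half to a latent genetic score (LGS); scaling
coefficients frozen in the base generation so that the base phenotypic
variance is exactly 1 with var(PGS) = r2_pgs_t0 and var(LGS) =
h2_t0 - r2_pgs_t0; thereafter, per generation: phenotypic mate matching to
a target correlation, free recombination of the unlinked CVs into
transmitted/nontransmitted gametes, two offspring per couple (constant
population size), vertical transmission F = f_p*Y_father + f_m*Y_mother,
fresh environmental noise, and phenotype assembly on the frozen scale —
so variances may inflate above their base values as AM and VT act.

An optional random-mating burn-in (``vt_burnin``) lets VT reach its
equilibrium before assortative mating begins; the disequilibrium-AM study
condition (a single generation of AM acting on a population whose VT is
already equilibrated) is ``vt_burnin=19, generations=1``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "CausalVariantSet",
    "Population",
    "draw_causal_variants",
    "init_base_population",
    "select_mates",
    "produce_offspring",
    "evolve",
    "extract_trios",
    "simulate_trios",
    "TRIO_COLUMNS",
]

TRIO_COLUMNS = ["fam_id", "T_p", "NT_p", "T_m", "NT_m", "Y_o", "Y_p", "Y_m"]


@dataclass(frozen=True)
class SimConfig:
    """All generative parameters of one simulation scenario.

    Defaults are the central study condition: h2_t0 = .5, r2_pgs_t0 = .05,
    V_F_t0 = .15, r_mate = .25, m = 100 CVs, 16K trio families, 20
    generations of assortative mating, no burn-in.
    """

    h2_t0: float = 0.5
    r2_pgs_t0: float = 0.05
    vf_t0: float = 0.15
    r_mate: float = 0.25
    m: int = 100
    n_fam: int = 16000
    generations: int = 20
    vt_burnin: int = 0
    f_p: Optional[float] = None
    f_m: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.r2_pgs_t0 <= self.h2_t0 <= 1.0):
            raise ValueError("need 0 <= r2_pgs_t0 <= h2_t0 <= 1")
        if self.vf_t0 < 0:
            raise ValueError("vf_t0 must be non-negative")
        default_f = float(np.sqrt(self.vf_t0 / 2.0))
        if self.f_p is None:
            object.__setattr__(self, "f_p", default_f)
        if self.f_m is None:
            object.__setattr__(self, "f_m", default_f)
        if abs(self.r_mate) >= 1:
            raise ValueError("|r_mate| must be < 1")
        if self.m < 2 or self.m % 2:
            raise ValueError("m must be an even integer >= 2")
        if self.n_fam < 1:
            raise ValueError("n_fam must be >= 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.vt_burnin < 0:
            raise ValueError("vt_burnin must be >= 0")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class CausalVariantSet:
    """Causal variants plus the scaling constants frozen at base.

    ``alpha_pgs``/``alpha_lgs`` are the scaled per-allele effects (zero on
    the loci of the other score); ``center_*`` are per-haplotype centering
    constants and ``sd_eps`` the frozen environmental standard deviation.
    """

    p: np.ndarray
    beta: np.ndarray
    is_pgs: np.ndarray
    alpha_pgs: np.ndarray
    alpha_lgs: np.ndarray
    center_pgs: float  # subtracted from each *haplotypic* PGS
    center_lgs: float
    sd_eps: float


@dataclass
class Population:
    """One generation: haplotypes, haplotypic scores and phenotypes.

    ``hap_pgs[i, k]`` is the haplotypic PGS of person ``i``'s haplotype
    ``k`` (k=0 paternal-origin, k=1 maternal-origin); the diploid score is
    the sum of the two.  ``father``/``mother`` index into the previous
    generation (None in the base generation).
    """

    haps: np.ndarray  # (n, 2, m) uint8
    hap_pgs: np.ndarray  # (n, 2)
    hap_lgs: np.ndarray  # (n, 2)
    F: np.ndarray
    eps: np.ndarray
    Y: np.ndarray
    father: Optional[np.ndarray] = None
    mother: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.haps.shape[0]

    @property
    def dip_pgs(self) -> np.ndarray:
        return self.hap_pgs[:, 0] + self.hap_pgs[:, 1]

    @property
    def dip_lgs(self) -> np.ndarray:
        return self.hap_lgs[:, 0] + self.hap_lgs[:, 1]


def draw_causal_variants(config: SimConfig, rng: np.random.Generator,
                         _defer_scaling: bool = False) -> CausalVariantSet:
    """Draw allele frequencies and raw effect sizes for ``m`` CVs.

    Frequencies are iid U(.1, .5); raw effects are N(0, h2/(2*m*p*(1-p)));
    the first m/2 CVs form the PGS, the rest the LGS (frequencies are iid,
    so the deterministic split is exchangeable with a random one).
    Scaling constants are placeholders until :func:`init_base_population`
    freezes them from empirical base-generation moments.
    """
    m = config.m
    if m < 2 or m % 2:
        raise ValueError("m must be an even integer >= 2")
    p = rng.uniform(0.1, 0.5, size=m)
    beta = rng.normal(0.0, np.sqrt(config.h2_t0 / (2.0 * m * p * (1.0 - p))))
    is_pgs = np.zeros(m, dtype=bool)
    is_pgs[: m // 2] = True
    return CausalVariantSet(
        p=p, beta=beta, is_pgs=is_pgs,
        alpha_pgs=np.where(is_pgs, beta, 0.0),
        alpha_lgs=np.where(is_pgs, 0.0, beta),
        center_pgs=0.0, center_lgs=0.0, sd_eps=float(np.sqrt(1 - config.h2_t0)),
    )


def _pop_var(x: np.ndarray) -> float:
    return float(np.var(x))


def init_base_population(
    cvs: CausalVariantSet, config: SimConfig, n_pop: int,
    rng: np.random.Generator,
) -> tuple[Population, CausalVariantSet]:
    """Base generation in linkage equilibrium, with scalings frozen so the
    empirical phenotypic variance is exactly 1.

    Haplotype alleles are independent Bernoulli(p_j).  The PGS and LGS are
    rescaled (and centered) to empirical variances r2_pgs_t0 and
    h2_t0 - r2_pgs_t0 exactly; the environmental score is residualized on
    the genetic score and scaled to the exact remainder, so var(Y) = 1 to
    machine precision.  The returned variant set carries the frozen
    scaling constants used for every later generation.
    """
    if n_pop % 2 or n_pop < 2 * config.n_fam:
        raise ValueError("n_pop must be even and at least 2*n_fam")
    m = config.m
    haps = (rng.random((n_pop, 2, m)) < cvs.p).astype(np.uint8)
    alpha = np.stack([cvs.alpha_pgs, cvs.alpha_lgs], axis=1)  # (m, 2)
    raw = (haps.reshape(-1, m) @ alpha).reshape(n_pop, 2, 2)
    raw_pgs = raw[:, :, 0]  # (n, 2)
    raw_lgs = raw[:, :, 1]
    dip_raw_pgs = raw_pgs.sum(axis=1)
    dip_raw_lgs = raw_lgs.sum(axis=1)
    c_pgs = float(np.sqrt(config.r2_pgs_t0 / _pop_var(dip_raw_pgs)))
    v_lgs_target = config.h2_t0 - config.r2_pgs_t0
    c_lgs = (
        float(np.sqrt(v_lgs_target / _pop_var(dip_raw_lgs)))
        if v_lgs_target > 0 else 0.0
    )
    alpha_pgs = cvs.alpha_pgs * c_pgs
    alpha_lgs = cvs.alpha_lgs * c_lgs
    center_pgs = float(np.mean(dip_raw_pgs) * c_pgs) / 2.0
    center_lgs = float(np.mean(dip_raw_lgs) * c_lgs) / 2.0
    hap_pgs = raw_pgs * c_pgs - center_pgs
    hap_lgs = raw_lgs * c_lgs - center_lgs
    G = hap_pgs.sum(axis=1) + hap_lgs.sum(axis=1)
    var_g = _pop_var(G)
    if var_g >= 1.0:
        raise ValueError("base genetic variance reached 1; cannot scale eps")
    eps_raw = rng.normal(size=n_pop)
    eps_raw -= eps_raw.mean() + (np.cov(eps_raw, G, ddof=0)[0, 1] / var_g) * G
    sd_eps = float(np.sqrt(1.0 - var_g))
    eps = eps_raw * (sd_eps / np.sqrt(_pop_var(eps_raw)))
    F = np.zeros(n_pop)
    Y = G + F + eps
    cvs_frozen = dataclasses.replace(
        cvs, alpha_pgs=alpha_pgs, alpha_lgs=alpha_lgs,
        center_pgs=center_pgs, center_lgs=center_lgs, sd_eps=sd_eps,
    )
    pop = Population(haps=haps, hap_pgs=hap_pgs, hap_lgs=hap_lgs,
                     F=F, eps=eps, Y=Y)
    return pop, cvs_frozen


def select_mates(
    pop: Population, r_mate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pair every individual with exactly one mate, targeting a phenotypic
    correlation ``r_mate`` between mates.

    The population is split randomly into two equal pools (no sex effects
    are modeled).  Pool A receives a latent matching score
    r*z(Y) + sqrt(1-r^2)*noise; both pools are sorted (A by the latent
    score, B by phenotype) and paired by rank, a standard construction
    whose realized correlation is r_mate up to Monte Carlo error and whose
    cross-mate covariances follow the copath rule.
    """
    if abs(r_mate) >= 1:
        raise ValueError("|r_mate| must be < 1")
    n = pop.n
    if n % 2:
        raise ValueError("population size must be even")
    perm = rng.permutation(n)
    pool_a, pool_b = perm[: n // 2], perm[n // 2:]
    y_a = pop.Y[pool_a]
    z = (y_a - y_a.mean()) / y_a.std()
    latent = r_mate * z + np.sqrt(1.0 - r_mate**2) * rng.normal(size=n // 2)
    fathers = pool_a[np.argsort(latent, kind="stable")]
    mothers = pool_b[np.argsort(pop.Y[pool_b], kind="stable")]
    return fathers, mothers


def produce_offspring(
    pop: Population,
    couples: tuple[np.ndarray, np.ndarray],
    cvs: CausalVariantSet,
    config: SimConfig,
    rng: np.random.Generator,
) -> Population:
    """Two offspring per couple via free recombination of unlinked CVs.

    For each offspring and each parent, one of the parent's two alleles is
    chosen independently per CV (valid free recombination because CVs are
    unlinked); the chosen alleles form the transmitted gamete.  Offspring
    F = f_p*Y_father + f_m*Y_mother; fresh environmental noise uses the
    frozen base-generation scale.
    """
    fathers, mothers = couples
    n_c = len(fathers)
    f_idx = np.repeat(fathers, 2)
    m_idx = np.repeat(mothers, 2)
    n_off = 2 * n_c
    m = config.m
    n_bytes = (m + 7) // 8
    haps = np.empty((n_off, 2, m), dtype=np.uint8)
    for k, parent_idx in ((0, f_idx), (1, m_idx)):
        parent_haps = pop.haps[parent_idx]  # (n_off, 2, m)
        # fair coin per CV, drawn as packed random bits (cheap at scale);
        # pick==1 selects the parent's first haplotype via the xor identity
        pick = np.unpackbits(
            rng.integers(0, 256, size=(n_off, n_bytes), dtype=np.uint8),
            axis=1,
        )[:, :m]
        diff = parent_haps[:, 0, :] ^ parent_haps[:, 1, :]
        haps[:, k, :] = parent_haps[:, 1, :] ^ (diff & pick)
    alpha = np.stack([cvs.alpha_pgs, cvs.alpha_lgs], axis=1)  # (m, 2)
    scores = (haps.reshape(-1, m).astype(np.float64) @ alpha)
    hap_pgs = scores[:, 0].reshape(n_off, 2) - cvs.center_pgs
    hap_lgs = scores[:, 1].reshape(n_off, 2) - cvs.center_lgs
    F = config.f_p * pop.Y[f_idx] + config.f_m * pop.Y[m_idx]
    eps = rng.normal(0.0, cvs.sd_eps, size=n_off)
    Y = hap_pgs.sum(axis=1) + hap_lgs.sum(axis=1) + F + eps
    return Population(haps=haps, hap_pgs=hap_pgs, hap_lgs=hap_lgs,
                      F=F, eps=eps, Y=Y, father=f_idx, mother=m_idx)


def evolve(
    config: SimConfig,
) -> tuple[Population, Population, CausalVariantSet]:
    """Run the full forward simulation.

    Base population of 2*n_fam individuals, then ``vt_burnin`` random-
    mating generations followed by ``generations`` assortative ones (all
    with VT).  Returns the penultimate (parental) and final (offspring)
    generations with pedigree links, plus the frozen causal variants.
    Fully reproducible from ``config.seed`` via named child streams.
    """
    ss = np.random.SeedSequence(config.seed)
    keys = ss.spawn(3)
    rng_cv, rng_base, rng_gen = (np.random.default_rng(k) for k in keys)
    cvs = draw_causal_variants(config, rng_cv)
    pop, cvs = init_base_population(cvs, config, 2 * config.n_fam, rng_base)
    total = config.vt_burnin + config.generations
    parents = pop
    for gen in range(total):
        r = 0.0 if gen < config.vt_burnin else config.r_mate
        couples = select_mates(pop, r, rng_gen)
        parents = pop
        pop = produce_offspring(pop, couples, cvs, config, rng_gen)
    return parents, pop, cvs


def extract_trios(
    parents: Population,
    offspring: Population,
    n_fam: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Trio table with one randomly chosen offspring per couple.

    Haplotypic transmitted scores come straight from the offspring's two
    haplotypes; the nontransmitted score is the parent's diploid PGS minus
    the transmitted one (the allele-partition identity, exact by
    construction).  No siblings appear in the output.
    """
    if offspring.father is None:
        raise ValueError("offspring population lacks pedigree links")
    n_couples = offspring.n // 2
    if n_fam > n_couples:
        raise ValueError(f"requested {n_fam} families but only "
                         f"{n_couples} couples exist")
    couple_ids = (np.arange(n_couples) if n_fam == n_couples
                  else rng.choice(n_couples, size=n_fam, replace=False))
    child = 2 * couple_ids + rng.integers(0, 2, size=n_fam)
    f_idx = offspring.father[child]
    m_idx = offspring.mother[child]
    t_p = offspring.hap_pgs[child, 0]
    t_m = offspring.hap_pgs[child, 1]
    nt_p = parents.dip_pgs[f_idx] - t_p
    nt_m = parents.dip_pgs[m_idx] - t_m
    return pd.DataFrame({
        "fam_id": np.arange(n_fam),
        "T_p": t_p, "NT_p": nt_p, "T_m": t_m, "NT_m": nt_m,
        "Y_o": offspring.Y[child],
        "Y_p": parents.Y[f_idx], "Y_m": parents.Y[m_idx],
    })


def simulate_trios(config: SimConfig) -> pd.DataFrame:
    """Convenience wrapper: evolve a population and extract the trio table."""
    parents, offspring, _ = evolve(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    return extract_trios(parents, offspring, config.n_fam, rng)
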