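"""Synthetic herd generator: pedigree, gene-dropped genotypes, QTL plans and
factor-structured phenotypes.

The generator produces data with the statistical structure the downstream
analysis assumes:

* a multi-generation pedigree with a configurable sire pool,
* genotypes gene-dropped through the pedigree (founders in linkage
  equilibrium, so linkage disequilibrium arises only from co-segregation),
* two latent traits linked by a causal path ``latent_B = beta * latent_A + ...``,
  each with a planted-QTL plus polygenic additive architecture,
* six observed indicator traits loading on the two latents, with additive
  year-of-birth and slaughter-age fixed effects on the indicators.

Planted QTL windows come in four classes:

``direct_A``     affects latent A only.
``direct_B``     affects latent B only (not through A).
``pleiotropic``  affects both latents directly.
``indirect``     affects latent A; its influence on B flows exclusively
                 through the causal path, so conditioning on A removes it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PedigreeTable

__all__ = [
    "QtlSpec",
    "FixedEffectPlan",
    "SimConfig",
    "SimOutput",
    "simulate_pedigree",
    "drop_genotypes",
    "simulate_latent_traits",
    "simulate_dataset",
]

EFFECT_CLASSES = ("direct_A", "direct_B", "pleiotropic", "indirect")


class ConfigurationError(ValueError):
    """Raised when a SimConfig cannot produce a valid dataset."""


@dataclass(frozen=True)
class QtlSpec:
    """One planted QTL window.

    ``effect_size`` is the standard-deviation contribution of the window to
    the latent trait(s) it acts on, in latent-SD units (so its variance
    contribution is ``effect_size**2`` of a unit-variance latent).
    """

    window_index: int
    effect_class: str
    effect_size: float

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ConfigurationError(
                f"unknown effect class {self.effect_class!r}; "
                f"expected one of {EFFECT_CLASSES}"
            )


@dataclass(frozen=True)
class FixedEffectPlan:
    """Additive fixed effects applied to the observed indicators."""

    year_offsets: tuple[float, ...] = (0.0, 0.4, -0.3)  # one per year level
    age_mean: float = 525.0
    age_sd: float = 30.0
    age_slope: float = 0.004  # indicator shift per day of slaughter age


@dataclass
class SimConfig:
    n_founders: int = 200
    n_generations: int = 3  # offspring cohorts bred after the founders
    n_sires: int = 30
    n_animals_target: int = 1100
    n_snps: int = 2000
    n_chromosomes: int = 10
    maf_range: tuple[float, float] = (0.1, 0.5)
    qtl_plan: list[QtlSpec] = field(default_factory=list)
    h2_A: float = 0.46
    h2_B: float = 0.36
    beta_causal: float = 0.28
    rg_target: float | None = 0.87  # None: no shared polygenic background
    polygenic_fraction: float = 0.5
    n_qtl_per_window: int = 2
    window_size: int = 20
    loadings_A: tuple[float, float, float] = (1.0, 0.8, 1.2)
    loadings_B: tuple[float, float, float] = (1.0, 0.9, 1.1)
    indicator_residual_sds: tuple[float, ...] = (0.6, 0.6, 0.6, 0.6, 0.6, 0.6)
    indicator_names: tuple[str, ...] = ("QG", "FOR", "MARB", "JC", "TD", "CT")
    fixed_effect_plan: FixedEffectPlan = field(default_factory=FixedEffectPlan)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ConfigurationError(f"invalid maf_range {self.maf_range}")
        for h2, tag in ((self.h2_A, "h2_A"), (self.h2_B, "h2_B")):
            if not (0.0 <= h2 <= 1.0):
                raise ConfigurationError(f"{tag}={h2} outside [0, 1]")
        if self.n_founders < 2 or self.n_generations < 1:
            raise ConfigurationError("need >=2 founders and >=1 generation")
        if len(self.indicator_residual_sds) != 6:
            raise ConfigurationError("need six indicator residual SDs")
        n_windows = self.n_snps // self.window_size
        seen: set[int] = set()
        for q in self.qtl_plan:
            if not (0 <= q.window_index < n_windows):
                raise ConfigurationError(
                    f"QTL window {q.window_index} out of range "
                    f"(0..{n_windows - 1})"
                )
            if q.window_index in seen:
                raise ConfigurationError(
                    f"QTL windows overlap at index {q.window_index}"
                )
            seen.add(q.window_index)


@dataclass
class SimOutput:
    pedigree: PedigreeTable
    genotypes: GenotypeMatrix
    true_breeding_values_A: np.ndarray
    true_breeding_values_B: np.ndarray
    latent_A: np.ndarray
    latent_B: np.ndarray
    indicators: pd.DataFrame  # six traits + fixed-effect columns, per animal
    true_snp_effects_A: np.ndarray
    true_snp_effects_B: np.ndarray
    config: SimConfig

    def phenotype_table(self) -> pd.DataFrame:
        return self.indicators.copy()

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pedigree.write(outdir / "pedigree.tsv")
        self.genotypes.write_plink_text(outdir / "genotypes.tsv")
        self.genotypes.write_map(outdir / "markers.tsv")
        self.indicators.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
        truth = pd.DataFrame(
            {
                "animal": self.genotypes.ids,
                "tbv_A": self.true_breeding_values_A,
                "tbv_B": self.true_breeding_values_B,
                "latent_A": self.latent_A,
                "latent_B": self.latent_B,
            }
        )
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        manifest = {
            "seed": self.config.seed,
            "h2_A": self.config.h2_A,
            "h2_B": self.config.h2_B,
            "beta_causal": self.config.beta_causal,
            "rg_target": self.config.rg_target,
            "qtl_plan": [
                [q.window_index, q.effect_class, q.effect_size]
                for q in self.config.qtl_plan
            ],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


# --------------------------------------------------------------------------
# pedigree
# --------------------------------------------------------------------------
def simulate_pedigree(cfg: SimConfig) -> PedigreeTable:
    """Breed ``n_generations`` offspring cohorts from a founder population.

    Founders are generation 0.  Each cohort's sires are drawn from a fresh
    quota of previously unused males so that the number of distinct sires in
    the pedigree equals ``cfg.n_sires`` (when offspring counts allow); dams
    are sampled with replacement from earlier-generation females.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_off_total = cfg.n_animals_target - cfg.n_founders
    if n_off_total < cfg.n_generations:
        raise ConfigurationError(
            "n_animals_target too small for the requested generations"
        )
    base, extra = divmod(n_off_total, cfg.n_generations)
    per_gen = [base + (1 if g < extra else 0) for g in range(cfg.n_generations)]

    quota_base, quota_extra = divmod(cfg.n_sires, cfg.n_generations)
    sire_quota = [
        quota_base + (1 if g < quota_extra else 0)
        for g in range(cfg.n_generations)
    ]

    animal, sire, dam, gen, sex = [], [], [], [], []
    males: list[int] = []
    females: list[int] = []
    next_id = 1
    for _ in range(cfg.n_founders):
        s = "M" if rng.random() < 0.5 else "F"
        animal.append(next_id)
        sire.append(0)
        dam.append(0)
        gen.append(0)
        sex.append(s)
        (males if s == "M" else females).append(next_id)
        next_id += 1
    if not males or not females:  # tiny founder sets: force both sexes
        sex[0], sex[1] = "M", "F"
        males, females = [animal[0]], [animal[1]]

    used_sires: set[int] = set()
    for g in range(1, cfg.n_generations + 1):
        avail = [m for m in males if m not in used_sires]
        want = min(sire_quota[g - 1], per_gen[g - 1])
        if want < 1:
            want = 1
        if len(avail) < want:
            raise ConfigurationError(
                f"generation {g}: need {want} new sires but only "
                f"{len(avail)} unused males available"
            )
        pool = rng.choice(avail, size=want, replace=False)
        used_sires.update(int(m) for m in pool)
        new_males, new_females = [], []
        for k in range(per_gen[g - 1]):
            s_id = int(pool[k % len(pool)])  # guarantee every sire is used
            d_id = int(rng.choice(females))
            s = "M" if rng.random() < 0.5 else "F"
            animal.append(next_id)
            sire.append(s_id)
            dam.append(d_id)
            gen.append(g)
            sex.append(s)
            (new_males if s == "M" else new_females).append(next_id)
            next_id += 1
        males.extend(new_males)
        females.extend(new_females)

    table = pd.DataFrame(
        {"animal": animal, "sire": sire, "dam": dam, "generation": gen, "sex": sex}
    )
    return PedigreeTable(table)


# --------------------------------------------------------------------------
# gene dropping
# --------------------------------------------------------------------------
def _marker_map(cfg: SimConfig) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    chroms, pos, names = [], [], []
    for c in range(cfg.n_chromosomes):
        n = int(per_chrom[c])
        chroms.extend([c + 1] * n)
        pos.extend((np.arange(n) + 1) * 10_000)
        names.extend(f"snp{c + 1}_{k + 1}" for k in range(n))
    return pd.DataFrame({"snp": names, "chrom": chroms, "pos": pos})


def drop_genotypes(
    ped: PedigreeTable, cfg: SimConfig, founder_freqs: np.ndarray | None = None
) -> GenotypeMatrix:
    """Gene-drop biallelic SNPs through the pedigree.

    Founder haplotypes are drawn in linkage equilibrium at frequencies
    uniform on ``cfg.maf_range`` (or supplied explicitly); each offspring
    receives one uniformly chosen allele per parent per SNP, so markers are
    unlinked and Mendelian consistency holds by construction.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    m = cfg.n_snps
    if founder_freqs is None:
        founder_freqs = rng.uniform(*cfg.maf_range, size=m)
    founder_freqs = np.asarray(founder_freqs, dtype=float)

    order = ped.topological_order()
    idx = {a: i for i, a in enumerate(order)}
    tab = ped.table.set_index("animal")
    n = len(order)
    alleles = np.zeros((n, 2, m), dtype=np.int8)
    for a in order:
        i = idx[a]
        s, d = int(tab.at[a, "sire"]), int(tab.at[a, "dam"])
        for slot, parent in enumerate((s, d)):
            if parent == 0:
                alleles[i, slot] = rng.random(m) < founder_freqs
            else:
                pick = rng.integers(0, 2, size=m)
                alleles[i, slot] = alleles[idx[parent], pick, np.arange(m)]
    dosages = alleles.sum(axis=1).astype(float)
    return GenotypeMatrix(dosages, order, _marker_map(cfg), founder_freqs=founder_freqs)


# --------------------------------------------------------------------------
# latent traits
# --------------------------------------------------------------------------
def _window_snp_indices(cfg: SimConfig, window_index: int, rng) -> np.ndarray:
    start = window_index * cfg.window_size
    within = rng.choice(
        cfg.window_size, size=min(cfg.n_qtl_per_window, cfg.window_size),
        replace=False,
    )
    return start + np.sort(within)


def _realize(zc: np.ndarray, u: np.ndarray) -> np.ndarray:
    return zc @ u


def _scaled_component(
    zc: np.ndarray, u: np.ndarray, target_sd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Scale a SNP-effect vector so its realized score SD hits target_sd."""
    g = _realize(zc, u)
    sd = g.std()
    if sd == 0:
        raise ConfigurationError("degenerate QTL component (no variation)")
    f = target_sd / sd
    return g * f, u * f


def _residualize(vec: np.ndarray, basis: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Joint OLS residual of ``vec`` on the non-degenerate basis vectors.

    Returns (residual, coefficients aligned to ``basis``; zero for dropped
    columns) so callers can apply the same combination to SNP-effect
    vectors.
    """
    cols = [b for b in basis if b.std() > 0]
    keep = [i for i, b in enumerate(basis) if b.std() > 0]
    coefs = np.zeros(len(basis))
    if not cols:
        return vec, coefs
    X = np.column_stack([np.ones(len(vec))] + cols)
    beta, *_ = np.linalg.lstsq(X, vec, rcond=None)
    resid = vec - X @ beta
    for k, i in enumerate(keep):
        coefs[i] = beta[k + 1]
    return resid, coefs


def simulate_latent_traits(
    ped: PedigreeTable, geno: GenotypeMatrix, cfg: SimConfig
) -> SimOutput:
    """Construct latent traits, breeding values and indicator phenotypes.

    The additive architecture is realized-scale: component scores are
    rescaled against their empirical standard deviations so that the
    realized genetic variances match ``h2_A``/``h2_B`` and (when
    ``rg_target`` is set) the realized genetic correlation matches the
    target.  All genetic variation flows through SNPs, so back-solved
    marker effects can recover it.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2)
    n, m = geno.n_animals, geno.n_snps
    freqs = geno.allele_frequencies()
    zc = geno.dosages - 2.0 * freqs  # NaN-free by construction here

    uA = np.zeros(m)
    uB_own = np.zeros(m)
    planted_snps: set[int] = set()
    gA = np.zeros(n)
    gB_planted = np.zeros(n)

    for q in cfg.qtl_plan:
        snps = _window_snp_indices(cfg, q.window_index, rng)
        # keep the polygenic background out of the whole planted window
        w0 = q.window_index * cfg.window_size
        planted_snps.update(range(w0, min(w0 + cfg.window_size, m)))
        raw = np.zeros(m)
        raw[snps] = rng.choice([-1.0, 1.0], size=len(snps))
        if q.effect_class in ("direct_A", "pleiotropic", "indirect"):
            g, u = _scaled_component(zc, raw, q.effect_size)
            gA += g
            uA += u
        if q.effect_class in ("direct_B", "pleiotropic"):
            g, u = _scaled_component(zc, raw, q.effect_size)
            gB_planted += g
            uB_own += u

    # polygenic background on SNPs outside planted windows
    free = np.setdiff1d(
        np.arange(m),
        np.fromiter(planted_snps, dtype=int, count=len(planted_snps)),
    )
    n_poly = max(1, int(round(cfg.polygenic_fraction * len(free))))
    poly_snps = rng.choice(free, size=min(n_poly, len(free)), replace=False)

    planted_A_var = sum(
        q.effect_size**2
        for q in cfg.qtl_plan
        if q.effect_class in ("direct_A", "pleiotropic", "indirect")
    )
    vA_poly = cfg.h2_A - planted_A_var
    if vA_poly < -1e-12:
        raise ConfigurationError(
            f"planted A variance {planted_A_var:.3f} exceeds h2_A={cfg.h2_A}"
        )
    polyA = np.zeros(n)
    u_polyA = np.zeros(m)
    if vA_poly > 1e-12 and cfg.h2_A > 0:
        raw = np.zeros(m)
        raw[poly_snps] = rng.standard_normal(len(poly_snps))
        polyA, u_polyA = _scaled_component(zc, raw, np.sqrt(vA_poly))
    gA = gA + polyA
    uA = uA + u_polyA
    # exact realized genetic variance for A
    if cfg.h2_A > 0 and gA.std() > 0:
        f = np.sqrt(cfg.h2_A) / gA.std()
        gA, uA, polyA, u_polyA = gA * f, uA * f, polyA * f, u_polyA * f
    elif cfg.h2_A == 0:
        gA, uA, polyA, u_polyA = np.zeros(n), np.zeros(m), np.zeros(n), np.zeros(m)

    beta = cfg.beta_causal

    # -- genetic side of B ------------------------------------------------
    # Target realized moments:
    #   Var(gA) = h2_A (done), Var(gB) = h2_B,
    #   Cov(gA, gB) = rg_target * sqrt(h2_A h2_B)   (genetic correlation)
    #   Cov(latent_A, latent_B) = beta              (so the SEM structural
    #       coefficient recovers the causal path; any genetic covariance in
    #       excess of beta*h2_A is cancelled by environmental covariance of
    #       the opposite sign, which is how a genetic correlation larger
    #       than the phenotypic regression coexists with the causal model).
    if cfg.rg_target is not None and cfg.h2_A > 0 and cfg.h2_B > 0:
        cov_g_target = cfg.rg_target * np.sqrt(cfg.h2_A * cfg.h2_B)
    else:
        cov_g_target = None  # no background sharing requested
    cp = float(np.mean((gA - gA.mean()) * (gB_planted - gB_planted.mean())))
    c1 = 0.0
    polyA_unit = np.zeros(n)
    u_polyA_unit = np.zeros(m)
    if polyA.std() > 0:
        polyA_unit = polyA / polyA.std()
        u_polyA_unit = u_polyA / polyA.std()
    if cov_g_target is not None:
        cov_share = cov_g_target - beta * cfg.h2_A  # beyond the causal path
        ca = float(np.mean((gA - gA.mean()) * (polyA_unit - polyA_unit.mean())))
        if abs(ca) < 1e-12:
            if abs(cov_share - cp) > 0.02:
                raise ConfigurationError(
                    "rg_target unreachable: no polygenic A component to share"
                )
            c1 = 0.0
        else:
            c1 = (cov_share - cp) / ca
    else:
        cov_share = cp + 0.0  # whatever pleiotropy produced

    part = gB_planted + c1 * polyA_unit
    u_part = uB_own + c1 * u_polyA_unit

    # independent polygenic reservoir for B.  Residualised against the
    # polygenic A component and the partial sum only (never against planted
    # QTL components, so indirect/direct_A QTL stay off B's own effects).
    raw = np.zeros(m)
    raw[poly_snps] = rng.standard_normal(len(poly_snps))
    polyB = _realize(zc, raw)
    u_polyB = raw.copy()
    polyB, ks = _residualize(polyB, [polyA, part])
    u_polyB = u_polyB - ks[0] * u_polyA - ks[1] * u_part
    if polyB.std() > 0:
        u_polyB = u_polyB / polyB.std()
        polyB = polyB / polyB.std()

    var_gB_own = cfg.h2_B - beta**2 * cfg.h2_A - 2.0 * beta * cov_share
    if var_gB_own < -1e-10:
        raise ConfigurationError(
            f"implied own-genetic variance of B is {var_gB_own:.3f} < 0; "
            "reduce beta_causal, rg_target or planted effects"
        )
    c2sq = var_gB_own - part.var()
    if c2sq < -1e-10:
        raise ConfigurationError(
            f"planted B variance {part.var():.3f} exceeds the budget "
            f"{var_gB_own:.3f}; reduce planted effect sizes"
        )
    c2 = np.sqrt(max(c2sq, 0.0))
    gB_own = part + c2 * polyB
    u_gB_own = u_part + c2 * u_polyB
    gB = beta * gA + gB_own
    uB = beta * uA + u_gB_own
    if cfg.h2_B == 0:
        gB, uB = np.zeros(n), np.zeros(m)

    # -- environmental side ----------------------------------------------
    veA = 1.0 - cfg.h2_A
    eA, _ = _residualize(rng.standard_normal(n), [gA, gB_own])
    eA = eA / eA.std() * np.sqrt(max(veA, 0.0)) if veA > 0 else np.zeros(n)
    latent_A = gA + eA

    # env covariance cancelling the extra genetic covariance, so that
    # Cov(latent_A, latent_B) = beta exactly
    veB_own = 1.0 - cfg.h2_B - beta**2 * veA + 2.0 * beta * cov_share
    if veB_own < 0:
        raise ConfigurationError(
            f"implied B environmental variance {veB_own:.3f} < 0; "
            "lower beta_causal or h2_B"
        )
    c3 = 0.0
    eA_unit = np.zeros(n)
    if veA > 1e-12 and eA.std() > 0:
        eA_unit = eA / eA.std()
        c3 = -cov_share / np.sqrt(veA)
    elif abs(cov_share) > 1e-8:
        raise ConfigurationError(
            "cannot cancel shared genetic covariance with h2_A = 1"
        )
    c4sq = veB_own - c3**2
    if c4sq < -1e-10:
        raise ConfigurationError(
            "environmental budget of B too small to offset rg_target"
        )
    noise, _ = _residualize(rng.standard_normal(n), [gA, gB_own, eA])
    noise = noise / noise.std() if noise.std() > 0 else noise
    eB_own = c3 * eA_unit + np.sqrt(max(c4sq, 0.0)) * noise
    latent_B = beta * latent_A + gB_own + eB_own

    # indicators with fixed effects
    plan = cfg.fixed_effect_plan
    n_levels = len(plan.year_offsets)
    year = rng.integers(0, n_levels, size=n)
    age = plan.age_mean + rng.standard_normal(n) * plan.age_sd
    shift = np.asarray(plan.year_offsets)[year] + plan.age_slope * (
        age - plan.age_mean
    )
    cols: dict[str, np.ndarray] = {"animal": geno.ids}
    sds = cfg.indicator_residual_sds
    for i, name in enumerate(cfg.indicator_names[:3]):
        cols[name] = (
            cfg.loadings_A[i] * latent_A
            + rng.standard_normal(n) * sds[i]
            + shift
        )
    for i, name in enumerate(cfg.indicator_names[3:]):
        cols[name] = (
            cfg.loadings_B[i] * latent_B
            + rng.standard_normal(n) * sds[3 + i]
            + shift
        )
    cols["year_of_birth"] = 1990 + year
    cols["slaughter_age"] = age
    indicators = pd.DataFrame(cols)

    return SimOutput(
        pedigree=ped,
        genotypes=geno,
        true_breeding_values_A=gA,
        true_breeding_values_B=gB,
        latent_A=latent_A,
        latent_B=latent_B,
        indicators=indicators,
        true_snp_effects_A=uA,
        true_snp_effects_B=uB,
        config=cfg,
    )


def simulate_dataset(cfg: SimConfig) -> SimOutput:
    """Pedigree -> gene drop -> latent traits, in one seeded call."""
    ped = simulate_pedigree(cfg)
    geno = drop_genotypes(ped, cfg)
    return simulate_latent_traits(ped, geno, cfg)
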