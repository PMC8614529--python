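"""Gene-dropping simulator for pedigree, genotypes and repeated phenotypes.

The generator produces data with the structure the analysis model assumes:
a multi-generation natural-mating pedigree with partially unknown parents,
unlinked biallelic SNPs dropped through the pedigree from founder allele
frequencies, marker-determined true breeding values (a QTL subset of the
SNPs carries i.i.d. normal effects, scaled so the founder variance of the
breeding values equals the target additive variance), a per-animal permanent
environmental effect, and repeated records built as

    y = year + color + beta1*age + beta2*age^2 + sex_status + u + pe + e

True breeding values are marker-determined rather than pedigree-sampled so
that genomic relationships genuinely carry information beyond the pedigree;
this is the mechanism by which single-step evaluation can out-predict
pedigree BLUP in simulation.

Default sizes are a desk-scale emulation of an alpaca fiber-trait recording
scheme (~3,000 pedigree animals, ~400 genotyped, 2,000 SNPs, 200 QTL,
~2 records per animal) with fiber-diameter-like variance components; the
``FD``, ``SD`` and ``PM`` presets differ in the variance triple and the
number of year levels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    Dataset,
    GenotypeMatrix,
    MISSING_DOSAGE,
    Pedigree,
    PhenotypeTable,
    SEX_STATUS_LEVELS,
)
import pandas as pd


@dataclass
class SimulationConfig:
    # pedigree
    n_founders: int = 500
    n_generations: int = 5
    offspring_per_dam: int = 2
    prop_sires: float = 0.15          # sire:dam ratio under natural mating
    prop_missing_parents: float = 0.10
    # genome
    n_snps: int = 2000
    n_qtl: int = 200
    founder_maf_low: float = 0.10     # founder frequencies ~ U(low, high),
    founder_maf_high: float = 0.50    # random allele labelled as reference
    prop_missing_genotypes: float = 0.0
    prop_genotyped: float = 0.133     # drawn from the youngest generations
    # trait (fiber-diameter-like defaults, micrometre^2 units)
    sigma_u2: float = 2.824
    sigma_c2: float = 1.289
    sigma_e2: float = 4.332
    trait_mean: float = 22.82
    trait: str = "FD"
    # fixed-effect structure
    n_years: int = 19
    n_colors: int = 9
    n_sex_status: int = 3
    age_range_days: tuple[float, float] = (365.0, 3650.0)
    mean_records: float = 2.0         # records ~ 1 + Poisson(mean_records - 1)
    fixed_effect_scale: float = 1.0   # multiplies all fixed-effect draws
    seed: int = 12345

    def __post_init__(self) -> None:
        for name in ("sigma_u2", "sigma_c2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed n_snps")
        for name in ("prop_sires", "prop_missing_parents",
                     "prop_missing_genotypes", "prop_genotyped"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.founder_maf_low <= self.founder_maf_high <= 0.5:
            raise ValueError("founder MAF range must satisfy 0 < low <= high <= 0.5")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-stage stream derived from the master seed."""
        key = zlib.crc32(stream.encode()) % (2**31)
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


#: trait presets: (sigma_u2, sigma_c2, sigma_e2, n_years, trait mean)
TRAIT_PRESETS = {
    "FD": dict(sigma_u2=2.824, sigma_c2=1.289, sigma_e2=4.332,
               n_years=19, trait_mean=22.82),
    "SD": dict(sigma_u2=0.354, sigma_c2=0.144, sigma_e2=0.431,
               n_years=19, trait_mean=5.38),
    "PM": dict(sigma_u2=27.416, sigma_c2=39.509, sigma_e2=106.316,
               n_years=4, trait_mean=47.75),
}


def preset_config(trait: str = "FD", **overrides) -> SimulationConfig:
    """A SimulationConfig for one of the FD / SD / PM trait presets."""
    if trait not in TRAIT_PRESETS:
        raise ValueError(f"unknown trait preset {trait!r}")
    kw = dict(TRAIT_PRESETS[trait], trait=trait)
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass
class TruthSet:
    """Simulation ground truth: per-animal u and pe, QTL model, fixed effects."""

    u: np.ndarray                     # true breeding values, internal ID order
    pe: np.ndarray                    # realized permanent-environment effects
    qtl_index: np.ndarray
    qtl_effects: np.ndarray
    b: dict = field(default_factory=dict)   # fixed-effect coefficient draws
    founder_freqs: np.ndarray | None = None

    def to_frame(self, pedigree: Pedigree) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": list(pedigree.original_ids),
                "true_bv": self.u,
                "true_pe": self.pe,
            }
        )


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Simulate a multi-generation natural-mating pedigree.

    Each generation mates a sampled sire set (``prop_sires`` x number of
    dams, at least one) to all dams of the previous generation; every dam
    produces ``offspring_per_dam`` offspring of random sex.  A fraction
    ``prop_missing_parents`` of non-founder parent links is then reset to
    unknown, mimicking incomplete recording.
    """
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = config.rng("pedigree")

    sire: list[int] = [0] * config.n_founders
    dam: list[int] = [0] * config.n_founders
    sex = list(rng.integers(0, 2, size=config.n_founders))  # 1 male, 0 female
    # guarantee both sexes among founders
    if sum(sex) == 0:
        sex[0] = 1
    if sum(sex) == len(sex):
        sex[0] = 0
    generation = [0] * config.n_founders

    prev = list(range(1, config.n_founders + 1))
    for g in range(1, config.n_generations + 1):
        males = [a for a in prev if sex[a - 1] == 1]
        females = [a for a in prev if sex[a - 1] == 0]
        if not males or not females:
            break
        n_sires = max(1, int(round(config.prop_sires * len(females))))
        n_sires = min(n_sires, len(males))
        sires = rng.choice(males, size=n_sires, replace=False)
        current = []
        for d in females:
            for _ in range(config.offspring_per_dam):
                s = int(rng.choice(sires))
                sire.append(s)
                dam.append(d)
                sex.append(int(rng.integers(0, 2)))
                generation.append(g)
                current.append(len(sire))
        prev = current

    n = len(sire)
    sire_arr = np.array(sire, dtype=np.int64)
    dam_arr = np.array(dam, dtype=np.int64)
    if config.prop_missing_parents > 0:
        drop_s = rng.random(n) < config.prop_missing_parents
        drop_d = rng.random(n) < config.prop_missing_parents
        sire_arr[drop_s] = 0
        dam_arr[drop_d] = 0
    return Pedigree(
        sire=sire_arr,
        dam=dam_arr,
        original_ids=np.array([str(i) for i in range(1, n + 1)], dtype=object),
        sex=np.array(sex, dtype=np.int8),
        generation=np.array(generation, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    pedigree: Pedigree, config: SimulationConfig
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Gene-drop unlinked SNPs through the pedigree.

    Founder (and unknown-parent) gametes are Bernoulli draws from per-SNP
    founder frequencies ``p_j ~ U(founder_maf_low, founder_maf_high)``
    randomly assigned to either allele; offspring receive one allele per
    known parent by Mendelian sampling.  Returns the complete dosage matrix
    (all animals, no missingness — missingness is injected when the observed
    subset is drawn) and the founder frequency vector.
    """
    rng = config.rng("genotypes")
    m = config.n_snps
    n = pedigree.n_animals
    p = rng.uniform(config.founder_maf_low, config.founder_maf_high, size=m)
    flip = rng.random(m) < 0.5
    p = np.where(flip, 1.0 - p, p)

    alleles = np.zeros((n, m, 2), dtype=np.int8)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        for slot, parent in enumerate((s, d)):
            if parent == 0:
                alleles[i, :, slot] = rng.random(m) < p
            else:
                pick = rng.integers(0, 2, size=m)
                alleles[i, :, slot] = alleles[
                    parent - 1, np.arange(m), pick
                ]
    dosages = alleles.sum(axis=2).astype(np.int8)
    gm = GenotypeMatrix(
        animal_ids=np.arange(1, n + 1, dtype=np.int64),
        dosages=dosages,
    )
    return gm, p


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    founder_freqs: np.ndarray | None = None,
) -> tuple[PhenotypeTable, TruthSet]:
    """Build repeated records on top of marker-determined breeding values.

    The QTL subset of SNPs receives i.i.d. normal effects; the raw genetic
    values ``(M_qtl - 2 p_qtl) a`` are rescaled so their variance among
    founders equals ``sigma_u2``.  Records per animal follow
    ``1 + Poisson(mean_records - 1)``; years track generations so that the
    last year of recording is populated by the youngest animals.
    """
    if genotypes.n_animals != pedigree.n_animals:
        raise ValueError("phenotype simulation needs genotypes for all animals")
    rng = config.rng("phenotypes")
    n = pedigree.n_animals

    # --- true breeding values ------------------------------------------------
    if config.sigma_u2 > 0 and config.n_qtl == 0:
        raise ValueError("sigma_u2 > 0 requires n_qtl > 0")
    if config.n_qtl > 0 and config.sigma_u2 > 0:
        qtl = np.sort(rng.choice(config.n_snps, size=config.n_qtl, replace=False))
        effects = rng.standard_normal(config.n_qtl)
        dos = genotypes.dosages[:, qtl].astype(float)
        if founder_freqs is not None:
            centre = 2.0 * founder_freqs[qtl]
        else:
            centre = dos.mean(axis=0)
        u_raw = (dos - centre) @ effects
        founders = pedigree.is_founder()
        base = u_raw[founders] if founders.sum() >= 2 else u_raw
        sd = base.std()
        if sd == 0:
            raise ValueError("QTL genotypes are monomorphic; cannot scale u")
        scale = np.sqrt(config.sigma_u2) / sd
        u = u_raw * scale
        effects = effects * scale
    else:
        qtl = np.zeros(0, dtype=np.int64)
        effects = np.zeros(0)
        u = np.zeros(n)

    pe = rng.normal(0.0, np.sqrt(config.sigma_c2), size=n)

    # --- fixed-effect coefficients -------------------------------------------
    sigma_p = np.sqrt(config.sigma_u2 + config.sigma_c2 + config.sigma_e2)
    fs = config.fixed_effect_scale
    year_eff = fs * rng.normal(0.0, 0.25 * sigma_p, size=config.n_years)
    color_eff = fs * rng.normal(0.0, 0.15 * sigma_p, size=config.n_colors)
    status_eff = fs * np.concatenate(
        [[0.0], rng.normal(0.0, 0.15 * sigma_p, size=2)]
    )
    beta_age = fs * rng.normal(0.0, 0.10 * sigma_p, size=2)  # on standardized age

    # --- records --------------------------------------------------------------
    n_rec = 1 + rng.poisson(max(config.mean_records - 1.0, 0.0), size=n)
    sex = pedigree.sex if pedigree.sex is not None else rng.integers(0, 2, n)
    gen = (
        pedigree.generation
        if pedigree.generation is not None
        else np.zeros(n, dtype=np.int64)
    )
    g_max = max(int(gen.max()), 1)
    color = rng.integers(0, config.n_colors, size=n)

    lo, hi = config.age_range_days
    mid = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)

    animal_col, value_col, year_col, color_col, age_col, status_col = (
        [], [], [], [], [], []
    )
    for i in range(n):
        base_year = int(round(gen[i] * (config.n_years - 1) / g_max))
        age0 = rng.uniform(lo, lo + 400.0)
        for r in range(n_rec[i]):
            year = min(base_year + r, config.n_years - 1)
            age = min(age0 + 365.0 * r, hi)
            a_std = (age - mid) / half
            if sex[i] == 1:
                status = 0
            else:
                status = int(rng.integers(1, 3))
            mean = (
                config.trait_mean
                + year_eff[year]
                + color_eff[color[i]]
                + beta_age[0] * a_std
                + beta_age[1] * a_std**2
                + status_eff[status]
            )
            y = mean + u[i] + pe[i] + rng.normal(0.0, np.sqrt(config.sigma_e2))
            animal_col.append(i + 1)
            value_col.append(y)
            year_col.append(f"y{year + 1}")
            color_col.append(f"c{color[i] + 1}")
            age_col.append(age)
            status_col.append(SEX_STATUS_LEVELS[status])

    table = PhenotypeTable(
        pd.DataFrame(
            {
                "animal": animal_col,
                "value": value_col,
                "year": year_col,
                "color": color_col,
                "age_days": age_col,
                "sex_status": status_col,
            }
        ),
        trait=config.trait,
    )
    truth = TruthSet(
        u=u,
        pe=pe,
        qtl_index=qtl,
        qtl_effects=effects,
        b={
            "year": year_eff,
            "color": color_eff,
            "sex_status": status_eff,
            "beta_age_std": beta_age,
            "intercept": config.trait_mean,
        },
        founder_freqs=founder_freqs,
    )
    return table, truth


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def select_genotyped(pedigree: Pedigree, config: SimulationConfig) -> np.ndarray:
    """Internal IDs of the observed genotyped subset (youngest generations).

    Mirrors a scheme where animals reaching their second fleece evaluation
    are the ones genotyped: candidates are taken from the last two
    generations, extended backwards if the quota exceeds them.
    """
    rng = config.rng("genotyped")
    n_target = int(round(config.prop_genotyped * pedigree.n_animals))
    if n_target == 0:
        return np.zeros(0, dtype=np.int64)
    gen = (
        pedigree.generation
        if pedigree.generation is not None
        else np.zeros(pedigree.n_animals, dtype=np.int64)
    )
    ids = np.arange(1, pedigree.n_animals + 1)
    g = int(gen.max())
    pool = ids[gen >= max(g - 1, 0)]
    lo = max(g - 1, 0)
    while len(pool) < n_target and lo > 0:
        lo -= 1
        pool = ids[gen >= lo]
    n_target = min(n_target, len(pool))
    return np.sort(rng.choice(pool, size=n_target, replace=False))


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[Dataset, TruthSet, GenotypeMatrix]:
    """Run the whole generator: pedigree, genotypes, phenotypes, subset.

    Returns the analysis-facing :class:`Dataset` (with the observed genotype
    subset, optionally with injected missingness), the :class:`TruthSet`,
    and the complete no-missingness genotype matrix for all animals.
    """
    pedigree = simulate_pedigree(config)
    full_geno, p = simulate_genotypes(pedigree, config)
    phenotypes, truth = simulate_phenotypes(pedigree, full_geno, config, p)
    geno_ids = select_genotyped(pedigree, config)
    observed = full_geno.subset_animals(geno_ids) if len(geno_ids) else None
    if observed is not None and config.prop_missing_genotypes > 0:
        rng = config.rng("missingness")
        mask = rng.random(observed.dosages.shape) < config.prop_missing_genotypes
        dos = observed.dosages.copy()
        dos[mask] = MISSING_DOSAGE
        observed = GenotypeMatrix(observed.animal_ids, dos, list(observed.snp_ids))
    return Dataset(pedigree, phenotypes, observed), truth, full_geno
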