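"""Synthetic pedigrees, gene-drop genotypes and repeated-record phenotypes.

The generator produces data with the statistical structure the analysis
stages assume: a multi-generation pedigree with elevated close matings, a
29-autosome SNP map (~1 SNP / 50 kb), genotypes dropped through the pedigree
with Haldane recombination (so recent inbreeding leaves long autozygous
tracts and older inbreeding short ones), and phenotypes from a
repeated-records animal model with contemporary-group effects, a quadratic
age curve, additive-genetic and permanent-environment components, a
genome-wide inbreeding-depression slope on the TRUE autozygous genome
fraction, and optional planted recessive loci that act through true local
autozygosity.  Truth (founder-haplotype identity, not allele sharing) is
returned alongside so estimator accuracy is measurable.

Three independent PRNG streams are derived from the master seed by fixed
spawn keys, so changing phenotype settings never perturbs the genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (GenotypeMatrix, INTERVAL_CLASSES, make_pedigree,
                         make_phenotype_table, make_snp_map, pedigree_indices)
from .pedigree_kinship import _mendelian_d, inbreeding_meuwissen_luo


@dataclass
class SimConfig:
    """Study conditions for the simulated bull population.

    Defaults emulate a closed beef-bull population: a few dozen founders,
    several overlapping generations with a substantial probability of
    close (sib or parent-offspring) matings, a 29-autosome 50K-style map,
    and a semen-quality-like trait (mean 80, additive variance 2, permanent
    environment 1, residual 4, ~30 collection records per bull) with a
    genome-wide depression slope of -1 trait unit per unit autozygosity.
    """

    n_founders: int = 50
    n_generations: int = 5
    n_per_generation: int = 100
    mating_scheme: str = "sib_biased"  # random | circular | sib_biased
    close_mating_prob: float = 0.3
    allow_selfing: bool = False
    n_chrom: int = 29
    chrom_length_bp: int = 86_000_000
    snp_spacing_bp: int = 50_000
    founder_maf_range: tuple = (0.05, 0.5)
    recomb_rate: float = 1e-8  # Morgan per bp (1 cM/Mb, Haldane)
    trait_name: str = "MOT"
    trait_mean: float = 80.0
    sigma_u2: float = 2.0
    sigma_pe2: float = 1.0
    sigma_e2: float = 4.0
    sigma_cg: float = 1.0
    n_cg: int = 20
    n_records_per_animal: int = 30
    interval_effects: tuple = (0.0, 0.1, 0.2, 0.3, 0.4)
    age_months_range: tuple = (12.0, 96.0)
    age_effect_linear: float = 0.02  # per month, age centered at its midpoint
    age_effect_quadratic: float = -0.001
    beta_f_true: float = -1.0  # trait units per unit autozygous fraction
    planted_loci: tuple = ()  # (chrom, bp, effect_in_trait_units)
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma_u2", "sigma_pe2", "sigma_e2", "sigma_cg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.snp_spacing_bp <= 0:
            raise ValueError("snp_spacing_bp must be positive")
        if self.mating_scheme not in ("random", "circular", "sib_biased"):
            raise ValueError(f"unknown mating scheme {self.mating_scheme!r}")
        if self.n_founders < 2 and not self.allow_selfing:
            raise ValueError("need >= 2 founders when selfing is disabled")
        for chrom, bp, _ in self.planted_loci:
            if not (1 <= chrom <= self.n_chrom) or not (1 <= bp <= self.chrom_length_bp):
                raise ValueError(f"planted locus ({chrom}, {bp}) off the map")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-specific stream: 1=pedigree, 2=gene drop, 3=phenotypes."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass
class TruthRecord:
    """Simulation ground truth, for tests and accuracy measurement only."""

    snp_map: pd.DataFrame
    autozygous: np.ndarray  # animals x SNPs, bool: both haplotypes IBD
    f_true: pd.Series  # genome fraction truly autozygous
    samples: list
    planted_loci: tuple = ()
    u_true: pd.Series | None = None
    pe_true: pd.Series | None = None
    cg_effects: dict | None = None
    varcomp_true: dict | None = None
    beta_f_true: float | None = None


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(cfg: SimConfig) -> pd.DataFrame:
    """Multi-generation pedigree; returns columns animal, sire, dam,
    generation (founders = generation 0, unknown parents)."""
    rng = cfg.rng(1)
    rows = []
    founders = [f"G0_{i:04d}" for i in range(cfg.n_founders)]
    for a in founders:
        rows.append((a, None, None, 0))
    prev = founders
    parents_of = {}
    for g in range(1, cfg.n_generations + 1):
        cur = []
        for k in range(cfg.n_per_generation):
            a = f"G{g}_{k:04d}"
            s, d = _pick_parents(prev, parents_of, cfg, rng, k)
            rows.append((a, s, d, g))
            parents_of[a] = (s, d)
            cur.append(a)
        prev = cur
    ped = make_pedigree([(a, s, d) for a, s, d, _ in rows])
    gen = {a: g for a, _, _, g in rows}
    ped["generation"] = ped["animal"].map(gen)
    return ped


def _pick_parents(prev, parents_of, cfg: SimConfig, rng, k):
    n = len(prev)
    if cfg.mating_scheme == "circular":
        s = prev[k % n]
        d = prev[(k + 1) % n]
        return s, d
    s = prev[rng.integers(n)]
    if cfg.mating_scheme == "sib_biased" and rng.random() < cfg.close_mating_prob:
        sp = parents_of.get(s, (None, None))
        if sp != (None, None):
            sibs = [a for a in prev
                    if a != s and not set(parents_of.get(a, ())).isdisjoint(
                        p for p in sp if p)]
            if sibs:
                return s, sibs[rng.integers(len(sibs))]
    d = prev[rng.integers(n)]
    if not cfg.allow_selfing:
        while d == s:
            d = prev[rng.integers(n)]
    return s, d


# ---------------------------------------------------------------------------
# gene drop
# ---------------------------------------------------------------------------

def _make_map(cfg: SimConfig) -> pd.DataFrame:
    ids, chroms, pos = [], [], []
    for c in range(1, cfg.n_chrom + 1):
        p = np.arange(cfg.snp_spacing_bp, cfg.chrom_length_bp + 1,
                      cfg.snp_spacing_bp)
        pos.append(p)
        chroms.append(np.full(len(p), c))
        ids.extend(f"snp{c}_{i}" for i in range(len(p)))
    pos = np.concatenate(pos)
    chroms = np.concatenate(chroms)
    return make_snp_map(ids, chroms, pos, ["A"] * len(pos), ["B"] * len(pos),
                        n_autosomes=cfg.n_chrom)


def _meiosis(hap0, hap1, pos, length_bp, rate, rng):
    """One recombinant gamete (Haldane model: Poisson crossovers, uniform
    breakpoints, random start phase)."""
    k = rng.poisson(length_bp * rate)
    start = rng.integers(2)
    if k == 0:
        return hap0 if start == 0 else hap1
    cuts = np.sort(rng.uniform(0, length_bp, size=k))
    phase = (start + np.searchsorted(cuts, pos)) % 2
    return np.where(phase == 0, hap0, hap1)


def gene_drop(ped: pd.DataFrame, cfg: SimConfig):
    """Drop founder haplotypes through the pedigree.

    Founders carry two uniquely labeled haplotypes whose alleles are drawn
    per SNP from the founder allele-frequency law; descendants inherit
    recombinant gametes.  A locus is truly autozygous when both haplotype
    labels descend from the same founder haplotype.  Returns
    (GenotypeMatrix, TruthRecord) over all pedigree animals.
    """
    rng = cfg.rng(2)
    snp_map = _make_map(cfg)
    n_snp = len(snp_map)
    chrom_arr = snp_map["chrom"].to_numpy()
    pos_arr = snp_map["pos_bp"].to_numpy()
    slices = []
    for c in range(1, cfg.n_chrom + 1):
        sel = np.flatnonzero(chrom_arr == c)
        slices.append((sel[0], sel[-1] + 1))

    _, sire, dam = pedigree_indices(ped)
    n = len(ped)
    freq_b = rng.uniform(*cfg.founder_maf_range, size=n_snp)
    founder_alleles = []  # list of allele rows, one per founder haplotype label
    lab = np.empty((n, 2, n_snp), dtype=np.int32)

    next_label = 0
    for i in range(n):
        for which, p in enumerate((sire[i], dam[i])):
            if p < 0:  # founder-side haplotype: new label, fresh alleles
                lab[i, which] = next_label
                founder_alleles.append(
                    (rng.random(n_snp) < freq_b).astype(np.int8))
                next_label += 1
            else:
                gam = np.empty(n_snp, dtype=np.int32)
                for a, b in slices:
                    gam[a:b] = _meiosis(lab[p, 0, a:b], lab[p, 1, a:b],
                                        pos_arr[a:b].astype(np.float64),
                                        cfg.chrom_length_bp, cfg.recomb_rate,
                                        rng)
                lab[i, which] = gam

    alleles = np.asarray(founder_alleles)  # labels x SNPs
    col = np.arange(n_snp)
    codes = np.empty((n, n_snp), dtype=np.int8)
    auto = np.empty((n, n_snp), dtype=bool)
    for i in range(n):
        codes[i] = alleles[lab[i, 0], col] + alleles[lab[i, 1], col]
        auto[i] = lab[i, 0] == lab[i, 1]

    samples = list(ped["animal"])
    geno = GenotypeMatrix(samples, snp_map, codes)
    truth = TruthRecord(snp_map, auto,
                        pd.Series(auto.mean(axis=1), index=samples,
                                  name="f_true"),
                        samples, planted_loci=tuple(cfg.planted_loci),
                        beta_f_true=cfg.beta_f_true,
                        varcomp_true={"sigma_u2": cfg.sigma_u2,
                                      "sigma_pe2": cfg.sigma_pe2,
                                      "sigma_e2": cfg.sigma_e2})
    return geno, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(ped: pd.DataFrame, truth: TruthRecord | None,
                        cfg: SimConfig, phenotyped=None):
    """Repeated phenotype records for the phenotyped cohort.

    Breeding values follow the pedigree recursion u = (u_s + u_d)/2 + m with
    Mendelian-sampling variance sigma_u2 * d_j (d_j uses exact parental
    inbreeding); each record adds contemporary-group, interval-class and
    quadratic age effects, the genome-wide depression slope times the TRUE
    autozygous fraction, planted-locus effects when the animal is truly
    autozygous across the planted position, and iid residual noise.

    ``truth=None`` simulates with zero autozygosity signal (no genotypes
    needed).  ``phenotyped`` defaults to the last generation.
    """
    if truth is None and (cfg.beta_f_true != 0 or cfg.planted_loci):
        raise ValueError("truth from gene_drop is required when beta_f_true "
                         "or planted loci are nonzero")
    rng = cfg.rng(3)
    _, sire, dam = pedigree_indices(ped)
    F = inbreeding_meuwissen_luo(ped).to_numpy()
    n = len(ped)
    su = np.sqrt(cfg.sigma_u2)
    u = np.zeros(n)
    for i in range(n):
        d = _mendelian_d(F, sire, dam, i)
        mean = 0.0
        if sire[i] >= 0:
            mean += 0.5 * u[sire[i]]
        if dam[i] >= 0:
            mean += 0.5 * u[dam[i]]
        u[i] = mean + rng.normal(0.0, su * np.sqrt(d))

    animals = list(ped["animal"])
    aidx = {a: i for i, a in enumerate(animals)}
    if phenotyped is None:
        if "generation" in ped.columns:
            last = ped["generation"].max()
            phenotyped = [a for a, g in zip(ped["animal"], ped["generation"])
                          if g == last]
        else:
            parents = set(ped["sire"].dropna()) | set(ped["dam"].dropna())
            phenotyped = [a for a in animals if a not in parents]

    pe = {a: rng.normal(0.0, np.sqrt(cfg.sigma_pe2)) for a in phenotyped}
    cg_labels = [f"cg{c:03d}" for c in range(cfg.n_cg)]
    cg_eff = {c: rng.normal(0.0, cfg.sigma_cg) for c in cg_labels}
    age_mid = 0.5 * (cfg.age_months_range[0] + cfg.age_months_range[1])

    planted_cols = []
    if truth is not None:
        pos_arr = truth.snp_map["pos_bp"].to_numpy()
        chrom_arr = truth.snp_map["chrom"].to_numpy()
        tidx = {a: i for i, a in enumerate(truth.samples)}
        for chrom, bp, eff in cfg.planted_loci:
            sel = np.flatnonzero(chrom_arr == chrom)
            j = sel[np.argmin(np.abs(pos_arr[sel] - bp))]
            planted_cols.append((j, eff, tidx))

    rows = []
    se = np.sqrt(cfg.sigma_e2)
    for a in phenotyped:
        base = cfg.trait_mean + u[aidx[a]] + pe[a]
        if truth is not None:
            f_true = float(truth.f_true.loc[a])
            base += cfg.beta_f_true * f_true
            for j, eff, tidx in planted_cols:
                if truth.autozygous[tidx[a], j]:
                    base += eff
        for _ in range(cfg.n_records_per_animal):
            cg = cg_labels[rng.integers(cfg.n_cg)]
            ic = rng.integers(len(INTERVAL_CLASSES))
            age = rng.uniform(*cfg.age_months_range)
            ac = age - age_mid
            y = (base + cg_eff[cg] + cfg.interval_effects[ic]
                 + cfg.age_effect_linear * ac
                 + cfg.age_effect_quadratic * ac * ac
                 + rng.normal(0.0, se))
            rows.append((a, cfg.trait_name, y, cg, INTERVAL_CLASSES[ic], age))

    pheno = make_phenotype_table(pd.DataFrame(
        rows, columns=["animal", "trait", "value", "cg", "interval_class",
                       "age_months"]))
    out_truth = truth if truth is not None else TruthRecord(
        pd.DataFrame(), np.zeros((0, 0), dtype=bool),
        pd.Series(dtype=float), [], beta_f_true=cfg.beta_f_true)
    out_truth.u_true = pd.Series(u, index=animals, name="u_true")
    out_truth.pe_true = pd.Series(pe, name="pe_true")
    out_truth.cg_effects = cg_eff
    out_truth.varcomp_true = {"sigma_u2": cfg.sigma_u2,
                              "sigma_pe2": cfg.sigma_pe2,
                              "sigma_e2": cfg.sigma_e2}
    out_truth.beta_f_true = cfg.beta_f_true
    return pheno, out_truth


def simulate_dataset(cfg: SimConfig, with_genotypes: bool = True):
    """Full bundle: (pedigree, genotypes, phenotypes, truth)."""
    ped = simulate_pedigree(cfg)
    if with_genotypes:
        geno, truth = gene_drop(ped, cfg)
    else:
        geno, truth = None, None
    pheno, truth = simulate_phenotypes(ped, truth, cfg)
    return ped, geno, pheno, truth
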