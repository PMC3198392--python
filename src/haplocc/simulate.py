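"""Synthetic case-control cohort generator.

Generates cohorts with the structure the downstream analysis assumes: gene
regions whose LD is induced purely by block haplotype pools (random mating,
no recombination model), logistic disease risk additive in haplotype copy
number with covariate effects and an optional diet-stratum interaction,
frequency-matched controls, and MCAR missingness.

The default configuration emulates a multi-centre renal-cell-carcinoma
candidate-gene study: 777 cases / 1,035 controls from 4 countries, 163 tag
SNPs in 13 one-carbon-metabolism gene regions (all control MAFs >= 5%), a
4-SNP SLC19A1 risk haplotype at ~6.4% control frequency with marginal
OR ~1.37 amplified to ~1.9 in the lowest vegetable-intake tertile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (MISSING, GeneRegionMap, GenotypeMatrix, SnpMeta,
                     apply_gene_map, validate_subjects)


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# haplotype pools
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePool:
    """Population haplotypes over one gene's SNPs with their frequencies."""

    gene: str
    haplotypes: list[tuple[str, float]]        # allele string (one char/SNP), freq
    rsids: list[str] = field(default_factory=list)
    chrom_band: str = ""

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise SimulationError(f"{self.gene}: empty haplotype pool")
        lengths = {len(h) for h, _ in self.haplotypes}
        if len(lengths) != 1:
            raise SimulationError(f"{self.gene}: haplotype strings differ in length")
        freqs = np.array([f for _, f in self.haplotypes], dtype=float)
        if (freqs <= 0).any():
            raise SimulationError(f"{self.gene}: non-positive haplotype frequency")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise SimulationError(
                f"{self.gene}: frequencies sum to {freqs.sum()!r}, not 1")
        if not self.rsids:
            self.rsids = [f"{self.gene}_snp{j}" for j in range(self.n_snps)]
        if len(self.rsids) != self.n_snps:
            raise SimulationError(f"{self.gene}: rsid count != SNP count")

    @property
    def n_snps(self) -> int:
        return len(self.haplotypes[0][0])

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for _, f in self.haplotypes])

    def snp_alleles(self) -> list[tuple[str, str]]:
        """Per-SNP (major, minor) pair from pool-implied allele frequencies."""
        out = []
        freqs = self.frequencies
        for j in range(self.n_snps):
            tally: dict[str, float] = {}
            for (h, f) in self.haplotypes:
                tally[h[j]] = tally.get(h[j], 0.0) + f
            if len(tally) == 1:
                a = next(iter(tally))
                out.append((a, next(x for x in "ACGT" if x != a)))
                continue
            if len(tally) > 2:
                raise SimulationError(f"{self.gene} SNP {j}: >2 alleles in pool")
            (a1, f1), (a2, f2) = sorted(tally.items())
            minor, major = (a1, a2) if (f1, a1) < (f2, a2) else (a2, a1)
            out.append((major, minor))
        return out

    def minor_matrix(self) -> np.ndarray:
        """H x m indicator of the minor allele per haplotype per SNP."""
        alleles = self.snp_alleles()
        return np.array([[1 if h[j] == alleles[j][1] else 0
                          for j in range(self.n_snps)]
                         for h, _ in self.haplotypes], dtype=np.int8)

    def snp_meta(self) -> list[SnpMeta]:
        return [SnpMeta(r, gene=self.gene, chrom_band=self.chrom_band,
                        position_index=j, alleles=al)
                for j, (r, al) in enumerate(zip(self.rsids, self.snp_alleles()))]


def product_pool(gene: str, blocks: Sequence[HaplotypePool],
                 chrom_band: str = "") -> HaplotypePool:
    """Combine independent block pools into one full-gene pool.

    LD exists only within blocks; across blocks haplotypes combine at
    linkage equilibrium (frequencies multiply).
    """
    haps = [("", 1.0)]
    rsids: list[str] = []
    for blk in blocks:
        rsids.extend(blk.rsids)
        haps = [(h + bh, f * bf) for h, f in haps for bh, bf in blk.haplotypes]
    return HaplotypePool(gene, haps, rsids=rsids, chrom_band=chrom_band)


def random_block_pool(rng: np.random.Generator, gene: str, n_snps: int,
                      rsids: Sequence[str] | None = None,
                      min_maf: float = 0.055, max_haps: int = 6) -> HaplotypePool:
    """Draw a random block pool whose every SNP has MAF >= ``min_maf``."""
    letters = [tuple(rng.choice(list("ACGT"), size=2, replace=False))
               for _ in range(n_snps)]
    n_haps = int(min(max_haps, max(3, n_snps + 1), 2 ** n_snps))
    for _ in range(500):
        codes = rng.integers(0, 2, size=(n_haps, n_snps))
        if len({tuple(c) for c in codes}) < n_haps:
            continue
        freqs = rng.dirichlet(np.full(n_haps, 1.5))
        if freqs.min() < 0.02:
            continue
        af = freqs @ codes
        if ((af < min_maf) | (af > 1 - min_maf)).any():
            continue
        haps = ["".join(letters[j][c] for j, c in enumerate(row)) for row in codes]
        return HaplotypePool(gene, list(zip(haps, freqs / freqs.sum())),
                             rsids=list(rsids) if rsids else [])
    raise SimulationError(f"{gene}: could not draw a valid block pool")


def sample_diplotypes(pool: HaplotypePool, n: int,
                      seed: int | np.random.Generator) -> np.ndarray:
    """Draw n ordered haplotype-index pairs under random mating (HWE)."""
    if n <= 0:
        raise SimulationError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.choice(len(pool.haplotypes), size=(n, 2), p=pool.frequencies)


# ---------------------------------------------------------------------------
# disease model and configuration
# ---------------------------------------------------------------------------

@dataclass
class DiseaseModel:
    """Logistic disease model, additive in haplotype copy number.

    ``hap_log_or`` maps (gene, haplotype string) -> per-copy log odds ratio;
    haplotypes absent from the mapping (including each gene's reference)
    have effect 0.  ``interaction`` optionally adds an extra per-copy log-OR
    for one haplotype among subjects in a named vegetable-intake stratum.
    """

    intercept: float = -0.5
    hap_log_or: dict[tuple[str, str], float] = field(default_factory=dict)
    age_per_year: float = 0.0
    sex_log_or: float = 0.0
    center_log_or: dict[str, float] = field(default_factory=dict)
    interaction: tuple[str, str, str, float] | None = None  # gene, hap, stratum, extra


#: Vegetable-intake frequency score distribution (servings/week-ish, 0..18):
#: Binomial(18, 0.45).  Population tertile cut-points derive from its CDF.
VEG_SCORE_N, VEG_SCORE_P = 18, 0.45


def veg_tertile_cutpoints() -> tuple[int, int]:
    d = stats.binom(VEG_SCORE_N, VEG_SCORE_P)
    return int(d.ppf(1 / 3)), int(d.ppf(2 / 3))


def veg_stratum(score: np.ndarray) -> np.ndarray:
    """Population-tertile stratum labels (low/medium/high) for veg scores."""
    c1, c2 = veg_tertile_cutpoints()
    return np.where(score <= c1, "low", np.where(score <= c2, "medium", "high"))


@dataclass
class SimulationConfig:
    n_cases: int
    n_controls: int
    pools: list[HaplotypePool]
    model: DiseaseModel
    center_probs: dict[str, float] = field(default_factory=dict)
    age_mean: float = 59.5
    age_sd: float = 10.4
    age_range: tuple[float, float] = (20.0, 79.0)
    p_male: float = 0.61
    missingness: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missingness < 1:
            raise SimulationError("missingness must be in [0,1)")
        if self.center_probs:
            tot = sum(self.center_probs.values())
            if abs(tot - 1.0) > 1e-9:
                raise SimulationError("center probabilities must sum to 1")

    def gene_map(self) -> GeneRegionMap:
        return GeneRegionMap({p.gene: list(p.rsids) for p in self.pools})


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    seed: int
    model: DiseaseModel
    diplotypes: dict[str, np.ndarray]      # gene -> (n, 2) haplotype indices
    pools: dict[str, HaplotypePool]

    def write(self, path: str | Path) -> None:
        rows = []
        for gene, dip in self.diplotypes.items():
            haps = [h for h, _ in self.pools[gene].haplotypes]
            for i in range(dip.shape[0]):
                rows.append((i, gene, haps[dip[i, 0]], haps[dip[i, 1]]))
        pd.DataFrame(rows, columns=["subject_index", "gene", "hap1", "hap2"]) \
            .to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

_SMOKING_P = (0.41, 0.24, 0.35)
_BMI_P = (0.34, 0.42, 0.24)


def _draw_covariates(rng: np.random.Generator, n: int,
                     cfg: SimulationConfig) -> pd.DataFrame:
    centers = list(cfg.center_probs) or ["C1"]
    probs = np.array([cfg.center_probs.get(c, 1.0) for c in centers])
    probs = probs / probs.sum()
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), *cfg.age_range)
    return pd.DataFrame({
        "age": np.round(age, 1),
        "sex": rng.binomial(1, cfg.p_male, n),
        "center": rng.choice(centers, size=n, p=probs),
        "bmi_class": rng.choice(["<25", "25-30", ">30"], size=n, p=_BMI_P),
        "smoking": rng.choice(["never", "former", "current"], size=n, p=_SMOKING_P),
        "hypertension": rng.binomial(1, 0.40, n),
        "family_history": rng.binomial(1, 0.30, n),
        "vegetable_freq": rng.binomial(VEG_SCORE_N, VEG_SCORE_P, n),
        "alcohol_freq": rng.binomial(1, 0.76, n) * (1 + rng.binomial(13, 0.4, n)),
    })


def _hap_copies(pool: HaplotypePool, dip: np.ndarray, hap: str) -> np.ndarray:
    """Per-subject copies of an effect haplotype.

    ``hap`` may name a full gene haplotype or the leading block of one
    (effect haplotypes refer to the gene's first LD block), in which case
    every pool haplotype sharing that prefix counts."""
    idx = np.array([i for i, (hstr, _) in enumerate(pool.haplotypes)
                    if hstr.startswith(hap)])
    if idx.size == 0:
        raise SimulationError(f"{pool.gene}: no pool haplotype matches {hap!r}")
    return np.isin(dip, idx).sum(axis=1)


def _risk_linear_predictor(cov: pd.DataFrame, dips: dict[str, np.ndarray],
                           pools: Mapping[str, HaplotypePool],
                           model: DiseaseModel) -> np.ndarray:
    n = len(cov)
    eta = np.full(n, model.intercept, dtype=float)
    eta += model.age_per_year * (cov["age"].to_numpy() - 60.0)
    eta += model.sex_log_or * cov["sex"].to_numpy()
    if model.center_log_or:
        eta += np.array([model.center_log_or.get(c, 0.0) for c in cov["center"]])
    for (gene, hap), beta in model.hap_log_or.items():
        if beta == 0.0 or gene not in dips:
            continue
        eta += beta * _hap_copies(pools[gene], dips[gene], hap)
    if model.interaction is not None:
        gene, hap, stratum, extra = model.interaction
        if extra != 0.0 and gene in dips:
            copies = _hap_copies(pools[gene], dips[gene], hap)
            in_stratum = veg_stratum(cov["vegetable_freq"].to_numpy()) == stratum
            eta += extra * copies * in_stratum
    return eta


def simulate_cohort(cfg: SimulationConfig,
                    ) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Simulate a frequency-matched case-control cohort.

    Cases are sampled from the population until ``n_cases`` are obtained
    (Bernoulli disease status from the logistic model); control covariates
    for the matching factors (age, sex, center) are resampled jointly from
    the realized case distribution, approximating frequency matching, and
    controls are retained on status 0.  Genotypes are the per-SNP sums of
    the two sampled haplotypes in minor-allele coding with MCAR missingness.
    """
    rng = np.random.default_rng(cfg.seed)
    pools = {p.gene: p for p in cfg.pools}
    effect_genes = {g for (g, _h), b in cfg.model.hap_log_or.items() if b != 0.0}
    if cfg.model.interaction is not None and cfg.model.interaction[3] != 0.0:
        effect_genes.add(cfg.model.interaction[0])

    def _collect(n_needed: int, want_case: bool,
                 match_from: pd.DataFrame | None) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
        got_cov: list[pd.DataFrame] = []
        got_dip: dict[str, list[np.ndarray]] = {g: [] for g in effect_genes}
        total = 0
        for attempt in range(60):
            batch = max(2000, int(1.5 * (n_needed - total)))
            cov = _draw_covariates(rng, batch, cfg)
            if match_from is not None:
                take = rng.integers(0, len(match_from), batch)
                for colname in ("age", "sex", "center"):
                    cov[colname] = match_from[colname].to_numpy()[take]
            dips = {g: sample_diplotypes(pools[g], batch, rng) for g in effect_genes}
            eta = _risk_linear_predictor(cov, dips, pools, cfg.model)
            y = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
            keep = y if want_case else ~y
            if keep.any():
                got_cov.append(cov.loc[keep].reset_index(drop=True))
                for g in effect_genes:
                    got_dip[g].append(dips[g][keep])
                total += int(keep.sum())
            if total >= n_needed:
                cov_all = pd.concat(got_cov, ignore_index=True).iloc[:n_needed]
                dip_all = {g: np.concatenate(got_dip[g])[:n_needed]
                           for g in effect_genes}
                return cov_all, dip_all
        raise SimulationError(
            f"could not reach {n_needed} {'cases' if want_case else 'controls'} "
            f"after {attempt + 1} batches; check the disease model")

    case_cov, case_dip = _collect(cfg.n_cases, True, None)
    ctrl_cov, ctrl_dip = _collect(cfg.n_controls, False, case_cov)

    cov = pd.concat([case_cov, ctrl_cov], ignore_index=True)
    n = len(cov)
    status = np.r_[np.ones(cfg.n_cases, int), np.zeros(cfg.n_controls, int)]

    # non-effect genes are independent of status: sample once for everyone
    diplotypes: dict[str, np.ndarray] = {}
    for p in cfg.pools:
        if p.gene in effect_genes:
            diplotypes[p.gene] = np.concatenate(
                [case_dip[p.gene], ctrl_dip[p.gene]])
        else:
            diplotypes[p.gene] = sample_diplotypes(p, n, rng)

    blocks = []
    snps: list[SnpMeta] = []
    for p in cfg.pools:
        minor = p.minor_matrix()
        dip = diplotypes[p.gene]
        blocks.append(minor[dip[:, 0]] + minor[dip[:, 1]])
        snps.extend(p.snp_meta())
    values = np.concatenate(blocks, axis=1).astype(np.int8)
    if cfg.missingness > 0:
        mask = rng.random(values.shape) < cfg.missingness
        values[mask] = MISSING

    ids = [f"S{i:05d}" for i in range(n)]
    subjects = pd.DataFrame({"id": ids, "status": status})
    subjects = pd.concat([subjects, cov], axis=1)
    subjects["country"] = subjects["center"]
    subjects = validate_subjects(subjects)

    gm = GenotypeMatrix(values, snps, ids)
    gm = apply_gene_map(gm, cfg.gene_map())
    truth = SimTruth(cfg.seed, cfg.model, diplotypes, pools)
    return gm, subjects, truth


# ---------------------------------------------------------------------------
# study-scale default configuration
# ---------------------------------------------------------------------------

#: Tag-SNP counts per gene region (totalling 163 across 13 regions).
GENE_SNP_COUNTS: dict[str, int] = {
    "SLC19A1": 6, "MTHFR": 8, "BHMT": 13, "MTR": 9, "GGH": 6,
    "ALDH1L1": 30, "CBS": 17, "FOLR1": 6, "MTRR": 20, "SHMT1": 10,
    "TYMS": 12, "CTH": 12, "GSS": 14,
}

_CHROM_BAND = {
    "SLC19A1": "21q22.3", "MTHFR": "1p36.3", "BHMT": "5q13.1-q15",
    "MTR": "1q43", "GGH": "8q12.3", "ALDH1L1": "3q21.3", "CBS": "21q22.3",
    "FOLR1": "11q13.4", "MTRR": "5p15.31", "SHMT1": "17p11.2",
    "TYMS": "18p11.32", "CTH": "1p31.1", "GSS": "20q11.22",
}

#: Centre sampling probabilities (realized case proportions of the emulated
#: study; controls are frequency-matched to cases so share them).
CENTER_PROBS = {"Bucharest": 0.0875, "Lodz": 0.1030,
                "Moscow": 0.3115, "CzechRepublic": 0.4980}

#: Control-frequency pool for the 4-SNP SLC19A1 risk block; the A-C-C-C
#: haplotype (6.4%) is the planted risk haplotype.
RISK_BLOCK_RSIDS = ["rs12483553", "rs2838950", "rs2838951", "rs17004785"]
RISK_HAPLOTYPE = "ACCC"


def slc19a1_pool() -> HaplotypePool:
    block1 = HaplotypePool("SLC19A1", [
        ("GCGG", 0.438), ("ACCC", 0.064), ("GCCG", 0.210),
        ("GTCG", 0.242), ("ACCG", 0.026), ("GCGC", 0.020),
    ], rsids=RISK_BLOCK_RSIDS)
    block2 = HaplotypePool("SLC19A1", [
        ("AA", 0.55), ("AG", 0.20), ("GA", 0.15), ("GG", 0.10),
    ], rsids=["rs914232", "rs914238"])
    return product_pool("SLC19A1", [block1, block2],
                        chrom_band=_CHROM_BAND["SLC19A1"])


def mthfr_pool() -> HaplotypePool:
    # 5-SNP block with control haplotype frequencies; 1.3% residual rare hap
    block1 = HaplotypePool("MTHFR", [
        ("GTCGA", 0.302), ("TCTAA", 0.176), ("TCCGA", 0.101),
        ("GCCGG", 0.244), ("GCCGA", 0.070), ("GCCAA", 0.094),
        ("TCCAA", 0.013),
    ], rsids=["rs12121543", "rs1801133", "rs17421511", "rs11121832", "rs9651118"])
    block2 = HaplotypePool("MTHFR", [
        ("CTA", 0.40), ("CTG", 0.25), ("TTA", 0.20), ("CCA", 0.15),
    ], rsids=["rs4846048", "rs1476413", "rs6541003"])
    return product_pool("MTHFR", [block1, block2],
                        chrom_band=_CHROM_BAND["MTHFR"])


def _generic_pool(rng: np.random.Generator, gene: str, n_snps: int,
                  gene_index: int = 0) -> HaplotypePool:
    sizes = []
    left = n_snps
    while left > 0:
        k = int(min(left, rng.integers(3, 6)))
        if left - k == 1:           # avoid a trailing 1-SNP block
            k -= 1
        sizes.append(k)
        left -= k
    blocks = []
    start = 0
    for k in sizes:
        rsids = [f"rs9{gene_index:02d}{start + j:03d}" for j in range(k)]
        # pool MAF floor 0.075 keeps sampled control MAFs >= 5% at study n
        blocks.append(random_block_pool(rng, gene, k, rsids=rsids,
                                        min_maf=0.075))
        start += k
    return product_pool(gene, blocks, chrom_band=_CHROM_BAND.get(gene, ""))


#: Fixed stream for the *structure* of the default study (pool shapes are a
#: property of the emulated population, not of any one simulated cohort).
_POOL_STRUCTURE_SEED = 20111019


def default_pools() -> list[HaplotypePool]:
    rng = np.random.default_rng(_POOL_STRUCTURE_SEED)
    pools: list[HaplotypePool] = []
    for gi, (gene, m) in enumerate(GENE_SNP_COUNTS.items()):
        if gene == "SLC19A1":
            pools.append(slc19a1_pool())
        elif gene == "MTHFR":
            pools.append(mthfr_pool())
        else:
            pools.append(_generic_pool(rng, gene, m, gene_index=gi))
    return pools


def default_disease_model(risk_or: float = 1.37,
                          low_veg_or: float = 1.9) -> DiseaseModel:
    """Study disease model: marginal per-copy OR ~``risk_or`` for the
    SLC19A1 A-C-C-C haplotype, amplified to ``low_veg_or`` in the lowest
    vegetable-intake tertile (main effect solves
    exp((log low + 2 log main)/3) = marginal over three equal strata)."""
    main = (3.0 * np.log(risk_or) - np.log(low_veg_or)) / 2.0
    return DiseaseModel(
        intercept=-0.6,
        hap_log_or={("SLC19A1", RISK_HAPLOTYPE): main},
        age_per_year=0.005,
        sex_log_or=0.05,
        center_log_or={"Lodz": -0.15, "Moscow": 0.05, "CzechRepublic": 0.1},
        interaction=("SLC19A1", RISK_HAPLOTYPE, "low", np.log(low_veg_or) - main),
    )


def default_study_config(seed: int = 0) -> SimulationConfig:
    """The full 13-gene / 163-SNP, 777-case / 1,035-control study config."""
    return SimulationConfig(
        n_cases=777, n_controls=1035,
        pools=default_pools(),
        model=default_disease_model(),
        center_probs=dict(CENTER_PROBS),
        missingness=0.02,
        seed=seed,
    )


def single_gene_config(seed: int = 0, risk_log_or: float = float(np.log(1.37)),
                       interaction_extra: float | None = None,
                       n_cases: int = 777, n_controls: int = 1035,
                       missingness: float = 0.02) -> SimulationConfig:
    """SLC19A1-only config for targeted experiments.

    With ``interaction_extra`` None the planted effect is homogeneous
    (per-copy log-OR ``risk_log_or``); otherwise the effect is
    ``risk_log_or`` everywhere plus ``interaction_extra`` in the low
    vegetable tertile (pass ``risk_log_or=0`` for a low-tertile-only effect).
    """
    model = DiseaseModel(
        intercept=-0.6,
        hap_log_or={("SLC19A1", RISK_HAPLOTYPE): risk_log_or},
        age_per_year=0.005, sex_log_or=0.05,
        center_log_or={"Lodz": -0.15, "Moscow": 0.05, "CzechRepublic": 0.1},
        interaction=None if interaction_extra is None else
        ("SLC19A1", RISK_HAPLOTYPE, "low", interaction_extra),
    )
    return SimulationConfig(
        n_cases=n_cases, n_controls=n_controls,
        pools=[slc19a1_pool()], model=model,
        center_probs=dict(CENTER_PROBS), missingness=missingness, seed=seed,
    )


def null_config(seed: int = 0, n_genes: int = 1, snps_per_gene: int = 3,
                n_cases: int = 777, n_controls: int = 1035,
                missingness: float = 0.02) -> SimulationConfig:
    """Config with no genetic effects, for calibration experiments."""
    rng = np.random.default_rng(_POOL_STRUCTURE_SEED + 1)
    pools = [_generic_pool(rng, f"NULL{g:03d}", snps_per_gene, gene_index=g + 13)
             for g in range(n_genes)]
    model = DiseaseModel(intercept=-0.4, age_per_year=0.005, sex_log_or=0.05,
                         center_log_or={"Moscow": 0.05, "CzechRepublic": 0.1})
    return SimulationConfig(n_cases=n_cases, n_controls=n_controls,
                            pools=pools, model=model,
                            center_probs=dict(CENTER_PROBS),
                            missingness=missingness, seed=seed)
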