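"""Synthetic open-pollinated half-sib multi-site progeny trials.

The generator emulates a conifer progeny test: a set of open-pollinated
(maternal half-sib) families planted across several sites in randomized
blocks, genotyped at biallelic SNPs with GBS-style heterogeneous
missingness, and phenotyped for traits with a purely additive architecture
plus site×genotype interaction.

Gene dropping: each family has one mother drawn from Hardy–Weinberg
proportions at the ancestral allele frequency; every offspring receives one
random maternal allele and one allele from an unrelated pollen pool at the
ancestral frequency.  An optional ``fullsib_fraction`` sires that share of
each family's offspring by a single hidden father, creating the pedigree
violations that inflate pedigree-based heritability.

Genotype-by-environment interaction is produced by giving every site its
own QTL-effect vector; vectors for two sites correlate at ``type_b_target``,
so the across-site (type-b) additive genetic correlation is known by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

#: measurement traits and rough real-world scales (mean, sd) used to place
#: synthetic phenotypes on plausible units
TRAIT_SCALES = {
    "HT": (20.0, 2.0),        # height, m
    "DBH": (25.0, 4.0),       # diameter at breast height, cm
    "V_Dir": (4.0, 0.3),      # acoustic velocity, km/s
    "WD_Res": (300.0, 30.0),  # drilling resistance, arbitrary units
    "WD_X-ray": (400.0, 35.0) # X-ray wood density, kg/m3
}
PRIMARY_TRAITS = tuple(TRAIT_SCALES)

#: genetic correlations among the primary traits: growth traits positively
#: correlated, wood-density traits positively correlated with each other and
#: antagonistic (negative) to growth — the classic wood-quality trade-off
TRAIT_CORR = pd.DataFrame(
    [
        [1.0, 0.7, 0.1, -0.4, -0.4],
        [0.7, 1.0, 0.1, -0.4, -0.4],
        [0.1, 0.1, 1.0, 0.3, 0.3],
        [-0.4, -0.4, 0.3, 1.0, 0.8],
        [-0.4, -0.4, 0.3, 0.8, 1.0],
    ],
    index=PRIMARY_TRAITS,
    columns=PRIMARY_TRAITS,
)


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """Configuration of a synthetic half-sib multi-site trial.

    Defaults give the "paper-like" preset: 25 open-pollinated families on
    3 sites with 10 trees per family per site (750 trees, family size 30)
    over 4 blocks per site, 30% GBS missingness.
    """

    n_families: int = 25
    n_offspring_per_family_site: int = 10
    n_sites: int = 3
    n_blocks_per_site: int = 4
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 300
    h2_target: float = 0.25
    type_b_target: float = 0.7
    block_var_fraction: float = 0.05
    missing_rate: float = 0.30
    fullsib_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_families", "n_offspring_per_family_site", "n_sites",
                     "n_blocks_per_site", "n_snps", "n_qtl"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not 0.0 <= self.h2_target <= 1.0:
            raise ConfigError(f"h2_target must be in [0, 1], got {self.h2_target}")
        if not -1.0 <= self.type_b_target <= 1.0:
            raise ConfigError(f"type_b_target must be in [-1, 1], got {self.type_b_target}")
        if not 0.0 <= self.block_var_fraction < 1.0:
            raise ConfigError(f"block_var_fraction must be in [0, 1), got {self.block_var_fraction}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not 0.0 <= self.fullsib_fraction <= 1.0:
            raise ConfigError(f"fullsib_fraction must be in [0, 1], got {self.fullsib_fraction}")
        if self.n_qtl > self.n_snps:
            raise ConfigError(f"n_qtl ({self.n_qtl}) exceeds n_snps ({self.n_snps})")
        if self.n_sites > 1:
            # equicorrelated site covariance must stay positive semidefinite
            min_rho = -1.0 / (self.n_sites - 1)
            if self.type_b_target < min_rho:
                raise ConfigError(
                    f"type_b_target {self.type_b_target} below PSD bound {min_rho:.3f} "
                    f"for {self.n_sites} sites"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(**raw)


@dataclass
class TruthRecord:
    """Ground truth behind one simulated trial, for recovery tests."""

    true_breeding_values: dict  # trait -> (n_individuals × n_sites) array
    qtl_indices: np.ndarray
    qtl_effects: dict           # trait -> (n_qtl × n_sites) array
    variance_components_true: dict  # trait -> {sigma2_a, sigma2_sb, sigma2_sa, sigma2_e}
    individual_ids: list[str]
    site_names: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "qtl_indices": self.qtl_indices.tolist(),
            "individual_ids": self.individual_ids,
            "site_names": self.site_names,
            "true_breeding_values": {
                t: v.tolist() for t, v in self.true_breeding_values.items()
            },
            "qtl_effects": {t: v.tolist() for t, v in self.qtl_effects.items()},
            "variance_components_true": self.variance_components_true,
        }
        Path(path).write_text(json.dumps(payload))


def simulate_pedigree(config: SimConfig) -> pd.DataFrame:
    """Lay out the trial design: one row per tree with family, site, block.

    Trees within a family×site cell are spread over the site's blocks
    round-robin, mirroring the randomized-block sampling of field trials.
    """
    rows = []
    for s in range(config.n_sites):
        site = f"site{s + 1}"
        for f in range(config.n_families):
            fam = f"fam{f + 1:02d}"
            for k in range(config.n_offspring_per_family_site):
                block = f"{site}_b{k % config.n_blocks_per_site + 1}"
                rows.append(
                    {
                        "individual": f"{fam}_{site}_t{k + 1:02d}",
                        "family": fam,
                        "site": site,
                        "block": block,
                    }
                )
    return pd.DataFrame(rows)


def simulate_genotypes(pedigree: pd.DataFrame, config: SimConfig) -> GenotypeMatrix:
    """Gene-drop complete genotypes down the half-sib pedigree.

    Returns an additive-coded matrix with no missing entries; apply
    :func:`apply_missingness` for GBS-like sparsity.
    """
    if pedigree.empty:
        raise ConfigError("pedigree is empty")
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    p = rng.uniform(*config.maf_range, size=m)
    # randomly orient: "A" allele frequency may sit on either side of 0.5
    flip = rng.random(m) < 0.5
    p = np.where(flip, 1.0 - p, p)

    families = pedigree["family"].drop_duplicates().tolist()
    mother_alleles = {
        f: (rng.random((2, m)) < p).astype(np.int8) for f in families
    }
    father_alleles = {
        f: (rng.random((2, m)) < p).astype(np.int8) for f in families
    }

    codes = np.empty((len(pedigree), m), dtype=float)
    fam_arr = pedigree["family"].to_numpy()
    for f in families:
        pos = np.flatnonzero(fam_arr == f)
        k = pos.size
        pick = rng.integers(0, 2, size=(k, m))
        maternal = np.where(pick == 0, mother_alleles[f][0], mother_alleles[f][1])
        pollen = (rng.random((k, m)) < p).astype(np.int8)
        if config.fullsib_fraction > 0:
            is_fs = rng.random(k) < config.fullsib_fraction
            if is_fs.any():
                fpick = rng.integers(0, 2, size=(int(is_fs.sum()), m))
                paternal_fs = np.where(
                    fpick == 0, father_alleles[f][0], father_alleles[f][1]
                )
                pollen[is_fs] = paternal_fs
        codes[pos] = maternal + pollen - 1.0

    snp_ids = [f"snp{j + 1:05d}" for j in range(m)]
    return GenotypeMatrix(
        codes,
        pedigree["individual"].astype(str).tolist(),
        snp_ids,
        pedigree["family"].astype(str).tolist(),
    )


def _site_trait_effects(config: SimConfig, n_traits: int, rng: np.random.Generator) -> np.ndarray:
    """QTL effects of shape (n_qtl, n_traits, n_sites) with cross-site
    correlation type_b_target and the preset cross-trait correlations."""
    s, t, q = config.n_sites, n_traits, config.n_qtl
    rho = config.type_b_target
    c_site = np.full((s, s), rho)
    np.fill_diagonal(c_site, 1.0)
    c_trait = TRAIT_CORR.to_numpy()[:t, :t]
    cov = np.kron(c_trait, c_site)
    # tiny jitter guards the Cholesky at rho = 1 or perfect trait correlation
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
    z = rng.standard_normal((q, t * s))
    eff = z @ chol.T
    return eff.reshape(q, t, s)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    pedigree: pd.DataFrame,
    config: SimConfig,
    traits: tuple[str, ...] = PRIMARY_TRAITS,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Build phenotypes = site mean + block effect + site-specific genetic
    value + residual, calibrated so the within-site narrow-sense
    heritability equals ``h2_target`` in expectation.

    Also derives VOL (from HT and DBH) and MoE_d (density × velocity²) when
    their parent traits are simulated.
    """
    unknown = set(traits) - set(PRIMARY_TRAITS)
    if unknown:
        raise ConfigError(f"unknown traits {sorted(unknown)}; choose from {PRIMARY_TRAITS}")
    rng = np.random.default_rng(config.seed + 1)
    n = genotypes.n_individuals
    qtl = rng.choice(config.n_snps, size=config.n_qtl, replace=False)
    qtl = np.sort(qtl)
    effects = _site_trait_effects(config, len(traits), rng)  # (q, t, s)
    wq = genotypes.values[:, qtl]  # raw codes at QTL
    wq = wq - wq.mean(axis=0)

    sites = pedigree["site"].drop_duplicates().tolist()
    site_of = pedigree["site"].to_numpy()
    blocks = pedigree["block"].to_numpy()

    pheno = pedigree[["individual", "family", "site", "block"]].copy()
    tbv: dict[str, np.ndarray] = {}
    qtl_eff: dict[str, np.ndarray] = {}
    vc_true: dict[str, dict] = {}

    for ti, trait in enumerate(traits):
        g_all = wq @ effects[:, ti, :]  # (n, n_sites): BV of each tree at each site
        if config.h2_target == 0.0:
            g_all = np.zeros_like(g_all)
        # realized genetic variance within each site's trees, at their own site
        g_own = g_all[np.arange(n), [sites.index(s) for s in site_of]]
        per_site_var = [
            np.var(g_own[site_of == s]) for s in sites if (site_of == s).sum() > 1
        ]
        sigma2_g = float(np.mean(per_site_var)) if per_site_var else float(np.var(g_own))
        if config.h2_target == 0.0:
            sigma2_e = 1.0
        elif config.h2_target == 1.0:
            sigma2_e = 0.0
        else:
            sigma2_e = sigma2_g * (1.0 - config.h2_target) / config.h2_target
        sigma2_p = sigma2_g + sigma2_e
        bvf = config.block_var_fraction
        sigma2_b = sigma2_p * bvf / (1.0 - bvf) if bvf > 0 else 0.0

        block_levels = pd.unique(blocks)
        block_eff = dict(
            zip(block_levels, rng.normal(0.0, np.sqrt(sigma2_b), size=len(block_levels)))
        )
        site_means = {
            s: 0.5 * np.sqrt(sigma2_p) * i for i, s in enumerate(sites)
        }
        resid = rng.normal(0.0, np.sqrt(sigma2_e), size=n)
        raw = (
            np.array([site_means[s] for s in site_of])
            + np.array([block_eff[b] for b in blocks])
            + g_own
            + resid
        )
        mean_t, sd_t = TRAIT_SCALES[trait]
        scale = sd_t / np.sqrt(sigma2_p) if sigma2_p > 0 else 1.0
        pheno[trait] = mean_t + raw * scale

        rho = config.type_b_target
        tbv[trait] = g_all * scale
        qtl_eff[trait] = effects[:, ti, :] * scale
        vc_true[trait] = {
            "sigma2_a": float(max(rho, 0.0) * sigma2_g * scale**2),
            "sigma2_sb": float(sigma2_b * scale**2),
            "sigma2_sa": float((1.0 - max(rho, 0.0)) * sigma2_g * scale**2),
            "sigma2_e": float(sigma2_e * scale**2),
        }

    if "HT" in pheno.columns and "DBH" in pheno.columns:
        pheno["VOL"] = 3e-5 * pheno["DBH"] ** 2 * pheno["HT"]
    if "WD_X-ray" in pheno.columns and "V_Dir" in pheno.columns:
        pheno["MoE_d"] = pheno["WD_X-ray"] * pheno["V_Dir"] ** 2 / 1000.0

    truth = TruthRecord(
        true_breeding_values=tbv,
        qtl_indices=qtl,
        qtl_effects=qtl_eff,
        variance_components_true=vc_true,
        individual_ids=list(genotypes.individual_ids),
        site_names=sites,
    )
    return pheno, truth


def apply_missingness(
    genotypes: GenotypeMatrix, rate: float, seed: int
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Knock out entries GBS-style: per-SNP missing rates are heterogeneous
    (Beta-distributed around ``rate``) while the overall missing fraction
    stays within ±1% of ``rate``.

    Returns the masked matrix and the boolean mask of newly missing cells,
    so masking-based imputation accuracy can be scored against the original.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missing rate must be in [0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    out = genotypes.copy()
    n, m = out.values.shape
    if rate == 0.0:
        return out, np.zeros((n, m), dtype=bool)
    conc = 6.0
    snp_rates = rng.beta(conc * rate, conc * (1.0 - rate), size=m)
    snp_rates *= rate / snp_rates.mean()
    snp_rates = np.clip(snp_rates, 0.0, 0.95)
    # renormalize after clipping so the expectation stays on target
    snp_rates *= rate / snp_rates.mean()
    snp_rates = np.clip(snp_rates, 0.0, 0.95)
    mask = rng.random((n, m)) < snp_rates
    out.values[mask] = np.nan
    return out, mask


def simulate_trial(
    config: SimConfig, traits: tuple[str, ...] = PRIMARY_TRAITS
) -> tuple[pd.DataFrame, GenotypeMatrix, GenotypeMatrix, np.ndarray, pd.DataFrame, TruthRecord]:
    """One-call convenience: pedigree, complete genotypes, masked genotypes
    with their mask, phenotypes and truth."""
    ped = simulate_pedigree(config)
    geno = simulate_genotypes(ped, config)
    pheno, truth = simulate_phenotypes(geno, ped, config, traits)
    masked, mask = apply_missingness(geno, config.missing_rate, config.seed + 2)
    return ped, geno, masked, mask, pheno, truth
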