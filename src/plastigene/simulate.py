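"""Synthetic factorial expression experiments and haplotype matrices.

The generator emulates a split-brood factorial design: full-sib families
reared in two seasonal environments (dry / wet rearing temperature) crossed
with two developmental food treatments (ad-libitum control / food stress).
Counts are drawn from a negative binomial whose log2 mean is an additive
combination of season, food, family and family-by-season (GxE) effects, so
every downstream inference stage has an exact ground truth to recover.

Haplotype matrices with a tunable site-frequency spectrum provide ground
truth for the nucleotide-diversity statistics: a 1/i spectrum matches the
neutral coalescent expectation, a 1/i^2 spectrum gives an excess of rare
alleles (negative Tajima's D), and a uniform spectrum an excess of
intermediate-frequency alleles (positive D).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SEASONS = ("dry", "wet")
FOODS = ("control", "stress")

#: season/food treatment coding used throughout: effects are half-applied to
#: each level so the wet-minus-dry (stress-minus-control) log2 difference
#: equals the stored effect and the baseline is the grand mean.
_SEASON_CODE = {"dry": -0.5, "wet": 0.5}
_FOOD_CODE = {"control": -0.5, "stress": 0.5}


class ConfigurationError(ValueError):
    """Invalid simulation parameters."""


@dataclass
class SimulationParams:
    """Parameters of the factorial count simulation.

    Defaults describe the reference experiment: seven full-sib families,
    three replicate females per family x season x food cell for four
    families and two for the remaining three (72 samples per tissue), with
    roughly 46% of genes season-affected, 50% family-affected, 5%
    food-affected and 1% carrying a family-by-season interaction.

    Effect scales are log2 units: season and food effects of affected
    genes have magnitude exactly ``sigma_season``/``sigma_food`` with
    random sign, while family and interaction effect vectors are drawn
    N(0, sigma) and centered to sum to zero. ``dispersion``
    is the negative-binomial dispersion (variance = mu + dispersion*mu^2);
    values <= 0 fall back to Poisson noise. Library sizes are lognormal
    with mean ``library_size_mean`` expected counts and coefficient of
    variation ``library_size_cv``.
    """

    n_genes: int = 2000
    n_families: int = 7
    reps_per_cell: Mapping[str, int] | int | None = None
    frac_season: float = 0.46
    frac_family: float = 0.50
    frac_food: float = 0.05
    frac_gxe: float = 0.01
    sigma_season: float = 1.0
    sigma_family: float = 1.0
    sigma_food: float = 0.5
    sigma_gxe: float = 0.5
    dispersion: float = 0.05
    baseline_log_sd: float = 1.2
    library_size_mean: float = 5e5
    library_size_cv: float = 0.2
    tissue: str = "abdomen"
    seed: int = 0

    def family_ids(self) -> list[str]:
        return [f"F{i + 1}" for i in range(self.n_families)]

    def reps_mapping(self) -> dict[str, int]:
        fams = self.family_ids()
        reps = self.reps_per_cell
        if reps is None:
            if self.n_families == 7:
                # four families with three females per cell, three with two
                return {f: (3 if i < 4 else 2) for i, f in enumerate(fams)}
            return {f: 3 for f in fams}
        if isinstance(reps, int):
            return {f: reps for f in fams}
        mapping = dict(reps)
        missing = [f for f in fams if f not in mapping]
        if missing:
            raise ConfigurationError(f"reps_per_cell missing families: {missing}")
        return {f: int(mapping[f]) for f in fams}

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")
        for name in ("frac_season", "frac_family", "frac_food", "frac_gxe"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} not in [0, 1]")
        for name in ("sigma_season", "sigma_family", "sigma_food", "sigma_gxe"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if any(r < 1 for r in self.reps_mapping().values()):
            raise ConfigurationError("every family needs >= 1 replicate per cell")
        if self.library_size_mean <= 0:
            raise ConfigurationError("library_size_mean must be > 0")


def simulate_design(params: SimulationParams) -> pd.DataFrame:
    """Lay out the split-brood factorial sample sheet.

    Returns one row per sample (index = sample id) with columns
    ``family``, ``season``, ``food``, ``tissue``. Each family contributes
    ``reps`` samples to every season x food cell, so the design is balanced
    within family. Deterministic: no randomness is involved.
    """
    params.validate()
    reps = params.reps_mapping()
    rows = []
    for fam in params.family_ids():
        for season in SEASONS:
            for food in FOODS:
                for r in range(reps[fam]):
                    sid = f"{fam}_{season}_{food}_{r + 1}"
                    rows.append((sid, fam, season, food, params.tissue))
    design = pd.DataFrame(
        rows, columns=["sample", "family", "season", "food", "tissue"]
    ).set_index("sample")
    return design


def _centered_effects(rng: np.random.Generator, n: int, k: int, sigma: float) -> np.ndarray:
    """n x k matrix of iid N(0, sigma) effects, centered to row-sum zero."""
    e = rng.normal(0.0, sigma, size=(n, k))
    return e - e.mean(axis=1, keepdims=True)


def simulate_counts(
    design: pd.DataFrame, params: SimulationParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a genes x samples count matrix with known factorial effects.

    The log2 mean for gene g in sample s is

        log2 mu_gs = log2(L_s * q_g) + s_g*x_season + d_g*x_food
                     + f_{g,fam(s)} + i_{g,fam(s)}*x_season

    with x_season = +-1/2 (wet/dry) and x_food = +-1/2 (stress/control),
    L_s the sample's lognormal library-size factor and q_g its baseline
    relative abundance. Family effects f and interaction slopes i are
    centered to sum to zero across families, so the wet-minus-dry log2
    fold change of gene g in family f is exactly s_g + i_{g,f} and its
    across-family mean is s_g.

    Returns ``(counts, truth)``: integer counts (genes x samples) and a
    truth table holding every drawn effect plus is_* flags. The number of
    flagged genes per factor is exactly round(frac * n_genes).
    """
    params.validate()
    if design.empty:
        raise ConfigurationError("design has no samples")
    rng = np.random.default_rng(params.seed)
    G = params.n_genes
    fams = params.family_ids()
    F = len(fams)
    genes = [f"g{i + 1:05d}" for i in range(G)]

    q = rng.lognormal(mean=0.0, sigma=params.baseline_log_sd, size=G)
    q /= q.sum()

    def pick(frac: float) -> np.ndarray:
        k = int(round(frac * G))
        idx = rng.choice(G, size=k, replace=False)
        mask = np.zeros(G, dtype=bool)
        mask[idx] = True
        return mask

    is_season = pick(params.frac_season)
    is_family = pick(params.frac_family)
    is_food = pick(params.frac_food)
    is_gxe = pick(params.frac_gxe)

    # season/food effects are fixed-magnitude spike-ins with random sign,
    # the usual construction in differential-expression power studies: it
    # makes detection and sign-recovery metrics well-defined at a stated
    # effect size (a N(0, sigma) draw would place a share of "true"
    # effects arbitrarily close to zero, where sign is unrecoverable).
    season_eff = np.zeros(G)
    season_eff[is_season] = params.sigma_season * rng.choice(
        [-1.0, 1.0], size=int(is_season.sum())
    )
    food_eff = np.zeros(G)
    food_eff[is_food] = params.sigma_food * rng.choice(
        [-1.0, 1.0], size=int(is_food.sum())
    )
    family_eff = np.zeros((G, F))
    family_eff[is_family] = _centered_effects(
        rng, int(is_family.sum()), F, params.sigma_family
    )
    gxe_eff = np.zeros((G, F))
    gxe_eff[is_gxe] = _centered_effects(rng, int(is_gxe.sum()), F, params.sigma_gxe)

    fam_idx = np.array([fams.index(f) for f in design["family"]])
    x_season = np.array([_SEASON_CODE[s] for s in design["season"]])
    x_food = np.array([_FOOD_CODE[f] for f in design["food"]])

    n_samples = len(design)
    sigma_ln = np.sqrt(np.log1p(params.library_size_cv**2))
    mu_ln = np.log(params.library_size_mean) - 0.5 * sigma_ln**2
    lib = rng.lognormal(mean=mu_ln, sigma=sigma_ln, size=n_samples)

    log2_off = (
        season_eff[:, None] * x_season[None, :]
        + food_eff[:, None] * x_food[None, :]
        + family_eff[:, fam_idx]
        + gxe_eff[:, fam_idx] * x_season[None, :]
    )
    mu = lib[None, :] * q[:, None] * np.exp2(log2_off)

    if params.dispersion <= 1e-12:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / params.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    count_df = pd.DataFrame(counts, index=genes, columns=design.index.copy())
    count_df.columns.name = None
    truth = pd.DataFrame(
        {
            "season_effect": season_eff,
            "food_effect": food_eff,
            "is_season": is_season,
            "is_family": is_family,
            "is_food": is_food,
            "is_gxe": is_gxe,
            "baseline_abundance": q,
        },
        index=genes,
    )
    for j, fam in enumerate(fams):
        truth[f"family_effect_{fam}"] = family_eff[:, j]
    for j, fam in enumerate(fams):
        truth[f"gxe_effect_{fam}"] = gxe_eff[:, j]
    return count_df, truth


@dataclass
class HaplotypeMatrix:
    """Binary haplotype alignment for one gene's coding sequence.

    ``sites`` is n_haplotypes x S with 0/1 entries (two alleles per site;
    every retained column is polymorphic). The 0/1 polarity is synthetic
    bookkeeping only; diversity statistics are polarity-agnostic.
    """

    gene_id: str
    sites: np.ndarray
    sequence_length: int = 1000

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=np.int8)
        if self.sites.ndim != 2:
            raise ValueError("sites must be a 2-D matrix")
        if self.n_haplotypes < 2:
            raise ValueError("need >= 2 haplotypes")
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be positive")
        if self.n_sites:
            freqs = self.sites.sum(axis=0)
            if ((freqs == 0) | (freqs == self.n_haplotypes)).any():
                raise ValueError("every site must be polymorphic")

    @property
    def n_haplotypes(self) -> int:
        return self.sites.shape[0]

    @property
    def n_sites(self) -> int:
        return self.sites.shape[1]


_SFS_MODES = ("neutral", "rare_skew", "common_skew")


def simulate_haplotypes(
    n_genes: int,
    n_haplotypes: int = 20,
    sites_per_gene: int = 20,
    sfs_mode: str = "neutral",
    seed: int = 0,
    sequence_length: int = 1000,
) -> list[HaplotypeMatrix]:
    """Simulate per-gene haplotype matrices with a controlled SFS.

    The minor/derived-allele count i at each segregating site is drawn
    from {1..n-1} with weight 1/i (``neutral``, the standard coalescent
    expectation), 1/i^2 (``rare_skew``, excess of rare alleles, pushes
    Tajima's D negative) or uniform (``common_skew``, excess of
    intermediate-frequency alleles, pushes D positive).
    """
    if sfs_mode not in _SFS_MODES:
        raise ConfigurationError(f"sfs_mode must be one of {_SFS_MODES}")
    if sites_per_gene < 0:
        raise ConfigurationError("sites_per_gene must be >= 0")
    if n_haplotypes < 4:
        raise ConfigurationError("need n_haplotypes >= 4 for meaningful Tajima's D")
    rng = np.random.default_rng(seed)
    i_vals = np.arange(1, n_haplotypes)
    if sfs_mode == "neutral":
        w = 1.0 / i_vals
    elif sfs_mode == "rare_skew":
        w = 1.0 / i_vals.astype(float) ** 2
    else:
        w = np.ones_like(i_vals, dtype=float)
    w /= w.sum()

    out = []
    for g in range(n_genes):
        sites = np.zeros((n_haplotypes, sites_per_gene), dtype=np.int8)
        if sites_per_gene:
            derived_counts = rng.choice(i_vals, size=sites_per_gene, p=w)
            for s, k in enumerate(derived_counts):
                carriers = rng.choice(n_haplotypes, size=int(k), replace=False)
                sites[carriers, s] = 1
        out.append(
            HaplotypeMatrix(
                gene_id=f"g{g + 1:05d}",
                sites=sites,
                sequence_length=sequence_length,
            )
        )
    return out
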