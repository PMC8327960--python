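"""Synthetic knockout-phenotyping panels with known truth.

Emulates the structure of large mouse knockout phenotyping data: each
knockout genotype is measured on ~7 animals per sex, genotype effects
on the two sexes are bivariate normal with sex-specific variances and
correlation rho, wild-type (control) genotypes sit exactly at the
population center, and phenotypes carry fixed sex and body-mass
effects, crossed environmental intercepts (center, meta-group, date)
and residual noise. An optional monotone distortion (an inverted power
transform) produces raw-scale data for exercising transform
estimation. Every generator is deterministic under its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sexarch.core_data import FEMALE, MALE, AnalysisConfig, TraitDataset
from sexarch.hier_model import GeneticCovariance
from sexarch.transform import TransformSpec, invert_transform

__all__ = ["SimulationConfig", "TruthRecord", "simulate_trait",
           "simulate_panel", "simulate_fertility", "recovery_study"]


@dataclass
class SimulationConfig:
    """Forward-model parameters for one synthetic trait.

    Defaults mirror a typical knockout-panel design: 7 animals per sex
    per genotype, a handful of phenotyping centers and test dates, and
    sex-dimorphic body mass (female 20 g, male 25 g, SD 2 g — generator
    conventions). Variance components are on the standardized phenotype
    scale.
    """

    n_genotypes: int = 150
    n_controls: int = 5
    n_per_sex: int = 7
    true_g: GeneticCovariance = field(
        default_factory=lambda: GeneticCovariance(0.5, 0.5, 0.65))
    beta_sex: float = 0.3
    beta_mass: float = 0.2
    intercept: float = 0.0
    sd_center: float = 0.2
    sd_meta: float = 0.1
    sd_date: float = 0.1
    sd_resid: float = 0.5
    n_centers: int = 5
    n_meta: int = 3
    n_dates: int = 30
    n_control_animals_per_sex: int = 50
    mass_mean_f: float = 20.0
    mass_mean_m: float = 25.0
    mass_sd: float = 2.0
    distortion: TransformSpec | None = None
    ratio_scale: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_sex < 1:
            raise ValueError("n_per_sex must be >= 1")
        if min(self.sd_center, self.sd_meta, self.sd_date) < 0:
            raise ValueError("environmental sds must be >= 0")
        if self.sd_resid <= 0:
            raise ValueError("sd_resid must be > 0")


@dataclass
class TruthRecord:
    """The generating parameters plus the realized per-genotype effects."""

    config: SimulationConfig
    genotype_ids: list[str]
    u: np.ndarray                 # (J, 2): realized (u_f, u_m) per genotype
    is_control: np.ndarray
    discordant_ids: list[str] = field(default_factory=list)

    def effects_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "genotype_id": self.genotype_ids,
            "u_female": self.u[:, 0],
            "u_male": self.u[:, 1],
            "is_control": self.is_control,
            "planted_discordant": [g in self.discordant_ids
                                   for g in self.genotype_ids],
        })


def _draw_genotype_effects(cfg: SimulationConfig,
                           rng: np.random.Generator) -> np.ndarray:
    g = cfg.true_g
    if abs(g.rho) == 1.0:
        # degenerate covariance: effects perfectly (anti)correlated
        z = rng.standard_normal(cfg.n_genotypes)
        return np.column_stack([g.sigma_f * z, np.sign(g.rho) * g.sigma_m * z])
    return rng.multivariate_normal(
        np.zeros(2), g.as_matrix(), size=cfg.n_genotypes,
        method="cholesky")


def _assemble(cfg: SimulationConfig, u_all: np.ndarray, ids: list[str],
              is_control: np.ndarray, rng: np.random.Generator,
              trait_name: str) -> TraitDataset:
    """Lay out animals and evaluate the forward model."""
    per_geno = []
    for j, gid in enumerate(ids):
        n_side = (cfg.n_control_animals_per_sex if is_control[j]
                  else cfg.n_per_sex)
        for s, sex in enumerate((FEMALE, MALE)):
            per_geno.append((j, s, sex, n_side))
    rows_j = np.concatenate([[j] * n for j, s, sex, n in per_geno])
    rows_s = np.concatenate([[s] * n for j, s, sex, n in per_geno])
    n = len(rows_j)

    male = rows_s == 1
    mass = np.where(male,
                    rng.normal(cfg.mass_mean_m, cfg.mass_sd, n),
                    rng.normal(cfg.mass_mean_f, cfg.mass_sd, n))
    mass_std = (mass - mass.mean()) / mass.std(ddof=1)

    center = rng.integers(cfg.n_centers, size=n)
    meta = rng.integers(cfg.n_meta, size=n)
    date = rng.integers(cfg.n_dates, size=n)
    c_eff = cfg.sd_center * rng.standard_normal(cfg.n_centers)
    m_eff = cfg.sd_meta * rng.standard_normal(cfg.n_meta)
    d_eff = cfg.sd_date * rng.standard_normal(cfg.n_dates)

    y = (cfg.intercept + cfg.beta_sex * male
         + cfg.beta_mass * mass_std
         + u_all[rows_j, rows_s]
         + c_eff[center] + m_eff[meta] + d_eff[date]
         + cfg.sd_resid * rng.standard_normal(n))

    if cfg.distortion is not None:
        y = invert_transform(y, cfg.distortion)

    dates = pd.to_datetime("2020-01-01") + pd.to_timedelta(date, unit="D")
    df = pd.DataFrame({
        "phenotype": y,
        "sex": np.where(male, MALE, FEMALE),
        "genotype_id": np.asarray(ids, dtype=object)[rows_j],
        "is_control": is_control[rows_j],
        "body_mass": mass,
        "center": np.char.add("center_", center.astype(str)),
        "meta_group": np.char.add("meta_", meta.astype(str)),
        "date": dates.date,
    })
    return TraitDataset(trait_name=trait_name, table=df,
                        ratio_scale=cfg.ratio_scale)


def simulate_trait(config: SimulationConfig, *, trait_name: str = "sim_trait"
                   ) -> tuple[TraitDataset, TruthRecord]:
    """Simulate one trait's panel from the forward model.

    Knockout genotype effects are drawn from the configured bivariate
    normal; control genotypes carry effects of exactly zero (they
    define the population center).
    """
    rng = np.random.default_rng(config.seed)
    ids = [f"gene{j:04d}:a1:B6N:hom" for j in range(config.n_genotypes)]
    ids += [f"control:wt:B6N-{k}:wt" for k in range(config.n_controls)]
    is_control = np.array([False] * config.n_genotypes
                          + [True] * config.n_controls)
    u_ko = _draw_genotype_effects(config, rng)
    u_all = np.vstack([u_ko, np.zeros((config.n_controls, 2))])
    data = _assemble(config, u_all, ids, is_control, rng, trait_name)
    return data, TruthRecord(config, ids, u_all, is_control)


def simulate_panel(config: SimulationConfig, n_traits: int,
                   n_discordant: int = 0, *, delta: float | None = None
                   ) -> tuple[list[TraitDataset], TruthRecord]:
    """Simulate a multi-trait panel sharing one genotype roster.

    The first ``n_discordant`` knockout genotypes are planted with
    purely discordant effects in every trait: ``u_f = delta,
    u_m = -delta`` (default delta = 3 sigma_f). All other knockout
    genotypes draw fresh effects per trait from the configured
    bivariate normal. Truth labels for the planted genotypes are
    carried in the returned record.
    """
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    if n_discordant >= config.n_genotypes:
        raise ValueError("n_discordant must be < n_genotypes")
    if delta is None:
        delta = 3.0 * config.true_g.sigma_f

    master = np.random.default_rng(config.seed)
    ids = [f"gene{j:04d}:a1:B6N:hom" for j in range(config.n_genotypes)]
    ids += [f"control:wt:B6N-{k}:wt" for k in range(config.n_controls)]
    is_control = np.array([False] * config.n_genotypes
                          + [True] * config.n_controls)
    discordant_ids = ids[:n_discordant]

    datasets = []
    u_last = None
    for t in range(n_traits):
        sub = dataclasses.replace(config, seed=int(master.integers(2**31)))
        rng = np.random.default_rng(sub.seed)
        u_ko = _draw_genotype_effects(sub, rng)
        u_ko[:n_discordant] = [delta, -delta]
        u_all = np.vstack([u_ko, np.zeros((config.n_controls, 2))])
        datasets.append(_assemble(sub, u_all, ids, is_control, rng,
                                  trait_name=f"trait_{t:03d}"))
        u_last = u_all
    truth = TruthRecord(config, ids, u_last, is_control,
                        discordant_ids=discordant_ids)
    return datasets, truth


# ---------------------------------------------------------------------------
# fertility generator


BIAS_CLASSES = ("female_biased", "male_biased", "unbiased")
FERTILITY_CLASSES = ("fertile", "female_limited_infertile",
                     "male_limited_infertile", "infertile")


def simulate_fertility(n_genes: int,
                       p_male_infertile_given_malebias: float = 0.11,
                       p_male_infertile_baseline: float = 0.015,
                       bias_fractions: tuple[float, float, float] = (0.1, 0.1, 0.8),
                       *, p_female_infertile: float = 0.01,
                       p_both_infertile: float = 0.005,
                       seed: int = 0) -> pd.DataFrame:
    """Genes with a gonadal expression-bias class and a fertility outcome.

    Knockouts of male-biased genes produce male-limited infertility at
    an elevated rate (default 11%) against a low baseline (1.5%);
    female-limited infertility shows no expression-bias enrichment.
    ``bias_fractions`` orders as (female_biased, male_biased, unbiased)
    and must sum to 1.
    """
    for p in (p_male_infertile_given_malebias, p_male_infertile_baseline,
              p_female_infertile, p_both_infertile, *bias_fractions):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    if abs(sum(bias_fractions) - 1.0) > 1e-9:
        raise ValueError("bias_fractions must sum to 1")

    rng = np.random.default_rng(seed)
    bias = rng.choice(BIAS_CLASSES, size=n_genes, p=list(bias_fractions))
    p_male = np.where(bias == "male_biased",
                      p_male_infertile_given_malebias,
                      p_male_infertile_baseline)
    out = np.empty(n_genes, dtype=object)
    v = rng.uniform(size=n_genes)
    # sequential thresholds: both-infertile, male-limited, female-limited, fertile
    c1 = p_both_infertile
    c2 = c1 + p_male
    c3 = c2 + p_female_infertile
    out[v < c1] = "infertile"
    out[(v >= c1) & (v < c2)] = "male_limited_infertile"
    out[(v >= c2) & (v < c3)] = "female_limited_infertile"
    out[v >= c3] = "fertile"
    return pd.DataFrame({"gene_id": [f"gene{i:05d}" for i in range(n_genes)],
                         "bias_class": bias, "fertility_class": out})


# ---------------------------------------------------------------------------
# parameter-recovery study


def recovery_study(rho_grid, n_reps: int, config: AnalysisConfig,
                   sim_config: SimulationConfig | None = None,
                   *, seed: int = 0) -> pd.DataFrame:
    """Simulate-and-refit across a grid of true correlations.

    For each rho in the grid and each replicate, a trait is simulated,
    the mixed model is fitted, and the posterior median and central
    95% interval of the correlation are recorded, along with whether
    the interval covers the truth. A per-rho summary of bias, RMSE and
    coverage is attached as ``DataFrame.attrs['summary']``. Fit
    failures are recorded as rows with NaN estimates, not raised.
    """
    from sexarch.hier_model import fit_model  # local import: avoids cycle at module load

    base = sim_config or SimulationConfig()
    master = np.random.SeedSequence(seed)
    rows = []
    for rho in rho_grid:
        for rep in range(n_reps):
            child = master.spawn(1)[0]
            s1, s2 = child.generate_state(2) % (2**31)
            g = base.true_g
            cfg = dataclasses.replace(
                base, true_g=GeneticCovariance(g.sigma_f, g.sigma_m, float(rho)),
                seed=int(s1))
            data, truth = simulate_trait(cfg)
            fit_cfg = dataclasses.replace(config, seed=int(s2))
            try:
                from sexarch.core_data import standardize_and_prepare
                std, sspec = standardize_and_prepare(data, fit_cfg)
                draws = fit_model(std, config=fit_cfg)
                r = draws.stacked("rho")
                med = float(np.median(r))
                lo, hi = np.percentile(r, [2.5, 97.5])
                # fixed-effect errors on the standardized-phenotype scale
                bsex_err = float(np.median(draws.stacked("beta_sex"))
                                 - cfg.beta_sex / sspec.phenotype_sd)
                # the generator applies beta_mass to standardized mass, so
                # only the phenotype scaling enters the comparison
                bmass_err = float(np.median(draws.stacked("beta_mass"))
                                  - cfg.beta_mass / sspec.phenotype_sd) \
                    if "beta_mass" in draws.params else np.nan
                rows.append({"true_rho": float(rho), "rep": rep,
                             "median": med, "lo95": float(lo),
                             "hi95": float(hi),
                             "covered": bool(lo <= rho <= hi),
                             "error": med - float(rho),
                             "beta_sex_err": bsex_err,
                             "beta_mass_err": bmass_err, "failed": False})
            except Exception as err:  # noqa: BLE001 - recorded, not fatal
                rows.append({"true_rho": float(rho), "rep": rep,
                             "median": np.nan, "lo95": np.nan, "hi95": np.nan,
                             "covered": False, "error": np.nan,
                             "failed": True, "failure": str(err)})
    table = pd.DataFrame(rows)
    ok = table.loc[~table["failed"]]
    summary = ok.groupby("true_rho").agg(
        bias=("error", "mean"),
        rmse=("error", lambda e: float(np.sqrt(np.mean(np.square(e))))),
        coverage=("covered", "mean"), n=("rep", "size")).reset_index()
    table.attrs["summary"] = summary
    return table
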