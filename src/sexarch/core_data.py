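"""Data model, validation, standardization and file I/O.

A trait dataset is one row per animal: a phenotype value, the animal's
sex, a genotype key (``gene:allele:background:zygosity``), a wild-type
flag, and design metadata (body mass, phenotyping center, meta-group,
test date, optional stratum such as age in weeks). All downstream
modules consume the :class:`TraitDataset` container defined here.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

#: canonical column order for trait tables
REQUIRED_COLUMNS = ("phenotype", "sex", "genotype_id", "is_control")
OPTIONAL_COLUMNS = ("body_mass", "center", "meta_group", "date", "stratum")
QUARTET_COLUMNS = ("gene", "allele", "background", "zygosity")


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class ValidationError(ValueError):
    """The table parses but violates a dataset invariant."""


@dataclass(frozen=True)
class StandardizationSpec:
    """Centering/scaling constants, kept so back-transforms are exact.

    Standard deviations use the n-1 (sample) convention.
    """

    phenotype_mean: float
    phenotype_sd: float
    mass_mean: float | None = None
    mass_sd: float | None = None

    def __post_init__(self) -> None:
        if self.phenotype_sd <= 0:
            raise ValidationError("phenotype sd must be > 0 (constant trait?)")
        if self.mass_sd is not None and self.mass_sd <= 0:
            raise ValidationError("body-mass sd must be > 0")

    def unstandardize_phenotype(self, z: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(z) * self.phenotype_sd + self.phenotype_mean


@dataclass
class AnalysisConfig:
    """Knobs for the whole pipeline, with full-scale defaults.

    ``iterations``/``warmup`` are per chain. ``rope`` is the interval of
    dimorphism index values treated as practically equivalent to
    monomorphism. ``genotype_min`` is the minimum number of distinct
    knockout genotypes a trait needs before its correlation estimate is
    considered trustworthy; by default a shortfall only warns
    (``strict_genotype_min`` enforces it).
    """

    include_body_mass: bool = True
    genotype_min: int = 100
    strict_genotype_min: bool = False
    rope: tuple[float, float] = (0.0, 0.05)
    chains: int = 2
    iterations: int = 8000
    warmup: int = 4000
    n_meta_draws: int = 500
    n_rank_draws: int = 100
    min_traits_for_rank: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValidationError("warmup must be < iterations")
        if self.rope[0] > self.rope[1]:
            raise ValidationError("rope lower bound exceeds upper bound")
        for name in ("genotype_min", "chains", "iterations", "warmup",
                     "n_meta_draws", "n_rank_draws", "min_traits_for_rank"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def desk_scale(self) -> "AnalysisConfig":
        """A reduced-iteration copy for quick runs (2 x 2000, half warmup)."""
        return dataclasses.replace(self, iterations=2000, warmup=1000)


@dataclass
class TraitDataset:
    """One trait's per-animal records plus trait-level metadata.

    ``table`` has the canonical columns (REQUIRED_COLUMNS, plus any of
    OPTIONAL_COLUMNS that were available). ``ratio_scale`` records
    whether comparisons to zero are biologically meaningful, which the
    dimorphism index requires.
    """

    trait_name: str
    table: pd.DataFrame
    ratio_scale: bool = True
    standardization: StandardizationSpec | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.table)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.table["genotype_id"].unique())

    @property
    def control_genotypes(self) -> list[str]:
        return sorted(self.table.loc[self.table["is_control"], "genotype_id"].unique())

    @property
    def n_knockout_genotypes(self) -> int:
        return self.table.loc[~self.table["is_control"], "genotype_id"].nunique()

    def has_column(self, name: str) -> bool:
        return name in self.table.columns and self.table[name].notna().any()

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        bad_sex = set(self.table["sex"].unique()) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unrecognized sex value(s): {sorted(bad_sex)}")
        present = set(self.table["sex"].unique())
        if present != set(SEXES):
            raise ValidationError(
                f"both sexes must be present; found only {sorted(present)}"
            )
        if not self.table["is_control"].any():
            raise ValidationError("no control (wild-type) rows in dataset")
        if (self.table["genotype_id"].astype(str).str.len() == 0).any():
            raise ValidationError("empty genotype_id")
        phen = self.table["phenotype"].to_numpy(float)
        if not np.all(np.isfinite(phen)):
            raise ValidationError("non-finite phenotype values present")

    def check_genotype_count(self, config: AnalysisConfig) -> bool:
        """Apply the minimum-genotype rule; warn (default) or raise (strict)."""
        n = self.n_knockout_genotypes
        if n < config.genotype_min:
            msg = (f"trait {self.trait_name!r}: {n} knockout genotypes "
                   f"< minimum {config.genotype_min}")
            if config.strict_genotype_min:
                raise ValidationError(msg)
            logger.warning(msg)
            return False
        return True


# ---------------------------------------------------------------------------
# reading


def _compose_genotype_id(df: pd.DataFrame) -> pd.Series:
    parts = [df[c].astype(str) for c in QUARTET_COLUMNS]
    out = parts[0]
    for p in parts[1:]:
        out = out.str.cat(p, sep=":")
    return out


def read_trait_table(path: str | Path, trait_name: str | None = None, *,
                     ratio_scale: bool = True) -> TraitDataset:
    """Read a delimited trait table (CSV, or TSV by extension) into a dataset.

    Accepts either a ``genotype_id`` column or the
    gene/allele/background/zygosity quartet, which is composed with ``:``
    separators. Rows with a missing phenotype are dropped with a logged
    count.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)

    if "genotype_id" not in df.columns:
        quartet_missing = [c for c in QUARTET_COLUMNS if c not in df.columns]
        if quartet_missing:
            raise SchemaError(
                "missing required column(s): genotype_id "
                f"(or quartet columns {', '.join(quartet_missing)})"
            )
        df = df.assign(genotype_id=_compose_genotype_id(df))

    for col in ("phenotype", "sex", "is_control"):
        if col not in df.columns:
            raise SchemaError(f"missing required column(s): {col}")

    n_missing = int(df["phenotype"].isna().sum())
    if n_missing:
        logger.info("dropping %d row(s) with missing phenotype", n_missing)
        df = df.loc[df["phenotype"].notna()]

    df = df.copy()
    df["sex"] = df["sex"].astype(str).str.lower()
    if df["is_control"].dtype != bool:
        df["is_control"] = df["is_control"].map(
            {True: True, False: False, "true": True, "false": False,
             "True": True, "False": False, 1: True, 0: False}
        )
        if df["is_control"].isna().any():
            raise SchemaError("is_control column not interpretable as boolean")
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.date

    keep = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    name = trait_name if trait_name is not None else path.stem
    return TraitDataset(trait_name=name, table=df[keep].reset_index(drop=True),
                        ratio_scale=ratio_scale)


# ---------------------------------------------------------------------------
# standardization


def standardize_and_prepare(
    data: TraitDataset, config: AnalysisConfig
) -> tuple[TraitDataset, StandardizationSpec]:
    """Center and scale phenotype (and body mass) to unit sample variance.

    Returns a new dataset plus the constants needed to invert the map.
    Rows missing body mass are dropped (with a logged count) when the
    mass covariate is in use; otherwise mass is left untouched.
    """
    df = data.table.copy()
    use_mass = config.include_body_mass and "body_mass" in df.columns
    if use_mass:
        n_missing = int(df["body_mass"].isna().sum())
        if n_missing:
            logger.info("dropping %d row(s) with missing body mass", n_missing)
            df = df.loc[df["body_mass"].notna()].reset_index(drop=True)

    phen = df["phenotype"].to_numpy(float)
    mu, sd = float(np.mean(phen)), float(np.std(phen, ddof=1))
    if not sd > 0:
        raise ValidationError(f"trait {data.trait_name!r} has zero variance")
    df["phenotype"] = (phen - mu) / sd

    mass_mu = mass_sd = None
    if use_mass:
        mass = df["body_mass"].to_numpy(float)
        mass_mu, mass_sd = float(np.mean(mass)), float(np.std(mass, ddof=1))
        if not mass_sd > 0:
            raise ValidationError("body mass has zero variance")
        df["body_mass"] = (mass - mass_mu) / mass_sd

    spec = StandardizationSpec(mu, sd, mass_mu, mass_sd)
    out = TraitDataset(data.trait_name, df, ratio_scale=data.ratio_scale,
                       standardization=spec)
    return out, spec


def split_by_stratum(data: TraitDataset) -> dict[str, TraitDataset]:
    """Partition a dataset on its stratum column (e.g., age week).

    Each stratum becomes an independently analyzable dataset. A stratum
    that fails validation (say, one sex only) maps to None and is
    reported with a warning, so one bad week does not sink the rest.
    """
    if "stratum" not in data.table.columns:
        raise SchemaError("no stratum column to split on")
    out: dict[str, TraitDataset | None] = {}
    for value, chunk in data.table.groupby("stratum", sort=True):
        try:
            out[str(value)] = TraitDataset(
                trait_name=f"{data.trait_name}[{value}]",
                table=chunk.reset_index(drop=True),
                ratio_scale=data.ratio_scale,
            )
        except ValidationError as err:
            logger.warning("stratum %r invalid: %s", value, err)
            out[str(value)] = None
    return out


# ---------------------------------------------------------------------------
# writing


SUMMARY_COLUMNS = [
    "trait_name",
    "rfmk_median", "rfmk_lo95", "rfmk_hi95", "rfmk_lo80", "rfmk_hi80",
    "rfmk_lo50", "rfmk_hi50",
    "fisher_z_median", "fisher_z_lo95", "fisher_z_hi95",
    "var_ratio_ordered_median", "var_ratio_ordered_lo95", "var_ratio_ordered_hi95",
    "var_ratio_mf_median", "var_ratio_mf_lo95", "var_ratio_mf_hi95",
    "riemann_median", "riemann_lo95", "riemann_hi95",
    "sd_index_median", "sd_index_lo95", "sd_index_hi95",
    "sd_ratio_fm_median", "sd_ratio_fm_lo95", "sd_ratio_fm_hi95",
    "rope_class",
]


def write_results(results: Iterable, path: str | Path, *,
                  config: AnalysisConfig | None = None,
                  draws: Mapping[str, pd.DataFrame] | None = None) -> Path:
    """Write per-trait summaries (CSV), optional draw tables, and a manifest.

    ``results`` is an iterable of objects with a ``to_row()`` method (see
    ``derived.TraitSummaries`` and ``discordance.RankResult``); rows are
    written in input order. Returns the directory written to.
    """
    out_dir = Path(path)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = [r.to_row() for r in results]
    if rows:
        df = pd.DataFrame(rows)
    else:
        logger.warning("writing empty results table")
        df = pd.DataFrame(columns=SUMMARY_COLUMNS)
    df.to_csv(out_dir / "summaries.csv", index=False, float_format="%.12g")

    if draws:
        draws_dir = out_dir / "draws"
        draws_dir.mkdir(exist_ok=True)
        for name, table in draws.items():
            table.to_csv(draws_dir / f"{name}.csv", index=False,
                         float_format="%.12g")

    manifest: dict = {"software": {"package": "sexarch", "version": "0.1.0"}}
    if config is not None:
        manifest["config"] = dataclasses.asdict(config)
        manifest["config"]["rope"] = list(config.rope)
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out_dir
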