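"""Configuration dataclasses and YAML round-trip helpers."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

UNKNOWN_PARENT = 0


@dataclass
class SimConfig:
    """Parameters of the synthetic laying-hen population.

    Defaults emulate the study design: a few hundred sires per cohort over
    five pedigree generations, part of the sires genotyped with a dense SNP
    chip, daughters housed five paternal half-sibs to a cage, and survival
    recorded in batches that end (and hence censor) at different days.
    Variance defaults are on the scale of the published sire-model REML
    estimates for brown layer lines (residual ~10^4 d^2, cage ~1.2*10^3 d^2,
    sire ~7*10^2 d^2).
    """

    n_generations: int = 5
    n_sires_per_gen: int = 50
    dams_per_sire: int = 8
    daughters_per_dam: int = 5
    cage_size: int = 5
    n_snps: int = 500
    maf_low: float = 0.05
    maf_high: float = 0.5
    sigma2_u: float = 675.0
    sigma2_c: float = 1403.0
    sigma2_e: float = 10350.0
    mu: float = 380.0
    batch_defs: Sequence[tuple[str, float]] = (
        ("b1", 360.0),
        ("b2", 400.0),
        ("b3", 420.0),
    )
    n_crosses: int = 3
    n_locations: int = 12
    fixed_effect_sds: dict = field(
        default_factory=lambda: {"batch": 15.0, "cross": 15.0, "house_row_level": 8.0}
    )
    prop_sires_genotyped: float = 0.8
    architecture: str = "snp"  # 'snp' | 'infinitesimal'
    strict_cages: bool = True
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_generations < 1 or self.n_sires_per_gen < 1:
            raise ValueError("need at least one cohort and one sire per cohort")
        if self.dams_per_sire < 1 or self.daughters_per_dam < 1:
            raise ValueError("need at least one mating per sire")
        if self.cage_size < 2:
            raise ValueError("cage_size must be >= 2")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        for name in ("sigma2_u", "sigma2_c", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.prop_sires_genotyped <= 1):
            raise ValueError("prop_sires_genotyped must be in (0, 1]")
        if any(day <= 0 for _, day in self.batch_defs):
            raise ValueError("censoring days must be positive")
        if self.architecture not in ("snp", "infinitesimal"):
            raise ValueError("architecture must be 'snp' or 'infinitesimal'")


@dataclass
class QCThresholds:
    """SNP quality-control thresholds (call rate, MAF, HWE chi-square)."""

    min_call_rate: float = 0.90
    min_maf_exclusive: float = 0.02
    max_hwe_chisq: float = 600.0

    def __post_init__(self) -> None:
        if not (0 <= self.min_maf_exclusive < 0.5):
            raise ValueError("min_maf_exclusive must be in [0, 0.5)")
        if self.min_call_rate <= 0 or self.max_hwe_chisq <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class TraitParams:
    """Genetic parameters of survival time and the marker pseudo-trait.

    The marker information of a genotyped candidate is modelled as a second,
    fully heritable trait whose genetic correlation with survival is ``r_g``;
    its phenotypic variance r_g^2 * h2 * sigma2_P makes the regression of the
    true survival breeding value on the marker EBV equal to one.
    """

    h2: float = 0.20
    sigma2_P: float = 11500.0
    sigma2_cage: float = 1243.5  # common environment shared by a cage of 5
    r_g: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.h2 <= 1):
            raise ValueError("h2 must be in [0, 1]")
        if self.sigma2_P <= 0 or self.sigma2_cage < 0:
            raise ValueError("variances must be positive")
        if self.r_g is not None and not (-1 <= self.r_g <= 1):
            raise ValueError("|r_g| must be <= 1")

    @property
    def sigma2_A(self) -> float:
        return self.h2 * self.sigma2_P

    @property
    def sigma2_Pm(self) -> float:
        if self.r_g is None:
            raise ValueError("r_g not set")
        return self.r_g**2 * self.h2 * self.sigma2_P

    @property
    def r_p(self) -> float:
        if self.r_g is None:
            raise ValueError("r_g not set")
        return self.h2**0.5 * self.r_g


@dataclass
class SchemeConfig:
    """Breeding-scheme structure for the deterministic engine.

    The defaults are the traditional progeny-testing scheme: 20 sires and 400
    dams per generation, each sire mated to 20 dams, 5 male and 5 female
    offspring per dam; males selected on parent average plus the mean of 40
    progeny from 8 dams, females on parent average only.
    """

    n_sires: int = 20
    n_dams: int = 400
    dams_per_sire: int = 20
    male_offspring_per_dam: int = 5
    female_offspring_per_dam: int = 5
    p_male: float = 0.08
    p_female: float = 0.08
    L_male_weeks: float = 99.0
    L_female_weeks: float = 55.0
    male_sources: tuple[str, ...] = ("parent_average", "progeny_mean")
    female_sources: tuple[str, ...] = ("parent_average",)
    progeny_group_size: int = 40
    progeny_dams: int = 8
    weeks_per_year: float = 52.0

    def __post_init__(self) -> None:
        if not (0 < self.p_male <= 1 and 0 < self.p_female <= 1):
            raise ValueError("selected proportions must be in (0, 1]")
        if self.L_male_weeks <= 0 or self.L_female_weeks <= 0:
            raise ValueError("generation intervals must be positive")
        for s in self.male_sources + self.female_sources:
            if s not in ("parent_average", "progeny_mean", "own_phenotype", "own_marker"):
                raise ValueError(f"unknown information source {s!r}")

    @property
    def mean_L_years(self) -> float:
        return 0.5 * (self.L_male_weeks + self.L_female_weeks) / self.weeks_per_year


def genomic_scheme() -> SchemeConfig:
    """The genomic-selection counterpart: both sexes selected on their own
    marker record, male generation interval shortened to 33 weeks, and a
    sharper male selected proportion (2%)."""
    return SchemeConfig(
        p_male=0.02,
        p_female=0.08,
        L_male_weeks=33.0,
        L_female_weeks=55.0,
        male_sources=("own_marker",),
        female_sources=("own_marker",),
    )


def _load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def load_sim_config(path: str | Path) -> SimConfig:
    raw = _load_yaml(path)
    if "batch_defs" in raw:
        raw["batch_defs"] = [tuple(b) for b in raw["batch_defs"]]
    return SimConfig(**raw)


def load_scheme_config(path: str | Path) -> SchemeConfig:
    raw = _load_yaml(path)
    for key in ("male_sources", "female_sources"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SchemeConfig(**raw)


def dump_config(cfg, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
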