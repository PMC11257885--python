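"""Virtual pediatric population with age-consistent physiology.

Generates individual subjects whose body size, organ volumes, blood flows,
plasma-protein binding, glomerular filtration and hepatic CYP3A4 activity
all vary with age, so that drug clearance and distribution scale through
childhood the way the underlying physiology does.  CYP3A4 activity rises
steeply over the first weeks to months of life, peaks above the adult level
in infancy/early childhood and settles back to the adult level through
adolescence.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict, fields as dc_fields
from typing import Sequence

import numpy as np
import pandas as pd

from .config import (
    GfrMaturationParams,
    MppglParams,
    OntogenyParams,
    PopulationConfig,
)

__all__ = [
    "DemographicSpec",
    "IndividualPhysiology",
    "bsa",
    "cyp3a4_ontogeny",
    "gfr_maturation",
    "fu_pediatric",
    "mppgl",
    "sample_population",
    "population_frame",
]

DAYS_PER_YEAR = 365.25
WEEKS_PER_YEAR = DAYS_PER_YEAR / 7.0


@dataclass(frozen=True)
class DemographicSpec:
    """Which subjects to draw: an age range, a size and a seed."""

    age_min_years: float
    age_max_years: float
    n_subjects: int
    proportion_female: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.age_min_years < self.age_max_years:
            raise ValueError("age_min_years must be < age_max_years")
        if self.age_min_years < 0:
            raise ValueError("ages must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.proportion_female <= 1.0:
            raise ValueError("proportion_female must lie in [0, 1]")


@dataclass(frozen=True)
class IndividualPhysiology:
    """One virtual subject's physiology, fully determining their PK."""

    subject_id: str
    age_years: float
    sex: str
    weight_kg: float
    height_cm: float
    bsa_m2: float
    liver_volume_L: float
    kidney_volume_L: float
    blood_volume_L: float
    cardiac_output_L_h: float
    hepatic_blood_flow_L_h: float
    renal_blood_flow_L_h: float
    mppgl_mg_g: float
    cyp3a4_ontogeny_fraction: float
    cyp3a4_abundance_multiplier: float
    gfr_ml_min: float
    albumin_ratio: float
    hematocrit: float

    def __post_init__(self) -> None:
        positive = (
            "weight_kg",
            "height_cm",
            "bsa_m2",
            "liver_volume_L",
            "kidney_volume_L",
            "blood_volume_L",
            "cardiac_output_L_h",
            "hepatic_blood_flow_L_h",
            "renal_blood_flow_L_h",
            "mppgl_mg_g",
            "cyp3a4_ontogeny_fraction",
            "cyp3a4_abundance_multiplier",
            "gfr_ml_min",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.albumin_ratio <= 1.5:
            raise ValueError("albumin_ratio must lie in (0, 1.5]")
        if abs(self.bsa_m2 - bsa(self.weight_kg, self.height_cm)) > 1e-6:
            raise ValueError("bsa_m2 inconsistent with weight/height")

    @property
    def liver_weight_g(self) -> float:
        # density applied where the liver volume is derived; volume is stored
        # in litres of tissue, weight in grams for microsomal scaling
        return self.liver_volume_L * 1000.0 * 1.05


def bsa(weight_kg: float, height_cm: float) -> float:
    """Body surface area in m² (Mosteller)."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return math.sqrt(weight_kg * height_cm / 3600.0)


def cyp3a4_ontogeny(age_years, params: OntogenyParams):
    """CYP3A4 activity per mg microsomal protein, as a fraction of adult.

    Base sigmoid in postnatal age plus an optional additive overshoot term
    (rising Hill x falling Hill), normalized so the adult limit is 1.0.
    Accepts scalars or arrays.
    """
    a = np.asarray(age_years, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be non-negative")
    p = params
    base = p.fraction_at_birth + (1.0 - p.fraction_at_birth) * _hill_up(
        a, p.age50_years, p.hill
    )
    if p.overshoot_amplitude > 0:
        bump = (
            p.overshoot_amplitude
            * _hill_up(a, p.overshoot_rise_age50_years, p.overshoot_rise_hill)
            * _hill_down(a, p.overshoot_fall_age50_years, p.overshoot_fall_hill)
        )
        base = base + bump
    return base if base.ndim else float(base)


def _hill_up(a, a50, n):
    with np.errstate(divide="ignore"):
        r = np.where(a > 0, (np.maximum(a, 1e-300) / a50) ** n, 0.0)
    return r / (1.0 + r)


def _hill_down(a, a50, n):
    return 1.0 - _hill_up(a, a50, n)


def gfr_maturation(
    age_years: float, weight_kg: float, params: GfrMaturationParams
) -> float:
    """Glomerular filtration rate in mL/min.

    Sigmoid maturation in postmenstrual age times an allometric size term
    referenced to a 70 kg adult.
    """
    if age_years < 0:
        raise ValueError("age must be non-negative")
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    p = params
    pma = p.term_pma_weeks + age_years * WEEKS_PER_YEAR
    mat = pma**p.hill / (p.pma50_weeks**p.hill + pma**p.hill)
    return p.adult_gfr_ml_min * mat * (weight_kg / 70.0) ** p.allometric_exponent


def fu_pediatric(fu_adult: float, albumin_ratio: float) -> float:
    """Unbound plasma fraction scaled for age-reduced binding-protein levels."""
    if not 0.0 < fu_adult <= 1.0:
        raise ValueError("fu_adult must lie in (0, 1]")
    if albumin_ratio <= 0:
        raise ValueError("albumin_ratio must be positive")
    return 1.0 / (1.0 + albumin_ratio * (1.0 - fu_adult) / fu_adult)


def mppgl(age_years: float, params: MppglParams) -> float:
    """Milligrams of microsomal protein per gram of liver at a given age."""
    if age_years < 0:
        raise ValueError("age must be non-negative")
    a = age_years
    return 10.0 ** (
        params.intercept
        + params.linear * a
        + params.quadratic * a**2
        + params.cubic * a**3
    )


def _interp_growth(
    table: pd.DataFrame, sex: str, age: float
) -> tuple[float, float, float, float]:
    grp = table[table["sex"] == sex].sort_values("age_years")
    ages = grp["age_years"].to_numpy()
    if age < ages[0] or age > ages[-1]:
        raise ValueError(
            f"age {age:.4g} y outside growth-table support "
            f"[{ages[0]:.4g}, {ages[-1]:.4g}]"
        )
    out = tuple(
        float(np.interp(age, ages, grp[col].to_numpy()))
        for col in ("weight_median_kg", "weight_cv", "height_median_cm", "height_cv")
    )
    return out  # type: ignore[return-value]


def growth_table_median_weight(config: PopulationConfig, age: float, sex: str = "M") -> float:
    """Median weight (kg) read directly off the configured growth table."""
    return _interp_growth(config.growth_table, sex, age)[0]


def _build_subject(
    idx: int,
    age: float,
    sex: str,
    z_size: float,
    z_height_extra: float,
    z_abundance: float,
    config: PopulationConfig,
) -> IndividualPhysiology:
    body = config.body
    w_med, w_cv, h_med, h_cv = _interp_growth(config.growth_table, sex, age)
    rho = config.iiv.weight_height_correlation
    z_h = rho * z_size + math.sqrt(max(0.0, 1.0 - rho**2)) * z_height_extra
    sigma_w = math.sqrt(math.log(1.0 + w_cv**2))
    sigma_h = math.sqrt(math.log(1.0 + h_cv**2))
    weight = w_med * math.exp(sigma_w * z_size)
    height = h_med * math.exp(sigma_h * z_h)
    surface = bsa(weight, height)

    liver_vol = (body.liver_ml_per_m2 * surface + body.liver_ml_intercept) / 1000.0
    kidney_vol = body.kidney_fraction_bw * weight
    blood_ml_kg = body.blood_ml_per_kg_adult + (
        body.blood_ml_per_kg_neonatal_excess
        * math.exp(-age / body.blood_volume_decay_years)
    )
    blood_vol = blood_ml_kg * weight / 1000.0
    co = body.cardiac_output_L_h_per_m2 * surface
    q_h = body.hepatic_flow_fraction_co * co
    q_k = body.renal_flow_fraction_co * co

    sigma_ab = math.sqrt(math.log(1.0 + config.iiv.cyp3a4_abundance_cv**2))
    abundance = math.exp(sigma_ab * z_abundance)

    albumin = 1.0 - body.albumin_neonatal_deficit * math.exp(
        -age / body.albumin_maturation_years
    )
    hct = body.hematocrit_adult + body.hematocrit_neonatal_excess * math.exp(
        -age / body.hematocrit_decay_years
    )
    return IndividualPhysiology(
        subject_id=f"S{idx:05d}",
        age_years=age,
        sex=sex,
        weight_kg=weight,
        height_cm=height,
        bsa_m2=surface,
        liver_volume_L=liver_vol,
        kidney_volume_L=kidney_vol,
        blood_volume_L=blood_vol,
        cardiac_output_L_h=co,
        hepatic_blood_flow_L_h=q_h,
        renal_blood_flow_L_h=q_k,
        mppgl_mg_g=mppgl(age, config.mppgl),
        cyp3a4_ontogeny_fraction=float(cyp3a4_ontogeny(age, config.ontogeny)),
        cyp3a4_abundance_multiplier=abundance,
        gfr_ml_min=gfr_maturation(age, weight, config.gfr),
        albumin_ratio=albumin,
        hematocrit=hct,
    )


def sample_population(
    spec: DemographicSpec, config: PopulationConfig
) -> list[IndividualPhysiology]:
    """Draw a reproducible virtual cohort.

    Ages are uniform over the spec's range, weight/height are log-normal
    around the growth-table medians with a shared size z-score, and CYP3A4
    abundance gets an independent log-normal inter-individual factor.
    """
    lo, hi = config.age_support
    if spec.age_min_years < lo or spec.age_max_years > hi:
        raise ValueError(
            f"requested age range [{spec.age_min_years}, {spec.age_max_years}] "
            f"outside growth-table support [{lo}, {hi}]"
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    ages = rng.uniform(spec.age_min_years, spec.age_max_years, size=n)
    sexes = np.where(rng.random(n) < spec.proportion_female, "F", "M")
    z = rng.standard_normal((n, 3))
    return [
        _build_subject(i, float(ages[i]), str(sexes[i]), z[i, 0], z[i, 1], z[i, 2], config)
        for i in range(n)
    ]


def population_frame(subjects: Sequence[IndividualPhysiology]) -> pd.DataFrame:
    """One row per subject with every physiology field (CSV-exportable)."""
    return pd.DataFrame([asdict(s) for s in subjects])[
        [f.name for f in dc_fields(IndividualPhysiology)]
    ]
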