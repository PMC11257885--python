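"""Configuration schemas and loaders.

All tunable physiology and compound parameters live in versioned, validated
config objects so that nothing age- or drug-specific is hard-coded in the
simulation code.  Defaults ship as YAML/CSV package data and every field can
be overridden from user-supplied files.
"""
from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class _FrozenModel(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class OntogenyParams(_FrozenModel):
    """CYP3A4 activity per mg microsomal protein, as fraction of adult.

    The base term is a sigmoid in postnatal age (fraction at birth,
    maturation half-age, Hill coefficient).  An optional additive overshoot
    term — the product of a rising and a falling Hill function — lets the
    activity peak above the adult level in infancy/early childhood before
    relaxing back to 1.0, the pattern reported for CYP3A4 substrates.
    """

    fraction_at_birth: float = Field(gt=0.0, lt=1.0)
    age50_years: float = Field(gt=0.0)
    hill: float = Field(gt=0.0)
    overshoot_amplitude: float = Field(default=0.0, ge=0.0)
    overshoot_rise_age50_years: float = Field(default=0.35, gt=0.0)
    overshoot_rise_hill: float = Field(default=2.5, gt=0.0)
    overshoot_fall_age50_years: float = Field(default=8.5, gt=0.0)
    overshoot_fall_hill: float = Field(default=5.0, gt=0.0)


class GfrMaturationParams(_FrozenModel):
    """Sigmoid maturation of GFR in postmenstrual age with allometric size."""

    adult_gfr_ml_min: float = Field(default=121.0, gt=0.0)
    pma50_weeks: float = Field(default=47.7, gt=0.0)
    hill: float = Field(default=3.4, gt=0.0)
    allometric_exponent: float = Field(default=0.75, gt=0.0)
    term_pma_weeks: float = Field(default=40.0, gt=0.0)


class MppglParams(_FrozenModel):
    """Cubic-in-age log10 polynomial for mg microsomal protein per g liver."""

    intercept: float = 1.407
    linear: float = 0.0158
    quadratic: float = -0.00038
    cubic: float = 0.0000024


class IIVParams(_FrozenModel):
    """Log-normal inter-individual variability magnitudes (CVs)."""

    cyp3a4_abundance_cv: float = Field(default=0.35, ge=0.0)
    flows_cv: float = Field(default=0.0, ge=0.0)
    volumes_cv: float = Field(default=0.0, ge=0.0)
    weight_height_correlation: float = Field(default=0.7, ge=-1.0, le=1.0)


class BodyCompositionParams(_FrozenModel):
    """Age functions for organ sizes, flows and binding physiology."""

    liver_ml_per_m2: float = Field(default=706.2, gt=0.0)
    liver_ml_intercept: float = 2.4
    liver_density_g_ml: float = Field(default=1.05, gt=0.0)
    kidney_fraction_bw: float = Field(default=0.0042, gt=0.0)
    cardiac_output_L_h_per_m2: float = Field(default=190.0, gt=0.0)
    hepatic_flow_fraction_co: float = Field(default=0.25, gt=0.0, lt=1.0)
    renal_flow_fraction_co: float = Field(default=0.19, gt=0.0, lt=1.0)
    blood_ml_per_kg_adult: float = Field(default=70.0, gt=0.0)
    blood_ml_per_kg_neonatal_excess: float = Field(default=15.0, ge=0.0)
    blood_volume_decay_years: float = Field(default=2.0, gt=0.0)
    albumin_neonatal_deficit: float = Field(default=0.25, ge=0.0, lt=1.0)
    albumin_maturation_years: float = Field(default=0.3, gt=0.0)
    hematocrit_adult: float = Field(default=0.42, gt=0.0, lt=1.0)
    hematocrit_neonatal_excess: float = Field(default=0.08, ge=0.0)
    hematocrit_decay_years: float = Field(default=0.3, gt=0.0)
    adult_reference_weight_kg: float = Field(default=70.0, gt=0.0)


class PopulationConfig(BaseModel):
    """Virtual-population physiology: growth table plus age functions."""

    model_config = ConfigDict(arbitrary_types_allowed=True, frozen=True)

    schema_version: int = 1
    growth_table: pd.DataFrame
    ontogeny: OntogenyParams
    gfr: GfrMaturationParams = GfrMaturationParams()
    mppgl: MppglParams = MppglParams()
    iiv: IIVParams = IIVParams()
    body: BodyCompositionParams = BodyCompositionParams()

    @field_validator("growth_table")
    @classmethod
    def _check_growth_table(cls, df: pd.DataFrame) -> pd.DataFrame:
        required = {
            "age_years",
            "sex",
            "weight_median_kg",
            "weight_cv",
            "height_median_cm",
            "height_cv",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"growth table missing columns: {sorted(missing)}")
        for sex, grp in df.groupby("sex"):
            ages = grp["age_years"].to_numpy()
            if ages.min() > 0.0 or ages.max() < 18.0:
                raise ValueError(
                    f"growth table for sex {sex!r} must cover 0-18 years"
                )
        if (df["weight_cv"] < 0).any() or (df["height_cv"] < 0).any():
            raise ValueError("growth-table CVs must be non-negative")
        return df

    @property
    def age_support(self) -> tuple[float, float]:
        ages = self.growth_table["age_years"]
        return float(ages.min()), float(ages.max())


class CompoundConfig(_FrozenModel):
    """Drug-specific parameters (dexamethasone literature defaults).

    The shipped values are literature defaults assembled for intravenous
    dexamethasone; every field is overridable from a user YAML file.
    """

    name: str = "dexamethasone"
    molecular_weight: float = Field(gt=0.0)
    fu_adult: float = Field(gt=0.0, le=1.0)
    blood_plasma_ratio: float = Field(gt=0.0)
    # unbound intrinsic clearance, uL/min per mg microsomal protein, adult
    clint_u_adult_ul_min_mg: Optional[float] = Field(default=None, ge=0.0)
    # alternative retrograde entry: whole-body adult plasma CL to back-calculate
    cl_adult_L_h: Optional[float] = Field(default=None, gt=0.0)
    fm_cyp3a4: float = Field(ge=0.0, le=1.0)
    renal_fraction: float = Field(ge=0.0, le=1.0)
    kp_liver: float = Field(gt=0.0)
    kp_kidney: float = Field(gt=0.0)
    kp_rest: float = Field(gt=0.0)
    default_infusion_duration_h: float = Field(default=0.1, ge=0.0)

    @model_validator(mode="after")
    def _one_clearance_entry(self) -> "CompoundConfig":
        if self.clint_u_adult_ul_min_mg is None and self.cl_adult_L_h is None:
            raise ValueError(
                "specify clint_u_adult_ul_min_mg or cl_adult_L_h (retrograde)"
            )
        return self


def _data_path(name: str) -> Path:
    return Path(str(resources.files("dexpbpk").joinpath("data", name)))


def load_growth_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read a growth-reference CSV (bundled table when *path* is None)."""
    src = Path(path) if path is not None else _data_path("growth_reference.csv")
    return pd.read_csv(src)


def load_population_config(path: str | Path | None = None) -> PopulationConfig:
    """Load a population YAML config; defaults to the bundled configuration."""
    src = Path(path) if path is not None else _data_path("population_default.yaml")
    raw = yaml.safe_load(src.read_text())
    table_ref = raw.pop("growth_table", None)
    if table_ref is not None and not Path(table_ref).is_absolute():
        candidate = src.parent / table_ref
        table_ref = candidate if candidate.exists() else table_ref
    growth = load_growth_table(table_ref)
    return PopulationConfig(
        growth_table=growth,
        ontogeny=OntogenyParams(**raw["ontogeny"]),
        gfr=GfrMaturationParams(**raw.get("gfr", {})),
        mppgl=MppglParams(**raw.get("mppgl", {})),
        iiv=IIVParams(**raw.get("iiv", {})),
        body=BodyCompositionParams(**raw.get("body", {})),
        schema_version=raw.get("schema_version", 1),
    )


def load_compound_config(path: str | Path | None = None) -> CompoundConfig:
    """Load a compound YAML config; defaults to bundled dexamethasone."""
    src = Path(path) if path is not None else _data_path("compound_dexamethasone.yaml")
    raw = yaml.safe_load(src.read_text())
    return CompoundConfig(**raw)


def config_fingerprint(*objects) -> str:
    """Stable SHA-256 over config contents, for run manifests."""
    payload = []
    for obj in objects:
        if isinstance(obj, pd.DataFrame):
            payload.append(obj.to_csv(index=False))
        elif isinstance(obj, BaseModel):
            payload.append(
                json.dumps(
                    obj.model_dump(exclude={"growth_table"}, mode="json"),
                    sort_keys=True,
                )
            )
            if hasattr(obj, "growth_table"):
                payload.append(obj.growth_table.to_csv(index=False))
        else:
            payload.append(json.dumps(obj, sort_keys=True, default=str))
    digest = hashlib.sha256("\n".join(payload).encode()).hexdigest()
    return digest
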