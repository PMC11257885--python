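"""Synthetic "observed" PK studies.

Real pediatric dexamethasone concentration data are not publicly
deposited, so the verification stage is exercised with synthetic stand-ins
that copy the structure of the published study designs: single 3 mg/m² IV,
single 0.3 mg/kg IV, 3 mg/m² every 6 h and 4 mg every 12 h, each with
inter-individual variability, proportional residual error and LLOQ
censoring.  Ground truth is either the pipeline's own PBPK model (for
self-consistency checks) or an independent closed-form bi-exponential
disposition (so NCA and verification tests do not share code with the
simulator they are checking).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .config import CompoundConfig, PopulationConfig
from .pbpk import DoseDesign, build_model, simulate_profile
from .population import DemographicSpec, sample_population
from .verification import ObservedStudy

__all__ = [
    "StudyTemplate",
    "BiexponentialTruth",
    "DEFAULT_TEMPLATES",
    "generate_study",
    "generate_independent_truth",
]

_DENSE_SINGLE = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)
_DENSE_MULTI = (0.5, 1.0, 2.0, 4.0, 6.0, 6.5, 8.0, 12.0, 12.5, 14.0, 18.0,
                18.5, 20.0, 24.0, 30.0, 36.0, 48.0)


@dataclass(frozen=True)
class StudyTemplate:
    """Recipe for one synthetic observed study."""

    study_id: str
    design: DoseDesign
    age_min_years: float
    age_max_years: float
    n_subjects: int
    sampling_times_h: tuple[float, ...]
    prop_error_cv: float = 0.2
    add_error_sd_mg_L: float = 0.0
    lloq_mg_L: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prop_error_cv < 0 or self.add_error_sd_mg_L < 0:
            raise ValueError("error magnitudes must be non-negative")
        t = np.asarray(self.sampling_times_h)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be increasing")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")


#: The four verification study designs (plausible dense sampling schedules;
#: the original papers' exact schedules are not public, all configurable).
DEFAULT_TEMPLATES: tuple[StudyTemplate, ...] = (
    StudyTemplate(
        "single_3mg_m2",
        DoseDesign(3.0, "mg_m2", n_doses=1),
        1.0, 16.0, 12, _DENSE_SINGLE,
    ),
    StudyTemplate(
        "single_0p3mg_kg",
        DoseDesign(0.3, "mg_kg", n_doses=1),
        2.0, 12.0, 10, _DENSE_SINGLE,
    ),
    StudyTemplate(
        "q6h_3mg_m2",
        DoseDesign(3.0, "mg_m2", n_doses=4, interval_h=6.0),
        1.0, 16.0, 8, _DENSE_MULTI,
    ),
    StudyTemplate(
        "q12h_4mg",
        DoseDesign(4.0, "mg", n_doses=2, interval_h=12.0),
        12.0, 18.0, 8, _DENSE_MULTI,
    ),
)


@dataclass(frozen=True)
class BiexponentialTruth:
    """Closed-form two-phase IV disposition C(t) = A e^{-at} + B e^{-bt}."""

    A: float
    alpha: float
    B: float
    beta: float

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise ValueError("coefficients must be non-negative")
        if not self.alpha > self.beta > 0:
            raise ValueError("require alpha > beta > 0")

    def conc(self, t):
        t = np.asarray(t, float)
        return self.A * np.exp(-self.alpha * t) + self.B * np.exp(-self.beta * t)

    @property
    def auc_0_inf(self) -> float:
        return self.A / self.alpha + self.B / self.beta

    @property
    def terminal_half_life_h(self) -> float:
        return float(np.log(2.0) / self.beta)


def generate_independent_truth(
    A: float, alpha: float, B: float, beta: float
) -> BiexponentialTruth:
    """Bi-exponential ground-truth profile with closed-form AUC and t1/2."""
    return BiexponentialTruth(A=A, alpha=alpha, B=B, beta=beta)


def _noisy(
    truth: np.ndarray, template: StudyTemplate, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    eps = rng.normal(0.0, 1.0, truth.size)
    obs = truth * (1.0 + template.prop_error_cv * eps)
    if template.add_error_sd_mg_L > 0:
        obs = obs + rng.normal(0.0, template.add_error_sd_mg_L, truth.size)
    obs = np.clip(obs, 0.0, None)
    censored = obs < template.lloq_mg_L
    return obs, censored


def generate_study(
    template: StudyTemplate,
    population: PopulationConfig,
    compound: CompoundConfig,
    truth: BiexponentialTruth | Sequence[BiexponentialTruth] | None = None,
) -> ObservedStudy:
    """Materialize a synthetic observed study from a template.

    With ``truth=None`` the pipeline's own PBPK model generates each
    subject's true profile (self-consistency mode).  Passing one
    bi-exponential truth (or one per subject) substitutes the independent
    closed-form disposition; doses are still resolved per subject so the
    records keep a meaningful dose column.
    """
    rng = np.random.default_rng(np.random.SeedSequence([template.seed, 77]))
    spec = DemographicSpec(
        max(template.age_min_years, 1e-9),
        template.age_max_years,
        template.n_subjects,
        seed=template.seed,
    )
    subjects = sample_population(spec, population)
    times = np.asarray(template.sampling_times_h, float)
    grid = np.union1d(times, [0.0])
    rows = []
    for k, subject in enumerate(subjects):
        regimen = template.design.regimen_for(subject)
        if truth is None:
            profile = simulate_profile(build_model(subject, compound), regimen, grid)
            true_conc = np.interp(times, profile.times_h, profile.plasma_conc_mg_L)
        else:
            fn = truth[k] if isinstance(truth, (list, tuple)) else truth
            true_conc = fn.conc(times)
        obs, censored = _noisy(true_conc, template, rng)
        for t, c, cen in zip(times, obs, censored):
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "age_years": subject.age_years,
                    "weight_kg": subject.weight_kg,
                    "dose_mg": regimen.total_dose_mg,
                    "time_h": float(t),
                    "conc_mg_L": float(c) if not cen else 0.0,
                    "below_lloq": bool(cen),
                }
            )
    records = pd.DataFrame(rows)
    return ObservedStudy(
        study_id=template.study_id,
        design=template.design,
        age_min_years=template.age_min_years,
        age_max_years=template.age_max_years,
        records=records,
        lloq_mg_L=template.lloq_mg_L,
    )
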