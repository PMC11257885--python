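"""Perfusion-limited PBPK model for intravenous dexamethasone.

Five compartments — venous blood, arterial blood, liver, kidney, rest of
body — connected by blood flows that sum to cardiac output.  Hepatic
elimination follows the well-stirred model with unbound intrinsic clearance
scaled by liver size, microsomal protein content and CYP3A4 ontogeny; renal
elimination is a configurable fraction of unbound glomerular filtration.

The system is linear and time-invariant between dose events, so profiles
are propagated with matrix exponentials: exact superposition, exact dose
linearity and mass balance at solver precision.  A conventional stiff ODE
integrator is available as an independent cross-check backend.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .config import CompoundConfig, PopulationConfig
from .population import IndividualPhysiology, bsa, fu_pediatric, mppgl

__all__ = [
    "DoseDesign",
    "DoseEvent",
    "Regimen",
    "ConcentrationProfile",
    "PBPKModel",
    "build_model",
    "hepatic_clearance",
    "scale_clint",
    "simulate_profile",
    "apply_caps",
    "regimen_from_mg_per_kg",
    "regimen_from_mg_per_m2",
    "regimen_fixed_mg",
    "clint_from_adult_cl",
    "adult_reference",
]

UL_MIN_TO_L_H = 60.0e-6  # 1 uL/min = 6e-5 L/h
ML_MIN_TO_L_H = 0.06


@dataclass(frozen=True)
class DoseEvent:
    start_h: float
    amount_mg: float
    infusion_duration_h: float = 0.1

    def __post_init__(self) -> None:
        if self.start_h < 0:
            raise ValueError("dose start time must be non-negative")
        if self.amount_mg <= 0:
            raise ValueError("dose amount must be positive")
        if self.infusion_duration_h < 0:
            raise ValueError("infusion duration must be non-negative")

    @property
    def end_h(self) -> float:
        return self.start_h + self.infusion_duration_h

    @property
    def rate_mg_h(self) -> float:
        if self.infusion_duration_h == 0:
            return math.inf
        return self.amount_mg / self.infusion_duration_h


@dataclass(frozen=True)
class Regimen:
    """Timed IV dose events, stored post-cap."""

    dose_events: tuple[DoseEvent, ...]
    max_per_dose_mg: float | None = None
    max_per_day_mg: float | None = None
    capped: bool = False

    def __post_init__(self) -> None:
        starts = [e.start_h for e in self.dose_events]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("dose start times must be strictly increasing")

    @property
    def total_dose_mg(self) -> float:
        return sum(e.amount_mg for e in self.dose_events)

    def dosed_by(self, t: float) -> float:
        """Cumulative amount administered up to time t (infusions pro-rated)."""
        total = 0.0
        for e in self.dose_events:
            if e.infusion_duration_h == 0:
                if t >= e.start_h:
                    total += e.amount_mg
            elif t > e.start_h:
                total += min(e.amount_mg, e.rate_mg_h * (t - e.start_h))
        return total


@dataclass(frozen=True)
class ConcentrationProfile:
    """Simulated plasma concentration-time course for one subject."""

    times_h: np.ndarray
    plasma_conc_mg_L: np.ndarray
    subject_ref: str = ""
    regimen_ref: str = ""
    mass_balance_residual: float = 0.0
    auc_diverges: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, float)
        c = np.asarray(self.plasma_conc_mg_L, float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if t[0] != 0.0:
            raise ValueError("time grid must start at 0")
        if np.any(c < -1e-12):
            raise ValueError("negative concentrations in profile")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "plasma_conc_mg_L", np.clip(c, 0.0, None))


def hepatic_clearance(q_h: float, fu_blood: float, clint_u: float) -> float:
    """Well-stirred hepatic blood clearance, L/h.

    CLh = Qh * fu_b * CLint_u / (Qh + fu_b * CLint_u); bounded above by Qh.
    """
    if min(q_h, fu_blood, clint_u) < 0:
        raise ValueError("inputs must be non-negative")
    denom = q_h + fu_blood * clint_u
    if denom == 0:
        return 0.0
    return q_h * fu_blood * clint_u / denom


def scale_clint(subject: IndividualPhysiology, compound: CompoundConfig) -> float:
    """Whole-liver unbound intrinsic clearance for a subject, L/h.

    Adult per-mg-protein activity times the CYP3A4-mediated fraction scaled
    by ontogeny and the subject's abundance factor (the non-CYP3A4 fraction
    is left unscaled), times microsomal protein content and liver mass.
    """
    if compound.clint_u_adult_ul_min_mg is None:
        raise ValueError(
            "compound has no direct CLint entry; resolve retrograde clearance "
            "first (clint_from_adult_cl)"
        )
    iso = (
        compound.fm_cyp3a4
        * subject.cyp3a4_ontogeny_fraction
        * subject.cyp3a4_abundance_multiplier
        + (1.0 - compound.fm_cyp3a4)
    )
    return (
        compound.clint_u_adult_ul_min_mg
        * iso
        * subject.mppgl_mg_g
        * subject.liver_weight_g
        * UL_MIN_TO_L_H
    )


@dataclass(frozen=True)
class _AdultReference:
    weight_kg: float
    liver_weight_g: float
    mppgl_mg_g: float
    hepatic_blood_flow_L_h: float
    gfr_ml_min: float


def adult_reference(config: PopulationConfig) -> _AdultReference:
    """Reference adult physiology used to anchor adult-normalized scalings."""
    body = config.body
    w = body.adult_reference_weight_kg
    h = 176.0
    surface = bsa(w, h)
    liver_g = (body.liver_ml_per_m2 * surface + body.liver_ml_intercept) * 1.05
    co = body.cardiac_output_L_h_per_m2 * surface
    return _AdultReference(
        weight_kg=w,
        liver_weight_g=liver_g,
        mppgl_mg_g=mppgl(30.0, config.mppgl),
        hepatic_blood_flow_L_h=body.hepatic_flow_fraction_co * co,
        gfr_ml_min=config.gfr.adult_gfr_ml_min,
    )


def clint_from_adult_cl(
    compound: CompoundConfig, config: PopulationConfig
) -> CompoundConfig:
    """Resolve a retrograde clearance entry to a per-mg-protein CLint.

    Subtracts the adult renal component from the stated adult plasma
    clearance, inverts the well-stirred model at adult hepatic blood flow
    and divides by adult liver microsomal protein.  Returns a compound
    config with ``clint_u_adult_ul_min_mg`` populated.
    """
    if compound.clint_u_adult_ul_min_mg is not None:
        return compound
    ref = adult_reference(config)
    fu_b = compound.fu_adult / compound.blood_plasma_ratio
    cl_b = compound.cl_adult_L_h / compound.blood_plasma_ratio
    cl_renal_b = (
        compound.renal_fraction
        * compound.fu_adult
        * ref.gfr_ml_min
        * ML_MIN_TO_L_H
        / compound.blood_plasma_ratio
    )
    cl_h = cl_b - cl_renal_b
    q_h = ref.hepatic_blood_flow_L_h
    if not 0.0 < cl_h < q_h:
        raise ValueError("adult hepatic clearance must lie in (0, Qh)")
    clint_L_h = q_h * cl_h / (fu_b * (q_h - cl_h))
    per_mg = clint_L_h / (ref.mppgl_mg_g * ref.liver_weight_g * UL_MIN_TO_L_H)
    return replace_compound(compound, clint_u_adult_ul_min_mg=per_mg)


def replace_compound(compound: CompoundConfig, **kw) -> CompoundConfig:
    return compound.model_copy(update=kw)


_STATE_NAMES = ("venous", "arterial", "liver", "kidney", "rest", "eliminated")


@dataclass
class PBPKModel:
    """ODE-system descriptor for one subject x compound pairing."""

    subject: IndividualPhysiology
    compound: CompoundConfig
    volumes_L: dict[str, float] = field(init=False)
    flows_L_h: dict[str, float] = field(init=False)
    fu_plasma: float = field(init=False)
    fu_blood: float = field(init=False)
    clint_u_L_h: float = field(init=False)
    renal_cl_unbound_L_h: float = field(init=False)
    A: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        s, c = self.subject, self.compound
        v_blood = s.blood_volume_L
        v_ven, v_art = 2.0 / 3.0 * v_blood, 1.0 / 3.0 * v_blood
        v_rest = s.weight_kg - v_blood - s.liver_volume_L - s.kidney_volume_L
        if v_rest <= 0:
            raise ValueError("rest-of-body volume must be positive")
        self.volumes_L = {
            "venous": v_ven,
            "arterial": v_art,
            "liver": s.liver_volume_L,
            "kidney": s.kidney_volume_L,
            "rest": v_rest,
        }
        co = s.cardiac_output_L_h
        q_rest = co - s.hepatic_blood_flow_L_h - s.renal_blood_flow_L_h
        self.flows_L_h = {
            "liver": s.hepatic_blood_flow_L_h,
            "kidney": s.renal_blood_flow_L_h,
            "rest": q_rest,
        }
        if abs(sum(self.flows_L_h.values()) - co) > 1e-3 * co:
            raise ValueError("tissue flows do not sum to cardiac output")
        self.fu_plasma = fu_pediatric(c.fu_adult, s.albumin_ratio)
        self.fu_blood = self.fu_plasma / c.blood_plasma_ratio
        self.clint_u_L_h = scale_clint(s, c)
        self.renal_cl_unbound_L_h = c.renal_fraction * s.gfr_ml_min * ML_MIN_TO_L_H
        self.A = self._system_matrix()

    def _system_matrix(self) -> np.ndarray:
        c = self.compound
        v = self.volumes_L
        q = self.flows_L_h
        co = self.subject.cardiac_output_L_h
        bp = c.blood_plasma_ratio
        kp = {"liver": c.kp_liver, "kidney": c.kp_kidney, "rest": c.kp_rest}
        # per-amount rate constants; states: ven, art, liv, kid, rest, elim
        A = np.zeros((6, 6))
        i = {name: k for k, name in enumerate(_STATE_NAMES)}
        # venous: tissue returns in, cardiac output out
        for t in ("liver", "kidney", "rest"):
            A[i["venous"], i[t]] += q[t] * bp / (kp[t] * v[t])
        A[i["venous"], i["venous"]] -= co / v["venous"]
        # arterial: from venous, out to tissues
        A[i["arterial"], i["venous"]] += co / v["venous"]
        A[i["arterial"], i["arterial"]] -= co / v["arterial"]
        # tissues
        for t in ("liver", "kidney", "rest"):
            A[i[t], i["arterial"]] += q[t] / v["arterial"]
            A[i[t], i[t]] -= q[t] * bp / (kp[t] * v[t])
        # hepatic elimination on unbound outflow concentration
        k_hep = self.clint_u_L_h * self.fu_plasma / (c.kp_liver * v["liver"])
        A[i["liver"], i["liver"]] -= k_hep
        A[i["eliminated"], i["liver"]] += k_hep
        # renal filtration elimination from kidney
        k_ren = self.renal_cl_unbound_L_h * self.fu_plasma / (c.kp_kidney * v["kidney"])
        A[i["kidney"], i["kidney"]] -= k_ren
        A[i["eliminated"], i["kidney"]] += k_ren
        return A

    @property
    def hepatic_cl_blood_L_h(self) -> float:
        return hepatic_clearance(
            self.flows_L_h["liver"], self.fu_blood, self.clint_u_L_h
        )

    @property
    def renal_cl_blood_L_h(self) -> float:
        return self.renal_cl_unbound_L_h * self.fu_blood

    @property
    def total_cl_plasma_L_h(self) -> float:
        """Steady-state total plasma clearance (well-stirred + filtration)."""
        return (
            self.hepatic_cl_blood_L_h + self.renal_cl_blood_L_h
        ) * self.compound.blood_plasma_ratio

    @property
    def auc_diverges(self) -> bool:
        return self.total_cl_plasma_L_h == 0.0


def build_model(subject: IndividualPhysiology, compound: CompoundConfig) -> PBPKModel:
    """Assemble the perfusion-limited ODE system for one subject."""
    return PBPKModel(subject=subject, compound=compound)


def default_grid(horizon_h: float = 48.0, dt_h: float = 0.1) -> np.ndarray:
    n = int(round(horizon_h / dt_h))
    return np.linspace(0.0, n * dt_h, n + 1)


def _event_times(regimen: Regimen) -> list[float]:
    extra = []
    for e in regimen.dose_events:
        extra.append(e.start_h)
        if e.infusion_duration_h > 0:
            extra.append(e.end_h)
    return extra


def _merge_grid(grid: np.ndarray, regimen: Regimen) -> np.ndarray:
    """Union of output grid and dose-event times, float-duplicate free."""
    extra = np.asarray(_event_times(regimen), float)
    t = np.union1d(np.asarray(grid, float), extra)
    t = t[t <= grid[-1] + 1e-12]
    keep = np.ones(t.size, bool)
    for j in range(1, t.size):
        if t[j] - t[j - 1] < 1e-9:
            # collapse near-duplicates, preferring the exact event time
            drop = j if np.min(np.abs(extra - t[j])) > 0 else j - 1
            keep[drop] = False
    return t[keep]


def _event_deltas(
    regimen: Regimen, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-grid-index infusion-rate changes and bolus amounts."""
    rate_delta = np.zeros(times.size)
    bolus = np.zeros(times.size)
    for e in regimen.dose_events:
        i0 = int(np.argmin(np.abs(times - e.start_h)))
        if e.infusion_duration_h == 0:
            bolus[i0] += e.amount_mg
        else:
            rate_delta[i0] += e.rate_mg_h
            if e.end_h <= times[-1] + 1e-9:
                rate_delta[int(np.argmin(np.abs(times - e.end_h)))] -= e.rate_mg_h
    return rate_delta, bolus


def _simulate_expm(model: PBPKModel, regimen: Regimen, times: np.ndarray) -> np.ndarray:
    """Propagate the augmented linear system through all grid/event times."""
    M = np.zeros((7, 7))
    M[:6, :6] = model.A
    M[0, 6] = 1.0  # constant infusion into venous blood
    cache: dict[float, np.ndarray] = {}

    def step(dt: float) -> np.ndarray:
        key = round(dt, 12)
        if key not in cache:
            cache[key] = expm(M * dt)
        return cache[key]

    rate_delta, bolus = _event_deltas(regimen, times)
    y = np.zeros(7)
    out = np.zeros((len(times), 6))
    t_prev = times[0]
    for j, t in enumerate(times):
        if t > t_prev:
            y = step(t - t_prev) @ y
            t_prev = t
        y[0] += bolus[j]
        y[6] += rate_delta[j]
        if abs(y[6]) < 1e-9:  # snap accumulated float error in the rate
            y[6] = 0.0
        out[j] = y[:6]
    return out


def _simulate_ivp(model: PBPKModel, regimen: Regimen, times: np.ndarray) -> np.ndarray:
    """Reference backend: stiff integrator restarted at each dose event."""

    def rate_at(t: float) -> float:
        r = 0.0
        for e in regimen.dose_events:
            if e.infusion_duration_h > 0 and e.start_h <= t < e.end_h:
                r += e.rate_mg_h
        return r

    breaks = sorted(
        {times[0], times[-1]}
        | {e.start_h for e in regimen.dose_events}
        | {e.end_h for e in regimen.dose_events if e.infusion_duration_h > 0}
    )
    breaks = [b for b in breaks if times[0] <= b <= times[-1]]
    y = np.zeros(6)
    out = np.zeros((len(times), 6))
    out[0] = y
    for a, b in zip(breaks, breaks[1:]):
        ev = next((e for e in regimen.dose_events if e.start_h == a), None)
        if ev is not None and ev.infusion_duration_h == 0:
            y[0] += ev.amount_mg
            out[times == a] = y
        mid = 0.5 * (a + b)
        r = rate_at(mid)

        def rhs(t, x):
            dx = model.A @ x
            dx[0] += r
            return dx

        mask = (times > a) & (times <= b)
        t_eval = times[mask]
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method="LSODA",
            t_eval=np.union1d(t_eval, [b]),
            rtol=1e-8,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        if t_eval.size:
            out[np.where(mask)[0]] = sol.y[:, np.isin(sol.t, t_eval)].T
        y = sol.y[:, -1]
    return out


def simulate_profile(
    model: PBPKModel,
    regimen: Regimen,
    grid: np.ndarray | None = None,
    backend: Literal["expm", "ivp"] = "expm",
) -> ConcentrationProfile:
    """Integrate the model under a regimen and return the plasma profile.

    The default backend propagates the linear system with matrix
    exponentials (exact between events); ``backend="ivp"`` uses a stiff
    adaptive integrator with restarts at dose events as a cross-check.
    """
    if grid is None:
        last = max((e.end_h for e in regimen.dose_events), default=0.0)
        grid = default_grid(max(48.0, last + 48.0))
    grid = np.asarray(grid, float)
    if regimen.dose_events and grid[-1] < max(e.start_h for e in regimen.dose_events):
        raise ValueError("grid must cover all dose events")
    times = _merge_grid(grid, regimen)
    if not regimen.dose_events:
        conc = np.zeros_like(times)
        return ConcentrationProfile(
            times, conc, subject_ref=model.subject.subject_id,
            auc_diverges=model.auc_diverges,
        )
    states = (
        _simulate_expm(model, regimen, times)
        if backend == "expm"
        else _simulate_ivp(model, regimen, times)
    )
    v_ven = model.volumes_L["venous"]
    conc_plasma = states[:, 0] / v_ven / model.compound.blood_plasma_ratio
    body_plus_elim = states.sum(axis=1)
    dosed = np.array([regimen.dosed_by(t) for t in times])
    with np.errstate(invalid="ignore"):
        residual = float(
            np.max(np.abs(body_plus_elim - dosed)) / max(regimen.total_dose_mg, 1e-300)
        )
    return ConcentrationProfile(
        times_h=times,
        plasma_conc_mg_L=conc_plasma,
        subject_ref=model.subject.subject_id,
        mass_balance_residual=residual,
        auc_diverges=model.auc_diverges,
    )


def apply_caps(
    mg_per_kg: float,
    n_doses: int,
    interval_h: float,
    weight_kg: float,
    max_per_dose_mg: float | None = None,
    max_per_day_mg: float | None = 40.0,
    infusion_duration_h: float = 0.1,
    first_dose_h: float = 0.0,
) -> Regimen:
    """Convert a weight-based schedule to absolute doses and apply caps.

    Per-dose amounts are mg/kg x weight, truncated at the per-dose cap;
    then any rolling 24 h window whose total exceeds the daily cap has all
    of its doses scaled down proportionally.
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    if n_doses < 1:
        raise ValueError("need at least one dose")
    amounts = np.full(n_doses, mg_per_kg * weight_kg)
    starts = first_dose_h + interval_h * np.arange(n_doses)
    capped = False
    if max_per_dose_mg is not None and np.any(amounts > max_per_dose_mg):
        amounts = np.minimum(amounts, max_per_dose_mg)
        capped = True
    if max_per_day_mg is not None:
        for _ in range(100):
            worst, worst_idx = 0.0, None
            for i in range(n_doses):
                window = (starts >= starts[i]) & (starts < starts[i] + 24.0)
                total = amounts[window].sum()
                if total > max_per_day_mg * (1 + 1e-12) and total > worst:
                    worst, worst_idx = total, np.where(window)[0]
            if worst_idx is None:
                break
            amounts[worst_idx] *= max_per_day_mg / worst
            capped = True
    events = tuple(
        DoseEvent(float(t), float(a), infusion_duration_h)
        for t, a in zip(starts, amounts)
    )
    return Regimen(
        dose_events=events,
        max_per_dose_mg=max_per_dose_mg,
        max_per_day_mg=max_per_day_mg,
        capped=capped,
    )


def regimen_from_mg_per_kg(
    mg_per_kg: float,
    n_doses: int,
    interval_h: float,
    subject: IndividualPhysiology,
    **cap_kw,
) -> Regimen:
    return apply_caps(mg_per_kg, n_doses, interval_h, subject.weight_kg, **cap_kw)


def regimen_from_mg_per_m2(
    mg_per_m2: float,
    n_doses: int,
    interval_h: float,
    subject: IndividualPhysiology,
    **cap_kw,
) -> Regimen:
    mg_per_kg = mg_per_m2 * subject.bsa_m2 / subject.weight_kg
    return apply_caps(mg_per_kg, n_doses, interval_h, subject.weight_kg, **cap_kw)


@dataclass(frozen=True)
class DoseDesign:
    """A study dosing description, resolvable per subject.

    ``basis`` is one of mg (fixed), mg_kg (weight-based) or mg_m2
    (surface-area based, resolved through each subject's BSA).
    """

    amount: float
    basis: Literal["mg", "mg_kg", "mg_m2"]
    n_doses: int = 1
    interval_h: float = 6.0
    infusion_duration_h: float = 0.1
    max_per_day_mg: float | None = None

    def __post_init__(self) -> None:
        if self.amount <= 0 or self.n_doses < 1:
            raise ValueError("design needs a positive amount and >=1 doses")
        if self.basis not in ("mg", "mg_kg", "mg_m2"):
            raise ValueError(f"unsupported dose basis {self.basis!r}")

    def regimen_for(self, subject: IndividualPhysiology) -> Regimen:
        kw = dict(
            max_per_day_mg=self.max_per_day_mg,
            infusion_duration_h=self.infusion_duration_h,
        )
        if self.basis == "mg_kg":
            return regimen_from_mg_per_kg(
                self.amount, self.n_doses, self.interval_h, subject, **kw
            )
        if self.basis == "mg_m2":
            return regimen_from_mg_per_m2(
                self.amount, self.n_doses, self.interval_h, subject, **kw
            )
        return apply_caps(
            self.amount, self.n_doses, self.interval_h, 1.0, **kw
        )

    def label(self) -> str:
        unit = {"mg": "mg", "mg_kg": "mg/kg", "mg_m2": "mg/m2"}[self.basis]
        sched = (
            "single dose"
            if self.n_doses == 1
            else f"q{self.interval_h:g}h x{self.n_doses}"
        )
        return f"{self.amount:g} {unit} {sched}"


def regimen_fixed_mg(
    amount_mg: float,
    n_doses: int,
    interval_h: float,
    infusion_duration_h: float = 0.1,
    max_per_day_mg: float | None = 40.0,
) -> Regimen:
    return apply_caps(
        amount_mg,
        n_doses,
        interval_h,
        1.0,
        max_per_day_mg=max_per_day_mg,
        infusion_duration_h=infusion_duration_h,
    )
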