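"""Non-compartmental analysis of concentration-time profiles.

Computes the standard exposure metrics — Cmax, Tmax, AUC over a stated
window, extrapolated AUC, clearance, volume of distribution and terminal
half-life — from a sampled plasma profile, with the linear-up/log-down
trapezoid as the default integration rule and terminal-slope selection by
best adjusted r² over candidate tails.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .pbpk import ConcentrationProfile

__all__ = ["PKSummary", "auc_trapezoid", "lambda_z", "summarize", "LambdaZError"]

LN2 = math.log(2.0)


class LambdaZError(ValueError):
    """No acceptable terminal log-linear phase could be estimated."""


@dataclass(frozen=True)
class PKSummary:
    """NCA metrics for a single profile."""

    cmax_mg_L: float
    tmax_h: float
    auc_0_t_mg_h_L: float
    t_last_h: float
    auc_0_inf_mg_h_L: float
    auc_0_48_mg_h_L: float
    cl_L_h: float
    vd_L: float
    t_half_h: float
    lambda_z_per_h: float
    n_points_lambda_z: int
    dose_mg: float

    def __post_init__(self) -> None:
        if self.auc_0_inf_mg_h_L < self.auc_0_t_mg_h_L - 1e-9:
            raise ValueError("AUC0-inf cannot be below AUC0-tlast")
        if abs(self.t_half_h - LN2 / self.lambda_z_per_h) > 1e-9 * self.t_half_h:
            raise ValueError("t_half must equal ln2/lambda_z")


def auc_trapezoid(
    times: Sequence[float],
    concs: Sequence[float],
    method: Literal["linear", "linear-up-log-down"] = "linear-up-log-down",
    t_end: float | None = None,
) -> float:
    """Piecewise trapezoidal AUC from time 0 of the grid up to ``t_end``.

    The log-down rule is applied only on intervals where the concentration
    decreases and both endpoint values are positive; other intervals use
    the linear trapezoid.  ``t_end`` must lie within the sampled grid (no
    extrapolation here); an interior ``t_end`` interpolates the final
    partial interval.
    """
    t = np.asarray(times, float)
    c = np.asarray(concs, float)
    if t.size < 2:
        raise ValueError("need at least two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t_end is None:
        t_end = float(t[-1])
    if t_end > t[-1] + 1e-12 or t_end < t[0]:
        raise ValueError("t_end outside the sampled grid")
    total = 0.0
    for i in range(t.size - 1):
        a, b = t[i], min(t[i + 1], t_end)
        if b <= a:
            break
        c1 = c[i]
        c2 = (
            c[i + 1]
            if b == t[i + 1]
            else _interp_conc(t[i], t[i + 1], c[i], c[i + 1], b, method)
        )
        if method == "linear-up-log-down" and c2 < c1 and c1 > 0 and c2 > 0:
            total += (b - a) * (c1 - c2) / math.log(c1 / c2)
        else:
            total += (b - a) * 0.5 * (c1 + c2)
        if b == t_end:
            break
    return total


def _interp_conc(t1, t2, c1, c2, t, method):
    if method == "linear-up-log-down" and c2 < c1 and c1 > 0 and c2 > 0:
        return c1 * (c2 / c1) ** ((t - t1) / (t2 - t1))
    return c1 + (c2 - c1) * (t - t1) / (t2 - t1)


def lambda_z(
    times: Sequence[float],
    concs: Sequence[float],
    selection: Sequence[int] | None = None,
    max_points: int = 6,
) -> tuple[float, int, float]:
    """Terminal slope by log-linear regression.

    Returns ``(lambda_z, n_points, adjusted r²)``.  By default the tail of
    3..max_points final positive concentrations (never including Tmax) is
    scanned and the fit with the best adjusted r² wins; an explicit index
    ``selection`` overrides the scan.
    """
    t = np.asarray(times, float)
    c = np.asarray(concs, float)
    if selection is not None:
        idx = np.asarray(selection, int)
        return _fit_tail(t, c, idx)
    pos = np.where(c > 0)[0]
    if pos.size < 3:
        raise LambdaZError("need at least three positive concentrations")
    i_max = int(np.argmax(c))
    best: tuple[float, int, float] | None = None
    for n in range(3, max_points + 1):
        idx = pos[-n:]
        if idx.size < n or idx.min() <= i_max:
            continue
        try:
            cand = _fit_tail(t, c, idx)
        except LambdaZError:
            continue
        if best is None or cand[2] > best[2]:
            best = cand
    if best is None:
        raise LambdaZError("no positive decreasing terminal phase found")
    return best


def _fit_tail(t, c, idx) -> tuple[float, int, float]:
    if np.any(c[idx] <= 0):
        raise LambdaZError("non-positive concentration in terminal selection")
    x, y = t[idx], np.log(c[idx])
    n = x.size
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise LambdaZError("terminal phase is not declining")
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise LambdaZError("degenerate terminal concentrations")
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return -float(slope), int(n), float(r2_adj)


def summarize(
    profile: ConcentrationProfile | tuple[Sequence[float], Sequence[float]],
    dose_mg: float,
    t_end_h: float = 48.0,
    method: Literal["linear", "linear-up-log-down"] = "linear-up-log-down",
) -> PKSummary:
    """Full NCA on one profile.

    CL = dose / AUC0-inf (single-dose interpretation), Vd = CL / lambda_z,
    AUC0-inf = AUC0-tlast + Clast / lambda_z.
    """
    if isinstance(profile, ConcentrationProfile):
        t, c = profile.times_h, profile.plasma_conc_mg_L
    else:
        t, c = np.asarray(profile[0], float), np.asarray(profile[1], float)
    pos = np.where(c > 0)[0]
    if pos.size < 3:
        raise LambdaZError("profile has fewer than three positive concentrations")
    i_last = int(pos[-1])
    t_last, c_last = float(t[i_last]), float(c[i_last])
    i_max = int(np.argmax(c))
    lz, n_lz, _ = lambda_z(t[: i_last + 1], c[: i_last + 1])
    auc_t = auc_trapezoid(t, c, method=method, t_end=t_last)
    auc_inf = auc_t + c_last / lz
    auc_48 = auc_trapezoid(t, c, method=method, t_end=min(t_end_h, float(t[-1])))
    cl = dose_mg / auc_inf
    return PKSummary(
        cmax_mg_L=float(c[i_max]),
        tmax_h=float(t[i_max]),
        auc_0_t_mg_h_L=auc_t,
        t_last_h=t_last,
        auc_0_inf_mg_h_L=auc_inf,
        auc_0_48_mg_h_L=auc_48,
        cl_L_h=cl,
        vd_L=cl / lz,
        t_half_h=LN2 / lz,
        lambda_z_per_h=lz,
        n_points_lambda_z=n_lz,
        dose_mg=dose_mg,
    )
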