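"""Compartmental disposition and non-compartmental analysis (NCA).

Disposition is a one- or two-compartment mamillary model with first-order
elimination from the central compartment, driven by an arbitrary systemic
input-rate function (typically the output of the GI absorption simulator)::

    dAc/dt = input(t) - (CL/Vc) Ac - k12 Ac + k21 Ap
    dAp/dt = k12 Ac - k21 Ap

Plasma concentration is C(t) = Ac / Vc (mg/L == ug/mL, reported in ng/mL).

NCA computes Cmax/Tmax, AUC0-t by the linear trapezoid, the terminal rate
constant lambda_z by unweighted log-linear regression over the last points
after Tmax, and AUC0-inf = AUC0-t + C_last / lambda_z.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    InsufficientDataError,
    IntegrationError,
    LambdaZEstimationError,
    ValidationError,
)
from .substances import DrugSubstance

__all__ = [
    "DispositionParams",
    "PlasmaProfile",
    "PKParameters",
    "derive_disposition",
    "simulate_disposition",
    "nca",
    "simulate_oral",
]

LN2 = math.log(2.0)


@dataclass
class DispositionParams:
    clearance_l_h: float
    vc_l: float
    k12_per_h: float = 0.0
    k21_per_h: float = 0.0

    def __post_init__(self) -> None:
        if self.clearance_l_h <= 0 or self.vc_l <= 0:
            raise ValidationError("clearance and Vc must be > 0")
        if (self.k12_per_h > 0) != (self.k21_per_h > 0):
            raise ValidationError("k12 and k21 must both be zero or both positive")
        if self.k12_per_h < 0 or self.k21_per_h < 0:
            raise ValidationError("micro-constants must be >= 0")

    @property
    def n_compartments(self) -> int:
        return 2 if self.k12_per_h > 0 else 1

    @property
    def ke_per_h(self) -> float:
        return self.clearance_l_h / self.vc_l


@dataclass
class PlasmaProfile:
    times_h: np.ndarray
    conc_ng_ml: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.conc_ng_ml, dtype=float)
        if t.size != c.size:
            raise ValidationError("times and concentrations differ in length")
        if t.size == 0:
            raise ValidationError("empty plasma profile")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing from >= 0")
        if np.any(c < -1e-9):
            raise ValidationError("negative plasma concentrations")
        self.times_h = t
        self.conc_ng_ml = np.maximum(c, 0.0)


@dataclass
class PKParameters:
    cmax_ng_ml: float
    tmax_h: float
    auc_0_t_ng_h_ml: float
    auc_0_inf_ng_h_ml: Optional[float]
    lambda_z_per_h: Optional[float]
    t_half_h: Optional[float]


def derive_disposition(drug: DrugSubstance) -> DispositionParams:
    """Fill disposition gaps from one-compartment relations.

    Missing clearance is computed as ``ln2 * Vc / t_half``; a missing
    half-life is implied by ``ln2 * Vc / CL``.  When all three are supplied
    but mutually inconsistent (beyond 5%) a warning is emitted and CL/Vc are
    treated as primary.  Micro-constants on the drug record (if any) switch
    the model to two compartments.
    """
    vc = drug.vc_l
    cl = drug.clearance_l_h
    t_half = drug.half_life_h
    if cl is None and t_half is None:
        raise InsufficientDataError(
            f"{drug.name}: need at least two of clearance, Vc, half-life"
        )
    if cl is None:
        cl = LN2 * vc / t_half
    elif t_half is not None:
        implied = LN2 * vc / cl
        if abs(implied - t_half) / t_half > 0.05:
            warnings.warn(
                f"{drug.name}: printed half-life {t_half} h is inconsistent "
                f"with CL/Vc (implied {implied:.2f} h); CL and Vc are treated "
                "as primary",
                stacklevel=2,
            )
    return DispositionParams(
        clearance_l_h=cl,
        vc_l=vc,
        k12_per_h=drug.k12_per_h or 0.0,
        k21_per_h=drug.k21_per_h or 0.0,
    )


InputRate = Union[Callable[[float], float], tuple[np.ndarray, np.ndarray]]


def simulate_disposition(
    input_rate: InputRate,
    params: DispositionParams,
    duration_h: float,
    step_h: float = 0.05,
    label: str = "",
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> PlasmaProfile:
    """Integrate the disposition ODEs driven by ``input_rate`` (mg/h).

    ``input_rate`` is either a callable of time (h) or a ``(times, rates)``
    pair interpolated linearly (zero outside its support).
    """
    if callable(input_rate):
        rate_fn = input_rate
    else:
        t_in, r_in = (np.asarray(a, dtype=float) for a in input_rate)
        rate_fn = lambda t: float(np.interp(t, t_in, r_in, left=0.0, right=0.0))

    ke = params.ke_per_h
    k12 = params.k12_per_h
    k21 = params.k21_per_h

    def rhs(t: float, y: np.ndarray) -> list[float]:
        ac, ap = y
        return [
            rate_fn(t) - ke * ac - k12 * ac + k21 * ap,
            k12 * ac - k21 * ap,
        ]

    times = np.arange(0.0, duration_h + 0.5 * step_h, step_h)
    result = solve_ivp(
        rhs, (0.0, times[-1]), [0.0, 0.0], t_eval=times, method="LSODA",
        rtol=rtol, atol=atol,
    )
    if not result.success:
        raise IntegrationError(f"disposition solver failed: {result.message}")
    conc = np.maximum(result.y[0], 0.0) / params.vc_l * 1000.0  # mg/L -> ng/mL
    return PlasmaProfile(times_h=times, conc_ng_ml=conc, label=label)


def _lambda_z(
    times: np.ndarray,
    conc: np.ndarray,
    tmax_idx: int,
    n_points: int,
    method: str,
) -> tuple[float, float]:
    """Terminal slope by log-linear regression; returns (lambda_z, r2_adj)."""
    mask = np.arange(times.size) > tmax_idx
    mask &= conc > 0
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        raise InsufficientDataError(
            "need >= 3 positive post-Tmax concentrations for lambda_z"
        )

    def fit(sel: np.ndarray) -> tuple[float, float]:
        x, y = times[sel], np.log(conc[sel])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        nn = sel.size
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        r2_adj = 1.0 - (1.0 - r2) * (nn - 1) / (nn - 2) if nn > 2 else r2
        return slope, r2_adj

    if method == "best_r2":
        best: Optional[tuple[float, float]] = None
        for k in range(3, idx.size + 1):
            slope, r2 = fit(idx[-k:])
            if slope < 0 and (best is None or r2 > best[1] + 1e-4):
                best = (slope, r2)
        if best is None:
            raise LambdaZEstimationError("no negative terminal slope found")
        slope, r2 = best
    else:
        sel = idx[-max(n_points, 3):]
        slope, r2 = fit(sel)
    if slope >= 0:
        raise LambdaZEstimationError(
            f"terminal regression slope {slope:.3g} is non-negative"
        )
    return -slope, r2


def nca(
    profile: PlasmaProfile,
    lambda_z_points: int = 3,
    lambda_z_method: str = "last_n",
) -> PKParameters:
    """Non-compartmental summary of a plasma concentration-time profile.

    ``lambda_z_method`` is ``"last_n"`` (default: the last
    ``lambda_z_points`` positive samples after Tmax) or ``"best_r2"``
    (adjusted-R2 maximisation over terminal windows).  When fewer than three
    usable terminal points exist, AUC0-inf/lambda_z are reported as None
    with a warning.
    """
    t = profile.times_h
    c = profile.conc_ng_ml
    if t.size < 2:
        raise InsufficientDataError("NCA requires at least two samples")
    tmax_idx = int(np.argmax(c))
    cmax = float(c[tmax_idx])
    tmax = float(t[tmax_idx])
    auc_t = float(np.trapezoid(c, t))
    if cmax == 0.0:
        warnings.warn("all-zero profile: lambda_z undefined", stacklevel=2)
        return PKParameters(0.0, tmax, 0.0, None, None, None)
    try:
        lam, _ = _lambda_z(t, c, tmax_idx, lambda_z_points, lambda_z_method)
    except InsufficientDataError as exc:
        warnings.warn(f"AUC0-inf omitted: {exc}", stacklevel=2)
        return PKParameters(cmax, tmax, auc_t, None, None, None)
    auc_inf = auc_t + float(c[-1]) / lam
    return PKParameters(cmax, tmax, auc_t, auc_inf, lam, LN2 / lam)


def simulate_oral(
    drug: DrugSubstance,
    physiology,
    config,
    disposition: Optional[DispositionParams] = None,
    label: str = "",
):
    """Convenience chain: GI absorption -> disposition -> NCA.

    Returns ``(absorption_result, plasma_profile, pk_parameters)``.
    """
    from .absorption import simulate_absorption  # local import: no cycle at module load

    absorption = simulate_absorption(drug, physiology, config)
    params = disposition or derive_disposition(drug)
    plasma = simulate_disposition(
        (absorption.times_h, absorption.input_rate_mg_h),
        params,
        duration_h=config.duration_h,
        step_h=config.output_step_h,
        label=label or drug.name,
    )
    if drug.dose_mg == 0:
        metrics = PKParameters(0.0, 0.0, 0.0, None, None, None)
    else:
        metrics = nca(plasma)
    return absorption, plasma, metrics
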