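"""Synthetic study-data generators.

Every pipeline stage can be exercised without external data:

* :func:`gen_dissolution` — monotone Weibull release curves
  ``F(t) = f_max (1 - exp(-(t/t_d)^beta))`` with additive Gaussian assay
  noise, clamped to the 0-110% assay window,
* :func:`gen_plasma` — oral concentration-time curves from the Bateman
  equation (first-order absorption, one-compartment disposition) with
  multiplicative lognormal noise,
* :func:`gen_stability` — first-order chemical degradation series
  ``A(t) = a0 exp(-k_deg t)`` with additive Gaussian assay noise.

All generators are deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dissolution import DissolutionProfile
from .errors import ValidationError
from .evaluation import StabilitySeries
from .pk import DispositionParams, PlasmaProfile

__all__ = [
    "WeibullReleaseSpec",
    "DegradationSpec",
    "gen_dissolution",
    "gen_plasma",
    "gen_stability",
    "bateman_concentration",
]

#: Default in-vitro sampling design (min).
DEFAULT_SAMPLING_MIN = (5.0, 10.0, 15.0, 20.0, 30.0)


@dataclass
class WeibullReleaseSpec:
    f_max: float = 100.0         # plateau, %
    t_d: float = 6.0             # 63.2% time scale, min
    beta: float = 1.0            # shape
    noise_sd: float = 0.0        # additive Gaussian sd, %
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f_max <= 110:
            raise ValidationError("f_max must be in (0, 110]")
        if self.t_d <= 0 or self.beta <= 0:
            raise ValidationError("t_d and beta must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class DegradationSpec:
    a0: float = 100.0            # initial assay, %
    k_deg: float = 0.01          # 1/week
    times_weeks: Sequence[float] = (0.0, 1.0, 2.0, 3.0, 4.0)
    noise_sd: float = 0.0        # additive Gaussian sd, %
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValidationError("a0 must be > 0")
        if self.k_deg < 0:
            raise ValidationError("k_deg must be >= 0")


def gen_dissolution(
    spec: WeibullReleaseSpec,
    times_min: Sequence[float] = DEFAULT_SAMPLING_MIN,
    product: str = "synthetic",
    medium_ph: float = 6.8,
) -> DissolutionProfile:
    """Weibull release curve sampled at ``times_min`` with assay noise."""
    t = np.asarray(times_min, dtype=float)
    curve = spec.f_max * (1.0 - np.exp(-((t / spec.t_d) ** spec.beta)))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        curve = curve + rng.normal(0.0, spec.noise_sd, size=t.size)
    curve = np.clip(curve, 0.0, 110.0)
    return DissolutionProfile(
        product=product, medium_ph=medium_ph, timepoints_min=t, pct_dissolved=curve
    )


def bateman_concentration(
    t_h: np.ndarray,
    disposition: DispositionParams,
    ka_per_h: float,
    dose_mg: float,
    f_abs: float,
) -> np.ndarray:
    """Analytic oral one-compartment curve (ng/mL); handles the ka == ke limit."""
    ke = disposition.ke_per_h
    amount_scale = f_abs * dose_mg / disposition.vc_l * 1000.0  # ng/mL
    t = np.asarray(t_h, dtype=float)
    if abs(ka_per_h - ke) < 1e-9 * max(ka_per_h, ke):
        return amount_scale * ke * t * np.exp(-ke * t)
    return (
        amount_scale * ka_per_h / (ka_per_h - ke)
        * (np.exp(-ke * t) - np.exp(-ka_per_h * t))
    )


def gen_plasma(
    disposition: DispositionParams,
    ka_per_h: float,
    dose_mg: float,
    f_abs: float,
    times_h: Sequence[float],
    noise_cv_pct: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> PlasmaProfile:
    """Bateman oral curve with multiplicative lognormal noise (median 1)."""
    if ka_per_h <= 0:
        raise ValidationError("ka must be > 0")
    if not 0 <= f_abs <= 1:
        raise ValidationError("f_abs must be in [0, 1]")
    if noise_cv_pct < 0:
        raise ValidationError("noise CV must be >= 0")
    t = np.asarray(times_h, dtype=float)
    conc = bateman_concentration(t, disposition, ka_per_h, dose_mg, f_abs)
    if noise_cv_pct > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + (noise_cv_pct / 100.0) ** 2))
        conc = conc * np.exp(sigma * rng.standard_normal(t.size))
    return PlasmaProfile(times_h=t, conc_ng_ml=np.maximum(conc, 0.0), label=label)


def gen_stability(spec: DegradationSpec, drug: str = "synthetic") -> StabilitySeries:
    """First-order degradation series with assay noise."""
    t = np.asarray(spec.times_weeks, dtype=float)
    values = spec.a0 * np.exp(-spec.k_deg * t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=t.size)
    labels = [
        "Initial" if w == 0 else f"Week {w:g}" for w in t
    ]
    return StabilitySeries(drug=drug, week_labels=labels,
                           pct_remaining=list(values))
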