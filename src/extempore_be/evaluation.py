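"""Model verification and product-quality assessment.

* percent prediction error (%PE) of simulated vs observed PK parameters,
* Monte-Carlo virtual bioequivalence: lognormal between-subject variability
  applied identically to test and reference (virtual crossover), geometric
  mean ratio with a 90% t-interval judged against the 80-125% window,
* stability-series assessment against a %-remaining acceptance band,
* rheology classification from a shear-rate/viscosity sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .absorption import GICompartment, SimulationConfig
from .errors import InsufficientDataError, UndefinedValueError, ValidationError
from .pk import DispositionParams, derive_disposition, simulate_oral
from .substances import DrugSubstance

__all__ = [
    "PEResult",
    "BEResult",
    "BEScenario",
    "StabilitySeries",
    "StabilityAssessment",
    "percent_prediction_error",
    "be_verdict",
    "virtual_bioequivalence",
    "assess_stability",
    "classify_rheology",
]

BE_LOWER_PCT = 80.0
BE_UPPER_PCT = 125.0

#: Default between-subject variability (CV%) for virtual bioequivalence.
DEFAULT_BE_VARIABILITY: Dict[str, float] = {
    "clearance": 20.0,
    "vc": 20.0,
    "peff": 20.0,
    "stomach_transit": 20.0,
}


@dataclass
class PEResult:
    parameter: str
    predicted: float
    observed: float
    pe_pct: float
    pe_abs_pct: float


@dataclass
class BEResult:
    metric: str                # "cmax" | "auc_inf"
    gmr_pct: float
    ci90_lo_pct: float
    ci90_hi_pct: float
    n_subjects: int
    seed: int
    verdict: str               # "pass" | "fail"
    subject_log_ratios: Optional[List[float]] = None  # audit trail


@dataclass
class StabilitySeries:
    drug: str
    week_labels: Sequence[str]
    pct_remaining: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.week_labels) != len(self.pct_remaining):
            raise ValidationError("week labels and values differ in length")
        if len(self.pct_remaining) == 0:
            raise ValidationError("empty stability series")
        if any(v <= 0 for v in self.pct_remaining):
            raise ValidationError("%-remaining values must be > 0")


@dataclass
class StabilityAssessment:
    passed: bool
    min_value: float
    first_failing_week: Optional[str]


@dataclass
class BEScenario:
    """Everything needed to simulate one formulation arm."""

    drug: DrugSubstance
    physiology: List[GICompartment]
    config: SimulationConfig
    disposition: Optional[DispositionParams] = None


def percent_prediction_error(
    predicted: float, observed: float, parameter: str = ""
) -> PEResult:
    """Signed %PE = (predicted - observed)/observed * 100, plus magnitude."""
    if observed == 0:
        raise UndefinedValueError("%PE undefined for a zero observed value")
    pe = (predicted - observed) / observed * 100.0
    return PEResult(parameter, predicted, observed, pe, abs(pe))


def be_verdict(ci_lo_pct: float, ci_hi_pct: float) -> str:
    """``pass`` iff the whole 90% CI lies within [80, 125]%."""
    if ci_lo_pct > ci_hi_pct:
        raise ValidationError("CI lower bound exceeds upper bound")
    ok = ci_lo_pct >= BE_LOWER_PCT and ci_hi_pct <= BE_UPPER_PCT
    return "pass" if ok else "fail"


def _perturbed_arm(
    scenario: BEScenario, multipliers: Dict[str, float]
) -> BEScenario:
    drug = scenario.drug.model_copy()
    base = scenario.disposition or derive_disposition(scenario.drug)
    disp = DispositionParams(
        clearance_l_h=base.clearance_l_h * multipliers.get("clearance", 1.0),
        vc_l=base.vc_l * multipliers.get("vc", 1.0),
        k12_per_h=base.k12_per_h,
        k21_per_h=base.k21_per_h,
    )
    drug.peff_cm_s = drug.peff_cm_s * multipliers.get("peff", 1.0)
    physiology = [replace(c) for c in scenario.physiology]
    physiology[0].transit_time_h *= multipliers.get("stomach_transit", 1.0)
    return BEScenario(drug, physiology, scenario.config, disp)


def virtual_bioequivalence(
    test: BEScenario,
    reference: BEScenario,
    variability: Optional[Dict[str, float]] = None,
    n_subjects: int = 24,
    seed: int = 0,
) -> List[BEResult]:
    """Monte-Carlo crossover bioequivalence trial on simulated subjects.

    Each virtual subject draws one lognormal multiplier (median 1, the
    stated CV%) per parameter in ``variability`` and both formulations are
    simulated with the *same* multipliers (within-subject crossover, so the
    ratio isolates the formulation effect).  Returns the geometric mean
    ratio and 90% t-interval for Cmax and AUC0-inf, each judged against
    80-125%.
    """
    if n_subjects < 2:
        raise ValidationError("need at least 2 subjects for a confidence interval")
    variability = DEFAULT_BE_VARIABILITY if variability is None else variability
    if any(cv < 0 for cv in variability.values()):
        raise ValidationError("CV% values must be >= 0")
    rng = np.random.default_rng(seed)

    log_ratios: Dict[str, List[float]] = {"cmax": [], "auc_inf": []}
    failures = 0
    for _ in range(n_subjects):
        multipliers = {}
        for param, cv in sorted(variability.items()):
            sigma = math.sqrt(math.log(1.0 + (cv / 100.0) ** 2))
            multipliers[param] = math.exp(sigma * rng.standard_normal())
        try:
            arms = {}
            for name, scenario in (("test", test), ("reference", reference)):
                arm = _perturbed_arm(scenario, multipliers)
                _, _, metrics = simulate_oral(
                    arm.drug, arm.physiology, arm.config, arm.disposition
                )
                if metrics.auc_0_inf_ng_h_ml is None:
                    raise UndefinedValueError("AUC0-inf unavailable")
                arms[name] = metrics
        except Exception:
            failures += 1
            if failures > 0.1 * n_subjects:
                raise
            continue
        log_ratios["cmax"].append(
            math.log(arms["test"].cmax_ng_ml / arms["reference"].cmax_ng_ml)
        )
        log_ratios["auc_inf"].append(
            math.log(arms["test"].auc_0_inf_ng_h_ml / arms["reference"].auc_0_inf_ng_h_ml)
        )

    results = []
    for metric, values in log_ratios.items():
        arr = np.asarray(values)
        n = arr.size
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if n > 1 else 0.0
        if sd > 0:
            half = stats.t.ppf(0.95, n - 1) * sd / math.sqrt(n)
        else:
            half = 0.0
        gmr = 100.0 * math.exp(mean)
        lo = 100.0 * math.exp(mean - half)
        hi = 100.0 * math.exp(mean + half)
        results.append(
            BEResult(metric, gmr, lo, hi, n, seed, be_verdict(lo, hi),
                     subject_log_ratios=list(arr))
        )
    return results


def assess_stability(
    series: StabilitySeries, lower_pct: float = 90.0, upper_pct: float = 110.0
) -> StabilityAssessment:
    """Pass iff every %-remaining value lies within [lower, upper]."""
    values = np.asarray(series.pct_remaining, dtype=float)
    in_range = (values >= lower_pct) & (values <= upper_pct)
    first_fail = None
    if not in_range.all():
        first_fail = series.week_labels[int(np.argmin(in_range))]
    return StabilityAssessment(
        passed=bool(in_range.all()),
        min_value=float(values.min()),
        first_failing_week=first_fail,
    )


def classify_rheology(
    shear_rates_per_s: Sequence[float],
    viscosities_cp: Sequence[float],
    rel_tol: float = 0.05,
) -> str:
    """``dilatant`` | ``pseudoplastic`` | ``newtonian`` from a shear sweep.

    The total relative viscosity change across the sweep must exceed
    ``rel_tol`` (default 5%) to call a trend; smaller changes are Newtonian.
    """
    rates = np.asarray(shear_rates_per_s, dtype=float)
    visc = np.asarray(viscosities_cp, dtype=float)
    if rates.size < 3 or visc.size != rates.size:
        raise InsufficientDataError("need >= 3 paired shear-rate/viscosity points")
    if np.any(np.diff(rates) <= 0):
        raise ValidationError("shear rates must be strictly increasing")
    rel_change = (visc[-1] - visc[0]) / visc[0]
    if rel_change > rel_tol:
        return "dilatant"
    if rel_change < -rel_tol:
        return "pseudoplastic"
    return "newtonian"
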