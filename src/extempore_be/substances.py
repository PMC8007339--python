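"""Drug substances: physicochemical/biopharmaceutic parameter sets and the
pH-dependent quantities derived from them.

A :class:`DrugSubstance` collects everything the oral-absorption simulator
needs to know about one active ingredient: ionization (pKa values tagged as
acidic or basic sites), a reference aqueous solubility at a stated pH,
effective intestinal permeability (with the assay it came from), dose and
dose volume, particle and diffusion properties governing dissolution
kinetics, and the disposition parameters (clearance, central volume,
half-life) used downstream.

Two derived quantities are computed here:

* :func:`solubility_at_ph` — Henderson–Hasselbalch scaling of the reference
  solubility, with a configurable cap on the total solubilization ratio
  (weak acids and bases otherwise extrapolate to physically absurd values
  far from their pKa).
* :func:`effective_permeability` — the human effective permeability, with an
  optional per-assay linear conversion (identity by default: assay values
  are used as given).
"""

from __future__ import annotations

from typing import Literal, Mapping, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Pka",
    "DrugSubstance",
    "solubility_at_ph",
    "effective_permeability",
    "ionization_factor",
]

DEFAULT_SR_MAX = 1000.0
"""Default cap on the solubilization ratio S(pH)/S0.

Anchored to the ~1000-fold solubility increase reported for valsartan
between pH 4 and pH 6; beyond that, other mechanisms (common-ion effects,
salt solubility products) limit dissolution and the pure ionization model
is no longer credible.
"""


class Pka(BaseModel):
    """One ionizable site: its pKa and whether it is acidic or basic."""

    value: float
    species: Literal["acid", "base"]


class DrugSubstance(BaseModel):
    """Complete per-drug parameter set for absorption + disposition modeling.

    Units are encoded in the field names.  ``clearance_l_h`` may be omitted
    when ``half_life_h`` and ``vc_l_kg`` are given (and vice versa); see
    :func:`extempore_be.pk.derive_disposition`.
    """

    model_config = ConfigDict(frozen=False)

    name: str
    molecular_weight_g_mol: float = Field(gt=0)
    log_d: float
    log_d_ref_ph: float = 7.4
    pka_values: list[Pka] = Field(default_factory=list)
    ref_solubility_mg_ml: float = Field(gt=0)
    ref_solubility_ph: float
    peff_cm_s: float = Field(ge=0)
    peff_assay: Literal["human", "caco2", "rat"] = "human"
    dose_mg: float = Field(ge=0)
    dose_volume_ml: float = Field(gt=0, default=250.0)
    mean_precipitation_time_s: float = Field(gt=0, default=900.0)
    diffusion_coefficient_cm2_s: float = Field(gt=0)
    particle_density_g_ml: float = Field(gt=0, default=1.2)
    particle_radius_um: float = Field(gt=0, default=25.0)
    blood_plasma_ratio: float = Field(gt=0, default=1.0)
    fraction_unbound_pct: float = Field(gt=0, le=100, default=100.0)
    clearance_l_h: Optional[float] = Field(default=None, gt=0)
    vc_l_kg: float = Field(gt=0)
    half_life_h: Optional[float] = Field(default=None, gt=0)
    body_weight_kg: float = Field(gt=0, default=70.0)
    # --- model-level constants (not physicochemical measurements) -------
    absorption_scale: float = Field(ge=0, default=1.0)
    """Drug-level multiplier on the compartmental absorption scale factors,
    fixed once during model verification against observed oral exposure
    (the in-silico analogue of calibrating a permeability input)."""
    colonic_absorption: bool = True
    """Whether the drug is absorbed from caecum/colon at all.  False for
    compounds whose absorption window is the upper GI tract (e.g. acids
    fully ionized at intestinal pH)."""
    k12_per_h: Optional[float] = Field(default=None, gt=0)
    k21_per_h: Optional[float] = Field(default=None, gt=0)
    simulation_time_h: float = Field(gt=0, default=72.0)

    @model_validator(mode="after")
    def _check_disposition_identifiable(self) -> "DrugSubstance":
        if self.clearance_l_h is None and self.half_life_h is None:
            raise ValueError(
                "at least two of clearance, Vc, half-life are required; "
                "got Vc only"
            )
        if (self.k12_per_h is None) != (self.k21_per_h is None):
            raise ValueError("k12 and k21 must be supplied together")
        return self

    @property
    def vc_l(self) -> float:
        """Central volume in litres (Vc per kg times body weight)."""
        return self.vc_l_kg * self.body_weight_kg


def ionization_factor(drug: DrugSubstance, ph: float) -> float:
    """Henderson–Hasselbalch total/neutral concentration ratio HH(pH).

    For a monoprotic base: ``1 + 10**(pKa - pH)``.  For a diprotic acid:
    ``1 + 10**(pH - pKa1) + 10**(2 pH - pKa1 - pKa2)``.  General polyprotic
    forms follow the same cumulative pattern.  A drug with no ionizable
    sites returns 1.  Mixed acid/base (zwitterionic) definitions are not
    supported and raise :class:`ConfigurationError`.
    """
    if not drug.pka_values:
        return 1.0
    species = {p.species for p in drug.pka_values}
    if species == {"base"}:
        pkas = sorted((p.value for p in drug.pka_values), reverse=True)
        total, cum = 1.0, 0.0
        for pka in pkas:
            cum += pka - ph
            total += 10.0**cum
        return total
    if species == {"acid"}:
        pkas = sorted(p.value for p in drug.pka_values)
        total, cum = 1.0, 0.0
        for pka in pkas:
            cum += ph - pka
            total += 10.0**cum
        return total
    raise ConfigurationError(
        f"{drug.name}: mixed or unknown ionization species tags {species!r}"
    )


def solubility_at_ph(
    drug: DrugSubstance, ph: float, sr_max: float = DEFAULT_SR_MAX
) -> float:
    """Aqueous solubility (mg/mL) at a luminal pH.

    The reference solubility is back-corrected to an intrinsic (neutral
    species) solubility ``S0 = S_ref / min(HH(ref_ph), sr_max)`` and then
    scaled forward: ``S(pH) = S0 * min(HH(pH), sr_max)``.  The cap makes the
    function saturate rather than grow without bound far from the pKa, and
    guarantees ``S(ref_ph) == S_ref`` exactly.

    Parameters
    ----------
    ph
        Luminal pH, restricted to the physiological window [1, 9].
    sr_max
        Maximum solubilization ratio (>= 1).
    """
    if not 1.0 <= ph <= 9.0:
        raise ValidationError(f"pH {ph} outside supported range [1, 9]")
    if sr_max < 1.0:
        raise ValidationError(f"sr_max must be >= 1, got {sr_max}")
    s0 = drug.ref_solubility_mg_ml / min(
        ionization_factor(drug, drug.ref_solubility_ph), sr_max
    )
    return s0 * min(ionization_factor(drug, ph), sr_max)


def effective_permeability(
    drug: DrugSubstance, conversion: Optional[Mapping[str, float]] = None
) -> float:
    """Human effective jejunal permeability (cm/s).

    ``conversion`` maps assay name -> linear scale factor; any assay not in
    the map uses factor 1.0.  The default (identity for every assay) takes
    the tabulated value at face value regardless of its experimental origin.
    """
    factor = 1.0
    if conversion is not None:
        factor = float(conversion.get(drug.peff_assay, 1.0))
    if factor < 0:
        raise ValidationError(f"negative permeability conversion factor {factor}")
    return drug.peff_cm_s * factor
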