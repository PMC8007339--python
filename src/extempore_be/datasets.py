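"""Bundled study inputs for the amlodipine/valsartan 5/80 worked example.

All printed inputs of the compounded-suspension study ship with the package
as plain-text data files: the two drug parameter sets, the two-timepoint
dissolution table (2 drugs x tablet/suspension x 3 media), the four-week
stability series, the batch formula, and the observed/reported PK values
used for model verification.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List

import yaml

from .dissolution import DissolutionProfile
from .evaluation import StabilitySeries
from .formulation import BatchSpec
from . import io as eio
from .substances import DrugSubstance

__all__ = [
    "load_drug",
    "two_point_dissolution",
    "dissolution_profiles_for",
    "stability_series",
    "batch_formula",
    "observed_pk",
    "DRUGS",
    "MEDIA_PH",
]

DRUGS = ("amlodipine", "valsartan")
MEDIA_PH = (1.2, 4.5, 6.8)


def _data_path(name: str):
    return resources.files("extempore_be").joinpath("data", name)


def load_drug(name: str) -> DrugSubstance:
    """Bundled drug definition: ``"amlodipine"`` or ``"valsartan"``."""
    if name not in DRUGS:
        raise KeyError(f"unknown bundled drug {name!r}; choose from {DRUGS}")
    with resources.as_file(_data_path(f"{name}.yaml")) as path:
        return eio.load_drug_file(path)


def two_point_dissolution() -> List[DissolutionProfile]:
    """All 12 bundled two-timepoint dissolution profiles."""
    with resources.as_file(_data_path("dissolution_two_point.csv")) as path:
        return eio.read_dissolution_csv(path)


def dissolution_profiles_for(
    drug: str, product: str
) -> Dict[float, DissolutionProfile]:
    """Map medium pH -> profile for one drug and product (tablet|suspension)."""
    wanted = f"{drug}_{product}"
    out = {
        p.medium_ph: p for p in two_point_dissolution() if p.product == wanted
    }
    if not out:
        raise KeyError(f"no bundled profiles for {wanted!r}")
    return out


def stability_series() -> Dict[str, StabilitySeries]:
    with resources.as_file(_data_path("stability_4week.csv")) as path:
        return {s.drug: s for s in eio.read_stability_csv(path)}


def batch_formula() -> BatchSpec:
    with resources.as_file(_data_path("formula_5_80.yaml")) as path:
        return eio.load_batch_file(path)


def observed_pk() -> Dict[str, Dict[str, Dict[str, float]]]:
    """Observed tablet PK and the published model predictions, per drug."""
    with resources.as_file(_data_path("observed_pk.yaml")) as path:
        with open(path) as fh:
            return yaml.safe_load(fh)
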