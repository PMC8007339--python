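"""File formats: delimited tables, structured configuration, JSON reports.

All schemas carry units in the column/key names (``time_min``,
``conc_ng_ml``); nothing is inferred.  Readers validate strictly and name
the offending row/column; every writer/reader pair round-trips to 12
significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd
import yaml

from .dissolution import DissolutionProfile
from .errors import ValidationError
from .evaluation import StabilitySeries
from .formulation import BatchSpec, FormulaComponent
from .absorption import GICompartment
from .pk import PlasmaProfile
from .substances import DrugSubstance

__all__ = [
    "read_dissolution_csv",
    "write_dissolution_csv",
    "read_plasma_csv",
    "write_plasma_csv",
    "read_stability_csv",
    "write_stability_csv",
    "load_drug_file",
    "load_batch_file",
    "load_physiology_file",
    "write_json_report",
]

PathLike = Union[str, Path]

_DISSOLUTION_COLS = ["product", "medium_ph", "time_min", "pct_dissolved"]
_PLASMA_COLS = ["time_h", "conc_ng_ml", "label"]
_STABILITY_COLS = ["week", "drug", "pct_remaining"]


def _require_columns(df: pd.DataFrame, cols: List[str], path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def _require_numeric(df: pd.DataFrame, cols: List[str], path: PathLike) -> None:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric value in column {col!r}, row {bad[0] + 2}"
            )
        if df[col].isna().any():
            raise ValidationError(f"{path}: empty cell in column {col!r}")
        df[col] = coerced


def read_dissolution_csv(path: PathLike) -> List[DissolutionProfile]:
    """One profile per (product, medium_ph) group, times sorted as given."""
    df = pd.read_csv(path)
    _require_columns(df, _DISSOLUTION_COLS, path)
    _require_numeric(df, ["medium_ph", "time_min", "pct_dissolved"], path)
    profiles = []
    for (product, ph), group in df.groupby(["product", "medium_ph"], sort=False):
        times = group["time_min"].to_numpy()
        if np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"{path}: times not strictly increasing for product={product!r}, "
                f"medium_ph={ph}"
            )
        sd = group["sd"].to_numpy() if "sd" in group.columns else None
        profiles.append(
            DissolutionProfile(
                product=str(product),
                medium_ph=float(ph),
                timepoints_min=times,
                pct_dissolved=group["pct_dissolved"].to_numpy(),
                replicate_sd=sd,
            )
        )
    if not profiles:
        raise ValidationError(f"{path}: no dissolution rows")
    return profiles


def write_dissolution_csv(profiles: List[DissolutionProfile], path: PathLike) -> None:
    rows = []
    for p in profiles:
        for i, t in enumerate(p.timepoints_min):
            row = {
                "product": p.product,
                "medium_ph": p.medium_ph,
                "time_min": t,
                "pct_dissolved": p.pct_dissolved[i],
            }
            if p.replicate_sd is not None:
                row["sd"] = p.replicate_sd[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_plasma_csv(path: PathLike) -> List[PlasmaProfile]:
    df = pd.read_csv(path)
    _require_columns(df, ["time_h", "conc_ng_ml"], path)
    if "label" not in df.columns:
        df["label"] = ""
    _require_numeric(df, ["time_h", "conc_ng_ml"], path)
    profiles = []
    for label, group in df.groupby("label", sort=False):
        times = group["time_h"].to_numpy()
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"{path}: times not strictly increasing for {label!r}")
        profiles.append(
            PlasmaProfile(
                times_h=times,
                conc_ng_ml=group["conc_ng_ml"].to_numpy(),
                label=str(label),
            )
        )
    return profiles


def write_plasma_csv(profiles: List[PlasmaProfile], path: PathLike) -> None:
    frames = [
        pd.DataFrame(
            {"time_h": p.times_h, "conc_ng_ml": p.conc_ng_ml, "label": p.label}
        )
        for p in profiles
    ]
    pd.concat(frames).to_csv(path, index=False, float_format="%.12g")


def read_stability_csv(path: PathLike) -> List[StabilitySeries]:
    df = pd.read_csv(path)
    _require_columns(df, _STABILITY_COLS, path)
    _require_numeric(df, ["pct_remaining"], path)
    return [
        StabilitySeries(
            drug=str(drug),
            week_labels=[str(w) for w in group["week"]],
            pct_remaining=list(group["pct_remaining"]),
        )
        for drug, group in df.groupby("drug", sort=False)
    ]


def write_stability_csv(series: List[StabilitySeries], path: PathLike) -> None:
    rows = [
        {"week": w, "drug": s.drug, "pct_remaining": v}
        for s in series
        for w, v in zip(s.week_labels, s.pct_remaining)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def load_drug_file(path: PathLike) -> DrugSubstance:
    """Parse a structured drug-definition document (YAML)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: drug file must be a mapping")
    raw = {k: v for k, v in raw.items() if v is not None}
    return DrugSubstance(**raw)


def load_batch_file(path: PathLike) -> BatchSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    components = [FormulaComponent(**c) for c in raw.pop("components", [])]
    return BatchSpec(components=components, **raw)


def load_physiology_file(path: PathLike) -> List[GICompartment]:
    """Structured list of GI compartments (full override of the defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValidationError(f"{path}: physiology file must be a non-empty list")
    return [GICompartment(**entry) for entry in raw]


class _ReportEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, Path):
            return str(obj)
        if hasattr(obj, "__dataclass_fields__"):
            return {f: getattr(obj, f) for f in obj.__dataclass_fields__}
        return super().default(obj)


def write_json_report(report: Dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, cls=_ReportEncoder)
        fh.write("\n")
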