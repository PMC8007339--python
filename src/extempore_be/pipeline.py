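"""End-to-end pipeline: dissolution -> absorption -> PK -> evaluation -> report.

The study workflow this orchestrates: build and verify an absorption+PK
model for the immediate-release tablet from its in-vitro dissolution, then
apply the same model to the compounded suspension's dissolution data to
predict its in-vivo behaviour, verify with %PE against observed tablet PK,
and (optionally) run a Monte-Carlo virtual bioequivalence trial with the
suspension as test and the tablet as reference.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field

from . import datasets
from . import io as eio
from .absorption import SimulationConfig, default_fasted_physiology
from .dissolution import (
    classify_release,
    f1_difference,
    f2_similarity,
    similarity_verdict,
)
from .errors import ConfigurationError, ExtemporeError
from .evaluation import (
    BEScenario,
    percent_prediction_error,
    virtual_bioequivalence,
)
from .pk import derive_disposition, simulate_oral
from .substances import DrugSubstance

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("extempore_be")

DosageForm = Literal["ir_tablet", "ir_suspension"]
_FORM_TO_PRODUCT = {"ir_tablet": "tablet", "ir_suspension": "suspension"}


class PipelineConfig(BaseModel):
    """Resolved description of one pipeline run."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    drug: Union[str, dict]
    dosage_form: DosageForm = "ir_tablet"
    dissolution_csv: Optional[Path] = None
    reference_dissolution_csv: Optional[Path] = None
    physiology_file: Optional[Path] = None
    duration_h: Optional[float] = None
    output_step_h: float = 0.05
    dissolution_mode: Literal["tabulated", "mechanistic_johnson"] = "tabulated"
    observed: Optional[Dict[str, float]] = None   # {"cmax": .., "auc_0_inf": ..}
    run_vbe: bool = False
    vbe_n_subjects: int = Field(default=24, ge=2)
    vbe_cv_pct: Optional[Dict[str, float]] = None
    seed: Optional[int] = None
    out_dir: Path = Path("extempore_be_out")


def _resolve_drug(config: PipelineConfig) -> DrugSubstance:
    if isinstance(config.drug, str):
        return datasets.load_drug(config.drug)
    return DrugSubstance(**config.drug)


def _profiles(config: PipelineConfig, drug_name: str, product: str, path_attr: str):
    path = getattr(config, path_attr)
    if path is not None:
        profiles = eio.read_dissolution_csv(path)
        return {p.medium_ph: p for p in profiles}
    return datasets.dissolution_profiles_for(drug_name, product)


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute the full chain and write the report bundle to ``out_dir``.

    Returns the report as a dict.  Stage failures raise
    :class:`ExtemporeError` subclasses after writing whatever partial
    outputs already exist.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: Dict = {"config": config.model_dump(mode="json"), "stages": {}}

    stage = "load"
    try:
        drug = _resolve_drug(config)
        product = _FORM_TO_PRODUCT[config.dosage_form]
        other = "tablet" if product == "suspension" else "suspension"
        logger.info("pipeline: drug=%s form=%s", drug.name, config.dosage_form)

        test_profiles = _profiles(config, drug.name, product, "dissolution_csv")
        try:
            ref_profiles = _profiles(
                config, drug.name, other, "reference_dissolution_csv"
            )
        except KeyError:
            ref_profiles = None

        stage = "dissolution"
        dissolution_report = {}
        for ph, profile in sorted(test_profiles.items()):
            entry = {"release_class": classify_release(profile)}
            if ref_profiles is not None and ph in ref_profiles:
                # reference role is always the tablet
                ref = ref_profiles[ph] if product == "suspension" else profile
                tst = profile if product == "suspension" else ref_profiles[ph]
                f1 = f1_difference(ref, tst)
                f2 = f2_similarity(ref, tst)
                entry.update(
                    f1=f1, f2=f2, verdict=similarity_verdict(f1, f2),
                    reference=ref.product, test=tst.product,
                )
            dissolution_report[f"ph_{ph:g}"] = entry
        report["stages"]["dissolution"] = dissolution_report
        logger.info("dissolution stage: %s", dissolution_report)

        stage = "absorption+pk"
        physiology = (
            eio.load_physiology_file(config.physiology_file)
            if config.physiology_file
            else default_fasted_physiology()
        )
        sim_config = SimulationConfig(
            duration_h=config.duration_h or drug.simulation_time_h,
            output_step_h=config.output_step_h,
            dissolution_mode=config.dissolution_mode,
            tabulated_profiles=(
                test_profiles if config.dissolution_mode == "tabulated" else None
            ),
        )
        disposition = derive_disposition(drug)
        absorption, plasma, metrics = simulate_oral(
            drug, physiology, sim_config, disposition,
            label=f"{drug.name}_{product}",
        )
        eio.write_plasma_csv([plasma], out_dir / "plasma.csv")
        pk_block = {
            "fraction_absorbed": absorption.fraction_absorbed,
            "mass_balance_error_mg": absorption.mass_balance_error_mg,
            "disposition": asdict(disposition),
            "nca": asdict(metrics),
        }
        report["stages"]["pk"] = pk_block
        eio.write_json_report(pk_block, out_dir / "pk_parameters.json")
        logger.info(
            "simulated %s %s: Fa=%.3f Cmax=%.4g AUCinf=%.5g",
            drug.name, product, absorption.fraction_absorbed,
            metrics.cmax_ng_ml, metrics.auc_0_inf_ng_h_ml or float("nan"),
        )

        stage = "evaluation"
        evaluation: Dict = {}
        observed = config.observed
        if observed is None and isinstance(config.drug, str):
            observed = datasets.observed_pk()[config.drug]["observed"]
        if observed and drug.dose_mg > 0:
            pe = {}
            if "cmax" in observed:
                pe["cmax"] = asdict(percent_prediction_error(
                    metrics.cmax_ng_ml, observed["cmax"], "cmax"))
            if "auc_0_inf" in observed and metrics.auc_0_inf_ng_h_ml is not None:
                pe["auc_0_inf"] = asdict(percent_prediction_error(
                    metrics.auc_0_inf_ng_h_ml, observed["auc_0_inf"], "auc_0_inf"))
            evaluation["percent_prediction_error"] = pe

        if config.run_vbe and drug.dose_mg > 0:
            if config.seed is None:
                raise ConfigurationError(
                    "virtual bioequivalence is stochastic: a seed is required"
                )
            suspension = BEScenario(
                drug, physiology,
                SimulationConfig(
                    duration_h=sim_config.duration_h,
                    output_step_h=max(config.output_step_h, 0.1),
                    dissolution_mode="tabulated",
                    tabulated_profiles=datasets.dissolution_profiles_for(
                        drug.name, "suspension"),
                    rtol=1e-6, atol=1e-9,
                ),
                disposition,
            )
            tablet = BEScenario(
                drug, physiology,
                SimulationConfig(
                    duration_h=sim_config.duration_h,
                    output_step_h=max(config.output_step_h, 0.1),
                    dissolution_mode="tabulated",
                    tabulated_profiles=datasets.dissolution_profiles_for(
                        drug.name, "tablet"),
                    rtol=1e-6, atol=1e-9,
                ),
                disposition,
            )
            be = virtual_bioequivalence(
                suspension, tablet,
                variability=config.vbe_cv_pct,
                n_subjects=config.vbe_n_subjects,
                seed=config.seed,
            )
            evaluation["virtual_bioequivalence"] = [asdict(b) for b in be]
            logger.info("virtual BE: %s", evaluation["virtual_bioequivalence"])

        report["stages"]["evaluation"] = evaluation
        eio.write_json_report(evaluation, out_dir / "evaluation.json")

        _write_summary(out_dir / "summary.txt", drug, product, report)
        eio.write_json_report(report, out_dir / "report.json")
        return report
    except ExtemporeError:
        eio.write_json_report(
            {"failed_stage": stage, "partial": report}, out_dir / "error_report.json"
        )
        raise


def _write_summary(path: Path, drug, product: str, report: Dict) -> None:
    lines = [
        f"extempore-be pipeline summary: {drug.name} ({product})",
        "",
        "Dissolution:",
    ]
    for ph, entry in report["stages"]["dissolution"].items():
        line = f"  {ph}: release={entry['release_class']}"
        if "f2" in entry:
            line += (f"  f1={entry['f1']:.2f} f2={entry['f2']:.2f}"
                     f" -> {entry['verdict']}")
        lines.append(line)
    pk = report["stages"]["pk"]
    nca_block = pk["nca"]
    lines += [
        "",
        f"Fraction absorbed: {pk['fraction_absorbed']:.3f}",
        f"Cmax: {nca_block['cmax_ng_ml']:.4g} ng/mL at Tmax {nca_block['tmax_h']:.2f} h",
    ]
    if nca_block["auc_0_inf_ng_h_ml"] is not None:
        lines.append(f"AUC0-inf: {nca_block['auc_0_inf_ng_h_ml']:.5g} ng*h/mL")
    ev = report["stages"].get("evaluation", {})
    for name, pe in ev.get("percent_prediction_error", {}).items():
        lines.append(
            f"%PE {name}: {pe['pe_pct']:+.2f}% "
            f"(predicted {pe['predicted']:.4g} vs observed {pe['observed']:.4g})"
        )
    for be in ev.get("virtual_bioequivalence", []):
        lines.append(
            f"VBE {be['metric']}: GMR {be['gmr_pct']:.1f}% "
            f"[{be['ci90_lo_pct']:.1f}, {be['ci90_hi_pct']:.1f}] -> {be['verdict']}"
        )
    path.write_text("\n".join(lines) + "\n")
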