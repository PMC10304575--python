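"""Configuration-driven experiment driver.

Reproduces the two in-silico experiment sets end to end on a model + diet:
(a) growth-rate changes under scaled-uptake scenarios (doubled glucose,
doubled essential amino acids, doubled single amino acid) and (b) fatty-acid
synthesis-rate ranges (FVA at 90% of the optimum) with the dietary
carbon-conversion efficiency, plus a model QC report.  Outputs are CSV/JSON
files and a machine-readable summary that is bit-identical across reruns
with the same configuration and seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import data
from .cce import cce_experiment
from .diet import ExchangeBounds, apply_diet
from .fluxopt import fba, run_perturbation_experiment
from .io import read_model
from .linear import PRIMAL_TOL, SOLVER_NAME
from .model import MetabolicModel
from .qc import qc_report
from .synthetic import SyntheticNetworkParams, generate_network, reference_diet

__all__ = ["ExperimentConfig", "run_pipeline"]

DEFAULT_SCENARIOS = ("doubled_glucose", "doubled_EAA", "doubled_valine")


@dataclass
class ExperimentConfig:
    model_source: str = "synthetic"  # "synthetic" or a model file path
    model_format: str | None = None
    synthetic_params: dict = field(default_factory=dict)
    diet: str = "reference"  # "reference" or a two-column CSV path
    scenarios: tuple[str, ...] = DEFAULT_SCENARIOS
    fva_fraction: float = 0.9
    eaa: tuple[str, ...] = tuple(sorted(data.ESSENTIAL_AMINO_ACIDS))
    fa_drains: tuple[str, ...] = ()  # autodetected when empty
    glucose_exchange: str = "EX_glc_e"
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("scenarios must be non-empty")
        if not 0 < self.fva_fraction <= 1:
            raise ValueError("fva_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("scenarios", "eaa", "fa_drains"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _load_model(config: ExperimentConfig) -> MetabolicModel:
    if config.model_source == "synthetic":
        params = SyntheticNetworkParams(
            **{**config.synthetic_params, "seed": config.seed}
        )
        return generate_network(params)
    return read_model(config.model_source, config.model_format)


def _load_diet(config: ExperimentConfig) -> ExchangeBounds:
    if config.diet == "reference":
        if config.model_source == "synthetic":
            params = SyntheticNetworkParams(
                **{**config.synthetic_params, "seed": config.seed}
            )
            return reference_diet(params)
        from .diet import reference_exchange_bounds

        return reference_exchange_bounds()
    return ExchangeBounds.from_csv(config.diet)


def _resolve_scenario(scenario: str, bounds: ExchangeBounds) -> str:
    """Map friendly scenario names onto exchange-level scenarios."""
    if scenario in ("doubled_glucose", "doubled_EAA"):
        return scenario
    if scenario.startswith("doubled_"):
        target = scenario[len("doubled_"):]
        if target in bounds.bounds:
            return scenario
        candidate = f"EX_{target}_e"
        if candidate in bounds.bounds:
            return f"doubled_{candidate}"
    raise PipelineError("scenarios", f"cannot resolve scenario {scenario!r}")


def run_pipeline(config: ExperimentConfig) -> dict:
    """Run QC, reference FBA, all scenarios, drain FVA and CCE; write bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"solver: {SOLVER_NAME}",
        f"primal tolerance: {PRIMAL_TOL}",
        f"seed: {config.seed}",
        f"started: {datetime.now(timezone.utc).isoformat()}",
    ]
    summary: dict = {"seed": config.seed, "scenarios": {}}

    try:
        model = _load_model(config)
    except Exception as exc:
        raise PipelineError("load_model", str(exc)) from exc
    try:
        bounds = _load_diet(config)
    except Exception as exc:
        raise PipelineError("load_diet", str(exc)) from exc

    fa_drains = list(config.fa_drains) or sorted(
        r.id for r in model.reactions if r.id.startswith("DM_fa")
    )
    eaa_exchanges = [
        f"EX_{aa}_e" for aa in config.eaa if f"EX_{aa}_e" in bounds.bounds
    ]

    try:
        report = qc_report(model)
        report.to_json(out / "qc.json")
        summary["qc"] = report.summary_row()
        log_lines.append("qc: done")
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc

    try:
        reference_model = apply_diet(model, bounds)
        reference = fba(reference_model)
        if not reference.optimal:
            raise PipelineError("fba", f"reference FBA {reference.status}")
        with open(out / "reference_fluxes.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["reaction", "flux_mmol_per_larva_day"])
            for rxn_id in sorted(reference.fluxes):
                writer.writerow([rxn_id, repr(reference.fluxes[rxn_id])])
        summary["reference_objective"] = reference.objective_value
        log_lines.append(f"reference fba: optimal {reference.objective_value}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("fba", str(exc)) from exc

    growth_rows = []
    fva_rows = []
    for scenario in config.scenarios:
        resolved = _resolve_scenario(scenario, bounds)
        try:
            res = run_perturbation_experiment(
                model, bounds, resolved,
                eaa_exchanges=eaa_exchanges,
                glucose_exchange=config.glucose_exchange,
                fa_drains=fa_drains,
                fva_fraction=config.fva_fraction,
            )
        except Exception as exc:
            raise PipelineError(f"scenario:{scenario}", str(exc)) from exc
        growth_rows.append({
            "scenario": scenario,
            "reference_objective": res["reference"].objective_value,
            "perturbed_objective": res["perturbed"].objective_value,
            "growth_change_percent": round(res["growth_change_percent"], 2),
        })
        summary["scenarios"][scenario] = {
            "growth_change_percent": round(res["growth_change_percent"], 2),
        }
        for state in ("reference", "perturbed"):
            variability = res.get(f"{state}_fva")
            if variability is None:
                continue
            for drain in fa_drains:
                lo, hi = variability.range(drain)
                fva_rows.append({
                    "scenario": scenario, "state": state, "reaction": drain,
                    "min_flux": lo, "max_flux": hi,
                    "fraction_of_optimum": config.fva_fraction,
                })
        log_lines.append(
            f"scenario {scenario}: growth change "
            f"{res['growth_change_percent']:+.2f}% (statuses: "
            f"{res['reference'].status}/{res['perturbed'].status})"
        )

    with open(out / "growth_changes.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(growth_rows[0]))
        writer.writeheader()
        writer.writerows(growth_rows)
    if fva_rows:
        with open(out / "fa_fva.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(fva_rows[0]))
            writer.writeheader()
            writer.writerows(fva_rows)

    try:
        if fa_drains:
            from .diet import scale_uptake

            cce_ref = cce_experiment(
                model, bounds, fa_drains, config.fva_fraction, "reference"
            )
            doubled = scale_uptake(
                bounds, [config.glucose_exchange], 2.0
            ) if config.glucose_exchange in bounds.bounds else None
            cce_ref.to_csv(out / "cce_reference.csv")
            summary["cce"] = {"reference": cce_ref.per_fatty_acid}
            if doubled is not None:
                cce_dbl = cce_experiment(
                    model, doubled, fa_drains, config.fva_fraction,
                    "doubled_glucose",
                )
                cce_dbl.to_csv(out / "cce_doubled_glucose.csv")
                summary["cce"]["doubled_glucose"] = cce_dbl.per_fatty_acid
            log_lines.append("cce: done")
    except Exception as exc:
        raise PipelineError("cce", str(exc)) from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
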