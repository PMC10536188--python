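"""End-to-end orchestration: retention -> logkw -> dlogP -> logBB report,
assay tables -> IC50, umbrella windows -> PMF summary, from a single config.

Each stage is optional; at least one must be enabled.  Numbers are
serialized at full precision in a JSON report (display rounding happens
only in human-readable summaries); per-stage TSV/CSV artefacts are written
next to it.  Re-running an identical config reproduces the report
byte-for-byte apart from the provenance timestamp.
"""

from __future__ import annotations

import datetime
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from . import __version__
from . import bioassay, chromatography, free_energy, qsar

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single-run configuration; every stage optional.

    logBB stage: ``retention_csv`` (raw times) and/or ``descriptor_csv``
    (system, logkw, logPcw, E); scalar ``logPcw``/``E`` fill in for systems
    fitted from retention data.  ``model`` is "eq2" (built-in) or a path to
    a model JSON.  Assay stage: ``plate_csv`` and/or ``densitometry_csv``
    (+ ``tlc_reference_response``, ``tlc_conversion``).  PMF stage:
    ``wham_meta`` metadata file plus optional region settings.
    """

    output_dir: str | None = None
    seed: int = 0
    # logBB stage
    retention_csv: str | None = None
    descriptor_csv: str | None = None
    logPcw: float | None = None
    E: float | None = None
    model: str = "eq2"
    # assay stage
    plate_csv: str | None = None
    densitometry_csv: str | None = None
    tlc_reference_response: float | None = None
    tlc_conversion: dict | None = None
    # PMF stage
    wham_meta: str | None = None
    wham_settings: dict = field(default_factory=dict)
    bulk_region: tuple[float, float] | None = None
    center_region: tuple[float, float] | None = None
    n_boot: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for attr in ("retention_csv", "descriptor_csv", "plate_csv",
                     "densitometry_csv", "wham_meta"):
            value = getattr(cfg, attr)
            if value is not None and not os.path.exists(value):
                raise FileNotFoundError(f"{attr}: {value!r} does not exist")
        return cfg

    def enabled_stages(self) -> list[str]:
        stages = []
        if self.retention_csv or self.descriptor_csv:
            stages.append("logbb")
        if self.plate_csv or self.densitometry_csv:
            stages.append("assay")
        if self.wham_meta:
            stages.append("pmf")
        return stages


def _load_model(spec: str) -> tuple[str, qsar.QSARModel]:
    if spec == "eq2":
        return "eq2 (built-in)", qsar.EQ2
    return spec, qsar.QSARModel.from_json(spec)


def _provenance(config: RunConfig, inputs: Mapping[str, Any]) -> dict:
    return {
        "package": f"bbbkit {__version__}",
        "seed": config.seed,
        "inputs": dict(inputs),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def run_logbb_pipeline(config: RunConfig) -> dict:
    """Retention/descriptor input -> per-system logBB prediction report.

    For each membrane-like system: fit the retention line (if raw times are
    supplied), assemble (logkw, dlogP, E), evaluate the model, and attach
    an applicability-domain flag when the model carries its training
    design.  Missing logPcw/E raise with the missing names listed.
    """
    if not (config.retention_csv or config.descriptor_csv):
        raise ValueError("logBB stage needs retention_csv or descriptor_csv")
    model_name, model = _load_model(config.model)

    per_system: dict[str, dict[str, float]] = {}
    swfits: list[chromatography.SWFit] = []
    if config.descriptor_csv:
        table = qsar.read_descriptor_csv(config.descriptor_csv)
        for row in table.itertuples():
            system = str(getattr(row, "system", "default"))
            per_system[system] = {"logkw": float(row.logkw),
                                  "logPcw": float(row.logPcw),
                                  "E": float(row.E)}
    if config.retention_csv:
        series = chromatography.read_retention_csv(config.retention_csv)
        for system, s in series.items():
            fit = chromatography.fit_soczewinski_wachtmeister(s)
            swfits.append(fit)
            entry = per_system.setdefault(system, {})
            entry["logkw"] = fit.logkw
            entry.setdefault("logPcw", config.logPcw)
            entry.setdefault("E", config.E)

    systems_report = {}
    for system, d in sorted(per_system.items()):
        missing = [k for k in ("logkw", "logPcw", "E") if d.get(k) is None]
        if missing:
            raise ValueError(f"system {system}: missing descriptors {missing}")
        desc = qsar.CompoundDescriptors(logkw=d["logkw"], logPcw=d["logPcw"],
                                        E=d["E"], system=system)
        entry = {"logkw": desc.logkw, "logPcw": desc.logPcw,
                 "delta_logp": desc.delta_logp, "E": desc.E,
                 "logBB": model.predict(desc)}
        if model.training_design is not None:
            leverage, in_domain = qsar.applicability_domain(model, desc)
            entry["leverage"] = leverage
            entry["in_domain"] = in_domain
        systems_report[system] = entry
        logger.info("system %s: logkw=%.4g dlogP=%.4g -> logBB=%.4g",
                    system, desc.logkw, desc.delta_logp, entry["logBB"])

    report = {
        "stage": "logbb",
        "model": {"name": model_name, "intercept": model.intercept,
                  "coefficients": model.coefficients},
        "retention_fits": [
            {"system": f.system_name, "logkw": f.logkw, "s": f.s,
             "r_squared": f.r_squared,
             "retention_decreases": f.retention_decreases} for f in swfits],
        "systems": systems_report,
        "provenance": _provenance(config, {
            "retention_csv": config.retention_csv,
            "descriptor_csv": config.descriptor_csv, "model": config.model}),
    }
    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        if swfits:
            chromatography.write_swfit_csv(
                swfits, os.path.join(config.output_dir, "retention_fits.csv"))
        with open(os.path.join(config.output_dir, "logbb.tsv"), "w") as fh:
            fh.write("system\tlogkw\tdelta_logp\tE\tlogBB\n")
            for system, e in systems_report.items():
                fh.write(f"{system}\t{e['logkw']!r}\t{e['delta_logp']!r}\t"
                         f"{e['E']!r}\t{e['logBB']!r}\n")
    return report


def run_assay_pipeline(config: RunConfig) -> dict:
    """Plate and/or densitometry inputs -> IC50 report."""
    if not (config.plate_csv or config.densitometry_csv):
        raise ValueError("assay stage needs plate_csv or densitometry_csv")
    report: dict[str, Any] = {"stage": "assay"}
    if config.plate_csv:
        plate = bioassay.read_plate_csv(config.plate_csv)
        curve = bioassay.plate_to_dose_response(plate)
        result = bioassay.ic50_dose_response(curve, seed=config.seed)
        report["mtt"] = {"ic50": result.ic50, "method": result.method,
                         "params": result.params,
                         "doses": curve.doses.tolist(),
                         "viability_percent": curve.responses.tolist()}
    if config.densitometry_csv:
        points = bioassay.read_densitometry_csv(config.densitometry_csv)
        calibration = bioassay.fit_linear_calibration(points)
        tlc_report = {"slope": calibration.slope,
                      "intercept": calibration.intercept,
                      "r_squared": calibration.r_squared}
        if config.tlc_reference_response is not None:
            if not config.tlc_conversion:
                raise ValueError("tlc_conversion constants required for TLC IC50")
            conversion = bioassay.TLCConversion(**config.tlc_conversion)
            tlc_report["ic50_uM"] = bioassay.ic50_tlc(
                calibration, config.tlc_reference_response, conversion)
        report["tlc"] = tlc_report
    report["provenance"] = _provenance(config, {
        "plate_csv": config.plate_csv,
        "densitometry_csv": config.densitometry_csv})
    return report


def run_pmf_pipeline(config: RunConfig) -> dict:
    """Umbrella window files -> WHAM profile (+ bootstrap errors, summary)."""
    if not config.wham_meta:
        raise ValueError("pmf stage needs wham_meta")
    windows = free_energy.read_metadata_file(config.wham_meta)
    settings = dict(config.wham_settings)
    profile = free_energy.wham_1d(windows, **settings)
    if config.n_boot >= 2:
        errors = free_energy.bayesian_bootstrap(
            windows, n_boot=config.n_boot, seed=config.seed, **settings)
        profile = profile.with_errors(errors)
    report: dict[str, Any] = {
        "stage": "pmf",
        "n_windows": len(windows),
        "converged": profile.converged,
        "kT": profile.kT,
    }
    if config.bulk_region and config.center_region:
        summary = free_energy.profile_summary(
            profile, tuple(config.bulk_region), tuple(config.center_region))
        report["summary"] = {"entry_barrier": summary.entry_barrier,
                             "central_barrier": summary.central_barrier,
                             "immersion_dg": summary.immersion_dg}
    report["provenance"] = _provenance(config, {"wham_meta": config.wham_meta})
    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        with open(os.path.join(config.output_dir, "profile.tsv"), "w") as fh:
            fh.write(profile.to_tsv())
    return report


def run(config: RunConfig) -> dict:
    """Run every enabled stage; write the combined JSON report."""
    stages = config.enabled_stages()
    if not stages:
        raise ValueError("no stage enabled in config")
    report: dict[str, Any] = {"stages": {}}
    runners = {"logbb": run_logbb_pipeline, "assay": run_assay_pipeline,
               "pmf": run_pmf_pipeline}
    for stage in stages:
        report["stages"][stage] = runners[stage](config)
    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        with open(os.path.join(config.output_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report
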