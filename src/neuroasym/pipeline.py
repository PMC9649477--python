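"""End-to-end pipeline: simulate → extract → asymmetry → diagnostics → report.

Stages communicate only through serialized artifacts (CSV/JSON); the run
manifest lists every output with a SHA-256 checksum, so re-running with the
same configuration reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .asymmetry import AI_ISIS, ai_table, profiles_from_curves
from .blink_reflex import build_recovery_cycle
from .cohort import CohortDataset, GeneratorConfig, fixture_cohort, generate_cohort
from .errors import ConfigurationError
from .io import (
    generator_config_from_dict,
    read_trace_battery,
    write_cohort_csv,
    write_trace_battery,
)
from .model import BlinkMRIDiagnosis

log = logging.getLogger("neuroasym")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cohort_source: str = "fixture"      # "fixture" | "summary" | "trace"
    isi: int = 100
    r2brrc_cutoff: float | None = None  # None -> Youden-estimated
    mri_cutoff: float | None = None
    output_dir: str = "neuroasym_run"
    make_plots: bool = True
    log_level: str = "INFO"

    def validate(self):
        if self.cohort_source not in ("fixture", "summary", "trace"):
            raise ConfigurationError(f"unknown cohort_source {self.cohort_source!r}")
        if self.isi not in AI_ISIS:
            raise ConfigurationError(f"classification ISI must be one of {AI_ISIS}")
        self.generator.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown key(s) in pipeline config: {sorted(unknown)}")
        if "generator" in data:
            data["generator"] = generator_config_from_dict(data["generator"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _make_cohort(config: PipelineConfig) -> CohortDataset:
    if config.cohort_source == "fixture":
        return fixture_cohort()
    return generate_cohort(config.generator, mode=config.cohort_source)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; return (and write) the run manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    # --- simulate ---------------------------------------------------------
    log.info("stage simulate: cohort_source=%s", config.cohort_source)
    cohort = _make_cohort(config)
    outputs.append(write_cohort_csv(cohort, out / "cohort.csv"))
    if cohort.traces:
        for pid, battery in cohort.traces.items():
            write_trace_battery(out / "traces", pid, battery)

    # --- extract + asymmetry ---------------------------------------------
    df = cohort.to_frame()
    if cohort.traces:
        log.info("stage extract: %d patients", len(cohort.traces))
        curves = {}
        rows = []
        for pid in sorted(cohort.traces):
            battery = read_trace_battery(out / "traces", pid)
            curves[pid] = {side: build_recovery_cycle(sw) for side, sw in battery.items()}
            for side, curve in curves[pid].items():
                cf = curve.to_frame()
                cf.insert(0, "patient_id", pid)
                rows.append(cf)
        curves_df = pd.concat(rows, ignore_index=True)
        curves_df.to_csv(out / "recovery_curves.csv", index=False)
        outputs.append(out / "recovery_curves.csv")

        mas_sides = {p.patient_id: p.mas_side for p in cohort.patients}
        profiles = profiles_from_curves(curves, cohort.metrics, mas_sides)
        ai_df = ai_table(cohort.patients, profiles)
        demo = df[["patient_id", "age"]] if "age" in df.columns else None
        if demo is not None:
            ai_df = ai_df.merge(demo, on="patient_id")
    else:
        cols = ["patient_id", "group", "mas_side", "ai_mri"] + \
               [c for c in df.columns if c.startswith("ai_r2brrc_")] + \
               (["age"] if "age" in df.columns else [])
        ai_df = df[cols]
    ai_df.to_csv(out / "ai_table.csv", index=False)
    outputs.append(out / "ai_table.csv")

    # --- diagnostics ------------------------------------------------------
    log.info("stage diagnostics: ISI=%d", config.isi)
    model = BlinkMRIDiagnosis(ai_df, isi=config.isi,
                              r2brrc_cutoff=config.r2brrc_cutoff,
                              mri_cutoff=config.mri_cutoff)
    res = model.fit()
    metrics = {
        "isi_ms": config.isi,
        "r2brrc_cutoff": res.r2brrc_cutoff,
        "mri_cutoff": res.mri_cutoff,
        "r2brrc": _metrics_dict(res.roc_r2brrc, res.metrics_r2brrc),
        "mri": _metrics_dict(res.roc_mri, res.metrics_mri),
        "combined": {
            mode: _metrics_dict(parts["roc"], parts["metrics"])
            for mode, parts in res.combined.items()
        },
        "separable_fit": bool(res.combined_logistic["result"].separable),
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    outputs.append(out / "metrics.json")
    for name, roc in (("roc_r2brrc", res.roc_r2brrc), ("roc_mri", res.roc_mri)):
        pd.DataFrame({"cutoff": roc.cutoffs, "fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
            out / f"{name}.csv", index=False)
        outputs.append(out / f"{name}.csv")
    if config.make_plots:
        res.plot_roc(out / "roc_curves.png")
        outputs.append(out / "roc_curves.png")

    # --- compare ----------------------------------------------------------
    res.comparison.to_csv(out / "group_comparison.csv", index=False)
    outputs.append(out / "group_comparison.csv")
    (out / "summary.txt").write_text(res.summary() + "\n")
    outputs.append(out / "summary.txt")

    manifest = {
        "version": __version__,
        "seed": config.generator.seed,
        "cohort_source": config.cohort_source,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _metrics_dict(roc, bm):
    return {
        "auc": roc.auc,
        "tp": bm.tp, "fn": bm.fn, "tn": bm.tn, "fp": bm.fp,
        "sensitivity": bm.sensitivity, "specificity": bm.specificity,
        "sens_ci": list(bm.sens_ci), "spec_ci": list(bm.spec_ci),
    }
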