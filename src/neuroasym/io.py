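"""Serialized interfaces: cohort CSV, AI tables, trace directories, YAML config.

Trace layout on disk: ``<root>/<patient>/<stim_side>/<name>.csv`` with
columns ``time_ms, amplitude_uv`` and a JSON sidecar ``<name>.json``
carrying ``sampling_rate_hz`` and ``stimulus_onsets_ms``; ``<name>`` is the
ISI in ms for conditioned sweeps (``_t<k>`` suffix for repeated trials) and
``unconditioned`` for single-stimulus sweeps. An optional EDF reader maps
channels by label (requires the ``mne`` extra).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .asymmetry import AsymmetryProfile, HemisphereMetrics
from .blink_reflex import EMGTrace
from .cohort import (
    CohortDataset,
    GeneratorConfig,
    GroupParams,
    PatientRecord,
    TraceParams,
)
from .errors import ConfigurationError, DataError

AI_COLUMNS_PREFIX = "ai_r2brrc_"


def write_cohort_csv(dataset: CohortDataset, path) -> Path:
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    return path


def read_cohort_csv(path) -> CohortDataset:
    """Rebuild a (summary-mode) cohort from its CSV representation."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"patient_id", "group", "mas_side", "ai_mri"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"cohort CSV missing columns: {sorted(missing)}")
    isis = sorted(
        int(c.removeprefix(AI_COLUMNS_PREFIX))
        for c in df.columns if c.startswith(AI_COLUMNS_PREFIX)
    )
    patients, profiles, metrics = [], {}, {}
    for _, r in df.iterrows():
        p = PatientRecord(
            patient_id=str(r.patient_id), group=str(r.group), sex=str(r.get("sex", "M")),
            age=float(r.get("age", 60.0)), disease_duration=float(r.get("disease_duration", 0.0)),
            updrs_me=float(r.get("updrs_me", 0.0)), hy_stage=float(r.get("hy_stage", 1.0)),
            mas_side=str(r.mas_side),
        )
        patients.append(p)
        profiles[p.patient_id] = AsymmetryProfile(
            {isi: float(r[f"{AI_COLUMNS_PREFIX}{isi}"]) for isi in isis},
            float(r.ai_mri), p.mas_side,
        )
        metrics[p.patient_id] = HemisphereMetrics(
            left_volume_mm3=float(r.left_volume_mm3),
            right_volume_mm3=float(r.right_volume_mm3),
            total_gm_volume_mm3=float(r.total_gm_volume_mm3),
            total_rel_tol=1e-6,
        )
    return CohortDataset(patients, profiles, metrics)


def write_trace_battery(root, patient_id: str, battery: dict) -> Path:
    """Write one patient's per-side sweeps under `root`/`patient_id`/."""
    root = Path(root)
    for side, sweeps in battery.items():
        d = root / patient_id / side
        d.mkdir(parents=True, exist_ok=True)
        counters: dict[str, int] = {}
        for tr in sweeps:
            stem = "unconditioned" if not tr.is_conditioned else str(int(round(tr.isi_ms)))
            k = counters.get(stem, 0)
            counters[stem] = k + 1
            name = stem if k == 0 else f"{stem}_t{k + 1}"
            t = np.arange(len(tr.samples)) * 1000.0 / tr.sampling_rate_hz
            pd.DataFrame({"time_ms": t, "amplitude_uv": tr.samples}).to_csv(
                d / f"{name}.csv", index=False
            )
            (d / f"{name}.json").write_text(json.dumps({
                "sampling_rate_hz": tr.sampling_rate_hz,
                "stimulus_onsets_ms": list(tr.stimulus_onsets_ms),
                "stim_side": side,
                "record_side": tr.record_side,
            }))
    return root / patient_id


def read_trace_battery(root, patient_id: str) -> dict:
    """Read one patient's battery back as {"MAS": [EMGTrace...], "LAS": [...]}."""
    pdir = Path(root) / patient_id
    if not pdir.is_dir():
        raise DataError(f"no trace directory for patient {patient_id} under {root}")
    battery = {}
    for side_dir in sorted(p for p in pdir.iterdir() if p.is_dir()):
        sweeps = []
        for csv_path in sorted(side_dir.glob("*.csv")):
            sidecar = csv_path.with_suffix(".json")
            if not sidecar.exists():
                raise DataError(f"missing JSON sidecar for {csv_path}")
            meta = json.loads(sidecar.read_text())
            df = pd.read_csv(csv_path, float_precision="round_trip")
            sweeps.append(EMGTrace(
                df["amplitude_uv"].to_numpy(float),
                float(meta["sampling_rate_hz"]),
                tuple(meta["stimulus_onsets_ms"]),
                meta.get("stim_side", side_dir.name),
                meta.get("record_side", "ipsilateral"),
            ))
        battery[side_dir.name] = sweeps
    if not battery:
        raise DataError(f"empty trace directory for patient {patient_id}")
    return battery


def read_edf_traces(path, channel_map: dict, stim_side: str, stimulus_onsets_ms) -> list:
    """Read sweeps from an EDF file, mapping channels by label.

    `channel_map` maps EDF channel labels to record sides. Requires mne.
    """
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("EDF ingestion requires the 'mne' package (pip extra 'edf')") from e
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    out = []
    for label, record_side in channel_map.items():
        if label not in raw.ch_names:
            raise DataError(f"channel {label!r} not present in {path}")
        data = raw.get_data(picks=[label])[0] * 1e6  # volts -> µV
        out.append(EMGTrace(data, float(raw.info["sfreq"]),
                            tuple(stimulus_onsets_ms), stim_side, record_side))
    return out


# ---------------------------------------------------------------------------
# YAML configuration

def _build(dc_type, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(dc_type)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)} in {path}")
    return data


def generator_config_from_dict(data: dict) -> GeneratorConfig:
    """Strict dict → GeneratorConfig (unknown keys are an error).

    Group sections accept ``ai_r2brrc`` keyed by ISI (YAML int keys).
    """
    data = dict(data or {})
    _build(GeneratorConfig, data, "generator config")
    kwargs = {}
    for grp in ("pd", "cbs"):
        if grp in data:
            section = dict(data[grp])
            _build(GroupParams, section, f"generator config: {grp}")
            default = GeneratorConfig().__getattribute__(grp)
            merged = dataclasses.asdict(default)
            for key, val in section.items():
                if key == "ai_r2brrc":
                    merged[key] = {int(k): tuple(v) for k, v in val.items()}
                elif isinstance(merged[key], tuple):
                    merged[key] = tuple(val)
                else:
                    merged[key] = val
            merged["ai_r2brrc"] = {int(k): tuple(v) for k, v in merged["ai_r2brrc"].items()}
            kwargs[grp] = GroupParams(**merged)
    if "traces" in data:
        section = dict(data["traces"])
        _build(TraceParams, section, "generator config: traces")
        merged = dataclasses.asdict(TraceParams())
        merged.update(section)
        merged["base_profile"] = {int(k): float(v) for k, v in merged["base_profile"].items()}
        kwargs["traces"] = TraceParams(**merged)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    cfg = GeneratorConfig(**kwargs)
    cfg.validate()
    return cfg


def load_generator_config(path) -> GeneratorConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return generator_config_from_dict(data)
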