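"""Synthetic cohort generation.

No per-patient data from the source study are published, so this module
generates cohorts with the same statistical structure: two groups (drug-naïve
Parkinson's disease, PD, and early corticobasal syndrome, CBS) with group
means/SDs of the demographic, recovery-cycle-asymmetry and hemispheric-MRI
quantities, and — in trace mode — per-patient paired-stimulation EMG
batteries whose extracted asymmetry indices match the drawn targets.

A fully deterministic, hand-placed fixture cohort (:func:`fixture_cohort`)
reproduces the study's misclassification structure exactly: 2 of 14 PD
patients without recovery-cycle asymmetry, 1 of 10 CBS patients with marked
asymmetry, 7 of 10 CBS and 2 of 14 PD above the MRI-asymmetry cutoff, and
linear separability of the cohort in the two-AI plane.

Sampling is "truncation corrected": printed mean±SD pairs are incompatible
with the bounded support of an asymmetry index (0.86±0.36 on [0,1] puts a
third of the mass above 1), so each sampler keeps the printed SD as the
latent normal scale and shifts the latent location until the *truncated*
mean equals the printed mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .asymmetry import AI_ISIS, AsymmetryProfile, HemisphereMetrics, contralateral
from .blink_reflex import BATTERY_ISIS, EMGTrace
from .errors import ConfigurationError, ProtocolError


@dataclass(frozen=True)
class PatientRecord:
    """One enrolled subject."""

    patient_id: str
    group: str                 # "PD" | "CBS"
    sex: str                   # "M" | "F"
    age: float                 # years
    disease_duration: float    # years
    updrs_me: float            # motor-examination score, 0–108
    hy_stage: float            # Hoehn & Yahr, 1–5 in 0.5 steps
    mas_side: str              # clinically more affected side, "left" | "right"

    def __post_init__(self):
        if self.group not in ("PD", "CBS"):
            raise ConfigurationError(f"group must be PD or CBS, got {self.group!r}")
        if not self.age > 0:
            raise ConfigurationError("age must be > 0")
        if self.disease_duration < 0:
            raise ConfigurationError("disease_duration must be >= 0")
        if not 0 <= self.updrs_me <= 108:
            raise ConfigurationError("updrs_me must lie in [0, 108]")
        if self.hy_stage not in {1 + 0.5 * k for k in range(9)}:
            raise ConfigurationError("hy_stage must be 1–5 in 0.5 steps")
        if self.mas_side not in ("left", "right"):
            raise ConfigurationError("mas_side must be 'left' or 'right'")


@dataclass(frozen=True)
class GroupParams:
    """Per-group generator parameters: (mean, sd) pairs and proportions."""

    n: int
    age: tuple
    disease_duration: tuple
    updrs_me: tuple
    hy_stage: tuple
    male_prop: float
    right_mas_prop: float
    ai_r2brrc: dict            # ISI -> (mean, sd), ISIs 100/150/200
    ai_mri: tuple
    total_gm_volume: tuple     # mm³
    mas_volume: tuple          # mm³, reference marginal (implied, not sampled)

    def validate(self):
        if self.n < 1:
            raise ConfigurationError("sample size must be >= 1")
        for name in ("age", "disease_duration", "updrs_me", "hy_stage",
                     "ai_mri", "total_gm_volume", "mas_volume"):
            m, s = getattr(self, name)
            if not (np.isfinite(m) and np.isfinite(s)):
                raise ConfigurationError(f"{name}: non-finite parameter")
            if s < 0:
                raise ConfigurationError(f"{name}: negative SD")
        for isi, (m, s) in self.ai_r2brrc.items():
            if not (np.isfinite(m) and np.isfinite(s)) or s < 0:
                raise ConfigurationError(f"ai_r2brrc[{isi}]: invalid (mean, sd)")
        for name in ("male_prop", "right_mas_prop"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must lie in [0,1]")


@dataclass(frozen=True)
class TraceParams:
    """Waveform-synthesis parameters for trace mode.

    The base recovery profile is a monotone saturating curve of the
    conditioned/unconditioned ratio (%) over ISI; per-ISI asymmetry targets
    split it into side-specific curves. In PD the less-affected-side
    stimulation carries the elevated short-ISI ratios.
    """

    sampling_rate_hz: float = 5000.0
    sweep_ms: float = 900.0
    pre_stim_ms: float = 50.0
    unconditioned_amp_uv: float = 300.0
    noise_sd_uv: float = 0.5
    trials_per_isi: int = 1
    r1_amp_uv: float = 90.0
    artifact_amp_uv: float = 200.0
    base_profile: dict = field(default_factory=lambda: {
        100: 8.0, 150: 15.0, 200: 30.0, 300: 55.0, 400: 70.0, 500: 85.0, 750: 100.0,
    })
    roundtrip_tol_pp: float = 5.0   # declared extraction tolerance, percentage points

    def validate(self):
        if self.sampling_rate_hz <= 0 or self.sweep_ms <= 0 or self.trials_per_isi < 1:
            raise ConfigurationError("invalid trace parameters")
        if self.noise_sd_uv < 0 or self.unconditioned_amp_uv <= 0:
            raise ConfigurationError("invalid trace amplitudes")
        missing = [i for i in BATTERY_ISIS if i not in self.base_profile]
        if missing:
            raise ConfigurationError(f"base_profile missing ISIs {missing}")


def _default_pd() -> GroupParams:
    return GroupParams(
        n=14, age=(64.6, 7.5), disease_duration=(1.7, 1.3), updrs_me=(24.8, 11.8),
        hy_stage=(1.9, 0.3), male_prop=0.50, right_mas_prop=0.50,
        ai_r2brrc={100: (0.86, 0.36), 150: (0.81, 0.37), 200: (0.42, 0.36)},
        ai_mri=(0.006, 0.005), total_gm_volume=(402387, 28257), mas_volume=(200090, 14971),
    )


def _default_cbs() -> GroupParams:
    return GroupParams(
        n=10, age=(71.1, 5.9), disease_duration=(2.9, 1.4), updrs_me=(37.6, 15.2),
        hy_stage=(2.1, 0.5), male_prop=0.40, right_mas_prop=0.70,
        ai_r2brrc={100: (0.10, 0.32), 150: (0.10, 0.32), 200: (0.04, 0.10)},
        ai_mri=(0.02, 0.02), total_gm_volume=(346242, 24986), mas_volume=(171191, 9009),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full generator configuration; defaults reproduce the study cohort sizes
    and group summaries."""

    pd: GroupParams = field(default_factory=_default_pd)
    cbs: GroupParams = field(default_factory=_default_cbs)
    traces: TraceParams = field(default_factory=TraceParams)
    seed: int = 0

    def validate(self):
        self.pd.validate()
        self.cbs.validate()
        self.traces.validate()

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass
class CohortDataset:
    """A generated cohort: patients, per-patient metrics, optional traces."""

    patients: list
    profiles: dict             # patient_id -> AsymmetryProfile (drawn targets)
    metrics: dict              # patient_id -> HemisphereMetrics
    traces: dict | None = None  # patient_id -> {"MAS": [EMGTrace...], "LAS": [...]}
    seed: int | None = None
    mode: str = "summary"

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("patient ids must be unique")
        for pid in ids:
            if pid not in self.profiles or pid not in self.metrics:
                raise ConfigurationError(f"metrics missing for patient {pid}")

    def to_frame(self) -> pd.DataFrame:
        """One row per patient: demographics, AIs and hemispheric volumes."""
        rows = []
        for p in self.patients:
            prof, met = self.profiles[p.patient_id], self.metrics[p.patient_id]
            row = {
                "patient_id": p.patient_id, "group": p.group, "sex": p.sex,
                "age": p.age, "disease_duration": p.disease_duration,
                "updrs_me": p.updrs_me, "hy_stage": p.hy_stage, "mas_side": p.mas_side,
            }
            for isi in sorted(prof.ai_r2brrc):
                row[f"ai_r2brrc_{isi}"] = prof.ai_r2brrc[isi]
            row["ai_mri"] = prof.ai_mri
            row["left_volume_mm3"] = met.left_volume_mm3
            row["right_volume_mm3"] = met.right_volume_mm3
            row["total_gm_volume_mm3"] = met.total_gm_volume_mm3
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truncation-corrected sampling

@lru_cache(maxsize=256)
def matched_truncnorm_params(target_mean: float, sd: float, lo: float, hi: float):
    """Latent (mu, sigma, a, b) of a truncated normal whose truncated mean
    equals `target_mean` on [lo, hi], keeping sigma at the nominal SD."""
    if not lo < target_mean < hi:
        raise ConfigurationError(
            f"target mean {target_mean} outside open support ({lo}, {hi})"
        )
    if sd == 0:
        return target_mean, 0.0, lo, hi
    # negligible truncation mass: latent location equals the target
    if (lo - target_mean) / sd < -8 and (hi - target_mean) / sd > 8:
        return target_mean, sd, (lo - target_mean) / sd, (hi - target_mean) / sd

    def trunc_mean(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        with np.errstate(all="ignore"):
            return stats.truncnorm.mean(a, b, loc=mu, scale=sd) - target_mean

    # expand the bracket outward from the target (trunc mean is monotone
    # increasing in mu) so the solver never probes absurd tail regimes
    lo_mu = hi_mu = target_mean
    step = sd
    while trunc_mean(lo_mu) > 0:
        lo_mu -= step
        step *= 2
    step = sd
    while trunc_mean(hi_mu) < 0:
        hi_mu += step
        step *= 2
    mu = brentq(trunc_mean, lo_mu, hi_mu, xtol=1e-12)
    return mu, sd, (lo - mu) / sd, (hi - mu) / sd


def truncated_moments(target_mean: float, sd: float, lo: float, hi: float):
    """Analytic (mean, sd) of the matched truncated-normal sampler."""
    mu, sigma, a, b = matched_truncnorm_params(target_mean, sd, lo, hi)
    if sigma == 0:
        return target_mean, 0.0
    m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


def _draw(rng, mean_sd, lo, hi, size):
    mean, sd = mean_sd
    if sd == 0:
        return np.full(size, float(mean))
    mu, sigma, a, b = matched_truncnorm_params(float(mean), float(sd), float(lo), float(hi))
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def _draw_hy(rng, mean_sd, size):
    raw = _draw(rng, mean_sd, 0.5, 5.5, size)
    return np.clip(np.round(raw * 2) / 2, 1.0, 5.0)


# ---------------------------------------------------------------------------
# trace synthesis

_R2_START, _R2_END = 27.0, 87.0      # ms post-stimulus, matches extractor default
_R1_START, _R1_END = 10.0, 16.0


def _component(t_ms, onset_ms, start, end, freq_hz, tau_ms):
    """Hann-windowed damped oscillation supported on [onset+start, onset+end]."""
    u = t_ms - onset_ms - start
    width = end - start
    inside = (u >= 0) & (u <= width)
    uc = np.clip(u, 0.0, width)
    w = np.sin(np.pi * uc / width) ** 2
    osc = np.sin(2 * np.pi * freq_hz * uc / 1000.0) * np.exp(-uc / tau_ms)
    return np.where(inside, w * osc, 0.0)


def _scaled(template, amp):
    p = np.ptp(template)
    return template * (amp / p) if p > 0 and amp > 0 else template * 0.0


def _synth_sweep(onsets_ms, r2_amps_uv, tp: TraceParams, rng) -> np.ndarray:
    n = int(round(tp.sweep_ms * tp.sampling_rate_hz / 1000.0))
    t = np.arange(n) * 1000.0 / tp.sampling_rate_hz
    x = np.zeros(n)
    for onset, amp in zip(onsets_ms, r2_amps_uv):
        x += _scaled(_component(t, onset, 0.0, 2.0, 900.0, 1.0), tp.artifact_amp_uv)
        x += _scaled(_component(t, onset, _R1_START, _R1_END, 250.0, 4.0), tp.r1_amp_uv)
        x += _scaled(_component(t, onset, _R2_START, _R2_END, 50.0, 25.0), amp)
    if tp.noise_sd_uv > 0:
        x = x + rng.normal(0.0, tp.noise_sd_uv, n)
    return x


def build_target_curves(profile_ai: dict, group: str, tp: TraceParams, rng) -> dict:
    """Side-specific target recovery curves consistent with per-ISI AI targets.

    At ISIs with an AI target a, the base ratio B splits into B(1+a) and
    B(1−a); in PD the elevated side is LAS-stimulation, in CBS the side is
    chosen at random (the AI is unchanged either way). Other ISIs are
    symmetric at the base profile.
    """
    mas, las = {}, {}
    for isi in BATTERY_ISIS:
        base = tp.base_profile[isi]
        if isi in profile_ai:
            a = profile_ai[isi]
            hi, lo = base * (1 + a), base * (1 - a)
            if group == "PD" or rng.random() < 0.5:
                las[isi], mas[isi] = hi, lo
            else:
                las[isi], mas[isi] = lo, hi
        else:
            mas[isi] = las[isi] = base
    return {"MAS": mas, "LAS": las}


def generate_blink_traces(patient: PatientRecord, config: GeneratorConfig,
                          target_ratios: dict, rng=None) -> dict:
    """Synthesize the paired-stimulation EMG battery for one patient.

    `target_ratios` maps side ("MAS"/"LAS") to {ISI: ratio %}; each side's
    battery contains one unconditioned sweep set plus `trials_per_isi`
    conditioned sweeps per ISI, with the test-stimulus R2 peak-to-peak
    amplitude programmed (before noise) to target × unconditioned amplitude.
    """
    tp = config.traces
    if rng is None:
        rng = np.random.default_rng(config.seed)
    battery = {}
    for side in ("MAS", "LAS"):
        targets = target_ratios[side]
        missing = [i for i in BATTERY_ISIS if i not in targets]
        if missing:
            raise ProtocolError(missing, f"target ratio map for {side} missing ISIs {missing}")
        if any(v < 0 for v in targets.values()):
            raise ConfigurationError("target ratios must be >= 0")
        sweeps = []
        t0 = tp.pre_stim_ms
        for _ in range(tp.trials_per_isi):
            sweeps.append(EMGTrace(
                _synth_sweep([t0], [tp.unconditioned_amp_uv], tp, rng),
                tp.sampling_rate_hz, (t0,), side,
            ))
        for isi in BATTERY_ISIS:
            amp = targets[isi] / 100.0 * tp.unconditioned_amp_uv
            for _ in range(tp.trials_per_isi):
                sweeps.append(EMGTrace(
                    _synth_sweep([t0, t0 + isi], [tp.unconditioned_amp_uv, amp], tp, rng),
                    tp.sampling_rate_hz, (t0, t0 + isi), side,
                ))
        battery[side] = sweeps
    return battery


# ---------------------------------------------------------------------------
# cohort generation

def _hemispheres(total, ai, mas_side, atrophy_contra_to_mas):
    """Split a total GM volume into hemispheres realising an exact AI."""
    small, large = total * (1 - ai) / 2.0, total * (1 + ai) / 2.0
    contra = contralateral(mas_side)
    if atrophy_contra_to_mas:
        vols = {contra: small, ("left" if contra == "right" else "right"): large}
    else:
        vols = {contra: large, ("left" if contra == "right" else "right"): small}
    return HemisphereMetrics(
        left_volume_mm3=vols["left"], right_volume_mm3=vols["right"],
        total_gm_volume_mm3=total, total_rel_tol=1e-9,
    )


def generate_cohort(config: GeneratorConfig | None = None, mode: str = "summary") -> CohortDataset:
    """Draw a synthetic two-group cohort.

    mode="summary" draws per-patient AI and MRI metrics directly;
    mode="trace" additionally synthesizes EMG batteries whose extracted
    recovery-cycle AIs match the drawn targets (within the declared
    extraction tolerance when noise is on; exactly when noise is off).
    """
    config = config or GeneratorConfig()
    config.validate()
    if mode not in ("summary", "trace"):
        raise ConfigurationError(f"mode must be 'summary' or 'trace', got {mode!r}")
    rng = np.random.default_rng(config.seed)

    patients, profiles, metrics = [], {}, {}
    traces = {} if mode == "trace" else None
    for group, gp in (("PD", config.pd), ("CBS", config.cbs)):
        n = gp.n
        male = rng.random(n) < gp.male_prop
        right = rng.random(n) < gp.right_mas_prop
        age = _draw(rng, gp.age, 0.0, np.inf, n)
        dur = _draw(rng, gp.disease_duration, 0.0, np.inf, n)
        updrs = _draw(rng, gp.updrs_me, 0.0, 108.0, n)
        hy = _draw_hy(rng, gp.hy_stage, n)
        ai_r2 = {isi: _draw(rng, gp.ai_r2brrc[isi], 0.0, 1.0, n) for isi in gp.ai_r2brrc}
        ai_mri = _draw(rng, gp.ai_mri, 0.0, 1.0, n)
        total = _draw(rng, gp.total_gm_volume, 0.0, np.inf, n)
        # CBS atrophy sits in the hemisphere contralateral to the MAS;
        # in PD the thinner hemisphere is unrelated to the clinical side.
        atrophy_contra = (np.ones(n, bool) if group == "CBS" else rng.random(n) < 0.5)

        for i in range(n):
            pid = f"{group}{i + 1:02d}"
            p = PatientRecord(
                patient_id=pid, group=group, sex="M" if male[i] else "F",
                age=float(age[i]), disease_duration=float(dur[i]),
                updrs_me=float(updrs[i]), hy_stage=float(hy[i]),
                mas_side="right" if right[i] else "left",
            )
            patients.append(p)
            prof_ai = {isi: float(ai_r2[isi][i]) for isi in ai_r2}
            profiles[pid] = AsymmetryProfile(prof_ai, float(ai_mri[i]), p.mas_side)
            metrics[pid] = _hemispheres(float(total[i]), float(ai_mri[i]),
                                        p.mas_side, bool(atrophy_contra[i]))
            if mode == "trace":
                curves = build_target_curves(prof_ai, group, config.traces, rng)
                traces[pid] = generate_blink_traces(p, config, curves, rng)

    return CohortDataset(patients, profiles, metrics, traces, seed=config.seed, mode=mode)


# ---------------------------------------------------------------------------
# deterministic fixture cohort
#
# Hand-placed (not sampled) so that every count of the misclassification
# narrative holds exactly and the cohort is linearly separable in the
# (recovery-cycle AI, MRI AI) plane. Adjacent observed values are arranged
# so the Youden midpoint cutoffs land exactly at 0.75 and 0.014.

_FIXTURE_ROWS = [
    # pid, sex, age, dur, updrs, hy, mas,  ai100, ai150, ai200, ai_mri, total_gm
    ("PD01", "M", 52, 0.5, 10, 1.5, "right", 0.97, 0.90, 0.44, 0.0015, 415000),
    ("PD02", "M", 56, 0.5, 14, 1.5, "left",  1.00, 0.94, 0.45, 0.0025, 398000),
    ("PD03", "M", 58, 1.0, 16, 1.5, "right", 0.92, 0.86, 0.41, 0.016,  422000),
    ("PD04", "M", 60, 1.0, 18, 2.0, "left",  0.89, 0.83, 0.40, 0.006,  405000),
    ("PD05", "M", 62, 1.0, 20, 2.0, "right", 0.84, 0.78, 0.38, 0.0065, 388000),
    ("PD06", "M", 63, 1.5, 22, 2.0, "left",  0.95, 0.89, 0.43, 0.008,  410000),
    ("PD07", "M", 64, 1.5, 24, 2.0, "right", 0.90, 0.84, 0.40, 0.019,  395000),
    ("PD08", "F", 65, 2.0, 26, 2.0, "left",  0.86, 0.80, 0.39, 0.0085, 430000),
    ("PD09", "F", 66, 2.0, 28, 2.0, "right", 0.80, 0.75, 0.36, 0.010,  392000),
    ("PD10", "F", 68, 2.0, 30, 2.0, "left",  0.78, 0.73, 0.35, 0.012,  385000),
    ("PD11", "F", 70, 2.5, 32, 2.0, "right", 0.99, 0.92, 0.44, 0.011,  418000),
    ("PD12", "F", 72, 2.5, 34, 2.0, "left",  0.82, 0.77, 0.37, 0.013,  400000),
    ("PD13", "F", 74, 3.0, 36, 2.0, "right", 0.03, 0.02, 0.01, 0.0035, 408000),
    ("PD14", "F", 75, 3.5, 38, 2.5, "left",  0.06, 0.05, 0.03, 0.0045, 378000),
    ("CBS01", "M", 62, 1.0, 18, 1.5, "right", 0.88, 0.82, 0.30, 0.030, 352000),
    ("CBS02", "M", 65, 1.5, 25, 2.0, "right", 0.00, 0.00, 0.00, 0.005, 340000),
    ("CBS03", "M", 68, 2.0, 30, 2.0, "right", 0.02, 0.02, 0.01, 0.007, 360000),
    ("CBS04", "M", 70, 2.5, 34, 2.0, "right", 0.05, 0.04, 0.02, 0.009, 335000),
    ("CBS05", "F", 71, 3.0, 38, 2.0, "right", 0.08, 0.07, 0.03, 0.015, 348000),
    ("CBS06", "F", 72, 3.0, 40, 2.0, "right", 0.10, 0.09, 0.04, 0.017, 330000),
    ("CBS07", "F", 73, 3.5, 42, 2.0, "right", 0.12, 0.11, 0.05, 0.021, 355000),
    ("CBS08", "F", 75, 4.0, 46, 2.5, "left",  0.15, 0.14, 0.06, 0.042, 342000),
    ("CBS09", "F", 77, 4.0, 51, 2.5, "left",  0.22, 0.20, 0.08, 0.055, 338000),
    ("CBS10", "F", 78, 4.5, 52, 2.5, "left",  0.72, 0.67, 0.25, 0.026, 365000),
]


def fixture_cohort() -> CohortDataset:
    """The packaged deterministic worked-example cohort (14 PD, 10 CBS)."""
    patients, profiles, metrics = [], {}, {}
    for k, (pid, sex, age, dur, updrs, hy, mas, a100, a150, a200, ami, tot) in enumerate(_FIXTURE_ROWS):
        group = "PD" if pid.startswith("PD") else "CBS"
        p = PatientRecord(pid, group, sex, float(age), float(dur), float(updrs),
                          float(hy), mas)
        patients.append(p)
        profiles[pid] = AsymmetryProfile({100: a100, 150: a150, 200: a200}, ami, mas)
        metrics[pid] = _hemispheres(float(tot), ami, mas,
                                    atrophy_contra_to_mas=(group == "CBS" or k % 2 == 0))
    return CohortDataset(patients, profiles, metrics, seed=None, mode="summary")
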