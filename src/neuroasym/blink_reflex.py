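"""R2 blink-reflex amplitude extraction and recovery-cycle construction.

The blink reflex to supraorbital nerve stimulation has an early ipsilateral
R1 component and a late bilateral R2 component. Paired (conditioning + test)
stimulation at a set of interstimulus intervals (ISIs) probes brainstem
excitability: the R2 recovery cycle is the conditioned/unconditioned R2
peak-to-peak amplitude ratio (%) as a function of ISI. Higher ratios at
short ISIs mean higher excitability.

This module measures peak-to-peak amplitudes inside a latency window locked
to a stimulus onset and assembles per-side recovery curves from a battery of
sweeps. It applies no filtering or rectification: recording-time filters are
treated as properties of the input data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DegenerateResponseError,
    ProtocolError,
    WindowBoundsError,
)

#: ISIs (ms) of the standard paired-stimulation battery.
BATTERY_ISIS = (100, 150, 200, 300, 400, 500, 750)

#: Default R2 latency window (ms post-stimulus), conventional clinical values.
DEFAULT_R2_WINDOW_MS = (27.0, 87.0)


@dataclass(frozen=True)
class ResponseWindow:
    """Latency window relative to a stimulus onset, in ms."""

    start_ms: float
    end_ms: float

    def __post_init__(self):
        if not (0 <= self.start_ms < self.end_ms):
            raise DataError(
                f"invalid window: require 0 <= start < end, got "
                f"[{self.start_ms}, {self.end_ms}]"
            )


#: Default R2 window object.
R2_WINDOW = ResponseWindow(*DEFAULT_R2_WINDOW_MS)


@dataclass
class EMGTrace:
    """One recorded EMG sweep from the orbicularis oculi.

    Parameters
    ----------
    samples : ndarray
        Amplitude vector in µV, t=0 at the first sample.
    sampling_rate_hz : float
        Sampling rate in Hz (must be > 0).
    stimulus_onsets_ms : tuple of float
        One onset for an unconditioned (single-stimulus) sweep, two onsets
        (conditioning, test) for a conditioned sweep. Strictly increasing
        and inside the sweep.
    stim_side : str
        Side of stimulation, ``"MAS"`` or ``"LAS"`` (clinically more / less
        affected side).
    record_side : str
        ``"ipsilateral"`` or ``"contralateral"`` to the stimulated side.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    stimulus_onsets_ms: tuple
    stim_side: str
    record_side: str = "ipsilateral"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise DataError("samples must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("samples contain non-finite values")
        if not self.sampling_rate_hz > 0:
            raise DataError("sampling_rate_hz must be > 0")
        onsets = tuple(float(t) for t in self.stimulus_onsets_ms)
        if len(onsets) not in (1, 2):
            raise DataError("expected 1 (unconditioned) or 2 (conditioned) onsets")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise DataError("stimulus onsets must be strictly increasing")
        if any(not (0 <= t < self.duration_ms) for t in onsets):
            raise DataError("stimulus onsets must lie within the sweep")
        self.stimulus_onsets_ms = onsets
        if self.stim_side not in ("MAS", "LAS"):
            raise DataError(f"stim_side must be 'MAS' or 'LAS', got {self.stim_side!r}")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.sampling_rate_hz

    @property
    def is_conditioned(self) -> bool:
        return len(self.stimulus_onsets_ms) == 2

    @property
    def isi_ms(self) -> float | None:
        """Interstimulus interval, None for unconditioned sweeps."""
        if not self.is_conditioned:
            return None
        return self.stimulus_onsets_ms[1] - self.stimulus_onsets_ms[0]


@dataclass
class R2RecoveryCurve:
    """Recovery cycle for one side of stimulation.

    ``ratios`` maps ISI (ms) to the conditioned/unconditioned R2 amplitude
    ratio in percent; ratios may exceed 100 (facilitation).
    """

    stim_side: str
    ratios: dict
    unconditioned_amplitude_uv: float
    metadata: dict = field(default_factory=dict)

    def ratio(self, isi_ms: int) -> float:
        try:
            return self.ratios[isi_ms]
        except KeyError:
            raise ProtocolError([isi_ms], f"ISI {isi_ms} ms absent from recovery curve") from None

    def is_complete(self, isis=BATTERY_ISIS) -> bool:
        return all(i in self.ratios for i in isis)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (stim_side, isi_ms, ratio_pct), one row per ISI."""
        isis = sorted(self.ratios)
        return pd.DataFrame(
            {
                "stim_side": self.stim_side,
                "isi_ms": isis,
                "ratio_pct": [self.ratios[i] for i in isis],
            }
        )


def _window_slice(trace: EMGTrace, onset_ms: float, window: ResponseWindow) -> slice:
    t0 = onset_ms + window.start_ms
    t1 = onset_ms + window.end_ms
    if t0 < 0 or t1 > trace.duration_ms:
        raise WindowBoundsError(
            f"window [{t0:.1f}, {t1:.1f}] ms outside sweep of {trace.duration_ms:.1f} ms"
        )
    fs = trace.sampling_rate_hz
    i0 = math.ceil(t0 * fs / 1000.0)
    i1 = math.floor(t1 * fs / 1000.0)
    if i1 < i0:
        raise WindowBoundsError("window empty after discretization")
    return slice(i0, i1 + 1)


def r2_peak_to_peak(trace: EMGTrace, stimulus_index: int, window: ResponseWindow = R2_WINDOW) -> float:
    """Peak-to-peak amplitude (µV) in `window` after the indexed stimulus.

    Returns max − min of the raw samples inside the window; always ≥ 0.
    """
    try:
        onset = trace.stimulus_onsets_ms[stimulus_index]
    except IndexError:
        raise DataError(
            f"stimulus_index {stimulus_index} out of range for "
            f"{len(trace.stimulus_onsets_ms)} onset(s)"
        ) from None
    seg = trace.samples[_window_slice(trace, onset, window)]
    return float(np.ptp(seg))


def recovery_ratio(conditioned_amp_uv: float, unconditioned_amp_uv: float) -> float:
    """Conditioned/unconditioned R2 amplitude ratio in percent.

    Raises ``DegenerateResponseError`` when the unconditioned amplitude is
    not positive (the baseline R2 is unmeasurable, so no ratio exists).
    """
    if not unconditioned_amp_uv > 0:
        raise DegenerateResponseError(
            f"unconditioned amplitude must be > 0 µV, got {unconditioned_amp_uv}"
        )
    if conditioned_amp_uv < 0:
        raise DataError("conditioned amplitude cannot be negative")
    return 100.0 * conditioned_amp_uv / unconditioned_amp_uv


def build_recovery_cycle(
    battery,
    window: ResponseWindow = R2_WINDOW,
    trials_policy: str = "mean_amplitude",
    isis=BATTERY_ISIS,
    overlap_flag_ms: float = 100.0,
) -> R2RecoveryCurve:
    """Assemble the R2 recovery cycle from a battery of sweeps for one side.

    Parameters
    ----------
    battery : iterable of EMGTrace
        Sweeps for a single side of stimulation: at least one unconditioned
        sweep and at least one conditioned sweep per ISI in `isis`.
    window : ResponseWindow
        R2 latency window relative to each stimulus onset. The conditioned
        R2 is measured relative to the *test* (second) stimulus.
    trials_policy : {"mean_amplitude", "mean_ratio"}
        How repeated trials at one ISI are combined. The default ratios the
        mean conditioned amplitude against the mean unconditioned amplitude,
        which stays stable when single trials are near zero; "mean_ratio"
        averages per-trial ratios instead.
    isis : sequence of int
        ISIs (ms) the battery must cover.
    overlap_flag_ms : float
        ISIs at or below this value are flagged in the output metadata as
        potentially overlapping late conditioning-response activity.

    Raises
    ------
    ProtocolError
        If any required ISI has no conditioned sweep, or no unconditioned
        sweep is present. Missing cells are listed, never imputed.
    """
    battery = list(battery)
    if not battery:
        raise ProtocolError(isis, "empty battery")
    sides = {t.stim_side for t in battery}
    if len(sides) != 1:
        raise DataError(f"battery mixes stimulation sides: {sorted(sides)}")
    (stim_side,) = sides

    uncond = [t for t in battery if not t.is_conditioned]
    if not uncond:
        raise ProtocolError(["unconditioned"], "no unconditioned sweep in battery")
    by_isi: dict[int, list[EMGTrace]] = {}
    for t in battery:
        if t.is_conditioned:
            by_isi.setdefault(int(round(t.isi_ms)), []).append(t)
    missing = [i for i in isis if i not in by_isi]
    if missing:
        raise ProtocolError(missing)

    uncond_amps = [r2_peak_to_peak(t, 0, window) for t in uncond]
    uncond_mean = float(np.mean(uncond_amps))

    ratios = {}
    for isi in isis:
        amps = [r2_peak_to_peak(t, 1, window) for t in by_isi[isi]]
        if trials_policy == "mean_amplitude":
            ratios[isi] = recovery_ratio(float(np.mean(amps)), uncond_mean)
        elif trials_policy == "mean_ratio":
            ratios[isi] = float(np.mean([recovery_ratio(a, uncond_mean) for a in amps]))
        else:
            raise DataError(f"unknown trials_policy {trials_policy!r}")

    meta = {
        "trials_policy": trials_policy,
        "window_ms": (window.start_ms, window.end_ms),
        "n_unconditioned_trials": len(uncond),
        "overlap_flagged_isis": [i for i in isis if i <= overlap_flag_ms],
    }
    return R2RecoveryCurve(stim_side, ratios, uncond_mean, meta)
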