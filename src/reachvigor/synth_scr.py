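"""Synthetic skin-conductance traces for the Pavlovian learning phase.

The generator emits a continuous conductance signal sampled at the
acquisition rate (1250 Hz by default): a tonic level with slow
random-walk drift, plus one event-related phasic response per CS
presentation, plus white measurement noise.  The phasic response uses
the standard biexponential (Bateman) shape, normalised to unit peak so
that the drawn amplitude is exactly the trough-to-peak deflection the
scorer should recover.  CS+ responses are drawn with a larger mean
amplitude than CS− responses (defaults 0.60 vs 0.26 μS, the group means
reported for this paradigm), which is the learning signature the
statistical stage tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScrParams",
    "ScrTrace",
    "phasic_kernel",
    "kernel_peak_time",
    "simulate_scr_trace",
]


@dataclass(frozen=True)
class ScrParams:
    sample_rate_hz: float = 1250.0
    tonic_level_uS: float = 5.0
    drift_sd_uS_per_sqrt_s: float = 0.005
    amp_cs_plus_uS: float = 0.60
    amp_cs_minus_uS: float = 0.26
    amp_sd_uS: float = 0.30
    latency_s: float = 1.5       # CS onset → deflection trough (inside 0.5–4.5 s)
    rise_tau_s: float = 0.75
    decay_tau_s: float = 3.0
    noise_sd_uS: float = 0.01        # white sensor noise before the hardware filter
    hardware_lowpass_hz: float = 10.0  # acquisition low-pass; 0 disables
    habituation_slope: float = 0.0   # fractional amplitude decay per trial

    def __post_init__(self):
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if min(self.amp_cs_plus_uS, self.amp_cs_minus_uS) < 0:
            raise ValueError("amplitudes must be non-negative")
        if not self.rise_tau_s < self.decay_tau_s:
            raise ValueError("rise_tau must be smaller than decay_tau")


@dataclass
class ScrTrace:
    """Continuous conductance signal with its CS event table."""

    t_s: np.ndarray
    conductance_uS: np.ndarray
    events: list                     # (cs_onset_s, cs_type) tuples
    sample_rate_hz: float
    participant_id: str = "p00"

    def to_frames(self):
        signal = pd.DataFrame({"t_s": self.t_s, "conductance_uS": self.conductance_uS})
        events = pd.DataFrame(self.events, columns=["cs_onset_s", "cs_type"])
        return signal, events

    @classmethod
    def from_frames(cls, signal: pd.DataFrame, events: pd.DataFrame, participant_id="p00"):
        for col in ("t_s", "conductance_uS"):
            if col not in signal.columns:
                raise ValueError(f"signal frame missing column {col!r}")
        for col in ("cs_onset_s", "cs_type"):
            if col not in events.columns:
                raise ValueError(f"events frame missing column {col!r}")
        t = signal["t_s"].to_numpy(float)
        dt = np.diff(t)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("signal must be uniformly sampled")
        rate = 1.0 / dt[0] if len(dt) else 0.0
        return cls(
            t_s=t,
            conductance_uS=signal["conductance_uS"].to_numpy(float),
            events=list(events.itertuples(index=False, name=None)),
            sample_rate_hz=rate,
            participant_id=participant_id,
        )


def kernel_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time of the biexponential peak: ln(d/r)·r·d/(d−r)."""
    return np.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)


def phasic_kernel(t, rise_tau: float = 0.75, decay_tau: float = 3.0):
    """Unit-peak biexponential SCR shape: e^(−t/d) − e^(−t/r) for t ≥ 0."""
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, np.exp(-t / decay_tau) - np.exp(-t / rise_tau), 0.0)
    tp = kernel_peak_time(rise_tau, decay_tau)
    peak = np.exp(-tp / decay_tau) - np.exp(-tp / rise_tau)
    return k / peak


def simulate_scr_trace(
    schedule,
    params: ScrParams = ScrParams(),
    seed=None,
    participant_id: str = "p00",
    amp_offset_uS: float = 0.0,
    pad_s: float = 12.0,
) -> ScrTrace:
    """Simulate the learning-phase conductance recording for one participant.

    Event times follow the schedule's jittered pre-stimulus and
    inter-trial intervals.  Per-trial amplitudes are drawn from
    Normal(amp_cs_type + amp_offset, amp_sd) truncated at zero;
    ``amp_offset_uS`` shifts this participant's CS+ amplitudes and is
    how cohort-level SCR reactivity is coupled to the motion
    generator's vigor gain.
    """
    if schedule.phase != "pavlovian":
        raise ValueError("SCR is simulated for the pavlovian phase only")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    onsets, cs_types = [], []
    t_cursor = 2.0
    for spec in schedule:
        t_cursor += spec.pre_stim_s
        onsets.append(t_cursor)
        cs_types.append(spec.cs_type)
        t_cursor += spec.stim_duration_s + spec.iti_s

    fs = params.sample_rate_hz
    n = int(np.ceil((t_cursor + pad_s) * fs))
    t = np.arange(n) / fs
    sig = np.full(n, params.tonic_level_uS)

    if params.drift_sd_uS_per_sqrt_s > 0:
        steps = rng.normal(0.0, params.drift_sd_uS_per_sqrt_s / np.sqrt(fs), n)
        sig = sig + np.cumsum(steps)

    # one kernel evaluation reused for every event
    kernel_len = int(np.ceil(25.0 * fs))
    kt = np.arange(kernel_len) / fs
    kernel = phasic_kernel(kt, params.rise_tau_s, params.decay_tau_s)

    for i, (onset, cs) in enumerate(zip(onsets, cs_types)):
        mean_amp = params.amp_cs_plus_uS if cs == "CS+" else params.amp_cs_minus_uS
        if cs == "CS+":
            mean_amp += amp_offset_uS
        mean_amp *= max(1.0 - params.habituation_slope * i, 0.0)
        amp = max(rng.normal(mean_amp, params.amp_sd_uS), 0.0) if params.amp_sd_uS > 0 else mean_amp
        start = int(round((onset + params.latency_s) * fs))
        stop = min(start + kernel_len, n)
        if start < n:
            sig[start:stop] += amp * kernel[: stop - start]

    if params.noise_sd_uS > 0:
        noise = rng.normal(0.0, params.noise_sd_uS, n)
        if params.hardware_lowpass_hz > 0:
            # emulate the acquisition chain's analog low-pass filter
            from scipy import signal as sps

            sos = sps.butter(4, params.hardware_lowpass_hz, fs=fs, output="sos")
            noise = sps.sosfiltfilt(sos, noise)
        sig = sig + noise

    return ScrTrace(
        t_s=t,
        conductance_uS=sig,
        events=list(zip(onsets, cs_types)),
        sample_rate_hz=fs,
        participant_id=participant_id,
    )
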