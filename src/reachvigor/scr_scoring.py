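"""Trough-to-peak scoring of event-related skin-conductance responses.

The continuous signal is first decimated to 200 Hz with an anti-aliasing
polyphase filter (optionally preceded by a 10 Hz low-pass for signals
that were not filtered at acquisition).  Each CS presentation is then
scored trough-to-peak: a deflection is valid when its trough onset falls
0.5–4.5 s after CS onset (bounds inclusive), its trough-to-peak rise
lasts at most 5 s, and its amplitude exceeds 0.02 μS.  Trials failing
any rule are scored as zero, with the first failing rule recorded as the
reason, and those zeros ARE included in condition means.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth_scr import ScrTrace

__all__ = [
    "ScrScore",
    "TraceCoverageError",
    "preprocess",
    "score_trial",
    "score_events",
    "participant_scr_summary",
]

DEFAULT_WINDOW_S = (0.5, 4.5)
DEFAULT_MAX_RISE_S = 5.0
DEFAULT_MIN_AMP_US = 0.02


class TraceCoverageError(ValueError):
    """The trace does not cover the scoring window for a trial."""


@dataclass
class ScrScore:
    trial_index: int
    cs_type: str
    amplitude_uS: float
    trough_t_s: float | None
    peak_t_s: float | None
    valid: bool
    zero_reason: str  # no_deflection | outside_window | too_long | too_small | none


def preprocess(
    trace: ScrTrace,
    target_rate_hz: float = 200.0,
    apply_lowpass: bool = False,
    lowpass_hz: float = 10.0,
) -> ScrTrace:
    """Anti-aliased decimation to the scoring rate.

    ``apply_lowpass`` adds a zero-phase 4th-order Butterworth low-pass
    (default 10 Hz) before decimation, for recordings that were not
    hardware-filtered.
    """
    if trace.sample_rate_hz < target_rate_hz:
        raise ValueError(
            f"input rate {trace.sample_rate_hz} Hz below target {target_rate_hz} Hz"
        )
    x = trace.conductance_uS
    if apply_lowpass:
        sos = sps.butter(4, lowpass_hz, fs=trace.sample_rate_hz, output="sos")
        x = sps.sosfiltfilt(sos, x)
    if trace.sample_rate_hz == target_rate_hz:
        y = x
    else:
        ratio = Fraction(target_rate_hz / trace.sample_rate_hz).limit_denominator(10_000)
        y = sps.resample_poly(x, ratio.numerator, ratio.denominator, padtype="line")
    n = len(y)
    return ScrTrace(
        t_s=np.arange(n) / target_rate_hz,
        conductance_uS=y,
        events=list(trace.events),
        sample_rate_hz=target_rate_hz,
        participant_id=trace.participant_id,
    )


def _deflections(
    x: np.ndarray,
    fs: float,
    t0: float,
    prominence: float,
    slide_lo_t: float | None = None,
    slide_tol: float = 0.0,
):
    """Candidate (trough_t, peak_t, amplitude) deflections in a signal chunk.

    Peaks are local maxima with the given prominence; each peak's trough
    is the last sample achieving the minimum value between the previous
    peak (or the chunk start) and the peak, so a flat-then-rising
    segment dates its trough to the start of the rise.

    Tonic drift robustness: a slow upward drift leaves no local minimum
    at a deflection's onset, which would date the trough to the chunk
    start.  When the raw trough falls before ``slide_lo_t`` but the
    signal has risen by at most ``slide_tol`` by that time (i.e. the
    deflection itself has not meaningfully started), the trough is
    re-dated to the last sample still within ``slide_tol`` of the
    minimum.  A response genuinely beginning before ``slide_lo_t`` has
    risen past the tolerance by then and keeps its early trough.
    """
    peaks, _ = sps.find_peaks(x, prominence=prominence)
    out = []
    prev = 0
    for p in peaks:
        seg = x[prev : p + 1]
        vmin = seg.min()
        # last index achieving the minimum before the peak
        trough = prev + int(np.nonzero(seg == vmin)[0][-1])
        if slide_lo_t is not None and t0 + trough / fs < slide_lo_t:
            lo_idx = min(int(round((slide_lo_t - t0) * fs)), p)
            if lo_idx >= prev and x[lo_idx] - vmin <= slide_tol:
                within = np.nonzero(seg - vmin <= slide_tol)[0]
                trough = prev + int(within[-1])
        out.append((t0 + trough / fs, t0 + p / fs, float(x[p] - x[trough])))
        prev = p
    return out


def score_trial(
    trace: ScrTrace,
    cs_onset_s: float,
    trial_index: int = 0,
    cs_type: str = "",
    window_s=DEFAULT_WINDOW_S,
    max_rise_s: float = DEFAULT_MAX_RISE_S,
    min_amp_uS: float = DEFAULT_MIN_AMP_US,
) -> ScrScore:
    """Score one CS presentation trough-to-peak.

    Among candidate deflections whose trough onset lies inside the
    validity window, the largest amplitude wins (ties to the earliest
    trough).  Otherwise the trial is scored zero with the first failing
    rule — window, then rise duration, then amplitude — as reason.
    """
    fs = trace.sample_rate_hz
    lo, hi = window_s
    need_end = cs_onset_s + hi + max_rise_s
    if cs_onset_s < trace.t_s[0] or need_end > trace.t_s[-1] + 1e-9:
        raise TraceCoverageError(
            f"trace does not cover [{cs_onset_s:.2f}, {need_end:.2f}] s"
        )
    i0 = int(np.floor((cs_onset_s - trace.t_s[0]) * fs))
    # search past the required coverage so a deflection still rising at
    # need_end can be identified (and reported as too_long) rather than missed
    i1 = min(
        int(np.ceil((need_end + max_rise_s - trace.t_s[0]) * fs)) + 1,
        len(trace.conductance_uS),
    )
    chunk = trace.conductance_uS[i0:i1]
    cands = _deflections(
        chunk,
        fs,
        trace.t_s[i0],
        prominence=min_amp_uS / 2,
        slide_lo_t=cs_onset_s + lo,
        slide_tol=min_amp_uS / 2,
    )

    tol = 0.5 / fs  # half-sample slack on the inclusive window bounds
    valid = [
        c
        for c in cands
        if lo - tol <= c[0] - cs_onset_s <= hi + tol
        and c[1] - c[0] <= max_rise_s + tol
        and c[2] > min_amp_uS
    ]
    if valid:
        best = max(valid, key=lambda c: (c[2], -c[0]))
        return ScrScore(trial_index, cs_type, best[2], best[0], best[1], True, "none")

    if not cands:
        return ScrScore(trial_index, cs_type, 0.0, None, None, False, "no_deflection")
    best = max(cands, key=lambda c: (c[2], -c[0]))
    onset_lat = best[0] - cs_onset_s
    if not (lo - tol <= onset_lat <= hi + tol):
        reason = "outside_window"
    elif best[1] - best[0] > max_rise_s + tol:
        reason = "too_long"
    else:
        reason = "too_small"
    return ScrScore(trial_index, cs_type, 0.0, None, None, False, reason)


def score_events(trace: ScrTrace, schedule=None, **kwargs) -> pd.DataFrame:
    """Score every CS event of a (preprocessed) trace into a tidy table."""
    rows = []
    positions = [t.position for t in schedule] if schedule is not None else None
    for i, (onset, cs) in enumerate(trace.events):
        s = score_trial(trace, onset, trial_index=i, cs_type=cs, **kwargs)
        rows.append(
            {
                "participant": trace.participant_id,
                "trial": i,
                "cs_type": cs,
                "position": positions[i] if positions else "",
                "amplitude_uS": s.amplitude_uS,
                "trough_t_s": s.trough_t_s,
                "peak_t_s": s.peak_t_s,
                "valid": s.valid,
                "zero_reason": s.zero_reason,
            }
        )
    return pd.DataFrame(rows)


def participant_scr_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean SCR per (cs_type, position) and the CS+ − CS− differential.

    Zero-scored trials are included in the means (they are zeros, not
    missing data).  Returns one row per participant with columns
    ``scr_<cs>_<position>``, the cs_type marginal means, and
    ``scr_differential_uS``.
    """
    out = []
    for pid, g in scores.groupby("participant", sort=True):
        row = {"participant": pid}
        cell = g.groupby(["cs_type", "position"])["amplitude_uS"].mean()
        for (cs, pos), v in cell.items():
            tag = "plus" if cs == "CS+" else "minus"
            row[f"scr_{tag}_{pos}"] = v
        marg = g.groupby("cs_type")["amplitude_uS"].mean()
        row["scr_cs_plus_uS"] = marg.get("CS+", float("nan"))
        row["scr_cs_minus_uS"] = marg.get("CS-", float("nan"))
        row["scr_differential_uS"] = row["scr_cs_plus_uS"] - row["scr_cs_minus_uS"]
        out.append(row)
    return pd.DataFrame(out)
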