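"""Kinematic scoring of reaching trials.

Per trial: speed and acceleration profiles from the raw 100 Hz cursor
samples, peak velocity / acceleration / deceleration, reaction time
(time from stimulus offset to the first sample at ≥ 2% of peak speed),
endpoint accuracy (distance from the cursor at the 2%-of-peak offset
point to the target centre), and an automated screen for erratic
trajectories.  Unflagged trials are then averaged per participant into
the 2 (CS type) × 3 (position) condition cells, per phase.

Differentiation uses plain central differences on the raw samples
(one-sided at the edges); the logger's 100 Hz samples are already
coarse, so no smoothing is applied by default and the minimum-jerk
closed forms (peak speed 1.875·D/T, peak acceleration 5.7735·D/T²)
serve as exact oracles.  An optional Savitzky–Golay window is exposed
for noisier data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "VelocityProfile",
    "KinematicFeatures",
    "TrialUnscorableError",
    "compute_profile",
    "extract_features",
    "flag_anomalous",
    "score_trials",
    "aggregate_conditions",
]


class TrialUnscorableError(ValueError):
    """The trial does not contain a scoreable movement."""


@dataclass
class VelocityProfile:
    t_ms: np.ndarray
    speed_cm_s: np.ndarray
    accel_cm_s2: np.ndarray
    vx_cm_s: np.ndarray
    vy_cm_s: np.ndarray
    peak_speed_index: int
    px_to_cm: float


@dataclass
class KinematicFeatures:
    participant_id: str
    trial_index: int
    phase: str
    cs_type: str
    position: str
    peak_velocity_cm_s: float
    peak_acceleration_cm_s2: float
    peak_deceleration_cm_s2: float
    reaction_time_ms: float
    accuracy_cm: float
    onset_index: int
    offset_index: int
    anomalous: bool = False
    anomaly_reasons: tuple = ()


def compute_profile(trial, px_to_cm: float, smooth_window: int = 0) -> VelocityProfile:
    """Speed (cm/s) and its signed derivative (cm/s²) for one trial.

    ``smooth_window`` > 2 enables a Savitzky–Golay (order 2) filter on
    the position samples before differencing; 0 (default) keeps the raw
    samples.
    """
    t_ms = np.asarray(trial.timestamps_ms, dtype=float)
    if len(t_ms) < 3:
        raise TrialUnscorableError("need at least 3 samples to differentiate")
    if np.any(np.diff(t_ms) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    x_cm = np.asarray(trial.x_px, float) * px_to_cm
    y_cm = np.asarray(trial.y_px, float) * px_to_cm
    if smooth_window and smooth_window > 2:
        x_cm = savgol_filter(x_cm, smooth_window, 2)
        y_cm = savgol_filter(y_cm, smooth_window, 2)
    t_s = t_ms / 1000.0
    vx = np.gradient(x_cm, t_s)
    vy = np.gradient(y_cm, t_s)
    speed = np.hypot(vx, vy)
    accel = np.gradient(speed, t_s)
    return VelocityProfile(
        t_ms=t_ms,
        speed_cm_s=speed,
        accel_cm_s2=accel,
        vx_cm_s=vx,
        vy_cm_s=vy,
        peak_speed_index=int(np.argmax(speed)),
        px_to_cm=px_to_cm,
    )


def extract_features(
    profile: VelocityProfile,
    trial,
    target_center,
    threshold_frac: float = 0.02,
    rt_reference: str = "offset",
) -> KinematicFeatures:
    """Movement onset/offset by the percent-of-peak rule and the derived features.

    Onset is the first sample with speed at or above ``threshold_frac``
    of the peak; reaction time is measured from the stimulus offset
    (the stimulus lasts 100 ms) unless ``rt_reference='onset'``.  The
    movement offset is the first sample at or after the peak whose
    speed falls to or below the threshold (the final sample if speed
    never does).  Accuracy is the distance in cm from the cursor at the
    offset sample to the target centre.  Acceleration extrema are taken
    over [onset, offset].
    """
    speed = profile.speed_cm_s
    peak_idx = profile.peak_speed_index
    peak = speed[peak_idx]
    if peak <= 0:
        raise TrialUnscorableError("no movement: peak speed is zero")
    thr = threshold_frac * peak

    onset_candidates = np.nonzero(speed >= thr)[0]
    onset = int(onset_candidates[0])
    below = np.nonzero(speed[peak_idx:] <= thr)[0]
    offset = int(peak_idx + below[0]) if len(below) else len(speed) - 1

    ref_ms = trial.stimulus_offset_ms if rt_reference == "offset" else trial.stimulus_onset_ms
    rt_ms = float(profile.t_ms[onset] - ref_ms)

    tx, ty = target_center
    dx_cm = (trial.x_px[offset] - tx) * profile.px_to_cm
    dy_cm = (trial.y_px[offset] - ty) * profile.px_to_cm
    accuracy = float(np.hypot(dx_cm, dy_cm))

    seg = profile.accel_cm_s2[onset : offset + 1]
    spec = trial.spec
    return KinematicFeatures(
        participant_id=trial.participant_id,
        trial_index=trial.trial_index,
        phase=spec.phase if spec else "",
        cs_type=spec.cs_type if spec else "",
        position=spec.position if spec else "",
        peak_velocity_cm_s=float(peak),
        peak_acceleration_cm_s2=float(np.max(seg)),
        peak_deceleration_cm_s2=float(np.min(seg)),
        reaction_time_ms=rt_ms,
        accuracy_cm=accuracy,
        onset_index=onset,
        offset_index=offset,
    )


def _axis_reversals(positions_cm: np.ndarray, min_excursion_cm: float) -> int:
    """Direction reversals along one axis, counting only excursions that
    travel at least ``min_excursion_cm`` on both flanks."""
    d = np.diff(positions_cm)
    d = d[d != 0]
    if len(d) == 0:
        return 0
    # merge consecutive same-sign steps into monotone runs
    signs = np.sign(d)
    run_bounds = np.nonzero(np.diff(signs))[0] + 1
    runs = np.split(d, run_bounds)
    amps = [abs(r.sum()) for r in runs]
    run_signs = [np.sign(r[0]) for r in runs]
    big = [(s, a) for s, a in zip(run_signs, amps) if a >= min_excursion_cm]
    reversals = sum(1 for i in range(1, len(big)) if big[i][0] != big[i - 1][0])
    return reversals


def flag_anomalous(
    trial,
    profile: VelocityProfile,
    max_reversals: int = 2,
    min_excursion_cm: float = 0.5,
):
    """Automated surrogate for visual trial inspection.

    Flags reaches with more than ``max_reversals`` left/right or up/down
    direction changes whose excursions exceed ``min_excursion_cm`` —
    the erratic, zig-zag movements a human rater would reject.  Returns
    ``(flagged, reasons)`` with machine-readable reason codes.
    """
    x_cm = np.asarray(trial.x_px, float) * profile.px_to_cm
    y_cm = np.asarray(trial.y_px, float) * profile.px_to_cm
    reasons = []
    rx = _axis_reversals(x_cm, min_excursion_cm)
    ry = _axis_reversals(y_cm, min_excursion_cm)
    if rx > max_reversals:
        reasons.append(f"x_reversals={rx}")
    if ry > max_reversals:
        reasons.append(f"y_reversals={ry}")
    return bool(reasons), tuple(reasons)


def score_trials(
    trials,
    px_to_cm: float,
    threshold_frac: float = 0.02,
    max_reversals: int = 2,
    min_excursion_cm: float = 0.5,
    rt_reference: str = "offset",
    smooth_window: int = 0,
) -> pd.DataFrame:
    """Score a batch of trials into a tidy per-trial feature table."""
    rows = []
    for tr in trials:
        profile = compute_profile(tr, px_to_cm, smooth_window=smooth_window)
        feats = extract_features(
            profile, tr, tr.spec.target_center,
            threshold_frac=threshold_frac, rt_reference=rt_reference,
        )
        flagged, reasons = flag_anomalous(
            tr, profile, max_reversals=max_reversals,
            min_excursion_cm=min_excursion_cm,
        )
        feats.anomalous = flagged
        feats.anomaly_reasons = reasons
        rows.append(
            {
                "participant": feats.participant_id,
                "phase": feats.phase,
                "trial": feats.trial_index,
                "cs_type": feats.cs_type,
                "position": feats.position,
                "peak_velocity_cm_s": feats.peak_velocity_cm_s,
                "peak_acceleration_cm_s2": feats.peak_acceleration_cm_s2,
                "peak_deceleration_cm_s2": feats.peak_deceleration_cm_s2,
                "reaction_time_ms": feats.reaction_time_ms,
                "accuracy_cm": feats.accuracy_cm,
                "anomalous": feats.anomalous,
                "anomaly_reasons": ";".join(feats.anomaly_reasons),
            }
        )
    return pd.DataFrame(rows)


MEASURES = (
    "peak_velocity_cm_s",
    "peak_acceleration_cm_s2",
    "peak_deceleration_cm_s2",
    "reaction_time_ms",
    "accuracy_cm",
)


def aggregate_conditions(features: pd.DataFrame, warn=None) -> pd.DataFrame:
    """Per-participant condition means over unflagged trials.

    Returns one row per (participant, phase, cs_type, position) with the
    mean of each kinematic measure, the number of trials entering the
    mean, and the number excluded as anomalous.  A condition cell with
    no surviving trials yields NaN means (never a silent zero); ``warn``
    is called with a message for each such cell.
    """
    grouped = features.groupby(
        ["participant", "phase", "cs_type", "position"], sort=True
    )
    rows = []
    for key, g in grouped:
        ok = g[~g["anomalous"]]
        row = dict(zip(["participant", "phase", "cs_type", "position"], key))
        row["n_trials"] = len(ok)
        row["n_excluded"] = int(g["anomalous"].sum())
        for m in MEASURES:
            row[m] = float(ok[m].mean()) if len(ok) else float("nan")
        if not len(ok) and warn is not None:
            warn(f"empty condition cell after exclusions: {key}")
        rows.append(row)
    return pd.DataFrame(rows)
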