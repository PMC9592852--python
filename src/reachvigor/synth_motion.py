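"""Synthetic mouse-reach trajectories with a minimum-jerk velocity profile.

Each simulated trial reproduces what a 100 Hz mouse-tracking logger would
record for a single, continuous reach from the fixed start point to the
cued target: a latency period with the cursor at rest, a smooth
minimum-jerk transport, and a stationary tail.  Movement vigor scales
with target distance (farther targets are reached in roughly the same
time, hence faster), and trials toward the threat-conditioned stimulus
(CS+) are executed with a configurable fractional reduction of movement
time — the invigoration effect the analysis pipeline is meant to
recover.  Peak speed of a noiseless trial has the closed form
1.875·D/T and peak acceleration ≈ 5.7735·D/T², which the kinematic
scorer is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import START_POINT, TrialSpec

__all__ = [
    "MotionParams",
    "TrajectoryTrial",
    "minimum_jerk_position",
    "simulate_reach",
    "simulate_cohort",
    "trajectories_to_frame",
    "trajectories_from_frame",
    "MIN_JERK_PEAK_SPEED",
    "MIN_JERK_PEAK_ACCEL",
]

#: peak of d/dτ (10τ³−15τ⁴+6τ⁵) — peak speed is this times D/T
MIN_JERK_PEAK_SPEED = 1.875
#: peak of the second derivative — peak acceleration is this times D/T²
MIN_JERK_PEAK_ACCEL = 10.0 / np.sqrt(3.0)  # ≈ 5.7735


@dataclass(frozen=True)
class MotionParams:
    """Generator knobs for one participant.

    Movement times (s) per position were chosen so that noiseless peak
    speeds land near the group position means reported for this task
    (≈ 212 / 313 / 398 cm/s for low / middle / high); the latency mean
    puts the offset-referenced reaction time near 230 ms.
    """

    base_movement_time: dict = field(
        default_factory=lambda: {"low": 0.140, "middle": 0.142, "high": 0.150}
    )
    cs_plus_vigor_gain: float = 0.03   # CS+ movement time scaled by (1 − gain)
    rt_mean_ms: float = 330.0          # stimulus onset → movement onset latency
    rt_sd_ms: float = 40.0
    endpoint_noise_sd_cm: float = 7.0
    path_noise_sd_cm: float = 0.05
    sample_rate_hz: float = 100.0
    anomaly_rate: float = 0.012   # ≈1.4 erratic trials per 120-trial phase
    px_to_cm: float = 0.049580
    tail_s: float = 0.25               # stationary samples after the reach

    def __post_init__(self):
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not 0 <= self.anomaly_rate < 1:
            raise ValueError("anomaly_rate must be in [0, 1)")
        if any(t <= 0 for t in self.base_movement_time.values()):
            raise ValueError("movement times must be positive")


@dataclass
class TrajectoryTrial:
    """Timestamped cursor samples for one reach, in logger coordinates."""

    participant_id: str
    trial_index: int
    timestamps_ms: np.ndarray   # ms since stimulus onset
    x_px: np.ndarray
    y_px: np.ndarray
    stimulus_onset_ms: float
    stimulus_offset_ms: float
    spec: TrialSpec
    anomalous_injected: bool = False

    def __len__(self):
        return len(self.timestamps_ms)


def minimum_jerk_position(t, T, start, end):
    """Point(s) along a straight minimum-jerk reach at time(s) ``t``.

    The displacement fraction is s(τ) = 10τ³ − 15τ⁴ + 6τ⁵ with τ = t/T;
    times outside [0, T] are clamped to the endpoints.
    """
    t = np.asarray(t, dtype=float)
    tau = np.clip(t / float(T), 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    return start + np.multiply.outer(s, end - start)


def _erratic_path(rng, start_px, end_px, n_move, lateral_cm, px_to_cm):
    """A zig-zag reach with ≥3 alternating lateral excursions (anomaly probe)."""
    base = minimum_jerk_position(
        np.linspace(0, 1, n_move), 1.0, start_px, end_px
    )
    phase_count = 4  # four alternating excursions → 3 reversals minimum
    frac = np.linspace(0, 1, n_move)
    lateral_px = lateral_cm / px_to_cm
    wiggle = lateral_px * np.sin(np.pi * phase_count * frac) * np.sin(np.pi * frac)
    base[:, 0] += wiggle
    return base


def simulate_reach(
    spec: TrialSpec,
    params: MotionParams,
    seed=None,
    participant_id: str = "p00",
    trial_index: int = 0,
) -> TrajectoryTrial:
    """Simulate the logger record of one reaching trial."""
    if spec.phase == "pavlovian":
        raise ValueError("reaches are only simulated for reaching phases")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    dt_ms = 1000.0 / params.sample_rate_hz
    latency_ms = -1.0
    while latency_ms <= 0:
        latency_ms = rng.normal(params.rt_mean_ms, params.rt_sd_ms)

    T = params.base_movement_time[spec.position]
    # invigoration is a consequence of learning: it applies at test,
    # never in the pre-learning baseline phase
    if spec.cs_type == "CS+" and spec.phase != "baseline":
        T *= 1.0 - params.cs_plus_vigor_gain

    start = np.array(START_POINT, dtype=float)
    end = np.array(spec.target_center, dtype=float)
    if params.endpoint_noise_sd_cm > 0:
        end = end + rng.normal(0, params.endpoint_noise_sd_cm / params.px_to_cm, 2)

    n_pre = int(np.ceil(latency_ms / dt_ms))
    n_move = max(int(np.ceil(T * 1000.0 / dt_ms)), 2)
    n_tail = int(np.ceil(params.tail_s * 1000.0 / dt_ms))
    n_total = n_pre + n_move + n_tail + 1
    t_ms = np.arange(n_total) * dt_ms

    anomalous = bool(rng.random() < params.anomaly_rate)
    move_t = (t_ms - latency_ms) / 1000.0
    if anomalous:
        frac_idx = np.clip(move_t / T, 0.0, 1.0)
        n_dense = 512
        dense = _erratic_path(rng, start, end, n_dense, lateral_cm=2.5,
                              px_to_cm=params.px_to_cm)
        idx = np.clip((frac_idx * (n_dense - 1)).astype(int), 0, n_dense - 1)
        xy = dense[idx]
    else:
        xy = minimum_jerk_position(move_t, T, start, end)

    if params.path_noise_sd_cm > 0:
        # tremor only while the hand moves: a resting mouse reports
        # identical samples, so pre-movement and tail stay exactly still
        moving = ((move_t > 0) & (move_t < T)).astype(float)
        noise = rng.normal(0, params.path_noise_sd_cm / params.px_to_cm, xy.shape)
        xy = xy + noise * moving[:, None]

    return TrajectoryTrial(
        participant_id=participant_id,
        trial_index=trial_index,
        timestamps_ms=t_ms,
        x_px=xy[:, 0],
        y_px=xy[:, 1],
        stimulus_onset_ms=0.0,
        stimulus_offset_ms=spec.stim_duration_s * 1000.0,
        spec=spec,
        anomalous_injected=anomalous,
    )


@dataclass(frozen=True)
class CohortEffects:
    """Per-participant random effects drawn by :func:`simulate_cohort`."""

    participant_id: str
    movement_time_scale: float
    vigor_gain: float
    latent_reactivity: float


def draw_participant_effects(
    params: MotionParams,
    n_participants: int,
    rng: np.random.Generator,
    movement_time_sd: float = 0.10,
    vigor_gain_sd: float = 0.015,
    reactivity_coupling: float = 0.6,
):
    """Random effects for a cohort.

    ``latent_reactivity`` is a standard-normal per-participant trait that
    is shared with the SCR generator so that participants who respond
    more strongly during learning also show a larger invigoration —
    the cross-participant correlation the analysis stage tests for.
    ``reactivity_coupling`` is the correlation between the latent trait
    and the participant's vigor gain.
    """
    z = rng.standard_normal(n_participants)                # latent reactivity
    e = rng.standard_normal(n_participants)
    rho = reactivity_coupling
    gain_dev = rho * z + np.sqrt(max(1 - rho**2, 0.0)) * e
    gains = params.cs_plus_vigor_gain + vigor_gain_sd * gain_dev
    scales = np.exp(rng.normal(0.0, movement_time_sd, n_participants))
    return [
        CohortEffects(
            participant_id=f"p{i:02d}",
            movement_time_scale=float(scales[i]),
            vigor_gain=float(gains[i]),
            latent_reactivity=float(z[i]),
        )
        for i in range(n_participants)
    ]


def simulate_cohort(
    schedules,
    params: MotionParams,
    n_participants: int,
    seed=0,
    effects=None,
) -> tuple:
    """Simulate every reaching trial for a cohort.

    ``schedules`` maps phase label → TrialSchedule; Pavlovian entries
    are skipped (no movement is made during learning).  Every
    participant runs the same trial orders with an independent noise
    stream.  Returns ``(trials, effects)`` where ``trials`` is a flat
    list of TrajectoryTrial.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    master = np.random.default_rng(seed)
    if effects is None:
        effects = draw_participant_effects(params, n_participants, master)

    trials = []
    for eff in effects:
        prng = np.random.default_rng(master.integers(2**31))
        p_params = replace(
            params,
            base_movement_time={
                k: v * eff.movement_time_scale
                for k, v in params.base_movement_time.items()
            },
            cs_plus_vigor_gain=max(eff.vigor_gain, 0.0),
        )
        for phase, schedule in schedules.items():
            if phase == "pavlovian":
                continue
            for i, spec in enumerate(schedule):
                trials.append(
                    simulate_reach(
                        spec, p_params, seed=prng,
                        participant_id=eff.participant_id, trial_index=i,
                    )
                )
    return trials, effects


# ---------------------------------------------------------------------------
# long-format CSV interchange (mousetrap-style logs)

def trajectories_to_frame(trials) -> pd.DataFrame:
    chunks = []
    for tr in trials:
        chunks.append(
            pd.DataFrame(
                {
                    "participant": tr.participant_id,
                    "phase": tr.spec.phase,
                    "trial": tr.trial_index,
                    "t_ms": tr.timestamps_ms,
                    "x_px": tr.x_px,
                    "y_px": tr.y_px,
                }
            )
        )
    return pd.concat(chunks, ignore_index=True)


def trajectories_from_frame(frame: pd.DataFrame, schedules=None):
    """Rebuild TrajectoryTrial objects from a long-format log.

    ``schedules`` maps phase → TrialSchedule so each trial can be linked
    back to its TrialSpec; required for downstream scoring.
    """
    required = {"participant", "phase", "trial", "t_ms", "x_px", "y_px"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"trajectory frame missing columns: {sorted(missing)}")
    out = []
    for (pid, phase, idx), g in frame.groupby(
        ["participant", "phase", "trial"], sort=True
    ):
        g = g.sort_values("t_ms")
        spec = None
        if schedules is not None and phase in schedules:
            spec = schedules[phase].trials[int(idx)]
        out.append(
            TrajectoryTrial(
                participant_id=str(pid),
                trial_index=int(idx),
                timestamps_ms=g["t_ms"].to_numpy(float),
                x_px=g["x_px"].to_numpy(float),
                y_px=g["y_px"].to_numpy(float),
                stimulus_onset_ms=0.0,
                stimulus_offset_ms=(spec.stim_duration_s * 1000.0) if spec else 100.0,
                spec=spec,
            )
        )
    return out
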