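"""Experimental design: screen geometry and constrained trial schedules.

The task presents a colored circle (CS+ or CS−) at one of three vertically
arranged positions on the screen.  Reaching phases (baseline and the two
test phases) show the stimulus for 100 ms and record a mouse reach;
the Pavlovian learning phase shows each stimulus for 6 s while the
participant only watches, with the CS+ reinforced by shock on a fixed
fraction of trials.

Coordinate convention (used throughout the package): Cartesian pixels,
origin at screen centre, y increasing upward.  The reach start point is
(0, −416); targets sit at (0, −96) / (0, 64) / (0, 224) for the
low / middle / high positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScreenGeometry",
    "TrialSpec",
    "TrialSchedule",
    "ScheduleInfeasibleError",
    "derive_px_to_cm",
    "generate_reaching_schedule",
    "generate_pavlovian_schedule",
    "schedule_to_frame",
    "schedule_from_frame",
]

#: target centres in px, origin at screen centre, y up
TARGET_CENTERS = {"low": (0, -96), "middle": (0, 64), "high": (0, 224)}
START_POINT = (0, -416)
POSITIONS = ("low", "middle", "high")
CS_TYPES = ("CS+", "CS-")

REACHING_PHASES = ("baseline", "test_safety", "test_threat")
STIM_DURATION_REACHING_S = 0.100
STIM_DURATION_PAVLOVIAN_S = 6.0

#: uniform jitter bounds, seconds
PRE_STIM_JITTER_S = (1.0, 1.5)
ITI_REACHING_S = (2.0, 4.0)
ITI_PAVLOVIAN_S = (12.0, 14.0)


class ScheduleInfeasibleError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the sequencing constraints."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical screen description; assumes square pixels."""

    diagonal_inches: float = 43.0
    resolution_x: int = 1920
    resolution_y: int = 1080

    def __post_init__(self):
        if self.diagonal_inches <= 0 or self.resolution_x <= 0 or self.resolution_y <= 0:
            raise ValueError("screen geometry must be strictly positive")

    @property
    def px_to_cm(self) -> float:
        return derive_px_to_cm(self)


def derive_px_to_cm(geometry: ScreenGeometry) -> float:
    """Physical pixel pitch in cm/px.

    With square pixels the pitch is diagonal_cm / diagonal_px.  For the
    study's 43-inch 1920×1080 display this gives 0.0496 cm/px, i.e. a
    64 px circle is 3.17 cm wide.
    """
    diag_px = math.hypot(geometry.resolution_x, geometry.resolution_y)
    return geometry.diagonal_inches * 2.54 / diag_px


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial."""

    phase: str
    cs_type: str            # "CS+" or "CS-"
    position: str           # "low" | "middle" | "high"
    target_center: tuple    # (x, y) px
    reinforced: bool = False
    iti_s: float = 3.0
    pre_stim_s: float = 1.25
    stim_duration_s: float = STIM_DURATION_REACHING_S

    def __post_init__(self):
        if self.cs_type not in CS_TYPES:
            raise ValueError(f"unknown cs_type {self.cs_type!r}")
        if self.position not in POSITIONS:
            raise ValueError(f"unknown position {self.position!r}")
        if tuple(self.target_center) != TARGET_CENTERS[self.position]:
            raise ValueError("target_center does not match position")
        if self.reinforced and not (self.cs_type == "CS+" and self.phase == "pavlovian"):
            raise ValueError("only pavlovian CS+ trials can be reinforced")


@dataclass
class TrialSchedule:
    """Ordered trials for one phase."""

    trials: list
    phase: str
    seed: int

    def __len__(self):
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def cell_counts(self) -> dict:
        counts: dict = {}
        for t in self.trials:
            key = (t.cs_type, t.position)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def reinforcement_rate(self) -> float:
        """Fraction of CS+ trials carrying the US."""
        plus = [t for t in self.trials if t.cs_type == "CS+"]
        if not plus:
            return float("nan")
        return sum(t.reinforced for t in plus) / len(plus)


def _jitters(rng: np.random.Generator, n: int, phase: str):
    iti_lo, iti_hi = ITI_PAVLOVIAN_S if phase == "pavlovian" else ITI_REACHING_S
    itis = rng.uniform(iti_lo, iti_hi, n)
    pres = rng.uniform(*PRE_STIM_JITTER_S, n)
    return itis, pres


def generate_reaching_schedule(
    n_per_cell: int = 20, seed: int = 0, phase: str = "baseline"
) -> TrialSchedule:
    """Fully randomised reaching schedule: 2 CS types × 3 positions × n_per_cell.

    The study's baseline and both test phases use n_per_cell = 20
    (120 trials), shuffled uniformly.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    if phase not in REACHING_PHASES:
        raise ValueError(f"phase must be one of {REACHING_PHASES}")
    rng = np.random.default_rng(seed)
    cells = [(cs, pos) for cs in CS_TYPES for pos in POSITIONS for _ in range(n_per_cell)]
    order = rng.permutation(len(cells))
    itis, pres = _jitters(rng, len(cells), phase)
    trials = [
        TrialSpec(
            phase=phase,
            cs_type=cells[i][0],
            position=cells[i][1],
            target_center=TARGET_CENTERS[cells[i][1]],
            iti_s=float(itis[k]),
            pre_stim_s=float(pres[k]),
            stim_duration_s=STIM_DURATION_REACHING_S,
        )
        for k, i in enumerate(order)
    ]
    return TrialSchedule(trials=trials, phase=phase, seed=seed)


def _max_run_length(labels) -> int:
    best = run = 0
    prev = None
    for lab in labels:
        run = run + 1 if lab == prev else 1
        prev = lab
        best = max(best, run)
    return best


def _constrained_cs_sequence(n_plus, n_minus, tail_type, tail_len, rng):
    """Random CS-type sequence with no run longer than 2.

    Builds the sequence left to right, at each step choosing among the
    types that (a) have trials remaining, (b) do not extend the current
    run beyond 2, and (c) leave a completable remainder, with
    probability proportional to the remaining counts.  ``tail_type`` /
    ``tail_len`` describe the run already in progress at the boundary
    (the end of the fixed lead-in), so the cap also holds across it.
    Returns None when the counts are infeasible.
    """
    rem = {"CS+": n_plus, "CS-": n_minus}
    other = {"CS+": "CS-", "CS-": "CS+"}
    run_type, run_len = tail_type, tail_len
    seq = []
    while rem["CS+"] + rem["CS-"] > 0:
        feasible = []
        for t in CS_TYPES:
            if rem[t] == 0:
                continue
            nl = run_len + 1 if t == run_type else 1
            if nl > 2:
                continue
            o = other[t]
            # completion exists iff neither type is forced into a run > 2
            if (rem[t] - 1) > (2 - nl) + 2 * rem[o]:
                continue
            if rem[o] > 2 * rem[t]:  # rem[t]-1 future t-runs + boundary gaps
                continue
            feasible.append(t)
        if not feasible:
            return None
        weights = np.array([rem[t] for t in feasible], dtype=float)
        t = feasible[rng.choice(len(feasible), p=weights / weights.sum())]
        seq.append(t)
        run_len = run_len + 1 if t == run_type else 1
        run_type = t
        rem[t] -= 1
    return seq


def generate_pavlovian_schedule(
    n_per_cell: int = 9,
    reinforced_per_cell: int = 7,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> TrialSchedule:
    """Constrained Pavlovian learning schedule.

    Layout (study defaults): 9 trials per (CS type × position) cell, 54
    trials total; 7 of the 9 CS+ trials in each position cell are
    reinforced (21/27 = 77.8% overall).  The first six trials are three
    CS− and three reinforced CS+ trials, one per position, in random
    order; the remaining trials are pseudo-random with no more than two
    consecutive stimuli of the same CS type (the cap also holds across
    the lead-in boundary).  The CS-type sequence is built by seeded
    constrained sequential sampling; position and reinforcement labels
    are then shuffled within each CS type, preserving exact cell
    counts.  Infeasible configurations raise after ``max_attempts``.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    if not 0 <= reinforced_per_cell <= n_per_cell:
        raise ValueError("reinforced_per_cell must be in [0, n_per_cell]")
    rng = np.random.default_rng(seed)

    # first six: one reinforced CS+ and one CS− per position, shuffled
    lead = [("CS+", pos, reinforced_per_cell > 0) for pos in POSITIONS]
    lead += [("CS-", pos, False) for pos in POSITIONS]
    lead = [lead[i] for i in rng.permutation(6)]

    rest = []
    n_rest = n_per_cell - 1
    if n_rest > 0:
        tail_type = lead[-1][0]
        tail_len = 2 if len(lead) > 1 and lead[-2][0] == tail_type else 1
        cs_seq = None
        for _ in range(max_attempts):
            cs_seq = _constrained_cs_sequence(
                3 * n_rest, 3 * n_rest, tail_type, tail_len, rng
            )
            if cs_seq is not None:
                break
        if cs_seq is None:
            raise ScheduleInfeasibleError(
                f"no ordering without >2 consecutive identical CS types "
                f"found in {max_attempts} attempts"
            )
        # per-type label pools: (position, reinforced), shuffled under seed
        n_reinf_left = max(reinforced_per_cell - 1, 0)
        pools = {
            "CS+": [
                (pos, j < n_reinf_left) for pos in POSITIONS for j in range(n_rest)
            ],
            "CS-": [(pos, False) for pos in POSITIONS for j in range(n_rest)],
        }
        for pool in pools.values():
            order = rng.permutation(len(pool))
            pool[:] = [pool[i] for i in order]
        for t in cs_seq:
            pos, reinf = pools[t].pop()
            rest.append((t, pos, reinf))

    labels = lead + rest
    itis, pres = _jitters(rng, len(labels), "pavlovian")
    trials = [
        TrialSpec(
            phase="pavlovian",
            cs_type=cs,
            position=pos,
            target_center=TARGET_CENTERS[pos],
            reinforced=bool(reinf),
            iti_s=float(itis[k]),
            pre_stim_s=float(pres[k]),
            stim_duration_s=STIM_DURATION_PAVLOVIAN_S,
        )
        for k, (cs, pos, reinf) in enumerate(labels)
    ]
    return TrialSchedule(trials=trials, phase="pavlovian", seed=seed)


# ---------------------------------------------------------------------------
# CSV interchange

_SCHEDULE_COLUMNS = [
    "phase",
    "trial_index",
    "cs_type",
    "position",
    "target_x_px",
    "target_y_px",
    "reinforced",
    "iti_s",
    "pre_stim_s",
    "stim_duration_s",
]


def schedule_to_frame(schedule: TrialSchedule) -> pd.DataFrame:
    rows = [
        {
            "phase": t.phase,
            "trial_index": i,
            "cs_type": t.cs_type,
            "position": t.position,
            "target_x_px": t.target_center[0],
            "target_y_px": t.target_center[1],
            "reinforced": t.reinforced,
            "iti_s": t.iti_s,
            "pre_stim_s": t.pre_stim_s,
            "stim_duration_s": t.stim_duration_s,
        }
        for i, t in enumerate(schedule.trials)
    ]
    return pd.DataFrame(rows, columns=_SCHEDULE_COLUMNS)


def schedule_from_frame(frame: pd.DataFrame, seed: int = -1) -> TrialSchedule:
    missing = set(_SCHEDULE_COLUMNS[:8]) - set(frame.columns)
    if missing:
        raise ValueError(f"schedule frame missing columns: {sorted(missing)}")
    frame = frame.sort_values("trial_index")
    trials = [
        TrialSpec(
            phase=row.phase,
            cs_type=row.cs_type,
            position=row.position,
            target_center=(int(row.target_x_px), int(row.target_y_px)),
            reinforced=bool(row.reinforced),
            iti_s=float(row.iti_s),
            pre_stim_s=float(getattr(row, "pre_stim_s", 1.25)),
            stim_duration_s=float(
                getattr(
                    row,
                    "stim_duration_s",
                    STIM_DURATION_PAVLOVIAN_S
                    if row.phase == "pavlovian"
                    else STIM_DURATION_REACHING_S,
                )
            ),
        )
        for row in frame.itertuples()
    ]
    phase = trials[0].phase if trials else "baseline"
    return TrialSchedule(trials=trials, phase=phase, seed=seed)
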