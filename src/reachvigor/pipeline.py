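"""End-to-end orchestration: simulate → score → analyze.

A run is a pure function of its :class:`RunConfig`.  Experiment layout 1
includes a baseline reaching phase before Pavlovian learning; layout 2
starts at learning.  The master seed is split into independent
per-stage streams (design / motion / SCR), so changing e.g. the SCR
noise level never perturbs the simulated trajectories.

Cross-participant coupling: the motion cohort draws a latent
"reactivity" trait per participant that shifts both the participant's
CS+ vigor gain and (scaled by ``scr_reactivity_sd_uS``) the CS+ SCR
amplitude, planting the positive correlation between learning-phase
sympathetic response and test-phase invigoration that the correlation
stage is designed to detect.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as dz
from . import kinematics as kin
from . import scr_scoring as scr
from . import stats as st
from . import synth_motion as sm
from . import synth_scr as ss

log = logging.getLogger("reachvigor")

__all__ = ["RunConfig", "ResultsBundle", "run_experiment", "run_on_external"]

TEST_PHASES = ("test_safety", "test_threat")


@dataclass
class RunConfig:
    seed: int = 0
    experiment: int = 1              # 1 = with baseline phase, 2 = without
    n_participants: int = 34
    n_per_cell_reaching: int = 20    # 120 trials per reaching phase
    n_per_cell_pavlovian: int = 9    # 54 learning trials
    reinforced_per_cell: int = 7     # 7-of-9 → 77.8% reinforcement
    motion: sm.MotionParams = field(default_factory=sm.MotionParams)
    scr: ss.ScrParams = field(default_factory=ss.ScrParams)
    geometry: dz.ScreenGeometry = field(default_factory=dz.ScreenGeometry)
    scr_reactivity_sd_uS: float = 0.15
    movement_time_sd: float = 0.10
    vigor_gain_sd: float = 0.015
    reactivity_coupling: float = 0.6
    threshold_frac: float = 0.02
    max_reversals: int = 2
    min_excursion_cm: float = 0.5
    rt_reference: str = "offset"
    scr_target_rate_hz: float = 200.0
    scr_apply_lowpass: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["motion"]["base_movement_time"] = dict(self.motion.base_movement_time)
        return d

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "motion" in d and isinstance(d["motion"], dict):
            d["motion"] = sm.MotionParams(**d["motion"])
        if "scr" in d and isinstance(d["scr"], dict):
            d["scr"] = ss.ScrParams(**d["scr"])
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = dz.ScreenGeometry(**d["geometry"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ResultsBundle:
    condition_means: pd.DataFrame
    scr_scores: pd.DataFrame
    scr_summary: pd.DataFrame
    anova_tables: dict          # name -> DataFrame
    contrasts: pd.DataFrame
    correlations: pd.DataFrame
    exclusions: pd.DataFrame
    provenance: dict

    def to_json(self) -> str:
        def df_records(df):
            return json.loads(df.to_json(orient="records")) if df is not None else None

        payload = {
            "schema_version": 1,
            "provenance": self.provenance,
            "condition_means": df_records(self.condition_means),
            "scr_summary": df_records(self.scr_summary),
            "anova_tables": {k: df_records(v) for k, v in self.anova_tables.items()},
            "contrasts": df_records(self.contrasts),
            "correlations": df_records(self.correlations),
            "exclusions": df_records(self.exclusions),
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    def write(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.condition_means.to_csv(out / "condition_means.csv", index=False)
        self.scr_scores.to_csv(out / "scr_scores.csv", index=False)
        self.scr_summary.to_csv(out / "scr_summary.csv", index=False)
        for name, tbl in self.anova_tables.items():
            tbl.to_csv(out / f"anova_{name}.csv", index=False)
        self.contrasts.to_csv(out / "contrasts.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.exclusions.to_csv(out / "exclusions.csv", index=False)
        (out / "results_bundle.json").write_text(self.to_json())


def _generate_schedules(config: RunConfig, rng: np.random.Generator) -> dict:
    schedules = {}
    phases = (("baseline",) if config.experiment == 1 else ()) + TEST_PHASES
    for phase in phases:
        schedules[phase] = dz.generate_reaching_schedule(
            config.n_per_cell_reaching, seed=int(rng.integers(2**31)), phase=phase
        )
    schedules["pavlovian"] = dz.generate_pavlovian_schedule(
        config.n_per_cell_pavlovian,
        config.reinforced_per_cell,
        seed=int(rng.integers(2**31)),
    )
    return schedules


def _analyze(
    config: RunConfig,
    cond_means: pd.DataFrame,
    scr_scores: pd.DataFrame,
    scr_summary: pd.DataFrame,
    exclusions: pd.DataFrame,
    provenance: dict,
) -> ResultsBundle:
    """Statistical stage shared by simulated and external runs."""
    anovas = {}
    contrast_rows = []

    def position_contrasts(df, measure, label):
        wide = df.pivot_table(
            index="participant", columns="position", values=measure
        )[["low", "middle", "high"]]
        for c in st.helmert_contrasts(wide.to_numpy()):
            contrast_rows.append(
                {
                    "analysis": label,
                    "contrast": c.label,
                    "estimate": c.estimate,
                    "t": c.t,
                    "df": c.df,
                    "p": c.p,
                }
            )

    # SCR during learning: 3 (position) × 2 (stimulus type)
    if len(scr_scores):
        scr_cells = (
            scr_scores.groupby(["participant", "cs_type", "position"])["amplitude_uS"]
            .mean()
            .reset_index()
        )
        anovas["scr_learning"] = st.rm_anova(
            scr_cells, dv="amplitude_uS", subject="participant",
            within=["position", "cs_type"],
        )

    # kinematics: per phase-group ANOVA per measure
    kin_groups = []
    if config.experiment == 1 and (cond_means["phase"] == "baseline").any():
        kin_groups.append(("baseline", ["baseline"], ["position", "cs_type"]))
    kin_groups.append(("test", list(TEST_PHASES), ["phase", "position", "cs_type"]))

    for label, phases, factors in kin_groups:
        sub = cond_means[cond_means["phase"].isin(phases)]
        if not len(sub):
            continue
        for measure in kin.MEASURES:
            cells = (
                sub.groupby(["participant"] + factors)[measure].mean().reset_index()
            )
            name = f"{label}_{measure}"
            anovas[name] = st.rm_anova(
                cells, dv=measure, subject="participant", within=factors
            )
            position_contrasts(cells, measure, name)

    # correlations: differential SCR at learning vs differential kinematics at test
    corr_rows = []
    test_means = cond_means[cond_means["phase"].isin(TEST_PHASES)]
    if len(test_means) and len(scr_summary):
        diffs = st.differential_scores(test_means, kin.MEASURES, phases=TEST_PHASES)
        merged = diffs.merge(
            scr_summary[["participant", "scr_differential_uS"]], on="participant"
        ).dropna()
        for measure in kin.MEASURES:
            col = f"{measure}_diff"
            if len(merged) >= 3:
                res = st.robust_pearson(
                    merged["scr_differential_uS"].to_numpy(), merged[col].to_numpy()
                )
                corr_rows.append(
                    {
                        "measure": measure,
                        "r": res.r,
                        "p": res.p,
                        "n_used": res.n_used,
                        "n_removed": len(res.removed_points),
                    }
                )

    return ResultsBundle(
        condition_means=cond_means,
        scr_scores=scr_scores,
        scr_summary=scr_summary,
        anova_tables=anovas,
        contrasts=pd.DataFrame(
            contrast_rows, columns=["analysis", "contrast", "estimate", "t", "df", "p"]
        ),
        correlations=pd.DataFrame(
            corr_rows, columns=["measure", "r", "p", "n_used", "n_removed"]
        ),
        exclusions=exclusions,
        provenance=provenance,
    )


def run_experiment(config: RunConfig, out_dir=None) -> ResultsBundle:
    """Simulate a full cohort under ``config`` and run the analysis suite."""
    seq = np.random.SeedSequence(config.seed)
    design_rng, motion_rng, scr_rng = (
        np.random.default_rng(s) for s in seq.spawn(3)
    )

    log.info("stage design: generating schedules")
    schedules = _generate_schedules(config, design_rng)

    log.info("stage motion: simulating %d participants", config.n_participants)
    motion = replace(config.motion, px_to_cm=config.geometry.px_to_cm)
    effects = sm.draw_participant_effects(
        motion,
        config.n_participants,
        motion_rng,
        movement_time_sd=config.movement_time_sd,
        vigor_gain_sd=config.vigor_gain_sd,
        reactivity_coupling=config.reactivity_coupling,
    )
    trials, _ = sm.simulate_cohort(
        schedules, motion, config.n_participants, seed=motion_rng, effects=effects
    )

    log.info("stage scr: simulating learning-phase conductance")
    scr_scores_frames = []
    for eff in effects:
        trace = ss.simulate_scr_trace(
            schedules["pavlovian"],
            config.scr,
            seed=scr_rng,
            participant_id=eff.participant_id,
            amp_offset_uS=config.scr_reactivity_sd_uS * eff.latent_reactivity,
        )
        pre = scr.preprocess(
            trace,
            target_rate_hz=config.scr_target_rate_hz,
            apply_lowpass=config.scr_apply_lowpass,
        )
        scr_scores_frames.append(scr.score_events(pre, schedule=schedules["pavlovian"]))
    scr_scores = pd.concat(scr_scores_frames, ignore_index=True)
    scr_summary = scr.participant_scr_summary(scr_scores)

    log.info("stage kinematics: scoring %d trials", len(trials))
    features = kin.score_trials(
        trials,
        px_to_cm=config.geometry.px_to_cm,
        threshold_frac=config.threshold_frac,
        max_reversals=config.max_reversals,
        min_excursion_cm=config.min_excursion_cm,
        rt_reference=config.rt_reference,
    )
    cond_means = kin.aggregate_conditions(features, warn=log.warning)
    exclusions = (
        features.groupby(["participant", "phase"])["anomalous"]
        .sum()
        .rename("n_excluded")
        .reset_index()
    )

    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_participants": config.n_participants,
        "experiment": config.experiment,
        "n_trials_simulated": len(trials),
    }
    log.info("stage stats: running the inferential suite")
    bundle = _analyze(
        config, cond_means, scr_scores, scr_summary, exclusions, provenance
    )
    if out_dir is not None:
        bundle.write(out_dir)
        sm.trajectories_to_frame(trials).to_csv(
            Path(out_dir) / "trajectories.csv", index=False
        )
        features.to_csv(Path(out_dir) / "trial_features.csv", index=False)
        pd.concat(
            [dz.schedule_to_frame(s) for s in schedules.values()], ignore_index=True
        ).to_csv(Path(out_dir) / "schedules.csv", index=False)
    return bundle


def run_detection_replicates(
    config: RunConfig, n_replicates: int, base_seed: int = 0
) -> pd.DataFrame:
    """Repeatedly simulate a cohort and record whether the two learning
    signatures are detected.

    For each replicate (seeded ``base_seed + i``) the full pipeline runs
    and two tests are extracted: the stimulus-type main effect on SCR
    during learning, and the stimulus-type main effect on peak velocity
    at test.  Returns one row per replicate with the p-values and the
    cohort-mean CS+ − CS− differentials.
    """
    rows = []
    for i in range(n_replicates):
        cfg = replace(config, seed=base_seed + i)
        bundle = run_experiment(cfg)
        scr_tbl = bundle.anova_tables["scr_learning"]
        scr_row = scr_tbl[scr_tbl.effect == "cs_type"].iloc[0]
        vel_tbl = bundle.anova_tables["test_peak_velocity_cm_s"]
        vel_row = vel_tbl[vel_tbl.effect == "cs_type"].iloc[0]
        vel_diff = st.differential_scores(
            bundle.condition_means[bundle.condition_means.phase.isin(TEST_PHASES)],
            ["peak_velocity_cm_s"],
            phases=TEST_PHASES,
        )["peak_velocity_cm_s_diff"].mean()
        rows.append(
            {
                "replicate": i,
                "seed": cfg.seed,
                "scr_p": scr_row["p"],
                "scr_F": scr_row["F"],
                "scr_diff_uS": bundle.scr_summary["scr_differential_uS"].mean(),
                "velocity_p": vel_row["p"],
                "velocity_F": vel_row["F"],
                "velocity_diff_cm_s": vel_diff,
            }
        )
    return pd.DataFrame(rows)


def run_on_external(
    trajectories: pd.DataFrame,
    scr_signals: dict,
    schedule: pd.DataFrame,
    config: RunConfig,
) -> ResultsBundle:
    """Score and analyze externally supplied data (no simulation).

    ``trajectories`` is the long-format log (participant, phase, trial,
    t_ms, x_px, y_px); ``scr_signals`` maps participant id →
    (signal_frame, events_frame); ``schedule`` is the full schedule
    table covering every phase present in the data.
    """
    required = {"participant", "phase", "trial", "t_ms", "x_px", "y_px"}
    missing = required - set(trajectories.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")

    schedules = {
        phase: dz.schedule_from_frame(g)
        for phase, g in schedule.groupby("phase", sort=False)
    }
    trials = sm.trajectories_from_frame(trajectories, schedules=schedules)
    features = kin.score_trials(
        trials,
        px_to_cm=config.geometry.px_to_cm,
        threshold_frac=config.threshold_frac,
        max_reversals=config.max_reversals,
        min_excursion_cm=config.min_excursion_cm,
        rt_reference=config.rt_reference,
    )
    cond_means = kin.aggregate_conditions(features, warn=log.warning)
    exclusions = (
        features.groupby(["participant", "phase"])["anomalous"]
        .sum()
        .rename("n_excluded")
        .reset_index()
    )

    frames = []
    pav = schedules.get("pavlovian")
    for pid, (signal, events) in scr_signals.items():
        trace = ss.ScrTrace.from_frames(signal, events, participant_id=pid)
        if trace.sample_rate_hz > config.scr_target_rate_hz:
            trace = scr.preprocess(
                trace,
                target_rate_hz=config.scr_target_rate_hz,
                apply_lowpass=config.scr_apply_lowpass,
            )
        frames.append(scr.score_events(trace, schedule=pav))
    scr_scores = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "participant", "trial", "cs_type", "position",
                "amplitude_uS", "trough_t_s", "peak_t_s", "valid", "zero_reason",
            ]
        )
    )
    scr_summary = (
        scr.participant_scr_summary(scr_scores) if len(scr_scores) else pd.DataFrame()
    )
    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "external_data": True,
    }
    return _analyze(config, cond_means, scr_scores, scr_summary, exclusions, provenance)
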