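"""Protocol orchestration: titration day, training sessions, post-test, cohorts.

`run_cohort` simulates the full study for a configured population — per
participant: practice + titration (day 1, no cue), ten 300-trial training
sessions with the staircase driven by the vertical component (AV observers
receive the auditory cue on every training trial), then a cue-free post-test
of 200 trials at each of the trained and untrained locations with dual
interleaved staircases — and writes the trial-log and per-session summary
CSVs.  All randomness descends deterministically from the master seed via
spawned substreams, so the same configuration reproduces byte-identical
files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import fit_sessions
from .config import GroupConfig, ProtocolConfig
from .observer import ObserverParams, ParametricObserver
from .records import TrialRecord, records_to_frame, run_staircase_block
from .staircase import DualStaircase, Staircase
from .stimulus import OBLIQUE_DIRECTIONS, TrialStimulus, component_truth, quadrant_label, score_response
from .titration import TitrationResult, practice_block, titrate

__all__ = [
    "sample_observer",
    "run_training_session",
    "run_posttest",
    "run_participant",
    "run_cohort",
    "replay_staircase",
]


def sample_observer(group: GroupConfig, rng: np.random.Generator) -> ParametricObserver:
    """Draw one participant's ground-truth parameters from a group population."""
    alpha_h = max(20.0, rng.normal(group.alpha_mean, group.alpha_sd))
    alpha_v = max(20.0, rng.normal(group.alpha_mean, group.alpha_sd))
    lr_v = max(0.0, rng.normal(group.learn_rate_v_mean, group.learn_rate_v_sd))
    lr_h = max(0.0, rng.normal(group.learn_rate_h_mean, group.learn_rate_h_sd))
    params = ObserverParams(
        alpha_h_deg=alpha_h,
        alpha_v_deg=alpha_v,
        beta=group.beta,
        lapse=group.lapse,
        learn_rate_h=lr_h,
        learn_rate_v=lr_v,
        transfer_h=group.transfer_h,
        transfer_v=group.transfer_v,
        av_cue=group.av_cue,
        cue_reliability=group.cue_reliability,
        abort_prob=group.abort_prob,
        noise_exponent=group.noise_exponent,
    )
    return ParametricObserver(params)


def run_training_session(
    observer: ParametricObserver,
    noise_fraction: float,
    day: int,
    staircase: Staircase,
    config: ProtocolConfig,
    rng: np.random.Generator,
    cue_present: bool = False,
    group: str = "",
) -> list[TrialRecord]:
    """One training session: a single block of completed trials.

    The staircase is updated by vertical-component correctness only (for
    both groups); the staircase object is mutated in place so state can
    carry over between days.
    """
    if not 1 <= day <= config.training_days:
        raise ValueError(f"day must be in [1, {config.training_days}]")
    if cue_present and not group:
        group = "AV"
    return run_staircase_block(
        observer,
        noise_fraction,
        staircase,
        config.trials_per_training_session,
        rng,
        session_day=day,
        cue_present=cue_present,
        location="trained",
        phase="training",
        group=group,
    )


def run_posttest(
    observer: ParametricObserver,
    noise_fraction: float,
    config: ProtocolConfig,
    rng: np.random.Generator,
    start_level_index: int,
) -> list[TrialRecord]:
    """Cue-free post-test: dual interleaved staircases at each location.

    200 completed trials per location by default; location order is
    counterbalanced by the rng; both staircases start at the participant's
    final training level; learning is evaluated at the last training day
    (perfect overnight retention).
    """
    levels = config.grid
    locations = ["trained", "untrained"]
    if rng.random() < 0.5:
        locations.reverse()
    day = config.training_days
    records: list[TrialRecord] = []
    trial_index = 0
    for loc in locations:
        ds = DualStaircase(
            levels,
            start_index_h=start_level_index,
            start_index_v=start_level_index,
            interleave=config.posttest_interleave,
            rng=rng if config.posttest_interleave == "random" else None,
        )
        completed = 0
        while completed < config.posttest_trials_per_location:
            sc_id, level = ds.next_assignment()
            direction = int(rng.choice(OBLIQUE_DIRECTIONS))
            trial = TrialStimulus.from_level(
                direction, level, noise_fraction, loc, levels
            )
            report = observer.respond(trial, day, rng, cue_present=False)
            base = dict(
                phase="posttest",
                session_day=day + 1,
                trial_index=trial_index,
                location=loc,
                global_direction_deg=direction,
                range_level_index=level,
                direction_range_deg=float(levels[level]),
                noise_fraction=noise_fraction,
                staircase_id=sc_id,
                cue_present=False,
            )
            if report.aborted:
                ds.abort()
                records.append(TrialRecord(aborted=True, **base))
            else:
                truth = component_truth(direction)
                combined, h_ok, v_ok = score_response(truth, report.response)
                ds.update(sc_id, h_ok if sc_id == "H" else v_ok)
                records.append(
                    TrialRecord(
                        response_quadrant=quadrant_label(report.response),
                        combined_correct=combined,
                        h_correct=h_ok,
                        v_correct=v_ok,
                        **base,
                    )
                )
                completed += 1
            trial_index += 1
    return records


def run_participant(
    observer: ParametricObserver,
    config: ProtocolConfig,
    rng: np.random.Generator,
    participant_id: str = "p00",
    group_label: str = "V",
    seed_tag: str = "",
) -> tuple[list[TrialRecord], TitrationResult]:
    """Simulate one participant through titration, training and post-test."""
    grid = config.grid
    records: list[TrialRecord] = []

    practice = practice_block(
        observer,
        rng,
        start_noise=config.practice_start_noise,
        start_level_index=config.start_level_index,
        level_grid=grid,
    )
    for r in practice.records:
        r.phase = "practice"
    records.extend(practice.records)
    titration = titrate(
        observer,
        practice.noise_fraction,
        rng,
        start_level_index=config.start_level_index,
        level_grid=grid,
        practice_adjustments=practice.adjustments,
    )
    for r in titration.records:
        r.phase = "titration"
    records.extend(titration.records)
    noise = titration.final_noise_fraction

    cue = observer.params.av_cue
    staircase = Staircase(grid, config.start_level_index, "vertical")
    for day in range(1, config.training_days + 1):
        if not config.carry_over_staircase:
            staircase = Staircase(grid, config.start_level_index, "vertical")
        session = run_training_session(
            observer, noise, day, staircase, config, rng,
            cue_present=cue, group=group_label,
        )
        records.extend(session)

    records.extend(
        run_posttest(observer, noise, config, rng, staircase.level_index)
    )

    for r in records:
        r.participant_id = participant_id
        r.group = group_label
        r.rng_seed_tag = seed_tag
    return records, titration


def run_cohort(
    config: ProtocolConfig,
    out_dir=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the whole cohort; optionally write ``trials.csv``/``summary.csv``.

    Deterministic given ``config.master_seed``: per-participant substreams
    are spawned from the master seed, so re-running the same configuration
    yields byte-identical CSVs.
    """
    root = np.random.SeedSequence(config.master_seed)
    n_total = sum(g.size for g in config.groups)
    children = root.spawn(n_total)
    all_records: list[TrialRecord] = []
    idx = 0
    for group in config.groups:
        for j in range(group.size):
            child = children[idx]
            rng = np.random.default_rng(child)
            observer = sample_observer(group, rng)
            pid = f"{group.label}{j:02d}"
            recs, _ = run_participant(
                observer,
                config,
                rng,
                participant_id=pid,
                group_label=group.label,
                seed_tag=f"seed{config.master_seed}/{idx}",
            )
            all_records.extend(recs)
            idx += 1

    trials = records_to_frame(all_records)
    summary = fit_sessions(trials)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trials.to_csv(out / "trials.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
    return trials, summary


def replay_staircase(trials: pd.DataFrame, level_grid=None) -> bool:
    """Round-trip check: re-derive every logged level trajectory from scratch.

    For each (participant, phase, session, location, staircase) the logged
    correctness sequence is replayed through a fresh controller starting at
    the first logged level; aborted rows must leave the state untouched.
    Returns True when every logged ``range_level_index`` matches the replay;
    raises AssertionError at the first mismatch.
    """
    from .stimulus import LEVEL_GRID

    grid = LEVEL_GRID if level_grid is None else np.asarray(level_grid, float)
    phases = trials[trials["phase"].isin(["training", "posttest", "titration"])]
    # Training sessions share one carried-over staircase, so they replay as a
    # single continuous trajectory per participant; titration and each
    # post-test location/staircase start fresh controllers.
    keys = ["participant_id", "phase", "location", "staircase_id"]
    for key, df in phases.groupby(keys, sort=False):
        df = df.sort_values(["session_day", "trial_index"])
        component = "v_correct" if key[-1] == "V" else "h_correct"
        sc = Staircase(grid, int(df.iloc[0]["range_level_index"]))
        for _, row in df.iterrows():
            if int(row["range_level_index"]) != sc.level_index:
                raise AssertionError(
                    f"replay mismatch at {key}, day {row['session_day']}, "
                    f"trial {row['trial_index']}: logged "
                    f"{row['range_level_index']}, replayed {sc.level_index}"
                )
            if bool(row["aborted"]):
                sc.abort()
            else:
                sc.update(bool(row[component]))
    return True
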