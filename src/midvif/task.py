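"""Synthetic Monetary Incentive Delay (MID) task behavior and timing.

Emulates the trial structure of the ABCD study's MID variant: each trial is
Cue -> Fixation -> Probe -> Feedback presented back to back with no
inter-trial interval.  A run is 50 trials, 10 per incentive condition
(LargeWin, SmallWin, Neutral, LargeLoss, SmallLoss).  The probe duration is
adapted by a staircase targeting 60% accuracy, adjusted every third trial
from the accuracy of the preceding six trials pooled over conditions.
Feedback lasts 1.950 s minus the current trial's probe duration.

The response model is a shifted log-normal reaction time.  A trial is a Hit
when the (preparation-adjusted) RT falls within the probe window, Too Slow
when the press lands after probe offset (or not at all), and Too Soon when a
premature press occurs before the probe; premature presses become more
likely the longer the fixation wait.  These mechanisms reproduce the
behavioral asymmetries seen in the real task: probe durations slightly
longer on Hit trials, fixations longer on Hit than Miss trials and much
longer on Too Soon than Too Slow trials, and RTs longer on Miss trials.

All times are seconds, zero-based from run start.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONDITIONS",
    "OUTCOMES",
    "CUE_DURATION_RANGE",
    "FIXATION_DURATION_RANGE",
    "FEEDBACK_TOTAL",
    "RT_RANGE",
    "BehaviorModelParams",
    "TrialRecord",
    "RunEvents",
    "staircase_update",
    "classify_outcome",
    "simulate_run",
    "simulate_runs",
    "simulate_trials",
    "run_to_events",
    "events_to_run",
    "write_events",
    "read_events",
    "summarize_behavior",
]

CONDITIONS = ("LargeWin", "SmallWin", "Neutral", "LargeLoss", "SmallLoss")
OUTCOMES = ("Hit", "TooSoon", "TooSlow")

CUE_DURATION_RANGE = (1.781, 2.039)
FIXATION_DURATION_RANGE = (1.5, 3.666)
#: Probe + Feedback always sum to this (feedback = 1.950 - probe duration).
FEEDBACK_TOTAL = 1.950
RT_RANGE = (0.105, 1.581)

TRIALS_PER_CONDITION = 10
TRIALS_PER_RUN = TRIALS_PER_CONDITION * len(CONDITIONS)


class ConfigurationError(ValueError):
    """Invalid behavioral-model parameters."""


@dataclass(frozen=True)
class BehaviorModelParams:
    """Parameters of the generative response model and staircase.

    RT is drawn as ``rt_shift + LogNormal(log(rt_location), rt_scale)``, then
    sped up by ``fixation_benefit`` seconds per second of fixation beyond the
    mid-range fixation (longer preparation -> faster press).  A premature
    press (Too Soon) occurs with probability growing as a power of the
    fixation duration, normalized so the marginal rate is
    ``p_too_soon_base``.
    """

    rt_location: float = 0.25   # median of the log-normal RT component (s)
    rt_scale: float = 0.26      # log-sd of the RT component
    rt_shift: float = 0.10      # non-decision time (s)
    fixation_benefit: float = 0.033  # s of RT speed-up per s of extra fixation
    p_too_soon_base: float = 0.07
    staircase_step: float = 0.030    # probe adjustment per staircase move (s)
    probe_min: float = 0.150
    probe_max: float = 0.500
    probe_init: float = 0.300
    target_accuracy: float = 0.60
    # shape of the premature-press hazard in fixation duration; larger values
    # concentrate Too Soon trials on long fixations
    too_soon_exponent: float = 4.0
    # probability that a Too Soon trial has a secondary press after probe
    # onset (which is the only case where an RT is recorded)
    p_too_soon_second_press: float = 0.5
    # Too Soon secondary-press RTs run slightly faster than Too Slow RTs
    too_soon_rt_deficit: float = 0.042

    def __post_init__(self) -> None:
        if not (self.probe_min < self.probe_init < self.probe_max):
            raise ConfigurationError(
                "probe bounds must satisfy probe_min < probe_init < probe_max"
            )
        if not 0.0 <= self.p_too_soon_base <= 1.0:
            raise ConfigurationError("p_too_soon_base must be in [0, 1]")
        if not 0.0 < self.target_accuracy < 1.0:
            raise ConfigurationError("target_accuracy must be in (0, 1)")
        for name in ("rt_location", "rt_scale", "staircase_step"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    def rt_distribution(self) -> stats.rv_continuous:
        """Frozen shifted log-normal RT distribution (before fixation benefit)."""
        return stats.lognorm(
            s=self.rt_scale, scale=self.rt_location, loc=self.rt_shift
        )


@dataclass(frozen=True)
class TrialRecord:
    """One MID trial: contiguous Cue, Fixation, Probe, Feedback events."""

    trial_index: int
    condition: str
    cue_onset: float
    cue_duration: float
    fixation_onset: float
    fixation_duration: float
    probe_onset: float
    probe_duration: float
    feedback_onset: float
    feedback_duration: float
    outcome: str
    rt: float | None = None

    def validate(self, atol: float = 1e-9) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        chain = (
            (self.cue_onset, self.cue_duration, self.fixation_onset),
            (self.fixation_onset, self.fixation_duration, self.probe_onset),
            (self.probe_onset, self.probe_duration, self.feedback_onset),
        )
        for onset, dur, nxt in chain:
            if abs(onset + dur - nxt) > atol:
                raise ValueError("trial events are not contiguous")
        if abs(self.feedback_duration - (FEEDBACK_TOTAL - self.probe_duration)) > atol:
            raise ValueError("feedback duration must be 1.950 s minus probe duration")
        if self.rt is not None and not (
            RT_RANGE[0] - atol <= self.rt <= RT_RANGE[1] + atol
        ):
            raise ValueError(f"rt {self.rt} outside {RT_RANGE}")

    @property
    def end(self) -> float:
        return self.feedback_onset + self.feedback_duration

    @property
    def is_hit(self) -> bool:
        return self.outcome == "Hit"


@dataclass(frozen=True)
class RunEvents:
    """An ordered, contiguous 50-trial MID run."""

    trials: tuple[TrialRecord, ...]
    run_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))

    @property
    def total_duration(self) -> float:
        return self.trials[-1].end if self.trials else 0.0

    def validate(self, atol: float = 1e-9) -> None:
        if len(self.trials) != TRIALS_PER_RUN:
            raise ValueError(f"a run must have {TRIALS_PER_RUN} trials")
        counts = pd.Series([t.condition for t in self.trials]).value_counts()
        for cond in CONDITIONS:
            if counts.get(cond, 0) != TRIALS_PER_CONDITION:
                raise ValueError(
                    f"condition {cond} has {counts.get(cond, 0)} trials, "
                    f"expected {TRIALS_PER_CONDITION}"
                )
        prev_end = 0.0
        for t in self.trials:
            t.validate(atol=atol)
            if abs(t.cue_onset - prev_end) > atol:
                raise ValueError("trials are not contiguous")
            prev_end = t.end


def staircase_update(
    current_probe_duration: float,
    last_six_outcomes: Sequence[str],
    trial_index: int,
    params: BehaviorModelParams,
) -> float:
    """Adaptive probe-duration update, applied every third trial.

    ``trial_index`` is 1-based.  On adjustment trials, the accuracy over the
    (up to six) most recent outcomes across all cue conditions is compared
    with the target: below target lengthens the probe by ``staircase_step``,
    otherwise it shrinks.  The result is clamped to [probe_min, probe_max].
    """
    if trial_index < 1:
        raise ValueError("trial_index must be >= 1")
    if trial_index % 3 != 0:
        return current_probe_duration
    recent = list(last_six_outcomes)[-6:]
    if not recent:
        return current_probe_duration
    accuracy = sum(o == "Hit" for o in recent) / len(recent)
    if accuracy < params.target_accuracy:
        new = current_probe_duration + params.staircase_step
    else:
        new = current_probe_duration - params.staircase_step
    return float(np.clip(new, params.probe_min, params.probe_max))


def classify_outcome(
    press_times: Sequence[float], probe_onset: float, probe_offset: float
) -> tuple[str, float | None]:
    """Classify a trial from its button presses.

    Too Soon if any press precedes the probe; else Hit if a press falls
    within the probe window; else Too Slow.  The RT is the first press at or
    after probe onset minus probe onset — so a Too Soon trial only records an
    RT when a secondary press follows probe onset.
    """
    presses = list(press_times)
    if any(b < a for a, b in zip(presses, presses[1:])):
        raise ValueError("press times must be sorted ascending")
    rt = None
    after = [p for p in presses if p >= probe_onset]
    if after:
        rt = after[0] - probe_onset
    if any(p < probe_onset for p in presses):
        return "TooSoon", rt
    if any(probe_onset <= p <= probe_offset for p in presses):
        return "Hit", rt
    return "TooSlow", rt


def _too_soon_fix_ref(params: BehaviorModelParams) -> float:
    """Normalizer so E[p(TooSoon | fixation)] = p_too_soon_base under the
    uniform fixation distribution: the k-th moment root of the fixation."""
    a, b = FIXATION_DURATION_RANGE
    k = params.too_soon_exponent
    moment = (b ** (k + 1) - a ** (k + 1)) / ((k + 1) * (b - a))
    return float(moment ** (1.0 / k))


def _simulate_trial_sequence(
    params: BehaviorModelParams,
    conditions: Sequence[str],
    rng: np.random.Generator,
    probe_start: float | None = None,
) -> list[TrialRecord]:
    """Core generator: one trial per entry of ``conditions``, carrying the
    staircase through the whole sequence."""
    rt_dist = params.rt_distribution()
    fix_ref = _too_soon_fix_ref(params)
    fix_mid = 0.5 * sum(FIXATION_DURATION_RANGE)

    probe_dur = params.probe_init if probe_start is None else float(probe_start)
    probe_dur = float(np.clip(probe_dur, params.probe_min, params.probe_max))
    outcomes: list[str] = []
    trials: list[TrialRecord] = []
    t = 0.0
    for i, cond in enumerate(conditions):
        cue_dur = rng.uniform(*CUE_DURATION_RANGE)
        fix_dur = rng.uniform(*FIXATION_DURATION_RANGE)
        p_ts = min(0.95, params.p_too_soon_base * (fix_dur / fix_ref) ** params.too_soon_exponent)
        rt: float | None
        if rng.random() < p_ts:
            outcome = "TooSoon"
            if rng.random() < params.p_too_soon_second_press:
                # secondary press after probe onset: drawn from the upper tail
                # of the RT law (a press that would have been Too Slow),
                # slightly faster than genuine Too Slow presses
                lo = rt_dist.cdf(probe_dur)
                u = rng.uniform(lo, 1.0)
                rt = float(rt_dist.ppf(u)) - params.too_soon_rt_deficit
                rt = float(np.clip(rt, RT_RANGE[0], RT_RANGE[1]))
            else:
                rt = None
        else:
            raw = params.rt_shift + rng.lognormal(
                np.log(params.rt_location), params.rt_scale
            )
            eff = raw - params.fixation_benefit * (fix_dur - fix_mid)
            if eff <= probe_dur:
                outcome = "Hit"
                rt = float(np.clip(eff, RT_RANGE[0], probe_dur))
            else:
                outcome = "TooSlow"
                rt = float(eff) if eff <= RT_RANGE[1] else None
                if rt is not None:
                    rt = max(rt, RT_RANGE[0])
        fb_dur = FEEDBACK_TOTAL - probe_dur
        trials.append(
            TrialRecord(
                trial_index=i,
                condition=cond,
                cue_onset=t,
                cue_duration=cue_dur,
                fixation_onset=t + cue_dur,
                fixation_duration=fix_dur,
                probe_onset=t + cue_dur + fix_dur,
                probe_duration=probe_dur,
                feedback_onset=t + cue_dur + fix_dur + probe_dur,
                feedback_duration=fb_dur,
                outcome=outcome,
                rt=rt,
            )
        )
        t += cue_dur + fix_dur + probe_dur + fb_dur
        outcomes.append(outcome)
        probe_dur = staircase_update(probe_dur, outcomes[-6:], i + 1, params)
    return trials


def simulate_run(
    params: BehaviorModelParams,
    run_id: int = 0,
    seed: int = 0,
    probe_start: float | None = None,
) -> RunEvents:
    """Simulate one 50-trial MID run (10 trials per condition).

    The condition order is a seeded permutation of the balanced multiset.
    ``probe_start`` lets callers carry the staircase across runs of a session.
    """
    rng = np.random.default_rng(seed)
    conditions = np.repeat(CONDITIONS, TRIALS_PER_CONDITION)
    conditions = list(rng.permutation(conditions))
    trials = _simulate_trial_sequence(params, conditions, rng, probe_start)
    run = RunEvents(trials=tuple(trials), run_id=run_id)
    run.validate()
    return run


def simulate_runs(
    params: BehaviorModelParams, n_runs: int, seed: int = 0
) -> list[RunEvents]:
    """Simulate a session of runs, carrying the staircase across runs."""
    runs: list[RunEvents] = []
    probe_start: float | None = None
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for run_id, child in enumerate(ss.spawn(n_runs)):
        run = simulate_run(
            params,
            run_id=run_id,
            seed=child,  # type: ignore[arg-type]
            probe_start=probe_start,
        )
        runs.append(run)
        probe_start = run.trials[-1].probe_duration
    return runs


def simulate_trials(
    params: BehaviorModelParams, n_trials: int, seed: int = 0
) -> list[TrialRecord]:
    """Simulate a long pooled trial sequence (for staircase diagnostics).

    Conditions repeat in shuffled balanced blocks of 50; the staircase runs
    uninterrupted over the whole sequence.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    while sum(len(b) for b in blocks) < n_trials:
        blocks.append(list(rng.permutation(np.repeat(CONDITIONS, TRIALS_PER_CONDITION))))
    conditions = [c for b in blocks for c in b][:n_trials]
    return _simulate_trial_sequence(params, conditions, rng)


# ---------------------------------------------------------------------------
# events-table I/O (BIDS-style TSV)
# ---------------------------------------------------------------------------

_EVENT_COMPONENTS = ("cue", "fixation", "probe", "feedback")


def run_to_events(run: RunEvents) -> pd.DataFrame:
    """One row per event (4 per trial): onset, duration, trial_type,
    response_time, outcome.  trial_type is component_condition, with the
    outcome appended for feedback rows (e.g. ``feedback_LargeWin_Hit``)."""
    rows = []
    for t in run.trials:
        parts = {
            "cue": (t.cue_onset, t.cue_duration),
            "fixation": (t.fixation_onset, t.fixation_duration),
            "probe": (t.probe_onset, t.probe_duration),
            "feedback": (t.feedback_onset, t.feedback_duration),
        }
        for comp in _EVENT_COMPONENTS:
            onset, dur = parts[comp]
            trial_type = f"{comp}_{t.condition}"
            if comp == "feedback":
                trial_type += f"_{t.outcome}"
            rows.append(
                {
                    "onset": onset,
                    "duration": dur,
                    "trial_type": trial_type,
                    "response_time": t.rt if comp == "probe" else np.nan,
                    "outcome": t.outcome,
                }
            )
    return pd.DataFrame(rows)


def events_to_run(events: pd.DataFrame, run_id: int = 0) -> RunEvents:
    """Reconstruct a RunEvents from an events table (inverse of run_to_events)."""
    required = {"onset", "duration", "trial_type"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table is missing columns: {sorted(missing)}")
    ev = events.sort_values("onset", kind="stable").reset_index(drop=True)
    if (ev["duration"] < 0).any():
        raise ValueError("events table contains negative durations")
    if not ev["onset"].is_monotonic_increasing:
        raise ValueError("event onsets are not monotone")
    if len(ev) % 4 != 0:
        raise ValueError("expected 4 event rows (cue/fixation/probe/feedback) per trial")
    trials = []
    for i in range(len(ev) // 4):
        chunk = ev.iloc[4 * i : 4 * (i + 1)]
        comps = [tt.split("_")[0] for tt in chunk["trial_type"]]
        if comps != list(_EVENT_COMPONENTS):
            raise ValueError(f"trial {i}: expected components {_EVENT_COMPONENTS}, got {comps}")
        fb_parts = chunk.iloc[3]["trial_type"].split("_")
        condition, outcome = fb_parts[1], fb_parts[2]
        rt = chunk.iloc[2].get("response_time", np.nan)
        trials.append(
            TrialRecord(
                trial_index=i,
                condition=condition,
                cue_onset=float(chunk.iloc[0]["onset"]),
                cue_duration=float(chunk.iloc[0]["duration"]),
                fixation_onset=float(chunk.iloc[1]["onset"]),
                fixation_duration=float(chunk.iloc[1]["duration"]),
                probe_onset=float(chunk.iloc[2]["onset"]),
                probe_duration=float(chunk.iloc[2]["duration"]),
                feedback_onset=float(chunk.iloc[3]["onset"]),
                feedback_duration=float(chunk.iloc[3]["duration"]),
                outcome=outcome,
                rt=None if pd.isna(rt) else float(rt),
            )
        )
    return RunEvents(trials=tuple(trials), run_id=run_id)


def write_events(run: RunEvents, path) -> None:
    # %.17g keeps the text round-trip exact for float64 times
    run_to_events(run).to_csv(path, sep="\t", index=False, na_rep="n/a",
                              float_format="%.17g")


def read_events(path, run_id: int = 0) -> RunEvents:
    events = pd.read_csv(path, sep="\t", na_values=["n/a"],
                         float_precision="round_trip")
    return events_to_run(events, run_id=run_id)


# ---------------------------------------------------------------------------
# behavioral summaries
# ---------------------------------------------------------------------------


def summarize_behavior(runs: Iterable[RunEvents]) -> pd.DataFrame:
    """Mean/SD of fixation, probe, and feedback durations and RT, split by
    trial outcome groups (Hit vs Miss; TooSoon vs TooSlow).

    Returns a tidy frame with columns measure, group, n, mean, sd.  Empty
    cells are kept with n=0 and NaN statistics.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("summarize_behavior requires at least one run")
    trials = [t for run in runs for t in run.trials]
    frame = pd.DataFrame(
        {
            "fixation_duration": [t.fixation_duration for t in trials],
            "probe_duration": [t.probe_duration for t in trials],
            "feedback_duration": [t.feedback_duration for t in trials],
            "rt": [t.rt if t.rt is not None else np.nan for t in trials],
            "outcome": [t.outcome for t in trials],
        }
    )
    groups = {
        "Hit": frame["outcome"] == "Hit",
        "Miss": frame["outcome"] != "Hit",
        "TooSoon": frame["outcome"] == "TooSoon",
        "TooSlow": frame["outcome"] == "TooSlow",
    }
    rows = []
    for measure in ("fixation_duration", "probe_duration", "feedback_duration", "rt"):
        for group, sel in groups.items():
            vals = frame.loc[sel, measure].dropna()
            rows.append(
                {
                    "measure": measure,
                    "group": group,
                    "n": len(vals),
                    "mean": vals.mean() if len(vals) else np.nan,
                    "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
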