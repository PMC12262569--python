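"""Emulation of ABCD-style Monetary Incentive Delay (MID) trial schedules.

Each MID trial presents four back-to-back components with no inter-trial
interval: a Cue announcing the incentive (Win $5, Win $0.20, Neutral,
Don't Lose $0.20, Don't Lose $5), a Fixation, a brief Probe requiring a
speeded button press, and Feedback reporting the outcome.  A press inside
the Probe window is a Hit; Too Slow and Too Soon presses are Misses.  A run
holds 50 trials, 10 per cue type, in random order; a session holds 2 runs.

The emulator reproduces the marginal timing structure of the real task:
component durations are drawn uniformly within the observed ranges, then
shifted by trial outcome so that Hit trials have slightly longer Probes
(~29 ms) and Fixations (~112 ms) while Miss trials have longer response
times (~89 ms), and Feedback fills 1.950 s minus the Probe duration.  An
optional staircase mimics the task's 60%-accuracy tracking of Probe
duration; by default outcomes are drawn i.i.d. (57% Hit / 36% Too Slow /
7% Too Soon) since only the marginal structure matters for design
diagnostics and simulation.

Two first-level model specifications are built in:

* ``CUEFEEDBACK`` — impulse regressors at Cue onsets (5, by cue type) and
  Feedback onsets (10, cue type x Hit/Miss), each paired with its temporal
  derivative: 30 task regressors.
* ``SATURATED`` — duration-matched boxcars for every component: 5 Cue +
  5 Fixation + 3 Probe (Win/Loss/Neutral) + 1 response-time + 10 Feedback
  = 24 task regressors, no derivatives (``SATURATED_WITH_DERIVS`` adds
  one derivative per regressor).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (
    DesignMatrix,
    EventTable,
    TimeGrid,
    assemble_design,
    canonical_hrf,
    make_regressor,
    per_run_drift_regressors,
)
from .diagnostics import ContrastSpec

__all__ = [
    "CUE_TYPES",
    "OUTCOMES",
    "MidParams",
    "MidTrial",
    "MidSchedule",
    "ModelSpec",
    "MODEL_SPECS",
    "CUEFEEDBACK",
    "SATURATED",
    "SATURATED_WITH_DERIVS",
    "CONTRAST_DEFINITIONS",
    "ABCD_CONTRASTS",
    "generate_mid_schedule",
    "staircase_probe_duration",
    "simulate_staircase",
    "schedule_to_events",
    "build_design",
    "contrast_library",
]

CUE_TYPES = ("LargeWin", "SmallWin", "Neutral", "SmallLoss", "LargeLoss")
OUTCOMES = ("Hit", "TooSlow", "TooSoon")
_VALENCE = {
    "LargeWin": "Win",
    "SmallWin": "Win",
    "Neutral": "Neutral",
    "SmallLoss": "Loss",
    "LargeLoss": "Loss",
}


def is_miss(outcome: str) -> bool:
    """ABCD convention: a Miss is either Too Slow or Too Soon."""
    return outcome in ("TooSlow", "TooSoon")


@dataclass(frozen=True)
class MidParams:
    """Timing and behavioral parameters of the emulated task.

    All times in seconds.  Ranges are the observed screen-display ranges;
    the ``*_hit_shift`` / ``rt_miss_shift`` values are mean Hit-Miss
    differences applied symmetrically around the uniform base draw.
    """

    cue_range: tuple[float, float] = (1.781, 2.039)
    fixation_range: tuple[float, float] = (1.500, 3.666)
    probe_range: tuple[float, float] = (0.172, 0.497)
    feedback_range: tuple[float, float] = (1.473, 1.789)
    feedback_total: float = 1.950  # feedback duration = total - probe duration
    rt_range: tuple[float, float] = (0.105, 1.581)
    rt_base_range: tuple[float, float] = (0.150, 1.000)
    outcome_probs: tuple[float, float, float] = (0.57, 0.36, 0.07)
    probe_hit_shift: float = 0.029
    fixation_hit_shift: float = 0.112
    rt_miss_shift: float = 0.089
    too_soon_rt_prob: float = 0.5  # Too Soon RTs recorded only for extra presses
    n_runs: int = 2
    trials_per_cue: int = 10
    dt: float = 0.8
    staircase: bool = False
    staircase_step: float = 0.02
    responder_rt_mean: float = 0.300
    responder_rt_sd: float = 0.080

    def validate(self) -> None:
        for name in ("cue_range", "fixation_range", "probe_range", "feedback_range",
                     "rt_range", "rt_base_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if abs(sum(self.outcome_probs) - 1.0) > 1e-9 or min(self.outcome_probs) < 0:
            raise ValueError("outcome probabilities must be non-negative and sum to 1")
        if self.probe_hit_shift >= self.probe_range[1] - self.probe_range[0]:
            raise ValueError("probe outcome shift exceeds the probe duration range")
        if self.fixation_hit_shift >= self.fixation_range[1] - self.fixation_range[0]:
            raise ValueError("fixation outcome shift exceeds the fixation duration range")
        lo, hi = self.rt_base_range
        if (lo - self.rt_miss_shift / 2 < self.rt_range[0] - 1e-9
                or hi + self.rt_miss_shift / 2 > self.rt_range[1] + 1e-9):
            raise ValueError("rt_base_range plus outcome shift leaves the legal RT range")
        if self.n_runs < 1 or self.trials_per_cue < 1:
            raise ValueError("need at least one run and one trial per cue type")


@dataclass(frozen=True)
class MidTrial:
    cue_type: str
    outcome: str
    cue_onset: float
    cue_duration: float
    fixation_duration: float
    probe_duration: float
    feedback_duration: float
    response_time: float | None

    @property
    def fixation_onset(self) -> float:
        return self.cue_onset + self.cue_duration

    @property
    def probe_onset(self) -> float:
        return self.fixation_onset + self.fixation_duration

    @property
    def feedback_onset(self) -> float:
        return self.probe_onset + self.probe_duration

    @property
    def end(self) -> float:
        return self.feedback_onset + self.feedback_duration


@dataclass
class MidSchedule:
    """A full emulated session: per-run trial lists plus the sampling grid."""

    runs: list[list[MidTrial]]
    params: MidParams
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return sum(len(r) for r in self.runs)

    @property
    def run_lengths(self) -> tuple[float, ...]:
        # last feedback offset rounded up to a whole number of scans
        dt = self.params.dt
        return tuple(float(np.ceil(run[-1].end / dt - 1e-9) * dt) for run in self.runs)

    def grid(self, oversampling: int = 50) -> TimeGrid:
        return TimeGrid(run_lengths=self.run_lengths, dt=self.params.dt,
                        oversampling=oversampling)

    def trials(self):
        for run_idx, run in enumerate(self.runs):
            for trial in run:
                yield run_idx, trial

    def to_run_frame(self, run: int) -> pd.DataFrame:
        """BIDS-style events frame for one run (one row per component)."""
        rows = []
        for t in self.runs[run]:
            for comp, onset, dur in (
                ("cue", t.cue_onset, t.cue_duration),
                ("fixation", t.fixation_onset, t.fixation_duration),
                ("probe", t.probe_onset, t.probe_duration),
                ("feedback", t.feedback_onset, t.feedback_duration),
            ):
                rows.append(
                    {
                        "onset": round(onset, 6),
                        "duration": round(dur, 6),
                        "trial_type": comp,
                        "cue_type": t.cue_type,
                        "outcome": t.outcome,
                        "response_time": (
                            round(t.response_time, 6) if t.response_time is not None else None
                        ),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_run_frames(cls, frames: list[pd.DataFrame], params: MidParams | None = None
                        ) -> "MidSchedule":
        """Rebuild a schedule from per-run BIDS event frames."""
        params = params or MidParams()
        runs = []
        for frame in frames:
            frame = frame.sort_values("onset").reset_index(drop=True)
            trials = []
            for i in range(0, len(frame), 4):
                block = frame.iloc[i : i + 4].set_index("trial_type")
                rt = block.loc["probe", "response_time"]
                trials.append(
                    MidTrial(
                        cue_type=str(block.loc["cue", "cue_type"]),
                        outcome=str(block.loc["cue", "outcome"]),
                        cue_onset=float(block.loc["cue", "onset"]),
                        cue_duration=float(block.loc["cue", "duration"]),
                        fixation_duration=float(block.loc["fixation", "duration"]),
                        probe_duration=float(block.loc["probe", "duration"]),
                        feedback_duration=float(block.loc["feedback", "duration"]),
                        response_time=None if pd.isna(rt) else float(rt),
                    )
                )
            runs.append(trials)
        return cls(runs=runs, params=params)


def staircase_probe_duration(
    recent_hits, current: float, step: float = 0.02,
    bounds: tuple[float, float] = (0.172, 0.497), target: float = 0.6,
) -> float:
    """Adaptive Probe duration update targeting a fixed accuracy.

    Applied every third trial: if accuracy over the last (up to) six trials
    exceeds the target, the Probe window shrinks by ``step``; otherwise it
    grows, clipped to the legal range.
    """
    recent = list(recent_hits)[-6:]
    accuracy = float(np.mean(recent)) if recent else 0.0
    nxt = current - step if accuracy > target else current + step
    return float(np.clip(nxt, *bounds))


def simulate_staircase(
    n_trials: int, rng, rt_mean: float = 0.300, rt_sd: float = 0.080,
    step: float = 0.02, bounds: tuple[float, float] = (0.172, 0.497),
    p_too_soon: float = 0.07,
):
    """Run the staircase against a latent normal-RT responder.

    Returns (probe durations, outcomes).  A trial is a Hit when the latent
    RT falls inside the Probe window; premature presses occur at a fixed
    rate independent of the window.
    """
    duration = float(np.mean(bounds))
    durations, outcomes, hits = [], [], []
    for i in range(n_trials):
        durations.append(duration)
        if rng.random() < p_too_soon:
            outcome = "TooSoon"
        else:
            rt = rng.normal(rt_mean, rt_sd)
            outcome = "Hit" if 0 < rt <= duration else "TooSlow"
        outcomes.append(outcome)
        hits.append(outcome == "Hit")
        if (i + 1) % 3 == 0:
            duration = staircase_probe_duration(hits, duration, step=step, bounds=bounds)
    return np.array(durations), outcomes


def _draw_trial(rng, cue_type: str, outcome: str, p: MidParams,
                probe_duration: float | None = None) -> MidTrial:
    hit = outcome == "Hit"
    sign = 0.5 if hit else -0.5
    cue = rng.uniform(*p.cue_range)
    fixation = float(np.clip(rng.uniform(*p.fixation_range) + sign * p.fixation_hit_shift,
                             *p.fixation_range))
    if probe_duration is None:
        probe = float(np.clip(rng.uniform(*p.probe_range) + sign * p.probe_hit_shift,
                              *p.probe_range))
    else:
        probe = float(probe_duration)
    feedback = float(np.clip(p.feedback_total - probe, *p.feedback_range))
    rt_base = rng.uniform(*p.rt_base_range)
    rt = float(np.clip(rt_base - sign * p.rt_miss_shift, *p.rt_range))
    if outcome == "TooSoon" and rng.random() >= p.too_soon_rt_prob:
        response_time = None  # single premature press: no RT recorded
    else:
        response_time = rt
    return MidTrial(
        cue_type=cue_type, outcome=outcome, cue_onset=0.0, cue_duration=float(cue),
        fixation_duration=fixation, probe_duration=probe,
        feedback_duration=feedback, response_time=response_time,
    )


def generate_mid_schedule(
    seed: int | None = None, params: MidParams | None = None, rng=None
) -> MidSchedule:
    """Generate a full emulated MID session (2 runs x 50 trials by default).

    Cue order is a uniform random permutation of the 5 x trials_per_cue
    multiset within each run; outcomes are i.i.d. draws unless the
    staircase mode is enabled; components abut with no gaps.
    """
    params = params or MidParams()
    params.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    runs = []
    for _ in range(params.n_runs):
        cues = np.repeat(CUE_TYPES, params.trials_per_cue)
        rng.shuffle(cues)
        if params.staircase:
            durations, outcomes = simulate_staircase(
                len(cues), rng, rt_mean=params.responder_rt_mean,
                rt_sd=params.responder_rt_sd, step=params.staircase_step,
                bounds=params.probe_range,
            )
        else:
            durations = [None] * len(cues)
            outcomes = rng.choice(OUTCOMES, size=len(cues), p=params.outcome_probs)
        trials = []
        clock = 0.0
        for cue_type, outcome, probe_dur in zip(cues, outcomes, durations):
            trial = _draw_trial(rng, str(cue_type), str(outcome), params,
                                probe_duration=probe_dur)
            trials.append(replace(trial, cue_onset=clock))
            clock += (trial.cue_duration + trial.fixation_duration
                      + trial.probe_duration + trial.feedback_duration)
        runs.append(trials)
    return MidSchedule(runs=runs, params=params, seed=seed)


# ---------------------------------------------------------------------------
# Model specifications


@dataclass(frozen=True)
class ComponentSpec:
    """How one trial component enters a model."""

    component: str            # cue | fixation | probe | rt | feedback
    shape: str                # impulse | boxcar
    split_by: str             # cue_type | valence | outcome_by_cue | none
    derivative: bool = False


@dataclass(frozen=True)
class ModelSpec:
    name: str
    components: tuple[ComponentSpec, ...]

    def with_derivatives(self, flag: bool = True) -> "ModelSpec":
        return ModelSpec(
            name=self.name + ("_WITH_DERIVS" if flag else ""),
            components=tuple(replace(c, derivative=flag) for c in self.components),
        )


CUEFEEDBACK = ModelSpec(
    name="CUEFEEDBACK",
    components=(
        ComponentSpec("cue", "impulse", "cue_type", derivative=True),
        ComponentSpec("feedback", "impulse", "outcome_by_cue", derivative=True),
    ),
)

SATURATED = ModelSpec(
    name="SATURATED",
    components=(
        ComponentSpec("cue", "boxcar", "cue_type"),
        ComponentSpec("fixation", "boxcar", "cue_type"),
        ComponentSpec("probe", "boxcar", "valence"),
        ComponentSpec("rt", "boxcar", "none"),
        ComponentSpec("feedback", "boxcar", "outcome_by_cue"),
    ),
)

SATURATED_WITH_DERIVS = SATURATED.with_derivatives()

MODEL_SPECS = {
    "CUEFEEDBACK": CUEFEEDBACK,
    "SATURATED": SATURATED,
    "SATURATED_WITH_DERIVS": SATURATED_WITH_DERIVS,
}


def _component_labels(comp: ComponentSpec) -> list[str]:
    if comp.split_by == "cue_type":
        return list(CUE_TYPES)
    if comp.split_by == "valence":
        return ["Win", "Loss", "Neutral"]
    if comp.split_by == "outcome_by_cue":
        return [f"{cue}{hm}" for cue in CUE_TYPES for hm in ("Hit", "Miss")]
    if comp.split_by == "none":
        return [""]
    raise ValueError(f"unknown split rule {comp.split_by!r}")


def _trial_label(comp: ComponentSpec, trial: MidTrial) -> str:
    if comp.split_by == "cue_type":
        return trial.cue_type
    if comp.split_by == "valence":
        return _VALENCE[trial.cue_type]
    if comp.split_by == "outcome_by_cue":
        return f"{trial.cue_type}{'Miss' if is_miss(trial.outcome) else 'Hit'}"
    return ""


def _component_onset_duration(comp: ComponentSpec, trial: MidTrial):
    if comp.component == "cue":
        return trial.cue_onset, trial.cue_duration
    if comp.component == "fixation":
        return trial.fixation_onset, trial.fixation_duration
    if comp.component == "probe":
        return trial.probe_onset, trial.probe_duration
    if comp.component == "feedback":
        return trial.feedback_onset, trial.feedback_duration
    if comp.component == "rt":
        if trial.response_time is None:
            return None
        return trial.probe_onset, trial.response_time
    raise ValueError(f"unknown trial component {comp.component!r}")


def schedule_to_events(schedule: MidSchedule, spec: ModelSpec) -> dict[str, EventTable]:
    """One event table per model regressor (before HRF convolution).

    Regressor names are ``component_Label`` (e.g. ``cue_LargeWin``,
    ``probe_Win``, ``feedback_SmallLossMiss``) or plain ``rt``.  The RT
    regressor covers Probe onset through the response time and only exists
    for trials with a recorded RT.
    """
    events: dict[str, list[dict]] = {}
    for comp in spec.components:
        for label in _component_labels(comp):
            name = f"{comp.component}_{label}" if label else comp.component
            events[name] = []
    for run_idx, trial in schedule.trials():
        for comp in spec.components:
            pair = _component_onset_duration(comp, trial)
            if pair is None:
                continue
            onset, duration = pair
            label = _trial_label(comp, trial)
            name = f"{comp.component}_{label}" if label else comp.component
            events[name].append(
                {"onset": onset, "duration": duration if comp.shape == "boxcar" else 0.0,
                 "trial_type": name, "run": run_idx}
            )
    out = {}
    for name, rows in events.items():
        frame = pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "run"])
        out[name] = EventTable(frame)
    return out


def build_design(
    schedule: MidSchedule,
    spec: ModelSpec,
    oversampling: int = 50,
    drift_cutoff: float | None = None,
    intercept: bool = True,
) -> DesignMatrix:
    """Convolve a model's event tables into a concatenated-run design.

    Derivative-flagged components contribute ``<name>_derivative`` columns;
    with ``drift_cutoff`` set, per-run discrete-cosine drift blocks are
    appended as nuisance columns.
    """
    grid = schedule.grid(oversampling=oversampling)
    kernel = canonical_hrf(grid.dt_micro)
    events = schedule_to_events(schedule, spec)
    shapes = {}
    derivs = {}
    for comp in spec.components:
        for label in _component_labels(comp):
            name = f"{comp.component}_{label}" if label else comp.component
            shapes[name] = comp.shape
            derivs[name] = comp.derivative
    task: dict[str, np.ndarray] = {}
    for name, table in events.items():
        reg = make_regressor(table, grid, shape=shapes[name], kernel=kernel,
                             with_derivative=derivs[name])
        if derivs[name]:
            task[name] = reg[:, 0]
            task[f"{name}_derivative"] = reg[:, 1]
        else:
            task[name] = reg
    nuisance = per_run_drift_regressors(grid, drift_cutoff) if drift_cutoff else None
    return assemble_design(task, grid, nuisance=nuisance, intercept=intercept)


#: The seven contrasts studied in the simulation and real-data analyses.
#: Asterisked names mark contrasts distributed with ABCD data releases.
CONTRAST_DEFINITIONS: dict[str, dict[str, float]] = {
    "Cue:LW-Neut": {"cue_LargeWin": 1.0, "cue_Neutral": -1.0},
    "Cue:LL-Neut": {"cue_LargeLoss": 1.0, "cue_Neutral": -1.0},
    "Cue:LW-Base": {"cue_LargeWin": 1.0},
    "FB:WHit-WMiss": {
        "feedback_LargeWinHit": 0.5, "feedback_SmallWinHit": 0.5,
        "feedback_LargeWinMiss": -0.5, "feedback_SmallWinMiss": -0.5,
    },
    "FB:LHit-LMiss": {
        "feedback_LargeLossHit": 0.5, "feedback_SmallLossHit": 0.5,
        "feedback_LargeLossMiss": -0.5, "feedback_SmallLossMiss": -0.5,
    },
    "FB:LWHit-NeutHit": {"feedback_LargeWinHit": 1.0, "feedback_NeutralHit": -1.0},
    "FB:LWHit-Base": {"feedback_LargeWinHit": 1.0},
}

#: Contrasts of focus distributed by the ABCD consortium.
ABCD_CONTRASTS = ("Cue:LW-Neut", "Cue:LL-Neut", "FB:WHit-WMiss", "FB:LHit-LMiss")


def contrast_library(column_names: list[str]) -> dict[str, ContrastSpec]:
    """The standard contrast set aligned to a design's columns.

    Derivative, drift and intercept columns get zero weight.  Raises if a
    contrast references a column the design lacks.
    """
    out = {}
    for name, definition in CONTRAST_DEFINITIONS.items():
        weights = np.zeros(len(column_names))
        for col, w in definition.items():
            if col not in column_names:
                raise ValueError(
                    f"contrast {name!r} needs column {col!r}, absent from this design"
                )
            weights[column_names.index(col)] = w
        out[name] = ContrastSpec(name=name, weights=weights)
    return out
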