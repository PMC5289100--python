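"""Transformed up-down (2-down/1-up) staircase for 4AFC letter acuity.

The track lowers the letter size by one step (0.125 logMAR by default) after
two consecutive correct responses and raises it by one step after any
incorrect response, converging on the level where p(correct)^2 = 1/2, i.e.
p = sqrt(0.5) ~ 70.7% correct.  A run ends after a fixed number of reversals
(8 by default) and the threshold is the arithmetic mean of the last 6
reversal levels.  Four runs are averaged into a session threshold.

The staircase tracks a NOMINAL level on a continuous 0.125-step ladder; when
a viewing geometry is supplied, presentation snaps each nominal level to the
nearest ACHIEVABLE letter size on the pixel grid (clamped at the one-pixel
floor) and reversal levels are logged at the achieved values — what the
display actually showed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ViewingGeometry, logmar_to_size, size_to_logmar
from .stimulus import LETTERS

__all__ = [
    "StaircaseConfig",
    "TrialRecord",
    "StaircaseState",
    "ThresholdEstimate",
    "ConvergenceReport",
    "staircase_update",
    "estimate_threshold",
    "run_staircase",
    "average_runs",
    "convergence_probe",
    "trials_to_frame",
]


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the adaptive track.

    ``n_down`` consecutive correct responses lower the level by
    ``step_logmar``; ``n_up`` consecutive errors raise it.  The run stops at
    ``n_reversals_stop`` reversals (or the ``max_trials`` safety cap) and the
    threshold uses the last ``n_reversals_used`` reversal levels.
    """

    start_logmar: float
    step_logmar: float = 0.125
    n_down: int = 2
    n_up: int = 1
    n_reversals_stop: int = 8
    n_reversals_used: int = 6
    n_alternatives: int = 4
    max_trials: int = 200

    def __post_init__(self) -> None:
        if self.step_logmar <= 0:
            raise ValueError("step_logmar must be positive")
        if self.n_down < 1 or self.n_up < 1:
            raise ValueError("n_down and n_up must be >= 1")
        if self.n_reversals_used > self.n_reversals_stop:
            raise ValueError("n_reversals_used must not exceed n_reversals_stop")
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    presented_letter: str
    nominal_logmar: float
    level_logmar: float  # achieved (post-quantization) level actually shown
    response_letter: str
    correct: bool
    reversal: bool


@dataclass
class StaircaseState:
    """Mutable track state; advanced one response at a time by staircase_update."""

    current_level: float
    current_achieved_level: float
    consecutive_correct: int = 0
    consecutive_incorrect: int = 0
    last_change_direction: str | None = None  # "down" | "up" | None
    reversal_levels: list[float] = field(default_factory=list)  # achieved
    reversal_levels_nominal: list[float] = field(default_factory=list)
    trials: list[TrialRecord] = field(default_factory=list)
    n_responses: int = 0
    finished: bool = False
    ended_by_cap: bool = False

    @classmethod
    def new(cls, config: StaircaseConfig) -> "StaircaseState":
        return cls(
            current_level=config.start_logmar,
            current_achieved_level=config.start_logmar,
        )


@dataclass(frozen=True)
class ThresholdEstimate:
    threshold_logmar: float
    reversal_levels_used: tuple[float, ...]
    n_trials: int
    converged: bool


def staircase_update(
    state: StaircaseState, correct: bool, config: StaircaseConfig
) -> StaircaseState:
    """Advance the track by one response (in place; the state is also returned).

    Level changes only after ``n_down`` consecutive corrects (down) or
    ``n_up`` consecutive errors (up); the run counter resets after any step.
    A reversal is logged when a level change reverses the direction of the
    previous change, at the level from which the change departs (the achieved
    level if the caller set one, otherwise the nominal level).
    """
    if state.finished:
        raise RuntimeError("staircase_update called on a finished staircase")
    state.n_responses += 1

    direction: str | None = None
    if correct:
        state.consecutive_correct += 1
        state.consecutive_incorrect = 0
        if state.consecutive_correct >= config.n_down:
            direction = "down"
            state.consecutive_correct = 0
    else:
        state.consecutive_incorrect += 1
        state.consecutive_correct = 0
        if state.consecutive_incorrect >= config.n_up:
            direction = "up"
            state.consecutive_incorrect = 0

    if direction is not None:
        if state.last_change_direction is not None and direction != state.last_change_direction:
            state.reversal_levels.append(state.current_achieved_level)
            state.reversal_levels_nominal.append(state.current_level)
        state.last_change_direction = direction
        delta = -config.step_logmar if direction == "down" else config.step_logmar
        state.current_level += delta
        state.current_achieved_level = state.current_level

    if len(state.reversal_levels) >= config.n_reversals_stop:
        state.finished = True
    elif state.n_responses >= config.max_trials:
        state.finished = True
        state.ended_by_cap = True
    return state


def estimate_threshold(state: StaircaseState, config: StaircaseConfig) -> ThresholdEstimate:
    """Mean of the last ``n_reversals_used`` (achieved) reversal levels.

    With fewer reversals than requested the estimate uses all available ones
    and is flagged as not converged; so is a run ended by the trial cap.
    """
    if not state.reversal_levels:
        raise ValueError("cannot estimate a threshold from zero reversals")
    used = tuple(state.reversal_levels[-config.n_reversals_used :])
    converged = (
        state.finished
        and not state.ended_by_cap
        and len(state.reversal_levels) >= config.n_reversals_used
    )
    n_trials = len(state.trials) if state.trials else state.n_responses
    return ThresholdEstimate(float(np.mean(used)), used, n_trials, converged)


def run_staircase(
    observer,
    config: StaircaseConfig,
    geometry: ViewingGeometry | None = None,
    seed=0,
    stim_factory=None,
) -> tuple[ThresholdEstimate, StaircaseState]:
    """Run one adaptive track against a simulated observer.

    Each trial presents one of H, O, T, V drawn uniformly at random.  With a
    geometry, the nominal level is snapped to the nearest achievable letter
    size (clamped at the one-pixel floor); without one, levels are presented
    as-is.  ``stim_factory(letter, achieved_level) -> stimulus`` is called
    when given, for observers that act on rendered images.
    """
    rng = np.random.default_rng(seed)
    state = StaircaseState.new(config)
    floor = size_to_logmar(geometry.letter_side_unit_px, geometry) if geometry else None
    while not state.finished:
        nominal = state.current_level
        if geometry is not None:
            if nominal <= floor.logmar:
                achieved = floor
            else:
                achieved = logmar_to_size(nominal, geometry)
            achieved_level = achieved.logmar
        else:
            achieved, achieved_level = None, nominal
        state.current_achieved_level = achieved_level

        letter = LETTERS[rng.integers(0, len(LETTERS))]
        stimulus = stim_factory(letter, achieved or achieved_level) if stim_factory else None
        try:
            response = observer.respond(letter, achieved_level, rng, stimulus=stimulus)
        except Exception as exc:  # attach trial context before propagating
            raise RuntimeError(
                f"observer failed on trial {state.n_responses} "
                f"(letter {letter}, level {achieved_level:.4f} logMAR)"
            ) from exc
        correct = response == letter
        n_rev_before = len(state.reversal_levels)
        staircase_update(state, correct, config)
        state.trials.append(
            TrialRecord(
                trial_index=state.n_responses - 1,
                presented_letter=letter,
                nominal_logmar=nominal,
                level_logmar=achieved_level,
                response_letter=response,
                correct=correct,
                reversal=len(state.reversal_levels) > n_rev_before,
            )
        )
    if not state.reversal_levels:
        # track pinned at the display floor (or ceiling) until the trial cap:
        # the threshold is censored at the last achievable level shown
        return (
            ThresholdEstimate(state.trials[-1].level_logmar, (), len(state.trials), False),
            state,
        )
    return estimate_threshold(state, config), state


def average_runs(estimates) -> tuple[float, float]:
    """Mean and standard error over run thresholds (logMAR).

    Accepts ThresholdEstimate objects or plain numbers; SE is the sample
    s.d. (ddof=1) over sqrt(n), NaN for a single run.
    """
    values = [
        e.threshold_logmar if isinstance(e, ThresholdEstimate) else float(e)
        for e in estimates
    ]
    if not values:
        raise ValueError("average_runs requires at least one estimate")
    mean = float(np.mean(values))
    se = float(np.std(values, ddof=1) / math.sqrt(len(values))) if len(values) > 1 else float("nan")
    return mean, se


@dataclass(frozen=True)
class ConvergenceReport:
    percent_correct: float
    equilibrium_level: float
    n_trials_at_equilibrium: int
    analytic_percent: float


def convergence_probe(
    config: StaircaseConfig,
    n_trials: int = 50_000,
    observer=None,
    seed=0,
    burn_in: int = 500,
) -> ConvergenceReport:
    """Estimate the percent-correct the track equilibrates at, by long simulation.

    Runs the up-down rule (reversal stopping disabled) against a stationary
    simulated observer, discards a burn-in, and reports the observed
    percent-correct at the most-visited (equilibrium) level.  The analytic
    value for an n-down/1-up rule solves p^n = 1/2, e.g. sqrt(0.5) = 70.71%
    for 2-down/1-up.
    """
    from .observers import PsychometricObserver

    if observer is None:
        # stationary observer whose 70.7% point sits a whole number of steps
        # below the start, so the level ladder contains it exactly
        observer = PsychometricObserver(alpha_logmar=config.start_logmar - 3 * config.step_logmar)
    if config.n_up != 1:
        raise ValueError("the closed-form equilibrium is defined for 1-up rules only")
    analytic = 100.0 * 0.5 ** (1.0 / config.n_down)

    rng = np.random.default_rng(seed)
    probe_cfg = StaircaseConfig(
        start_logmar=config.start_logmar,
        step_logmar=config.step_logmar,
        n_down=config.n_down,
        n_up=config.n_up,
        n_reversals_stop=10**9,
        n_reversals_used=1,
        n_alternatives=config.n_alternatives,
        max_trials=10**9,
    )
    state = StaircaseState.new(probe_cfg)
    levels = np.empty(n_trials)
    corrects = np.empty(n_trials, dtype=bool)
    for t in range(n_trials):
        p = observer.p_correct(state.current_level)
        correct = rng.random() < p
        levels[t] = state.current_level
        corrects[t] = correct
        staircase_update(state, correct, probe_cfg)

    burn_in = min(burn_in, n_trials // 5)
    levels, corrects = levels[burn_in:], corrects[burn_in:]
    # the ladder is start - k*step; key on integer step offsets from the start
    keys = np.round((levels - config.start_logmar) / config.step_logmar).astype(int)
    uniq, counts = np.unique(keys, return_counts=True)
    eq_key = uniq[np.argmax(counts)]
    at_eq = keys == eq_key
    pc = 100.0 * float(corrects[at_eq].mean())
    eq_level = config.start_logmar + eq_key * config.step_logmar
    return ConvergenceReport(pc, float(eq_level), int(at_eq.sum()), analytic)


def trials_to_frame(states, run_ids=None) -> pd.DataFrame:
    """Long-format trial log (one row per trial) for one or more runs."""
    if isinstance(states, StaircaseState):
        states = [states]
    run_ids = run_ids if run_ids is not None else list(range(len(states)))
    rows = []
    for rid, st in zip(run_ids, states):
        for tr in st.trials:
            rows.append(
                {
                    "run_id": rid,
                    "trial_index": tr.trial_index,
                    "nominal_logmar": tr.nominal_logmar,
                    "achieved_logmar": tr.level_logmar,
                    "letter": tr.presented_letter,
                    "response": tr.response_letter,
                    "correct": tr.correct,
                    "reversal_flag": tr.reversal,
                }
            )
    return pd.DataFrame(rows)
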