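"""Simulated observers and the synthetic cohort generator.

Two observer families stand in for human participants:

* :class:`PsychometricObserver` — a parametric 4AFC observer whose
  probability of a correct response rises from the guess rate (1/4) to
  1 - lapse along a Weibull-type function of logMAR.  The function is
  anchored so that p(alpha) = sqrt(0.5) exactly: ``alpha_logmar`` IS the
  level a 2-down/1-up staircase converges to, which makes staircase
  estimates directly comparable to the generating parameter.

* :class:`TemplateObserver` — an image-domain observer that correlates the
  rendered stimulus against the four letter templates.  Its linear
  (pixel-correlation) rule reads LM letters but is blind, in expectation, to
  CM letters — the computational restatement of "same mean luminance as the
  background" — whereas its rectified-contrast rule (absolute deviation from
  mean luminance, then correlate) reads CM letters.

:func:`simulate_cohort` emulates the study design: two groups (older,
younger) of five participants, four conditions (LM/CM x monocular/binocular),
four staircase runs per condition averaged into a threshold, and an optional
neutral-density-filter scenario expressed as a threshold shift per log-unit
of attenuation (default coefficient 0: no effect of retinal illuminance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import ViewingGeometry
from .staircase import StaircaseConfig, run_staircase, average_runs
from .stimulus import LETTERS, StimulusFrame, StimulusMovie

__all__ = [
    "PsychometricObserver",
    "TemplateObserver",
    "CohortSpec",
    "STUDY_CONDITION_MEANS",
    "STUDY_CONDITION_SES",
    "GROUPS",
    "CONDITIONS",
    "p_correct",
    "respond",
    "template_respond",
    "simulate_cohort",
    "default_start_logmar",
    "default_geometries",
]

_SQRT_HALF = math.sqrt(0.5)

#: Group x stimulus-type x viewing condition mean thresholds (logMAR) used as
#: cohort defaults, and their standard errors (n = 5 per group).
STUDY_CONDITION_MEANS: dict[tuple[str, str, str], float] = {
    ("older", "LM", "monocular"): -0.12,
    ("older", "LM", "binocular"): -0.15,
    ("older", "CM", "monocular"): 0.44,
    ("older", "CM", "binocular"): 0.39,
    ("younger", "LM", "monocular"): -0.18,
    ("younger", "LM", "binocular"): -0.24,
    ("younger", "CM", "monocular"): 0.34,
    ("younger", "CM", "binocular"): 0.20,
}
STUDY_CONDITION_SES: dict[tuple[str, str, str], float] = {
    ("older", "LM", "monocular"): 0.06,
    ("older", "LM", "binocular"): 0.07,
    ("older", "CM", "monocular"): 0.02,
    ("older", "CM", "binocular"): 0.03,
    ("younger", "LM", "monocular"): 0.04,
    ("younger", "LM", "binocular"): 0.04,
    ("younger", "CM", "monocular"): 0.05,
    ("younger", "CM", "binocular"): 0.03,
}

GROUPS = ("older", "younger")
CONDITIONS = tuple(
    (stim, view) for stim in ("LM", "CM") for view in ("monocular", "binocular")
)


def default_start_logmar(stimulus_type: str) -> float:
    """Comfortably suprathreshold staircase start: 0.2 for LM, 0.8 for CM."""
    return 0.2 if stimulus_type == "LM" else 0.8


def default_geometries() -> dict[str, ViewingGeometry]:
    """Viewing distances used for the two stimulus types: 9 m LM, 4.5 m CM."""
    return {"LM": ViewingGeometry(9.0), "CM": ViewingGeometry(4.5)}


@dataclass(frozen=True)
class PsychometricObserver:
    """Parametric 4AFC observer.

    p(correct at level x) = g + (1 - g - lam) * F((x - alpha)/beta + z0)
    with F(z) = 1 - exp(-ln2 * 10^z) (a Weibull in logMAR) and z0 chosen so
    that p(alpha) = sqrt(0.5) exactly.  Larger logMAR means a larger letter,
    so p is monotone non-decreasing in the level.
    """

    alpha_logmar: float
    slope: float = 0.08
    guess_rate: float = 0.25
    lapse_rate: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_rate <= 0.05:
            raise ValueError("lapse_rate must lie in [0, 0.05]")
        if not 0.0 < self.guess_rate < _SQRT_HALF:
            raise ValueError("guess_rate must lie in (0, sqrt(0.5))")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if 1.0 - self.guess_rate - self.lapse_rate <= _SQRT_HALF - self.guess_rate:
            raise ValueError("lapse too high to reach the 70.7% point")

    def _z0(self) -> float:
        f0 = (_SQRT_HALF - self.guess_rate) / (1.0 - self.guess_rate - self.lapse_rate)
        return math.log10(-math.log1p(-f0) / math.log(2.0))

    def p_correct(self, level_logmar: float) -> float:
        z = (level_logmar - self.alpha_logmar) / self.slope + self._z0()
        z = min(z, 300.0)  # exp underflows anyway; avoid 10**z overflow
        f = 1.0 - math.exp(-math.log(2.0) * 10.0 ** z)
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * f

    def respond(self, presented_letter: str, level_logmar: float, rng, stimulus=None) -> str:
        """Correct with probability p_correct; errors uniform over the other 3."""
        if rng.random() < self.p_correct(level_logmar):
            return presented_letter
        others = [c for c in LETTERS if c != presented_letter]
        return others[rng.integers(0, len(others))]


def p_correct(observer: PsychometricObserver, level_logmar: float) -> float:
    return observer.p_correct(level_logmar)


def respond(observer, presented_letter: str, level_logmar: float, rng, stimulus=None) -> str:
    return observer.respond(presented_letter, level_logmar, rng, stimulus=stimulus)


@dataclass(frozen=True)
class TemplateObserver:
    """Image-domain template matcher over the four letter alternatives.

    decision_rule:
      * ``pixel_correlation`` — correlate the (zero-meaned) luminance image
        with each letter support; the linear pooling appropriate for LM.
      * ``rectified_contrast_correlation`` — first rectify (|luminance -
        mean|, a local-contrast map), then correlate; required for CM.

    Gaussian internal noise of s.d. ``internal_noise_sd`` (in luminance
    units per check) is added to each of the four decision variables; the
    response is the argmax, ties broken in the fixed order H < O < T < V.
    """

    decision_rule: str = "pixel_correlation"
    internal_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.decision_rule not in ("pixel_correlation", "rectified_contrast_correlation"):
            raise ValueError(f"unknown decision_rule {self.decision_rule!r}")
        if self.internal_noise_sd < 0:
            raise ValueError("internal_noise_sd must be >= 0")

    def _feature_map(self, frame: StimulusFrame) -> np.ndarray:
        x = frame.check_image
        if self.decision_rule == "rectified_contrast_correlation":
            x = np.abs(x - frame.spec.mean_luminance)
        return x

    def decide(self, stimulus, rng=None) -> str:
        from .stimulus import make_letter_template, _support_maps

        frames = stimulus.frames if isinstance(stimulus, StimulusMovie) else (stimulus,)
        ref = frames[0]
        feat = np.mean([self._feature_map(f) for f in frames], axis=0)
        feat = feat - feat.mean()
        scores = np.empty(len(LETTERS))
        for i, letter in enumerate(LETTERS):
            tmpl = make_letter_template(letter, ref.template.checks_per_stroke)
            if tmpl.check_grid.shape[0] > ref.check_image.shape[0]:
                raise ValueError(
                    f"template {tmpl.check_grid.shape} exceeds stimulus "
                    f"{ref.check_image.shape} (in checks)"
                )
            support, _ = _support_maps(tmpl, ref.noise, ref.spec.bipolar_modulation)
            t = support - support.mean()
            scores[i] = float((feat * t).sum())
        if self.internal_noise_sd > 0:
            if rng is None:
                raise ValueError("internal noise requires an rng")
            scores = scores + self.internal_noise_sd * rng.standard_normal(len(scores))
        return LETTERS[int(np.argmax(scores))]

    def respond(self, presented_letter: str, level_logmar: float, rng, stimulus=None) -> str:
        if stimulus is None:
            raise ValueError("TemplateObserver needs a rendered stimulus (stim_factory)")
        return self.decide(stimulus, rng)


def template_respond(observer: TemplateObserver, stimulus, rng=None) -> str:
    """Response of an image-domain observer to a rendered frame or movie."""
    return observer.decide(stimulus, rng)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort mirroring the study.

    Per-cell true thresholds are drawn Normal(condition mean, between-subject
    s.d.); each of ``n_runs`` staircase runs adds run-level jitter of s.d.
    ``run_sd`` to the observer's 70.7% point.  Between-subject s.d. defaults
    to SE*sqrt(5) per cell, reconstructed from the group standard errors.
    The neutral-density scenario shifts every true threshold by
    ``nd_coefficient * log10(1/nd_transmission)`` logMAR (default 0: acuity
    independent of retinal illuminance over this range).
    """

    groups: tuple[str, ...] = GROUPS
    n_per_group: int = 5
    n_runs: int = 4
    condition_means: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(STUDY_CONDITION_MEANS)
    )
    between_subject_sd: Mapping[tuple[str, str, str], float] | float | None = None
    run_sd: float = 0.05
    nd_transmission: float = 1.0
    nd_coefficient: float = 0.0
    slope: float = 0.08
    lapse_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.run_sd < 0:
            raise ValueError("run_sd must be >= 0")
        if not 0.0 < self.nd_transmission <= 1.0:
            raise ValueError("nd_transmission must lie in (0, 1]")

    def cell_sd(self, cell: tuple[str, str, str]) -> float:
        if self.between_subject_sd is None:
            return STUDY_CONDITION_SES[cell] * math.sqrt(5.0)
        if isinstance(self.between_subject_sd, Mapping):
            return float(self.between_subject_sd[cell])
        return float(self.between_subject_sd)


def simulate_cohort(
    cohort_spec: CohortSpec,
    staircase_config: StaircaseConfig | None = None,
    geometry_by_type: Mapping[str, ViewingGeometry] | None = None,
    seed=0,
    return_states: bool = False,
    session: int = 0,
):
    """Simulate the full cohort: every participant x condition threshold.

    For each participant and condition a true threshold is drawn around the
    group mean, a psychometric observer is built, ``n_runs`` staircases are
    run (with per-run threshold jitter) and averaged.  Levels are presented
    on the continuous logMAR ladder unless ``geometry_by_type`` supplies
    display geometries, in which case presentation is pixel-quantized.

    All randomness derives from ``seed`` via per-(participant, condition,
    run) spawn keys, so the result is bit-reproducible and independent of
    iteration order.  ``session`` re-keys only the run-level randomness:
    simulating the same (seed, cohort) at a different session re-tests the
    SAME participants (identical true thresholds) with fresh staircases, as
    in a filter re-test.  Returns a DataFrame with one row per participant x
    condition (plus the per-run staircase states when ``return_states``).
    """
    rows = []
    states: dict[tuple, list] = {}
    nd_shift = cohort_spec.nd_coefficient * math.log10(1.0 / cohort_spec.nd_transmission)
    for gi, group in enumerate(cohort_spec.groups):
        for pi in range(cohort_spec.n_per_group):
            pid = f"{group}-{pi + 1}"
            for ci, (stim, view) in enumerate(CONDITIONS):
                cell = (group, stim, view)
                if cell not in cohort_spec.condition_means:
                    raise KeyError(f"no condition mean for cell {cell}")
                mean = cohort_spec.condition_means[cell]
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(gi, pi, ci))
                )
                true_threshold = mean + rng.normal(0.0, cohort_spec.cell_sd(cell)) + nd_shift
                if staircase_config is None:
                    cfg = StaircaseConfig(start_logmar=default_start_logmar(stim))
                else:
                    cfg = staircase_config
                geometry = geometry_by_type.get(stim) if geometry_by_type else None
                estimates = []
                for run in range(cohort_spec.n_runs):
                    run_rng = np.random.default_rng(
                        np.random.SeedSequence(seed, spawn_key=(gi, pi, ci, run, session))
                    )
                    alpha = true_threshold + run_rng.normal(0.0, cohort_spec.run_sd)
                    obs = PsychometricObserver(
                        alpha_logmar=alpha,
                        slope=cohort_spec.slope,
                        lapse_rate=cohort_spec.lapse_rate,
                    )
                    est, st = run_staircase(obs, cfg, geometry=geometry, seed=run_rng)
                    estimates.append(est)
                    if return_states:
                        states.setdefault((pid, stim, view), []).append(st)
                mean_thr, _ = average_runs(estimates)
                rows.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "stimulus_type": stim,
                        "viewing": view,
                        "nd_filter": cohort_spec.nd_transmission < 1.0,
                        "true_threshold_logmar": true_threshold,
                        "threshold_logmar": mean_thr,
                        "n_runs": cohort_spec.n_runs,
                    }
                )
    result = pd.DataFrame(rows)
    return (result, states) if return_states else result


def simulate_nd_control(
    cohort_spec: CohortSpec | None = None,
    seed=0,
    n_participants: int = 3,
    nd_transmission: float = 0.19,
    geometry_by_type: Mapping[str, ViewingGeometry] | None = None,
) -> pd.DataFrame:
    """Neutral-density re-test: the same younger participants with and without filter.

    Simulates ``n_participants`` younger observers twice — once unfiltered,
    once through an ND filter of the given transmission (19% by default,
    emulating the reduced retinal illuminance of the ageing eye).  True
    thresholds are identical across sessions (same participants); staircase
    randomness is fresh.  Returns the stacked paired DataFrame.
    """
    from dataclasses import replace

    base = cohort_spec if cohort_spec is not None else CohortSpec()
    base = replace(base, groups=("younger",), n_per_group=n_participants, nd_transmission=1.0)
    with_nd = replace(base, nd_transmission=nd_transmission)
    df0 = simulate_cohort(base, geometry_by_type=geometry_by_type, seed=seed, session=0)
    df1 = simulate_cohort(with_nd, geometry_by_type=geometry_by_type, seed=seed, session=1)
    return pd.concat([df0, df1], ignore_index=True)
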