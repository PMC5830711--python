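"""Balanced session plans and simulated visual-search trials.

Each session is 10 training trials followed by 120 test trials: the six
weather x pattern cells (cloudy/sunny x no_CS/cloudy_CS/sunny_CS) appear 20
times each, and within every cell the distractor count splits 10/10 between
20 and 40. Trial order is randomized.

The simulator mirrors the generative structure the analysis assumes:

* correctness ~ Bernoulli(expit(logit-baseline + cell effect + session
  effect + participant intercept)),
* reaction time ~ Gamma(shape, mean = exp(log-baseline + cell effect +
  session effect + participant intercept)),

with independent Normal participant intercepts on each linear-predictor
scale. Cell effects are specified per weather x pattern cell because the
phenomenon of interest is an interaction: the pattern matched to the
current weather is cryptic in *both* weathers. The default effect sizes
place the matched-CS cells at a 3x reaction-time slowdown and at half the
detection probability of the uniform target, with a mild benefit for the
sun-optimized pattern under a cloudy sky and essentially none for the
cloud-optimized pattern under sun.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WEATHERS",
    "PATTERNS",
    "Trial",
    "SessionPlan",
    "ObserverParams",
    "TrialRecord",
    "build_session_plan",
    "simulate_trials",
    "simulate_experiment",
    "write_trial_table",
    "records_to_frame",
]

WEATHERS = ("cloudy", "sunny")
PATTERNS = ("no_CS", "cloudy_CS", "sunny_CS")
DISTRACTOR_COUNTS = (20, 40)

N_TRAINING = 10
N_TEST = 120
TRIALS_PER_CELL = 20

TRIAL_COLUMNS = [
    "participant",
    "session",
    "weather",
    "pattern",
    "n_distractors",
    "correct",
    "rt_s",
]


@dataclass(frozen=True)
class Trial:
    weather: str
    pattern: str
    n_distractors: int
    scene_seed: int
    phase: str  # "training" | "test"


@dataclass
class SessionPlan:
    trials: list[Trial]

    def __post_init__(self) -> None:
        test = self.test_trials
        if len([t for t in self.trials if t.phase == "training"]) != N_TRAINING:
            raise ValueError(f"plan must contain {N_TRAINING} training trials")
        if len(test) != N_TEST:
            raise ValueError(f"plan must contain {N_TEST} test trials")
        if any(t.phase == "test" for t in self.trials[:N_TRAINING]):
            raise ValueError("training trials must precede test trials")
        for w in WEATHERS:
            for p in PATTERNS:
                cell = [t for t in test if t.weather == w and t.pattern == p]
                if len(cell) != TRIALS_PER_CELL:
                    raise ValueError(f"cell {w}/{p} must have {TRIALS_PER_CELL}")
                for nd in DISTRACTOR_COUNTS:
                    if sum(t.n_distractors == nd for t in cell) != (
                        TRIALS_PER_CELL // 2
                    ):
                        raise ValueError("distractor counts must split 10/10")

    @property
    def test_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.phase == "test"]


def build_session_plan(rng: np.random.Generator) -> SessionPlan:
    """Randomized balanced session: 10 training then 120 test trials."""
    test = [
        Trial(w, p, nd, int(rng.integers(2**31)), "test")
        for w in WEATHERS
        for p in PATTERNS
        for nd in DISTRACTOR_COUNTS
        for _ in range(TRIALS_PER_CELL // 2)
    ]
    order = rng.permutation(len(test))
    test = [test[i] for i in order]
    training = [
        Trial(
            WEATHERS[int(rng.integers(2))],
            PATTERNS[int(rng.integers(3))],
            DISTRACTOR_COUNTS[int(rng.integers(2))],
            int(rng.integers(2**31)),
            "training",
        )
        for _ in range(N_TRAINING)
    ]
    return SessionPlan(training + test)


def _default_accuracy_effects() -> dict:
    # cell probabilities (at session 1, average participant):
    # uniform target ~0.92 correct; matched CS at half that; the sunny
    # pattern under cloud mildly cryptic; the cloudy pattern under sun not.
    from scipy.special import logit

    base = logit(0.92)
    return {
        ("cloudy", "no_CS"): 0.0,
        ("cloudy", "cloudy_CS"): float(logit(0.46) - base),
        ("cloudy", "sunny_CS"): float(logit(0.85) - base),
        ("sunny", "no_CS"): 0.0,
        ("sunny", "sunny_CS"): float(logit(0.46) - base),
        ("sunny", "cloudy_CS"): 0.0,
    }


def _default_rt_effects() -> dict:
    # log-scale multipliers: matched CS trebles the search time; the sunny
    # pattern under cloud slows search slightly.
    return {
        ("cloudy", "no_CS"): 0.0,
        ("cloudy", "cloudy_CS"): float(np.log(3.0)),
        ("cloudy", "sunny_CS"): float(np.log(1.15)),
        ("sunny", "no_CS"): 0.0,
        ("sunny", "sunny_CS"): float(np.log(3.0)),
        ("sunny", "cloudy_CS"): 0.0,
    }


@dataclass
class ObserverParams:
    """Generative parameters of the synthetic observer population."""

    accuracy_baseline_logit: float = 2.44234563  # expit -> 0.92
    accuracy_cell_effects: dict = field(default_factory=_default_accuracy_effects)
    accuracy_session_effect: float = 0.15  # logit shift in session 2
    accuracy_intercept_sd: float = 0.3

    rt_baseline_log_mean: float = float(np.log(1.2))  # log seconds
    rt_cell_effects: dict = field(default_factory=_default_rt_effects)
    rt_session_effect: float = -0.10  # session 2 is faster
    rt_intercept_sd: float = 0.15
    rt_gamma_shape: float = 4.0

    n_participants: int = 9
    n_sessions: int = 2

    def __post_init__(self) -> None:
        if self.rt_gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.accuracy_intercept_sd < 0 or self.rt_intercept_sd < 0:
            raise ValueError("random-intercept SDs must be >= 0")


@dataclass(frozen=True)
class TrialRecord:
    participant: int
    session: int
    weather: str
    pattern: str
    n_distractors: int
    correct: int
    rt_s: float

    def __post_init__(self) -> None:
        if self.rt_s <= 0:
            raise ValueError("reaction time must be positive")
        if self.weather not in WEATHERS or self.pattern not in PATTERNS:
            raise ValueError("unknown weather/pattern level")
        if self.correct not in (0, 1):
            raise ValueError("correct must be 0 or 1")


def simulate_trials(
    plans: dict,
    params: ObserverParams,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    """Simulate test-trial records for ``plans[(participant, session)]``.

    Participant intercepts are drawn once per participant (shared across
    sessions); trials are conditionally independent given the intercepts.
    Training trials generate no records, as in the experimental procedure.
    """
    from scipy.special import expit

    participants = sorted({p for p, _ in plans})
    acc_u = {
        p: rng.normal(0.0, params.accuracy_intercept_sd) for p in participants
    }
    rt_u = {p: rng.normal(0.0, params.rt_intercept_sd) for p in participants}

    records: list[TrialRecord] = []
    for (pid, session), plan in sorted(plans.items()):
        for trial in plan.test_trials:
            cell = (trial.weather, trial.pattern)
            sess2 = 1.0 if session == 2 else 0.0
            eta_acc = (
                params.accuracy_baseline_logit
                + params.accuracy_cell_effects[cell]
                + params.accuracy_session_effect * sess2
                + acc_u[pid]
            )
            eta_rt = (
                params.rt_baseline_log_mean
                + params.rt_cell_effects[cell]
                + params.rt_session_effect * sess2
                + rt_u[pid]
            )
            mean_rt = float(np.exp(eta_rt))
            records.append(
                TrialRecord(
                    participant=pid,
                    session=session,
                    weather=trial.weather,
                    pattern=trial.pattern,
                    n_distractors=trial.n_distractors,
                    correct=int(rng.random() < expit(eta_acc)),
                    rt_s=float(
                        rng.gamma(
                            params.rt_gamma_shape,
                            mean_rt / params.rt_gamma_shape,
                        )
                    ),
                )
            )
    return records


def simulate_experiment(
    params: ObserverParams | None = None,
    seed: int | np.random.Generator = 0,
) -> list[TrialRecord]:
    """Full default experiment: every participant runs ``n_sessions``
    balanced sessions."""
    params = params or ObserverParams()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    plans = {
        (pid, sess): build_session_plan(rng)
        for pid in range(1, params.n_participants + 1)
        for sess in range(1, params.n_sessions + 1)
    }
    return simulate_trials(plans, params, rng)


def records_to_frame(records) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("no trial records")
    return pd.DataFrame([r.__dict__ for r in records], columns=TRIAL_COLUMNS)


def write_trial_table(records, path_or_buffer) -> None:
    """Tab-delimited trial table with header; round-trips through
    ``glmm_analysis.read_trial_data``."""
    frame = records_to_frame(records)
    # %.17g preserves every float64 exactly across the write/read cycle
    frame.to_csv(path_or_buffer, sep="\t", index=False, float_format="%.17g")
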