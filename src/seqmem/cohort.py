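"""Synthetic cohorts emulating the further-training phase of the experiment.

The emulated design: for each array size (4, 6, 8 items, i.e. 2, 3, 4 pairs)
the participant first receives five unreinforced test trials (always run to
completion), then error-corrected training trials (20 at 4 items, 40 at 6 and
8 items) that end at the first incorrect touch.  The learning-curve clock
(``gompertz_t``) counts training trials cumulatively across array sizes.

Ground-truth parameters and architectures are recorded per participant so the
fitting stage can be validated by parameter- and model-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .grammar import CENTER_EMBEDDED, GrammarSpec
from .model import ModelParams, TrialRecord, simulate_trial

DEFAULT_LENGTHS = (2, 3, 4)
DEFAULT_TEST_TRIALS = 5
DEFAULT_TRAINING_TRIALS = {2: 20, 3: 40, 4: 40}

#: Parameter ranges used for recovery studies: uniform draws wide enough to
#: span the realistic accuracy/RT regime of the task without degenerate fits.
DEFAULT_RECOVERY_RANGES: dict[str, tuple[float, float]] = {
    "p_mem": (0.02, 0.15),
    "p_lapse": (0.0, 0.1),
    "gompertz_a": (0.6, 1.0),
    "gompertz_b": (0.5, 5.0),
    "gompertz_c": (0.05, 0.5),
    "t_base": (200.0, 600.0),
    "t_op": (50.0, 300.0),
    "sigma_rt": (0.1, 0.4),
}


@dataclass(frozen=True)
class ExperimentDesign:
    """Trial-count structure of the further-training phase."""

    condition: str = CENTER_EMBEDDED
    lengths: tuple[int, ...] = DEFAULT_LENGTHS
    test_trials_per_length: int = DEFAULT_TEST_TRIALS
    training_trials_per_length: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_TRAINING_TRIALS)
    )

    def __post_init__(self) -> None:
        if self.test_trials_per_length <= 0:
            raise ValueError("test_trials_per_length must be > 0")
        for n in self.lengths:
            if self.training_trials_per_length.get(n, 0) <= 0:
                raise ValueError(f"missing/invalid training count for length {n}")


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic cohort: size, architecture, and parameter distributions.

    ``param_dists`` maps each ModelParams field to either a fixed value or a
    (low, high) uniform range; unspecified fields use DEFAULT_RECOVERY_RANGES.
    """

    n_participants: int = 50
    architecture: str = "queue"
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    param_dists: dict[str, object] = field(default_factory=dict)
    seed: int = 0


def draw_params(spec_dists: dict[str, object], rng: np.random.Generator) -> ModelParams:
    """Draw one participant's true parameters from the cohort distributions."""
    values = {}
    for f in fields(ModelParams):
        dist = spec_dists.get(f.name, DEFAULT_RECOVERY_RANGES[f.name])
        if isinstance(dist, (tuple, list)):
            lo, hi = dist
            values[f.name] = float(rng.uniform(lo, hi))
        else:
            values[f.name] = float(dist)
    return ModelParams(**values)


def simulate_participant(
    params: ModelParams,
    design: ExperimentDesign,
    architecture: str,
    rng: np.random.Generator,
    participant_id: str | None = None,
) -> list[TrialRecord]:
    """All trials for one participant, in presentation order.

    Test trials run to completion and do not advance the learning-curve
    clock; training trials are truncated at the first error and advance it.
    """
    trials: list[TrialRecord] = []
    t_clock = 0  # cumulative training trials completed so far
    for n in design.lengths:
        grammar = GrammarSpec(design.condition, n)
        for i in range(1, design.test_trials_per_length + 1):
            tr = simulate_trial(grammar, architecture, params, t_clock, feedback=False, rng=rng)
            tr.trial_index = i
            tr.participant_id = participant_id
            trials.append(tr)
        for i in range(1, design.training_trials_per_length[n] + 1):
            tr = simulate_trial(grammar, architecture, params, t_clock, feedback=True, rng=rng)
            tr.trial_index = i
            tr.participant_id = participant_id
            trials.append(tr)
            t_clock += 1
    return trials


def trials_to_table(trials: list[TrialRecord]) -> pd.DataFrame:
    """Long-format trial log: one row per touch."""
    rows = []
    for tr in trials:
        for k, (touch, rt) in enumerate(zip(tr.touches, tr.rts), start=1):
            rows.append(
                {
                    "participant_id": tr.participant_id,
                    "condition": tr.condition,
                    "n_pairs": tr.n_pairs,
                    "phase": "training" if tr.feedback else "test",
                    "trial_index": tr.trial_index,
                    "touch_index": k,
                    "pair_id": touch.pair_id,
                    "item_class": touch.item_class,
                    "rt_ms": rt,
                    "complete": tr.complete,
                    "first_error_index": tr.first_error_index,
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (trial log table, ground-truth table)."""
    rng = np.random.default_rng(spec.seed)
    all_trials: list[TrialRecord] = []
    truth_rows = []
    for p in range(spec.n_participants):
        pid = f"P{p + 1:03d}"
        params = draw_params(spec.param_dists, rng)
        all_trials.extend(
            simulate_participant(params, spec.design, spec.architecture, rng, participant_id=pid)
        )
        row = {"participant_id": pid, "architecture": spec.architecture}
        row.update({f.name: getattr(params, f.name) for f in fields(ModelParams)})
        truth_rows.append(row)
    return trials_to_table(all_trials), pd.DataFrame(truth_rows)
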