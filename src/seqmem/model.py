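"""Trial-level generative model of indexed AnBn sequence production.

On each trial the participant runs one of three latent programs:

* **correct** — picks an arbitrary order for the A (blue) items, stores them
  in the working-memory buffer (stack or queue), then retrieves the B (red)
  items through the architecture; each store may corrupt the buffer, which is
  how memory errors arise.  The probability of running the correct program
  grows over training following a Gompertz curve A·exp(-B·exp(-C·t)).
* **blue_then_red** — the wrong-but-partial program: all A items in a random
  order, then all B items in a random order, with no pair matching and no
  buffer engagement (one op per touch).
* **lapse** — inattention: every touch is uniform over all displayed items
  (items stay selectable after being touched, so repeats are possible).

Response times scale with the per-touch operation count:
rt = (t_base + t_op * ops) * exp(eps), eps ~ Normal(0, sigma_rt^2), so the RT
is lognormal with median t_base + t_op * ops.

On feedback (training) trials the trial ends at the first incorrect touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .architectures import MemoryBuffer, retrieve_next, store
from .grammar import A, B, GrammarSpec, ItemToken, next_correct_items

PROGRAM_CORRECT = "correct"
PROGRAM_BLUE_THEN_RED = "blue_then_red"
PROGRAM_LAPSE = "lapse"
PROGRAMS = (PROGRAM_CORRECT, PROGRAM_BLUE_THEN_RED, PROGRAM_LAPSE)


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the generative model (same count for stack and queue).

    p_mem       probability each store corrupts the buffer (0-1)
    p_lapse     probability a trial is random responding (0-1)
    gompertz_a  asymptotic P(correct program) (0-1)
    gompertz_b  displacement of the learning curve (>= 0)
    gompertz_c  learning rate (>= 0)
    t_base      base latency per touch, ms (> 0)
    t_op        latency per memory operation, ms (>= 0)
    sigma_rt    log-space RT noise sd (> 0)
    """

    p_mem: float = 0.05
    p_lapse: float = 0.02
    gompertz_a: float = 0.9
    gompertz_b: float = 2.0
    gompertz_c: float = 0.1
    t_base: float = 400.0
    t_op: float = 150.0
    sigma_rt: float = 0.25

    def __post_init__(self) -> None:
        for name in ("p_mem", "p_lapse", "gompertz_a"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("gompertz_b", "gompertz_c", "t_op"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.t_base <= 0:
            raise ValueError("t_base must be > 0")
        if self.sigma_rt <= 0:
            raise ValueError("sigma_rt must be > 0")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class TrialRecord:
    """One produced sequence with touches, RTs and latent labels.

    ``trial_index`` is the 1-based index within phase and length;
    ``gompertz_t`` is the cumulative further-training trial count across
    lengths at which this trial occurred (the learning-curve clock).  On
    feedback trials the touches end at ``first_error_index`` (1-based,
    inclusive of the error touch).
    """

    condition: str
    n_pairs: int
    trial_index: int
    feedback: bool
    touches: list[ItemToken]
    rts: list[float]
    first_error_index: int | None
    complete: bool
    latent_program: str | None = None
    gompertz_t: float = 0.0
    participant_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.touches) != len(self.rts):
            raise ValueError("touches and rts must have equal length")
        if self.feedback and self.first_error_index is not None:
            if len(self.touches) != self.first_error_index:
                raise ValueError("feedback trial must end at its first error")


def gompertz_p_correct(trial_index: float, a: float, b: float, c: float) -> float:
    """A * exp(-B * exp(-C * t)): P(correct program) after t training trials."""
    return a * np.exp(-b * np.exp(-c * trial_index))


def sample_program(trial_index: float, params: ModelParams, rng: np.random.Generator) -> str:
    """Draw the latent program: lapse first, then correct vs blue-then-red."""
    if rng.random() < params.p_lapse:
        return PROGRAM_LAPSE
    g = gompertz_p_correct(trial_index, params.gompertz_a, params.gompertz_b, params.gompertz_c)
    return PROGRAM_CORRECT if rng.random() < g else PROGRAM_BLUE_THEN_RED


def rt_for_touch(ops: int, params: ModelParams, rng: np.random.Generator) -> float:
    """Lognormal latency with median t_base + t_op * ops."""
    if ops < 1:
        raise ValueError("ops must be >= 1")
    scale = params.t_base + params.t_op * ops
    return float(scale * np.exp(rng.normal(0.0, params.sigma_rt)))


def program_weights(trial_index: float, params: ModelParams) -> dict[str, float]:
    """Prior trial-level mixture over the three programs."""
    g = gompertz_p_correct(trial_index, params.gompertz_a, params.gompertz_b, params.gompertz_c)
    return {
        PROGRAM_LAPSE: params.p_lapse,
        PROGRAM_CORRECT: (1.0 - params.p_lapse) * g,
        PROGRAM_BLUE_THEN_RED: (1.0 - params.p_lapse) * (1.0 - g),
    }


def _generate_touches(
    grammar: GrammarSpec,
    architecture: str,
    params: ModelParams,
    program: str,
    rng: np.random.Generator,
    a_order: list[int] | None,
) -> tuple[list[ItemToken], list[int]]:
    """Full 2n touch sequence and per-touch op counts for one latent program."""
    n = grammar.n_pairs
    if program == PROGRAM_LAPSE:
        items = grammar.items
        touches = [items[rng.integers(2 * n)] for _ in range(2 * n)]
        return touches, [1] * (2 * n)

    order = list(a_order) if a_order is not None else list(rng.permutation(np.arange(1, n + 1)))
    if program == PROGRAM_BLUE_THEN_RED:
        b_order = list(rng.permutation(np.arange(1, n + 1)))
        touches = [A(i) for i in order] + [B(int(i)) for i in b_order]
        return touches, [1] * (2 * n)

    # correct program: store the A's, retrieve the B's through the buffer
    buf = MemoryBuffer(architecture)
    touches = []
    ops_list = []
    for pid in order:
        store(buf, int(pid), params.p_mem, rng)
        touches.append(A(int(pid)))
        ops_list.append(1)
    emitted: list[int] = []
    for step in range(1, n + 1):
        untouched = [i for i in range(1, n + 1) if i not in emitted]
        pid, ops = retrieve_next(buf, grammar.condition, step, untouched=untouched, rng=rng)
        emitted.append(pid)
        touches.append(B(pid))
        ops_list.append(ops)
    return touches, ops_list


def simulate_trial(
    grammar: GrammarSpec,
    architecture: str,
    params: ModelParams,
    trial_index: float,
    feedback: bool,
    rng: np.random.Generator,
    a_order: list[int] | None = None,
    program: str | None = None,
) -> TrialRecord:
    """Simulate one trial; feedback trials are truncated at the first error.

    ``trial_index`` is the learning-curve clock (cumulative training trials so
    far).  ``a_order`` forces the correct program's blue order (tests);
    ``program`` forces the latent program.
    """
    if program is None:
        program = sample_program(trial_index, params, rng)
    touches, ops_list = _generate_touches(grammar, architecture, params, program, rng, a_order)
    rts = [rt_for_touch(o, params, rng) for o in ops_list]

    first_error = None
    prefix: list[ItemToken] = []
    for k, t in enumerate(touches, start=1):
        if t not in next_correct_items(prefix, grammar):
            first_error = k
            break
        prefix.append(t)

    complete = True
    if feedback and first_error is not None:
        touches = touches[:first_error]
        rts = rts[:first_error]
        complete = False
    return TrialRecord(
        condition=grammar.condition,
        n_pairs=grammar.n_pairs,
        trial_index=0,
        feedback=feedback,
        touches=touches,
        rts=rts,
        first_error_index=first_error,
        complete=complete,
        latent_program=program,
        gompertz_t=float(trial_index),
    )
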