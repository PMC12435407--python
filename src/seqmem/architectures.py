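"""Stack and queue memory buffers, their op-count schedules, and storage noise.

Producing an indexed AnBn sequence compiles into per-touch store/traverse/pop
operations whose count depends on the memory architecture and the grammar:

* stack + center-embedded: each B is one pop off the top (last-in first-out);
* stack + cross-serial: the stack must first be reversed onto a second stack
  (one op per transferred item) before the first B, then one pop each;
* queue + cross-serial: each B is read off the front (first-in first-out);
* queue + center-embedded: the k-th-from-last item is found by iteratively
  traversing from the front, so op counts decrease n, n-1, ..., 1 — the
  downward-sloping response-time signature that discriminates the
  architectures.

Each store may corrupt the buffer (swap of the two most recent items, or
deletion of a uniformly chosen item), which is the model's memory-error
mechanism: a corrupted buffer yields wrong items at retrieval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STACK = "stack"
QUEUE = "queue"
ARCHITECTURES = (STACK, QUEUE)

from .grammar import CENTER_EMBEDDED, CROSS_SERIAL, GrammarSpec  # noqa: E402


@dataclass
class OpSchedule:
    """Per-touch memory-operation counts for one architecture x grammar."""

    first_half_ops: list[int]
    second_half_ops: list[int]

    def __post_init__(self) -> None:
        if any(o < 1 for o in self.first_half_ops + self.second_half_ops):
            raise ValueError("all op counts must be >= 1")


@dataclass
class MemoryBuffer:
    """An ordered store of pair_ids; index 0 is the first-stored item.

    For a stack the accessible end is the back (top); for a queue it is the
    front.  ``reversed_for_cs`` flags that a stack has already been dumped
    onto its auxiliary stack for cross-serial production, after which the
    first-stored item sits on top.
    """

    architecture: str
    contents: list[int] = field(default_factory=list)
    reversed_for_cs: bool = False

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")

    def __len__(self) -> int:
        return len(self.contents)


def store(buffer: MemoryBuffer, pair_id: int, p_mem: float, rng: np.random.Generator) -> MemoryBuffer:
    """Append ``pair_id``; then with probability ``p_mem`` corrupt the buffer.

    Corruption kind is equiprobable: a *swap* transposes the just-stored item
    with its immediate predecessor (a no-op on a length-1 buffer); a
    *deletion* removes one uniformly chosen stored item.  Mutates and returns
    ``buffer``.
    """
    if not 0.0 <= p_mem <= 1.0:
        raise ValueError("p_mem must be a probability")
    buffer.contents.append(pair_id)
    if p_mem > 0 and rng.random() < p_mem:
        c = buffer.contents
        if rng.random() < 0.5:  # swap
            if len(c) >= 2:
                c[-1], c[-2] = c[-2], c[-1]
        else:  # deletion
            del c[rng.integers(len(c))]
    return buffer


def retrieve_schedule(architecture: str, condition: str, n_pairs: int) -> OpSchedule:
    """The noiseless op-count schedule for one architecture x condition x n.

    First half: one store per A touch for every architecture.  Second half:
    see module docstring.
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    n = n_pairs
    if n < 1:
        raise ValueError("n_pairs must be >= 1")
    first = [1] * n
    if architecture == QUEUE and condition == CROSS_SERIAL:
        second = [1] * n
    elif architecture == QUEUE and condition == CENTER_EMBEDDED:
        second = list(range(n, 0, -1))
    elif architecture == STACK and condition == CENTER_EMBEDDED:
        second = [1] * n
    elif architecture == STACK and condition == CROSS_SERIAL:
        second = [n + 1] + [1] * (n - 1)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return OpSchedule(first, second)


def retrieve_next(
    buffer: MemoryBuffer,
    condition: str,
    step: int,
    untouched: list[int] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[int, int]:
    """Yield the next pair_id for second-half ``step`` (1-based) and its op count.

    The returned item reflects the *current* (possibly corrupted) buffer, so
    it may be grammatically wrong — that is the error mechanism.  If deletions
    have exhausted the buffer, falls back to a uniform choice among
    ``untouched`` items (one op), which must then be provided along with
    ``rng``.
    """
    c = buffer.contents
    if not c:
        if not untouched:
            raise ValueError("buffer exhausted and no untouched items to fall back on")
        if rng is None:
            raise ValueError("rng required for exhausted-buffer fallback")
        return int(untouched[rng.integers(len(untouched))]), 1

    if buffer.architecture == QUEUE:
        if condition == CROSS_SERIAL:
            return c.pop(0), 1  # read the front, advance
        # CE: iteratively traverse from the front to the last-stored item
        ops = len(c)
        return c.pop(), ops
    # stack
    if condition == CENTER_EMBEDDED:
        return c.pop(), 1  # top of stack
    # CS: reverse onto the auxiliary stack once, at the first B touch
    if not buffer.reversed_for_cs:
        moved = len(c)
        c.reverse()
        buffer.reversed_for_cs = True
        return c.pop(), moved + 1
    return c.pop(), 1
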