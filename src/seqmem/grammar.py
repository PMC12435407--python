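"""Indexed AnBn grammars: validation, enumeration, and analytic accuracy baselines.

An indexed AnBn sequence is built from n item pairs (A_i, B_i).  All A items
(the "blue" first half) precede all B items (the "red" second half).  The A
items may be produced in any order; the grammar then fixes the B order:

* center-embedded (CE): the B items reverse the A order, A1 A2 A3 B3 B2 B1,
  as in nested brackets (context-free);
* cross-serial (CS): the B items repeat the A order, A1 A2 A3 B1 B2 B3
  (context-sensitive).

Because any A order is acceptable, a complete array of n pairs admits exactly
n! grammatical orderings under either grammar.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

CENTER_EMBEDDED = "center_embedded"
CROSS_SERIAL = "cross_serial"
CONDITIONS = (CENTER_EMBEDDED, CROSS_SERIAL)

_MAX_PAIRS = 6


class ItemToken(NamedTuple):
    """One touchable item: pair identity (1-based) and class A (blue) or B (red)."""

    pair_id: int
    item_class: str  # "A" or "B"

    def __repr__(self) -> str:  # compact: A1, B3
        return f"{self.item_class}{self.pair_id}"


def A(pair_id: int) -> ItemToken:
    return ItemToken(pair_id, "A")


def B(pair_id: int) -> ItemToken:
    return ItemToken(pair_id, "B")


@dataclass(frozen=True)
class GrammarSpec:
    """A condition (center_embedded | cross_serial) with a number of pairs."""

    condition: str
    n_pairs: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 1 <= self.n_pairs <= _MAX_PAIRS:
            raise ValueError(f"n_pairs must be in 1..{_MAX_PAIRS}, got {self.n_pairs}")

    @property
    def items(self) -> list[ItemToken]:
        """All 2n displayed items, A1..An then B1..Bn."""
        n = self.n_pairs
        return [A(i) for i in range(1, n + 1)] + [B(i) for i in range(1, n + 1)]

    def b_order_for(self, a_order: Iterable[int]) -> list[int]:
        """The grammatical B pair_id order implied by a realized A order."""
        a_order = list(a_order)
        if self.condition == CENTER_EMBEDDED:
            return a_order[::-1]
        return a_order


TouchSequence = tuple[ItemToken, ...]


def is_grammatical(seq: Iterable[ItemToken], grammar: GrammarSpec) -> bool:
    """True iff a *complete* touch sequence is licensed by the grammar.

    The first n touches must be the n distinct A items in any order; the last
    n touches must be the B items in the reversed (CE) or repeated (CS) pair
    order.  Raises ValueError on an incomplete sequence.
    """
    seq = list(seq)
    n = grammar.n_pairs
    if len(seq) != 2 * n:
        raise ValueError(f"sequence has {len(seq)} touches; expected {2 * n}")
    first, second = seq[:n], seq[n:]
    if any(t.item_class != "A" for t in first):
        return False
    a_order = [t.pair_id for t in first]
    if sorted(a_order) != list(range(1, n + 1)):
        return False
    want_b = grammar.b_order_for(a_order)
    return [t for t in second] == [B(i) for i in want_b]


def next_correct_items(prefix: Iterable[ItemToken], grammar: GrammarSpec) -> set[ItemToken]:
    """The set of touches that grammatically extend ``prefix``.

    During the first half every untouched A item is allowed; at each
    second-half position exactly one B item is allowed, determined by the
    realized A order.  Raises ValueError if the prefix is not itself a
    grammatical prefix (callers truncating at the first error should never
    pass one in).
    """
    prefix = list(prefix)
    n = grammar.n_pairs
    if len(prefix) >= 2 * n:
        raise ValueError("prefix is already a complete sequence")
    first = prefix[: min(len(prefix), n)]
    if any(t.item_class != "A" for t in first):
        raise ValueError(f"prefix {prefix} is not a grammatical prefix")
    a_seen = [t.pair_id for t in first]
    if len(set(a_seen)) != len(a_seen):
        raise ValueError(f"prefix {prefix} repeats an A item")
    if len(prefix) < n:
        remaining = set(range(1, n + 1)) - set(a_seen)
        return {A(i) for i in remaining}
    want_b = grammar.b_order_for(a_seen)
    expect = [B(i) for i in want_b]
    done = prefix[n:]
    if done != expect[: len(done)]:
        raise ValueError(f"prefix {prefix} has an ungrammatical second half")
    return {expect[len(done)]}


def enumerate_correct_sequences(grammar: GrammarSpec) -> set[TouchSequence]:
    """All n! complete grammatical sequences (one per A permutation)."""
    n = grammar.n_pairs
    out: set[TouchSequence] = set()
    for a_order in itertools.permutations(range(1, n + 1)):
        seq = [A(i) for i in a_order] + [B(i) for i in grammar.b_order_for(a_order)]
        out.add(tuple(seq))
    return out


def chance_baseline(n_pairs: int) -> float:
    """P(grammatical) for a uniformly random ordering of all 2n items.

    n! grammatical sequences out of (2n)! orderings; identical for both
    conditions.  n=2 gives 2/24 = 8.3%.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    return math.factorial(n_pairs) / math.factorial(2 * n_pairs)


def blue_first_baseline(n_pairs: int) -> float:
    """P(grammatical) given the partial "touch blue then red" strategy.

    Both halves are ordered uniformly at random with all A items first; only
    the B half can be wrong, so the probability is 1/n!.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    return 1.0 / math.factorial(n_pairs)


def format_baseline_percent(p: float, n_pairs: int) -> str:
    """Render a baseline at conventional printed precision.

    One decimal place for arrays up to 6 items (n_pairs <= 3), whole percent
    for larger arrays.
    """
    pct = 100.0 * p
    if n_pairs <= 3:
        return f"{pct:.1f}"
    return f"{pct:.0f}"
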