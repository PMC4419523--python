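"""Pairwise grouping of post-neurons and first-to-fire decision logic.

The six post-neurons are paired into three groups, each comparing two of the
three vowels: /a/ vs /i/, /a/ vs /u/ and /i/ vs /u/.  Within a group the
member that fires first wins; a firing member beats a non-firing one, and a
group with no firing member (or an exact tie) abstains.  The predicted class
is the one winning at least two of the three groups; a cyclic outcome (one
win each) or too many abstentions yields an overall abstention.

Because each class sits in exactly two groups, the training label for a
class is a 6-vector with exactly two ones: on a correctly recognised input
exactly two of the six neurons generate a fire signal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .codes import CLASSES

__all__ = [
    "PairGrouping",
    "DEFAULT_GROUPING",
    "label_vector",
    "depression_vector",
    "classify",
    "recognize",
    "fired_count",
]


@dataclass(frozen=True)
class PairGrouping:
    """Ordered list of three (neuron index, class) pairs of post-neurons."""

    groups: Tuple[Tuple[Tuple[int, str], Tuple[int, str]], ...] = (
        ((0, "a"), (1, "i")),
        ((2, "a"), (3, "u")),
        ((4, "i"), (5, "u")),
    )

    def __post_init__(self):
        idx = [i for g in self.groups for i, _ in g]
        if sorted(idx) != list(range(len(idx))):
            raise ValueError("groups must use each neuron index exactly once, 0..n-1")
        counts = Counter(c for g in self.groups for _, c in g)
        for cls in CLASSES:
            if counts.get(cls, 0) != 2:
                raise ValueError(f"class {cls!r} must appear in exactly 2 groups")

    @property
    def n_neurons(self) -> int:
        return 2 * len(self.groups)

    def neurons_for(self, cls: str) -> List[int]:
        """Indices of the neurons representing ``cls`` (one per group containing it)."""
        return [i for g in self.groups for i, c in g if c == cls]

    def rivals_of(self, cls: str) -> List[int]:
        """Indices of the opposing neurons in the groups containing ``cls``."""
        out = []
        for g in self.groups:
            members = dict((c, i) for i, c in g)
            if cls in members:
                out.extend(i for i, c in g if c != cls)
        return out


DEFAULT_GROUPING = PairGrouping()


def label_vector(cls: str, grouping: PairGrouping = DEFAULT_GROUPING) -> np.ndarray:
    """Desired-fire 0/1 vector over the post-neurons for class ``cls``."""
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    v = np.zeros(grouping.n_neurons, dtype=int)
    v[grouping.neurons_for(cls)] = 1
    return v


def depression_vector(cls: str, grouping: PairGrouping = DEFAULT_GROUPING) -> np.ndarray:
    """0/1 vector marking the rival neurons to depress when training class ``cls``.

    These are the neurons with desired output 0 inside the two groups that
    contain ``cls`` — the losers of the pairwise comparisons.
    """
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    v = np.zeros(grouping.n_neurons, dtype=int)
    v[grouping.rivals_of(cls)] = 1
    return v


def _winner(t1: Optional[float], t2: Optional[float]) -> int:
    """0/1 for the earlier-firing member, -1 for abstention (no fire or tie)."""
    if t1 is None and t2 is None:
        return -1
    if t2 is None:
        return 0
    if t1 is None:
        return 1
    if t1 == t2:
        return -1
    return 0 if t1 < t2 else 1


def classify(
    t_fire: Sequence[Optional[float]],
    grouping: PairGrouping = DEFAULT_GROUPING,
) -> Tuple[Optional[str], List[Optional[str]]]:
    """First-to-fire majority vote.

    Parameters
    ----------
    t_fire : sequence of float or None
        Fire time per post-neuron (None / NaN = did not fire).

    Returns
    -------
    (predicted, group_winners)
        ``predicted`` is the class winning >= 2 groups, or None (abstain);
        ``group_winners`` lists the winning class per group (None = group
        abstained).
    """
    t = [None if (x is None or (isinstance(x, float) and np.isnan(x))) else float(x) for x in t_fire]
    if len(t) != grouping.n_neurons:
        raise ValueError("fire record length does not match the grouping")
    if any(x is not None and x < 0 for x in t):
        raise ValueError("fire times must be non-negative")
    winners: List[Optional[str]] = []
    for (i1, c1), (i2, c2) in grouping.groups:
        w = _winner(t[i1], t[i2])
        winners.append(None if w < 0 else (c1, c2)[w])
    counts = Counter(w for w in winners if w is not None)
    for cls, n in counts.most_common(1):
        if n >= 2:
            return cls, winners
    return None, winners


def recognize(
    t_fire: Sequence[Optional[float]],
    grouping: PairGrouping = DEFAULT_GROUPING,
) -> Tuple[Optional[str], List[Optional[str]], int, Optional[float]]:
    """Event-ordered recognition with a decision latch.

    Fire events are replayed in time order; a group resolves the moment its
    first member fires.  As soon as one class has won two groups the
    decision latches — the system recognises the input and starts the
    refractory phase, so later would-be crossings never become fire
    signals.  Returns ``(predicted, group_winners, n_fired, t_decision)``
    where ``n_fired`` counts the fire signals generated up to (and
    including) the decisive one; if no majority is ever reached the full
    window plays out and ``n_fired`` counts every crossing.

    The predicted class always equals :func:`classify` on the same record —
    the latch changes when integration stops, not the outcome.
    """
    t = [None if (x is None or (isinstance(x, float) and np.isnan(x))) else float(x) for x in t_fire]
    if len(t) != grouping.n_neurons:
        raise ValueError("fire record length does not match the grouping")
    group_of = {}
    for gi, g in enumerate(grouping.groups):
        for idx, cls in g:
            group_of[idx] = (gi, cls)
    events = sorted((ti, i) for i, ti in enumerate(t) if ti is not None)
    winners: List[Optional[str]] = [None] * len(grouping.groups)
    resolved = [False] * len(grouping.groups)
    counts: Counter = Counter()
    n_fired = 0
    k = 0
    while k < len(events):
        ti = events[k][0]
        simultaneous = [i for tj, i in events[k:] if tj == ti]
        k += len(simultaneous)
        n_fired += len(simultaneous)
        touched = Counter(group_of[i][0] for i in simultaneous)
        for i in simultaneous:
            gi, cls = group_of[i]
            if resolved[gi]:
                continue
            resolved[gi] = True
            if touched[gi] > 1:
                continue  # exact within-group tie: the group abstains
            winners[gi] = cls
            counts[cls] += 1
        for cls, n in counts.items():
            if n >= 2:
                return cls, winners, n_fired, ti
    return None, winners, n_fired, None


def fired_count(t_fire: Sequence[Optional[float]]) -> int:
    """Number of neurons that fired in a trial record."""
    return sum(
        1
        for x in t_fire
        if x is not None and not (isinstance(x, float) and np.isnan(x))
    )
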