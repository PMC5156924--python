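"""Single production events under frequency-dependent cultural transmission.

The unit of time is one *production event*: ``v`` material items are made,
each one either copied from the current sampling pool (the variants of the
last ``w`` production events) or invented as a never-before-seen type
(infinite-alleles innovation).  The probability of copying variant type ``j``
with pool counts ``m_j`` is

    pi_j = (1 - mu) * m_j**(1 - b) / sum_l m_l**(1 - b)

so ``b = 0`` is unbiased copying proportional to relative frequency,
``b > 0`` disproportionately favours rare types (anti-conformity) and
``b < 0`` disproportionately favours common types (conformity).  With
probability ``mu`` a novel type is produced instead.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Dict, Hashable, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "VariantLabel",
    "VariantRegistry",
    "TransmissionParams",
    "SamplingPool",
    "copy_probabilities",
    "production_event",
    "advance_pool",
    "EmptyPoolError",
]

TypeId = Hashable


class EmptyPoolError(ValueError):
    """Raised when transmission is attempted before the pool has been seeded."""


@dataclass(frozen=True)
class VariantLabel:
    """A variant type identity: a unique id and the event that minted it."""

    id: int
    origin_event: int


class VariantRegistry:
    """Mints globally unique variant ids (infinite-alleles bookkeeping).

    Ids are integers and are never reused; every innovation event mints a
    previously unseen id.  Observed datasets use string type names, which
    never collide with minted integer ids.
    """

    def __init__(self, start: int = 0) -> None:
        self._next = int(start)
        self._labels: Dict[int, VariantLabel] = {}

    def mint(self, origin_event: int) -> int:
        label = VariantLabel(self._next, int(origin_event))
        self._labels[label.id] = label
        self._next += 1
        return label.id

    def label(self, type_id: int) -> VariantLabel:
        return self._labels[type_id]

    def __len__(self) -> int:
        return len(self._labels)


@dataclass
class TransmissionParams:
    """Parameters of one transmission regime.

    mu : innovation rate, probability in [0, 1] per produced item.
    b : strength/sign of frequency dependence (b < 0 conformity,
        b > 0 anti-conformity, b = 0 unbiased).
    w_events : memory window, number of past production events forming
        the sampling pool.
    v : items produced per event; a positive integer for a constant
        production size or a sequence giving a per-event schedule.
    """

    mu: float
    b: float
    w_events: int
    v: Union[int, Sequence[int]] = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if int(self.w_events) < 1:
            raise ValueError(f"w_events must be >= 1, got {self.w_events}")
        self.w_events = int(self.w_events)
        v = self.v
        if np.isscalar(v):
            if int(v) < 1:
                raise ValueError("v must be >= 1")
            self.v = int(v)
        else:
            v = np.asarray(v, dtype=int)
            if v.size == 0 or (v < 1).any():
                raise ValueError("every entry of the v schedule must be >= 1")
            self.v = v


class SamplingPool:
    """The multiset of variants produced in the last ``w`` production events.

    Entries are (type id, event stamp) pairs grouped by event.  The pool may
    additionally hold *unmarked* entries (no event stamp): these arise when a
    run is initialised from observed frequencies rather than from simulated
    history, and are displaced a fixed number at a time during the first
    ``w`` events until every entry in the pool carries a chronological
    marker.
    """

    def __init__(
        self,
        window_w: int,
        registry: Optional[VariantRegistry] = None,
        unmarked: Optional[Mapping[TypeId, int]] = None,
        unmarked_removal_per_event: int = 0,
    ) -> None:
        if int(window_w) < 1:
            raise ValueError("window_w must be >= 1")
        self.window_w = int(window_w)
        self.registry = registry if registry is not None else VariantRegistry()
        self._events: deque = deque()  # (event_index, list of type ids)
        self._counts: Dict[TypeId, int] = {}
        self._unmarked: Dict[TypeId, int] = {}
        self.unmarked_removal_per_event = int(unmarked_removal_per_event)
        self.last_event_index: Optional[int] = None
        if unmarked:
            for t, c in unmarked.items():
                c = int(c)
                if c < 0:
                    raise ValueError("unmarked counts must be non-negative")
                if c:
                    self._unmarked[t] = c
                    self._counts[t] = self._counts.get(t, 0) + c

    # -- views ---------------------------------------------------------

    def counts(self) -> Dict[TypeId, int]:
        """Counts by type over stamped and unmarked entries combined."""
        return {t: c for t, c in self._counts.items() if c > 0}

    @property
    def size(self) -> int:
        return sum(c for c in self._counts.values() if c > 0)

    @property
    def n_unmarked(self) -> int:
        return sum(self._unmarked.values())

    @property
    def n_events(self) -> int:
        return len(self._events)

    def event_stamps(self) -> List[int]:
        return [e for e, _ in self._events]

    # -- updates -------------------------------------------------------

    def _add(self, t: TypeId, n: int = 1) -> None:
        self._counts[t] = self._counts.get(t, 0) + n

    def _remove(self, t: TypeId, n: int = 1) -> None:
        c = self._counts[t] - n
        if c < 0:  # pragma: no cover - internal consistency guard
            raise RuntimeError("pool count went negative")
        if c:
            self._counts[t] = c
        else:
            del self._counts[t]

    def append_event(self, event_index: int, type_ids: Iterable[TypeId]) -> None:
        if self.last_event_index is not None and event_index <= self.last_event_index:
            raise ValueError(
                f"event_index must be strictly increasing "
                f"(got {event_index} after {self.last_event_index})"
            )
        ids = list(type_ids)
        self._events.append((int(event_index), ids))
        for t in ids:
            self._add(t)
        self.last_event_index = int(event_index)

    def expire(self, event_index: int) -> None:
        """Drop stamped events older than the window ending at ``event_index``."""
        horizon = int(event_index) - self.window_w
        while self._events and self._events[0][0] <= horizon:
            _, ids = self._events.popleft()
            for t in ids:
                self._remove(t)

    def displace_unmarked(self, n: int, rng: np.random.Generator) -> int:
        """Randomly delete up to ``n`` unmarked entries; returns how many."""
        total = self.n_unmarked
        n = min(int(n), total)
        if n <= 0:
            return 0
        types = sorted(self._unmarked, key=str)
        counts = np.array([self._unmarked[t] for t in types], dtype=np.int64)
        removed = rng.multivariate_hypergeometric(counts, n)
        for t, k in zip(types, removed):
            if k:
                left = self._unmarked[t] - int(k)
                if left:
                    self._unmarked[t] = left
                else:
                    del self._unmarked[t]
                self._remove(t, int(k))
        return n


def copy_probabilities(
    pool_counts: Mapping[TypeId, int], b: float, mu: float
) -> Tuple[Dict[TypeId, float], float]:
    """Copying probabilities over pool types, plus the innovation mass.

    Returns ``(probs, mu)`` where ``probs[j] = (1-mu) * m_j^(1-b) / Z`` and
    ``Z`` normalises over the types present in the pool, so that the copy
    mass sums to ``1 - mu`` and the total mass is 1.  Computed in log space
    so that large ``|b|`` cannot overflow.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu must lie in [0, 1], got {mu}")
    items = [(t, int(c)) for t, c in pool_counts.items() if c != 0]
    if any(c < 0 for _, c in items):
        raise ValueError("pool counts must be non-negative integers")
    if not items:
        raise EmptyPoolError(
            "sampling pool is empty: seed the pool before running transmission"
        )
    logw = np.array([(1.0 - b) * math.log(c) for _, c in items])
    logw -= logw.max()
    wts = np.exp(logw)
    wts /= wts.sum()
    probs = {t: (1.0 - mu) * p for (t, _), p in zip(items, wts)}
    return probs, mu


def production_event(
    pool: SamplingPool,
    params: TransmissionParams,
    v_now: int,
    rng: np.random.Generator,
) -> List[TypeId]:
    """Produce ``v_now`` items from the pool: copies and/or novel types.

    Each item is independently a copy drawn according to
    :func:`copy_probabilities` (probability ``1 - mu``) or a freshly minted
    type (probability ``mu``).
    """
    v_now = int(v_now)
    if v_now < 1:
        raise ValueError("v_now must be >= 1")
    counts = pool.counts()
    if not counts:
        raise EmptyPoolError(
            "sampling pool is empty: seed the pool before running transmission"
        )
    n_new = int(rng.binomial(v_now, params.mu)) if params.mu > 0 else 0
    n_copy = v_now - n_new
    out: List[TypeId] = []
    if n_copy:
        probs, _ = copy_probabilities(counts, params.b, 0.0)
        types = list(probs)
        p = np.fromiter(probs.values(), dtype=float, count=len(types))
        p /= p.sum()
        drawn = rng.multinomial(n_copy, p)
        for t, k in zip(types, drawn):
            out.extend([t] * int(k))
    origin = (pool.last_event_index or 0) + 1
    for _ in range(n_new):
        out.append(pool.registry.mint(origin))
    return out


def advance_pool(
    pool: SamplingPool,
    new_variants: Iterable[TypeId],
    event_index: int,
    rng: Optional[np.random.Generator] = None,
) -> SamplingPool:
    """Append one event's output and retire entries that left the window.

    Stamped entries older than ``window_w`` events are expired; if the pool
    still holds unmarked (initial) entries, ``unmarked_removal_per_event`` of
    them are deleted at random instead, which requires ``rng``.
    """
    pool.append_event(event_index, new_variants)
    if pool.n_unmarked > 0 and pool.unmarked_removal_per_event > 0:
        if rng is None:
            raise ValueError("rng is required while unmarked entries remain")
        pool.displace_unmarked(pool.unmarked_removal_per_event, rng)
    pool.expire(event_index)
    return pool
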