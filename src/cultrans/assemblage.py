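"""Phase-level accumulation (time-averaging) and archaeological sampling.

An archaeological phase ``i`` accumulates every item produced by its
``eta_i`` production events into a deposited population of size
``N_i = round(n_i * r)``; the observed sample of size ``n_i`` is then a
simple random draw (without replacement) from that population, emulating a
recovery rate of ``1/r``.  Production sizes ``v(t)`` within a phase follow a
demographic schedule proportional to ``rho * H_i`` (potters per household
times house count), integerised so the within-phase sum is exactly ``N_i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Hashable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import SamplingPool, TransmissionParams, advance_pool, production_event

__all__ = [
    "PhaseSpec",
    "Assemblage",
    "DemographyParams",
    "round_half_up",
    "phase_specs_from_sizes",
    "accumulate_phase",
    "sample_assemblage",
    "production_schedule",
    "integerize",
    "read_count_table",
    "write_count_table",
    "read_house_counts",
    "write_house_counts",
]


def round_half_up(x: float) -> int:
    """Round with .5 going up; used for N_i = round(n_i * r)."""
    return int(math.floor(float(x) + 0.5))


@dataclass
class PhaseSpec:
    """Bookkeeping for one phase.

    phase_id : ordered label (e.g. "VII").
    n_i : observed sample size.
    r : recovery factor; the sample is a fraction 1/r of the population.
    N_i : deposited population size, round(n_i * r).
    eta_i : number of production events in the phase.
    t_i : global event index at phase start (first event is t_i + 1).
    """

    phase_id: Hashable
    n_i: int
    r: float
    N_i: int
    eta_i: int
    t_i: int = 0

    def __post_init__(self) -> None:
        if self.n_i < 0:
            raise ValueError("n_i must be non-negative")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.N_i < max(1, self.n_i):
            raise ValueError(
                f"population size N_i={self.N_i} smaller than sample size "
                f"n_i={self.n_i}: the recovery factor r must be >= 1"
            )
        if not 1 <= self.eta_i <= self.N_i:
            raise ValueError(
                f"eta_i={self.eta_i} infeasible for N_i={self.N_i} "
                "(each event must produce at least one item)"
            )

    @classmethod
    def build(
        cls,
        phase_id: Hashable,
        n_i: int,
        r: float,
        v_mean: float,
        t_i: int = 0,
    ) -> "PhaseSpec":
        """Derive N_i and eta_i from the sample size, recovery factor and a
        mean production size."""
        N_i = max(int(n_i), round_half_up(n_i * r), 1)
        eta_i = min(N_i, max(1, round_half_up(N_i / max(v_mean, 1.0))))
        return cls(phase_id, int(n_i), float(r), N_i, eta_i, int(t_i))


@dataclass
class Assemblage:
    """A population or sample of variants belonging to one phase."""

    phase_id: Hashable
    variant_counts: Dict[Hashable, int]

    def __post_init__(self) -> None:
        self.variant_counts = {
            t: int(c) for t, c in self.variant_counts.items() if int(c) != 0
        }
        if any(c < 0 for c in self.variant_counts.values()):
            raise ValueError("assemblage counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.variant_counts.values())

    @property
    def types(self) -> List[Hashable]:
        return list(self.variant_counts)

    @classmethod
    def from_tokens(cls, phase_id: Hashable, tokens: Sequence[Hashable]) -> "Assemblage":
        counts: Dict[Hashable, int] = {}
        for t in tokens:
            counts[t] = counts.get(t, 0) + 1
        return cls(phase_id, counts)


@dataclass
class DemographyParams:
    """Per-phase house counts and the potters-per-household factor."""

    H_i: Sequence[int]
    rho: float

    def __post_init__(self) -> None:
        H = np.asarray(self.H_i, dtype=float)
        if H.size == 0 or (H <= 0).any():
            raise ValueError("house counts must be strictly positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        self.H_i = H


def phase_specs_from_sizes(
    phase_ids: Sequence[Hashable],
    n: Sequence[int],
    r: float,
    v_mean_per_phase: Sequence[float],
) -> List[PhaseSpec]:
    """Build abutting PhaseSpecs (contiguous global event indices)."""
    specs: List[PhaseSpec] = []
    t = 0
    for pid, n_i, vm in zip(phase_ids, n, v_mean_per_phase):
        s = PhaseSpec.build(pid, int(n_i), r, vm, t_i=t)
        specs.append(s)
        t += s.eta_i
    return specs


def integerize(x: np.ndarray, total: int, minimum: int = 1) -> np.ndarray:
    """Largest-remainder rounding of non-negative weights to a fixed sum.

    Entries are floored, the remaining units go to the largest fractional
    parts (stable ties), and a per-entry minimum is enforced by taking units
    from the largest entries.
    """
    x = np.asarray(x, dtype=float)
    total = int(total)
    if x.size == 0:
        raise ValueError("empty schedule")
    if total < minimum * x.size:
        raise ValueError(
            f"total {total} cannot support {x.size} entries of at least {minimum}"
        )
    x = np.clip(x, 1e-12, None)
    scaled = x * (total / x.sum())
    out = np.floor(scaled).astype(np.int64)
    rem = total - int(out.sum())
    if rem > 0:
        frac = scaled - np.floor(scaled)
        order = np.argsort(-frac, kind="stable")
        out[order[:rem]] += 1
    while (out < minimum).any():
        i = int(np.argmin(out))
        j = int(np.argmax(out))
        if out[j] <= minimum:  # pragma: no cover - guarded by total check
            raise ValueError("cannot enforce minimum")
        out[i] += 1
        out[j] -= 1
    return out


def production_schedule(
    H: Sequence[int],
    rho: float,
    specs: Sequence[PhaseSpec],
) -> List[np.ndarray]:
    """Per-event production sizes v(t_i + tau) for each phase.

    The demographic signal ``rho * H_i`` is attached to phase midpoints and
    piecewise-linearly interpolated at the event positions of each phase
    (phases have equal calendar duration); the interpolated values are then
    integerised so that the within-phase sum is exactly ``N_i`` and every
    event produces at least one item.
    """
    H = np.asarray(H, dtype=float)
    if len(H) != len(specs):
        raise ValueError("one house count per phase is required")
    if (H <= 0).any() or rho <= 0:
        raise ValueError("house counts and rho must be strictly positive")
    mid = np.arange(len(specs)) + 0.5
    signal = rho * H
    out: List[np.ndarray] = []
    for i, spec in enumerate(specs):
        if spec.N_i < spec.eta_i:
            raise ValueError(
                f"phase {spec.phase_id}: N_i={spec.N_i} < eta_i={spec.eta_i}"
            )
        pos = i + (np.arange(spec.eta_i) + 0.5) / spec.eta_i
        target = np.interp(pos, mid, signal)
        out.append(integerize(target, spec.N_i))
    return out


def accumulate_phase(
    pool: SamplingPool,
    params: TransmissionParams,
    spec: PhaseSpec,
    rng: np.random.Generator,
    schedule: Optional[Sequence[int]] = None,
) -> Tuple[Assemblage, SamplingPool]:
    """Run the eta_i production events of a phase, collecting *all* produced
    items into the phase population (time-averaging), and return the
    population together with the advanced pool."""
    if schedule is None:
        schedule = expand_schedule(params, spec)
    sched = np.asarray(schedule, dtype=np.int64)
    if sched.size != spec.eta_i:
        raise ValueError(
            f"schedule length {sched.size} does not match eta_i={spec.eta_i}"
        )
    if int(sched.sum()) != spec.N_i:
        raise ValueError(
            f"schedule sums to {int(sched.sum())} but N_i={spec.N_i}"
        )
    if (sched < 1).any():
        raise ValueError("every production event must produce at least one item")
    counts: Dict[Hashable, int] = {}
    for tau in range(spec.eta_i):
        event_index = spec.t_i + tau + 1
        produced = production_event(pool, params, int(sched[tau]), rng)
        for t in produced:
            counts[t] = counts.get(t, 0) + 1
        advance_pool(pool, produced, event_index, rng=rng)
    population = Assemblage(spec.phase_id, counts)
    assert population.total == spec.N_i
    return population, pool


def expand_schedule(params: TransmissionParams, spec: PhaseSpec) -> np.ndarray:
    """Expand a constant v into a per-event schedule summing to N_i exactly
    (any remainder is absorbed by the final event of the phase)."""
    if not np.isscalar(params.v):
        sched = np.asarray(params.v, dtype=np.int64)
        return sched
    v = int(params.v)
    sched = np.full(spec.eta_i, v, dtype=np.int64)
    sched[-1] = spec.N_i - v * (spec.eta_i - 1)
    if sched[-1] < 1:
        return integerize(np.full(spec.eta_i, float(v)), spec.N_i)
    return sched


def sample_assemblage(
    population: Assemblage, n_i: int, rng: np.random.Generator
) -> Assemblage:
    """Simple random sample of n_i items without replacement."""
    n_i = int(n_i)
    if n_i < 0:
        raise ValueError("n_i must be non-negative")
    if n_i > population.total:
        raise ValueError(
            f"cannot sample n_i={n_i} from a population of {population.total}: "
            "the recovery factor r must be >= 1"
        )
    if n_i == 0:
        return Assemblage(population.phase_id, {})
    types = population.types
    counts = np.array([population.variant_counts[t] for t in types], dtype=np.int64)
    drawn = rng.multivariate_hypergeometric(counts, n_i)
    return Assemblage(
        population.phase_id,
        {t: int(k) for t, k in zip(types, drawn) if k},
    )


# ---------------------------------------------------------------------------
# CSV interfaces: count tables (rows = phases in order, columns = type names)
# and house counts (phase, H).
# ---------------------------------------------------------------------------


def read_count_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index.name = "phase"
    df = df.fillna(0).astype(int)
    if (df.to_numpy() < 0).any():
        raise ValueError("count table contains negative entries")
    return df


def write_count_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "phase"
    out.astype(int).to_csv(path)


def read_house_counts(path) -> pd.Series:
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] != 1:
        raise ValueError("house-count file must have exactly two columns (phase, H)")
    s = df.iloc[:, 0].astype(int)
    s.name = "H"
    if (s <= 0).any():
        raise ValueError("house counts must be strictly positive")
    return s


def write_house_counts(H: pd.Series, path) -> None:
    out = H.rename("H").to_frame()
    out.index.name = "phase"
    out.to_csv(path)
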