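"""The three generative regimes of the transmission simulator.

* ``run_equilibrium`` — constant parameters throughout; the system is
  brought to innovation-drift stationarity by a burn-in (default 5,000
  production events) before the phase assemblages are generated.
* ``run_variable_population`` — per-event production sizes follow the
  demographic schedule; no burn-in, the initial sampling pool is
  reconstructed from the observed first-phase frequencies via a Dirichlet
  draw; the pool is carried across phases.
* ``run_variable_population_transmission`` — each phase is simulated
  independently with its own transmission parameters, re-seeding the pool
  from the observed frequencies at the end of the previous phase.

Each run returns per-phase populations of exactly ``N_i`` items and samples
of exactly ``n_i`` items.  The observed first phase only seeds the
non-equilibrium versions; the simulated phases are the subsequent ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, Hashable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _engine
from .assemblage import (
    Assemblage,
    DemographyParams,
    PhaseSpec,
    accumulate_phase,
    expand_schedule,
    production_schedule,
    sample_assemblage,
)
from .core import (
    SamplingPool,
    TransmissionParams,
    VariantRegistry,
    advance_pool,
    production_event,
)

__all__ = [
    "RunResult",
    "dirichlet_initial_pool",
    "run_equilibrium",
    "run_variable_population",
    "run_variable_population_transmission",
]

NOVEL_PREFIX = "sim"


@dataclass
class RunResult:
    """Per-phase outputs of one simulated run."""

    samples: List[Assemblage]
    populations: Optional[List[Assemblage]]
    params_used: Union[TransmissionParams, List[TransmissionParams]]

    def sample_table(self) -> pd.DataFrame:
        """Samples as a phase x type count table (novel types stringified)."""
        rows = {a.phase_id: a.variant_counts for a in self.samples}
        df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
        df.index.name = "phase"
        df.columns = [str(c) for c in df.columns]
        return df.loc[[a.phase_id for a in self.samples]]


def _counts_of(observed) -> Dict[Hashable, int]:
    if isinstance(observed, Assemblage):
        return dict(observed.variant_counts)
    if isinstance(observed, pd.Series):
        return {t: int(c) for t, c in observed.items() if int(c) > 0}
    return {t: int(c) for t, c in dict(observed).items() if int(c) > 0}


def dirichlet_counts(
    observed_counts: Sequence[int],
    pool_size: int,
    rng: np.random.Generator,
    smoothing: float = 0.0,
    max_retries: int = 100,
) -> np.ndarray:
    """Draw pool counts of total ``pool_size`` from a Dirichlet-multinomial
    with concentration equal to the observed counts, under the constraint
    that every observed type is present.

    The constraint is enforced by rejection (regenerating the draw); after
    ``max_retries`` failures each still-missing type is force-inserted by
    replacing a random removable token.
    """
    alpha = np.asarray(observed_counts, dtype=float) + float(smoothing)
    k = alpha.size
    if k == 0 or (alpha <= 0).any():
        raise ValueError("observed counts must be strictly positive")
    pool_size = int(pool_size)
    if pool_size < k:
        raise ValueError(
            f"pool of {pool_size} entries cannot contain all {k} observed "
            "types: increase w or v"
        )
    # common case first: a single draw usually succeeds for large pools
    draw = rng.multinomial(pool_size, rng.dirichlet(alpha))
    if (draw > 0).all():
        return draw
    n_batch = int(max_retries) - 1
    if n_batch > 0:
        batch = rng.multinomial(pool_size, rng.dirichlet(alpha, size=n_batch))
        ok = np.flatnonzero((batch > 0).all(axis=1))
        if ok.size:
            return batch[ok[0]]
        draw = batch[-1]
    # force the remaining missing types in, replacing random tokens
    draw = np.asarray(draw, dtype=np.int64)
    for t in np.flatnonzero(draw == 0):
        removable = np.maximum(draw - 1, 0)
        donor = rng.choice(k, p=removable / removable.sum())
        draw[donor] -= 1
        draw[t] += 1
    return draw


def dirichlet_initial_pool(
    observed,
    w_events: int,
    v1: int,
    rng: np.random.Generator,
    smoothing: float = 0.0,
    max_retries: int = 100,
    registry: Optional[VariantRegistry] = None,
) -> SamplingPool:
    """Reconstruct an initial sampling pool of ``w * v1`` entries from
    observed frequencies.

    The entries carry no event stamp; during the first ``w`` production
    events of the subsequent run, ``v1`` of them are deleted at random per
    event until every entry in the pool is associated with a chronological
    marker.
    """
    counts = _counts_of(observed)
    if not counts:
        raise ValueError("observed assemblage is empty")
    types = list(counts)
    draw = dirichlet_counts(
        [counts[t] for t in types], int(w_events) * int(v1), rng,
        smoothing=smoothing, max_retries=max_retries,
    )
    return SamplingPool(
        window_w=int(w_events),
        registry=registry,
        unmarked={t: int(c) for t, c in zip(types, draw)},
        unmarked_removal_per_event=int(v1),
    )


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _registry_above(*observed_sets) -> VariantRegistry:
    """A registry whose minted integer ids cannot alias integer type names
    already present in the seeding assemblages."""
    top = -1
    for obs in observed_sets:
        for t in obs:
            if isinstance(t, (int, np.integer)):
                top = max(top, int(t))
    return VariantRegistry(start=top + 1)


def _assemblages_from_matrix(
    pop: np.ndarray,
    seed_names: Sequence[Hashable],
    specs: Sequence[PhaseSpec],
    tag: int,
) -> List[Assemblage]:
    """Wrap kernel output in Assemblages.  Novel types are named
    ``sim<tag>_<id>``; the tag (the run's kernel seed) keeps names from
    chained runs distinct, so a carried-over type can never be aliased by a
    new one."""
    n0 = len(seed_names)
    out = []
    for i, spec in enumerate(specs):
        row = pop[i]
        counts: Dict[Hashable, int] = {}
        for t in np.flatnonzero(row):
            t = int(t)
            name = seed_names[t] if t < n0 else f"{NOVEL_PREFIX}{tag}_{t}"
            counts[name] = int(row[t])
        a = Assemblage(spec.phase_id, counts)
        if a.total != spec.N_i:  # conservation guard
            raise RuntimeError(
                f"phase {spec.phase_id}: population has {a.total} items, "
                f"expected N_i={spec.N_i}"
            )
        out.append(a)
    return out


def _sample_phases(
    populations: List[Assemblage],
    specs: Sequence[PhaseSpec],
    rng: np.random.Generator,
) -> List[Assemblage]:
    return [
        sample_assemblage(pop, spec.n_i, rng)
        for pop, spec in zip(populations, specs)
    ]


def _phase_schedules(
    params: TransmissionParams, specs: Sequence[PhaseSpec]
) -> List[np.ndarray]:
    return [expand_schedule(params, s) for s in specs]


# ---------------------------------------------------------------------------
# version 1: equilibrium
# ---------------------------------------------------------------------------


def run_equilibrium(
    params: TransmissionParams,
    specs: Sequence[PhaseSpec],
    rng: np.random.Generator,
    burn_in: int = 5000,
    backend: str = "kernel",
    keep_populations: bool = False,
    initial_pool: Optional[SamplingPool] = None,
) -> RunResult:
    """Constant-parameter run: seed ``v`` distinct types, burn in, then
    generate and sample every phase."""
    if not np.isscalar(params.v):
        raise ValueError("the equilibrium version requires a constant v")
    v = int(params.v)
    schedules = _phase_schedules(params, specs)

    if backend == "kernel":
        schedule = np.concatenate(
            [np.full(burn_in, v, dtype=np.int64)] + schedules
        )
        eta = np.array([s.eta_i for s in specs], dtype=np.int64)
        if initial_pool is None:
            init_counts = np.ones(v, dtype=np.int64)
            seed_names: Sequence[Hashable] = list(range(v))
        else:
            c = initial_pool.counts()
            seed_names = list(c)
            init_counts = np.array([c[t] for t in seed_names], dtype=np.int64)
        kseed = _kernel_seed(rng)
        pop, _, ok = _engine.simulate_run(
            kseed, params.b, params.mu, params.w_events,
            schedule, int(burn_in), eta, init_counts,
            init_unmarked=False, v1_del=0,
        )
        if not ok:
            raise RuntimeError("simulation failed (pool exhausted or capacity)")
        populations = _assemblages_from_matrix(pop, seed_names, specs, kseed)
        samples = _sample_phases(populations, specs, rng)
        return RunResult(samples, populations if keep_populations else None, params)

    # reference backend
    if initial_pool is None:
        registry = VariantRegistry()
        pool = SamplingPool(params.w_events, registry)
        advance_pool(pool, [registry.mint(0) for _ in range(v)], 0)
    else:
        pool = initial_pool
    for e in range(1, int(burn_in) + 1):
        produced = production_event(pool, params, v, rng)
        advance_pool(pool, produced, e, rng=rng)
    offset = int(burn_in)
    populations, samples = [], []
    for spec, sched in zip(specs, schedules):
        shifted = dataclasses.replace(spec, t_i=spec.t_i + offset)
        population, pool = accumulate_phase(pool, params, shifted, rng, schedule=sched)
        population.phase_id = spec.phase_id
        populations.append(population)
        samples.append(sample_assemblage(population, spec.n_i, rng))
    return RunResult(samples, populations if keep_populations else None, params)


# ---------------------------------------------------------------------------
# version 2: variable population
# ---------------------------------------------------------------------------


def run_variable_population(
    params: TransmissionParams,
    demography: DemographyParams,
    observed_first_phase,
    specs: Sequence[PhaseSpec],
    rng: np.random.Generator,
    backend: str = "kernel",
    keep_populations: bool = False,
    initial_pool: Optional[SamplingPool] = None,
    smoothing: float = 0.0,
) -> RunResult:
    """Time-dependent production sizes, constant transmission mode.

    ``specs`` are the simulated phases (the observed first phase only seeds
    the pool); ``demography`` provides one house count per simulated phase.
    """
    schedules = production_schedule(demography.H_i, demography.rho, specs)
    v1 = int(schedules[0][0])
    if initial_pool is None:
        counts0 = _counts_of(observed_first_phase)
        pool = dirichlet_initial_pool(
            counts0, params.w_events, v1, rng, smoothing=smoothing,
            registry=_registry_above(counts0),
        )
    else:
        pool = initial_pool

    if backend == "kernel":
        c = pool.counts()
        seed_names = list(c)
        init_counts = np.array([c[t] for t in seed_names], dtype=np.int64)
        schedule = np.concatenate(schedules)
        eta = np.array([s.eta_i for s in specs], dtype=np.int64)
        kseed = _kernel_seed(rng)
        pop, _, ok = _engine.simulate_run(
            kseed, params.b, params.mu, params.w_events,
            schedule, 0, eta, init_counts,
            init_unmarked=pool.n_unmarked > 0,
            v1_del=pool.unmarked_removal_per_event,
        )
        if not ok:
            raise RuntimeError("simulation failed (pool exhausted or capacity)")
        populations = _assemblages_from_matrix(pop, seed_names, specs, kseed)
        samples = _sample_phases(populations, specs, rng)
        return RunResult(samples, populations if keep_populations else None, params)

    populations, samples = [], []
    for spec, sched in zip(specs, schedules):
        population, pool = accumulate_phase(pool, params, spec, rng, schedule=sched)
        populations.append(population)
        samples.append(sample_assemblage(population, spec.n_i, rng))
    return RunResult(samples, populations if keep_populations else None, params)


# ---------------------------------------------------------------------------
# version 3: variable population and transmission mode
# ---------------------------------------------------------------------------


def run_variable_population_transmission(
    per_phase_params: Sequence[TransmissionParams],
    demography: DemographyParams,
    observed_counts_by_phase: Sequence,
    specs: Sequence[PhaseSpec],
    rng: np.random.Generator,
    backend: str = "kernel",
    keep_populations: bool = False,
    chain_pools: bool = False,
    smoothing: float = 0.0,
) -> RunResult:
    """Per-phase transmission parameters; each phase re-seeded from the
    observed end-of-previous-phase frequencies.

    ``observed_counts_by_phase[i]`` are the observed counts of the phase
    preceding simulated phase ``i``.  With ``chain_pools=True`` (debug
    reduction) the pool is seeded once from the first predecessor and then
    carried across phases, which with tied parameters reproduces
    :func:`run_variable_population`.
    """
    if len(per_phase_params) != len(specs):
        raise ValueError("one TransmissionParams per simulated phase is required")
    if len(observed_counts_by_phase) != len(specs):
        raise ValueError(
            "observed counts of each predecessor phase are required "
            "(missing predecessor-phase counts)"
        )
    schedules = production_schedule(demography.H_i, demography.rho, specs)
    registry = _registry_above(
        *[_counts_of(o) for o in observed_counts_by_phase]
    )
    populations: List[Assemblage] = []
    samples: List[Assemblage] = []
    pool: Optional[SamplingPool] = None
    for i, (params, spec, sched) in enumerate(zip(per_phase_params, specs, schedules)):
        v1 = int(sched[0])
        reseed = pool is None or not chain_pools
        if reseed:
            pool = dirichlet_initial_pool(
                observed_counts_by_phase[i], params.w_events, v1, rng,
                smoothing=smoothing, registry=registry,
            )
        if backend == "kernel":
            c = pool.counts()
            seed_names = list(c)
            init_counts = np.array([c[t] for t in seed_names], dtype=np.int64)
            kseed = _kernel_seed(rng)
            pop, _, ok = _engine.simulate_run(
                kseed, params.b, params.mu, params.w_events,
                np.asarray(sched, dtype=np.int64), 0,
                np.array([spec.eta_i], dtype=np.int64), init_counts,
                init_unmarked=pool.n_unmarked > 0,
                v1_del=pool.unmarked_removal_per_event,
            )
            if not ok:
                raise RuntimeError("simulation failed (pool exhausted or capacity)")
            population = _assemblages_from_matrix(pop, seed_names, [spec], kseed)[0]
            if chain_pools:
                raise NotImplementedError(
                    "chain_pools is a reference-backend debug mode"
                )
        else:
            population, pool = accumulate_phase(pool, params, spec, rng, schedule=sched)
        populations.append(population)
        samples.append(sample_assemblage(population, spec.n_i, rng))
    return RunResult(
        samples, populations if keep_populations else None, list(per_phase_params)
    )
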