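"""ABC rejection inference: priors, error levels, retention, summaries.

The rejection algorithm draws parameter vectors from independent uniform
priors, forward-simulates the chosen model version, measures the error
level ``eps`` as a euclidean distance between observed and simulated
frequencies, and retains the proportion ``alpha`` of the ``s`` draws with
the smallest ``eps``.  The retained draws approximate the joint posterior.

Three version-specific error levels are provided:

* ``distance_fully_matched`` — one-to-one label correspondence (the
  variable population-transmission mode version); euclidean distance over
  all (phase, type) cells of the union of types, absolute counts, with
  unmatched types entering as zeros.
* ``distance_first_phase_matched`` — labels correspond only for the types
  present in the observed first phase (variable population version);
  distance restricted to those types, absolute counts.
* ``distance_rank_matched`` — no label correspondence (equilibrium
  version); types are rank-matched by relative frequency at the first
  phase, surplus simulated types dropped, missing ones padded with a
  constant zero series, and the distance taken on relative frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .assemblage import round_half_up

__all__ = [
    "PriorSpec",
    "ABCConfig",
    "ParamDraw",
    "PosteriorSample",
    "draw_priors",
    "distance_fully_matched",
    "distance_first_phase_matched",
    "distance_rank_matched",
    "rejection_sample",
    "retain_smallest",
    "hpdi",
    "posterior_summary",
]

PARAM_NAMES = ("mu", "b", "w_years", "rho", "r")


@dataclass
class PriorSpec:
    """Independent uniform prior ranges for the five inferred parameters.

    The memory window is drawn in years (default U(0.2, 5), from
    ethnographic pottery life-spans) and converted to production events
    using the events-per-year density of the reference (first) phase and
    the phase duration in calendar years (default 20).
    """

    mu_range: Tuple[float, float] = (5e-4, 0.05)
    b_range: Tuple[float, float] = (-0.5, 0.5)
    w_years_range: Tuple[float, float] = (0.2, 5.0)
    rho_range: Tuple[float, float] = (0.5, 5.0)
    r_range: Tuple[float, float] = (1.0, 50.0)
    phase_duration_years: float = 20.0

    def __post_init__(self) -> None:
        for name in ("mu_range", "b_range", "w_years_range", "rho_range", "r_range"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi)) or hi < lo:
                raise ValueError(f"{name} must be a non-empty interval, got {(lo, hi)}")
        if not (0.0 <= self.mu_range[0] and self.mu_range[1] <= 1.0):
            raise ValueError("mu_range must be contained in [0, 1]")
        if self.w_years_range[0] <= 0:
            raise ValueError("w_years_range must be positive")
        if self.rho_range[0] <= 0:
            raise ValueError("rho_range must be positive")
        if self.r_range[0] < 1.0:
            raise ValueError("r_range must start at >= 1 (samples cannot exceed populations)")
        if self.phase_duration_years <= 0:
            raise ValueError("phase_duration_years must be positive")

    def w_events_from_years(self, w_years: float, eta_ref: int) -> int:
        """Convert a memory length in years to production events using the
        events-per-year density eta_ref / phase_duration."""
        events_per_year = float(eta_ref) / self.phase_duration_years
        return max(1, round_half_up(w_years * events_per_year))

    def check_innovation_feasibility(
        self, observed: pd.DataFrame, houses: Optional[Sequence[float]] = None
    ) -> bool:
        """Validate that the lower innovation bound can plausibly mint the
        number of types first appearing after the first phase."""
        arr = observed.to_numpy()
        new_types = int(((arr[0] == 0) & (arr[1:].sum(axis=0) > 0)).sum())
        r_mid = 0.5 * (self.r_range[0] + self.r_range[1])
        total_items = float(arr.sum()) * r_mid
        expected = self.mu_range[1] * total_items
        return expected >= new_types


@dataclass
class ABCConfig:
    """Rejection settings: number of simulations and retention proportion."""

    s: int = 10_000_000
    alpha: float = 2e-5
    distance_mode: str = "rank_matched"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.s * self.alpha < 1:
            raise ValueError("s * alpha must retain at least one draw")

    @property
    def n_retained(self) -> int:
        return max(1, round_half_up(self.s * self.alpha))


@dataclass(frozen=True)
class ParamDraw:
    mu: float
    b: float
    w_years: float
    rho: float
    r: float
    w_events: Optional[int] = None

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.b, self.w_years, self.rho, self.r])


def draw_priors(
    spec: PriorSpec, rng: np.random.Generator, eta_ref: Optional[int] = None
) -> ParamDraw:
    """One independent uniform draw of (mu, b, w_years, rho, r); if the
    reference phase's event count is supplied, the memory window is also
    converted to events."""
    mu = float(rng.uniform(*spec.mu_range))
    b = float(rng.uniform(*spec.b_range))
    w_years = float(rng.uniform(*spec.w_years_range))
    rho = float(rng.uniform(*spec.rho_range))
    r = float(rng.uniform(*spec.r_range))
    w_events = spec.w_events_from_years(w_years, eta_ref) if eta_ref else None
    return ParamDraw(mu, b, w_years, rho, r, w_events)


# ---------------------------------------------------------------------------
# error levels
# ---------------------------------------------------------------------------


def _check_phases(observed: pd.DataFrame, simulated: pd.DataFrame) -> None:
    if len(observed.index) != len(simulated.index) or list(observed.index) != list(
        simulated.index
    ):
        raise ValueError(
            "observed and simulated tables must cover the same phases "
            f"(got {list(observed.index)} vs {list(simulated.index)})"
        )


def distance_fully_matched(observed: pd.DataFrame, simulated: pd.DataFrame) -> float:
    """Euclidean distance over all (phase, type) cells; types present in only
    one table enter with zero counts in the other."""
    _check_phases(observed, simulated)
    cols = list(observed.columns) + [
        c for c in simulated.columns if c not in set(observed.columns)
    ]
    o = observed.reindex(columns=cols, fill_value=0).to_numpy(dtype=float)
    s = simulated.reindex(columns=cols, fill_value=0).to_numpy(dtype=float)
    return float(np.sqrt(((o - s) ** 2).sum()))


def distance_first_phase_matched(
    observed: pd.DataFrame,
    simulated: pd.DataFrame,
    first_phase_types: Optional[Sequence] = None,
) -> float:
    """Euclidean distance restricted to the types present in the observed
    first phase, across all phases of the tables."""
    _check_phases(observed, simulated)
    if first_phase_types is None:
        row0 = observed.iloc[0]
        first_phase_types = [c for c in observed.columns if row0[c] > 0]
    cols = list(first_phase_types)
    o = observed.reindex(columns=cols, fill_value=0).to_numpy(dtype=float)
    s = simulated.reindex(columns=cols, fill_value=0).to_numpy(dtype=float)
    return float(np.sqrt(((o - s) ** 2).sum()))


def _rank_order(row: np.ndarray) -> np.ndarray:
    """Indices of the strictly positive entries sorted by decreasing value;
    ties broken by stable (first-appearance) column order."""
    present = np.flatnonzero(row > 0)
    order = np.argsort(-row[present], kind="stable")
    return present[order]


def distance_rank_matched(observed: pd.DataFrame, simulated: pd.DataFrame) -> float:
    """Rank-match types at the first phase by relative frequency, track the
    matched types through all phases, and take the euclidean distance on
    relative frequencies.  Surplus simulated types are dropped; missing ones
    are padded as constant-zero series."""
    _check_phases(observed, simulated)
    o = observed.to_numpy(dtype=float)
    s = simulated.to_numpy(dtype=float)
    o_tot = o.sum(axis=1, keepdims=True)
    s_tot = s.sum(axis=1, keepdims=True)
    if o[0].sum() == 0 or s[0].sum() == 0:
        raise ValueError("the first phase must contain at least one variant")
    o_rel = np.divide(o, o_tot, out=np.zeros_like(o), where=o_tot > 0)
    s_rel = np.divide(s, s_tot, out=np.zeros_like(s), where=s_tot > 0)
    obs_rank = _rank_order(o_rel[0])
    sim_rank = _rank_order(s_rel[0])
    k_obs = obs_rank.size
    obs_cells = o_rel[:, obs_rank]  # phases x k_obs
    sim_cells = np.zeros_like(obs_cells)
    k = min(k_obs, sim_rank.size)
    sim_cells[:, :k] = s_rel[:, sim_rank[:k]]
    return float(np.sqrt(((obs_cells - sim_cells) ** 2).sum()))


# ---------------------------------------------------------------------------
# rejection sampling
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSample:
    """All draws of a rejection run with their error levels.

    ``values`` has one row per draw (columns ``param_names``); ``retained``
    flags the round(s*alpha) draws with the smallest eps (ties broken by
    draw index).  Failed simulations carry eps = +inf and are never
    retained.
    """

    param_names: Sequence[str]
    values: np.ndarray
    eps: np.ndarray
    retained: np.ndarray

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def n_failed(self) -> int:
        return int(np.isinf(self.eps).sum())

    def retained_values(self, parameter: str) -> np.ndarray:
        j = list(self.param_names).index(parameter)
        return self.values[self.retained, j]

    def retained_draws(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values[self.retained], columns=list(self.param_names)
        )
        df["eps"] = self.eps[self.retained]
        df.index = np.flatnonzero(self.retained)
        df.index.name = "draw"
        return df


def retain_smallest(eps: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean mask of the round(s*alpha) smallest error levels (ties broken
    by draw index, infinities never retained ahead of finite values)."""
    eps = np.asarray(eps, dtype=float)
    s = eps.size
    m = max(1, round_half_up(s * alpha))
    order = np.lexsort((np.arange(s), eps))
    mask = np.zeros(s, dtype=bool)
    mask[order[:m]] = True
    return mask


def _run_chunk(runner, seeds: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    thetas = np.empty((seeds.shape[0], len(runner.param_names)))
    eps = np.empty(seeds.shape[0])
    for i in range(seeds.shape[0]):
        try:
            th, e = runner.draw_and_simulate(int(seeds[i, 0]), int(seeds[i, 1]))
        except Exception:
            th = np.full(len(runner.param_names), np.nan)
            e = np.inf
        thetas[i] = th
        eps[i] = e
    return thetas, eps


def rejection_sample(
    runner,
    config: ABCConfig,
    seed: int,
    n_jobs: int = 1,
) -> PosteriorSample:
    """Run ``config.s`` independent prior-predictive simulations and retain
    the proportion ``alpha`` with the smallest error level.

    Every draw receives its own RNG substream derived from the master seed,
    so results are identical regardless of chunking or parallel execution;
    failed simulations are recorded with eps = +inf, never silently
    dropped.
    """
    s = int(config.s)
    root = np.random.SeedSequence(int(seed))
    seeds = root.generate_state(2 * s, dtype=np.uint32).reshape(s, 2)
    if n_jobs == 1:
        thetas, eps = _run_chunk(runner, seeds)
    else:
        n_chunks = max(1, min(s, 4 * n_jobs))
        bounds = np.linspace(0, s, n_chunks + 1).astype(int)
        results = Parallel(n_jobs=n_jobs)(
            delayed(_run_chunk)(runner, seeds[a:b])
            for a, b in zip(bounds[:-1], bounds[1:])
            if b > a
        )
        thetas = np.concatenate([t for t, _ in results])
        eps = np.concatenate([e for _, e in results])
    retained = retain_smallest(eps, config.alpha)
    return PosteriorSample(tuple(runner.param_names), thetas, eps, retained)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def hpdi(values: Sequence[float], level: float = 0.95) -> Tuple[float, float]:
    """Shortest contiguous interval containing ceil(level * n) of the sorted
    values; ties broken to the leftmost window."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n * level < 1:
        raise ValueError("n * level must be at least 1")
    m = min(n, int(math.ceil(level * n)))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def posterior_summary(
    sample: PosteriorSample, parameter: str, level: float = 0.95
) -> Tuple[float, float, float]:
    """Median and level-HPDI of one parameter over the retained draws."""
    vals = sample.retained_values(parameter)
    if vals.size < 2:
        raise ValueError("at least two retained draws are required")
    lo, hi = hpdi(vals, level)
    return float(np.median(vals)), lo, hi
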