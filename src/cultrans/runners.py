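"""Version-specific forward-simulation runners for the rejection loop.

A runner binds an observed count table, house counts and a prior
specification to one model version.  Its job per prior draw: derive the
per-phase population sizes ``N_i = round(n_i * r)``, event counts
``eta_i = round(N_i / (rho * H_i))`` and the production schedule, build the
initial pool, run the compiled event loop, draw the archaeological samples
and measure the error level.  Every draw is seeded explicitly so rejection
runs are reproducible under any chunking or parallel execution.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import _engine
from .assemblage import integerize, round_half_up
from .inference import PARAM_NAMES, PriorSpec, _rank_order
from .versions import dirichlet_counts

__all__ = [
    "EquilibriumRunner",
    "VariablePopulationRunner",
    "TransmissionModeRunner",
    "make_runner",
]


def _uniform_theta(priors: PriorSpec, rng: np.random.Generator) -> np.ndarray:
    return np.array(
        [
            rng.uniform(*priors.mu_range),
            rng.uniform(*priors.b_range),
            rng.uniform(*priors.w_years_range),
            rng.uniform(*priors.rho_range),
            rng.uniform(*priors.r_range),
        ]
    )


def _interp_schedules(
    H: np.ndarray,
    rho: float,
    N: np.ndarray,
    eta: np.ndarray,
) -> List[np.ndarray]:
    """Piecewise-linear rho*H interpolation at event positions, integerised
    to the exact phase totals (the fast twin of
    :func:`cultrans.assemblage.production_schedule`)."""
    mid = np.arange(H.size) + 0.5
    signal = rho * H
    out = []
    for i in range(N.size):
        pos = i + (np.arange(eta[i]) + 0.5) / eta[i]
        out.append(integerize(np.interp(pos, mid, signal), int(N[i])))
    return out


def _round_vec(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


class _BaseRunner:
    param_names: Sequence[str] = PARAM_NAMES

    def draw_and_simulate(self, seed_np: int, seed_kernel: int):
        rng = np.random.default_rng(int(seed_np))
        theta = _uniform_theta(self.priors, rng)
        cells = self._simulate_cells(theta, rng, int(seed_kernel))
        return theta, self._distance(cells)

    def simulate_cells(self, theta: np.ndarray, seed_np: int, seed_kernel: int):
        """Replicated values of the observed cells (used by the posterior
        predictive check); any unmatched novel-type tail is dropped."""
        rng = np.random.default_rng(int(seed_np))
        cells = self._simulate_cells(np.asarray(theta, dtype=float), rng, int(seed_kernel))
        return cells[: self.observed_cells.size]

    def _distance(self, cells: np.ndarray) -> float:
        d2 = float(((self.observed_cells - cells[: self.observed_cells.size]) ** 2).sum())
        if cells.size > self.observed_cells.size:  # unmatched simulated mass
            d2 += float((cells[self.observed_cells.size :] ** 2).sum())
        return float(np.sqrt(d2 + self._const_sq))

    _const_sq = 0.0


class EquilibriumRunner(_BaseRunner):
    """Equilibrium version: burn-in to stationarity, all phases simulated,
    rank-matched error level on relative frequencies."""

    def __init__(
        self,
        observed: pd.DataFrame,
        houses: Sequence[float],
        priors: PriorSpec,
        burn_in: int = 5000,
    ) -> None:
        self.priors = priors
        self.burn_in = int(burn_in)
        self.n = observed.sum(axis=1).to_numpy(dtype=np.int64)
        if (self.n <= 0).any():
            raise ValueError("every phase must contain at least one observation")
        self.H = np.asarray(houses, dtype=float)
        if self.H.size != self.n.size:
            raise ValueError("one house count per phase is required")
        obs = observed.to_numpy(dtype=float)
        obs_rel = obs / obs.sum(axis=1, keepdims=True)
        self._obs_rank = _rank_order(obs_rel[0])
        if self._obs_rank.size == 0:
            raise ValueError("the observed first phase is empty")
        self.k_obs = int(self._obs_rank.size)
        self.observed_cells = obs_rel[:, self._obs_rank].ravel()
        self.cell_labels = [
            (observed.index[p], observed.columns[t])
            for p in range(obs.shape[0])
            for t in self._obs_rank
        ]
        self.phase_ids = list(observed.index)

    def _simulate_cells(
        self, theta: np.ndarray, rng: np.random.Generator, seed_kernel: int
    ) -> np.ndarray:
        mu, b, w_years, rho, r = theta
        v = max(1, round_half_up(rho * float(self.H.mean())))
        N = np.maximum(_round_vec(self.n * r), self.n)
        eta = np.clip(_round_vec(N / v), 1, N)
        scheds = []
        for N_i, eta_i in zip(N, eta):
            sched = np.full(int(eta_i), v, dtype=np.int64)
            sched[-1] = int(N_i) - v * (int(eta_i) - 1)
            if sched[-1] < 1:
                sched = integerize(np.full(int(eta_i), float(v)), int(N_i))
            scheds.append(sched)
        w_events = self.priors.w_events_from_years(w_years, int(eta[0]))
        schedule = np.concatenate(
            [np.full(self.burn_in, v, dtype=np.int64)] + scheds
        )
        pop, _, ok = _engine.simulate_run(
            seed_kernel, b, mu, w_events, schedule, self.burn_in, eta,
            np.ones(v, dtype=np.int64), init_unmarked=False, v1_del=0,
        )
        if not ok:
            raise RuntimeError("simulation failed")
        n_phases = self.n.size
        sim_rel = np.empty((n_phases, pop.shape[1]))
        for i in range(n_phases):
            sample = rng.multivariate_hypergeometric(pop[i], int(self.n[i]))
            sim_rel[i] = sample / self.n[i]
        sim_rank = _rank_order(sim_rel[0])
        cells = np.zeros((n_phases, self.k_obs))
        k = min(self.k_obs, sim_rank.size)
        cells[:, :k] = sim_rel[:, sim_rank[:k]]
        return cells.ravel()


class VariablePopulationRunner(_BaseRunner):
    """Variable population version: demographic production schedule, pool
    seeded from the observed first phase and carried across the simulated
    phases; error level restricted to the first-phase types (absolute
    counts)."""

    def __init__(
        self,
        observed: pd.DataFrame,
        houses: Sequence[float],
        priors: PriorSpec,
        smoothing: float = 0.0,
    ) -> None:
        if observed.shape[0] < 2:
            raise ValueError("at least two phases are required")
        self.priors = priors
        self.smoothing = float(smoothing)
        n_all = observed.sum(axis=1).to_numpy(dtype=np.int64)
        H_all = np.asarray(houses, dtype=float)
        if H_all.size != n_all.size:
            raise ValueError("one house count per phase is required")
        if (n_all <= 0).any():
            raise ValueError("every phase must contain at least one observation")
        row0 = observed.iloc[0].to_numpy(dtype=float)
        self._seed_cols = np.flatnonzero(row0 > 0)
        if self._seed_cols.size == 0:
            raise ValueError("the observed first phase is empty")
        self.alpha = row0[self._seed_cols]
        self.K = int(self._seed_cols.size)
        self.n1 = int(n_all[0])
        self.H1 = float(H_all[0])
        self.n = n_all[1:]
        self.H = H_all[1:]
        self.H_all = H_all
        obs_mod = observed.iloc[1:].to_numpy(dtype=float)
        self.observed_cells = obs_mod[:, self._seed_cols].ravel()
        self.cell_labels = [
            (observed.index[p + 1], observed.columns[t])
            for p in range(self.n.size)
            for t in self._seed_cols
        ]
        self.phase_ids = list(observed.index[1:])
        self.seed_type_names = [observed.columns[t] for t in self._seed_cols]

    def _simulate_cells(
        self, theta: np.ndarray, rng: np.random.Generator, seed_kernel: int
    ) -> np.ndarray:
        mu, b, w_years, rho, r = theta
        N = np.maximum(_round_vec(self.n * r), self.n)
        vbar = np.maximum(_round_vec(rho * self.H), 1)
        eta = np.clip(_round_vec(N / vbar), 1, N)
        # the year->events conversion is anchored on the first (seeding) phase
        N1 = max(round_half_up(self.n1 * r), self.n1)
        eta1 = max(1, min(N1, round_half_up(N1 / max(1, round_half_up(rho * self.H1)))))
        w_events = self.priors.w_events_from_years(w_years, eta1)
        scheds = _interp_schedules(self.H, rho, N, eta)
        v1 = int(scheds[0][0])
        init = dirichlet_counts(
            self.alpha, w_events * v1, rng, smoothing=self.smoothing
        )
        pop, _, ok = _engine.simulate_run(
            seed_kernel, b, mu, w_events, np.concatenate(scheds), 0, eta,
            init, init_unmarked=True, v1_del=v1,
        )
        if not ok:
            raise RuntimeError("simulation failed")
        cells = np.empty((self.n.size, self.K))
        for i in range(self.n.size):
            sample = rng.multivariate_hypergeometric(pop[i], int(self.n[i]))
            cells[i] = sample[: self.K]
        return cells.ravel()


class TransmissionModeRunner(_BaseRunner):
    """One phase of the variable population-transmission mode version: pool
    re-seeded from the observed end of the previous phase, fully label-
    matched error level (absolute counts; unmatched novel mass enters as
    zeros on the other side)."""

    def __init__(
        self,
        observed: pd.DataFrame,
        houses: Sequence[float],
        priors: PriorSpec,
        phase_index: int,
        smoothing: float = 0.0,
    ) -> None:
        if not 1 <= phase_index < observed.shape[0]:
            raise ValueError("phase_index must have a predecessor phase")
        self.priors = priors
        self.smoothing = float(smoothing)
        self.phase_index = int(phase_index)
        H_all = np.asarray(houses, dtype=float)
        prev = observed.iloc[phase_index - 1].to_numpy(dtype=float)
        target = observed.iloc[phase_index].to_numpy(dtype=float)
        self._seed_cols = np.flatnonzero(prev > 0)
        if self._seed_cols.size == 0:
            raise ValueError(
                f"missing predecessor-phase counts for phase "
                f"{observed.index[phase_index]}"
            )
        self.alpha = prev[self._seed_cols]
        self.K = int(self._seed_cols.size)
        self.n_i = int(target.sum())
        if self.n_i <= 0:
            raise ValueError("the fitted phase must contain observations")
        self.H_i = float(H_all[phase_index])
        self.H_all = H_all
        self.observed_cells = target[self._seed_cols]
        # observed types with no predecessor label can only be mismatched
        only_obs = np.flatnonzero((prev == 0) & (target > 0))
        self._const_sq = float((target[only_obs] ** 2).sum())
        self.cell_labels = [
            (observed.index[phase_index], observed.columns[t])
            for t in self._seed_cols
        ]
        self.phase_id = observed.index[phase_index]
        self.seed_type_names = [observed.columns[t] for t in self._seed_cols]

    def _simulate_cells(
        self, theta: np.ndarray, rng: np.random.Generator, seed_kernel: int
    ) -> np.ndarray:
        mu, b, w_years, rho, r = theta
        N_i = max(round_half_up(self.n_i * r), self.n_i)
        vbar = max(1, round_half_up(rho * self.H_i))
        eta_i = max(1, min(N_i, round_half_up(N_i / vbar)))
        w_events = self.priors.w_events_from_years(w_years, eta_i)
        sched = _interp_schedules(
            np.array([self.H_i]), rho,
            np.array([N_i], dtype=np.int64), np.array([eta_i], dtype=np.int64),
        )[0]
        v1 = int(sched[0])
        init = dirichlet_counts(
            self.alpha, w_events * v1, rng, smoothing=self.smoothing
        )
        pop, _, ok = _engine.simulate_run(
            seed_kernel, b, mu, w_events, sched, 0,
            np.array([eta_i], dtype=np.int64), init,
            init_unmarked=True, v1_del=v1,
        )
        if not ok:
            raise RuntimeError("simulation failed")
        sample = rng.multivariate_hypergeometric(pop[0], self.n_i)
        # matched predecessor-type counts, then unmatched novel counts
        return np.concatenate([sample[: self.K], sample[self.K :]])


def make_runner(
    version: str,
    observed: pd.DataFrame,
    houses: Sequence[float],
    priors: PriorSpec,
    burn_in: int = 5000,
    smoothing: float = 0.0,
    phase_index: Optional[int] = None,
):
    if version == "equilibrium":
        return EquilibriumRunner(observed, houses, priors, burn_in=burn_in)
    if version == "variable_population":
        return VariablePopulationRunner(observed, houses, priors, smoothing=smoothing)
    if version == "variable_population_transmission":
        if phase_index is None:
            raise ValueError("phase_index is required for the per-phase version")
        return TransmissionModeRunner(
            observed, houses, priors, phase_index, smoothing=smoothing
        )
    raise ValueError(f"unknown version {version!r}")
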