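"""Synthetic observed datasets with known ground truth.

The default scenario emulates a Merzbach-like assemblage sequence at about
one fifth of its scale: eight ~20-year phases, per-phase sample sizes in
the low hundreds (rising then falling with the house counts), a few dozen
variant types with right-skewed abundances, and types appearing and going
extinct across phases.  The first phase is generated by the equilibrium
version (burn-in to innovation-drift stationarity); each subsequent phase
is generated by the non-equilibrium machinery seeded from the previous
phase's sample, which is exactly the data-generating process the
inference assumes.  The generator is a thin client of
:mod:`cultrans.versions`: it contains no transmission logic of its own.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd

from .assemblage import (
    Assemblage,
    DemographyParams,
    PhaseSpec,
    round_half_up,
    write_count_table,
    write_house_counts,
)
from .core import TransmissionParams
from .versions import (
    run_equilibrium,
    run_variable_population,
    run_variable_population_transmission,
)

__all__ = [
    "SyntheticScenario",
    "SyntheticDataset",
    "merzbach_like_scenario",
    "generate_dataset",
    "perturb_scenario",
]

_DEFAULT_N = (80, 120, 160, 200, 240, 200, 160, 140)
_DEFAULT_H = (8, 12, 16, 20, 24, 20, 16, 14)


@dataclass
class SyntheticScenario:
    """Ground-truth configuration for one synthetic dataset.

    ``b`` may be a scalar (constant transmission mode; the dataset is drawn
    from the variable population version) or one value per phase (the
    per-phase transmission-mode version; the first value also governs the
    equilibrium generation of the seeding phase).
    """

    n_phases: int = 8
    n_per_phase: Sequence[int] = _DEFAULT_N
    H_per_phase: Sequence[int] = _DEFAULT_H
    b: Union[float, Sequence[float]] = 0.0
    mu: float = 0.01
    w_years: float = 3.0
    rho: float = 2.0
    r: float = 2.0
    phase_duration_years: float = 20.0
    burn_in: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phases < 2:
            raise ValueError("at least two phases are required")
        if len(self.n_per_phase) != self.n_phases or len(self.H_per_phase) != self.n_phases:
            raise ValueError("n_per_phase and H_per_phase must have n_phases entries")
        if any(int(n) <= 0 for n in self.n_per_phase):
            raise ValueError("per-phase sample sizes must be positive")
        if any(int(h) <= 0 for h in self.H_per_phase):
            raise ValueError("house counts must be positive")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.r < 1.0:
            raise ValueError("r must be >= 1")
        if self.rho <= 0 or self.w_years <= 0:
            raise ValueError("rho and w_years must be positive")
        if not np.isscalar(self.b) and len(self.b) != self.n_phases:
            raise ValueError("per-phase b needs one value per phase")

    @property
    def phase_ids(self) -> List[str]:
        return [f"P{i + 1}" for i in range(self.n_phases)]

    def b_at(self, phase: int) -> float:
        return float(self.b) if np.isscalar(self.b) else float(self.b[phase])

    def truth(self) -> Dict[str, object]:
        d = dataclasses.asdict(self)
        d["n_per_phase"] = list(map(int, self.n_per_phase))
        d["H_per_phase"] = list(map(int, self.H_per_phase))
        d["b"] = float(self.b) if np.isscalar(self.b) else list(map(float, self.b))
        return d


@dataclass
class SyntheticDataset:
    counts: pd.DataFrame
    houses: pd.Series
    truth: Dict[str, object]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_count_table(self.counts, out / "counts.csv")
        write_house_counts(self.houses, out / "houses.csv")
        with open(out / "truth.txt", "w") as fh:
            for k in sorted(self.truth):
                fh.write(f"{k}={self.truth[k]}\n")


def merzbach_like_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """The default study scenario (~1/5 of the Merzbach assemblage scale)."""
    return SyntheticScenario(seed=seed, **overrides)


def perturb_scenario(base: SyntheticScenario, field_name: str, value) -> SyntheticScenario:
    """A modified copy of a scenario; unknown fields are rejected."""
    names = {f.name for f in dataclasses.fields(SyntheticScenario)}
    if field_name not in names:
        raise ValueError(f"unknown scenario field {field_name!r}")
    return dataclasses.replace(base, **{field_name: value})


def _w_events(scenario: SyntheticScenario, eta_ref: int) -> int:
    per_year = eta_ref / scenario.phase_duration_years
    return max(1, round_half_up(scenario.w_years * per_year))


def generate_dataset(
    scenario: SyntheticScenario, out_dir=None, backend: str = "kernel"
) -> SyntheticDataset:
    """Forward-run the model with the scenario's true parameters and return
    the observed count table, house counts and truth manifest.

    Rerunning with the same scenario (seed included) reproduces the files
    byte for byte.
    """
    rng = np.random.default_rng(int(scenario.seed))
    n = list(map(int, scenario.n_per_phase))
    H = np.asarray(scenario.H_per_phase, dtype=float)
    ids = scenario.phase_ids

    # --- seeding phase: equilibrium run of the first phase only ----------
    v1 = max(1, round_half_up(scenario.rho * float(H[0])))
    spec1 = PhaseSpec.build(ids[0], n[0], scenario.r, v1)
    w_seed = _w_events(scenario, spec1.eta_i)
    params1 = TransmissionParams(
        mu=scenario.mu, b=scenario.b_at(0), w_events=w_seed, v=v1
    )
    first = run_equilibrium(
        params1, [spec1], rng, burn_in=scenario.burn_in, backend=backend
    ).samples[0]

    samples: List[Assemblage] = [first]
    if np.isscalar(scenario.b):
        # constant transmission mode: one variable-population run seeded
        # from the first phase, pool carried across phases
        specs = _build_specs(scenario, n, H)
        params = TransmissionParams(
            mu=scenario.mu, b=float(scenario.b), w_events=w_seed, v=1
        )
        demog = DemographyParams(H_i=H[1:], rho=scenario.rho)
        run = run_variable_population(
            params, demog, first, specs, rng, backend=backend
        )
        samples.extend(run.samples)
    else:
        # per-phase transmission mode: each phase seeded from the previous
        # phase's generated sample
        specs = _build_specs(scenario, n, H)
        for i, spec in enumerate(specs):
            params_i = TransmissionParams(
                mu=scenario.mu,
                b=scenario.b_at(i + 1),
                w_events=_w_events(scenario, spec.eta_i),
                v=1,
            )
            demog_i = DemographyParams(H_i=H[i + 1 : i + 2], rho=scenario.rho)
            run = run_variable_population_transmission(
                [params_i], demog_i, [samples[-1]],
                [dataclasses.replace(spec, t_i=0)], rng, backend=backend,
            )
            samples.append(run.samples[0])

    counts = _to_table(samples, ids)
    houses = pd.Series(list(map(int, scenario.H_per_phase)), index=ids, name="H")
    houses.index.name = "phase"
    ds = SyntheticDataset(counts, houses, scenario.truth())
    if out_dir is not None:
        ds.write(out_dir)
    return ds


def _build_specs(
    scenario: SyntheticScenario, n: Sequence[int], H: np.ndarray
) -> List[PhaseSpec]:
    specs = []
    t = 0
    for i in range(1, scenario.n_phases):
        vbar = max(1.0, round_half_up(scenario.rho * float(H[i])))
        s = PhaseSpec.build(scenario.phase_ids[i], n[i], scenario.r, vbar, t_i=t)
        specs.append(s)
        t += s.eta_i
    return specs


def _to_table(samples: Sequence[Assemblage], ids: Sequence[str]) -> pd.DataFrame:
    """Combine per-phase samples into a named count table.

    Types are renamed T01, T02, ... ordered by first appearance and, within
    the first phase, by decreasing abundance — mirroring how an excavation
    catalogue numbers band types.
    """
    raw = pd.DataFrame.from_dict(
        {a.phase_id: a.variant_counts for a in samples}, orient="index"
    ).fillna(0).astype(int)
    raw = raw.loc[list(ids)]
    order: List = []
    seen = set()
    for _, row in raw.iterrows():
        present = row[row > 0]
        for t in present.sort_values(ascending=False, kind="stable").index:
            if t not in seen:
                seen.add(t)
                order.append(t)
    raw = raw[order]
    width = max(2, len(str(len(order))))
    raw.columns = [f"T{i + 1:0{width}d}" for i in range(len(order))]
    raw.index.name = "phase"
    return raw
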