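"""Model / Results facade over the simulation and inference machinery.

``CulturalTransmissionModel`` is built from an observed phase-by-type count
table and per-phase house counts; ``fit`` runs ABC rejection sampling and
returns a results object carrying the retained joint posterior, posterior
medians and 95% HPDIs, a ``summary()`` table, and posterior predictive
checks.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .assemblage import read_count_table, read_house_counts
from .inference import (
    ABCConfig,
    PosteriorSample,
    PriorSpec,
    hpdi,
    posterior_summary,
    rejection_sample,
)
from .ppc import PPCResult, posterior_predictive
from .runners import make_runner

__all__ = [
    "CulturalTransmissionModel",
    "CulturalTransmissionResults",
    "PhasewiseResults",
    "VERSIONS",
]

VERSIONS = {
    "equilibrium": "equilibrium",
    "variable_population": "variable_population",
    "varpop": "variable_population",
    "variable_population_transmission": "variable_population_transmission",
    "varpop-transmission": "variable_population_transmission",
}


class CulturalTransmissionModel:
    """Frequency-dependent transmission model for an assemblage sequence.

    Parameters
    ----------
    counts : DataFrame
        Observed counts, rows = phases in temporal order, columns = variant
        type names.
    houses : sequence or Series
        Number of houses per phase (same order as ``counts``); together
        with the potters-per-household factor rho it sets the production
        sizes.
    version : str
        ``"equilibrium"``, ``"variable_population"`` or
        ``"variable_population_transmission"``.
    priors : PriorSpec, optional
    burn_in : int
        Burn-in production events for the equilibrium version.
    smoothing : float
        Additive smoothing of the Dirichlet concentration used to
        reconstruct initial pools (0 = raw observed counts).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        houses,
        version: str = "variable_population",
        priors: Optional[PriorSpec] = None,
        burn_in: int = 5000,
        smoothing: float = 0.0,
    ) -> None:
        if version not in VERSIONS:
            raise ValueError(f"unknown version {version!r}")
        self.version = VERSIONS[version]
        self.counts = counts.fillna(0).astype(int)
        if isinstance(houses, pd.Series):
            houses = houses.reindex(self.counts.index).to_numpy()
        self.houses = np.asarray(houses, dtype=float)
        if self.houses.size != self.counts.shape[0]:
            raise ValueError("one house count per phase is required")
        self.priors = priors if priors is not None else PriorSpec()
        self.burn_in = int(burn_in)
        self.smoothing = float(smoothing)
        if not self.priors.check_innovation_feasibility(self.counts):
            warnings.warn(
                "the innovation-rate prior can barely mint the number of "
                "variant types appearing after the first phase; consider "
                "raising mu_range",
                stacklevel=2,
            )

    @classmethod
    def from_csv(cls, counts_csv, houses_csv, **kwargs) -> "CulturalTransmissionModel":
        return cls(read_count_table(counts_csv), read_house_counts(houses_csv), **kwargs)

    # ------------------------------------------------------------------

    def _runner(self, phase_index: Optional[int] = None):
        return make_runner(
            self.version,
            self.counts,
            self.houses,
            self.priors,
            burn_in=self.burn_in,
            smoothing=self.smoothing,
            phase_index=phase_index,
        )

    def fit(
        self,
        s: int = 50_000,
        alpha: float = 0.004,
        seed: int = 0,
        n_jobs: int = 1,
    ) -> Union["CulturalTransmissionResults", "PhasewiseResults"]:
        """ABC rejection fit: ``s`` prior-predictive simulations, retaining
        the proportion ``alpha`` with the smallest error level.

        The transmission-mode version fits each phase independently and
        returns :class:`PhasewiseResults`.
        """
        config = ABCConfig(s=int(s), alpha=float(alpha), distance_mode=self.version)
        if self.version == "variable_population_transmission":
            phase_results = {}
            root = np.random.SeedSequence(int(seed))
            phase_seeds = root.generate_state(self.counts.shape[0], dtype=np.uint32)
            for i in range(1, self.counts.shape[0]):
                runner = self._runner(phase_index=i)
                post = rejection_sample(
                    runner, config, int(phase_seeds[i - 1]), n_jobs=n_jobs
                )
                phase_results[self.counts.index[i]] = CulturalTransmissionResults(
                    self, post, config, int(seed), runner=runner
                )
            return PhasewiseResults(self, phase_results, config, int(seed))
        runner = self._runner()
        post = rejection_sample(runner, config, int(seed), n_jobs=n_jobs)
        return CulturalTransmissionResults(self, post, config, int(seed), runner=runner)


class CulturalTransmissionResults:
    """Joint ABC posterior for one model version (one phase for the
    per-phase version)."""

    def __init__(
        self,
        model: CulturalTransmissionModel,
        posterior: PosteriorSample,
        config: ABCConfig,
        seed: int,
        runner=None,
    ) -> None:
        self.model = model
        self.posterior = posterior
        self.config = config
        self.seed = int(seed)
        self._runner = runner

    # -- point and interval estimates ----------------------------------

    @property
    def param_names(self) -> Sequence[str]:
        return self.posterior.param_names

    @property
    def median(self) -> pd.Series:
        return pd.Series(
            {p: posterior_summary(self.posterior, p)[0] for p in self.param_names},
            name="median",
        )

    def hpdi(self, level: float = 0.95) -> pd.DataFrame:
        rows = {}
        for p in self.param_names:
            lo, hi = hpdi(self.posterior.retained_values(p), level)
            rows[p] = {"hpdi_low": lo, "hpdi_high": hi}
        return pd.DataFrame.from_dict(rows, orient="index")

    def summary_frame(self, level: float = 0.95) -> pd.DataFrame:
        med = self.median
        ci = self.hpdi(level)
        out = ci.copy()
        out.insert(0, "median", med)
        out.index.name = "parameter"
        return out

    def summary(self, level: float = 0.95) -> str:
        eps = self.posterior.eps[self.posterior.retained]
        lines = [
            "ABC rejection fit: frequency-dependent cultural transmission",
            f"  version:  {self.model.version}",
            f"  draws s:  {self.config.s}    retained: {self.posterior.n_retained}"
            f" (alpha={self.config.alpha:g})    failed: {self.posterior.n_failed}",
            f"  error level eps of retained draws: median {np.median(eps):.4g}, "
            f"max {eps.max():.4g}",
            "",
            self.summary_frame(level).to_string(float_format=lambda x: f"{x:.4f}"),
            "",
            f"(intervals are {level:.0%} highest posterior density intervals)",
        ]
        return "\n".join(lines)

    def retained_draws(self) -> pd.DataFrame:
        return self.posterior.retained_draws()

    # -- posterior predictive ------------------------------------------

    def posterior_predictive(
        self, n_reps: int = 1000, level: float = 0.95, seed: int = 0
    ) -> PPCResult:
        if self._runner is None:
            raise ValueError("results object has no attached runner")
        return posterior_predictive(
            self.posterior, self._runner, n_reps=n_reps, level=level, seed=seed
        )

    # -- persistence ----------------------------------------------------

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.retained_draws().to_csv(out / "retained.csv")
        self.summary_frame().to_csv(out / "summary.csv")


class PhasewiseResults:
    """Per-phase posteriors of the variable population-transmission mode
    version (each phase fitted independently)."""

    def __init__(
        self,
        model: CulturalTransmissionModel,
        phase_results: Dict,
        config: ABCConfig,
        seed: int,
    ) -> None:
        self.model = model
        self.phase_results = phase_results
        self.config = config
        self.seed = int(seed)

    @property
    def phases(self) -> List:
        return list(self.phase_results)

    def summary_frame(self, level: float = 0.95) -> pd.DataFrame:
        frames = []
        for phase, res in self.phase_results.items():
            f = res.summary_frame(level).reset_index()
            f.insert(0, "phase", phase)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def summary(self, level: float = 0.95) -> str:
        df = self.summary_frame(level)
        b = df[df["parameter"] == "b"].set_index("phase")
        lines = [
            "ABC rejection fit: per-phase transmission mode",
            f"  version:  {self.model.version}",
            f"  draws s:  {self.config.s} per phase    retained: "
            f"{self.config.n_retained} per phase (alpha={self.config.alpha:g})",
            "",
            "  frequency-dependence b by phase:",
            b[["median", "hpdi_low", "hpdi_high"]].to_string(
                float_format=lambda x: f"{x:.4f}"
            ),
            "",
            f"(intervals are {level:.0%} highest posterior density intervals)",
        ]
        return "\n".join(lines)

    def posterior_predictive(
        self, n_reps: int = 1000, level: float = 0.95, seed: int = 0
    ) -> PPCResult:
        """Concatenated bands of the independent per-phase checks."""
        root = np.random.SeedSequence(int(seed))
        seeds = root.generate_state(len(self.phase_results), dtype=np.uint32)
        parts = []
        n_reps_total = 0
        for sd, (phase, res) in zip(seeds, self.phase_results.items()):
            r = res.posterior_predictive(n_reps=n_reps, level=level, seed=int(sd))
            parts.append(r.bands)
            n_reps_total = r.n_reps
        bands = pd.concat(parts, ignore_index=True)
        return PPCResult(bands, float(level), n_reps_total)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frames = []
        for phase, res in self.phase_results.items():
            f = res.retained_draws().reset_index()
            f.insert(0, "phase", phase)
            frames.append(f)
        pd.concat(frames, ignore_index=True).to_csv(out / "retained.csv", index=False)
        self.summary_frame().to_csv(out / "summary.csv", index=False)
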