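"""Posterior predictive checks.

Joint parameter vectors are resampled (with replacement) from the retained
ABC draws — never marginally, so parameter correlations are preserved — the
model is re-run for each, and the central ``level`` interval of every
(phase, type) frequency cell is compared with the observed value.  Cells
whose observed frequency falls outside the interval flag variant types
whose temporal evolution the fitted transmission process cannot reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .inference import PosteriorSample

__all__ = ["PredictiveBand", "PPCResult", "posterior_predictive"]


@dataclass(frozen=True)
class PredictiveBand:
    """Prediction interval for one (phase, variant type) cell."""

    phase_id: object
    variant_type: object
    low: float
    high: float
    observed: float

    @property
    def inside(self) -> bool:
        return bool(self.low <= self.observed <= self.high)


@dataclass
class PPCResult:
    """Band table plus the raw replicated cell values."""

    bands: pd.DataFrame
    level: float
    n_reps: int
    reps: Optional[np.ndarray] = None

    @property
    def inside_fraction(self) -> float:
        return float(self.bands["inside"].mean())

    def outliers(self) -> pd.DataFrame:
        return self.bands[~self.bands["inside"]]

    def to_band_list(self) -> List[PredictiveBand]:
        return [
            PredictiveBand(r.phase, r.variant_type, r.low, r.high, r.observed)
            for r in self.bands.itertuples(index=False)
        ]

    def plot(self, phase_id=None, ax=None):
        """Observed frequencies (dots) against predicted ranges (bars);
        observations outside their band are drawn in red."""
        import matplotlib.pyplot as plt

        df = self.bands
        if phase_id is not None:
            df = df[df["phase"] == phase_id]
        if ax is None:
            _, ax = plt.subplots(figsize=(max(4, 0.35 * len(df)), 4))
        x = np.arange(len(df))
        ax.vlines(x, df["low"], df["high"], color="0.6", lw=3, label="predicted range")
        colors = np.where(df["inside"], "black", "red")
        ax.scatter(x, df["observed"], c=colors, zorder=3, s=18, label="observed")
        labels = [
            f"{p}:{t}" if phase_id is None else str(t)
            for p, t in zip(df["phase"], df["variant_type"])
        ]
        ax.set_xticks(x)
        ax.set_xticklabels(labels, rotation=90, fontsize=7)
        ax.set_ylabel("frequency")
        title = f"posterior predictive check ({self.level:.0%} range)"
        if phase_id is not None:
            title += f", phase {phase_id}"
        ax.set_title(title)
        return ax


def posterior_predictive(
    sample: PosteriorSample,
    runner,
    n_reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> PPCResult:
    """Generate predicted frequency ranges for every observed cell.

    ``runner`` must expose ``simulate_cells``, ``observed_cells`` and
    ``cell_labels`` (any runner from :mod:`cultrans.runners`).  Intervals
    are central (equal-tailed) ``level`` quantile ranges over the
    replicated cell values; failed replications are dropped from the
    quantiles.
    """
    if sample.n_retained == 0:
        raise ValueError("the posterior sample has no retained draws")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    n_reps = int(n_reps)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    retained = sample.values[sample.retained]
    root = np.random.SeedSequence(int(seed))
    state = root.generate_state(2 * n_reps + 1, dtype=np.uint32)
    pick = np.random.default_rng(int(state[-1])).integers(
        0, retained.shape[0], size=n_reps
    )
    n_cells = len(runner.observed_cells)
    reps = np.full((n_reps, n_cells), np.nan)
    for j in range(n_reps):
        theta = retained[pick[j]]
        try:
            reps[j] = runner.simulate_cells(theta, int(state[2 * j]), int(state[2 * j + 1]))
        except Exception:
            pass  # failed replication: stays NaN, excluded from quantiles
    lo_q = (1.0 - level) / 2.0
    with np.errstate(all="ignore"):
        low = np.nanquantile(reps, lo_q, axis=0)
        high = np.nanquantile(reps, 1.0 - lo_q, axis=0)
    obs = np.asarray(runner.observed_cells, dtype=float)
    bands = pd.DataFrame(
        {
            "phase": [p for p, _ in runner.cell_labels],
            "variant_type": [t for _, t in runner.cell_labels],
            "low": low,
            "high": high,
            "observed": obs,
        }
    )
    bands["inside"] = (bands["low"] <= bands["observed"]) & (
        bands["observed"] <= bands["high"]
    )
    return PPCResult(bands, float(level), n_reps, reps=reps)
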