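"""Priors, error levels, rejection retention and posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cultrans.inference import (
    ABCConfig,
    PosteriorSample,
    PriorSpec,
    distance_first_phase_matched,
    distance_fully_matched,
    distance_rank_matched,
    draw_priors,
    hpdi,
    posterior_summary,
    rejection_sample,
    retain_smallest,
)


def _table(data, phases):
    return pd.DataFrame(data, index=pd.Index(phases, name="phase"))


class TestPriors:
    def test_degenerate_intervals_are_deterministic(self, rng):
        spec = PriorSpec(
            mu_range=(0.01, 0.01), b_range=(0.2, 0.2), w_years_range=(1, 1),
            rho_range=(2, 2), r_range=(3, 3),
        )
        d = draw_priors(spec, rng)
        assert (d.mu, d.b, d.w_years, d.rho, d.r) == (0.01, 0.2, 1.0, 2.0, 3.0)

    def test_year_to_event_conversion(self, rng):
        spec = PriorSpec(w_years_range=(1, 1), phase_duration_years=20.0)
        d = draw_priors(spec, rng, eta_ref=200)
        assert d.w_events == 10
        assert spec.w_events_from_years(0.01, 200) == 1  # floor at one event

    def test_uniform_mean_recovered(self, rng):
        spec = PriorSpec(mu_range=(0.01, 0.03))
        draws = np.array([draw_priors(spec, rng).mu for _ in range(10_000)])
        se = (0.03 - 0.01) / np.sqrt(12 * 10_000)
        assert abs(draws.mean() - 0.02) < 3 * se

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(mu_range=(0.5, 0.1))
        with pytest.raises(ValueError):
            PriorSpec(r_range=(0.5, 2.0))

    def test_innovation_feasibility_check(self):
        obs = _table({"A": [10, 10], "B": [0, 40]}, ["P1", "P2"])
        assert PriorSpec(mu_range=(0.01, 0.05)).check_innovation_feasibility(obs)
        tight = PriorSpec(mu_range=(1e-6, 1e-5))
        assert not tight.check_innovation_feasibility(obs)


class TestDistances:
    def test_all_modes_vanish_on_self_comparison(self, toy_counts):
        for dist in (
            distance_fully_matched,
            distance_first_phase_matched,
            distance_rank_matched,
        ):
            assert dist(toy_counts, toy_counts.copy()) == 0.0

    def test_fully_matched_disjoint_types(self):
        obs = _table({"A": [10], "B": [0]}, ["P1"])
        sim = _table({"A": [0], "B": [10]}, ["P1"])
        assert distance_fully_matched(obs, sim) == pytest.approx(np.sqrt(200))

    def test_fully_matched_single_cell_difference(self, toy_counts):
        sim = toy_counts.copy()
        sim.loc["P2", "B"] += 7
        assert distance_fully_matched(toy_counts, sim) == pytest.approx(7.0)

    def test_fully_matched_unmatched_types_count_as_zeros(self, toy_counts):
        sim = toy_counts.copy()
        sim["new1"] = [0, 4]
        assert distance_fully_matched(toy_counts, sim) == pytest.approx(4.0)

    def test_first_phase_matched_ignores_late_types(self):
        obs = _table({"A": [30, 20], "B": [20, 25], "C": [0, 5]}, ["P1", "P2"])
        sim = obs.copy()
        sim.loc["P2", "C"] = 50  # C is absent from phase 1: not tracked
        assert distance_first_phase_matched(obs, sim) == 0.0

    def test_first_phase_matched_hand_value(self):
        obs = _table({"A": [10, 10], "B": [5, 5]}, ["P1", "P2"])
        sim = obs.copy()
        sim["A"] = [13, 13]  # one first-phase type off by 3 in each phase
        assert distance_first_phase_matched(obs, sim) == pytest.approx(np.sqrt(18))

    def test_rank_matched_invariant_to_consistent_relabelling(self):
        obs = _table({"A": [12, 6], "B": [8, 14]}, ["P1", "P2"])
        sim = _table({"x": [8, 14], "y": [12, 6]}, ["P1", "P2"])
        # y matches A (both rank 1 at phase 1), x matches B
        assert distance_rank_matched(obs, sim) == 0.0

    def test_rank_matched_hand_value(self):
        obs = _table({"A": [6], "B": [4]}, ["P1"])
        sim = _table({"x": [7], "y": [3]}, ["P1"])
        assert distance_rank_matched(obs, sim) == pytest.approx(np.sqrt(0.02))

    def test_rank_matched_zero_padding(self):
        # simulated richness 1 < observed 2: the missing series is a
        # constant zero, giving sqrt(4 * 0.16) = 0.8 over two phases
        obs = _table({"A": [6, 6], "B": [4, 4]}, ["P1", "P2"])
        sim = _table({"x": [10, 10]}, ["P1", "P2"])
        assert distance_rank_matched(obs, sim) == pytest.approx(0.8)

    def test_rank_matched_truncates_surplus_simulated_types(self):
        obs = _table({"A": [10]}, ["P1"])
        sim = _table({"x": [8], "y": [2]}, ["P1"])
        # only the largest simulated frequency is kept: |1.0 - 0.8|
        assert distance_rank_matched(obs, sim) == pytest.approx(0.2)

    def test_phase_mismatch_rejected(self, toy_counts):
        sim = toy_counts.iloc[:1]
        for dist in (
            distance_fully_matched,
            distance_first_phase_matched,
            distance_rank_matched,
        ):
            with pytest.raises(ValueError, match="phase"):
                dist(toy_counts, sim)

    @given(
        st.lists(st.integers(0, 30), min_size=4, max_size=4),
        st.lists(st.integers(0, 30), min_size=4, max_size=4),
    )
    def test_fully_matched_nonnegative_and_faithful(self, a, b):
        obs = _table({"A": a[:2], "B": a[2:]}, ["P1", "P2"])
        sim = _table({"A": b[:2], "B": b[2:]}, ["P1", "P2"])
        d = distance_fully_matched(obs, sim)
        assert d >= 0
        assert (d == 0) == (a == b)


class TestRejection:
    class _StubRunner:
        """Runner whose eps values are a known function of the draw seed."""

        param_names = ("mu", "b", "w_years", "rho", "r")

        def draw_and_simulate(self, seed_np, seed_kernel):
            rng = np.random.default_rng(seed_np)
            theta = rng.uniform(size=5)
            return theta, float(np.random.default_rng(seed_kernel).uniform())

    def test_retained_set_matches_sort_oracle(self):
        eps = np.random.default_rng(0).uniform(size=1000)
        eps[::100] = eps[0]  # inject ties
        mask = retain_smallest(eps, 0.05)
        m = 50
        oracle = sorted(range(1000), key=lambda i: (eps[i], i))[:m]
        assert sorted(np.flatnonzero(mask)) == sorted(oracle)
        assert mask.sum() == m

    def test_alpha_one_percent_of_100_keeps_single_minimum(self):
        runner = self._StubRunner()
        post = rejection_sample(runner, ABCConfig(s=100, alpha=0.01), seed=3)
        assert post.n_retained == 1
        assert post.eps[post.retained][0] == post.eps.min()

    def test_parallel_execution_is_identical_to_serial(self):
        runner = self._StubRunner()
        cfg = ABCConfig(s=200, alpha=0.05)
        serial = rejection_sample(runner, cfg, seed=9, n_jobs=1)
        parallel = rejection_sample(runner, cfg, seed=9, n_jobs=2)
        assert np.array_equal(serial.eps, parallel.eps)
        assert np.array_equal(serial.values, parallel.values)
        assert np.array_equal(serial.retained, parallel.retained)

    def test_failed_draws_get_infinite_eps(self):
        class Failing(self._StubRunner):
            def draw_and_simulate(self, seed_np, seed_kernel):
                if seed_np % 2 == 0:
                    raise RuntimeError("boom")
                return super().draw_and_simulate(seed_np, seed_kernel)

        post = rejection_sample(Failing(), ABCConfig(s=50, alpha=0.1), seed=1)
        assert post.n_failed > 0
        assert np.isfinite(post.eps[post.retained]).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ABCConfig(s=10, alpha=0.001)
        assert ABCConfig(s=10_000_000, alpha=2e-5).n_retained == 200


def _hpdi_oracle(values, level):
    """Exhaustive search over all contiguous sorted windows."""
    x = np.sort(values)
    n = x.size
    m = int(np.ceil(level * n))
    best = None
    for i in range(n - m + 1):
        w = x[i + m - 1] - x[i]
        if best is None or w < best[0]:
            best = (w, x[i], x[i + m - 1])
    return best[1], best[2]


class TestPosteriorSummary:
    def _sample(self, values):
        v = np.asarray(values, dtype=float)
        vals = np.column_stack([v] * 5)
        return PosteriorSample(
            ("mu", "b", "w_years", "rho", "r"), vals, np.zeros(v.size),
            np.ones(v.size, dtype=bool),
        )

    def test_outlier_resistant_window(self):
        lo, hi = hpdi([1, 2, 3, 4, 100], level=0.8)
        assert (lo, hi) == (1, 4)

    def test_degenerate_sample(self):
        med, lo, hi = posterior_summary(self._sample([5.0] * 10), "b")
        assert (med, lo, hi) == (5.0, 5.0, 5.0)

    def test_leftmost_tie_breaking(self):
        lo, hi = hpdi([-2, -1, 0, 1, 2], level=0.6)
        assert (lo, hi) == (-2, 0)

    def test_median_of_symmetric_sample(self):
        med, _, _ = posterior_summary(self._sample([-2, -1, 0, 1, 2]), "b", level=0.6)
        assert med == 0.0

    def test_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            x = rng.gamma(2.0, 1.0, size=500) * rng.choice([-1, 1])
            for level in (0.5, 0.9, 0.95):
                assert hpdi(x, level) == _hpdi_oracle(x, level)

    def test_insufficient_mass_rejected(self):
        with pytest.raises(ValueError):
            hpdi([1.0, 2.0], level=0.3)

    def test_agrees_with_arviz_hdi(self):
        """Independent cross-check against arviz's shortest-interval HDI
        (conventions differ by at most one sample point)."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(8)
        for dist in (rng.normal(size=2000), rng.gamma(2.0, 1.0, size=2000)):
            ours = np.array(hpdi(dist, 0.94))
            theirs = az.hdi(dist, hdi_prob=0.94)
            assert np.abs(ours - theirs).max() < 0.05
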