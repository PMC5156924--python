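"""The three generative regimes: seeding, chaining, reductions and the
agreement between the compiled kernel and the reference implementation."""

import numpy as np
import pytest

from cultrans.assemblage import DemographyParams, PhaseSpec
from cultrans.core import SamplingPool, TransmissionParams, advance_pool
from cultrans.versions import (
    dirichlet_initial_pool,
    run_equilibrium,
    run_variable_population,
    run_variable_population_transmission,
)


def _specs(ns, r, v, ids=None):
    specs, t = [], 0
    for i, n in enumerate(ns):
        s = PhaseSpec.build(ids[i] if ids else f"P{i+1}", n, r, v, t_i=t)
        specs.append(s)
        t += s.eta_i
    return specs


class TestDirichletInitialPool:
    def test_monotypic_observation_gives_monotypic_pool(self, rng):
        pool = dirichlet_initial_pool({"A": 40}, w_events=3, v1=5, rng=rng)
        assert pool.counts() == {"A": 15}

    def test_every_observed_type_present_in_every_pool(self, rng):
        obs = {"A": 50, "B": 50, "C": 2}
        a_counts = []
        for _ in range(100):
            pool = dirichlet_initial_pool(obs, w_events=10, v1=10, rng=rng)
            counts = pool.counts()
            assert set(counts) == {"A", "B", "C"}
            assert sum(counts.values()) == 100
            a_counts.append(counts["A"])
        # Dirichlet-multinomial mean for A is ~49 of 100
        assert 35 <= np.mean(a_counts) <= 65

    def test_minimal_pool_is_one_token_per_type(self, rng):
        pool = dirichlet_initial_pool({"A": 9, "B": 1, "C": 1}, w_events=1, v1=3, rng=rng)
        assert pool.counts() == {"A": 1, "B": 1, "C": 1}

    def test_infeasible_pool_size_raises(self, rng):
        with pytest.raises(ValueError, match="cannot contain"):
            dirichlet_initial_pool({"A": 1, "B": 1, "C": 1}, w_events=1, v1=2, rng=rng)


class TestEquilibrium:
    def test_no_innovation_drifts_to_few_types(self, rng):
        params = TransmissionParams(mu=0.0, b=0.0, w_events=5, v=4)
        specs = _specs([20, 20], r=2.0, v=4)
        run = run_equilibrium(params, specs, rng, burn_in=2000)
        for sample in run.samples:
            assert len(sample.variant_counts) <= 4
        # unbiased drift without innovation fixes a single type long before
        # a 2,000-event burn-in ends
        assert len(run.samples[0].variant_counts) == 1

    def test_pure_innovation_gives_all_singletons(self, rng):
        params = TransmissionParams(mu=1.0, b=0.0, w_events=5, v=4)
        specs = _specs([15], r=1.0, v=4)
        run = run_equilibrium(params, specs, rng, burn_in=50)
        counts = run.samples[0].variant_counts
        assert sum(counts.values()) == 15
        assert set(counts.values()) == {1}

    def test_sample_sizes_match_specs(self, rng):
        params = TransmissionParams(mu=0.02, b=-0.2, w_events=8, v=5)
        specs = _specs([30, 45, 20], r=1.5, v=5)
        run = run_equilibrium(params, specs, rng, burn_in=500, keep_populations=True)
        for spec, sample, popn in zip(specs, run.samples, run.populations):
            assert sample.total == spec.n_i
            assert popn.total == spec.N_i

    def test_richness_increases_with_innovation_rate(self):
        params_lo = TransmissionParams(mu=0.01, b=0.0, w_events=10, v=10)
        params_hi = TransmissionParams(mu=0.05, b=0.0, w_events=10, v=10)
        specs = _specs([50], r=1.0, v=10)
        rich = {}
        for key, params in [("lo", params_lo), ("hi", params_hi)]:
            rng = np.random.default_rng(7)
            rich[key] = np.mean(
                [
                    len(run_equilibrium(params, specs, rng, burn_in=300).samples[0].variant_counts)
                    for _ in range(200)
                ]
            )
        assert rich["hi"] > rich["lo"]


class TestVariablePopulation:
    def _demog(self, H):
        return DemographyParams(H_i=np.asarray(H, dtype=float), rho=1.0)

    def test_monotypic_seed_without_innovation_stays_monotypic(self, rng):
        params = TransmissionParams(mu=0.0, b=0.4, w_events=3, v=1)
        specs = _specs([20, 20], r=2.0, v=10)
        run = run_variable_population(
            params, self._demog([10, 10]), {"A": 30}, specs, rng
        )
        for sample in run.samples:
            assert set(sample.variant_counts) <= {"A"}

    def test_same_seed_reproduces_sample_counts_exactly(self):
        params = TransmissionParams(mu=0.03, b=0.2, w_events=4, v=1)
        specs = _specs([25, 30], r=2.0, v=8)
        obs = {"A": 20, "B": 10}
        tables = []
        for _ in range(2):
            rng = np.random.default_rng(4242)
            run = run_variable_population(
                params, self._demog([8, 8]), obs, specs, rng
            )
            tables.append(run.sample_table())
        assert tables[0].equals(tables[1])

    def test_no_innovation_never_creates_types(self, rng):
        params = TransmissionParams(mu=0.0, b=0.0, w_events=4, v=1)
        specs = _specs([30, 30, 30], r=1.5, v=6)
        run = run_variable_population(
            params, self._demog([6, 6, 6]), {"A": 10, "B": 5, "C": 1}, specs, rng
        )
        for sample in run.samples:
            assert set(sample.variant_counts) <= {"A", "B", "C"}


class TestTransmissionModeVersion:
    def test_pure_innovation_phase_has_only_new_types(self, rng):
        params = [TransmissionParams(mu=1.0, b=0.0, w_events=3, v=1)]
        specs = _specs([20], r=2.0, v=8)
        run = run_variable_population_transmission(
            params, DemographyParams(H_i=[8.0], rho=1.0), [{"A": 30, "B": 10}],
            specs, rng,
        )
        assert not set(run.samples[0].variant_counts) & {"A", "B"}

    def test_missing_predecessor_counts_rejected(self, rng):
        params = [TransmissionParams(mu=0.1, b=0.0, w_events=3, v=1)] * 2
        specs = _specs([20, 20], r=2.0, v=8)
        with pytest.raises(ValueError, match="predecessor"):
            run_variable_population_transmission(
                params, DemographyParams(H_i=[8.0, 8.0], rho=1.0),
                [{"A": 30}], specs, rng,
            )

    def test_chained_tied_params_reduce_to_variable_population(self):
        """Version 3 with tied parameters and chained pools equals version 2
        under the same seed (reference backend)."""
        params = TransmissionParams(mu=0.05, b=0.1, w_events=3, v=1)
        specs = _specs([20, 24], r=2.0, v=8)
        demog = DemographyParams(H_i=np.array([8.0, 8.0]), rho=1.0)
        obs = {"A": 25, "B": 15}

        t2 = run_variable_population(
            params, demog, obs, specs, np.random.default_rng(77),
            backend="reference",
        ).sample_table()
        t3 = run_variable_population_transmission(
            [params, params], demog, [obs, obs], specs,
            np.random.default_rng(77), backend="reference", chain_pools=True,
        ).sample_table()
        assert t2.equals(t3)

    def test_equilibrium_without_burnin_reduces_to_variable_population(self):
        """With a constant demographic schedule and a shared stamped pool,
        version 1 without burn-in and version 2 follow identical
        trajectories under the same seed."""
        params = TransmissionParams(mu=0.05, b=-0.2, w_events=3, v=8)
        specs = _specs([20, 24], r=2.0, v=8)
        demog = DemographyParams(H_i=np.array([8.0, 8.0]), rho=1.0)

        def stamped_pool():
            pool = SamplingPool(3)
            advance_pool(pool, ["A"] * 5 + ["B"] * 3, 0)
            return pool

        t1 = run_equilibrium(
            params, specs, np.random.default_rng(5), burn_in=0,
            backend="reference", initial_pool=stamped_pool(),
        ).sample_table()
        t2 = run_variable_population(
            params, demog, {"A": 5, "B": 3}, specs, np.random.default_rng(5),
            backend="reference", initial_pool=stamped_pool(),
        ).sample_table()
        assert t1.equals(t2)

    def test_per_phase_anticonformity_lifts_rare_types(self):
        """Paired comparison against b=0: anti-conformity (b>0) raises the
        mean relative frequency of the initially rare type."""
        obs = {"common": 32, "rare": 8}
        specs = _specs([40], r=1.0, v=8)
        demog = DemographyParams(H_i=[8.0], rho=1.0)
        means = {}
        for key, b in [("anti", 0.8), ("neutral", 0.0)]:
            params = [TransmissionParams(mu=0.0, b=b, w_events=3, v=1)]
            rng = np.random.default_rng(3)
            vals = []
            for _ in range(300):
                run = run_variable_population_transmission(
                    params, demog, [obs], specs, rng
                )
                vals.append(run.samples[0].variant_counts.get("rare", 0) / 40)
            means[key] = np.mean(vals)
        assert means["anti"] > means["neutral"] + 0.02


class TestBackendAgreement:
    def test_kernel_and_reference_backends_agree_statistically(self):
        """Mean richness and mean top-type share of the two implementations
        agree within Monte-Carlo tolerance."""
        params = TransmissionParams(mu=0.03, b=0.15, w_events=3, v=1)
        specs = _specs([25, 30], r=2.0, v=8)
        demog = DemographyParams(H_i=np.array([8.0, 8.0]), rho=1.0)
        obs = {"A": 20, "B": 12, "C": 4}
        stats = {}
        n_rep = 250
        for backend in ("kernel", "reference"):
            rng = np.random.default_rng(5150)
            rich, top = [], []
            for _ in range(n_rep):
                run = run_variable_population(
                    params, demog, obs, specs, rng, backend=backend
                )
                for s in run.samples:
                    vals = np.array(list(s.variant_counts.values()))
                    rich.append(vals.size)
                    top.append(vals.max() / vals.sum())
            stats[backend] = (np.mean(rich), np.std(rich) / np.sqrt(len(rich)),
                              np.mean(top), np.std(top) / np.sqrt(len(top)))
        r_k, se_k, t_k, tse_k = stats["kernel"]
        r_r, se_r, t_r, tse_r = stats["reference"]
        assert abs(r_k - r_r) < 4 * np.hypot(se_k, se_r)
        assert abs(t_k - t_r) < 4 * np.hypot(tse_k, tse_r)
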