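"""Stochastic engine: propensity bookkeeping, division/partitioning,
dilution protocol, and exactness against analytic oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import chisquare

import luxswitch as lx
from luxswitch import ode, ssa
from luxswitch.parameters import MOLECULES_PER_NM_UM3 as F


def quiet_params(**over):
    """A parameterization with all chemistry silenced; individual channels
    are re-enabled per test."""
    base = dict(alphaR=0.0, alphaI=0.0, k1_minus=0.0, k2_minus=0.0,
                klux_minus=0.0, D=0.0, dA=0.0, dmR=0.0, dmI=0.0, dR=0.0,
                dI=0.0, dC=0.0, dC2=0.0, tau=1e7, lam=1.0, N=1)
    base.update(over)
    return lx.build_parameter_set(base, "lux01")


def make_pop(params, counts_per_cell, aext=0.0, ages=None):
    N = params.N
    x = np.tile(np.asarray(counts_per_cell, dtype=np.int64), (N, 1))
    ages = np.zeros(N) if ages is None else np.asarray(ages, dtype=float)
    return ssa.PopulationState(
        x=x, aext=aext, t_min=0.0, birth=-ages,
        taui=np.full(N, params.tau), ids=np.arange(N, dtype=np.int64),
        next_id=N)


class TestPropensities:
    def test_volume_scaling_of_second_order(self):
        p = lx.build_parameter_set({"N": 2})
        counts = [0, 0, 10, 0, 10, 4, 3, 1, 0]
        pop = make_pop(p, counts, ages=[0.0, p.tau])  # volumes V0 and 2·V0
        a = ssa.compute_propensities(pop, p)
        for name in ("binding_R_A", "dimerization", "promoter_binding"):
            assert a[(1, name)] == pytest.approx(a[(0, name)] / 2.0)
        # first-order channels are volume independent
        assert a[(1, "unbinding_C")] == pytest.approx(a[(0, "unbinding_C")])

    def test_dimerization_uses_pair_count(self):
        p = lx.build_parameter_set({"N": 1})
        pop = make_pop(p, [0, 0, 0, 0, 0, 5, 0, 1, 0])
        a = ssa.compute_propensities(pop, p)
        expected = (p.k2_minus / p.Kd2) / (F * p.V0) * 5 * 4 / 2.0
        assert a[(0, "dimerization")] == pytest.approx(expected)

    def test_zero_counts_zero_propensity(self):
        p = lx.build_parameter_set({"N": 1})
        pop = make_pop(p, [0, 0, 0, 0, 0, 0, 0, 1, 0])
        a = ssa.compute_propensities(pop, p)
        assert a[(0, "binding_R_A")] == 0.0
        assert a[(0, "degradation_luxR")] == 0.0

    def test_influx_off_at_zero_control(self):
        p = lx.build_parameter_set({"N": 1, "cA_star": 0.0})
        pop = make_pop(p, [0, 0, 0, 0, 0, 0, 0, 1, 0], aext=1000.0)
        a = ssa.compute_propensities(pop, p)
        assert a[(-1, "influx_Aext")] == 0.0
        assert a[(-1, "efflux_Aext")] == pytest.approx(p.gamma * 1000.0)
        assert a[(-1, "degradation_Aext")] == pytest.approx(p.dA * 1000.0)

    def test_negative_counts_detected(self):
        p = lx.build_parameter_set({"N": 1})
        pop = make_pop(p, [0, 0, 0, 0, 0, 0, 0, 1, 0])
        pop.x[0, 2] = -1
        with pytest.raises(ValueError):
            ssa.compute_propensities(pop, p)


class TestDivision:
    def _mother(self, counts, params):
        return ssa.CellState(np.array(counts, dtype=np.int64), 2 * params.V0,
                             params.tau, params.tau, cell_id=7)

    def test_counts_conserved(self, rng):
        p = lx.build_parameter_set()
        mother = self._mother([3, 2, 10, 8, 5, 4, 6, 1, 0], p)
        d1, d2 = ssa.divide_cell(mother, p, rng)
        np.testing.assert_array_equal(d1.counts[:7] + d2.counts[:7],
                                      mother.counts[:7])

    def test_bound_complex_detached_before_partition(self, rng):
        p = lx.build_parameter_set()
        mother = self._mother([0, 0, 0, 0, 0, 0, 0, 0, 1], p)
        d1, d2 = ssa.divide_cell(mother, p, rng)
        assert d1.counts[7] == d2.counts[7] == 1     # both promoters free
        assert d1.counts[8] == d2.counts[8] == 0
        assert d1.counts[6] + d2.counts[6] == 1      # the detached dimer

    def test_daughters_reset(self, rng):
        p = lx.build_parameter_set()
        d1, d2 = ssa.divide_cell(self._mother([0] * 7 + [1, 0], p), p, rng)
        for d in (d1, d2):
            assert d.volume == p.V0 and d.clock == 0.0
            assert d.tau_i >= p.lam * p.tau
        assert d1.tau_i != d2.tau_i                  # independent draws

    def test_division_requires_completed_cycle(self, rng):
        p = lx.build_parameter_set()
        cell = ssa.CellState(np.array([0] * 7 + [1, 0]), p.V0, 10.0, 45.0, 1)
        with pytest.raises(ValueError):
            ssa.divide_cell(cell, p, rng)


class TestConstantPopulation:
    def test_requires_overfull_census(self, rng):
        with pytest.raises(ValueError):
            ssa.enforce_constant_population(1, rng)

    def test_uniform_over_newborns_and_residents(self, rng):
        n_events, n_present = 10_000, 11
        picks = np.array([ssa.enforce_constant_population(n_present, rng)
                          for _ in range(n_events)])
        observed = np.bincount(picks, minlength=n_present)
        stat, pvalue = chisquare(observed)
        assert pvalue > 0.01

    def test_census_constant_through_divisions(self, rng):
        p = lx.build_parameter_set({"N": 5, "tau": 30.0, "lam": 1.0})
        pop = make_pop(p, [0, 0, 0, 0, 0, 0, 0, 1, 0])
        pop.taui = np.full(5, 30.0)
        res = ssa.advance(pop, 95.0, p.replace(cA_star=0.0), rng,
                          sample_every=10.0)
        assert res.pop.n_cells == 5
        divs = res.log.of_kind("division")
        assert len(divs) == len(res.log.of_kind("removal")) >= 5

    def test_single_cell_lineage_survives(self, rng):
        p = lx.build_parameter_set({"N": 1, "tau": 20.0, "lam": 1.0})
        pop = make_pop(p, [0, 0, 4, 0, 0, 0, 0, 1, 0])
        pop.taui = np.array([20.0])
        res = ssa.advance(pop, 25.0, p, rng, sample_every=25.0)
        assert res.pop.n_cells == 1
        assert len(res.log.of_kind("division")) == 1


class TestAdvance:
    def test_frozen_system_stays_put(self, rng):
        p = quiet_params()
        pop = make_pop(p, [0, 0, 5, 3, 2, 0, 0, 1, 0])
        res = ssa.advance(pop, 500.0, p, rng, sample_every=100.0)
        np.testing.assert_array_equal(res.pop.x,
                                      [[0, 0, 5, 3, 2, 0, 0, 1, 0]])
        assert res.n_events == 0
        assert res.pop.t_min == 500.0

    def test_seed_determinism(self):
        p = lx.build_parameter_set({"N": 3, "cA_star": 20.0})
        basal = ode.basal_state(p)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            pop = ssa.population_from_concentrations(basal, p, rng)
            res = ssa.advance(pop, 60.0, p, rng, sample_every=10.0,
                              log_reactions=5000)
            out.append(res)
        np.testing.assert_array_equal(out[0].trajectory.gfp_counts,
                                      out[1].trajectory.gfp_counts)
        np.testing.assert_array_equal(out[0].pop.x, out[1].pop.x)
        assert out[0].log.events == out[1].log.events

    def test_one_dna_copy_per_cell_always(self, rng):
        p = lx.build_parameter_set({"N": 4, "cA_star": 30.0})
        pop = ssa.population_from_concentrations(ode.basal_state(p), p, rng)
        res = ssa.advance(pop, 180.0, p, rng, sample_every=60.0)
        assert np.all(res.pop.x >= 0)
        np.testing.assert_array_equal(res.pop.x[:, 7] + res.pop.x[:, 8], 1)

    def test_max_events_guard_returns_partial_result(self, rng):
        p = lx.build_parameter_set({"N": 2, "cA_star": 50.0})
        pop = ssa.population_from_concentrations(ode.basal_state(p), p, rng)
        res = ssa.advance(pop, 600.0, p, rng, max_events=1000)
        assert res.pop.t_min < 600.0
        assert res.n_events <= 1100


class TestOracles:
    def test_pure_degradation_matches_exponential_decay(self, rng):
        """Mean count under a single first-order decay channel follows
        n₀·e^(−dA·t); 1000 independent cells, three standard errors."""
        n0, dA, t = 100, 0.001, 600.0
        p = quiet_params(dA=dA, N=1000)
        conc0 = n0 / (F * p.V0)
        pop = make_pop(p, [0, 0, 0, 0, n0, 0, 0, 1, 0])
        res = ssa.advance(pop, t, p, rng, sample_every=t)
        counts = res.pop.x[:, 4]
        expected = n0 * math.exp(-dA * t)
        surv = expected / n0
        se = math.sqrt(n0 * surv * (1 - surv) / 1000)
        assert abs(counts.mean() - expected) < 3 * se

    def test_linear_expression_matches_count_ode_through_divisions(self):
        """With the feedback silenced, the ensemble-mean counts obey the
        linear transcription-translation-degradation ODE with an exact
        halving at every (synchronous) division."""
        dm, dI, kI, pI = 0.347, 0.01, 2.5, 6.94
        p = quiet_params(alphaI=1.0, dmI=dm, dI=dI, N=300, tau=45.0, lam=1.0)
        pop = make_pop(p, [0, 0, 0, 0, 0, 0, 0, 1, 0])
        pop.taui = np.full(300, 45.0)

        def oracle(t_end):
            # piecewise-linear count ODE, halved at 45-minute marks
            y = np.array([0.0, 0.0])     # (mRNA, protein)
            t = 0.0
            while t < t_end - 1e-9:
                t_next = min(math.floor(t / 45.0 + 1.0) * 45.0, t_end)
                sol = solve_ivp(
                    lambda s, y: [kI - dm * y[0], pI * y[0] - dI * y[1]],
                    (t, t_next), y, rtol=1e-10, atol=1e-12)
                y = sol.y[:, -1]
                t = t_next
                if abs(t % 45.0) < 1e-9 and t < t_end - 1e-9:
                    y = y / 2.0
            return y

        rng = np.random.default_rng(2024)
        res = ssa.advance(pop, 100.0, p, rng, sample_every=20.0,
                          record_species=True)
        tr = res.trajectory
        for t_check in (40.0, 60.0, 100.0):
            i = int(np.argmin(np.abs(tr.times - t_check)))
            m_exp, n_exp = oracle(tr.times[i])
            m_obs = tr.species[i, :, 1]
            n_obs = tr.species[i, :, 3]
            assert abs(m_obs.mean() - m_exp) < 3 * m_obs.std(ddof=1) / math.sqrt(300) + 1e-9
            assert abs(n_obs.mean() - n_exp) < 3 * n_obs.std(ddof=1) / math.sqrt(300) + 1e-9


class TestFptSingleCell:
    def test_censoring_at_horizon(self, rng):
        p = lx.build_parameter_set({"N": 1})
        basal = ode.basal_state(p)
        t, censored = ssa.fpt_single_cell(p, 5.0, basal, 1e9, 30.0, rng)
        assert censored and t == 30.0

    def test_immediate_crossing_for_trivial_threshold(self, rng):
        p = lx.build_parameter_set({"N": 1})
        basal = ode.basal_state(p)
        t, censored = ssa.fpt_single_cell(p, 5.0, basal, 0.5, 60.0, rng)
        assert not censored and t < 60.0
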