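import numpy as np
import pytest

import fse
from fse.errors import ConstantRegionError, ShapeError, TooLargeError
from fse.ising_sim import metropolis_sweep

from conftest import complete_graph_coupling, config_codes, random_symmetric


class TestHamiltonian:
    def test_two_spin_values(self):
        J = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert fse.hamiltonian([1, 1], J) == -1.0
        assert fse.hamiltonian([1, -1], J) == 1.0

    def test_global_flip_invariance(self, rng):
        J = random_symmetric(rng, 7)
        s = rng.choice([-1, 1], 7)
        assert fse.hamiltonian(s, J) == pytest.approx(fse.hamiltonian(-s, J))

    def test_invalid_spins_rejected(self):
        with pytest.raises(ShapeError):
            fse.hamiltonian([1, 0], np.zeros((2, 2)))


class _ForcedRng:
    """Generator stub: cycles through sites in order, random() always
    returning 1.0 so only downhill (dE <= 0) proposals are ever accepted."""

    def __init__(self):
        self._next = 0

    def integers(self, low, high=None):
        n = low if high is None else high
        i = self._next % n
        self._next += 1
        return i

    def random(self):
        return 1.0


class TestMetropolisSweep:
    def test_downhill_always_accepted(self):
        # J = 0 means dE = 0 for every proposal: all N flips must happen
        s, accepted = metropolis_sweep(np.ones(5), np.zeros((5, 5)), 2.0, _ForcedRng())
        assert accepted == 5
        np.testing.assert_array_equal(s, -np.ones(5))

    def test_uphill_rejected_when_rand_is_one(self):
        # deep ferromagnetic state: every flip raises the energy
        J = complete_graph_coupling(6)
        s, accepted = metropolis_sweep(np.ones(6), J, 3.0, _ForcedRng())
        assert accepted == 0
        np.testing.assert_array_equal(s, np.ones(6))


class TestSimulate:
    def test_same_seed_bitwise_identical(self, rng):
        J = random_symmetric(rng, 10)
        cfg = fse.McmcConfig(runs=200, seed=42)
        t1 = fse.simulate(J, 0.9, cfg)
        t2 = fse.simulate(J, 0.9, cfg)
        np.testing.assert_array_equal(t1.states, t2.states)
        assert t1.acceptance_rate == t2.acceptance_rate

    def test_pair_moments_match_enumeration(self, rng):
        J = random_symmetric(rng, 6, scale=0.6)
        trace = fse.simulate(J, 0.8, fse.McmcConfig(runs=50000, seed=1))
        emp = (trace.states.astype(float) @ trace.states.T.astype(float)) / trace.runs
        _, exact, _, _ = fse.exact_moments(J, 0.8)
        iu = np.triu_indices(6, 1)
        assert np.abs(emp - exact)[iu].max() < 0.02

    def test_free_spins_uncorrelated(self):
        trace = fse.simulate(np.zeros((8, 8)), 1.0, fse.McmcConfig(runs=4000, seed=3))
        emp = (trace.states.astype(float) @ trace.states.T.astype(float)) / trace.runs
        iu = np.triu_indices(8, 1)
        assert np.abs(emp[iu]).max() < 3 / np.sqrt(trace.runs) + 0.02

    def test_infinite_temperature_is_disordered(self, rng):
        """beta -> 0: every proposal accepted, the long-run signed
        magnetization averages to zero for any coupling matrix, and the
        per-sweep |m| sits at its CLT scale sqrt(2/(pi N))."""
        J = random_symmetric(rng, 64, scale=1.0)
        trace = fse.simulate(J, 1e-9, fse.McmcConfig(runs=2000, seed=7))
        assert abs(trace.states.mean()) < 0.05
        M_abs, _ = fse.observables(trace, beta=1.0)
        assert M_abs == pytest.approx(np.sqrt(2 / (np.pi * 64)), abs=0.03)

    def test_deep_ferromagnet_stays_ordered(self):
        J = complete_graph_coupling(64)
        trace = fse.simulate(J, 3.0, fse.McmcConfig(runs=1000, burn_in=0, seed=2, init="all_up"))
        m = trace.states.mean(axis=0)
        assert np.abs(m).mean() >= 0.99
        assert np.abs(m).min() >= 0.9  # rare few-spin excursions only

    def test_literal_printed_rule_is_not_boltzmann(self, rng):
        """The alternative local-energy flip rule runs, but its stationary
        distribution deviates grossly from the Boltzmann distribution that
        the standard Metropolis rule reproduces."""
        J = random_symmetric(rng, 4, scale=1.0)
        dist, _, _, _ = fse.exact_moments(J, 1.0)
        p = np.zeros(16)
        p[config_codes(dist.configurations.T)] = dist.probabilities

        def tv(rule):
            tr = fse.simulate(J, 1.0, fse.McmcConfig(runs=100000, seed=9, rule=rule))
            freq = np.bincount(config_codes(tr.states), minlength=16) / tr.runs
            return 0.5 * np.abs(freq - p).sum()

        assert tv("metropolis") < 0.02
        assert tv("local_energy") > 10 * tv("metropolis")


class TestObservables:
    def test_complete_order(self):
        trace = fse.SpinTrace(np.ones((5, 100), dtype=int), 1.0, 0.0)
        M_abs, chi = fse.observables(trace)
        assert M_abs == 1.0
        assert chi == 0.0

    def test_alternating_order_has_unit_magnitude(self):
        states = np.ones((4, 50), dtype=int)
        states[:, 1::2] = -1
        trace = fse.SpinTrace(states, 1.0, 0.0)
        M_abs, chi = fse.observables(trace)
        assert M_abs == 1.0
        assert trace.states.mean() == 0.0

    def test_chi_nonnegative(self, rng):
        J = random_symmetric(rng, 10)
        trace = fse.simulate(J, 1.2, fse.McmcConfig(runs=500, seed=5))
        _, chi = fse.observables(trace)
        assert chi >= 0


class TestReconstructedFc:
    def test_simulated_source_and_symmetry(self, rng):
        J = random_symmetric(rng, 8)
        fc = fse.reconstructed_fc(fse.simulate(J, 0.8, fse.McmcConfig(runs=2000, seed=1)))
        assert fc.source == "simulated"
        np.testing.assert_allclose(fc.fc, fc.fc.T)

    def test_frozen_trace_raises(self):
        trace = fse.SpinTrace(np.ones((4, 50), dtype=int), 3.0, 0.0)
        with pytest.raises(ConstantRegionError):
            fse.reconstructed_fc(trace)


class TestPositivePart:
    def test_cases(self, rng):
        J = random_symmetric(rng, 6)
        pos = fse.positive_part(J)
        assert (pos.J >= 0).all()
        np.testing.assert_array_equal(pos.J > 0, (J > 0))
        np.testing.assert_array_equal(fse.positive_part(-np.abs(J)).J, 0.0)
        np.testing.assert_array_equal(fse.positive_part(np.abs(J)).J, np.abs(J))


class TestExactMoments:
    def test_two_spin_closed_form(self):
        J = np.array([[0.0, 1.0], [1.0, 0.0]])
        dist, pair, _, _ = fse.exact_moments(J, 1.0)
        assert pair[0, 1] == pytest.approx(np.tanh(1.0))
        assert dist.Z == pytest.approx(2 * np.e + 2 / np.e)
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_free_spins(self):
        dist, pair, M_abs, _ = fse.exact_moments(np.zeros((5, 5)), 1.0)
        assert dist.Z == pytest.approx(2**5)
        iu = np.triu_indices(5, 1)
        np.testing.assert_allclose(pair[iu], 0.0, atol=1e-12)

    def test_size_cap(self):
        with pytest.raises(TooLargeError):
            fse.exact_moments(np.zeros((16, 16)), 1.0)

    def test_mcmc_error_shrinks_with_runs(self, rng):
        """Sampling error roughly halves when runs quadruple (1/sqrt(t))."""
        J = random_symmetric(rng, 5, scale=0.5)
        _, exact, _, _ = fse.exact_moments(J, 1.0)
        iu = np.triu_indices(5, 1)

        def err(runs, seed):
            es = []
            for s in range(seed, seed + 6):
                tr = fse.simulate(J, 1.0, fse.McmcConfig(runs=runs, seed=s))
                emp = (tr.states.astype(float) @ tr.states.T.astype(float)) / runs
                es.append(np.abs((emp - exact)[iu]).mean())
            return np.mean(es)

        e_small, e_big = err(2000, 1), err(32000, 11)
        assert e_big < e_small / 2  # expect /4; allow 2x slack


class TestThermoCurve:
    def test_invariants_on_small_scan(self, rng):
        J = np.abs(random_symmetric(rng, 12, scale=0.4))
        cfg = fse.McmcConfig(runs=800, beta_grid=(0.5, 1.0, 2.0, 4.0), seed=4, init="all_up")
        curve = fse.thermo_sweep(J, cfg)
        assert (curve.chi >= 0).all()
        assert ((curve.M_abs >= 0) & (curve.M_abs <= 1)).all()
        np.testing.assert_allclose(curve.T, 1.0 / curve.betas)
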