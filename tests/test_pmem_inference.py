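import warnings

import numpy as np
import pytest

import fse
from fse.errors import NonConvergenceWarning
from fse.pmem_inference import _objective, gradient, local_fields, log_pseudolikelihood

from conftest import random_symmetric


def spins(rows):
    return fse.BinarizedActivity(np.asarray(rows, dtype=int))


class TestLocalFields:
    def test_zero_coupling(self):
        S = spins([[1, -1], [1, 1]])
        np.testing.assert_array_equal(local_fields(np.zeros((2, 2)), S, 1.0), 0.0)

    def test_two_region_substitution(self):
        J = np.array([[0.0, 0.5], [0.5, 0.0]])
        C = local_fields(J, np.array([[1.0], [1.0]]), 1.0)
        np.testing.assert_allclose(C, [[0.5], [0.5]])

    def test_linear_in_beta(self, rng):
        J = random_symmetric(rng, 6)
        S = rng.choice([-1.0, 1.0], (6, 20))
        np.testing.assert_allclose(
            local_fields(J, S, 2.0), 2.0 * local_fields(J, S, 1.0)
        )


class TestLogPseudolikelihood:
    def test_zero_coupling_gives_n_ln2(self, rng):
        S = rng.choice([-1.0, 1.0], (7, 31))
        logpl, pen = log_pseudolikelihood(np.zeros((7, 7)), S, 1.3)
        assert logpl == pytest.approx(-7 * np.log(2))
        assert pen == 0.0

    def test_zero_A_has_no_penalty(self, rng):
        J = random_symmetric(rng, 4)
        S = rng.choice([-1.0, 1.0], (4, 10))
        _, pen = log_pseudolikelihood(J, S, 1.0, W=None, A=0.0)
        assert pen == 0.0

    def test_small_case_against_direct_sum(self):
        """N=2, t=4: every conditional term evaluated with plain floats."""
        cols = [(1, 1), (1, 1), (-1, -1), (1, -1)]
        S = spins(np.array(cols).T)
        beta, J12 = 1.0, 0.3
        expected = 0.0
        for s1, s2 in cols:
            for si, sother in ((s1, s2), (s2, s1)):
                C = beta * J12 * sother
                expected += C * si - np.log(np.exp(C) + np.exp(-C))
        expected /= 4
        J = np.array([[0.0, J12], [J12, 0.0]])
        logpl, _ = log_pseudolikelihood(J, S, beta)
        assert logpl == pytest.approx(expected, abs=1e-12)
        assert logpl <= 0

    def test_logpl_always_nonpositive(self, rng):
        for _ in range(5):
            J = random_symmetric(rng, 5, scale=2.0)
            S = rng.choice([-1.0, 1.0], (5, 12))
            logpl, _ = log_pseudolikelihood(J, S, rng.uniform(0.1, 3.0))
            assert logpl <= 0


class TestGradient:
    def test_perfectly_correlated_pair_at_zero(self):
        s = np.array([[1, -1, 1, 1], [1, -1, 1, 1]])
        G = gradient(np.zeros((2, 2)), spins(s), beta=0.7)
        assert G[0, 1] == pytest.approx(0.7)  # tanh(0)=0, s_i s_j = 1

    def test_penalty_vanishes_at_zero_coupling(self, rng):
        W = np.abs(random_symmetric(rng, 4)) + 0.1
        np.fill_diagonal(W, 0.0)
        S = rng.choice([-1.0, 1.0], (4, 16))
        G0 = gradient(np.zeros((4, 4)), S, 1.0)
        Gp = gradient(np.zeros((4, 4)), S, 1.0, W=W, A=5.0)
        np.testing.assert_allclose(G0, Gp)  # sgn(0)=0: no pull at J=0

    def test_matches_central_differences(self, rng):
        N, t, eps = 5, 40, 1e-6
        S = rng.choice([-1.0, 1.0], (N, t))
        J = random_symmetric(rng, N, scale=0.4) + 0.05  # keep entries off 0
        np.fill_diagonal(J, 0.0)
        W = np.abs(random_symmetric(rng, N)) + 0.2
        np.fill_diagonal(W, 0.0)
        beta, A = 0.8, 1.3
        G = gradient(J, S, beta, W, A, symmetrize=False)
        for i in range(N):
            for j in range(N):
                if i == j:
                    continue
                E = np.zeros((N, N))
                E[i, j] = eps
                fd = (
                    _objective(J + E, S, beta, W, A)
                    - _objective(J - E, S, beta, W, A)
                ) / (2 * eps)
                assert G[i, j] == pytest.approx(fd, abs=1e-5)


class TestFit:
    def test_two_spin_closed_form(self, two_spin_samples):
        """Pseudolikelihood optimum of a 2-spin system is atanh of the
        empirical correlation (zero-field Ising closed form)."""
        S, _, _ = two_spin_samples
        cfg = fse.InferenceConfig(beta=1.0, tol=1e-9, max_iter=20000, init="zeros")
        J_hat = fse.fit(S, cfg)
        c = (S.states[0].astype(float) * S.states[1]).mean()
        assert J_hat.J[0, 1] == pytest.approx(np.arctanh(c), abs=1e-3)

    def test_zero_A_matches_unconstrained(self, rng):
        S = spins(rng.choice([-1, 1], (8, 200)))
        W = fse.gen_structural(fse.SyntheticSpec(N=8, seed=3), seed=3)
        J0 = fse.fit(S, fse.InferenceConfig(beta=1.0, A=0.0, seed=11, tol=1e-8))
        Jeps = fse.fit(S, fse.InferenceConfig(beta=1.0, A=1e-8, seed=11, tol=1e-8), W)
        np.testing.assert_allclose(J0.J, Jeps.J, atol=1e-6)

    def test_huge_A_pins_magnitudes_to_structure(self, rng):
        from scipy import stats

        S = spins(rng.choice([-1, 1], (10, 300)))
        W = fse.gen_structural(fse.SyntheticSpec(N=10, density=1.0, seed=5), seed=5)
        J = fse.fit(S, fse.InferenceConfig(beta=1.0, A=1e8, tol=1e-10), W)
        iu = np.triu_indices(10, 1)
        assert np.abs(np.abs(J.J) - W.W)[iu].max() < 1e-4
        assert stats.pearsonr(np.abs(J.J[iu]), W.W[iu])[0] > 0.999
        assert J.provenance == "fse"

    def test_objective_monotone_at_small_gamma(self, rng):
        """Fixed-rate ascent never decreases the penalized objective."""
        S = rng.choice([-1.0, 1.0], (10, 150))
        W = np.abs(random_symmetric(rng, 10)) + 0.05
        np.fill_diagonal(W, 0.0)
        J = random_symmetric(rng, 10, scale=0.01)
        beta, A, gamma = 1.0, 0.8, 0.01
        prev = _objective(J, S, beta, W, A)
        for _ in range(100):
            J = J + gamma * gradient(J, S, beta, W, A)
            cur = _objective(J, S, beta, W, A)
            assert cur >= prev - 1e-10
            prev = cur

    def test_permutation_equivariance(self, rng):
        S = rng.choice([-1, 1], (6, 120))
        perm = rng.permutation(6)
        cfg = fse.InferenceConfig(beta=1.0, init="zeros", tol=1e-8)
        J = fse.fit(spins(S), cfg).J
        Jp = fse.fit(spins(S[perm]), cfg).J
        np.testing.assert_allclose(Jp, J[np.ix_(perm, perm)], atol=1e-7)

    def test_row_negation_symmetry(self, rng):
        """Flipping one region's spins negates exactly its row/column of the
        unconstrained fit (no-external-field model)."""
        S = rng.choice([-1, 1], (6, 120))
        cfg = fse.InferenceConfig(beta=1.0, init="zeros", tol=1e-8)
        J = fse.fit(spins(S), cfg).J
        S2 = S.copy()
        S2[2] *= -1
        J2 = fse.fit(spins(S2), cfg).J
        flip = np.ones((6, 6))
        flip[2, :] = -1
        flip[:, 2] = -1
        np.fill_diagonal(flip, 1.0)
        np.testing.assert_allclose(J2, J * flip, atol=1e-7)

    def test_nonconvergence_warns_but_returns(self, rng):
        S = spins(rng.choice([-1, 1], (5, 60)))
        with pytest.warns(NonConvergenceWarning):
            J = fse.fit(S, fse.InferenceConfig(beta=1.0, max_iter=1, tol=1e-15))
        assert J.fit_info["converged"] is False
        assert np.allclose(J.J, J.J.T)

    def test_A_without_W_rejected(self, rng):
        S = spins(rng.choice([-1, 1], (4, 20)))
        with pytest.raises(ValueError):
            fse.fit(S, fse.InferenceConfig(beta=1.0, A=1.0))
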