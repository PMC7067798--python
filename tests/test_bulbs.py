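"""Tests of the truncated 2-D bulb chain: generator, stationary law, KL fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from filokin.bulbs import (
    BulbStationaryModel,
    build_generator,
    fit_bulb_parameters,
    kl_divergence,
    marginal_densities,
    stationary_distribution,
    stationary_mean_bulbs,
    _stationary_vector_direct,
)

rates = st.floats(1e-3, 1.0)


class TestGenerator:
    def test_n1_matrix_entry_by_entry(self):
        """Manual enumeration of the 4-state (N=1) generator."""
        r3, c4, c5, c6, B50 = 0.3, 0.2, 0.1, 0.05, 2.0
        gen = build_generator(r3, c4, c5, c6, B50, N=1)
        G = gen.matrix
        f1_0 = 1.0  # f1(j=0)
        f1_1 = 2.0 / 3.0  # f1(j=1, B50=2)
        # states: 0=(0,0) 1=(0,1) 2=(1,0) 3=(1,1)
        expect = np.zeros((4, 4))
        expect[0, 2] = r3 * f1_0          # birth from (0,0)
        expect[1, 0] = c6                 # maturation from (0,1)
        expect[1, 3] = r3 * f1_1          # birth from (0,1)
        expect[2, 0] = c4                 # retraction from (1,0)
        expect[2, 1] = c5                 # stabilization (1,0)->(0,1)
        expect[3, 1] = c4                 # retraction from (1,1)
        expect[3, 2] = c6                 # maturation from (1,1)
        # stabilization from (1,1) would need j=2 > N: reflected (absent)
        for i in range(4):
            expect[i, i] = -expect[i].sum()
        assert np.allclose(G, expect)

    @given(rates, rates, rates, rates, st.floats(0.5, 20.0), st.integers(1, 6))
    @settings(max_examples=30, deadline=None)
    def test_rows_sum_to_zero_and_offdiag_nonneg(self, r3, c4, c5, c6, B50, N):
        G = build_generator(r3, c4, c5, c6, B50, N=N).matrix
        assert np.allclose(G.sum(axis=1), 0.0, atol=1e-12)
        off = G - np.diag(np.diag(G))
        assert np.all(off >= 0)

    def test_reduces_to_birth_death_block_when_decoupled(self):
        """With c5 = c6 = 0 the j = 0 block is a plain birth-death chain."""
        gen = build_generator(0.3, 0.2, 0.0, 0.0, 2.0, N=4)
        G = gen.matrix
        m = 5
        for i in range(4):
            assert G[i * m, (i + 1) * m] == pytest.approx(0.3)
            assert G[(i + 1) * m, i * m] == pytest.approx((i + 1) * 0.2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_generator(0.1, 0.1, 0.1, 0.1, 1.0, N=0)
        with pytest.raises(ValueError):
            build_generator(-0.1, 0.1, 0.1, 0.1, 1.0, N=2)


class TestStationary:
    def test_two_state_symmetric(self):
        from filokin.bulbs import BulbGenerator

        G = np.array([[-0.4, 0.4], [0.4, -0.4]])
        gen = BulbGenerator(N=0, r3=0, c4=0, c5=0, c6=0, B50=1.0,
                            f1_mode="inhibition", generator_mode="reaction_consistent",
                            matrix=G)
        d = stationary_distribution(gen)
        assert np.allclose(d.probabilities, [0.5, 0.5])
        assert abs(d.eigenvalue) < 1e-12

    def test_truncated_poisson_closed_form(self):
        """Without stabilization the sB marginal is pi_i ∝ (r3/c4)^i / i!.

        c5 = 0 makes every j > 0 state transient (maturation only drains
        synB), so the stationary law lives on the j = 0 birth-death block.
        """
        r3, c4, N = 0.3, 0.2, 8
        gen = build_generator(r3, c4, 0.0, 0.1, 1.0, N=N)
        d = stationary_distribution(gen)
        p_sB, p_synB = marginal_densities(d)
        rho = r3 / c4
        expect = np.array([rho**i / math.factorial(i) for i in range(N + 1)])
        expect /= expect.sum()
        assert np.allclose(p_sB, expect, atol=1e-8)
        assert p_synB[0] == pytest.approx(1.0)

    @given(rates, rates, rates, rates, st.floats(0.5, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_zero_eigenvalue_recovered(self, r3, c4, c5, c6, B50):
        gen = build_generator(r3, c4, c5, c6, B50, N=4)
        d = stationary_distribution(gen)
        assert abs(d.eigenvalue) < 1e-9
        assert d.residual < 1e-9
        assert d.probabilities.sum() == pytest.approx(1.0)

    def test_reducible_chain_rejected(self):
        from filokin.bulbs import BulbGenerator

        G = np.zeros((4, 4))  # two isolated pairs
        G[0, 1] = G[1, 0] = 1.0
        G[2, 3] = G[3, 2] = 1.0
        np.fill_diagonal(G, -G.sum(axis=1))
        gen = BulbGenerator(N=1, r3=0, c4=0, c5=0, c6=0, B50=1.0,
                            f1_mode="inhibition", generator_mode="reaction_consistent",
                            matrix=G)
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(gen)

    def test_direct_solver_matches_eigensolver(self):
        gen = build_generator(0.05, 1 / 120, 0.03, 0.008, 2.0, N=10)
        d = stationary_distribution(gen)
        v = _stationary_vector_direct(gen.matrix)
        assert np.allclose(v, d.probabilities, atol=1e-10)

    def test_brute_force_occupancy_oracle(self):
        """Long-run CTMC occupancy frequencies match the eigen-solve.

        Independent oracle: simulate the jump chain with exponential
        holding times and tally time-weighted state occupancy.
        """
        rng = np.random.default_rng(12)
        for trial in range(3):
            r3, c4, c5, c6 = rng.uniform(0.05, 0.5, size=4)
            B50 = rng.uniform(0.5, 5.0)
            gen = build_generator(r3, c4, c5, c6, B50, N=3)
            pi = stationary_distribution(gen).probabilities
            G = gen.matrix
            rates_out = -np.diag(G)
            jump = G.copy()
            np.fill_diagonal(jump, 0.0)
            occ = np.zeros(len(pi))
            s = 0
            T = 0.0
            while T < 50_000.0:
                dwell = rng.exponential(1.0 / rates_out[s]) if rates_out[s] > 0 else 1.0
                occ[s] += dwell
                T += dwell
                if rates_out[s] > 0:
                    s = rng.choice(len(pi), p=jump[s] / rates_out[s])
            occ /= occ.sum()
            tv = 0.5 * np.abs(occ - pi).sum()
            assert tv < 0.02


class TestMarginals:
    def test_point_mass(self):
        gen = build_generator(0.0, 0.1, 0.0, 0.1, 1.0, N=2)
        d = stationary_distribution(gen)
        p_sB, p_synB = marginal_densities(d)
        assert p_sB[0] == pytest.approx(1.0)
        assert p_synB[0] == pytest.approx(1.0)

    def test_product_form_recovers_factors(self):
        from filokin.bulbs import StationaryDistribution

        a = np.array([0.5, 0.3, 0.2])
        b = np.array([0.7, 0.2, 0.1])
        v = np.outer(a, b).ravel()
        d = StationaryDistribution(probabilities=v, eigenvalue=0.0, residual=0.0, N=2)
        p_sB, p_synB = marginal_densities(d)
        assert np.allclose(p_sB, a)
        assert np.allclose(p_synB, b)

    def test_uniform_two_by_two(self):
        from filokin.bulbs import StationaryDistribution

        d = StationaryDistribution(np.full(4, 0.25), 0.0, 0.0, N=1)
        p_sB, p_synB = marginal_densities(d)
        assert np.allclose(p_sB, [0.5, 0.5])
        assert np.allclose(p_synB, [0.5, 0.5])


class TestKL:
    def test_identical_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(p, p, pseudocount=0.0) == pytest.approx(0.0, abs=1e-15)

    def test_hand_value(self):
        # 0.5 ln(0.5/0.9) + 0.5 ln(0.5/0.1) = 0.51082562376599068
        got = kl_divergence([0.5, 0.5], [0.9, 0.1], pseudocount=0.0)
        assert got == pytest.approx(0.5108256237659907, rel=1e-12)

    def test_zero_model_bin_gives_inf(self):
        with pytest.warns(UserWarning, match="zero probability"):
            assert kl_divergence([0.5, 0.5], [1.0, 0.0], pseudocount=0.0) == np.inf

    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=6))
    @settings(max_examples=30, deadline=None)
    def test_nonnegative(self, w):
        rng = np.random.default_rng(hash(tuple(w)) % 2**31)
        p = np.array(w) / np.sum(w)
        q = rng.dirichlet(np.ones(len(w)))
        assert kl_divergence(p, q) >= 0.0


class TestFit:
    def test_self_consistency_on_exact_marginals(self):
        """Fitting model-generated marginals recovers the parameters."""
        truth = dict(c5=0.05, B50=2.0, r3=0.019)
        gen = build_generator(truth["r3"], 1 / 120, truth["c5"], 1 / 132,
                              truth["B50"], N=15)
        p_sB, p_synB = marginal_densities(stationary_distribution(gen))
        fit = fit_bulb_parameters(p_sB, p_synB, c4=1 / 120, c6=1 / 132, N=15)
        assert fit.kl_total < 1e-8
        assert fit.c5 == pytest.approx(truth["c5"], rel=0.02)
        assert fit.B50 == pytest.approx(truth["B50"], rel=0.02)
        assert fit.r3 == pytest.approx(truth["r3"], rel=0.02)

    def test_initial_guess_at_optimum_stays_there(self):
        gen = build_generator(0.02, 1 / 120, 0.04, 0.01, 3.0, N=10)
        p_sB, p_synB = marginal_densities(stationary_distribution(gen))
        fit = fit_bulb_parameters(p_sB, p_synB, c4=1 / 120, c6=0.01, N=10,
                                  grid_size=2, n_refine=1, x0=(0.04, 3.0, 0.02))
        assert fit.kl_total < 1e-8

    def test_degenerate_observation_flagged(self):
        p = np.zeros(6)
        p[0] = 1.0
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = fit_bulb_parameters(p, p, c4=0.01, c6=0.01, N=5,
                                      grid_size=2, n_refine=1)
        assert "unidentifiable" in " ".join(fit.flags)

    def test_modes_identical_when_no_stabilization(self):
        """reaction_consistent and as_printed generators agree at c5 = 0."""
        for mode in ("reaction_consistent", "as_printed"):
            gen = build_generator(0.1, 0.05, 0.0, 0.02, 2.0, N=6, generator_mode=mode)
            if mode == "reaction_consistent":
                ref = stationary_distribution(gen).probabilities
            else:
                assert np.allclose(stationary_distribution(gen).probabilities, ref)

    def test_truncation_insensitivity(self):
        """Doubling N barely moves the fit when the tail mass is negligible."""
        gen = build_generator(0.019, 1 / 120, 0.05, 1 / 132, 2.0, N=10)
        p_sB, p_synB = marginal_densities(stationary_distribution(gen))
        fit10 = fit_bulb_parameters(p_sB, p_synB, c4=1 / 120, c6=1 / 132, N=10,
                                    grid_size=3, n_refine=1, x0=(0.05, 2.0, 0.019))
        pad = lambda p: np.pad(p, (0, 10))
        fit20 = fit_bulb_parameters(pad(p_sB), pad(p_synB), c4=1 / 120, c6=1 / 132,
                                    N=20, grid_size=3, n_refine=1,
                                    x0=(0.05, 2.0, 0.019))
        for k in ("c5", "B50", "r3"):
            assert getattr(fit20, k) == pytest.approx(getattr(fit10, k), rel=0.01)


def test_model_wrapper_pads_and_fits():
    gen = build_generator(0.019, 1 / 120, 0.05, 1 / 132, 2.0, N=15)
    p_sB, p_synB = marginal_densities(stationary_distribution(gen))
    model = BulbStationaryModel(p_sB[:8], p_synB[:8], c4=1 / 120, c6=1 / 132, N=15)
    res = model.fit(grid_size=3, n_refine=1, x0=(0.05, 2.0, 0.019))
    assert res.kl_total < 1e-3
    assert "c5" in res.summary()


def test_stationary_mean_bulbs_reports_totals():
    gen = build_generator(0.019, 1 / 120, 0.05, 1 / 132, 2.0, N=15)
    m = stationary_mean_bulbs(stationary_distribution(gen))
    assert m["total"] == pytest.approx(m["sB"] + m["synB"])
    assert 0 < m["sB"] < m["synB"]
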