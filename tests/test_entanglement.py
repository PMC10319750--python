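"""Concurrence (two routes), entanglement of formation, sudden death."""

import math

import numpy as np
import pytest

from tautodyn import (
    ChannelParams,
    InitialState,
    TwoQubitDensityMatrix,
    binary_entropy,
    concurrence_closed_form,
    entanglement_of_formation,
    error_basis_populations,
    evolve_entanglement,
    lambda_elements,
    reduced_density_matrix,
    sudden_death_time,
    wootters_concurrence,
    xstate_eigenvalues,
)
from conftest import random_parameter_draw


def werner_state(p: float) -> np.ndarray:
    bell = np.zeros((4, 4))
    bell[np.ix_([0, 3], [0, 3])] = 0.5
    return p * bell + (1.0 - p) * np.eye(4) / 4.0


class TestWoottersConcurrence:
    def test_bell_state_is_maximal(self, bell_rho):
        assert wootters_concurrence(bell_rho) == pytest.approx(1.0, abs=1e-12)

    def test_product_state_is_separable(self, product_rho):
        assert wootters_concurrence(product_rho) == pytest.approx(0.0, abs=1e-12)

    def test_werner_boundary(self):
        """C(p) = max(0, (3p-1)/2) vanishes exactly at p = 1/3."""
        assert wootters_concurrence(werner_state(1 / 3)) == pytest.approx(0.0, abs=1e-10)
        assert wootters_concurrence(werner_state(1 / 3 + 1e-3)) == pytest.approx(
            1.5e-3, abs=1e-9
        )
        assert wootters_concurrence(werner_state(1 / 3 - 1e-3)) == 0.0

    def test_scale_invariance_under_normalization(self, bell_rho):
        assert wootters_concurrence(0.25 * bell_rho.matrix) == pytest.approx(1.0, abs=1e-12)

    def test_rejects_non_hermitian(self):
        m = np.eye(4, dtype=complex)
        m[0, 1] = 1.0
        with pytest.raises(ValueError, match="Hermitian"):
            wootters_concurrence(m)


class TestXStateEigenvalues:
    def test_bell_point(self, bell_state):
        lam = lambda_elements(bell_state, ChannelParams(1, 1), ChannelParams(1, 1), 0.0)
        l1, l2, l3, l4 = xstate_eigenvalues(lam)
        assert l1 == l2 == 0.0
        assert math.sqrt(l4) - math.sqrt(l3) == pytest.approx(1.0, abs=1e-12)

    def test_vanishing_coherence_degeneracy(self):
        from tautodyn.dynamics import LambdaElements

        lam = LambdaElements(l11=0.4, l14=0.0, l22=0.1, l33=0.2, l44=0.3, mode="paper")
        _, _, l3, l4 = xstate_eigenvalues(lam)
        assert l3 == pytest.approx(l4)

    def test_matches_brute_force_spectrum(self):
        """Closed-form spin-flip eigenvalues vs numpy eigvals, unordered."""
        sy = np.array([[0, -1j], [1j, 0]])
        flip = np.kron(sy, sy)
        rng = np.random.default_rng(23)
        for _ in range(100):
            state, ch1, ch2 = random_parameter_draw(rng)
            t = rng.uniform(0.0, 8.0)
            lam = lambda_elements(state, ch1, ch2, t)
            rho = TwoQubitDensityMatrix.from_lambda(lam).matrix
            brute = np.sort(np.linalg.eigvals(rho @ flip @ rho.conj() @ flip).real)
            closed = np.sort(xstate_eigenvalues(lam))
            np.testing.assert_allclose(closed, brute, atol=1e-10)

    def test_negative_population_rejected(self):
        from tautodyn.dynamics import LambdaElements

        lam = LambdaElements(l11=-0.1, l14=0.0, l22=0.1, l33=0.2, l44=0.3, mode="paper")
        with pytest.raises(ValueError):
            xstate_eigenvalues(lam)


class TestClosedFormConcurrence:
    def test_initial_value_is_2ab(self):
        s = InitialState(0.6, 0.8)
        ch = ChannelParams(1.0, 0.5)
        assert concurrence_closed_form(s, ch, ch, 0.0) == pytest.approx(0.96)
        assert concurrence_closed_form(InitialState.bell(), ch, ch, 0.0) == pytest.approx(1.0)

    def test_constant_without_damping(self):
        s = InitialState(0.6, 0.8)
        ch = ChannelParams(delta=3.0, gamma=0.0)
        t = np.linspace(0, 50, 101)
        np.testing.assert_allclose(concurrence_closed_form(s, ch, ch, t), 0.96, rtol=1e-12)

    def test_hand_evaluated_point(self, bell_state, equal_channels):
        assert concurrence_closed_form(bell_state, *equal_channels, 1.0) == pytest.approx(
            0.25, rel=1e-12
        )

    def test_unclamped_goes_negative_where_wootters_is_zero(self):
        """Past sudden death the raw bracket is negative; the measure is 0."""
        s = InitialState(0.6, 0.8)
        ch = ChannelParams(1.0, 1.0)
        t = 3.0  # beyond t* = ln 4 ~ 1.386
        raw = concurrence_closed_form(s, ch, ch, t, clamp=False)
        assert raw < 0.0
        assert concurrence_closed_form(s, ch, ch, t) == 0.0
        rho = reduced_density_matrix(s, ch, ch, t)
        assert wootters_concurrence(rho) == 0.0

    def test_oracle_equivalence_both_modes(self):
        """Closed form == Wootters eigenvalue route on the assembled rho_S."""
        rng = np.random.default_rng(29)
        times = np.linspace(0.0, 10.0, 20)
        for _ in range(100):
            state, ch1, ch2 = random_parameter_draw(rng)
            closed = concurrence_closed_form(state, ch1, ch2, times)
            for mode, normalize in (("trace_preserving", True), ("paper", False)):
                numeric = [
                    wootters_concurrence(
                        reduced_density_matrix(state, ch1, ch2, float(t), mode=mode),
                        normalize=normalize,
                    )
                    for t in times
                ]
                np.testing.assert_allclose(numeric, closed, atol=1e-8)

    def test_monotone_nonincreasing_under_damping(self):
        rng = np.random.default_rng(31)
        t = np.linspace(0.0, 15.0, 300)
        for _ in range(50):
            state, ch1, ch2 = random_parameter_draw(rng)
            if ch1.gamma == 0 or ch2.gamma == 0:
                continue
            c = concurrence_closed_form(state, ch1, ch2, t)
            assert np.all(np.diff(c) <= 1e-12)

    def test_phase_invariance_in_tunnel_splitting(self):
        s = InitialState(0.6, 0.8)
        t = np.linspace(0, 10, 50)
        base = concurrence_closed_form(s, ChannelParams(0.0, 0.4), ChannelParams(0.0, 0.9), t)
        for d1, d2 in [(1.0, 0.0), (5.0, 2.0), (0.3, 7.0)]:
            c = concurrence_closed_form(s, ChannelParams(d1, 0.4), ChannelParams(d2, 0.9), t)
            np.testing.assert_allclose(c, base, rtol=1e-14)
            numeric = [
                wootters_concurrence(
                    reduced_density_matrix(s, ChannelParams(d1, 0.4), ChannelParams(d2, 0.9), float(ti))
                )
                for ti in t
            ]
            np.testing.assert_allclose(numeric, base, atol=1e-10)

    def test_channel_swap_symmetry(self):
        s = InitialState(0.6, 0.8)
        ch1, ch2 = ChannelParams(2.0, 0.3), ChannelParams(0.5, 1.1)
        t = np.linspace(0, 10, 50)
        np.testing.assert_allclose(
            concurrence_closed_form(s, ch1, ch2, t),
            concurrence_closed_form(s, ch2, ch1, t),
            rtol=1e-14,
        )


class TestEntropyAndEoF:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.5, 1.0), (0.0, 0.0), (1.0, 0.0), (0.25, 0.8112781244591328)],
    )
    def test_binary_entropy_values(self, x, expected):
        assert binary_entropy(x) == pytest.approx(expected, abs=1e-12)

    def test_binary_entropy_symmetry(self):
        x = np.linspace(0.0, 1.0, 101)
        np.testing.assert_allclose(binary_entropy(x), binary_entropy(1.0 - x), atol=1e-14)

    def test_binary_entropy_domain(self):
        with pytest.raises(ValueError):
            binary_entropy(1.2)

    @pytest.mark.parametrize(
        "c, expected",
        [(0.0, 0.0), (1.0, 1.0), (0.6, 0.46899559358928133)],
    )
    def test_eof_values(self, c, expected):
        assert entanglement_of_formation(c) == pytest.approx(expected, abs=1e-10)

    def test_eof_monotone_in_concurrence(self):
        c = np.linspace(0.0, 1.0, 10_000)
        e = entanglement_of_formation(c)
        assert np.all(np.diff(e) >= 0.0)

    def test_eof_domain(self):
        with pytest.raises(ValueError):
            entanglement_of_formation(-0.1)


class TestSuddenDeath:
    def test_equal_amplitudes_never_die(self, bell_state):
        ch = ChannelParams(1.0, 1.0)
        assert sudden_death_time(bell_state, ch, ch, t_max=500.0) is None

    def test_closed_form_inversion(self):
        """alpha=0.6, beta=0.8, G=1: 1 - e^{-t*} = 0.75, t* = ln 4."""
        s = InitialState(0.6, 0.8)
        ch = ChannelParams(1.0, 1.0)
        tstar = sudden_death_time(s, ch, ch, t_max=50.0)
        assert tstar == pytest.approx(math.log(4.0), abs=1e-9)

    def test_undamped_channels_never_die(self):
        s = InitialState(0.6, 0.8)
        assert sudden_death_time(s, ChannelParams(1, 0.0), ChannelParams(1, 1.0)) is None

    def test_concurrence_zero_beyond_death_with_population_left(self):
        s = InitialState(0.6, 0.8)
        ch = ChannelParams(1.0, 1.0)
        tstar = sudden_death_time(s, ch, ch, t_max=50.0)
        for t in np.linspace(tstar * 1.001, tstar + 3.0, 25):
            assert concurrence_closed_form(s, ch, ch, float(t)) == 0.0
            lam = lambda_elements(s, ch, ch, float(t))
            assert lam.l44 > 0.0

    def test_root_is_where_closed_form_crosses(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            b = rng.uniform(0.75, 0.95)
            s = InitialState(math.sqrt(1 - b * b), b)
            ch1 = ChannelParams(1.0, rng.uniform(0.3, 2.0))
            ch2 = ChannelParams(1.0, rng.uniform(0.3, 2.0))
            tstar = sudden_death_time(s, ch1, ch2, t_max=200.0)
            assert tstar is not None
            assert concurrence_closed_form(s, ch1, ch2, tstar, clamp=False) == pytest.approx(
                0.0, abs=1e-8
            )


class TestErrorBasisPopulations:
    def test_bell_state_perfectly_correlated(self, bell_rho):
        probs = error_basis_populations(bell_rho)
        np.testing.assert_allclose(probs, [0.5, 0.0, 0.0, 0.5], atol=1e-12)

    def test_product_ground_state_uncorrelated(self, product_rho):
        np.testing.assert_allclose(
            error_basis_populations(product_rho), [0.25] * 4, atol=1e-12
        )

    def test_maximally_mixed_invariant(self):
        np.testing.assert_allclose(
            error_basis_populations(np.eye(4) / 4.0), [0.25] * 4, atol=1e-14
        )

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(43)
        for _ in range(50):
            state, ch1, ch2 = random_parameter_draw(rng)
            rho = reduced_density_matrix(state, ch1, ch2, rng.uniform(0, 5))
            probs = error_basis_populations(rho)
            assert np.all(probs >= -1e-12)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestEvolveEntanglement:
    def test_result_consistency(self):
        s = InitialState(0.6, 0.8)
        ch = ChannelParams(1.0, 0.5)
        t = np.linspace(0, 8, 60)
        res = evolve_entanglement(s, ch, ch, t)
        np.testing.assert_allclose(res.concurrence_numeric, res.concurrence_closed, atol=1e-8)
        np.testing.assert_allclose(
            res.eof, entanglement_of_formation(res.concurrence_closed), atol=1e-14
        )
        assert res.sudden_death == pytest.approx(-math.log(1 - 0.75) / 0.5, abs=1e-8)
        assert res.params["mode"] == "trace_preserving"
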