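"""Cross-repressilator drift, simulation and stability analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import fsolve

from cfrlineage import (
    CFRParams,
    SignalParams,
    SimSettings,
    drift,
    hopf_scan,
    linear_stability,
    signal_g,
    simulate_ode,
    simulate_sde,
    simulate_sde_ensemble,
    symmetric_equilibrium,
)
from cfrlineage.dynamics import jacobian_at_equilibrium


class TestSignal:
    @pytest.mark.parametrize(
        "t,expected",
        [(0.0, 0.0), (2000.0, 2.0), (500.0, 0.8)],
    )
    def test_reference_values(self, t, expected):
        assert signal_g(t) == pytest.approx(expected)

    def test_saturates_at_amplitude(self):
        assert signal_g(1e12) == pytest.approx(4.0, rel=1e-5)

    def test_monotone_increasing(self):
        t = np.linspace(0, 5000, 200)
        assert np.all(np.diff(signal_g(t)) > 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            signal_g(-1.0)


class TestDrift:
    def test_origin_rate_is_basal_production(self):
        out = drift((0.0, 0.0, 0.0), 0.0, CFRParams())
        assert out == pytest.approx([1e-3, 1e-3, 1e-3])

    def test_value_at_unit_state(self):
        # direct arithmetic: b + g(2000)/((1+alpha)(1+beta)) - d at x=(1,1,1)
        p = CFRParams(alpha=1.0, beta=0.1)
        expected = 1e-3 + 2.0 / (2.0 * 1.1) - 0.1
        out = drift((1.0, 1.0, 1.0), 2000.0, p)
        assert out == pytest.approx([expected] * 3)

    @given(
        x=st.floats(0.0, 50.0),
        t=st.floats(0.0, 2000.0),
        alpha=st.floats(0.1, 1000.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_diagonal_states_have_equal_components(self, x, t, alpha):
        out = drift((x, x, x), t, CFRParams(alpha=alpha))
        assert out[0] == pytest.approx(out[1]) == pytest.approx(out[2])

    @given(
        state=st.tuples(
            st.floats(0.0, 30.0), st.floats(0.0, 30.0), st.floats(0.0, 30.0)
        ),
        t=st.floats(0.0, 2000.0),
        alpha=st.floats(0.1, 1000.0),
        beta=st.floats(0.01, 10.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_cyclic_equivariance(self, state, t, alpha, beta):
        """drift(P x) = P drift(x) for the cyclic shift P: (x1,x2,x3)->(x3,x1,x2)."""
        p = CFRParams(alpha=alpha, beta=beta)
        direct = np.roll(drift(state, t, p), 1)
        permuted = drift(np.roll(np.asarray(state), 1), t, p)
        np.testing.assert_allclose(permuted, direct, rtol=1e-12, atol=1e-15)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            drift((-0.1, 0.0, 0.0), 0.0, CFRParams())


class TestOde:
    def test_diagonal_is_invariant(self):
        # weak inhibition keeps the symmetric state attracting; a diagonal
        # start must stay diagonal (cyclic symmetry)
        p = CFRParams(alpha=0.01, beta=0.01)
        traj = simulate_ode(
            p, settings=SimSettings(t_end=500.0, x0=(0.1, 0.1, 0.1))
        )
        spread = traj.states.max(axis=1) - traj.states.min(axis=1)
        assert spread.max() < 1e-6

    def test_one_fate_dominates_at_final_time(self):
        traj = simulate_ode(CFRParams(alpha=1.0))
        terminal = np.sort(traj.states[-1])[::-1]
        assert terminal[0] > 10.0 * terminal[1]
        assert terminal[0] > 10.0 * terminal[2]

    def test_terminal_state_matches_fixed_point_oracle(self):
        """Dominant level approaches the root of the g=2 fixed-point system."""
        p = CFRParams(alpha=1.0)
        traj = simulate_ode(p)
        terminal = traj.states[-1]
        dom = int(np.argmax(terminal))

        def fp(x):
            return drift(np.abs(x), 2000.0, p)

        sol = np.abs(fsolve(fp, terminal, xtol=1e-12))
        # the non-autonomous trajectory lags the instantaneous equilibrium a little
        assert terminal[dom] == pytest.approx(sol[dom], rel=0.05)


class TestSde:
    def test_reproducible_from_seed(self):
        p = CFRParams(alpha=1000.0)
        s = SimSettings(sigma=0.02, seed=7, t_end=200.0)
        a = simulate_sde(p, settings=s)
        b = simulate_sde(p, settings=s)
        np.testing.assert_array_equal(a.states, b.states)

    def test_states_stay_nonnegative(self):
        traj = simulate_sde(
            CFRParams(alpha=1000.0), settings=SimSettings(sigma=0.02, seed=3)
        )
        assert traj.states.min() >= 0.0

    def test_noise_free_path_converges_to_ode(self):
        """sigma=0 Euler error vs the adaptive solution halves with dt."""
        p = CFRParams(alpha=1.0)
        ref = simulate_ode(p, settings=SimSettings(t_end=500.0, dt=0.05))
        errs = {}
        for dt in (0.2, 0.1):
            em = simulate_sde(p, settings=SimSettings(sigma=0.0, dt=dt, t_end=500.0))
            step = int(round(dt / 0.05))
            errs[dt] = np.abs(em.states - ref.states[::step]).max()
        assert errs[0.1] < 0.7 * errs[0.2]

    def test_ensemble_spread_grows_with_sigma(self):
        """Path-to-path dispersion at fixed t increases with the noise level."""
        p = CFRParams(alpha=1000.0)
        spreads = []
        for sigma in (0.005, 0.01, 0.02):
            _, states = simulate_sde_ensemble(
                p, settings=SimSettings(sigma=sigma, seed=5), n_paths=100
            )
            # t = 300: pre-commitment, where dispersion tracks sigma directly
            # (post-commitment spread is dominated by escape-time jitter)
            at_t = states[3000]
            spreads.append(float(np.linalg.norm(at_t.std(axis=0))))
        assert spreads[0] < spreads[1] < spreads[2]

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            SimSettings(dt=0.0)


class TestEquilibrium:
    def test_no_signal_limit_is_basal_over_degradation(self):
        p = CFRParams(alpha=1000.0)
        assert symmetric_equilibrium(p, 0.0) == pytest.approx(
            p.b_prod / p.d_deg, rel=1e-10
        )

    def test_monotone_in_signal(self):
        p = CFRParams(alpha=100.0)
        levels = [symmetric_equilibrium(p, g) for g in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(levels) > 0)

    def test_matches_dense_bisection_oracle(self):
        p = CFRParams(alpha=1000.0, beta=0.1)
        g = 0.5
        lo, hi = 0.0, 100.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            xh = mid**p.hill_h
            resid = p.d_deg * mid - p.b_prod - g / (
                (1 + p.alpha * xh) * (1 + p.beta * xh)
            )
            if resid < 0:
                lo = mid
            else:
                hi = mid
        assert symmetric_equilibrium(p, g) == pytest.approx(lo, abs=1e-8)


class TestLinearStability:
    def test_equal_rings_give_no_oscillation(self):
        p = CFRParams(alpha=0.5, beta=0.5)
        assert linear_stability(p, 1.0).eig_imag_pair == pytest.approx(0.0, abs=1e-14)

    def test_closed_form_matches_dense_eigensolver(self, rng):
        """Circulant eigenvalues agree with numpy on 100 random draws."""
        for _ in range(100):
            p = CFRParams(
                alpha=10 ** rng.uniform(-1, 3),
                beta=10 ** rng.uniform(-2, 1),
                d_deg=rng.uniform(0.01, 1.0),
                hill_h=rng.integers(1, 5),
            )
            g = rng.uniform(0.0, 4.0)
            res = linear_stability(p, g)
            eig = np.linalg.eigvals(jacobian_at_equilibrium(p, g))
            imag = np.sort(np.abs(eig.imag))
            real_pair = eig.real[np.argmax(np.abs(eig.imag))]
            assert res.eig_imag_pair == pytest.approx(imag[-1], abs=1e-10)
            if res.eig_imag_pair > 1e-8:
                assert res.eig_real_pair == pytest.approx(real_pair, abs=1e-10)
            assert np.min(eig.real) == pytest.approx(
                min(res.eig_real_sym, res.eig_real_pair), abs=1e-10
            )

    def test_oscillation_frequency_proportional_to_ring_asymmetry(self):
        """At small x* the imaginary part scales linearly with alpha - beta."""
        g = 1e-3  # keeps x* small so the Hill terms stay linearizable
        ratios = []
        for alpha in (0.2, 1.0, 5.0):
            p = CFRParams(alpha=alpha, beta=0.1)
            ratios.append(linear_stability(p, g).eig_imag_pair / (alpha - 0.1))
        assert max(ratios) / min(ratios) == pytest.approx(1.0, rel=0.01)


class TestHopfScan:
    def test_negligible_inhibition_never_destabilizes(self):
        p = CFRParams(alpha=1e-6, beta=1e-6)
        assert hopf_scan(p, SignalParams(), np.linspace(1, 2000, 50)) is None

    def test_default_parameters_lose_stability_in_finite_time(self):
        p = CFRParams(alpha=1.0)
        onset = hopf_scan(p, SignalParams(), np.linspace(1, 2000, 400))
        assert onset is not None and 0 < onset < 2000

    def test_onset_agrees_with_numerical_eigensolver(self):
        p = CFRParams(alpha=100.0)
        grid = np.linspace(1, 2000, 200)
        onset = hopf_scan(p, SignalParams(), grid)
        numeric = None
        for t in grid:
            eig = np.linalg.eigvals(jacobian_at_equilibrium(p, signal_g(t)))
            if eig.real.max() > 0:
                numeric = t
                break
        assert onset == pytest.approx(numeric)
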