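"""Dual-cutoff state labeling, transition counting, the exchange-rate closed
form, block errors, and the TST upper bound."""

import numpy as np
import pytest

from mgff.binding import FreeEnergyProfile
from mgff.errors import ConfigError, DomainError, InputError
from mgff.exchange import (
    ShellIndicator,
    StateSeries,
    block_error,
    count_transitions,
    exchange_rate,
    expected_transitions,
    label_states,
    tst_rate,
)
from mgff.synthetic import (
    MG_WATER_REDUCED_MASS,
    HoppingSpec,
    gen_hopping_traj,
    matched_profile,
)
from mgff.units import kT


class TestLabeling:
    def test_water_inside_bound_cutoff_never_transitions(self, make_single_water):
        traj = make_single_water([0.21] * 20)
        series = label_states(traj)
        assert np.all(series.states == 0)
        assert count_transitions(series) == 0

    def test_forward_and_reverse_each_count(self, make_single_water):
        traj = make_single_water([0.27, 0.41, 0.27])
        series = label_states(traj)
        assert list(series.states[:, 0]) == [0, -1, 0]
        assert count_transitions(series) == 2

    def test_hysteresis_suppresses_recrossing_noise(self, make_single_water):
        # oscillation strictly between the cutoffs commits nothing
        traj = make_single_water([0.27, 0.30, 0.38, 0.30, 0.38, 0.30])
        series = label_states(traj)
        assert count_transitions(series) == 0
        assert np.all(series.states == 0)  # initial committed state persists

    def test_initial_state_resolved_by_nearest_cutoff(self, make_single_water):
        near_unbound = label_states(make_single_water([0.38, 0.38]))
        assert near_unbound.states[0, 0] == -1
        near_bound = label_states(make_single_water([0.30, 0.30]))
        assert near_bound.states[0, 0] == 0

    def test_bad_cutoffs_rejected(self):
        with pytest.raises(ConfigError):
            ShellIndicator(r_bound=0.4, r_unbound=0.3)


class TestCounting:
    def test_constant_series(self):
        s = StateSeries(np.zeros((50, 4), dtype=int), np.arange(50.0))
        assert count_transitions(s) == 0

    def test_markov_series_matches_renewal_expectation(self):
        """A stationary two-state Markov chain produces transitions at the
        renewal rate 2 N_w t / (1/k12 + 1/k21), checked within 3 sqrt(N)
        using the exact discrete-chain expectation."""
        rng = np.random.default_rng(7)
        k12, k21, dt, n_frames, n_w = 0.02, 0.05, 1.0, 4000, 50
        p12, p21 = 1 - np.exp(-k12 * dt), 1 - np.exp(-k21 * dt)
        pi0 = p21 / (p12 + p21)  # stationary occupancy of state 0
        states = np.empty((n_frames, n_w), dtype=int)
        states[0] = (rng.uniform(size=n_w) > pi0).astype(int)
        u = rng.uniform(size=(n_frames - 1, n_w))
        for t in range(1, n_frames):
            flip = np.where(states[t - 1] == 0, u[t - 1] < p12, u[t - 1] < p21)
            states[t] = np.where(flip, 1 - states[t - 1], states[t - 1])
        n = count_transitions(StateSeries(states, np.arange(n_frames) * dt))
        # exact per-step flip probability at stationarity (detailed balance)
        expected = (n_frames - 1) * n_w * 2 * pi0 * p12
        assert abs(n - expected) < 3 * np.sqrt(expected)
        # and the discrete expectation is itself within ~k dt of the
        # continuous renewal formula the chain discretizes
        renewal = 2 * n_frames * dt * n_w / (1 / k12 + 1 / k21)
        assert expected == pytest.approx(renewal, rel=0.05)

    def test_concatenation_additivity(self):
        rng = np.random.default_rng(1)
        states = rng.integers(-1, 2, size=(60, 3))
        full = StateSeries(states, np.arange(60.0))
        s1 = StateSeries(states[:30], np.arange(30.0))
        s2 = StateSeries(states[30:], np.arange(30.0, 60.0))
        boundary = int(np.sum(states[30] != states[29]))
        assert count_transitions(full) == count_transitions(s1) + count_transitions(s2) + boundary
        assert 0 <= boundary <= 3


class TestRateClosedForm:
    @pytest.mark.parametrize(
        "N,k_printed,k_tol",
        [
            (376, 8.04e5, 1.20e5),
            (52086, 1.11e8, 0.01e8),
            (6720, 1.44e7, 0.03e7),
        ],
    )
    def test_reference_transition_counts(self, N, k_printed, k_tol):
        """The closed form applied to the reference 1 us, 1 M transition
        counts lands inside the printed rate uncertainties."""
        stats = exchange_rate(N, 2160, 39, 1e-6)
        assert abs(stats.k - k_printed) <= k_tol

    def test_zero_transitions_zero_rate(self):
        assert exchange_rate(0, 2160, 39, 1e-6).k == 0.0

    def test_rate_linear_in_count(self):
        k1 = exchange_rate(100, 2160, 39, 1e-6).k
        k2 = exchange_rate(200, 2160, 39, 1e-6).k
        assert k2 == pytest.approx(2 * k1)

    def test_inversion_round_trip(self):
        n = expected_transitions(5.3e5, 2160, 39, 1e-6)
        assert exchange_rate(n, 2160, 39, 1e-6).k == pytest.approx(5.3e5)
        assert round(n) == 249  # the ~248 exchange events expected in 1 us

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            exchange_rate(10, N_H2O=5, N_Mg=1, t_sim=1e-6, n1=6)
        with pytest.raises(DomainError):
            exchange_rate(10, t_sim=0.0)


class TestBlockError:
    def test_identical_blocks(self):
        mean, err = block_error(np.array([5.0] * 40), n_blocks=4)
        assert err == 0.0

    def test_two_block_hand_arithmetic(self):
        mean, err = block_error(np.array([160.0, 216.0]), n_blocks=2)
        assert mean == pytest.approx(188.0)
        assert err == pytest.approx(28.0)

    def test_permutation_invariance(self):
        a = np.array([160.0, 216.0])
        assert block_error(a, 2)[1] == block_error(a[::-1], 2)[1]

    def test_state_series_blocks(self, make_single_water):
        traj = make_single_water([0.27, 0.41] * 10)
        series = label_states(traj)
        mean, err = block_error(series, n_blocks=2)
        assert mean > 0 and err >= 0

    def test_short_input_rejected(self):
        with pytest.raises(InputError):
            block_error(np.array([1.0]), n_blocks=2)


class TestTST:
    @staticmethod
    def _well_barrier_profile(barrier_extra=0.0):
        r = np.linspace(0.12, 0.7, 4000)
        well = -12.0 * np.exp(-0.5 * ((r - 0.21) / 0.02) ** 2)
        bump = (3.0 + barrier_extra) * np.exp(-0.5 * ((r - 0.35) / 0.02) ** 2)
        return FreeEnergyProfile(r=r, F=well + bump)

    def test_arrhenius_barrier_scaling(self):
        """Raising the barrier by 1 k_BT with the well fixed divides the TST
        rate by e."""
        k0 = tst_rate(self._well_barrier_profile(0.0), MG_WATER_REDUCED_MASS)
        k1 = tst_rate(self._well_barrier_profile(1.0), MG_WATER_REDUCED_MASS)
        assert k1 / k0 == pytest.approx(np.exp(-1.0), rel=1e-3)

    def test_harmonic_well_closed_form(self):
        """For a harmonic well truncated at a sharp barrier the TST rate is
        sqrt(kBT/2 pi mu) e^{-F_barrier} / sqrt(2 pi / kappa)."""
        kappa, f_dagger, mu, T = 4000.0, 9.0, 10.0, 300.0
        r = np.linspace(0.05, 0.61, 8000)
        F = np.minimum(0.5 * kappa * (r - 0.25) ** 2, f_dagger)
        F[r > 0.45] = f_dagger - 10.0 * (r[r > 0.45] - 0.45)  # downhill exit
        prof = FreeEnergyProfile(r=r, F=F)
        analytic = (
            np.sqrt(kT(T) / (2 * np.pi * mu))
            * np.exp(-f_dagger)
            / np.sqrt(2 * np.pi / kappa)
            * 1e12
        )
        assert tst_rate(prof, mu, T) == pytest.approx(analytic, rel=0.01)

    def test_tst_bounds_counting_rate(self, small_hopping):
        """On the matched Kramers benchmark, TST (which neglects diffusive
        recrossing) exceeds the transition-counting estimate."""
        spec, traj = small_hopping
        series = label_states(traj)
        n = count_transitions(series)
        k_count = exchange_rate(n, spec.N_H2O, spec.N_Mg, spec.t_sim).k
        k_tst = tst_rate(matched_profile(spec.k_true), MG_WATER_REDUCED_MASS)
        assert k_tst >= k_count


class TestPipelineConsistency:
    def test_recovers_generator_rate(self, small_hopping):
        spec, traj = small_hopping
        series = label_states(traj)
        n = count_transitions(series)
        k_hat = exchange_rate(n, spec.N_H2O, spec.N_Mg, spec.t_sim).k
        sigma = spec.k_true / np.sqrt(max(n / 2.0, 1.0))
        assert abs(k_hat - spec.k_true) < 3 * sigma

    def test_cutoff_insensitivity(self, small_hopping):
        """+-10% changes of the dual cutoffs move the rate by < 5%."""
        spec, traj = small_hopping
        ks = []
        for rb, ru in [(0.28, 0.40), (0.252, 0.36), (0.308, 0.44)]:
            series = label_states(traj, ShellIndicator(rb, ru))
            n = count_transitions(series)
            ks.append(exchange_rate(n, spec.N_H2O, spec.N_Mg, spec.t_sim).k)
        base = ks[0]
        assert all(abs(k - base) / base < 0.05 for k in ks[1:])
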