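"""Within-compartment dynamics: fixed points, oracles, rounding, bookkeeping."""

import numpy as np
import pytest
from numba import njit

from replinet.core import (
    HOST,
    PARASITE,
    CoefficientMatrix,
    CompartmentState,
    ConfigurationError,
    DynamicsConfig,
    Species,
    SpeciesRegistry,
    discretize_counts,
    integrate_compartments,
    replicate_compartment,
)


# ---------------------------------------------------------------------------
# Independent oracle: fixed-step classical RK4 at dt = 1e-5
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rk4_oracle(y0, k, n_cap, horizon, dt):
    y = y0.copy()
    s = y.shape[0]
    steps = int(round(horizon / dt))
    k1 = np.empty(s); k2 = np.empty(s); k3 = np.empty(s); k4 = np.empty(s)
    tmp = np.empty(s)

    def deriv(y, out):
        tot = 0.0
        for i in range(s):
            tot += y[i]
        fac = 1.0 - tot / n_cap
        for i in range(s):
            lam = 0.0
            for j in range(s):
                lam += k[j, i] * y[j]
            out[i] = y[i] * lam * fac

    for _ in range(steps):
        deriv(y, k1)
        for i in range(s):
            tmp[i] = y[i] + 0.5 * dt * k1[i]
        deriv(tmp, k2)
        for i in range(s):
            tmp[i] = y[i] + 0.5 * dt * k2[i]
        deriv(tmp, k3)
        for i in range(s):
            tmp[i] = y[i] + dt * k3[i]
        deriv(tmp, k4)
        for i in range(s):
            y[i] += dt / 6.0 * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i])
    return y


def _random_states(rng, n, max_total=200):
    """Random 3-species integer states with totals <= 2N."""
    states = []
    while len(states) < n:
        y = rng.integers(0, 80, size=3)
        if 0 < y.sum() <= max_total:
            states.append(y)
    return np.array(states, dtype=np.int64)


HP_K = np.array([[2.0, 2.3, 7.0], [1.7, 2.0, 0.1], [0.0, 0.0, 0.0]])


class TestFixedPoints:
    def setup_method(self):
        h = Species("H1", HOST)
        p = Species("P1", PARASITE)
        self.matrix = CoefficientMatrix(
            [h, p], coeffs={("H1", "H1"): 2.0, ("H1", "P1"): 7.0}
        )
        self.cfg = DynamicsConfig(rounding_mode="nearest")

    def test_empty_compartment_stays_empty(self):
        state, reps = replicate_compartment(
            CompartmentState({}), self.matrix, self.cfg
        )
        assert state.counts == {"H1": 0, "P1": 0}
        assert all(v == 0 for v in reps.values())

    def test_parasite_without_host_cannot_replicate(self):
        state, reps = replicate_compartment(
            CompartmentState({"P1": 50}), self.matrix, self.cfg
        )
        assert state.counts["P1"] == 50
        assert reps == {"H1": 0, "P1": 0}

    def test_capacity_is_a_fixed_point(self):
        state, reps = replicate_compartment(
            CompartmentState({"H1": 100}), self.matrix, self.cfg
        )
        assert state.counts["H1"] == 100
        assert reps["H1"] == 0

    def test_species_at_zero_stays_zero(self):
        state, _ = replicate_compartment(
            CompartmentState({"H1": 10}), self.matrix, self.cfg
        )
        assert state.counts["P1"] == 0


class TestOracleAgreement:
    def test_single_host_matches_fine_step_oracle(self):
        # k = 2, H0 = 10, N = 100, T = 1
        k = np.array([[2.0]])
        ours = integrate_compartments(
            np.array([[10]]), k, DynamicsConfig()
        )[0, 0]
        ref = _rk4_oracle(np.array([10.0]), k, 100.0, 1.0, 1e-5)[0]
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_random_three_species_states_match_oracle(self, rng):
        cfg = DynamicsConfig()
        states = _random_states(rng, 25)
        ours = integrate_compartments(states, HP_K, cfg)
        for row, y0 in zip(ours, states):
            ref = _rk4_oracle(y0.astype(np.float64), HP_K, 100.0, 1.0, 1e-5)
            rel = np.abs(row - ref) / np.maximum(np.abs(ref), 1e-6)
            assert rel.max() < 1e-4

    def test_agrees_with_scipy_adaptive_solver(self, rng):
        from scipy.integrate import solve_ivp

        cfg = DynamicsConfig()
        states = _random_states(rng, 10)
        ours = integrate_compartments(states, HP_K, cfg)

        def f(_, y):
            return y * (HP_K.T @ y) * (1 - y.sum() / 100.0)

        for row, y0 in zip(ours, states):
            ref = solve_ivp(
                f, (0, 1), y0.astype(float), rtol=1e-10, atol=1e-12
            ).y[:, -1]
            assert np.allclose(row, ref, rtol=1e-4, atol=1e-6)

    def test_decay_from_above_capacity(self):
        # fused compartments can exceed N; counts decay toward N, never < 0
        k = np.array([[2.0]])
        out = integrate_compartments(np.array([[180]]), k, DynamicsConfig())
        ref = _rk4_oracle(np.array([180.0]), k, 100.0, 1.0, 1e-5)[0]
        assert 100.0 <= out[0, 0] <= 180.0
        assert out[0, 0] == pytest.approx(ref, rel=1e-6)


class TestSaturationProperties:
    def test_monotone_saturation_bounded_by_capacity(self):
        k = np.array([[1.7]])
        prev = 3.0
        for horizon in (0.1, 0.3, 1.0, 3.0, 10.0):
            out = integrate_compartments(
                np.array([[3]]), k, DynamicsConfig(horizon=horizon)
            )[0, 0]
            assert out >= prev - 1e-9
            assert out <= 100.0 + 1e-6
            prev = out

    def test_horizon_insensitivity_at_screen_coefficients(self):
        # saturation by T = 1 makes the endpoint independent of T for the
        # coefficient magnitudes the screens use
        for k in (1.7, 2.0, 2.6):
            km = np.array([[k]])
            for y0 in (5, 30, 80):
                a = integrate_compartments(
                    np.array([[y0]]), km, DynamicsConfig(horizon=1.0)
                )[0, 0]
                b = integrate_compartments(
                    np.array([[y0]]), km, DynamicsConfig(horizon=10.0)
                )[0, 0]
                assert abs(a - b) < 1e-6

    def test_horizon_matters_for_weak_replicators(self):
        # k ~ 0.2 with a small inoculum does NOT saturate by T = 1: the
        # endpoint is genuinely horizon-dependent in that corner
        km = np.array([[0.2]])
        a = integrate_compartments(
            np.array([[5]]), km, DynamicsConfig(horizon=1.0)
        )[0, 0]
        b = integrate_compartments(
            np.array([[5]]), km, DynamicsConfig(horizon=10.0)
        )[0, 0]
        assert a < 50.0
        assert b > 99.0


class TestDiscretization:
    def test_stochastic_rounding_is_unbiased(self, rng):
        value = np.full((10_000,), 41.37)
        rounded = discretize_counts(value, "stochastic", rng)
        assert set(np.unique(rounded)) <= {41, 42}
        se = np.sqrt(0.37 * 0.63 / 10_000)
        assert abs(rounded.mean() - 41.37) < 3 * se

    def test_nearest_rounding_is_deterministic(self):
        out = discretize_counts(np.array([41.37, 41.6]), "nearest", None)
        assert out.tolist() == [41, 42]

    def test_negative_noise_clips_to_zero(self, rng):
        out = discretize_counts(np.array([-1e-12]), "stochastic", rng)
        assert out[0] == 0


class TestValidation:
    def test_unknown_species_in_state_is_a_configuration_error(self, hp_matrix):
        with pytest.raises(ConfigurationError, match="not covered"):
            replicate_compartment(
                CompartmentState({"HX": 5}), hp_matrix, DynamicsConfig()
            )

    def test_parasites_cannot_be_replicase(self, host1, parasite1):
        with pytest.raises(ConfigurationError, match="replicase"):
            CoefficientMatrix(
                [host1, parasite1],
                coeffs={("P1", "H1"): 1.0},
            )

    def test_negative_coefficients_rejected(self, host1):
        with pytest.raises(ConfigurationError):
            CoefficientMatrix([host1], coeffs={("H1", "H1"): -0.5})

    def test_registry_rejects_duplicate_ids(self, host1):
        reg = SpeciesRegistry([host1])
        with pytest.raises(ConfigurationError, match="duplicate"):
            reg.add(Species("H1", PARASITE))

    def test_species_role_is_validated(self):
        with pytest.raises(ConfigurationError):
            Species("X", "virus")

    @pytest.mark.parametrize("field,value", [
        ("carrying_capacity", 0), ("horizon", 0.0), ("rounding_mode", "up"),
    ])
    def test_dynamics_config_validation(self, field, value):
        with pytest.raises(ConfigurationError):
            DynamicsConfig(**{field: value})


class TestCoefficientMatrixIO:
    def test_csv_round_trip_is_identity(self, table1_matrix, tmp_path):
        path = tmp_path / "k.csv"
        table1_matrix.to_csv(path)
        back = CoefficientMatrix.from_csv(path)
        assert back == table1_matrix

    def test_host_and_parasite_views(self, table1_matrix):
        assert table1_matrix.host_coeffs[("H2", "H1")] == 2.3
        assert table1_matrix.parasite_coeffs[("H1", "P1")] == 6.7
        assert ("P1", "H1") not in table1_matrix.host_coeffs
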