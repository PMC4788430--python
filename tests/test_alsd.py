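import dataclasses

import numpy as np
import pytest

from tailensemble.alsd import (ALSDConfig, ALSDState, AdaptationError, BiasEstimate,
                               IntegrationError, Trajectory, adapt_bias,
                               hamiltonian_potential, initial_state, lambda_force,
                               run_production, run_ttp, step_langevin)
from tailensemble.constants import rt
from tailensemble.energetics import (CGEnergetics, EnergyDecomposition,
                                     HarmonicTailSystem)


@pytest.fixture
def config():
    return ALSDConfig(timestep=0.02, friction=1.0)


@pytest.fixture
def flat_bias(config):
    return BiasEstimate.zero(config.lambda_min, config.lambda_max, 30)


class TestConfigValidation:
    def test_lambda_range_must_contain_one(self):
        with pytest.raises(ValueError):
            ALSDConfig(lambda_min=0.5, lambda_max=0.9)
        ALSDConfig(lambda_min=1.0, lambda_max=1.0)  # equality allowed

    def test_positive_parameters(self):
        with pytest.raises(ValueError):
            ALSDConfig(m_lambda=-1.0)
        with pytest.raises(ValueError):
            ALSDConfig(timestep=0.0)


class TestBiasEstimate:
    def test_grid_validation(self):
        with pytest.raises(ValueError):
            BiasEstimate(np.array([1.0, 0.5]), np.zeros(2))
        with pytest.raises(ValueError):
            BiasEstimate(np.array([0.5, 1.0]), np.array([0.0, np.inf]))

    def test_interpolation_continuity(self):
        grid = np.linspace(0.6, 1.03, 10)
        bias = BiasEstimate(grid, -np.log(grid))
        for knot in grid[1:-1]:
            left = bias.value(knot - 1e-9)
            right = bias.value(knot + 1e-9)
            assert left == pytest.approx(right, abs=1e-6)
            dl = bias.derivative(knot - 1e-9)
            dr = bias.derivative(knot + 1e-9)
            assert dl == pytest.approx(dr, abs=1e-4)

    def test_linear_continuation_outside_range(self):
        grid = np.linspace(0.6, 1.03, 10)
        bias = BiasEstimate(grid, -np.log(grid))
        slope_lo = bias.derivative(0.6)
        assert bias.value(0.55) == pytest.approx(bias.value(0.6) - 0.05 * slope_lo)
        assert bias.derivative(0.55) == slope_lo
        assert bias.derivative(1.2) == bias.derivative(1.03)

    def test_hash_changes_with_content(self):
        a = BiasEstimate.zero(0.6, 1.03, 10)
        b = a.shifted(1.0)
        assert a.content_hash() != b.content_hash()

    def test_dict_roundtrip(self):
        a = BiasEstimate(np.linspace(0.6, 1.03, 8), np.arange(8.0))
        b = BiasEstimate.from_dict(a.to_dict())
        assert a.content_hash() == b.content_hash()


class TestHamiltonian:
    def test_identity_at_lambda_one(self, config, flat_bias):
        d = EnergyDecomposition(2.0, 3.0, 5.0)
        assert hamiltonian_potential(d, 1.0, flat_bias, config) == pytest.approx(10.0)

    def test_scaling_arithmetic(self, config, flat_bias):
        d = EnergyDecomposition(2.0, 3.0, 5.0)
        v = hamiltonian_potential(d, 0.6, flat_bias, config)
        assert v == pytest.approx(7.52, abs=1e-12)

    def test_bias_gauge_shift(self, config, flat_bias):
        d = EnergyDecomposition(1.0, 1.0, 1.0)
        shifted = flat_bias.shifted(2.5)
        for lam in (0.7, 0.9, 1.0):
            dv = (hamiltonian_potential(d, lam, shifted, config)
                  - hamiltonian_potential(d, lam, flat_bias, config))
            assert dv == pytest.approx(config.rt * 2.5, rel=1e-10)

    def test_wall_inside_is_zero(self, config, flat_bias):
        d = EnergyDecomposition(0.0, 0.0, 0.0)
        assert hamiltonian_potential(d, config.lambda_max, flat_bias, config) == 0.0
        assert hamiltonian_potential(d, config.lambda_min, flat_bias, config) == 0.0

    def test_wall_outside_positive(self, config, flat_bias):
        d = EnergyDecomposition(0.0, 0.0, 0.0)
        v = hamiltonian_potential(d, config.lambda_max + 0.05, flat_bias, config)
        assert v == pytest.approx(config.wall_k * 0.05 ** 2)

    def test_far_outside_walls_error(self, config, flat_bias):
        d = EnergyDecomposition(0.0, 0.0, 0.0)
        with pytest.raises(IntegrationError):
            hamiltonian_potential(d, 2.0, flat_bias, config)


class TestLambdaForce:
    def test_zero_when_flat(self, config, flat_bias):
        d = EnergyDecomposition(0.0, 0.0, 7.0)
        assert lambda_force(d, 0.8, flat_bias, config) == 0.0

    def test_matches_finite_difference(self, config):
        grid = np.linspace(config.lambda_min, config.lambda_max, 20)
        bias = BiasEstimate(grid, np.sin(grid * 3))
        d = EnergyDecomposition(1.7, -2.3, 4.0)
        for lam in (0.65, 0.8, 1.0, 1.02):
            eps = 1e-7
            fd = -(hamiltonian_potential(d, lam + eps, bias, config)
                   - hamiltonian_potential(d, lam - eps, bias, config)) / (2 * eps)
            assert lambda_force(d, lam, bias, config) == pytest.approx(fd, rel=1e-5)

    def test_positive_e_tail_pushes_lambda_down(self, config, flat_bias):
        d = EnergyDecomposition(5.0, 0.0, 0.0)
        assert lambda_force(d, 0.9, flat_bias, config) < 0


class TestStepLangevin:
    def test_deterministic_given_seed(self, harmonic_system, config, flat_bias):
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            state = initial_state(harmonic_system, config, rng)
            for _ in range(50):
                state = step_langevin(state, harmonic_system, flat_bias, config, rng)
            runs.append((state.positions.copy(), state.lam, state.lambda_velocity))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]

    def test_overdamped_limit_descends(self, harmonic_system, flat_bias):
        config = ALSDConfig(timestep=0.01, friction=1e8, freeze_lambda=True)

        class ZeroRng:
            def standard_normal(self, size=None):
                return np.zeros(size) if size is not None else 0.0

        state = ALSDState(np.array([[2.0, 0.0, 0.0]]), np.zeros((1, 3)), 1.0, 0.0)
        e0 = harmonic_system.decompose(state.positions).e_tail
        new = step_langevin(state, harmonic_system, flat_bias, config, ZeroRng())
        e1 = harmonic_system.decompose(new.positions).e_tail
        assert e1 < e0  # moved along the force (steepest descent direction)

    def test_equipartition_harmonic(self, flat_bias):
        # <x^2> = RT / k for a harmonic coordinate at 300 K
        k = 2.0
        system = HarmonicTailSystem(k=k)
        config = ALSDConfig(timestep=0.05, friction=1.0, freeze_lambda=True)
        rng = np.random.default_rng(2024)
        state = initial_state(system, config, rng)
        xs = []
        from tailensemble.alsd import _integrate

        _integrate(state, system, flat_bias, config, rng, 2000)  # equilibrate
        for _ in range(200):
            _integrate(state, system, flat_bias, config, rng, 50)
            xs.append(state.positions[0, 0])
        var = np.var(xs)
        assert var == pytest.approx(rt(300.0) / k, rel=0.05)

    def test_nonfinite_force_reports_step(self, config, flat_bias):
        class BadSystem(HarmonicTailSystem):
            def forces_and_decompose(self, pos, lam):
                f, d = super().forces_and_decompose(pos, lam)
                return f * np.nan, d

        rng = np.random.default_rng(0)
        system = BadSystem()
        state = initial_state(system, config, rng)
        with pytest.raises(IntegrationError, match="step"):
            step_langevin(state, system, flat_bias, config, rng)


class TestFastPathEquivalence:
    def test_jit_loop_matches_python_loop(self, small_system):
        """The chunked jit integrator reproduces the python loop bit-for-bit
        over a short window (same noise stream, same arithmetic)."""
        from tailensemble.alsd import _integrate, initial_state

        eng = CGEnergetics(small_system)
        if not eng.supports_jit_integration(small_system.positions):
            pytest.skip("numba unavailable")
        config = ALSDConfig(timestep=0.01, friction=0.2, m_lambda=5.0)
        grid = np.linspace(config.lambda_min, config.lambda_max, 12)
        bias = BiasEstimate(grid, -3.0 * np.log(grid))

        def run(force_slow: bool):
            rng = np.random.default_rng(31)
            state = initial_state(eng, config, rng, small_system.positions)
            if force_slow:
                original = eng.supports_jit_integration
                eng.supports_jit_integration = lambda pos: False
                try:
                    _integrate(state, eng, bias, config, rng, 150)
                finally:
                    eng.supports_jit_integration = original
            else:
                _integrate(state, eng, bias, config, rng, 150)
            return state

        fast = run(False)
        slow = run(True)
        assert np.allclose(fast.positions, slow.positions, atol=1e-10)
        assert fast.lam == pytest.approx(slow.lam, abs=1e-12)
        assert np.allclose(fast.velocities, slow.velocities, atol=1e-10)


class TestAdaptBias:
    def test_flat_target_stays_flat(self, flat_bias):
        # E_tail constant (zero), no coupling: ln_p converges to a constant
        class FreeSystem(HarmonicTailSystem):
            def decompose(self, pos):
                return EnergyDecomposition(0.0, 0.0, 0.0)

            def forces_and_decompose(self, pos, lam):
                return np.zeros_like(pos), self.decompose(pos)

        config = ALSDConfig(timestep=0.02, friction=1.0)
        result = adapt_bias(FreeSystem(), config, n_iterations=6,
                            steps_per_iteration=4000, seed=3)
        spread = result.bias.ln_p.max() - result.bias.ln_p.min()
        assert spread < 0.35  # constant within stochastic tolerance

    def test_requires_iterations(self, harmonic_system):
        config = ALSDConfig()
        with pytest.raises(ValueError):
            adapt_bias(harmonic_system, config, 0, 100, seed=1)

    def test_stuck_lambda_diagnostic(self, harmonic_system):
        # an immovable lambda (huge mass, tiny steps) never leaves one bin
        config = ALSDConfig(timestep=1e-6, friction=1.0, m_lambda=1e12)
        with pytest.raises(AdaptationError, match="m_lambda"):
            adapt_bias(harmonic_system, config, n_iterations=2,
                       steps_per_iteration=300, seed=1)


class TestProduction:
    def test_zero_steps_initial_frame_only(self, harmonic_system, flat_bias):
        config = ALSDConfig(n_steps=0)
        traj = run_production(harmonic_system, config, flat_bias, seed=9)
        assert traj.n_frames == 1
        assert traj.steps[0] == 0

    def test_frame_energies_recomputable(self, small_system, flat_bias):
        eng = CGEnergetics(small_system)
        config = ALSDConfig(timestep=0.01, n_steps=400, save_interval=100)
        traj = run_production(eng, config, flat_bias, seed=5)
        for f in range(traj.n_frames):
            d = eng.decompose(traj.positions[f])
            assert d.e_tail == pytest.approx(traj.e_tail[f], rel=1e-8)
            assert d.e_tail_rest == pytest.approx(traj.e_tail_rest[f], rel=1e-8)

    def test_metadata_records_hashes(self, harmonic_system, flat_bias):
        config = ALSDConfig(n_steps=10)
        traj = run_production(harmonic_system, config, flat_bias, seed=1)
        assert traj.metadata["bias_hash"] == flat_bias.content_hash()
        assert traj.metadata["config_hash"] == config.content_hash()

    def test_npz_roundtrip(self, harmonic_system, flat_bias, tmp_path):
        config = ALSDConfig(n_steps=50, save_interval=10)
        traj = run_production(harmonic_system, config, flat_bias, seed=1)
        path = tmp_path / "t.npz"
        traj.save_npz(path)
        back = Trajectory.load_npz(path)
        assert np.array_equal(back.positions, traj.positions)
        assert np.array_equal(back.lambdas, traj.lambdas)
        assert back.metadata == traj.metadata

    def test_text_export(self, harmonic_system, flat_bias, tmp_path):
        config = ALSDConfig(n_steps=30, save_interval=10)
        traj = run_production(harmonic_system, config, flat_bias, seed=1)
        path = tmp_path / "t.txt"
        traj.export_text(path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("#")
        assert len(lines) == traj.n_frames + 1


class TestTTP:
    def test_determinism(self, small_system, flat_bias):
        config = ALSDConfig(timestep=0.01, n_steps=200, save_interval=50)
        a = run_ttp(small_system, config, flat_bias, n_runs=2, base_seed=3)
        b = run_ttp(small_system, config, flat_bias, n_runs=2, base_seed=3)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.positions, tb.positions)
            assert np.array_equal(ta.lambdas, tb.lambdas)

    def test_distinct_seeds_and_starts(self, small_system, flat_bias):
        config = ALSDConfig(timestep=0.01, n_steps=100, save_interval=50)
        trajs = run_ttp(small_system, config, flat_bias, n_runs=4, base_seed=1)
        seeds = {t.metadata["seed"] for t in trajs}
        assert len(seeds) == 4
        starts = [t.positions[0] for t in trajs]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not np.array_equal(starts[i], starts[j])

    def test_minimum_runs(self, small_system, flat_bias):
        with pytest.raises(ValueError):
            run_ttp(small_system, ALSDConfig(), flat_bias, n_runs=1, base_seed=0)

    def test_between_run_variance_nonzero(self, small_system, flat_bias):
        config = ALSDConfig(timestep=0.01, n_steps=300, save_interval=50)
        trajs = run_ttp(small_system, config, flat_bias, n_runs=3, base_seed=2)
        means = [t.e_tail.mean() for t in trajs]
        assert np.std(means) > 0


class TestEquivalenceWithPlainLangevin:
    def test_frozen_lambda_matches_plain_md(self, flat_bias):
        """With lambda pinned at 1 and zero bias the sampler is plain Langevin.

        Oracle: an independently coded BAOAB integrator for the harmonic
        bead, driven by the same noise stream.
        """
        k = 2.0
        system = HarmonicTailSystem(k=k)
        config = ALSDConfig(timestep=0.05, friction=1.0, freeze_lambda=True,
                            lambda_min=1.0, lambda_max=1.0)
        rng = np.random.default_rng(77)
        state = ALSDState(np.zeros((1, 3)), np.zeros((1, 3)), 1.0, 0.0)
        n = 500
        from tailensemble.alsd import _integrate

        _integrate(state, system, flat_bias_one := BiasEstimate.zero(1.0, 1.0 + 1e-9, 2),
                   config, rng, n)

        # independent plain BAOAB with identical noise stream
        rng2 = np.random.default_rng(77)
        kt = rt(300.0)
        dt, gamma, m = 0.05, 1.0, 1.0
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt((1 - c1 * c1) * kt / m)
        x = np.zeros(3)
        v = np.zeros(3)

        def force(x):
            return np.array([-k * x[0], 0.0, 0.0])

        f = force(x)
        for _ in range(n):
            v = v + 0.5 * dt * f / m
            x = x + 0.5 * dt * v
            v = c1 * v + c2 * rng2.standard_normal(size=(1, 3))[0]
            x = x + 0.5 * dt * v
            f = force(x)
            v = v + 0.5 * dt * f / m
        assert np.allclose(state.positions[0], x, atol=1e-10)
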