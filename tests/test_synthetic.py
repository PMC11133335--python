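"""Ground-truth generators: stable systems, impulse responses, fixtures."""

import numpy as np
import pytest

from era_lfp import (
    MultiChannelRecording,
    StateSpaceSystem,
    SyntheticConfig,
    generate_piecewise_linear,
    generate_state_space_system,
    generate_synthetic_lfp,
    impulse_response,
    samples_per_phase,
)


class TestGenerateSystem:
    def test_scalar_eigenvalue_placed_exactly(self):
        sys_ = generate_state_space_system(1, spectral_radius=0.5, seed=0)
        assert np.allclose(sys_.A, [[0.5]])
        assert np.allclose(np.linalg.eigvals(sys_.A), [0.5])

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_spectral_radius_bound(self, seed):
        sys_ = generate_state_space_system(4, spectral_radius=0.9, seed=seed)
        assert np.max(np.abs(np.linalg.eigvals(sys_.A))) <= 0.9 + 1e-12

    def test_seed_determinism(self):
        a = generate_state_space_system(5, 2, 3, 0.85, seed=42)
        b = generate_state_space_system(5, 2, 3, 0.85, seed=42)
        assert np.array_equal(a.A, b.A)
        assert np.array_equal(a.B, b.B)
        assert np.array_equal(a.C, b.C)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError, match="order"):
            generate_state_space_system(0)
        with pytest.raises(ValueError, match="spectral_radius"):
            generate_state_space_system(2, spectral_radius=1.0)
        with pytest.raises(ValueError, match="spectral_radius"):
            generate_state_space_system(2, spectral_radius=-0.1)

    def test_prescribed_eigenvalues_modal_sum(self):
        # closed-form oracle: diagonal A with B = C = ones gives the
        # impulse response sum_i lambda_i^(k-1)
        lam = np.array([0.9, 0.5, 0.1])
        sys_ = StateSpaceSystem(A=np.diag(lam), B=np.ones((3, 1)), C=np.ones((1, 3)))
        y = impulse_response(sys_, 10).samples[0]
        k = np.arange(1, 10)
        expected = np.concatenate(([0.0], np.sum(lam[None, :] ** (k[:, None] - 1), axis=1)))
        assert np.allclose(y, expected, atol=1e-12)

    def test_prescribed_eigenvalues_via_generator(self):
        sys_ = generate_state_space_system(3, eigenvalues=[0.9, 0.5, 0.1], seed=1)
        assert np.allclose(sorted(np.linalg.eigvals(sys_.A)), [0.1, 0.5, 0.9])


class TestImpulseResponse:
    def test_scalar_geometric(self):
        sys_ = StateSpaceSystem(A=[[0.5]], B=[[1.0]], C=[[1.0]])
        y = impulse_response(sys_, 4).samples[0]
        assert np.allclose(y, [0.0, 1.0, 0.5, 0.25])

    def test_nilpotent_truncates(self, rng):
        B = rng.standard_normal((2, 1))
        C = rng.standard_normal((1, 2))
        sys_ = StateSpaceSystem(A=np.zeros((2, 2)), B=B, C=C)
        y = impulse_response(sys_, 5).samples
        assert y[0, 0] == 0.0
        assert np.isclose(y[0, 1], (C @ B).item())
        assert np.allclose(y[:, 2:], 0.0)

    def test_matches_brute_force_matrix_powers(self, order3_system):
        m = 10
        y = impulse_response(order3_system, m).samples
        b1 = order3_system.B @ np.ones(order3_system.n_inputs)
        for k in range(1, m):
            expected = order3_system.C @ np.linalg.matrix_power(order3_system.A, k - 1) @ b1
            assert np.allclose(y[:, k], expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            StateSpaceSystem(A=np.eye(2), B=np.ones((3, 1)), C=np.ones((1, 2)))


class TestPiecewiseLinear:
    def test_two_knot_line(self):
        rec = generate_piecewise_linear([0.0, 1.0], [0.0, 1.0], rate=10.0)
        assert np.allclose(rec.samples[0], np.arange(11) / 10.0)

    def test_collinear_knots_match_two_knot_line(self):
        a = generate_piecewise_linear([0.0, 2.0], [1.0, 3.0], rate=20.0)
        b = generate_piecewise_linear([0.0, 1.0, 2.0], [1.0, 2.0, 3.0], rate=20.0)
        assert np.allclose(a.samples, b.samples)

    def test_17_knot_interpolant_exact(self, rng):
        kt = np.arange(17.0)
        kv = rng.standard_normal(17)
        rec = generate_piecewise_linear(kt, kv, rate=50.0)
        expected = np.interp(rec.times(), kt, kv)
        assert np.abs(rec.samples[0] - expected).max() == 0.0

    def test_unsorted_knots_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            generate_piecewise_linear([0.0, 2.0, 1.0], [0, 1, 2], rate=10.0)

    def test_noise_reproducible(self):
        a = generate_piecewise_linear([0, 1], [0, 1], 100.0, noise_sd=0.3, seed=5)
        b = generate_piecewise_linear([0, 1], [0, 1], 100.0, noise_sd=0.3, seed=5)
        assert np.array_equal(a.samples, b.samples)


def _tiny_config(**kw):
    base = dict(
        n_channels=2, rate=100.0, phase_duration=2.0, n_phases=3,
        true_order_schedule=(6, 4, 2), amplitude_schedule=(1.0, 0.5, 0.25),
        noise_sd=0.0, trend_knot_count=0, seed=0,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestSyntheticLfp:
    def test_paper_scale_phase_arithmetic(self):
        # 5 minutes at 3000 Hz is exactly 900k samples per channel
        assert samples_per_phase(3000.0, 300.0) == 900_000

    def test_all_zero_when_everything_off(self):
        cfg = _tiny_config(amplitude_schedule=(0.0, 0.0, 0.0))
        rec = generate_synthetic_lfp(cfg)
        assert np.all(rec.samples == 0.0)

    def test_phase_boundaries_and_counts(self):
        cfg = _tiny_config()
        rec = generate_synthetic_lfp(cfg)
        assert rec.n_samples == 3 * samples_per_phase(100.0, 2.0)
        assert np.array_equal(rec.phase_boundaries, [0, 200, 400, 600])

    def test_rms_follows_amplitude_schedule(self):
        cfg = _tiny_config()
        rec = generate_synthetic_lfp(cfg)
        rms = [
            np.sqrt(np.mean(rec.samples[:, a:b] ** 2))
            for a, b in zip(rec.phase_boundaries[:-1], rec.phase_boundaries[1:])
        ]
        assert np.allclose(rms, cfg.amplitude_schedule, rtol=1e-9)
        assert np.all(np.diff(rms) < 0)

    def test_zero_amplitude_leaves_only_trend(self):
        cfg = _tiny_config(amplitude_schedule=(0.0, 0.0, 0.0),
                           trend_knot_count=4, trend_scale=1.0)
        rec = generate_synthetic_lfp(cfg)
        # trend is piecewise linear: second differences vanish away from knots
        d2 = np.diff(rec.samples[0], n=2)
        assert np.count_nonzero(np.abs(d2) > 1e-9) <= 2 * (4 + 2)

    def test_bit_identical_under_same_seed(self):
        a = generate_synthetic_lfp(_tiny_config(noise_sd=0.1, trend_knot_count=3))
        b = generate_synthetic_lfp(_tiny_config(noise_sd=0.1, trend_knot_count=3))
        assert np.array_equal(a.samples, b.samples)

    def test_schedule_length_validation(self):
        with pytest.raises(ValueError, match="true_order_schedule"):
            _tiny_config(true_order_schedule=(4, 2))

    def test_recording_validation(self):
        with pytest.raises(ValueError, match="rate"):
            MultiChannelRecording(samples=np.zeros((1, 5)), rate=0.0)
        with pytest.raises(ValueError, match="increasing"):
            MultiChannelRecording(samples=np.zeros((1, 5)), rate=1.0,
                                  phase_boundaries=[0, 3, 3])
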