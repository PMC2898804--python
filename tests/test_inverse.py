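"""Noise covariance, minimum-norm operator, and dSPM normalization."""

import numpy as np
import pytest
from scipy import stats

from spindlesync import (
    GainMatrix,
    Modality,
    NoiseCovariance,
    SourceEstimate,
    apply_dspm,
    combined_inverse,
    compute_inverse_operator,
    estimate_noise_covariance,
    f_significance,
)


def _random_gain(n_ch, n_src, rng, orthonormal=False):
    G = rng.standard_normal((n_ch, 3 * n_src))
    if orthonormal:
        G = np.linalg.qr(G.T)[0].T[:n_ch]
    names = [f"ch{i}" for i in range(n_ch)]
    return GainMatrix(G, names, np.arange(n_src), Modality.MEG)


class TestNoiseCovariance:
    def test_identical_epochs_reduce_to_single_epoch_variance(self, rng):
        epoch = rng.standard_normal((8, 300))
        epochs = [epoch] * 20
        cov = estimate_noise_covariance(epochs, "baseline_epochs")
        assert np.allclose(cov.diagonal, epoch.var(axis=1), rtol=1e-12)
        assert cov.provenance == "baseline_epochs"
        assert cov.n_epochs_used == 20

    def test_averaging_scales_variance_by_one_over_k(self, rng):
        K, sigma = 100, 2.0
        epochs = sigma * rng.standard_normal((K, 8, 300))
        cov = estimate_noise_covariance(list(epochs), "baseline_epochs")
        assert np.all(np.abs(cov.diagonal / (sigma**2 / K) - 1) < 0.25)

    def test_too_few_epochs(self, rng):
        with pytest.raises(ValueError, match=">= 10"):
            estimate_noise_covariance(list(rng.standard_normal((5, 4, 100))), "baseline_epochs")

    def test_empty_room_mode(self, rng):
        rec = 3.0 * rng.standard_normal((6, 50_000))
        cov = estimate_noise_covariance(rec, "empty_room")
        assert np.all(np.abs(cov.diagonal / 9.0 - 1) < 0.05)

    def test_channel_order_mismatch(self, rng):
        with pytest.raises(ValueError, match="channel"):
            estimate_noise_covariance(
                rng.standard_normal((6, 1000)), "empty_room", channel_order=["a", "b"]
            )


class TestInverseOperator:
    def test_pseudoinverse_limit(self, rng):
        """Orthonormal gain rows, identity noise, vanishing regularization:
        the minimum-norm weights are the Moore-Penrose pseudoinverse."""
        gain = _random_gain(12, 20, rng, orthonormal=True)
        cov = NoiseCovariance(np.ones(12), gain.channel_order, "empty_room", 1)
        op = compute_inverse_operator(gain, cov, snr=1e8)
        assert np.allclose(op.weights, np.linalg.pinv(gain.values), atol=1e-10)

    def test_dspm_norm_positive(self, rng):
        gain = _random_gain(16, 30, rng)
        cov = NoiseCovariance(rng.uniform(0.5, 2.0, 16), gain.channel_order, "empty_room", 1)
        op = compute_inverse_operator(gain, cov, snr=1.0)
        assert np.all(op.dspm_norm > 0)

    def test_dead_source_reported(self, rng):
        gain = _random_gain(16, 10, rng)
        gain.values[:, 9:12] = 0.0
        cov = NoiseCovariance(np.ones(16), gain.channel_order, "empty_room", 1)
        with pytest.raises(np.linalg.LinAlgError, match="\\[3\\]"):
            compute_inverse_operator(gain, cov, snr=1.0)

    def test_nonpositive_snr(self, rng):
        gain = _random_gain(8, 5, rng)
        cov = NoiseCovariance(np.ones(8), gain.channel_order, "empty_room", 1)
        with pytest.raises(ValueError, match="snr"):
            compute_inverse_operator(gain, cov, snr=0.0)

    def test_null_calibration_small(self, rng):
        """E[F] = 1 under noise drawn from the operator's covariance."""
        gain = _random_gain(24, 40, rng)
        diag = rng.uniform(0.5, 3.0, 24)
        cov = NoiseCovariance(diag, gain.channel_order, "empty_room", 1)
        op = compute_inverse_operator(gain, cov, snr=1.0)
        x = np.sqrt(diag)[:, None] * rng.standard_normal((24, 50_000))
        est = apply_dspm(op, x)
        assert (est.values**2).mean() == pytest.approx(1.0, abs=0.05)


class TestApplyDspm:
    def test_zero_input(self, rng):
        gain = _random_gain(10, 8, rng)
        cov = NoiseCovariance(np.ones(10), gain.channel_order, "empty_room", 1)
        op = compute_inverse_operator(gain, cov, snr=1.0)
        est = apply_dspm(op, np.zeros((10, 50)))
        assert np.all(est.values == 0)

    def test_quadratic_scaling(self, rng):
        gain = _random_gain(10, 8, rng)
        cov = NoiseCovariance(np.ones(10), gain.channel_order, "empty_room", 1)
        op = compute_inverse_operator(gain, cov, snr=1.0)
        x = rng.standard_normal((10, 64))
        f1 = apply_dspm(op, x).values ** 2
        f2 = apply_dspm(op, 3.0 * x).values ** 2
        assert np.allclose(f2, 9.0 * f1, rtol=1e-12)

    def test_orientation_invariance(self, rng):
        """Rotating the three global dipole axes leaves F unchanged."""
        from scipy.spatial.transform import Rotation

        gain = _random_gain(12, 10, rng)
        R = Rotation.from_rotvec([0.3, -0.5, 0.9]).as_matrix()
        rotated = GainMatrix(
            (gain.values.reshape(12, -1, 3) @ R).reshape(12, -1),
            gain.channel_order,
            gain.source_order,
            gain.modality,
        )
        cov = NoiseCovariance(rng.uniform(0.5, 2, 12), gain.channel_order, "empty_room", 1)
        x = rng.standard_normal((12, 32))
        f_a = apply_dspm(compute_inverse_operator(gain, cov, 1.0), x).values
        f_b = apply_dspm(compute_inverse_operator(rotated, cov, 1.0), x).values
        assert np.allclose(f_a, f_b, rtol=1e-10)

    def test_whitening_invariance(self, rng):
        """Scaling one channel's data and noise variance together does
        not change the estimate."""
        gain = _random_gain(12, 10, rng)
        diag = rng.uniform(0.5, 2, 12)
        x = rng.standard_normal((12, 32))
        scale = np.ones(12)
        scale[3] = 7.0
        gain2 = GainMatrix(
            gain.values * scale[:, None], gain.channel_order, gain.source_order, gain.modality
        )
        cov1 = NoiseCovariance(diag, gain.channel_order, "empty_room", 1)
        cov2 = NoiseCovariance(diag * scale**2, gain.channel_order, "empty_room", 1)
        f1 = apply_dspm(compute_inverse_operator(gain, cov1, 1.0), x).values
        f2 = apply_dspm(compute_inverse_operator(gain2, cov2, 1.0), x * scale[:, None]).values
        assert np.allclose(f1, f2, rtol=1e-9)

    def test_channel_mismatch(self, rng):
        gain = _random_gain(10, 8, rng)
        cov = NoiseCovariance(np.ones(10), gain.channel_order, "empty_room", 1)
        op = compute_inverse_operator(gain, cov, snr=1.0)
        with pytest.raises(ValueError, match="channel"):
            apply_dspm(op, np.zeros((9, 50)))


class TestCombinedInverse:
    def test_degenerate_stack_equals_single_modality(self, rng):
        """With one modality's gain zeroed, the combined operator reduces
        to the surviving modality's whitened solution."""
        g_e = _random_gain(8, 12, rng)
        g_m = GainMatrix(np.zeros((6, 36)), [f"m{i}" for i in range(6)], np.arange(12), Modality.MEG)
        n_e = NoiseCovariance(rng.uniform(0.5, 2, 8), g_e.channel_order, "baseline_epochs", 50)
        n_m = NoiseCovariance(np.ones(6), g_m.channel_order, "empty_room", 1)
        comb = combined_inverse(g_e, g_m, n_e, n_m, snr=1.0)
        # reference: EEG-only on the whitened system at the same lambda^2
        w = 1.0 / np.sqrt(n_e.diagonal)
        g_white = GainMatrix(g_e.values * w[:, None], g_e.channel_order, g_e.source_order, Modality.EEG)
        ref = compute_inverse_operator(
            g_white,
            NoiseCovariance(np.ones(8), g_e.channel_order, "baseline_epochs", 50),
            snr=1.0,
            lam2=comb.regularization,
        )
        x_e = rng.standard_normal((8, 40))
        x_m = rng.standard_normal((6, 40))
        f_comb = apply_dspm(comb, np.vstack([x_e, x_m])).values
        f_ref = apply_dspm(ref, x_e * w[:, None]).values
        assert np.allclose(f_comb, f_ref, rtol=1e-9)

    def test_prewhitened_unit_variance(self, rng):
        g_e = _random_gain(8, 12, rng)
        g_m = _random_gain(6, 12, rng)
        n_e = NoiseCovariance(rng.uniform(0.5, 2, 8), g_e.channel_order, "baseline_epochs", 50)
        n_m = NoiseCovariance(rng.uniform(0.1, 9, 6), g_m.channel_order, "empty_room", 1)
        comb = combined_inverse(g_e, g_m, n_e, n_m, snr=1.0)
        diag = np.concatenate([n_e.diagonal, n_m.diagonal])
        assert np.allclose(comb.prewhitener**2 * diag, 1.0)

    def test_source_space_mismatch(self, rng):
        g_e = _random_gain(8, 12, rng)
        g_m = _random_gain(6, 10, rng)
        n_e = NoiseCovariance(np.ones(8), g_e.channel_order, "baseline_epochs", 50)
        n_m = NoiseCovariance(np.ones(6), g_m.channel_order, "empty_room", 1)
        with pytest.raises(ValueError, match="source space"):
            combined_inverse(g_e, g_m, n_e, n_m, snr=1.0)


class TestFSignificance:
    def _estimate(self, F, eig=None):
        F = np.atleast_1d(np.asarray(F, dtype=float))
        return SourceEstimate(
            values=np.sqrt(F)[:, None],
            sampling_rate=500.0,
            modality=Modality.MEG,
            component_noise_eigvals=eig,
        )

    def test_f_equal_one_large_dof(self):
        """F = 1 with equal components and infinite noise dof: the upper
        tail of chi2_3/3 at 1, ~0.3916."""
        p = f_significance(self._estimate([1.0]), n_noise_dof=10**9)
        assert p[0] == pytest.approx(stats.chi2.sf(3.0, 3), abs=1e-3)

    def test_monotone_decreasing_in_f(self):
        F = np.linspace(0.1, 40.0, 150)
        p = f_significance(self._estimate(F), n_noise_dof=10**7)
        assert np.all(np.diff(p) < 1e-6)
        assert p[-1] < 1e-12

    def test_low_dof_rejected(self):
        with pytest.raises(ValueError, match="n_noise_dof"):
            f_significance(self._estimate([1.0]), n_noise_dof=2)

    def test_unequal_components_calibrated(self, rng):
        """Null p-values stay uniform when one dipole component carries
        almost no noise power (the radially silent MEG case)."""
        lam = np.array([1.0, 0.6, 1e-9])
        n = 4000
        q = (lam[:, None] * rng.standard_normal((3, n)) ** 2).sum(axis=0)
        est = SourceEstimate(
            values=np.sqrt(q / lam.sum())[:, None],
            sampling_rate=500.0,
            modality=Modality.MEG,
            component_noise_eigvals=np.tile(lam, (n, 1)),
        )
        p = f_significance(est, n_noise_dof=10**7)
        assert stats.kstest(p, "uniform").statistic < 0.03
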