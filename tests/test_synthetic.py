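"""Ground-truth correctness and determinism of the synthetic generators."""

import numpy as np
import pytest

from ccpol.polarity import polarity_angle, polarity_index
from ccpol.synthetic import (ForceCurveSpec, MonolayerSpec, VelocityFieldSpec,
                             gen_activation_trace, gen_coloc_pair,
                             gen_force_curve, gen_monolayer,
                             gen_photobleach_pair, gen_velocity_field,
                             kappa_step, merge_events)
from tests.conftest import von_mises_resultant_length


class TestMonolayer:
    def test_deterministic_for_fixed_seed(self):
        spec = MonolayerSpec(n_cells=200, kappa_profile=1.0, seed=42)
        _, _, t1 = gen_monolayer(spec)
        _, _, t2 = gen_monolayer(MonolayerSpec(n_cells=200, kappa_profile=1.0, seed=42))
        assert t1.equals(t2)

    def test_golgi_offset_exact(self):
        spec = MonolayerSpec(n_cells=100, kappa_profile=2.0, golgi_offset=8.0, seed=1)
        recs, _, _ = gen_monolayer(spec)
        for r in recs:
            assert np.hypot(*r.polarity_vector) == pytest.approx(8.0)

    def test_sampled_angle_matches_recomputed_angle(self):
        recs, edge, truth = gen_monolayer(MonolayerSpec(n_cells=300, kappa_profile=1.5, seed=3))
        recomputed = [polarity_angle(r.nucleus_xy, r.golgi_xy, edge) for r in recs]
        assert np.allclose(recomputed, truth["alpha_true_deg"], atol=1e-8)

    def test_degenerate_concentration_gives_pi_near_one(self):
        recs, edge, truth = gen_monolayer(MonolayerSpec(n_cells=500, kappa_profile=1e4, seed=0))
        assert polarity_index(truth["alpha_true_deg"]).pi > 0.99

    def test_uniform_limit_gives_pi_near_zero(self):
        _, _, truth = gen_monolayer(MonolayerSpec(n_cells=100_000,
                                                  field_size=(2000, 2500),
                                                  kappa_profile=0.0, seed=0))
        assert polarity_index(truth["alpha_true_deg"]).pi < 0.01

    @pytest.mark.parametrize("kappa", [0.5, 2.0])
    def test_resultant_length_matches_integration_oracle(self, kappa):
        """Empirical mean resultant length converges to the von Mises value."""
        _, _, truth = gen_monolayer(MonolayerSpec(
            n_cells=50_000, field_size=(2000, 2500), kappa_profile=kappa, seed=7))
        expected = von_mises_resultant_length(kappa)
        assert polarity_index(truth["alpha_true_deg"]).pi == pytest.approx(expected, abs=0.01)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            gen_monolayer(MonolayerSpec(n_cells=0))
        with pytest.raises(ValueError):
            gen_monolayer(MonolayerSpec(n_cells=10, field_size=(-1, 10)))
        with pytest.raises(ValueError):
            gen_monolayer(MonolayerSpec(n_cells=10, kappa_profile=-1.0))

    def test_kappa_step_profile(self):
        prof = kappa_step(((50.0, 2.0), (100.0, 1.0)), beyond=0.0)
        assert np.allclose(prof([10.0, 50.0, 99.0, 150.0]), [2.0, 1.0, 1.0, 0.0])


class TestColocPair:
    @pytest.mark.parametrize("target", [0.0, 0.4, 1.0])
    def test_truth_near_target(self, target):
        a, b, truth = gen_coloc_pair(20, 20, target, seed=9)
        assert truth == pytest.approx(target, abs=0.02)
        measured = (a & b).sum() / a.sum()
        assert measured == pytest.approx(truth, abs=1e-12)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            gen_coloc_pair(5, 5, 1.2)


class TestPhotobleachPair:
    def test_zero_efficiency_identical_means(self):
        pre, post, roi = gen_photobleach_pair(0.0, noise_sd=0.0)
        assert pre[roi].mean() == pytest.approx(post[roi].mean())

    def test_algebraic_inversion(self):
        pre, post, roi = gen_photobleach_pair(0.4, i_post=100.0, noise_sd=0.0)
        assert pre[roi].mean() == pytest.approx(60.0)

    def test_noisy_recovery_monte_carlo(self):
        from ccpol.fret import PhotobleachPair, fret_efficiency
        pre, post, roi = gen_photobleach_pair(0.2, noise_sd=1.0,
                                              shape=(128, 128), seed=11)
        ef = fret_efficiency(PhotobleachPair(pre, post, roi))
        assert ef == pytest.approx(0.2, abs=0.01)

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValueError):
            gen_photobleach_pair(1.0)


class TestActivationTrace:
    @pytest.mark.parametrize("frames, expected", [
        ([10, 12], 1),          # within 3 frames: same event
        ([10, 20, 30], 3),      # well separated
        ([5, 7, 9, 30], 2),     # transitive chaining of 5-7-9
    ])
    def test_merge_rule_ground_truth(self, frames, expected):
        _, truth = gen_activation_trace(frames, seed=0)
        assert truth == expected

    def test_merge_idempotent(self):
        merged = merge_events([5, 7, 9, 30, 32, 50], window=3)
        assert merge_events(merged, window=3) == merged
        assert np.all(np.diff(merged) > 3)

    def test_out_of_range_frames_rejected(self):
        with pytest.raises(ValueError):
            gen_activation_trace([200], n_frames=100)


class TestForceCurve:
    def test_analytic_triangular_area(self):
        table, work, fmax = gen_force_curve(ForceCurveSpec(
            adhesion_depth=100.0, adhesion_width=2.0, baseline_noise_sd=0.0))
        assert work == pytest.approx(0.1)    # 1/2 * 100 pN * 2 um = 0.1 fJ
        assert fmax == pytest.approx(100.0)
        # numerically integrated retract well matches the analytic area
        ret = table[table.segment == "retract"]
        s = ret.separation_um.to_numpy()
        f = ret.force_pN.to_numpy()
        area = np.trapezoid(np.clip(-f, 0, None), s) * 1e-3
        assert area == pytest.approx(work, rel=1e-6)

    def test_zero_depth_flat(self):
        with pytest.raises(ValueError):
            gen_force_curve(ForceCurveSpec(adhesion_depth=10.0, adhesion_width=0.0))
        table, work, fmax = gen_force_curve(ForceCurveSpec(adhesion_depth=0.0))
        assert work == 0.0 and fmax == 0.0

    def test_depth_sets_max_force(self):
        _, _, fmax = gen_force_curve(ForceCurveSpec(adhesion_depth=200.0))
        assert fmax == pytest.approx(200.0)


class TestVelocityField:
    def test_deterministic(self):
        spec = VelocityFieldSpec(grid_shape=(32, 32), seed=5)
        out1 = gen_velocity_field(spec)
        out2 = gen_velocity_field(VelocityFieldSpec(grid_shape=(32, 32), seed=5))
        assert all(np.array_equal(a, b) for a, b in zip(out1, out2))

    def test_rms_speed_scaling(self):
        _, _, u, _ = gen_velocity_field(VelocityFieldSpec(
            grid_shape=(64, 64), rms_speed=7.0, seed=2))
        assert u.std() == pytest.approx(7.0, rel=1e-6)

    def test_correlation_decays_with_prescribed_length(self):
        from ccpol.motion import VelocityField, spatial_correlation
        x, y, u, v = gen_velocity_field(VelocityFieldSpec(
            grid_shape=(256, 256), grid_spacing=10.0,
            correlation_length=100.0, seed=4))
        curve = spatial_correlation(VelocityField(x, y, u, v), max_lag=300.0)
        expected = np.exp(-curve.lag_um / 100.0)
        assert np.all(np.abs(curve.c - expected) < 0.08)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            gen_velocity_field(VelocityFieldSpec(correlation_length=5.0,
                                                 grid_spacing=10.0))
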