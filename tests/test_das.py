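"""Delay geometry, DAS linearity, localization, and compounding."""

import numpy as np
import pytest

from pwcoh import (
    AngleSequence,
    BeamformConfig,
    PixelGrid,
    ProbeConfig,
    PWAcquisition,
    Scene,
    beamform_all,
    coherent_compound,
    das_beamform_frame,
    rf_to_iq,
    simulate_channel_data,
)
from pwcoh.das import dynamic_aperture_mask, receive_delay, transmit_delay


@pytest.fixture(scope="module")
def probe():
    return ProbeConfig(n_elements=64, pitch=0.3e-3, f0=5e6, c=1540.0, fs=20e6)


class TestTransmitDelay:
    def test_normal_incidence_is_depth_over_c(self, probe):
        z = 20e-3
        assert transmit_delay(0.0, z, 0.0, probe) == pytest.approx(z / probe.c)

    def test_steep_angle_rejected(self, probe):
        with pytest.raises(ValueError, match="90"):
            transmit_delay(0.0, 1e-3, 90.0, probe)

    def test_matches_wavefront_projection_oracle(self, probe):
        # distance from the pixel to the wavefront through the aperture edge,
        # measured along the propagation normal (sin θ, cos θ)
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.uniform(-15e-3, 15e-3)
            z = rng.uniform(1e-3, 50e-3)
            th = rng.uniform(-45.0, 45.0)
            normal = np.array([np.sin(np.deg2rad(th)), np.cos(np.deg2rad(th))])
            projection = np.dot([x, z], normal)
            offset = probe.aperture_width / 2 * abs(normal[0])
            assert transmit_delay(x, z, th, probe) == pytest.approx(
                (projection + offset) / probe.c, rel=1e-12
            )

    def test_delay_non_negative_over_aperture(self, probe):
        for th in (-30.0, -5.0, 5.0, 30.0):
            tau = transmit_delay(probe.element_positions, 0.0, th, probe)
            assert np.all(tau >= -1e-15)


class TestReceiveDelay:
    def test_on_axis_element(self, probe):
        assert receive_delay(2e-3, 30e-3, 2e-3, probe.c) == pytest.approx(30e-3 / probe.c)

    def test_three_four_five_triangle(self, probe):
        assert receive_delay(4e-3, 3e-3, 0.0, probe.c) == pytest.approx(5e-3 / probe.c)

    def test_random_cases_against_hypot(self, probe):
        rng = np.random.default_rng(1)
        x, z, ex = rng.uniform(-20e-3, 20e-3, (3, 30))
        z = np.abs(z)
        np.testing.assert_allclose(
            receive_delay(x, z, ex, probe.c), np.hypot(z, x - ex) / probe.c, rtol=1e-12
        )

    def test_monotone_in_lateral_offset(self, probe):
        offsets = np.linspace(0, 10e-3, 20)
        d = receive_delay(offsets, 10e-3, 0.0, probe.c)
        assert np.all(np.diff(d) > 0)


def _point_acq(probe, angles_deg, z=20e-3, x=0.0):
    angles = AngleSequence(np.asarray(angles_deg, dtype=float))
    scene = Scene(
        positions=np.array([[x, z]]), amplitudes=np.array([1.0]),
        extent=(-5e-3, 5e-3, z - 5e-3, z + 5e-3),
    )
    return simulate_channel_data(scene, probe, angles, noise_snr_db=None)


class TestBeamformer:
    def test_zero_data_gives_zero_image(self, probe):
        acq = _point_acq(probe, [-5.0, 0.0, 5.0])
        acq.channel_data[...] = 0.0
        grid = PixelGrid.lambda_third(probe, z0=18e-3, nz=16, nx=16)
        img = das_beamform_frame(acq, 1, BeamformConfig(grid=grid))
        np.testing.assert_array_equal(img, 0.0)

    def test_linearity_in_the_data(self, probe):
        rng = np.random.default_rng(0)
        acq = _point_acq(probe, [-5.0, 0.0, 5.0])
        noise = rng.standard_normal(acq.channel_data.shape)
        grid = PixelGrid.lambda_third(probe, z0=18e-3, nz=24, nx=24)
        cfg = BeamformConfig(grid=grid)

        def bf(data):
            a = PWAcquisition(probe=probe, angles=acq.angles, channel_data=data,
                              data_kind="rf", t0=acq.t0)
            return das_beamform_frame(a, 1, cfg)

        img_a = bf(acq.channel_data)
        img_b = bf(noise)
        np.testing.assert_allclose(bf(acq.channel_data * 2.5), 2.5 * img_a, rtol=1e-9)
        np.testing.assert_allclose(
            bf(acq.channel_data + noise), img_a + img_b, rtol=1e-7, atol=1e-9
        )

    @pytest.mark.parametrize("steer", [-10.0, 0.0, 10.0])
    def test_point_target_localized_within_one_cell(self, probe, steer):
        z_true = 20e-3
        acq = _point_acq(probe, [steer - 1.0, steer, steer + 1.0])
        grid = PixelGrid.lambda_third(probe, z0=18e-3, nz=40, nx=40)
        img = das_beamform_frame(acq, 1, BeamformConfig(grid=grid))
        env = np.abs(img)
        iz, ix = np.unravel_index(env.argmax(), env.shape)
        assert abs(grid.z[iz] - z_true) <= grid.dz
        assert abs(grid.x[ix] - 0.0) <= grid.dx

    def test_beamform_all_matches_per_frame_calls(self, probe):
        acq = _point_acq(probe, [-5.0, 0.0, 5.0])
        grid = PixelGrid.lambda_third(probe, z0=18e-3, nz=16, nx=16)
        cfg = BeamformConfig(grid=grid)
        fs = beamform_all(acq, cfg)
        assert len(fs) == 3
        iq = rf_to_iq(acq)
        for i in range(3):
            np.testing.assert_allclose(fs.frames[i], das_beamform_frame(iq, i, cfg), atol=1e-12)

    def test_deterministic_across_runs(self, probe):
        acq = _point_acq(probe, [0.0, 2.0])
        grid = PixelGrid.lambda_third(probe, z0=18e-3, nz=16, nx=16)
        cfg = BeamformConfig(grid=grid)
        np.testing.assert_array_equal(
            beamform_all(acq, cfg).frames, beamform_all(acq, cfg).frames
        )


class TestDynamicAperture:
    def test_element_count_grows_with_depth_at_expected_slope(self, probe):
        f_number = 2.0
        ex = probe.element_positions
        depths = np.linspace(1e-3, 15e-3, 30)
        counts = np.array(
            [dynamic_aperture_mask(z, 0.0, ex, f_number).sum() for z in depths]
        )
        assert np.all(np.diff(counts) >= 0)
        # full width z/f_number corresponds to z/(f_number·pitch) elements
        expected = depths / (f_number * probe.pitch)
        assert np.all(np.abs(counts - expected) <= 2)

    def test_saturates_at_full_aperture(self, probe):
        ex = probe.element_positions
        assert dynamic_aperture_mask(1.0, 0.0, ex, 2.0).sum() == probe.n_elements


class TestCoherentCompound:
    def test_two_opposite_frames_cancel(self):
        from pwcoh import FrameSet

        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        fs = FrameSet(
            frames=np.stack([x, -x]),
            grid=PixelGrid(z0=0, dz=1e-4, dx=1e-4, nz=8, nx=8),
            angles=AngleSequence.symmetric(5.0, 2),
        )
        np.testing.assert_allclose(coherent_compound(fs), 0.0, atol=1e-15)

    def test_mean_of_identical_frames_is_the_frame(self):
        from pwcoh import FrameSet

        rng = np.random.default_rng(1)
        x = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        fs = FrameSet(
            frames=np.stack([x, x, x]),
            grid=PixelGrid(z0=0, dz=1e-4, dx=1e-4, nz=8, nx=8),
            angles=AngleSequence.symmetric(5.0, 3),
        )
        np.testing.assert_allclose(coherent_compound(fs), x, rtol=1e-14)

    def test_compounding_improves_signal_to_noise(self, desk_probe):
        """Compounding averages down additive channel noise while the
        (angle-coherent) speckle signal survives, so the beamformed
        signal-to-noise energy ratio rises. Speckle *texture* SNR
        (envelope mean/std) is invariant under coherent summation —
        the sum stays circular Gaussian — so the noise ratio is the
        quantity compounding actually improves."""
        from pwcoh import PWAcquisition, SceneConfig, make_scene

        angles = AngleSequence.symmetric(12.0, 5)
        grid = PixelGrid.lambda_third(desk_probe, z0=8e-3, nz=32, nx=32)
        cfg = BeamformConfig(grid=grid)
        wins = 0
        n_trials = 20
        for seed in range(n_trials):
            scene = make_scene(
                SceneConfig(rng_seed=seed), (-4e-3, 4e-3, 6e-3, 13e-3)
            )
            sig = simulate_channel_data(scene, desk_probe, angles, noise_snr_db=None)
            sigma = np.sqrt(np.mean(sig.channel_data**2)) * 10 ** (-10 / 20)
            rng = np.random.default_rng(1000 + seed)
            noise = PWAcquisition(
                probe=desk_probe, angles=angles,
                channel_data=rng.normal(0.0, sigma, size=sig.channel_data.shape),
                data_kind="rf", t0=sig.t0,
            )
            S = beamform_all(sig, cfg).frames
            N = beamform_all(noise, cfg).frames
            snr_single = np.sum(np.abs(S[2]) ** 2) / np.sum(np.abs(N[2]) ** 2)
            snr_comp = np.sum(np.abs(S.mean(0)) ** 2) / np.sum(np.abs(N.mean(0)) ** 2)
            wins += snr_comp > snr_single
        assert wins >= 0.75 * n_trials
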