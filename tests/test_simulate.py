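"""Simulator physics: scatterer statistics, arrival times, reverberation."""

import numpy as np
import pytest
import yaml
from scipy.signal import hilbert
from scipy.stats import kstest, rayleigh

from pwcoh import (
    AngleSequence,
    BeamformConfig,
    Inclusion,
    PixelGrid,
    ReverbLayer,
    Scene,
    SceneConfig,
    add_reverberation,
    das_beamform_frame,
    load_acquisition,
    make_scene,
    simulate_channel_data,
)
from pwcoh.loss import normalized_xcorr

EXTENT = (-5e-3, 5e-3, 2e-3, 20e-3)


class TestMakeScene:
    def test_count_within_poisson_bounds(self):
        cfg = SceneConfig(speckle_density=10.0, rng_seed=0)
        mean = 10.0 * 10 * 18  # density × area in mm²
        n = len(make_scene(cfg, EXTENT).amplitudes)
        assert abs(n - mean) <= 3 * np.sqrt(mean)

    def test_anechoic_inclusion_contains_no_scatterers(self):
        inc = Inclusion(center=(0.0, 10e-3), radius=2e-3, echogenicity=0.0)
        scene = make_scene(SceneConfig(inclusions=(inc,), rng_seed=1), EXTENT)
        d2 = (scene.positions[:, 0] - 0.0) ** 2 + (scene.positions[:, 1] - 10e-3) ** 2
        assert np.all(d2 > (2e-3) ** 2)

    def test_seed_reproducibility(self):
        a = make_scene(SceneConfig(rng_seed=5), EXTENT)
        b = make_scene(SceneConfig(rng_seed=5), EXTENT)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)

    def test_zero_area_extent_rejected(self):
        with pytest.raises(ValueError, match="area"):
            make_scene(SceneConfig(), (0.0, 0.0, 0.0, 10e-3))


class TestChannelData:
    def test_single_scatterer_arrival_times_match_geometry(self, desk_probe):
        z = 20e-3
        scene = Scene(
            positions=np.array([[0.0, z]]), amplitudes=np.array([1.0]),
            extent=(-1e-3, 1e-3, z - 2e-3, z + 2e-3),
        )
        acq = simulate_channel_data(
            scene, desk_probe, AngleSequence.symmetric(1.0, 2) , noise_snr_db=None
        )
        # envelope peak of each trace: plane-wave transmit delay (with the
        # aperture-center reference and its non-negativity offset) plus the
        # return distance, for theta = -1 deg
        th = np.deg2rad(-1.0)
        offset = desk_probe.aperture_width / 2 * abs(np.sin(th))
        env = np.abs(hilbert(acq.channel_data[0], axis=0))
        for e in (0, 16, 32, 48, 63):
            xe = desk_probe.element_positions[e]
            t_true = (z * np.cos(th) + 0.0 * np.sin(th) + offset + np.hypot(z, xe)) / desk_probe.c
            peak = env[:, e].argmax() / desk_probe.fs + acq.t0
            assert peak == pytest.approx(t_true, abs=1.5 / desk_probe.fs)

    def test_linearity_in_scatterer_amplitudes(self, desk_probe):
        rng = np.random.default_rng(0)
        pos = np.column_stack([rng.uniform(-3e-3, 3e-3, 20), rng.uniform(5e-3, 15e-3, 20)])
        amps = rng.standard_normal(20)
        angles = AngleSequence.symmetric(5.0, 3)
        a = simulate_channel_data(
            Scene(pos, amps, EXTENT), desk_probe, angles, noise_snr_db=None
        )
        b = simulate_channel_data(
            Scene(pos, 2 * amps, EXTENT), desk_probe, angles, noise_snr_db=None
        )
        np.testing.assert_allclose(b.channel_data, 2 * a.channel_data, atol=1e-14)

    def test_empty_scene_gives_noise_at_configured_level(self, desk_probe):
        scene = Scene(np.empty((0, 2)), np.empty(0), EXTENT)
        acq = simulate_channel_data(
            scene, desk_probe, AngleSequence.symmetric(5.0, 3), noise_snr_db=40.0, rng=0
        )
        # with no signal the reference amplitude is 1.0 -> noise std 10^(-40/20)
        assert acq.channel_data.std() == pytest.approx(1e-2, rel=0.05)

    def test_truncation_warning_when_scene_outside_window(self, desk_probe):
        scene = Scene(np.array([[0.0, 30e-3]]), np.array([1.0]), EXTENT)
        with pytest.warns(UserWarning, match="truncated"):
            simulate_channel_data(
                scene, desk_probe, AngleSequence.symmetric(1.0, 2),
                noise_snr_db=None, n_samples=100,
            )


class TestReverberation:
    def _single_scatterer_acq(self, probe):
        z = 10e-3
        scene = Scene(
            positions=np.array([[0.0, z]]), amplitudes=np.array([1.0]),
            extent=(-1e-3, 1e-3, 2e-3, 18e-3),
        )
        return simulate_channel_data(
            scene, probe, AngleSequence.symmetric(1.0, 3), noise_snr_db=None
        )

    def test_vanishing_reflectivity_leaves_data_unchanged(self, desk_probe):
        acq = self._single_scatterer_acq(desk_probe)
        out = add_reverberation(acq, (ReverbLayer(depth=5e-3, reflection_coefficient=1e-12),))
        np.testing.assert_allclose(out.channel_data, acq.channel_data, atol=1e-10)

    def test_ghost_appears_at_shifted_depth_with_half_amplitude(self, desk_probe):
        acq = self._single_scatterer_acq(desk_probe)
        layer = ReverbLayer(depth=5e-3, reflection_coefficient=0.5, max_order=1)
        out = add_reverberation(acq, (layer,))
        grid = PixelGrid.lambda_third(desk_probe, z0=8e-3, nz=120, nx=24)
        img = np.abs(das_beamform_frame(out, 1, BeamformConfig(grid=grid)))
        col = img[:, np.abs(grid.x).argmin()]
        true_peak = col[np.abs(grid.z - 10e-3) < 1e-3].max()
        ghost_region = np.abs(grid.z - 15e-3) < 1e-3
        ghost_peak = col[ghost_region].max()
        iz = np.where(ghost_region)[0][col[ghost_region].argmax()]
        assert abs(grid.z[iz] - 15e-3) <= 3 * grid.dz
        assert 0.3 <= ghost_peak / true_peak <= 0.7

    def test_added_energy_bounded_by_geometric_series(self, desk_probe):
        acq = self._single_scatterer_acq(desk_probe)
        r, M = 0.6, 3
        out = add_reverberation(
            acq, (ReverbLayer(depth=5e-3, reflection_coefficient=r, max_order=M),)
        )
        added = out.channel_data - acq.channel_data
        bound = sum(r**m for m in range(1, M + 1)) * np.linalg.norm(acq.channel_data)
        assert np.linalg.norm(added) <= bound + 1e-12


class TestSpeckleStatistics:
    def test_envelope_is_rayleigh_in_uniform_region(self, desk_probe):
        """Fully developed speckle at the default density has a Rayleigh
        envelope. Each depth row is normalized by its own RMS (the dynamic
        aperture makes the scale depth-dependent) and pixels are subsampled
        beyond the point-spread-function size so the KS test sees
        approximately independent draws."""
        scene = make_scene(SceneConfig(rng_seed=11), EXTENT)
        angles = AngleSequence.symmetric(2.0, 2)
        acq = simulate_channel_data(scene, desk_probe, angles, noise_snr_db=None)
        grid = PixelGrid.lambda_third(desk_probe, z0=8e-3, nz=96, nx=56)
        env = np.abs(das_beamform_frame(acq, 0, BeamformConfig(grid=grid)))
        row_rms = np.sqrt(np.mean(env**2, axis=1, keepdims=True))
        sub = (env / row_rms)[::4, ::6].ravel()
        p = kstest(sub, rayleigh(scale=1 / np.sqrt(2)).cdf).pvalue
        assert p > 0.01


class TestDecorrelationEmulation:
    def test_ghost_decorrelates_faster_than_tissue(self, clutter_frame_sets, desk_grid):
        """Clutter inside the anechoic inclusion loses inter-frame correlation
        with angular separation while speckle at the same depth stays coherent."""
        from pwcoh.metrics import annulus_mask, disk_mask

        ghost = disk_mask(desk_grid, (0.0, 10e-3), 1.0e-3)
        tissue = annulus_mask(desk_grid, (0.0, 10e-3), 3.5e-3, 5e-3)
        seps = (1, 4, 7)
        ghost_rows = []
        tissue_curves = []
        for fs in clutter_frame_sets:
            k = len(fs)
            g_curve, t_curve = [], []
            for sep in seps:
                g, t = [], []
                for i in range(0, k - sep, 2):
                    a, b = fs.frames[i], fs.frames[i + sep]
                    g.append(abs(normalized_xcorr(a[ghost], b[ghost], mode="magnitude")))
                    t.append(abs(normalized_xcorr(a[tissue], b[tissue], mode="magnitude")))
                g_curve.append(np.mean(g))
                t_curve.append(np.mean(t))
            ghost_rows.append(g_curve)
            tissue_curves.append(t_curve)
        ghost_curves = np.array(ghost_rows)
        tissue_curves = np.array(tissue_curves)
        # clutter correlation falls with separation in the majority of scenes
        falls = (ghost_curves[:, -1] < ghost_curves[:, 0]).sum()
        assert falls >= len(clutter_frame_sets) - 1
        # and at the widest separation tissue stays more correlated than clutter
        better = (tissue_curves[:, -1] > ghost_curves[:, -1]).sum()
        assert better >= len(clutter_frame_sets) - 1


class TestMakeCorpus:
    def test_corpus_files_and_sidecar_geometry(self, clutter_corpus):
        assert len(clutter_corpus) == 4
        for path in clutter_corpus:
            roi = yaml.safe_load(open(path.with_name(path.stem + "_roi.yaml")))
            assert roi["target"]["shape"] == "disk"
            assert roi["target"]["radius"] < roi["background"]["r_inner"]

    def test_distinct_acquisitions(self, clutter_corpus):
        a = load_acquisition(clutter_corpus[0]).channel_data
        b = load_acquisition(clutter_corpus[1]).channel_data
        assert not np.array_equal(a, b)

    def test_target_roi_inside_inclusion_is_clutter_only(self, clutter_corpus, desk_probe):
        # the target disk was cut from the anechoic inclusion: its radius is
        # strictly smaller than the jittered inclusion radius by construction
        for path in clutter_corpus:
            roi = yaml.safe_load(open(path.with_name(path.stem + "_roi.yaml")))
            assert roi["target"]["radius"] == pytest.approx(
                0.6 / 1.3 * roi["background"]["r_inner"], rel=1e-6
            )
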