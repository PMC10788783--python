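import numpy as np
import pytest

from drybench import preprocess, simmetrics, synthgen
from drybench.ioformats import ChannelMeta, ElectrodeLayout, ValidationError


class TestLayout:
    def test_grid_geometry(self, default_layout):
        dry = default_layout.of_kind("dry")
        assert len(dry) == 16
        pos = np.array([ch.position for ch in dry])
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(6.0)
        assert d[np.isfinite(d)].max() == pytest.approx(np.hypot(18, 18))  # ~25.456

    def test_contact_diameters(self, default_layout):
        assert all(ch.diameter_mm == 3.0 for ch in default_layout.of_kind("dry"))
        assert all(ch.diameter_mm == 10.0 for ch in default_layout.of_kind("gelled"))

    def test_single_electrode_grid(self):
        lay = synthgen.gen_layout(6.0, 1, 1, reference_offsets_mm=[])
        assert lay.labels == ["MX01"]
        assert np.allclose(lay["MX01"].position, [0.0, 0.0])

    def test_invalid_pitch(self):
        with pytest.raises(ValidationError, match="pitch"):
            synthgen.gen_layout(pitch_mm=0.0)


class TestTrialSchedule:
    def test_trial_count_near_85(self):
        counts = [
            len(synthgen.gen_trial_schedule(synthgen.TrialSpec(), 2000.0, seed))
            for seed in range(100)
        ]
        assert abs(np.mean(counts) - 85) < 15
        assert min(counts) > 85 - 15 and max(counts) < 85 + 15

    def test_delays_within_bounds(self):
        spec = synthgen.TrialSpec()
        ev = synthgen.gen_trial_schedule(spec, 2000.0, 5)
        gaps = np.diff(ev.sample_indices) / 2000.0 - spec.overhead_s
        assert np.all(gaps >= spec.delay_lo_s - 1e-3)
        assert np.all(gaps <= spec.delay_hi_s + 1e-3)

    def test_deterministic(self):
        a = synthgen.gen_trial_schedule(synthgen.TrialSpec(), 2000.0, 9)
        b = synthgen.gen_trial_schedule(synthgen.TrialSpec(), 2000.0, 9)
        assert np.array_equal(a.sample_indices, b.sample_indices)

    def test_events_clear_epoch_window(self):
        ev = synthgen.gen_trial_schedule(synthgen.TrialSpec(), 2000.0, 3)
        assert ev.sample_indices[0] >= 0.2 * 2000
        assert ev.sample_indices[-1] + 1.0 * 2000 < 600 * 2000

    def test_window_longer_than_block(self):
        spec = synthgen.TrialSpec(block_s=5.0)
        with pytest.raises(ValidationError):
            synthgen.gen_trial_schedule(spec, 2000.0, 0, epoch_window_s=(-1.0, 6.0))


class TestImpedanceDraws:
    def test_median_recovery(self):
        model = synthgen.ImpedanceModel()
        draws = synthgen.gen_impedance(model, 100_000, "dry", seed=1)
        assert np.median(draws) == pytest.approx(3.948, rel=0.02)
        assert np.all(draws > 0)

    def test_zero_dispersion_degenerates_to_median(self):
        model = synthgen.ImpedanceModel(gelled_sigma=0.0)
        draws = synthgen.gen_impedance(model, 50, "gelled", seed=0)
        assert np.allclose(draws, 1.107)

    def test_iqr_matches_model(self):
        model = synthgen.ImpedanceModel()
        draws = synthgen.gen_impedance(model, 200_000, "gelled", seed=2)
        q1, q3 = np.percentile(draws, [25, 75])
        assert q3 - q1 == pytest.approx(1.000, rel=0.03)


class TestRecordingGeneration:
    def test_deterministic_bit_identical(self, default_layout):
        cfg = synthgen.default_config(duration_s=4.0, seed=21)
        a = synthgen.gen_recording(cfg, default_layout)
        b = synthgen.gen_recording(cfg, default_layout)
        assert np.array_equal(a.recording.samples, b.recording.samples)
        assert np.array_equal(a.events.sample_indices, b.events.sample_indices)

    def test_rank_one_field_when_scale_huge(self, default_layout):
        cfg = synthgen.GeneratorConfig(
            fs=200.0,
            duration_s=10.0,
            bands=(synthgen.BandSpec("Wide", 2.0, 30.0, 5.0, 1e9),),
            burst=None,
            erp=None,
            noise=synthgen.NoiseSpec(0.0, 1.0, 0.0, 0.0),
            seed=3,
        )
        syn = synthgen.gen_recording(cfg, default_layout, point_contacts=True)
        x = syn.recording.samples
        # the covariance jitter (1e-10) leaves channel differences orders of
        # magnitude below typical inter-channel differences of O(1)
        assert np.allclose(x, x[0][None, :], atol=1e-3 * np.abs(x).max())

    def test_ground_truth_kernel_psd_unit_diagonal(self, quiet_field_config, default_layout):
        syn = synthgen.gen_recording(quiet_field_config, default_layout)
        K = syn.kernels["Wide"]
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), 1.0)
        assert np.min(np.linalg.eigvalsh(K)) > -1e-8

    def test_kernel_strictly_decreasing_with_distance(self):
        band = synthgen.BandSpec("Wide", 2.0, 30.0, 5.0, 20.0)
        d = np.array([0.0, 6.0, 12.0, 25.0, 40.0])
        k = band.kernel(d)
        assert np.all(np.diff(k) < 0)

    def test_noise_rms_increasing_in_impedance(self):
        # pure-noise config: channel RMS must track sqrt(floor^2 + kappa * Z)
        lay = synthgen.gen_layout(6.0, 2, 2, reference_offsets_mm=[])
        cfg = synthgen.GeneratorConfig(
            fs=200.0,
            duration_s=30.0,
            bands=(synthgen.BandSpec("Wide", 2.0, 30.0, 0.0, 20.0),),
            burst=None,
            erp=None,
            noise=synthgen.NoiseSpec(floor_uv=0.5, pink_exponent=1.0, pink_rms_uv=0.0, kappa=1.0),
            seed=17,
        )
        syn = synthgen.gen_recording(cfg, lay)
        rms = np.sqrt((syn.recording.samples**2).mean(axis=1))
        order = np.argsort(syn.impedances_kohm_cm2)
        assert np.all(np.diff(rms[order]) > 0)

    def test_burst_creates_alpha_peak(self, default_layout):
        def alpha_contrast(gain):
            cfg = synthgen.default_config(
                duration_s=30.0,
                seed=5,
                burst=synthgen.BurstSpec(gain=gain),
                erp=None,
            )
            syn = synthgen.gen_recording(cfg, default_layout)
            ep = preprocess.extract_regular_epochs(syn.recording, 2.0)
            f, _, db = simmetrics.welch_psd(ep, "MX01")
            alpha = db[(f >= 8) & (f <= 12)].mean()
            flank = db[((f >= 5) & (f <= 7)) | ((f >= 13) & (f <= 17))].mean()
            return alpha - flank

        assert alpha_contrast(3.0) > alpha_contrast(1.0) + 2.0  # dB
        assert alpha_contrast(3.0) > 0.0

    def test_erp_template_added_at_events(self, default_layout):
        cfg = synthgen.default_config(
            duration_s=30.0,
            seed=2,
            bands=(synthgen.BandSpec("Wide", 2.0, 30.0, 0.0, 20.0),),
            burst=None,
            noise=synthgen.NoiseSpec(0.0, 1.0, 0.0, 0.0),
        )
        syn = synthgen.gen_recording(cfg, default_layout)
        assert len(syn.events) >= 1
        s = syn.events.sample_indices[0]
        chunk = syn.recording.samples[0, s : s + len(syn.erp_template)]
        assert np.allclose(chunk, syn.erp_template[: len(chunk)])

    def test_fs_must_exceed_twice_band_edge(self):
        with pytest.raises(ValidationError, match="twice"):
            synthgen.GeneratorConfig(fs=50.0)


class TestSpatialSampling:
    def test_disc_stencil_shape(self):
        assert synthgen.disc_stencil(3.0).shape == (37, 2)
        assert synthgen.disc_stencil(0.0).shape == (1, 2)
        # all points within the contact radius
        assert np.all(np.linalg.norm(synthgen.disc_stencil(10.0), axis=1) <= 5.0 + 1e-12)

    def test_disc_integration_monotone_in_diameter(self):
        """Larger contacts spatially integrate: with a correlation length no
        larger than the pitch, pairwise coherence grows with contact size."""
        params = simmetrics.SpectralParams()
        mean_corr, mean_msc = [], []
        for diam, points in ((0.0, True), (3.0, False), (10.0, False)):
            lay = synthgen.gen_layout(
                6.0, 3, 3, reference_offsets_mm=[], dry_diameter_mm=max(diam, 1e-6)
            )
            cfg = synthgen.GeneratorConfig(
                fs=200.0,
                duration_s=120.0,
                bands=(synthgen.BandSpec("Wide", 2.0, 30.0, 5.0, 5.0),),
                burst=None,
                erp=None,
                noise=synthgen.NoiseSpec(0.0, 1.0, 0.0, 0.0),
                seed=29,
            )
            syn = synthgen.gen_recording(cfg, lay, point_contacts=points)
            C = syn.effective_corr["Wide"]
            iu = np.triu_indices_from(C, 1)
            mean_corr.append(C[iu].mean())
            ep = preprocess.extract_regular_epochs(syn.recording, 2.0)
            cohs = [
                simmetrics.msc(ep, ("MX01", "MX02"), params, mode="pooled")[1].mean(),
                simmetrics.msc(ep, ("MX01", "MX05"), params, mode="pooled")[1].mean(),
            ]
            mean_msc.append(np.mean(cohs))
        assert mean_corr[0] < mean_corr[1] < mean_corr[2]
        assert mean_msc[0] <= mean_msc[1] <= mean_msc[2]

    def test_spatial_scales_monotone_in_default_config(self):
        cfg = synthgen.default_config()
        centers = [b.center for b in cfg.bands]
        scales = [b.spatial_scale_mm for b in cfg.bands]
        order = np.argsort(centers)
        assert np.all(np.diff(np.array(scales)[order]) <= 0)

    def test_coincident_electrodes_degenerate(self):
        lay = ElectrodeLayout(
            [ChannelMeta("A", "dry", 0, 0, 3), ChannelMeta("B", "dry", 0, 0, 3)]
        )
        cfg = synthgen.GeneratorConfig(
            fs=200.0,
            duration_s=2.0,
            bands=(synthgen.BandSpec("Wide", 2.0, 30.0, 1.0, 10.0),),
            burst=None,
            erp=None,
            seed=0,
        )
        # coincident electrodes give a singular covariance; jitter keeps the
        # factorization alive, and the two channels must then be identical
        syn = synthgen.gen_recording(cfg, lay, point_contacts=True)
        x = syn.recording.samples
        noise = synthgen.NoiseSpec(0.0, 1.0, 0.0, 0.0)
        cfg2 = synthgen.GeneratorConfig(
            fs=200.0, duration_s=2.0, bands=cfg.bands, burst=None, erp=None,
            noise=noise, seed=0,
        )
        syn2 = synthgen.gen_recording(cfg2, lay, point_contacts=True)
        x2 = syn2.recording.samples
        assert np.allclose(x2[0], x2[1], atol=1e-4 * np.abs(x2).max())
        assert x.shape == x2.shape
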