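"""Site detection and nuclear-microenvironment statistics."""

import numpy as np
import pytest

from phenoquant import microenv, synthetic
from phenoquant._matching import greedy_match, precision_recall_f1


def _flat_stack(value=5.0, shape=(12, 40, 40), vsz=(0.25, 0.1, 0.1)):
    return microenv.VolumeStack({"c": np.full(shape, value)}, vsz)


class TestDetectSites:
    def test_all_zero_channel_gives_empty_set(self):
        stack = _flat_stack(0.0)
        assert len(microenv.detect_sites(stack, "c")) == 0

    def test_unknown_channel_raises(self):
        with pytest.raises(KeyError):
            microenv.detect_sites(_flat_stack(), "missing")

    def test_noiseless_phantom_sites_recovered_within_one_voxel(self):
        cfg = synthetic.ConfocalPhantomConfig(n_sites=50, site_peak_snr=10,
                                              noise_model="none", seed=4)
        stack, truth = synthetic.gen_confocal_phantom(cfg)
        sites = microenv.detect_sites(stack, "rna")
        assert len(sites) == 50
        pairs, _, _ = greedy_match(sites.voxels(),
                                   truth.sites[["z", "y", "x"]].to_numpy(),
                                   radius=1.0)
        assert len(pairs) == 50

    def test_detection_f1_on_standard_phantom(self, standard_phantom):
        _, stack, truth = standard_phantom
        sites = microenv.detect_sites(stack, "rna")
        pairs, _, _ = greedy_match(sites.voxels(),
                                   truth.sites[["z", "y", "x"]].to_numpy(),
                                   radius=3.0)
        _, _, f1 = precision_recall_f1(len(pairs), len(sites), 100)
        assert f1 >= 0.95

    def test_threshold_monotonicity(self, standard_phantom):
        _, stack, _ = standard_phantom
        counts = [len(microenv.detect_sites(
            stack, "rna", microenv.DetectionParams(threshold_k=k)))
            for k in (2.0, 3.0, 4.0, 5.0, 8.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_sites_sorted_by_descending_peak(self, standard_phantom):
        _, stack, _ = standard_phantom
        sites = microenv.detect_sites(stack, "rna")
        peaks = [s.peak_intensity for s in sites.sites]
        assert peaks == sorted(peaks, reverse=True)

    def test_min_separation_enforced(self, standard_phantom):
        cfg, stack, _ = standard_phantom
        sites = microenv.detect_sites(stack, "rna")
        pos = np.array([s.position_um for s in sites.sites])
        d2 = ((pos[:, None] - pos[None]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert np.sqrt(d2.min()) >= sites.detection_params.min_separation_um


class TestSiteIntensities:
    def test_single_voxel_site_on_zero_background(self):
        vol = np.zeros((9, 9, 9))
        vol[4, 4, 4] = 100.0
        stack = microenv.VolumeStack({"c": vol}, (0.3, 0.3, 0.3))
        sites = microenv.SiteSet([microenv.TranscriptionSite(
            (4, 4, 4), (1.2, 1.2, 1.2), 100.0)])
        tbl = microenv.site_intensities(stack, "c", sites, r_int_um=0.29)
        assert tbl.peak_intensity.iloc[0] == 100.0
        assert tbl.integrated_intensity.iloc[0] == 100.0
        assert not tbl.clipped.iloc[0]

    def test_identical_sites_have_identical_intensities(self):
        vol = np.zeros((9, 21, 21))
        for y in (5, 15):
            vol[4, y, 10] = 7.0
        stack = microenv.VolumeStack({"c": vol}, (0.3, 0.1, 0.1))
        sites = microenv.SiteSet([
            microenv.TranscriptionSite((4, 5, 10), (1.2, 0.5, 1.0), 7.0),
            microenv.TranscriptionSite((4, 15, 10), (1.2, 1.5, 1.0), 7.0)])
        tbl = microenv.site_intensities(stack, "c", sites)
        assert tbl.peak_intensity.iloc[0] == tbl.peak_intensity.iloc[1]
        assert (tbl.integrated_intensity.iloc[0]
                == tbl.integrated_intensity.iloc[1])

    def test_lognormal_amplitudes_recovered(self):
        cfg = synthetic.ConfocalPhantomConfig(
            n_sites=40, site_peak_snr=10, site_amplitude_sigma=0.5,
            noise_model="none", seed=6)
        stack, truth = synthetic.gen_confocal_phantom(cfg)
        sites = microenv.detect_sites(stack, "rna")
        assert len(sites) == 40
        tbl = microenv.site_intensities(stack, "rna", sites)
        pairs, _, _ = greedy_match(sites.voxels(),
                                   truth.sites[["z", "y", "x"]].to_numpy(),
                                   radius=2.0)
        det_idx, true_idx = zip(*pairs)
        r = np.corrcoef(tbl.integrated_intensity.to_numpy()[list(det_idx)],
                        truth.sites.peak_amplitude.to_numpy()[list(true_idx)])
        assert r[0, 1] >= 0.99

    def test_border_site_flagged_clipped(self):
        vol = np.ones((6, 10, 10))
        stack = microenv.VolumeStack({"c": vol}, (0.3, 0.1, 0.1))
        sites = microenv.SiteSet([microenv.TranscriptionSite(
            (0, 0, 0), (0, 0, 0), 1.0)])
        tbl = microenv.site_intensities(stack, "c", sites, r_int_um=0.3)
        assert tbl.clipped.iloc[0]


class TestRadialProfile:
    def test_uniform_channel_profile_is_one_with_zero_variance(self):
        stack = _flat_stack(3.7, shape=(20, 60, 60))
        sites = microenv.SiteSet([microenv.TranscriptionSite(
            (10, 30, 30), (2.5, 3.0, 3.0), 3.7)])
        prof = microenv.radial_profile(stack, "c", sites)
        assert np.allclose(prof.mean[np.isfinite(prof.mean)], 1.0)
        assert np.allclose(prof.variance[np.isfinite(prof.variance)], 0.0)

    def test_gaussian_enrichment_recovered(self, enrichment_phantom):
        cfg, stack, _ = enrichment_phantom
        sites = microenv.detect_sites(stack, "rna")
        prof = microenv.radial_profile(stack, "mark", sites)
        assert abs(prof.mean[0] - cfg.enrichment_amplitude) \
            / cfg.enrichment_amplitude < 0.10
        n2sig = int(2 * cfg.enrichment_sigma_um / 0.1)
        assert np.all(np.diff(prof.mean[:n2sig]) <= 1e-9)

    def test_profile_invariant_to_z_spacing(self):
        # doubling dz with physically resampled content changes the
        # profile by < 2% per bin: distances must be physical
        def profile_for(dz, nz, zc):
            zz = (np.arange(nz) - zc)[:, None, None] * dz
            yy = (np.arange(81) - 40)[None, :, None] * 0.1
            xx = (np.arange(81) - 40)[None, None, :] * 0.1
            mark = 100 * (1 + np.exp(-(zz**2 + yy**2 + xx**2) / (2 * 0.25)))
            stack = microenv.VolumeStack({"mark": mark}, (dz, 0.1, 0.1))
            ss = microenv.SiteSet([microenv.TranscriptionSite(
                (zc, 40, 40), (zc * dz, 4.0, 4.0), 1.0)])
            return microenv.radial_profile(stack, "mark", ss)

        p1 = profile_for(0.25, 41, 20)
        p2 = profile_for(0.5, 21, 10)
        assert np.nanmax(np.abs(p1.mean - p2.mean) / p1.mean) < 0.02

    def test_bad_arguments(self):
        stack = _flat_stack()
        ss = microenv.SiteSet([microenv.TranscriptionSite(
            (6, 20, 20), (1.5, 2.0, 2.0), 5.0)])
        with pytest.raises(ValueError):
            microenv.radial_profile(stack, "c", ss, r_max_um=0.1, dr_um=0.2)
        with pytest.raises(ValueError):
            microenv.radial_profile(stack, "c", microenv.SiteSet([]))


class TestSiteDensity:
    def test_count_over_area(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[:20, :50] = True  # 1000 pixels
        sites = microenv.SiteSet([
            microenv.TranscriptionSite((0, y, x), (0, 0, 0), 1.0)
            for y, x in [(5, 5), (10, 10), (15, 15), (19, 49)]])
        d = microenv.site_density(sites, mask)
        assert d["density_per_px"] == 4 / 1000

    def test_zero_sites(self):
        d = microenv.site_density(microenv.SiteSet([]),
                                  np.ones((10, 10), dtype=bool))
        assert d["density_per_px"] == 0.0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            microenv.site_density(microenv.SiteSet([]),
                                  np.zeros((5, 5), dtype=bool))

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            mask = rng.uniform(size=(30, 30)) > 0.5
            if not mask.any():
                continue
            pts = rng.integers(0, 30, size=(15, 2))
            sites = microenv.SiteSet([
                microenv.TranscriptionSite((0, int(y), int(x)), (0, 0, 0), 1.0)
                for y, x in pts])
            d = microenv.site_density(sites, mask)
            brute = sum(bool(mask[y, x]) for y, x in pts)
            assert d["count"] == brute
            assert d["density_per_px"] == brute / mask.sum()

    def test_physical_density_units(self):
        mask = np.ones((10, 10), dtype=bool)
        sites = microenv.SiteSet([microenv.TranscriptionSite(
            (0, 5, 5), (0, 0, 0), 1.0)])
        d = microenv.site_density(sites, mask, pixel_size_um=(0.5, 0.5))
        assert d["density_per_um2"] == pytest.approx(1 / (100 * 0.25))


class TestEnrichmentAtSites:
    def test_uniform_channel(self):
        stack = _flat_stack(4.2)
        ss = microenv.SiteSet([microenv.TranscriptionSite(
            (6, 20, 20), (1.5, 2.0, 2.0), 4.2)])
        tbl = microenv.enrichment_at_sites(stack, "c", ss)
        assert tbl.mean_intensity.iloc[0] == pytest.approx(4.2)

    def test_two_populations_ratio_recovered(self):
        cfg = synthetic.ConfocalPhantomConfig(
            shape_voxels=(40, 256, 256), n_sites=20, site_peak_snr=10,
            enrichment_amplitude=2.0, enrichment_sigma_um=0.5,
            enriched_fraction=0.5, min_separation_um=2.5,
            noise_model="none", seed=8)
        stack, truth = synthetic.gen_confocal_phantom(cfg)
        tv = truth.sites
        ss = microenv.SiteSet([
            microenv.TranscriptionSite(
                (int(r.z), int(r.y), int(r.x)),
                (r.z_um, r.y_um, r.x_um), r.peak_amplitude)
            for _, r in tv.iterrows()])
        tbl = microenv.enrichment_at_sites(stack, "mark", ss, r_sample_um=0.2)
        enr = tbl.mean_intensity[tv.enriched.to_numpy()].mean()
        base = tbl.mean_intensity[~tv.enriched.to_numpy()].mean()
        assert abs(enr / base - 2.0) / 2.0 < 0.10


class TestRegionCellIntensities:
    def test_two_labels(self):
        vol = np.zeros((4, 10, 10))
        mask = np.zeros((10, 10), dtype=int)
        mask[:5] = 1
        mask[5:] = 2
        vol[:, :5] = 10.0
        vol[:, 5:] = 20.0
        stack = microenv.VolumeStack({"c": vol}, (0.3, 0.1, 0.1))
        tbl = microenv.region_cell_intensities(stack, "c", mask)
        assert list(tbl.label) == [1, 2]
        assert list(tbl.mean_intensity) == [10.0, 20.0]

    def test_no_labels_raises(self):
        with pytest.raises(ValueError):
            microenv.region_cell_intensities(
                _flat_stack(), "c", np.zeros((40, 40), dtype=int))


def test_stack_roundtrip(tmp_path):
    cfg = synthetic.ConfocalPhantomConfig(shape_voxels=(8, 32, 32),
                                          n_sites=3, seed=1)
    stack, _ = synthetic.gen_confocal_phantom(cfg)
    path = tmp_path / "stack.tif"
    microenv.write_stack(stack, path)
    back = microenv.read_stack(path)
    assert set(back.channels) == {"rna", "mark"}
    assert back.voxel_size_um == stack.voxel_size_um
    np.testing.assert_allclose(back.channels["rna"], stack.channels["rna"],
                               rtol=1e-6)
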