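"""MALDI deconvolution: segmentation, abundances, batch, PCA, enrichment."""

import numpy as np
import pandas as pd
import pytest

from phenoquant import maldi, synthetic


def _iou(a, b):
    return (a & b).sum() / (a | b).sum()


class TestSegmentation:
    def test_ten_larvae_recovered(self, noiseless_ion_phantom):
        _, stack, truth = noiseless_ion_phantom
        mask = maldi.segment_larvae(stack)
        assert mask.n_larvae == 10
        for i in range(1, 11):
            assert _iou(mask.labels == i, truth.labels == i) >= 0.95

    def test_blank_stack(self):
        stack = maldi.IonImageStack(
            planes=np.zeros((2, 20, 20)),
            channels=[maldi.IonChannel(700.1), maldi.IonChannel(800.2)],
            pixel_size_um=100)
        assert maldi.segment_larvae(stack).n_larvae == 0

    def test_adjacent_larvae_stay_separate(self):
        # two blobs separated by a single background pixel column
        plane = np.zeros((11, 21))
        plane[3:8, 2:10] = 5.0
        plane[3:8, 11:19] = 5.0
        stack = maldi.IonImageStack(planes=plane[None],
                                    channels=[maldi.IonChannel(700.0)],
                                    pixel_size_um=100)
        mask = maldi.segment_larvae(stack)
        assert mask.n_larvae == 2

    def test_label_count_across_seeds(self):
        for seed in range(20):
            cfg = synthetic.IonPhantomConfig(n_larvae=8, noise_sd=2.0,
                                             seed=seed)
            stack, truth = synthetic.gen_ion_phantom(cfg)
            assert maldi.segment_larvae(stack).n_larvae == 8


class TestAbundance:
    def test_uniform_plane_mean(self):
        plane = np.zeros((10, 10))
        plane[2:5, 2:5] = 4.5
        labels = np.zeros((10, 10), dtype=int)
        labels[2:5, 2:5] = 1
        stack = maldi.IonImageStack(planes=plane[None],
                                    channels=[maldi.IonChannel(700.0)],
                                    pixel_size_um=100)
        m = maldi.per_larva_abundance(stack, maldi.LarvaLabelMask(labels))
        assert m.values.iloc[0, 0] == 4.5

    def test_noiseless_exact_recovery(self, noiseless_ion_phantom):
        _, stack, truth = noiseless_ion_phantom
        mask = maldi.segment_larvae(stack)
        m = maldi.per_larva_abundance(stack, mask, meta=truth.meta)
        np.testing.assert_allclose(m.values.to_numpy(),
                                   truth.abundance.to_numpy(), rtol=1e-12)

    def test_noisy_recovery_correlates(self):
        cfg = synthetic.IonPhantomConfig(n_larvae=10, noise_sd=5.0, seed=9)
        stack, truth = synthetic.gen_ion_phantom(cfg)
        m = maldi.per_larva_abundance(stack, maldi.segment_larvae(stack))
        for c in range(m.values.shape[1]):
            r = np.corrcoef(m.values.iloc[:, c], truth.abundance.iloc[:, c])
            assert r[0, 1] >= 0.95

    def test_sum_aggregation(self, noiseless_ion_phantom):
        _, stack, truth = noiseless_ion_phantom
        mask = maldi.segment_larvae(stack)
        m = maldi.per_larva_abundance(stack, mask, aggregation="sum")
        counts = mask.pixel_counts()
        expect = truth.abundance.to_numpy() * np.array(
            [counts[i] for i in range(1, 11)])[:, None]
        np.testing.assert_allclose(m.values.to_numpy(), expect, rtol=1e-9)

    def test_empty_mask_raises(self, noiseless_ion_phantom):
        _, stack, _ = noiseless_ion_phantom
        with pytest.raises(ValueError):
            maldi.per_larva_abundance(
                stack, maldi.LarvaLabelMask(np.zeros(stack.grid, dtype=int)))


def _matrix(values, batches, groups=None):
    values = pd.DataFrame(values, columns=[f"ch{i}"
                                           for i in range(values.shape[1])])
    meta = pd.DataFrame({"group": groups or ["A"] * len(values),
                         "batch": batches}, index=values.index)
    return maldi.AbundanceMatrix(values, meta)


class TestBatchAdjust:
    def test_single_batch_passthrough(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(6, 4)), ["b0"] * 6)
        out = maldi.batch_adjust(m)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   m.values.to_numpy(), atol=1e-9)

    def test_additive_offset_removed(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 2, size=(8, 3))
        vals = base.copy()
        vals[4:] += 10.0
        out = maldi.batch_adjust(_matrix(vals, ["b0"] * 4 + ["b1"] * 4))
        means = out.values.groupby(out.meta["batch"]).mean()
        assert np.abs(means.diff().iloc[1]).max() < 1e-9

    def test_scale_effect_removed(self):
        rng = np.random.default_rng(2)
        base = rng.normal(10, 2, size=(8, 3))
        vals = base.copy()
        vals[4:] *= 3.0
        out = maldi.batch_adjust(_matrix(vals, ["b0"] * 4 + ["b1"] * 4))
        sds = out.values.groupby(out.meta["batch"]).std(ddof=0)
        assert np.abs(sds.diff().iloc[1]).max() < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(10, 5))
        vals[5:] = vals[5:] * 2 + 4
        once = maldi.batch_adjust(_matrix(vals, ["b0"] * 5 + ["b1"] * 5))
        twice = maldi.batch_adjust(once)
        assert np.abs(twice.values.to_numpy()
                      - once.values.to_numpy()).max() < 1e-9


class TestPCA:
    def test_identical_rows_give_zero_scores(self):
        m = _matrix(np.tile([1.0, 2.0, 3.0], (5, 1)), ["b0"] * 5)
        with pytest.warns(UserWarning):
            scores, _, _ = maldi.pca_profiles(m)
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_pc1_matches_eigendecomposition(self):
        rng = np.random.default_rng(4)
        # two columns with known covariance structure
        z = rng.normal(size=500)
        x = np.c_[z + 0.1 * rng.normal(size=500),
                  z + 0.1 * rng.normal(size=500)]
        m = _matrix(x, ["b0"] * 500)
        _, loadings, frac = maldi.pca_profiles(m, n_components=2)
        xs = (x - x.mean(0)) / x.std(0)
        w, v = np.linalg.eigh(np.cov(xs.T))
        lead = v[:, np.argmax(w)]
        lead = lead * np.sign(lead[np.argmax(np.abs(lead))])
        np.testing.assert_allclose(loadings["PC1"].to_numpy(), lead,
                                   atol=1e-6)
        assert abs(frac.sum() - 1.0) < 1e-9

    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(20, 6))
        m1 = _matrix(x, ["b0"] * 20)
        perm = rng.permutation(20)
        m2 = maldi.AbundanceMatrix(
            m1.values.iloc[perm].reset_index(drop=True),
            m1.meta.iloc[perm].reset_index(drop=True))
        s1, _, f1 = maldi.pca_profiles(m1)
        s2, _, f2 = maldi.pca_profiles(m2)
        np.testing.assert_allclose(np.sort(s1["PC1"].to_numpy()),
                                   np.sort(s2["PC1"].to_numpy()), atol=1e-8)
        np.testing.assert_allclose(f1, f2, atol=1e-12)
        assert np.all(np.diff(f1) <= 1e-12)


class TestClassEnrichment:
    def _class_map(self, channels):
        return {c.name: c.lipid_class for c in channels}

    def test_constructed_fold_change(self):
        channels = synthetic.default_lipid_panel(4, 4, 0)
        names = [c.name for c in channels]
        rng = np.random.default_rng(6)
        a = np.abs(rng.normal(10, 0.5, size=(5, 8)))
        b = a.copy()
        b[:, :4] *= 2.0   # triglycerides doubled
        vals = pd.DataFrame(np.vstack([a, b]), columns=names)
        meta = pd.DataFrame({"group": ["A"] * 5 + ["B"] * 5,
                             "batch": "b0"}, index=vals.index)
        m = maldi.AbundanceMatrix(vals, meta)
        out = maldi.class_enrichment(m, "A", "B", self._class_map(channels))
        tg = out[out.lipid_class == "triglyceride"].iloc[0]
        assert tg.median_log2fc > 0.9
        assert tg.p == out.p.min()

    def test_identical_groups(self):
        channels = synthetic.default_lipid_panel(3, 3, 0)
        names = [c.name for c in channels]
        vals = pd.DataFrame(np.tile(np.arange(1.0, 7.0), (6, 1)),
                            columns=names)
        meta = pd.DataFrame({"group": ["A"] * 3 + ["B"] * 3, "batch": "b0"},
                            index=vals.index)
        out = maldi.class_enrichment(maldi.AbundanceMatrix(vals, meta),
                                     "A", "B", self._class_map(channels))
        assert np.allclose(out.median_log2fc, 0.0)
        assert np.all(out.p > 0.99)

    def test_signature_signs_recovered_from_phantom(self):
        cfg = synthetic.IonPhantomConfig(
            n_larvae=12, noise_sd=1.0, seed=13,
            group_effects={"B": {"triglyceride": 1.72,
                                 "glycerophospholipid": 0.7}})
        stack, truth = synthetic.gen_ion_phantom(cfg)
        m = maldi.per_larva_abundance(stack, maldi.segment_larvae(stack),
                                      meta=truth.meta)
        cm = {c.name: c.lipid_class for c in stack.channels}
        out = maldi.class_enrichment(m, "A", "B", cm).set_index("lipid_class")
        assert out.loc["triglyceride", "median_log2fc"] > 0
        assert out.loc["glycerophospholipid", "median_log2fc"] < 0


def test_ion_dir_roundtrip(tmp_path, noiseless_ion_phantom):
    _, stack, _ = noiseless_ion_phantom
    maldi.write_ion_dir(stack, tmp_path / "ions")
    back = maldi.read_ion_dir(tmp_path / "ions")
    np.testing.assert_allclose(back.planes, stack.planes, rtol=1e-6)
    assert [c.mz for c in back.channels] == [c.mz for c in stack.channels]
    assert [c.lipid_class for c in back.channels] == \
        [c.lipid_class for c in stack.channels]


def test_imzml_roundtrip(tmp_path):
    writer_mod = pytest.importorskip("pyimzml.ImzMLWriter")
    channels = [maldi.IonChannel(700.5), maldi.IonChannel(815.65)]
    path = str(tmp_path / "t.imzML")
    rng = np.random.default_rng(7)
    truth = rng.uniform(1, 10, size=(2, 4, 5))
    with writer_mod.ImzMLWriter(path) as w:
        for y in range(4):
            for x in range(5):
                mzs = np.array([c.mz for c in channels])
                w.addSpectrum(mzs, truth[:, y, x], (x + 1, y + 1))
    stack = maldi.read_imzml(path, channels, pixel_size_um=100.0)
    np.testing.assert_allclose(stack.planes, truth, rtol=1e-4)
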