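"""Plane bookkeeping, patch sampling and the training protocol."""

import numpy as np
import pytest
from scipy.stats import chisquare

import orthosr as o
from orthosr.training import (
    TABLE_SETTINGS,
    TrainConfig,
    extract_plane_slices,
    restack_plane_slices,
    sample_patch_pair,
)


class TestPlaneSlicing:
    def test_single_bright_voxel_bookkeeping(self):
        arr = np.zeros((5, 6, 7))
        i, j, k = 2, 4, 6
        arr[i, j, k] = 1.0
        axial = extract_plane_slices(arr, "axial")
        coronal = extract_plane_slices(arr, "coronal")
        sagittal = extract_plane_slices(arr, "sagittal")
        # exactly one bright slice per plane, at the coherent 2-D position
        assert [s.max() for s in axial].count(1.0) == 1
        assert axial[k][j, i] == 1.0
        assert coronal[j][k, i] == 1.0
        assert sagittal[i][k, j] == 1.0

    def test_slice_counts_per_plane(self):
        arr = np.zeros((5, 6, 7))
        assert extract_plane_slices(arr, "axial").shape == (7, 6, 5)
        assert extract_plane_slices(arr, "coronal").shape == (6, 7, 5)
        assert extract_plane_slices(arr, "sagittal").shape == (5, 7, 6)

    @pytest.mark.parametrize("plane", ["axial", "coronal", "sagittal"])
    def test_restack_round_trip(self, plane, rng):
        arr = rng.normal(size=(5, 6, 7))
        stack = extract_plane_slices(arr, plane)
        np.testing.assert_array_equal(restack_plane_slices(stack, plane), arr)


class TestPatchSampling:
    def test_patch_shape_and_shared_location(self, rng):
        hr = rng.normal(size=(120, 130))
        lr = hr * 2.0
        hp, lp = sample_patch_pair(hr, lr, 96, rng)
        assert hp.shape == lp.shape == (96, 96)
        np.testing.assert_array_equal(lp, hp * 2.0)

    def test_same_seed_same_crop(self, rng):
        hr = np.arange(120.0 * 120).reshape(120, 120)
        a = sample_patch_pair(hr, hr, 96, np.random.default_rng(5))
        b = sample_patch_pair(hr, hr, 96, np.random.default_rng(5))
        np.testing.assert_array_equal(a[0], b[0])

    def test_small_slices_reflect_padded(self, rng):
        hr = rng.normal(size=(40, 48))
        hp, lp = sample_patch_pair(hr, hr, 96, rng)
        assert hp.shape == (96, 96)

    def test_crop_offsets_uniform(self):
        """Chi-square uniformity of crop offsets over 10^4 draws."""
        rng = np.random.default_rng(12)
        hr = np.zeros((40, 40))
        patch = 32
        n_offsets = 40 - patch + 1
        counts = np.zeros((n_offsets, n_offsets))
        marker = np.arange(40.0)[:, None] * 100 + np.arange(40.0)[None, :]
        for _ in range(10_000):
            hp, _ = sample_patch_pair(marker, marker, patch, rng)
            i, j = int(hp[0, 0] // 100), int(hp[0, 0] % 100)
            counts[i, j] += 1
        _, p = chisquare(counts.ravel())
        assert p > 0.01


class TestTrainProtocol:
    def _tiny_setup(self):
        cases = []
        for s in (0, 1):
            hr, ta, tc = o.make_triplet(o.PhantomSpec(size=(24, 24, 20), seed=s))
            lr = o.fuse(ta, tc, hr.geometry).lr
            cases.append((hr, lr))
        return cases[:1], cases[1:]

    def _tiny_config(self, **kw):
        base = dict(
            patch_size=16, batch_size=16, batches_per_epoch=2, total_epochs=3,
            learning_rate=1e-3, loss="MSE", plane="sagittal", seed=0,
        )
        base.update(kw)
        return TrainConfig(**base)

    def test_patch_counter_equals_batches_times_epochs(self):
        train_cases, eval_cases = self._tiny_setup()
        net = o.build_model(o.ArchitectureSpec("SRCNN", width=4), rng=0)
        model = o.train(net, train_cases, eval_cases, self._tiny_config())
        assert model.patch_counter == 16 * 2 * 3 == 96
        assert len(model.train_log) == 3

    def test_training_reproducible_given_seed(self):
        train_cases, eval_cases = self._tiny_setup()
        logs = []
        for _ in range(2):
            net = o.build_model(o.ArchitectureSpec("SRCNN", width=4), rng=9)
            model = o.train(net, train_cases, eval_cases, self._tiny_config(seed=9))
            logs.append([e["loss"] for e in model.train_log])
        assert logs[0] == logs[1]

    def test_empty_eval_set_rejected(self):
        train_cases, _ = self._tiny_setup()
        net = o.build_model(o.ArchitectureSpec("SRCNN", width=4), rng=0)
        with pytest.raises(ValueError, match="evaluation set"):
            o.train(net, train_cases, [], self._tiny_config())

    def test_published_settings_per_architecture(self):
        cfg = TrainConfig.published("EDSR")
        assert (cfg.learning_rate, cfg.loss) == (1e-4, "L1")
        assert TrainConfig.published("VDSR").grad_clip == 1.0
        assert TrainConfig.published("SRCNN").loss == "MSE"
        for arch, (bpe, epochs, _, _) in TABLE_SETTINGS.items():
            c = TrainConfig.published(arch)
            assert (c.batches_per_epoch, c.total_epochs) == (bpe, epochs)


class TestInference:
    def test_identity_model_round_trips_all_planes(self, fused_case):
        """Slicing/restacking with an identity network is lossless."""
        hr, lr = fused_case
        net = o.build_model(o.ArchitectureSpec("VDSR", width=4), rng=0)
        tail = net.final_conv()
        tail.weight.value[...] = 0.0
        tail.bias.value[...] = 0.0
        model = o.TrainedModel(network=net, spec=net.spec,
                               config=TrainConfig(plane="sagittal"))
        import warnings

        for plane in ("axial", "coronal", "sagittal"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)  # cross-plane is intended here
                out = o.infer_volume(model, lr, plane)
            np.testing.assert_allclose(out.intensities, lr.intensities, atol=1e-8)
            assert out.shape == lr.shape
            assert out.geometry.same_grid(lr.geometry)

    def test_cross_plane_inference_warns_not_errors(self, fused_case):
        _, lr = fused_case
        net = o.build_model(o.ArchitectureSpec("SRCNN", width=4), rng=0)
        model = o.TrainedModel(network=net, spec=net.spec,
                               config=TrainConfig(plane="sagittal"))
        with pytest.warns(UserWarning, match="trained on"):
            o.infer_volume(model, lr, "axial")

    def test_save_load_round_trip(self, tmp_path, fused_case):
        from orthosr.training import load_model, save_model

        _, lr = fused_case
        net = o.build_model(o.ArchitectureSpec("SRResNet", width=4), rng=0)
        model = o.TrainedModel(network=net, spec=net.spec,
                               config=TrainConfig(plane="coronal"))
        a = o.infer_volume(model, lr)
        save_model(model, tmp_path / "m.npz")
        loaded = load_model(tmp_path / "m.npz")
        b = o.infer_volume(loaded, lr)
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestLearning:
    def test_sagittal_edsr_improves_over_lr(self, short_training_results):
        """Short sagittal EDSR training lifts held-out PSNR above LR."""
        lr_psnr = short_training_results["lr_psnr"]
        runs = short_training_results["runs"]["EDSR"]
        improved = sum(r["sr_psnr"] > lr_psnr for r in runs)
        assert improved >= 2
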