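import numpy as np
import pytest
from scipy import ndimage

from thyrus.nn import (
    AugmentParams,
    NetworkConfig,
    SliceDataset,
    TrainConfig,
    augment,
    build_network,
    predict_masks,
    train,
)
from thyrus.preprocess import normalize_slices


def _ellipse_slices(n, rng, hw=32):
    imgs, masks = [], []
    for _ in range(n):
        a, b = rng.uniform(6, 11), rng.uniform(5, 9)
        cy, cx = rng.uniform(13, 19, size=2)
        yy, xx = np.mgrid[0:hw, 0:hw]
        r = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)
        mask = (r < 1).astype(np.float32)
        img = np.where(mask > 0, 0.25, 0.5) * rng.rayleigh(np.sqrt(2 / np.pi), (hw, hw))
        img[np.abs(r - 1) < 0.12] = 0.9
        imgs.append(ndimage.gaussian_filter(img, 0.7).astype(np.float32))
        masks.append(mask)
    return normalize_slices(np.stack(imgs)), np.stack(masks)


@pytest.fixture(scope="module")
def tiny_dataset():
    rng = np.random.default_rng(12)
    xtr, ttr = _ellipse_slices(10, rng)
    xva, tva = _ellipse_slices(4, rng)
    return SliceDataset(xtr, ttr, xva, tva, train_lobes=[("a", 1)], val_lobes=[("b", 1)])


class TestTrainLoop:
    def test_memorizes_small_slice_set(self, tiny_dataset):
        """~200 steps on 10 slices of one synthetic lobe reach training
        Dice ≥ 0.95 (memorization sanity check of loss + optimizer)."""
        model = build_network(NetworkConfig(n_enc_dec=3, base_channels=8, dropout=0.0), seed=0)
        cfg = TrainConfig(lr=2e-3, batch_size=2, max_epochs=40, early_stop_patience=40,
                          augment=AugmentParams(vflip_prob=0.0, elastic_alpha=0.0), seed=0)
        model, report = train(model, tiny_dataset, cfg)
        pred = predict_masks(model, tiny_dataset.train_images)
        inter = 2.0 * np.logical_and(pred > 0, tiny_dataset.train_masks > 0).sum()
        dice = inter / (pred.sum() + tiny_dataset.train_masks.sum())
        assert dice >= 0.95
        assert report.epochs_run <= 40

    def test_loss_descends(self, tiny_dataset):
        model = build_network(NetworkConfig(n_enc_dec=3, base_channels=8, dropout=0.0), seed=1)
        cfg = TrainConfig(lr=1e-3, batch_size=2, max_epochs=6, early_stop_patience=6,
                          augment=AugmentParams(vflip_prob=0.0, elastic_alpha=0.0), seed=1)
        _, report = train(model, tiny_dataset, cfg)
        assert report.train_loss[-1] < report.train_loss[0]

    def test_same_seed_identical_validation_dice(self, tiny_dataset):
        results = []
        for _ in range(2):
            model = build_network(NetworkConfig(n_enc_dec=3, base_channels=4), seed=3)
            cfg = TrainConfig(lr=1e-3, batch_size=2, max_epochs=2, seed=3)
            _, report = train(model, tiny_dataset, cfg)
            results.append(report.val_dice)
        assert results[0] == results[1]

    def test_empty_split_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="empty"):
            SliceDataset(tiny_dataset.train_images[:0], tiny_dataset.train_masks[:0],
                         tiny_dataset.val_images, tiny_dataset.val_masks)

    def test_straddling_lobes_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="straddle"):
            SliceDataset(tiny_dataset.train_images, tiny_dataset.train_masks,
                         tiny_dataset.val_images, tiny_dataset.val_masks,
                         train_lobes=[("a", 1)], val_lobes=[("a", 1)])


class TestAugment:
    def test_no_op_configuration_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16)).astype(np.float32)
        msk = (rng.random((16, 16)) > 0.5).astype(np.float32)
        out_i, out_m = augment(img, msk, AugmentParams(vflip_prob=0.0, elastic_alpha=0.0),
                               np.random.default_rng(1))
        assert np.array_equal(out_i, img)
        assert np.array_equal(out_m, msk)

    def test_vertical_flip_is_involution(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16)).astype(np.float32)
        msk = (rng.random((16, 16)) > 0.5).astype(np.float32)
        p = AugmentParams(vflip_prob=1.0, elastic_alpha=0.0)
        i1, m1 = augment(img, msk, p, np.random.default_rng(0))
        i2, m2 = augment(i1, m1, p, np.random.default_rng(0))
        assert np.array_equal(i2, img)
        assert np.array_equal(m2, msk)

    def test_mask_stays_binary_under_elastic_deformation(self):
        rng = np.random.default_rng(5)
        img = rng.random((32, 32)).astype(np.float32)
        msk = np.zeros((32, 32), np.float32)
        msk[8:22, 10:25] = 1
        p = AugmentParams(vflip_prob=0.5, elastic_alpha=12.0, elastic_sigma=4.0, elastic_prob=1.0)
        for seed in range(5):
            _, m = augment(img, msk, p, np.random.default_rng(seed))
            assert set(np.unique(m)) <= {0.0, 1.0}

    def test_image_and_mask_warped_by_same_field(self):
        """A mask tracking a bright blob stays on the blob after warping."""
        img = np.zeros((32, 32), np.float32)
        img[10:20, 12:22] = 1.0
        msk = (img > 0.5).astype(np.float32)
        p = AugmentParams(vflip_prob=0.0, elastic_alpha=8.0, elastic_sigma=5.0, elastic_prob=1.0)
        wi, wm = augment(img, msk, p, np.random.default_rng(3))
        inter = np.logical_and(wi > 0.5, wm > 0.5).sum()
        union = np.logical_or(wi > 0.5, wm > 0.5).sum()
        assert inter / union > 0.9
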