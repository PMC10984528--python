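"""Dataset I/O, preprocessing, augmentation, splits and phantom generation."""

import numpy as np
import pytest
from PIL import Image
from scipy import ndimage

from pmffnet.data import (SampleRecord, augment, load_dataset, preprocess,
                          split_train_val)
from pmffnet.phantom import (PhantomConfig, generate_corpus, generate_phantom,
                             shifted_config)


def write_pair(root, subset, sid, size=(20, 24), lesion=True):
    (root / subset / "images").mkdir(parents=True, exist_ok=True)
    (root / subset / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(abs(hash(sid)) % 2 ** 31)
    img = rng.integers(0, 255, (*size, 3), dtype=np.uint8)
    mask = np.zeros(size, np.uint8)
    if lesion:
        mask[4:9, 5:11] = 255
    Image.fromarray(img).save(root / subset / "images" / f"{sid}.png")
    Image.fromarray(mask).save(root / subset / "masks" / f"{sid}.png")


class TestLoadDataset:
    def test_loads_paired_records(self, tmp_path):
        for sid in ("a", "b", "c"):
            write_pair(tmp_path, "train", sid)
        recs = load_dataset(tmp_path, "train")
        assert [r.id for r in recs] == ["a", "b", "c"]
        assert set(np.unique(recs[0].mask)) <= {0, 1}

    def test_unpaired_image_warns_and_skips(self, tmp_path):
        for sid in ("a", "b"):
            write_pair(tmp_path, "train", sid)
        orphan = tmp_path / "train" / "images" / "c.png"
        Image.fromarray(np.zeros((8, 8, 3), np.uint8)).save(orphan)
        with pytest.warns(UserWarning, match="no mask"):
            recs = load_dataset(tmp_path, "train")
        assert len(recs) == 2

    def test_manifest_excludes_normal_ovary(self, tmp_path):
        for sid in ("a", "b", "c"):
            write_pair(tmp_path, "train", sid)
        (tmp_path / "classes.csv").write_text(
            "id,category\na,Teratoma\nb,Normal ovary\nc,Simple cyst\n")
        recs = load_dataset(tmp_path, "train")
        assert [r.id for r in recs] == ["a", "c"]

    def test_empty_dataset_errors(self, tmp_path):
        (tmp_path / "train" / "images").mkdir(parents=True)
        (tmp_path / "train" / "masks").mkdir(parents=True)
        with pytest.raises(ValueError):
            load_dataset(tmp_path, "train")


class TestPreprocess:
    def test_resizes_arbitrary_input_to_square(self):
        rec = SampleRecord("x", np.zeros((500, 400, 3), np.uint8),
                           np.zeros((500, 400), np.uint8))
        x, m = preprocess(rec, side=384)
        assert x.shape == (3, 384, 384) and m.shape == (384, 384)

    def test_mask_stays_binary_and_empty_stays_empty(self):
        rec = SampleRecord("x", np.zeros((100, 80, 3), np.uint8),
                           np.zeros((100, 80), np.uint8))
        _, m = preprocess(rec, side=64)
        assert m.sum() == 0

    def test_lesion_topology_preserved(self):
        cfg = PhantomConfig(image_size=(100, 160), seed=5)
        for s in range(5):
            rec = generate_phantom(cfg, seed=50 + s)
            _, m = preprocess(rec, side=96)
            _, n_in = ndimage.label(rec.mask)
            _, n_out = ndimage.label(m)
            assert (n_in, n_out) == (1, 1)


class TestAugment:
    def _forced_rng(self, h_flip, v_flip):
        class R:
            def __init__(self):
                self.vals = iter([0.0 if h_flip else 1.0,
                                  0.0 if v_flip else 1.0])

            def random(self):
                return next(self.vals)
        return R()

    def test_double_flip_matches_manual(self):
        img = np.arange(2 * 4 * 4, dtype=np.float32).reshape(2, 4, 4)
        mask = (np.arange(16).reshape(4, 4) % 2).astype(np.float32)
        ai, am = augment(img, mask, self._forced_rng(True, True))
        np.testing.assert_array_equal(ai, img[:, ::-1, ::-1])
        np.testing.assert_array_equal(am, mask[::-1, ::-1])

    def test_flips_are_involutions(self):
        img = np.random.default_rng(0).random((3, 6, 6)).astype(np.float32)
        mask = (img[0] > 0.5).astype(np.float32)
        once = augment(img, mask, self._forced_rng(True, True))
        twice = augment(once[0], once[1], self._forced_rng(True, True))
        np.testing.assert_array_equal(twice[0], img)
        np.testing.assert_array_equal(twice[1], mask)

    def test_lesion_area_invariant(self):
        rng = np.random.default_rng(1)
        img = rng.random((3, 8, 8)).astype(np.float32)
        mask = (rng.random((8, 8)) > 0.6).astype(np.float32)
        for _ in range(10):
            _, am = augment(img, mask, rng)
            assert am.sum() == mask.sum()


class TestSplit:
    def _dummies(self, n):
        img = np.zeros((4, 4, 3), np.uint8)
        msk = np.zeros((4, 4), np.uint8)
        return [SampleRecord(str(i), img, msk) for i in range(n)]

    def test_published_split_arithmetic(self):
        train, val = split_train_val(self._dummies(820), 0.8, seed=0)
        assert (len(train), len(val)) == (656, 164)

    def test_small_split(self):
        train, val = split_train_val(self._dummies(10), 0.8, seed=0)
        assert (len(train), len(val)) == (8, 2)

    def test_deterministic_and_exhaustive(self):
        recs = self._dummies(37)
        t1, v1 = split_train_val(recs, 0.8, seed=3)
        t2, v2 = split_train_val(recs, 0.8, seed=3)
        assert [r.id for r in t1] == [r.id for r in t2]
        assert [r.id for r in v1] == [r.id for r in v2]
        assert sorted(r.id for r in t1 + v1) == sorted(r.id for r in recs)
        assert not set(r.id for r in t1) & set(r.id for r in v1)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            split_train_val(self._dummies(1), 0.8, seed=0)


class TestPhantom:
    CFG = PhantomConfig(image_size=(64, 96), seed=9)

    def test_seed_determinism(self):
        a = generate_phantom(self.CFG)
        b = generate_phantom(self.CFG)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_area_fraction_within_bounds(self):
        f_min, f_max = self.CFG.area_fraction
        for s in range(100):
            rec = generate_phantom(self.CFG, seed=1000 + s)
            frac = rec.mask.mean()
            # the drawn fraction parameterizes the ellipse; boundary wobble
            # perturbs the realized area slightly
            assert 0.8 * f_min < frac < 1.25 * f_max

    def test_lesion_is_hypoechoic(self):
        darker = 0
        for s in range(100):
            rec = generate_phantom(self.CFG, seed=2000 + s)
            gray = rec.image[..., 0].astype(float)
            darker += gray[rec.mask == 1].mean() < gray[rec.mask == 0].mean()
        assert darker == 100

    def test_single_connected_lesion(self):
        for s in range(20):
            rec = generate_phantom(self.CFG, seed=3000 + s)
            _, n = ndimage.label(rec.mask)
            assert n == 1

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(area_fraction=(0.3, 0.2))
        with pytest.raises(ValueError):
            PhantomConfig(area_fraction=(0.1, 0.7))


class TestCorpus:
    CFG = PhantomConfig(image_size=(48, 64), seed=21)

    def test_roundtrip_is_lossless(self, tmp_path):
        generate_corpus(6, self.CFG, tmp_path, subset="train")
        recs = load_dataset(tmp_path, "train")
        assert len(recs) == 6
        for i, rec in enumerate(recs):
            ref = generate_phantom(self.CFG, seed=self.CFG.seed + i)
            np.testing.assert_array_equal(rec.mask, ref.mask)
            np.testing.assert_array_equal(rec.image, ref.image)

    def test_refuses_nonempty_target(self, tmp_path):
        generate_corpus(2, self.CFG, tmp_path, subset="train")
        with pytest.raises(FileExistsError):
            generate_corpus(2, self.CFG, tmp_path, subset="train")
        generate_corpus(2, self.CFG, tmp_path, subset="train", force=True)

    def test_zero_size_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_corpus(0, self.CFG, tmp_path)

    def test_shifted_variant_differs_in_contrast(self, tmp_path):
        shifted = shifted_config(self.CFG)
        assert shifted.contrast > self.CFG.contrast
        ratios = {"base": [], "shift": []}
        for s in range(30):
            for key, cfg in (("base", self.CFG), ("shift", shifted)):
                rec = generate_phantom(cfg, seed=5000 + s)
                gray = rec.image[..., 0].astype(float)
                ratios[key].append(gray[rec.mask == 1].mean()
                                   / gray[rec.mask == 0].mean())
        assert np.mean(ratios["shift"]) > np.mean(ratios["base"]) + 0.1
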