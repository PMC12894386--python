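"""Image IO, preprocessing, splits, noise, and the synthetic generator."""

import numpy as np
import pytest
from PIL import Image

import lightwavenet as lwn
from lightwavenet.data import (
    ImageRecord,
    add_gaussian_noise,
    augment,
    balance_classes,
    default_class_specs,
    generate_synthetic_dataset,
    load_image_folder,
    save_image_folder,
    stratified_split,
)
from lightwavenet.errors import DataError
from lightwavenet.wavelet_ops import haar_dwt2


def _record(seed=0, size=32, label=0):
    rng = np.random.default_rng(seed)
    return ImageRecord(rng.random((3, size, size), dtype=np.float32), label, f"c{label}")


class TestFolderIO:
    @pytest.fixture()
    def folder(self, tmp_path):
        rng = np.random.default_rng(0)
        for cname, n in (("blast", 3), ("healthy", 3)):
            d = tmp_path / cname
            d.mkdir()
            for i in range(n):
                side = 448 if i == 0 else 64
                arr = (rng.random((side, side, 3)) * 255).astype(np.uint8)
                arr[0, 0] = 255  # guarantees max pixel 255
                Image.fromarray(arr).save(d / f"{i}.png")
        return tmp_path

    def test_loads_resizes_and_scales(self, folder):
        records = load_image_folder(folder, size=224)
        assert len(records) == 6
        assert sorted({r.label for r in records}) == [0, 1]
        assert {r.class_name for r in records} == {"blast", "healthy"}
        assert all(r.pixels.shape == (3, 224, 224) for r in records)
        assert max(r.pixels.max() for r in records) == pytest.approx(1.0)
        assert min(r.pixels.min() for r in records) >= 0.0

    def test_unreadable_file_is_skipped(self, folder, caplog):
        (folder / "blast" / "broken.png").write_bytes(b"not an image")
        with caplog.at_level("WARNING"):
            records = load_image_folder(folder, size=32)
        assert len(records) == 6
        assert "skipped 1" in caplog.text

    def test_missing_directory_raises(self, tmp_path):
        with pytest.raises(DataError):
            load_image_folder(tmp_path / "nope")

    def test_save_then_load_roundtrip_preserves_labels(self, tmp_path):
        records = generate_synthetic_dataset(default_class_specs(4), 2, size=32, seed=0)
        manifest = save_image_folder(records, tmp_path / "ds")
        assert manifest.exists()
        loaded = load_image_folder(tmp_path / "ds", size=32)
        assert len(loaded) == len(records)
        assert [r.label for r in loaded] == sorted(r.label for r in records)


class TestAugment:
    def test_neutral_parameters_are_identity(self):
        rec = _record(1)
        out = augment(rec, rotation=0.0, hflip=False, vflip=False,
                      brightness=1.0, contrast=1.0)
        assert np.allclose(out.pixels, rec.pixels, atol=1e-7)
        assert out.label == rec.label

    def test_double_horizontal_flip_restores_image(self):
        rec = _record(2)
        once = augment(rec, rotation=0.0, hflip=True, vflip=False,
                       brightness=1.0, contrast=1.0)
        twice = augment(once, rotation=0.0, hflip=True, vflip=False,
                        brightness=1.0, contrast=1.0)
        assert np.allclose(twice.pixels, rec.pixels, atol=1e-7)

    def test_seeded_augmentation_is_reproducible_and_bounded(self):
        rec = _record(3)
        a = augment(rec, rng=42)
        b = augment(rec, rng=42)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.pixels.min() >= 0.0 and a.pixels.max() <= 1.0


class TestSplit:
    def test_single_class_ratio_arithmetic(self):
        records = [_record(i) for i in range(100)]
        split = stratified_split(records, (5, 1, 4), seed=0)
        assert split.sizes() == (50, 10, 40)

    def test_partitions_are_disjoint_exhaustive_and_stratified(self):
        records = [_record(i, label=i % 3) for i in range(30)]
        split = stratified_split(records, (5, 1, 4), seed=1)
        ids = [id(r) for part in split for r in part]
        assert len(ids) == 30 and len(set(ids)) == 30
        for part in split:
            labels = np.bincount([r.label for r in part], minlength=3)
            assert labels.max() - labels.min() == 0

    def test_same_seed_same_partition(self):
        records = [_record(i, label=i % 2) for i in range(20)]
        a = stratified_split(records, seed=3)
        b = stratified_split(records, seed=3)
        assert [id(r) for r in a.train] == [id(r) for r in b.train]

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            stratified_split([], (5, 1, 4))


class TestNoise:
    def test_zero_level_is_identity(self):
        rec = _record(4)
        assert np.array_equal(add_gaussian_noise(rec, 0.0).pixels, rec.pixels)

    def test_empirical_std_matches_level(self):
        rec = ImageRecord(np.full((3, 224, 224), 0.5, np.float32), 0, "c")
        noisy = add_gaussian_noise(rec, 0.05, rng=0)
        assert (noisy.pixels - rec.pixels).std() == pytest.approx(0.05, abs=0.002)

    def test_huge_level_stays_clipped(self):
        noisy = add_gaussian_noise(_record(5), 10.0, rng=1)
        assert noisy.pixels.min() >= 0.0 and noisy.pixels.max() <= 1.0

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            add_gaussian_noise(_record(6), -0.1)


class TestGenerator:
    def test_counts_labels_and_range(self):
        records = generate_synthetic_dataset(default_class_specs(4), 5, size=48, seed=0)
        assert len(records) == 20
        assert np.bincount([r.label for r in records]).tolist() == [5, 5, 5, 5]
        for r in records:
            assert r.pixels.shape == (3, 48, 48)
            assert 0.0 <= r.pixels.min() and r.pixels.max() <= 1.0

    def test_same_seed_is_bitwise_identical(self):
        a = generate_synthetic_dataset(default_class_specs(4), 2, size=32, seed=7)
        b = generate_synthetic_dataset(default_class_specs(4), 2, size=32, seed=7)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.pixels, rb.pixels)

    def test_spots_raise_high_frequency_energy(self):
        specs = default_class_specs(4)
        records = generate_synthetic_dataset(specs, 10, size=64, seed=3)
        by_name = {}
        for r in records:
            by_name.setdefault(r.class_name, []).append(r)

        def hf_energy(recs):
            total = 0.0
            for r in recs:
                s = haar_dwt2(r.pixels)
                total += float(sum(np.sum(np.square(d)) for d in (s.lh, s.hl, s.hh)))
            return total / len(recs)

        assert hf_energy(by_name["leaf_spots"]) > hf_energy(by_name["leaf_clean"])

    def test_validation_errors(self):
        specs = default_class_specs(4)
        with pytest.raises(ValueError):
            generate_synthetic_dataset(specs[:1], 5)
        with pytest.raises(ValueError):
            generate_synthetic_dataset(specs, 0)
        with pytest.raises(ValueError):
            generate_synthetic_dataset(specs, 10, max_images=5)

    def test_ten_class_recipes_have_distinct_sorted_names(self):
        specs = default_class_specs(10)
        names = [s.class_name for s in specs]
        assert len(set(names)) == 10 and names == sorted(names)


class TestBalance:
    def test_minority_classes_are_topped_up(self):
        records = [_record(i, label=0) for i in range(6)] + [
            _record(100 + i, label=1) for i in range(2)
        ]
        out = balance_classes(records, seed=0)
        counts = np.bincount([r.label for r in out])
        assert counts.tolist() == [6, 6]

    def test_min_per_class_expands_small_datasets(self):
        records = [_record(i, label=i % 2) for i in range(8)]
        out = balance_classes(records, seed=0, min_per_class=10)
        counts = np.bincount([r.label for r in out])
        assert counts.tolist() == [10, 10]
        assert all(r.pixels.min() >= 0 and r.pixels.max() <= 1 for r in out)
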