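"""Folder loading, splitting, and the phantom generator."""

import numpy as np
import pytest
from PIL import Image

from actsign import (LabeledImageSet, PhantomSpec, SplitSpec,
                     generate_phantoms, load_image_folder, save_image_folder,
                     split_dataset)
from actsign.data_io import (DATASET_PRINTED_CLASS_TOTALS, DATASET_PRINTED_TOTAL,
                             DatasetError, PHANTOM_CLASS_NAMES,
                             dataset_class_totals, dataset_total)


# -- phantoms ----------------------------------------------------------------

def test_phantom_counts_and_labels():
    ds = generate_phantoms(PhantomSpec(n_per_class=5, image_size=(32, 32), seed=7))
    assert len(ds) == 20
    assert ds.class_names == PHANTOM_CLASS_NAMES
    assert list(ds.class_counts()) == [5, 5, 5, 5]
    assert ds.images.shape == (20, 32, 32, 3)
    assert ds.images.min() >= 0.0 and ds.images.max() <= 1.0
    assert ds.provenance == "phantom"


def test_phantom_bit_identical_regeneration():
    spec = PhantomSpec(n_per_class=4, image_size=(40, 40), noise_sd=0.0, seed=3)
    a = generate_phantoms(spec)
    b = generate_phantoms(spec)
    np.testing.assert_array_equal(a.images, b.images)
    np.testing.assert_array_equal(a.labels, b.labels)
    # noisy regeneration is deterministic too (same seeded stream)
    spec_n = PhantomSpec(n_per_class=4, image_size=(40, 40), noise_sd=0.05, seed=3)
    np.testing.assert_array_equal(generate_phantoms(spec_n).images,
                                  generate_phantoms(spec_n).images)


def test_phantom_class_means_separate():
    """Pairwise L2 distance between class mean-images exceeds 5x noise_sd."""
    spec = PhantomSpec(n_per_class=30, image_size=(64, 64), noise_sd=0.05, seed=1)
    ds = generate_phantoms(spec)
    means = [ds.images[ds.labels == k].mean(axis=0) for k in range(4)]
    for i in range(4):
        for j in range(i + 1, 4):
            dist = np.linalg.norm(means[i] - means[j])
            assert dist > 5 * spec.noise_sd, (i, j, dist)


def test_phantom_nearest_centroid_separability():
    """Nearest-centroid on 8x8 block-averaged pixels clears 90% accuracy."""
    ds = generate_phantoms(
        PhantomSpec(n_per_class=100, image_size=(64, 64), noise_sd=0.05, seed=2))
    gray = ds.images.mean(axis=3)                       # (N, 64, 64)
    small = gray.reshape(len(ds), 8, 8, 8, 8).mean(axis=(2, 4))
    feats = small.reshape(len(ds), -1)
    # leave-one-in split: centroids from even indices, evaluate odd indices
    fit, hold = np.arange(0, len(ds), 2), np.arange(1, len(ds), 2)
    centroids = np.stack([feats[fit][ds.labels[fit] == k].mean(axis=0)
                          for k in range(4)])
    d = ((feats[hold][:, None, :] - centroids[None]) ** 2).sum(axis=2)
    acc = (d.argmin(axis=1) == ds.labels[hold]).mean()
    assert acc > 0.9, acc


def test_phantom_masks_cover_lesions():
    ds, masks = generate_phantoms(
        PhantomSpec(n_per_class=3, image_size=(48, 48), noise_sd=0.0, seed=9),
        return_masks=True)
    for img_label, mask in zip(ds.labels, masks):
        if PHANTOM_CLASS_NAMES[img_label] == "notumor":
            assert not mask.any()
        else:
            assert mask.any()


def test_phantom_spec_validation():
    with pytest.raises(DatasetError):
        PhantomSpec(n_per_class=0)
    with pytest.raises(DatasetError):
        PhantomSpec(noise_sd=0.7)


# -- splitting ---------------------------------------------------------------

def _toy_set(n_per_class=25, k=4):
    n = n_per_class * k
    rng = np.random.default_rng(0)
    return LabeledImageSet(rng.random((n, 4, 4, 3), dtype=np.float32),
                           np.repeat(np.arange(k), n_per_class),
                           [f"c{i}" for i in range(k)])


def test_split_partition_and_stratified_counts():
    ds = _toy_set(25)
    tr, va, te = split_dataset(ds, SplitSpec(seed=3))
    assert len(tr) + len(va) + len(te) == 100
    assert (len(tr), len(va), len(te)) == (68, 12, 20)  # floor-based per class
    for part in (tr, va, te):
        counts = part.class_counts()
        assert counts.max() - counts.min() <= 1
    # per-class: 17/{2 or 3}/5 within one image of the exact fractions
    assert list(tr.class_counts()) == [17, 17, 17, 17]
    assert list(te.class_counts()) == [5, 5, 5, 5]


def test_split_is_deterministic_and_disjoint():
    ds = _toy_set(10)
    ds.images[:, 0, 0, 0] = np.arange(len(ds))  # tag every image uniquely
    a = split_dataset(ds, SplitSpec(seed=9))
    b = split_dataset(ds, SplitSpec(seed=9))
    for pa, pb in zip(a, b):
        np.testing.assert_array_equal(pa.images, pb.images)
    tags = np.concatenate([p.images[:, 0, 0, 0] for p in a])
    assert len(np.unique(tags)) == len(ds)      # partition: no repeats, full cover


def test_split_fraction_validation():
    with pytest.raises(DatasetError):
        SplitSpec(train=0.5, val=0.5, test=0.1)
    with pytest.raises(DatasetError):
        SplitSpec(train=1.0, val=0.0, test=0.0)


def test_split_tiny_class_is_error():
    ds = _toy_set(2)
    with pytest.raises(DatasetError, match="c0"):
        split_dataset(ds, SplitSpec(seed=0))


# -- folder round trip -------------------------------------------------------

def test_folder_round_trip(tmp_path):
    ds = generate_phantoms(PhantomSpec(n_per_class=3, image_size=(48, 48),
                                       noise_sd=0.0, seed=4))
    save_image_folder(ds, tmp_path)
    loaded = load_image_folder(tmp_path, target_size=(48, 48))
    assert loaded.class_names == PHANTOM_CLASS_NAMES
    assert len(loaded) == 12
    assert loaded.images.shape == (12, 48, 48, 3)
    # 8-bit quantization is the only loss
    orig = np.sort(ds.images.mean(axis=(1, 2, 3)))
    back = np.sort(loaded.images.mean(axis=(1, 2, 3)))
    np.testing.assert_allclose(orig, back, atol=1 / 255)


def test_folder_grayscale_replicated_and_resized(tmp_path):
    d = tmp_path / "only"
    d.mkdir()
    Image.fromarray((np.arange(100, dtype=np.uint8).reshape(10, 10)), "L").save(
        d / "g.png")
    loaded = load_image_folder(tmp_path, target_size=(224, 224))
    assert loaded.images.shape == (1, 224, 224, 3)
    np.testing.assert_array_equal(loaded.images[0, :, :, 0],
                                  loaded.images[0, :, :, 1])


def test_folder_empty_class_is_error(tmp_path):
    (tmp_path / "a").mkdir()
    (tmp_path / "b").mkdir()
    Image.new("RGB", (8, 8)).save(tmp_path / "a" / "x.png")
    with pytest.raises(DatasetError, match="b"):
        load_image_folder(tmp_path)


def test_folder_undecodable_skipped(tmp_path, caplog):
    d = tmp_path / "a"
    d.mkdir()
    Image.new("RGB", (8, 8)).save(d / "ok.png")
    (d / "junk.jpg").write_bytes(b"not an image")
    loaded = load_image_folder(tmp_path, target_size=(16, 16))
    assert len(loaded) == 1


def test_preprocessing_idempotent(tmp_path):
    """Saving and reloading an already-sized [0,1] image changes nothing
    beyond 8-bit quantization."""
    ds = generate_phantoms(PhantomSpec(n_per_class=1, image_size=(32, 32),
                                       noise_sd=0.0, seed=6))
    save_image_folder(ds, tmp_path)
    once = load_image_folder(tmp_path, target_size=(32, 32))
    save_image_folder(once, tmp_path / "again")
    twice = load_image_folder(tmp_path / "again", target_size=(32, 32))
    np.testing.assert_array_equal(once.images, twice.images)


# -- reference dataset arithmetic -------------------------------------------

def test_dataset_table_sums():
    assert dataset_class_totals() == DATASET_PRINTED_CLASS_TOTALS
    assert dataset_total() == DATASET_PRINTED_TOTAL == 7023
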