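"""Dataset I/O round-trips, label parsing, and the feature map."""

import numpy as np
import pytest
from PIL import Image

from domainmatch import (Annotation, DomainDataset, FeatureConfig,
                         ImageRecord, extract_features, joint_scale,
                         joint_standardize, load_domain,
                         load_domains_from_manifest, record_pixels,
                         save_domain)
from domainmatch.imageio_features import register_feature_hook

from conftest import feature_matrix


def _write_dataset(root, images, labels):
    (root / "images").mkdir(parents=True)
    (root / "labels").mkdir()
    for name, arr in images.items():
        Image.fromarray(arr).save(root / "images" / f"{name}.png")
    for name, text in labels.items():
        (root / "labels" / f"{name}.txt").write_text(text)


class TestYoloIO:
    def test_load_counts_and_order(self, tmp_path):
        img = np.full((16, 16), 128, dtype=np.uint8)
        _write_dataset(tmp_path,
                       {"b": img, "a": img, "c": img},
                       {"a": "0 0.5 0.5 0.25 0.25\n",
                        "b": "1 0.5 0.5 0.2 0.2\n",
                        "c": "0 0.3 0.3 0.1 0.1\n"})
        ds = load_domain(tmp_path, "dom")
        assert [r.image_id for r in ds.records] == ["a", "b", "c"]
        assert ds.n_annotations == 3

    def test_missing_label_file_gives_empty_annotations(self, tmp_path):
        img = np.full((16, 16), 128, dtype=np.uint8)
        _write_dataset(tmp_path, {"only": img}, {})
        ds = load_domain(tmp_path, "dom")
        assert ds.n_images == 1
        assert ds.records[0].annotations == []

    @pytest.mark.parametrize("bad_line", [
        "1 0.5 0.5 1.5 0.2",      # w > 1
        "0 0.5 0.5 0.2",          # wrong field count
        "0 x 0.5 0.2 0.2",        # non-numeric
        "7 0.5 0.5 0.2 0.2",      # class outside label space
        "0 1.2 0.5 0.2 0.2",      # center out of range
    ])
    def test_malformed_label_line_rejected_record_kept(self, tmp_path, bad_line):
        img = np.full((16, 16), 128, dtype=np.uint8)
        _write_dataset(tmp_path, {"a": img},
                       {"a": bad_line + "\n0 0.5 0.5 0.2 0.2\n"})
        ds = load_domain(tmp_path, "dom")
        assert ds.n_images == 1
        assert ds.n_annotations == 1  # only the valid line survives

    def test_missing_images_dir_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_domain(tmp_path / "nope", "dom")

    def test_round_trip_bit_identical(self, tmp_path, tiny_domain):
        out = tmp_path / "saved"
        save_domain(tiny_domain, out)
        back = load_domain(out, tiny_domain.domain_id, tiny_domain.label_space)
        assert back.n_images == tiny_domain.n_images
        for orig, rec in zip(tiny_domain.records, back.records):
            assert rec.image_id == orig.image_id
            assert rec.annotations == orig.annotations  # bit-for-bit
            np.testing.assert_array_equal(record_pixels(rec), record_pixels(orig))

    def test_manifest_loading(self, tmp_path, tiny_domain):
        save_domain(tiny_domain, tmp_path / "dom1")
        (tmp_path / "study.yaml").write_text(
            "label_space: [intact, cracked]\n"
            "domains:\n"
            "  - {domain_id: dom1, path: dom1, origin: test,"
            " washed: washed, acquisition: static}\n"
        )
        domains = load_domains_from_manifest(tmp_path / "study.yaml")
        assert len(domains) == 1
        assert domains[0].domain_id == "dom1"
        assert domains[0].metadata.origin == "test"
        assert domains[0].n_annotations == tiny_domain.n_annotations


class TestAnnotationInvariants:
    def test_rejects_out_of_range_boxes(self):
        with pytest.raises(ValueError):
            Annotation(class_id=0, bbox=(0.5, 0.5, 1.5, 0.2))
        with pytest.raises(ValueError):
            Annotation(class_id=0, bbox=(-0.1, 0.5, 0.2, 0.2))

    def test_dataset_rejects_class_outside_label_space(self):
        rec = ImageRecord("i", np.zeros((8, 8), dtype=np.uint8),
                          [Annotation(5, (0.5, 0.5, 0.2, 0.2))])
        with pytest.raises(ValueError, match="label space"):
            DomainDataset("d", [rec], label_space=("intact", "cracked"))


class TestExtractFeatures:
    def _dataset(self, arrays):
        recs = [ImageRecord(f"i{k}", a, []) for k, a in enumerate(arrays)]
        return DomainDataset("d", recs)

    def test_identity_resize_flattens_row_major(self):
        # 4x4 grayscale: top half 0, bottom half 255; identity resize
        img = np.zeros((4, 4), dtype=np.uint8)
        img[2:] = 255
        ds = self._dataset([img])
        cfg = FeatureConfig(resize=(4, 4), standardize="none")
        fm = extract_features(ds, cfg)
        np.testing.assert_array_equal(fm.values[0], [0] * 8 + [255] * 8)

    def test_gray_conversion_uses_luma_weights(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[..., 0] = 100  # pure red
        ds = self._dataset([img])
        fm = extract_features(ds, FeatureConfig(resize=(4, 4), standardize="none"))
        assert fm.values[0] == pytest.approx(np.full(16, 29.9))

    def test_uniform_image_histogram_degenerate(self):
        img = np.full((8, 8, 3), 128, dtype=np.uint8)
        ds = self._dataset([img])
        fm = extract_features(ds, FeatureConfig(mode="color_histogram",
                                                standardize="none"))
        assert fm.d == 96
        row = fm.values[0].reshape(3, 32)
        for channel in row:
            assert channel.sum() == pytest.approx(1.0)
            assert np.count_nonzero(channel) == 1

    def test_subsampling_deterministic(self, tiny_preset):
        from domainmatch import generate_domain
        ds = generate_domain(tiny_preset, n_images=30, seed=4)
        cfg = FeatureConfig(max_samples_per_domain=10, standardize="none")
        a = extract_features(ds, cfg, rng_seed=11)
        b = extract_features(ds, cfg, rng_seed=11)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.n == 10

    def test_empty_dataset_fatal(self):
        ds = DomainDataset("d", [])
        with pytest.raises(ValueError, match="empty"):
            extract_features(ds, FeatureConfig())

    def test_custom_hook(self):
        register_feature_hook("mean_px", lambda img: np.array([img.mean()]))
        img = np.full((8, 8), 42, dtype=np.uint8)
        ds = self._dataset([img])
        cfg = FeatureConfig(mode="custom_hook", hook_name="mean_px",
                            standardize="none")
        assert extract_features(ds, cfg).values[0][0] == 42.0

    def test_unregistered_hook_fatal(self):
        ds = self._dataset([np.zeros((8, 8), dtype=np.uint8)])
        cfg = FeatureConfig(mode="custom_hook", hook_name="missing",
                            standardize="none")
        with pytest.raises(ValueError, match="hook"):
            extract_features(ds, cfg)


class TestStandardization:
    def test_hand_zscore_population_std(self):
        m = feature_matrix([[0.0], [2.0]])
        (out,) = joint_standardize([m])
        np.testing.assert_array_equal(out.values, [[-1.0], [1.0]])

    def test_fixed_point(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(50, 3))
        vals -= vals.mean(axis=0)
        vals /= vals.std(axis=0, ddof=0)
        a = feature_matrix(vals[:25])
        b = feature_matrix(vals[25:], domain_id="y")
        out = joint_standardize([a, b])
        np.testing.assert_allclose(out[0].values, a.values, atol=1e-12)
        np.testing.assert_allclose(out[1].values, b.values, atol=1e-12)

    def test_constant_feature_zeroed(self):
        a = feature_matrix([[1.0, 5.0], [2.0, 5.0]])
        b = feature_matrix([[3.0, 5.0]], domain_id="y")
        out = joint_standardize([a, b])
        assert np.all(out[0].values[:, 1] == 0.0)
        assert np.all(out[1].values[:, 1] == 0.0)

    def test_pooled_moments_after_zscore(self):
        rng = np.random.default_rng(8)
        mats = [feature_matrix(rng.normal(loc=i, size=(20, 4)), domain_id=str(i))
                for i in range(3)]
        out = joint_standardize(mats)
        pooled = np.concatenate([m.values for m in out])
        assert np.all(np.abs(pooled.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(pooled.std(axis=0, ddof=0) - 1) < 1e-9)

    def test_mixed_hashes_fatal(self):
        a = feature_matrix([[1.0]], config_hash="a")
        b = feature_matrix([[1.0]], config_hash="b")
        with pytest.raises(ValueError, match="hash"):
            joint_standardize([a, b])
        with pytest.raises(ValueError, match="hash"):
            joint_scale([a, b])

    def test_joint_scale_preserves_mean_structure(self):
        # scaling must not center: same-sign shifted copies stay ordered
        a = feature_matrix([[10.0], [12.0]])
        b = feature_matrix([[20.0], [22.0]], domain_id="y")
        out = joint_scale([a, b])
        assert np.all(out[1].values > out[0].values.max() - 1e-12)
        pooled = np.concatenate([m.values for m in out])
        assert pooled.std(ddof=0) == pytest.approx(1.0)
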