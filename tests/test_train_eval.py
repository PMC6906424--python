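import numpy as np
import pytest

from proj2proj import (
    ConeBeamGeometry,
    ProjectionImage,
    TrainingConfig,
    angle_report,
    edge_pixel_fraction,
    make_dataset,
    normalize_subject,
    prepare_records,
    train,
)
from proj2proj.train import PairedDataset

FAST = dict(generator_budget=20_000, disc_channels=8, learning_rate=2e-3)


class TestNormalizeSubject:
    def test_pooled_mean_zero_std_one(self):
        rng = np.random.default_rng(0)
        projections = [rng.random((16, 16)) * 7 + 3 for _ in range(4)]
        normed, stats = normalize_subject(projections)
        pool = np.concatenate([a.ravel() for a in normed])
        assert pool.mean() == pytest.approx(0.0, abs=1e-6)
        assert pool.std() == pytest.approx(1.0, abs=1e-6)
        assert stats[1] > 0

    def test_constant_projections_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            normalize_subject([np.full((8, 8), 2.0)])

    def test_subjects_normalize_independently(self):
        """Two subjects with different intensity scales each map to mean 0 /
        std 1 with their own statistics."""
        rng = np.random.default_rng(1)
        base = [rng.random((8, 8)) for _ in range(3)]
        scaled = [100.0 * a + 55.0 for a in base]
        n1, s1 = normalize_subject(base)
        n2, s2 = normalize_subject(scaled)
        for a, b in zip(n1, n2):
            np.testing.assert_allclose(a, b, atol=1e-9)
        assert s2[0] != s1[0] and s2[1] != s1[1]

    def test_precomputed_stats_reused_for_heldout(self):
        rng = np.random.default_rng(2)
        train_projs = [rng.random((8, 8)) for _ in range(3)]
        _, stats = normalize_subject(train_projs)
        held = [rng.random((8, 8))]
        normed, stats2 = normalize_subject(held, stats=stats)
        assert stats2 == stats
        np.testing.assert_allclose(normed[0], (held[0] - stats[0]) / stats[1])


class TestPrepareRecords:
    def test_counts_and_mask_sources(self, tiny_dataset):
        train_recs, test_recs, stats = prepare_records(tiny_dataset)
        assert len(train_recs) == 2 * 6 and len(test_recs) == 2 * 4
        for rec in test_recs:
            assert rec.mr.shape == rec.label.shape == rec.raw_label.shape
            assert np.any(rec.raw_label == 0)  # air stays exactly zero pre-normalization
        assert stats["label_std"] > 0


class TestTraining:
    def test_zero_epochs_leaves_generator_at_init(self, tiny_dataset):
        cfg = TrainingConfig(epochs=0, seed=3, **FAST)
        r1 = train(tiny_dataset, cfg)
        r2 = train(tiny_dataset, cfg)
        assert r1.history == []
        for p1, p2 in zip(r1.generator.parameters(), r2.generator.parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_same_seed_reproduces_loss_history_bitwise(self, tiny_dataset):
        cfg = TrainingConfig(epochs=1, max_iterations=6, seed=5, **FAST)
        h1 = train(tiny_dataset, cfg).history
        h2 = train(tiny_dataset, cfg).history
        assert h1 == h2
        cfg_other = TrainingConfig(epochs=1, max_iterations=6, seed=6, **FAST)
        h3 = train(tiny_dataset, cfg_other).history
        assert h1 != h3

    def test_max_iterations_caps_history(self, tiny_dataset):
        cfg = TrainingConfig(epochs=10, max_iterations=4, seed=1, **FAST)
        result = train(tiny_dataset, cfg)
        assert len(result.history) == 4

    def test_training_moves_parameters_and_logs_finite_losses(self, tiny_dataset):
        cfg = TrainingConfig(epochs=1, max_iterations=6, seed=7, **FAST)
        init = train(tiny_dataset, TrainingConfig(epochs=0, seed=7, **FAST))
        result = train(tiny_dataset, cfg)
        assert any(
            not np.array_equal(a.data, b.data)
            for a, b in zip(init.generator.parameters(), result.generator.parameters())
        )
        for row in result.history:
            assert np.isfinite(row["weighted_total"])
            assert np.isfinite(row["discriminator_loss"])
            assert row["fm_term"] >= 0

    def test_config_rejects_bad_values(self):
        with pytest.raises(ValueError):
            TrainingConfig(batch_size=2)
        with pytest.raises(ValueError):
            TrainingConfig(architecture="unet")


class TestDatasetRoundTrip:
    def test_directory_dataset_loads_and_prepares(self, tmp_path):
        geo = ConeBeamGeometry(detector_shape=(32, 32), detector_spacing_mm=(8.0, 8.0))
        make_dataset(tmp_path, n_subjects=1, n_train_views=3, n_test_views=2,
                     geometry=geo, seed=9, phantom_shape=(32, 32, 32),
                     phantom_spacing=(2.0, 2.0, 2.0), step_mm=1.0)
        ds = PairedDataset.from_directory(tmp_path)
        train_recs, test_recs, _ = prepare_records(ds)
        assert len(train_recs) == 3 and len(test_recs) == 2
        assert train_recs[0].mr.shape == (32, 32)

    def test_missing_directory_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            PairedDataset.from_directory(tmp_path)


class TestAngleReport:
    def test_identity_oracle_reaches_perfect_scores(self, tiny_dataset):
        """Feeding the label itself as the generated image gives MAE 0,
        SSIM 1, PSNR inf per view."""
        _, test_recs, _ = prepare_records(tiny_dataset)
        by_label = {id(r): r.label for r in test_recs}
        report = angle_report(test_recs, lambda mr: _lookup(test_recs, mr))
        assert len(report.per_view) == 8
        assert np.allclose(report.per_view["mae_percent"], 0.0)
        assert np.allclose(report.per_view["ssim"], 1.0)
        assert np.all(np.isinf(report.per_view["psnr"]))

    def test_records_ordered_by_azimuth_with_aggregates(self, tiny_dataset):
        _, test_recs, _ = prepare_records(tiny_dataset)
        report = angle_report(test_recs, lambda mr: mr)
        azs = report.per_view["azimuth_deg"].to_numpy()
        assert np.all(np.diff(azs) >= 0)
        agg = report.aggregates()
        assert set(agg) == {"mae_percent", "ssim", "psnr"}
        finite = report.per_view["mae_percent"].to_numpy()
        assert agg["mae_percent"][0] == pytest.approx(finite.mean())

    def test_opposing_views_score_differently_on_asymmetric_phantom(self, tiny_dataset):
        """Perspective distortion makes a view and its opposite inequivalent,
        so per-view metrics differ."""
        _, test_recs, _ = prepare_records(tiny_dataset)
        report = angle_report(test_recs, lambda mr: mr)
        df = report.per_view
        front = df[df["azimuth_deg"] == 0.0]["mae_percent"].iloc[0]
        back = df[df["azimuth_deg"] == 180.0]["mae_percent"].iloc[0]
        assert front != pytest.approx(back, rel=1e-6)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            angle_report([], lambda mr: mr)

    def test_report_serializes_csv_and_plot(self, tiny_dataset, tmp_path):
        _, test_recs, _ = prepare_records(tiny_dataset)
        report = angle_report(test_recs, lambda mr: mr)
        report.to_csv(tmp_path / "report.csv")
        report.plot(tmp_path / "angles.png")
        assert (tmp_path / "report.csv").stat().st_size > 0
        assert (tmp_path / "angles.png").stat().st_size > 0


def _lookup(records, mr):
    for r in records:
        if r.mr is mr:
            return r.label
    raise AssertionError("unknown input image")


class TestEdgePixelFraction:
    def test_constant_images_have_no_edges(self):
        assert edge_pixel_fraction([np.full((16, 16), 2.0)]) == 0.0

    def test_zero_threshold_counts_nonzero_gradient_pixels(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 1.0
        from proj2proj import sobel_gradient

        frac = edge_pixel_fraction([img], threshold=0.0, floor=0.0)
        assert frac == pytest.approx(np.mean(sobel_gradient(img) > 0))

    def test_phantom_labels_have_sparse_edges(self, tiny_dataset):
        """On the seeded phantom test views the edge set is sparse but
        nonempty under the default 0.4 threshold."""
        _, test_recs, _ = prepare_records(tiny_dataset)
        frac = edge_pixel_fraction([r.label for r in test_recs])
        assert 0.0 < frac < 0.5
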