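"""Channel scaling, PCA, LISI closed forms, correction, and the decision rule."""

import numpy as np
import pytest

from cytospec import (
    Embedding,
    EventMatrix,
    IntegrationConfig,
    batch_correct,
    compute_lisi,
    embed_umap,
    pca_embed,
    recommend_correction,
    scale_channels,
)


def _events(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"c{i}" for i in range(values.shape[1])]
    return EventMatrix(values, names, ["marker"] * values.shape[1])


class TestScaleChannels:
    def test_two_point_channel_maps_to_unit_interval(self):
        out = scale_channels(_events([[0.0], [10.0]]))
        np.testing.assert_allclose(sorted(out.values[:, 0]), [-1.0, 1.0])

    def test_output_extremes_are_plus_minus_one(self, rng):
        out = scale_channels(_events(rng.lognormal(5, 1, (500, 4))))
        np.testing.assert_allclose(out.values.max(axis=0), 1.0)
        np.testing.assert_allclose(out.values.min(axis=0), -1.0)

    def test_idempotent_on_symmetric_scaled_data(self, rng):
        sym = np.linspace(-1, 1, 101)[:, None]
        out = scale_channels(_events(sym))
        np.testing.assert_allclose(out.values, sym, atol=1e-12)

    def test_constant_channel_zeroed_with_warning(self):
        vals = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        with pytest.warns(UserWarning, match="constant"):
            out = scale_channels(_events(vals, ["a", "flat"]))
        assert (out.channel("flat") == 0).all()

    def test_needs_two_events(self):
        with pytest.raises(ValueError, match=">= 2"):
            scale_channels(_events([[1.0, 2.0]]))


class TestPcaEmbed:
    def test_planar_data_reconstructs_exactly(self, rng):
        basis = rng.normal(size=(2, 6))
        coords = rng.normal(size=(200, 2))
        X = coords @ basis
        emb = pca_embed(_events(X), IntegrationConfig(n_components=2))
        # rank-2 data: 2 components explain everything
        from sklearn.linear_model import LinearRegression

        recon = LinearRegression().fit(emb.coordinates, X).predict(emb.coordinates)
        assert np.abs(recon - X).max() < 1e-8

    def test_duplicated_events_get_identical_rows(self, rng):
        X = rng.normal(size=(50, 5))
        X = np.vstack([X, X[:3]])
        emb = pca_embed(_events(X), IntegrationConfig(n_components=3))
        np.testing.assert_allclose(emb.coordinates[-3:], emb.coordinates[:3], atol=1e-10)

    def test_isotropic_noise_spreads_variance_evenly(self, rng):
        X = rng.normal(size=(5000, 6))
        emb = pca_embed(_events(X), IntegrationConfig(n_components=6))
        var = emb.coordinates.var(axis=0)
        # eigenvalues of an isotropic sample covariance are all ~1
        assert var.max() / var.min() < 1.3

    def test_deterministic_sign_convention(self, rng):
        X = rng.normal(size=(100, 4))
        a = pca_embed(_events(X), IntegrationConfig(n_components=3))
        b = pca_embed(_events(X.copy()), IntegrationConfig(n_components=3))
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            pca_embed(_events(rng.normal(size=(10, 3))), IntegrationConfig(n_components=5))


class TestComputeLisi:
    def test_single_batch_scores_one_everywhere(self, rng):
        emb = Embedding(rng.normal(size=(200, 2)), "umap")
        out = compute_lisi(emb, ["only"] * 200)
        assert (out.lisi == 1.0).all()

    def test_colocated_uniform_three_batches_scores_three(self):
        # all cells at one point: the tuned kernel is uniform over the k
        # neighbors, so LISI approaches B as n grows
        n = 900
        emb = Embedding(np.zeros((n, 2)), "umap")
        batches = np.tile(["A", "B", "C"], n // 3)
        out = compute_lisi(emb, batches, IntegrationConfig(neighbors_k=n - 1))
        np.testing.assert_allclose(out.lisi, 3.0, atol=1e-3)

    def test_half_half_neighborhood_scores_two(self):
        n = 600
        emb = Embedding(np.zeros((n, 2)), "umap")
        batches = np.tile(["A", "B"], n // 2)
        out = compute_lisi(emb, batches, IntegrationConfig(neighbors_k=n - 1))
        np.testing.assert_allclose(out.lisi, 2.0, atol=1e-3)  # 1/(0.25+0.25)

    def test_segregated_batches_score_near_one(self, rng):
        a = rng.normal(0, 1, size=(300, 2))
        b = rng.normal(100, 1, size=(300, 2))
        out = compute_lisi(Embedding(np.vstack([a, b]), "umap"), ["A"] * 300 + ["B"] * 300)
        assert out.lisi.mean() < 1.05

    def test_range_and_permutation_invariance(self, rng):
        coords = rng.normal(size=(400, 2))
        batches = rng.choice(["A", "B", "C"], 400)
        out = compute_lisi(Embedding(coords, "umap"), batches)
        assert ((out.lisi >= 1.0) & (out.lisi <= 3.0)).all()
        perm = rng.permutation(400)
        out2 = compute_lisi(Embedding(coords[perm], "umap"), batches[perm])
        np.testing.assert_allclose(out2.lisi, out.lisi[perm], atol=1e-9)

    def test_oversized_k_reduced_with_warning(self, rng):
        emb = Embedding(rng.normal(size=(20, 2)), "umap")
        with pytest.warns(UserWarning, match="reducing"):
            out = compute_lisi(emb, ["A", "B"] * 10, IntegrationConfig(neighbors_k=50))
        assert out.lisi.shape == (20,)


class TestRecommendation:
    def test_thresholds_for_two_and_three_batches(self):
        cfg = IntegrationConfig()
        assert cfg.threshold_for(2) == pytest.approx(1.667)
        assert cfg.threshold_for(3) == pytest.approx(2.0)
        with pytest.raises(ValueError, match="explicit"):
            cfg.threshold_for(4)
        assert IntegrationConfig(high_lisi_threshold=2.5).threshold_for(4) == 2.5

    def test_segregated_batches_recommend_correction(self, rng):
        blobs = [rng.normal(100 * i, 1, size=(200, 2)) for i in range(3)]
        batches = np.repeat(["A", "B", "C"], 200)
        lisi = compute_lisi(Embedding(np.vstack(blobs), "umap"), batches)
        out = recommend_correction(lisi, batches)
        assert out.high_fraction < 0.01
        assert out.recommendation == "correct"

    def test_fully_mixed_batches_recommend_nothing(self):
        n = 900
        emb = Embedding(np.zeros((n, 2)), "umap")
        batches = np.tile(["A", "B", "C"], n // 3)
        lisi = compute_lisi(emb, batches, IntegrationConfig(neighbors_k=n - 1))
        out = recommend_correction(lisi, batches)
        assert out.high_fraction > 0.95
        assert out.recommendation == "no-correction"


class TestBatchCorrect:
    def test_single_batch_is_identity(self, rng):
        pcs = Embedding(rng.normal(size=(100, 5)), "pca")
        out = batch_correct(pcs, ["A"] * 100)
        np.testing.assert_array_equal(out.coordinates, pcs.coordinates)
        assert out.space == "corrected"

    def test_constant_offset_between_batches_removed(self, rng):
        base = rng.normal(size=(400, 5))
        shift = np.array([8.0, -5.0, 3.0, 0.0, 1.0])
        coords = np.vstack([base, base + shift])
        batches = np.array(["A"] * 400 + ["B"] * 400)
        out = batch_correct(Embedding(coords, "pca"), batches, IntegrationConfig(seed=0))
        cents = [out.coordinates[batches == b].mean(axis=0) for b in ("A", "B")]
        pre_dist = np.linalg.norm(shift)
        post_dist = np.linalg.norm(cents[0] - cents[1])
        assert post_dist < 0.10 * pre_dist
        # contract: mixing does not regress
        pre_lisi = compute_lisi(Embedding(coords, "pca"), batches).lisi.mean()
        post_lisi = compute_lisi(out, batches).lisi.mean()
        assert post_lisi >= pre_lisi - 1e-9

    def test_event_count_preserved(self, rng):
        coords = rng.normal(size=(300, 4))
        batches = np.repeat(["A", "B", "C"], 100)
        out = batch_correct(Embedding(coords, "pca"), batches)
        assert out.n_events == 300

    def test_batch_smaller_than_dimension_rejected(self, rng):
        coords = rng.normal(size=(24, 20))
        batches = ["A"] * 20 + ["B"] * 4
        with pytest.raises(ValueError, match="smaller"):
            batch_correct(Embedding(coords, "pca"), batches)

    def test_external_backend_requires_harmonypy(self, rng):
        try:
            import harmonypy  # noqa: F401

            pytest.skip("harmonypy installed; external backend available")
        except ImportError:
            pass
        coords = rng.normal(size=(100, 5))
        batches = ["A"] * 50 + ["B"] * 50
        with pytest.raises(RuntimeError, match="harmonypy"):
            batch_correct(
                Embedding(coords, "pca"), batches, IntegrationConfig(backend="external")
            )


class TestUmap:
    def test_deterministic_and_shape(self, rng):
        pcs = Embedding(rng.normal(size=(150, 5)), "pca")
        cfg = IntegrationConfig(seed=11)
        a = embed_umap(pcs, cfg)
        b = embed_umap(pcs, cfg)
        assert a.coordinates.shape == (150, 2)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_separated_populations_stay_separated(self, rng):
        from sklearn.metrics import silhouette_score

        x = np.vstack([rng.normal(0, 1, (150, 6)), rng.normal(12, 1, (150, 6))])
        labels = [0] * 150 + [1] * 150
        emb = embed_umap(Embedding(x, "pca"), IntegrationConfig(seed=2))
        assert silhouette_score(emb.coordinates, labels) > 0.5

    def test_appends_coordinates_to_events(self, rng):
        ev = _events(rng.normal(size=(60, 4)))
        emb, widened = embed_umap(
            Embedding(rng.normal(size=(60, 3)), "pca"), IntegrationConfig(seed=1), events=ev
        )
        assert widened.channel_names[-2:] == ["UMAP_1", "UMAP_2"]
        np.testing.assert_array_equal(widened.values[:, -2:], emb.coordinates)

    def test_too_few_events_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 10"):
            embed_umap(Embedding(rng.normal(size=(5, 3)), "pca"))
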