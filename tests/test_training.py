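"""Chunk-to-model training: augmentation, bootstrap, SFS, composition."""

import numpy as np
import pytest

from harlearn import FeatureSet, TrainConfig, bootstrap_sample, noise_inject, sfs_select, train_base_model
from harlearn.errors import ConfigError, DataError, TrainingError
from harlearn.training import _sfs_generic, _stratified_folds


def feature_set(X, y, names=None):
    X = np.asarray(X, dtype=float)
    return FeatureSet(
        subject_ids=np.repeat("S", len(X)), w=np.arange(len(X)),
        X=X, labels=np.asarray(y, dtype=object),
        feature_names=names or [f"f{i}" for i in range(X.shape[1])],
    )


class TestNoiseInject:
    def test_r_zero_is_identity(self, rng):
        fs = feature_set(rng.normal(size=(10, 4)), ["a"] * 5 + ["b"] * 5)
        assert noise_inject(fs, 0, 0.1, rng) is fs

    def test_alpha_zero_copies_identical(self, rng):
        fs = feature_set(rng.normal(size=(6, 3)), ["a", "b"] * 3)
        out = noise_inject(fs, 2, 0.0, rng)
        assert len(out) == 18
        np.testing.assert_array_equal(out.X[6:12], fs.X)
        np.testing.assert_array_equal(out.X[12:18], fs.X)
        np.testing.assert_array_equal(out.labels[6:12], fs.labels)

    def test_noise_sd_tracks_feature_sd(self, rng):
        """With R=50, α=0.1 the per-feature SD of (copy − original) is within
        10% of 0.1·sd_f."""
        X = rng.normal(0, [1.0, 5.0, 0.2], size=(40, 3))
        fs = feature_set(X, ["a", "b"] * 20)
        out = noise_inject(fs, 50, 0.1, rng)
        sd_f = X.std(axis=0)
        diffs = out.X[40:] - np.tile(X, (50, 1))
        got = diffs.std(axis=0)
        np.testing.assert_allclose(got, 0.1 * sd_f, rtol=0.10)

    def test_negative_alpha_rejected(self, rng):
        fs = feature_set(rng.normal(size=(4, 2)), ["a", "b", "a", "b"])
        with pytest.raises(ConfigError):
            noise_inject(fs, 1, -0.1, rng)


class TestBootstrap:
    def test_single_row_pool(self, rng):
        fs = feature_set([[1.0, 2.0]], ["a"])
        out = bootstrap_sample(fs, 1, rng)
        np.testing.assert_array_equal(out.X, fs.X)

    def test_seeded_reproducibility(self):
        fs = feature_set(np.arange(20).reshape(10, 2), ["a", "b"] * 5)
        a = bootstrap_sample(fs, 10, np.random.default_rng(5))
        b = bootstrap_sample(fs, 10, np.random.default_rng(5))
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.w, b.w)  # draws keep their w indices

    def test_draw_frequencies_multinomial(self, rng):
        fs = feature_set(np.arange(8).reshape(4, 2), list("abcd"))
        out = bootstrap_sample(fs, 10_000, rng)
        _, counts = np.unique(out.w, return_counts=True)
        p, n = 0.25, 10_000
        sd = np.sqrt(p * (1 - p) / n)
        np.testing.assert_allclose(counts / n, p, atol=3 * sd)

    def test_empty_pool_rejected(self, rng):
        fs = feature_set(np.empty((0, 2)), [])
        with pytest.raises(DataError):
            bootstrap_sample(fs, 3, rng)


def _informative_problem(rng, n=60, p=12):
    """Feature 0 separates two classes perfectly; the rest are pure noise."""
    y = np.repeat(["a", "b"], n // 2).astype(object)
    X = rng.normal(size=(n, p))
    X[:, 0] = np.where(y == "a", -5.0, 5.0) + rng.normal(0, 0.1, n)
    return X, y


class TestSFS:
    def test_perfect_feature_selected_first(self, rng):
        X, y = _informative_problem(rng)
        cfg = TrainConfig(sfs_max_features=3)
        for kind in ("lda", "qda", "cart"):
            selected = sfs_select(X, y, kind, cfg, np.random.default_rng(0))
            assert selected[0] == 0

    def test_exhaustive_single_feature_confirms_maximizer(self, rng):
        """The first SFS pick equals the argmax of per-feature CV scores
        computed by an exhaustive loop over single-feature classifiers."""
        X, y = _informative_problem(rng, p=8)
        cfg = TrainConfig(sfs_max_features=1)
        picked = sfs_select(X, y, "lda", cfg, np.random.default_rng(3))
        # exhaustive evaluation, reusing the generic (loop) scorer path
        classes = np.unique(y)
        y_idx = np.searchsorted(classes, y)
        folds = _stratified_folds(
            y_idx, cfg.sfs_folds,
            int(np.random.default_rng(3).integers(2 ** 31 - 1)))
        best = _sfs_generic(X, y, "lda", folds, 1, 0.0, None, 0)
        assert picked == best

    def test_max_features_cap(self, rng):
        X, y = _informative_problem(rng)
        out = sfs_select(X, y, "lda", TrainConfig(sfs_max_features=1),
                         np.random.default_rng(1))
        assert len(out) == 1

    def test_duplicate_feature_tie_break(self, rng):
        X, y = _informative_problem(rng, p=10)
        X[:, 3] = X[:, 0]
        X[:, 7] = X[:, 0]
        X[:, 0] = rng.normal(size=len(X))  # duplicates now live at 3 and 7
        out = sfs_select(X, y, "lda", TrainConfig(sfs_max_features=4),
                         np.random.default_rng(2))
        assert 3 in out
        assert 7 not in out  # zero marginal gain + smallest-index tie-break

    def test_fast_lda_path_matches_generic_loop(self, rng):
        """The batched closed-form LDA scorer selects the same features as a
        per-candidate fit loop over the same folds."""
        X = rng.normal(size=(45, 6))
        y = np.repeat(["a", "b", "c"], 15).astype(object)
        X[:, 2] += np.where(y == "a", 2.0, 0.0)
        X[:, 4] += np.where(y == "c", -2.0, 0.0)
        cfg = TrainConfig(sfs_max_features=3)
        fast = sfs_select(X, y, "lda", cfg, np.random.default_rng(9))
        classes = np.unique(y)
        folds = _stratified_folds(
            np.searchsorted(classes, y), cfg.sfs_folds,
            int(np.random.default_rng(9).integers(2 ** 31 - 1)))
        slow = _sfs_generic(X, y, "lda", folds, 3, 0.0, None, 0)
        assert fast == slow

    def test_degenerate_labels_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(TrainingError):
            sfs_select(X, np.repeat("a", 20), "lda", TrainConfig(),
                       np.random.default_rng(0))


class TestTrainBaseModel:
    def _chunk(self, rng, n=60, p=15):
        X, y = _informative_problem(rng, n=n, p=p)
        return feature_set(X, y)

    def test_same_seed_same_model(self, rng):
        chunk = self._chunk(rng)
        cfg = TrainConfig(sfs_max_features=3)
        a = train_base_model(chunk, "lda", "personal", cfg,
                             np.random.default_rng(4))
        b = train_base_model(chunk, "lda", "personal", cfg,
                             np.random.default_rng(4))
        np.testing.assert_array_equal(a.selected_features, b.selected_features)
        np.testing.assert_array_equal(a.clf.coef_, b.clf.coef_)

    def test_separable_chunk_trains_perfectly(self, rng):
        chunk = self._chunk(rng)
        model = train_base_model(chunk, "lda", "personal",
                                 TrainConfig(sfs_max_features=3),
                                 np.random.default_rng(0))
        assert model.origin == "personal"
        assert np.mean(model.predict(chunk.X) == chunk.labels) == 1.0

    def test_seed_diversity_in_selected_features(self, rng):
        """On a noisy wide chunk, different seeds generally select different
        feature subsets (ensemble diversity)."""
        X = rng.normal(size=(80, 50))
        y = np.repeat(["a", "b"], 40).astype(object)
        X[:, :10] += np.where(y == "a", 0.8, 0.0)[:, None]
        chunk = feature_set(X, y)
        cfg = TrainConfig(sfs_max_features=3)
        selections = {
            tuple(train_base_model(chunk, "lda", "personal", cfg,
                                   np.random.default_rng(s)).selected_features)
            for s in range(10)
        }
        assert len(selections) > 1

    def test_pipeline_stage_order(self, rng):
        """Personal models: inject → sample → select → fit; UI models skip
        injection."""
        chunk = self._chunk(rng)
        stages = []
        hook = [lambda stage, payload: stages.append(stage)]
        train_base_model(chunk, "lda", "personal", TrainConfig(sfs_max_features=2),
                         np.random.default_rng(0), hooks=hook)
        assert stages == ["noise_inject", "bootstrap", "sfs", "fit"]
        stages.clear()
        train_base_model(chunk, "lda", "user_independent",
                         TrainConfig(sfs_max_features=2),
                         np.random.default_rng(0), hooks=hook)
        assert stages == ["bootstrap", "sfs", "fit"]

    def test_bootstrap_size_rules(self, rng):
        chunk = self._chunk(rng, n=30)
        sizes = {}
        hook = [lambda stage, payload: sizes.update(payload)
                if stage == "bootstrap" else None]
        cfg = TrainConfig(sfs_max_features=2, noise_copies=2)
        train_base_model(chunk, "lda", "personal", cfg,
                         np.random.default_rng(0), hooks=hook)
        assert sizes["n"] == 30  # original chunk size, not the augmented 90
        cfg2 = TrainConfig(sfs_max_features=2, noise_copies=2,
                           bootstrap_size_rule="pool_size")
        train_base_model(chunk, "lda", "personal", cfg2,
                         np.random.default_rng(0), hooks=hook)
        assert sizes["n"] == 90

    def test_degenerate_chunk_rejected(self, rng):
        chunk = feature_set(rng.normal(size=(10, 3)), ["a"] * 10)
        with pytest.raises(TrainingError, match="degenerate"):
            train_base_model(chunk, "lda", "personal", TrainConfig(),
                             np.random.default_rng(0))
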