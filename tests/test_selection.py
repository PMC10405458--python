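"""Hybrid selection: Pearson screen, embedded importances, f-score, autoencoder."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxygait.core import ConfigurationError, InputError
from oxygait.nn import Autoencoder
from oxygait.selection import (
    FeatureSelector,
    SelectionConfig,
    embedded_coefficients,
    f_score,
    fit_autoencoder,
    pearson_screen,
    select_top,
)


def _frame(arr):
    return pd.DataFrame(np.asarray(arr, dtype=float))


class TestPearsonScreen:
    def test_feature_equal_to_target_retained_with_p_one(self):
        y = np.arange(20.0)
        p = pearson_screen(_frame(y[:, None]), y)
        assert list(p.index) == [0]
        assert p.iloc[0] == pytest.approx(1.0)

    def test_pure_noise_dropped(self):
        rng = np.random.default_rng(0)
        y = np.arange(500.0)
        p = pearson_screen(_frame(rng.normal(size=(500, 3))), y)
        assert len(p) == 0

    def test_negative_correlation_counts_by_magnitude(self):
        y = np.arange(20.0)
        p = pearson_screen(_frame(-y[:, None]), y)
        assert p.iloc[0] == pytest.approx(1.0)

    def test_threshold_is_strict(self):
        """A feature built to have |r| = 0.3 exactly is dropped at threshold 0.3."""
        u = np.array([1.0, -1.0, -1.0, 1.0]) / 2.0  # centered, unit norm
        z = np.array([1.0, 1.0, -1.0, -1.0]) / 2.0  # orthogonal, centered, unit
        y = u
        x = 0.3 * u + np.sqrt(1 - 0.09) * z
        all_p = pearson_screen(_frame(x[:, None]), y, threshold=0.0)
        p_val = float(all_p.iloc[0])
        assert p_val == pytest.approx(0.3, abs=1e-12)
        assert len(pearson_screen(_frame(x[:, None]), y, threshold=p_val)) == 0

    def test_zero_variance_feature_dropped(self, caplog):
        y = np.arange(10.0)
        X = _frame(np.column_stack([np.ones(10), y]))
        with caplog.at_level("WARNING", logger="oxygait.selection"):
            p = pearson_screen(X, y)
        assert list(p.index) == [1]
        assert "zero-variance" in caplog.text

    def test_misaligned_rows_rejected(self):
        with pytest.raises(InputError):
            pearson_screen(_frame(np.zeros((5, 2))), np.zeros(4))


class TestEmbedded:
    def test_single_informative_feature_dominates(self):
        rng = np.random.default_rng(1)
        X = _frame(rng.normal(size=(200, 6)))
        y = 3.0 * X[2].to_numpy()
        c = embedded_coefficients(X, y, seed=0)
        assert c.idxmax() == 2
        assert c.loc[2] > 0.9

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        X = _frame(rng.normal(size=(50, 4)))
        y = rng.normal(size=50)
        np.testing.assert_array_equal(
            embedded_coefficients(X, y, seed=5).to_numpy(),
            embedded_coefficients(X, y, seed=5).to_numpy(),
        )

    def test_too_few_rows_rejected(self):
        with pytest.raises(InputError):
            embedded_coefficients(_frame(np.zeros((5, 2))), np.zeros(5))


class TestFScore:
    @pytest.mark.parametrize(
        "p,c,expected",
        [(0.5, 0.5, 0.5), (0.3, 0.0, 0.0), (0.4, -0.6, 0.48), (0.0, 0.0, 0.0)],
    )
    def test_examples(self, p, c, expected):
        assert f_score(p, c) == pytest.approx(expected, abs=1e-15)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(1e-6, 1.0), st.floats(-1.0, 1.0).filter(lambda c: abs(c) > 1e-6))
    def test_harmonic_mean_bounds_and_symmetry(self, p, c):
        s = f_score(p, c)
        lo, hi = sorted([p, abs(c)])
        assert lo - 1e-12 <= s <= hi + 1e-12
        assert s == pytest.approx(f_score(abs(c), p), rel=1e-12)


class TestSelectTop:
    def test_identity_when_k_covers_all(self):
        scores = pd.Series([0.4, 0.2, 0.9], index=list("abc"))
        assert select_top(scores, 3).equals(scores)

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.random(50))
        top = select_top(scores, 10)
        expected = set(scores.sort_values(ascending=False).index[:10])
        assert set(top.index) == expected

    def test_ties_broken_by_position(self):
        scores = pd.Series([0.5, 0.5, 0.5, 0.1], index=[10, 11, 12, 13])
        assert list(select_top(scores, 2).index) == [10, 11]

    def test_invalid_k_rejected(self):
        with pytest.raises(ConfigurationError):
            select_top(pd.Series([1.0]), 0)


class TestAutoencoder:
    def test_linear_subspace_reconstructed_near_exactly(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(200, 3))
        A = rng.normal(size=(3, 10))
        X = Z @ A
        model = Autoencoder(input_dim=10, latent_dim=3, seed=0)
        model.fit(X, max_epochs=3000, patience=200, learning_rate=3e-2)
        assert model.reconstruction_error(X) < 1e-3

    def test_full_rank_noise_cannot_be_compressed_losslessly(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 8))
        model = fit_autoencoder(X, latent_dim=7, seed=0)
        assert model.reconstruction_error(X) > 1e-4

    def test_seeded_determinism_of_encodings(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 6))
        a = fit_autoencoder(X, latent_dim=2, seed=3).encode(X)
        b = fit_autoencoder(X, latent_dim=2, seed=3).encode(X)
        np.testing.assert_array_equal(a, b)

    def test_latent_dim_must_shrink(self):
        with pytest.raises(ConfigurationError):
            Autoencoder(input_dim=4, latent_dim=4)

    def test_loss_curve_best_checkpoint_is_minimum(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 6))
        model = fit_autoencoder(X, latent_dim=2, seed=1)
        assert model.best_iteration == int(np.argmin(model.loss_curve))


class TestFeatureSelector:
    def _fixture(self, n=120, seed=8):
        rng = np.random.default_rng(seed)
        y = np.linspace(1.0, 3.0, n) + rng.normal(0, 0.05, n)
        informative = np.column_stack([y * g + rng.normal(0, 0.1, n) for g in (1.0, -0.5, 2.0)])
        noise = rng.normal(size=(n, 12))
        X = pd.DataFrame(np.column_stack([informative, noise]))
        return X, y

    def test_screen_then_score_never_retains_weak_features(self):
        X, y = self._fixture()
        sel = FeatureSelector(SelectionConfig(top_k=5, latent_dim=2)).fit(X, y)
        assert (sel.score_table.loc[sel.score_table["retained"], "p"] > 0.3).all()

    def test_transform_maps_to_latent_dim(self):
        X, y = self._fixture()
        sel = FeatureSelector(SelectionConfig(top_k=3, latent_dim=2)).fit(X, y)
        assert sel.transform(X).shape == (len(X), 2)

    def test_informative_features_outrank_noise(self):
        X, y = self._fixture()
        sel = FeatureSelector(SelectionConfig(top_k=5, latent_dim=2)).fit(X, y)
        assert set(sel.selected) <= {0, 1, 2}

    def test_score_table_export(self, tmp_path):
        X, y = self._fixture()
        X.columns = pd.MultiIndex.from_tuples(
            [("b", "s", f"ch{i}", "mean") for i in range(X.shape[1])],
            names=("band", "species", "channel", "feature"),
        )
        sel = FeatureSelector(SelectionConfig(top_k=3, latent_dim=2)).fit(X, y)
        path = tmp_path / "scores.csv"
        sel.export_scores(path)
        table = pd.read_csv(path)
        assert {"feature_id", "p", "c", "f_score", "retained"} <= set(table.columns)
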