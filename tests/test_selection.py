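"""PCA selection: 95%-variance retention, loadings, projection."""
import numpy as np
import pandas as pd
import pytest

import emogait as eg
from emogait.errors import DegeneracyError, SchemaError
from emogait import selection as sel

from .oracles import naive_projection


def _df(X, prefix="f"):
    return pd.DataFrame(X, columns=[f"{prefix}{j}" for j in range(X.shape[1])])


@pytest.fixture
def random_features(rng):
    # anisotropic: a few dominant directions plus noise
    n, d = 120, 20
    basis = rng.normal(size=(d, d))
    scales = np.linspace(3.0, 0.1, d)
    return _df(rng.normal(size=(n, d)) * scales @ basis)


class TestFitSelect:
    def test_rank_one_data_needs_one_component(self, rng):
        direction = rng.normal(size=10)
        X = np.outer(rng.normal(size=50), direction)
        model = eg.fit_select(_df(X))
        assert model.n_retained == 1
        assert model.cumulative_share >= 0.95

    def test_threshold_one_keeps_full_rank(self, rng):
        X = rng.normal(size=(60, 8))
        model = eg.fit_select(_df(X), threshold=1.0)
        assert model.n_retained == np.linalg.matrix_rank(X - X.mean(0))

    def test_isotropic_data_keeps_about_95_percent_of_dimensions(self, rng):
        d = 40
        model = eg.fit_select(_df(rng.normal(size=(4000, d))))
        assert abs(model.n_retained - int(np.ceil(0.95 * d))) <= 2

    def test_minimality_of_n_retained(self, random_features):
        model = eg.fit_select(random_features)
        shares = model.explained_variance_shares
        assert shares[: model.n_retained].sum() >= 0.95
        assert shares[: model.n_retained - 1].sum() < 0.95

    def test_variance_shares_non_increasing_and_directions_orthogonal(self, random_features):
        model = eg.fit_select(random_features)
        assert np.all(np.diff(model.explained_variance_shares) <= 1e-12)
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(model.n_retained), atol=1e-8)

    def test_loadings_bounded_by_one(self, random_features):
        model = eg.fit_select(random_features)
        assert np.all(np.abs(model.load_matrix) <= 1.0)

    def test_sign_convention_largest_loading_positive(self, random_features):
        model = eg.fit_select(random_features)
        for k in range(model.n_retained):
            j = np.argmax(np.abs(model.load_matrix[:, k]))
            assert model.load_matrix[j, k] >= 0

    def test_all_constant_matrix_is_degenerate(self):
        with pytest.raises(DegeneracyError):
            eg.fit_select(_df(np.full((10, 4), 7.0)))

    def test_reconstruction_of_standardized_training_data(self, rng):
        X = rng.normal(size=(80, 12))
        df = _df(X)
        model = eg.fit_select(df, threshold=1.0)
        Z = (X - model.means) / model.sigmas
        scores = eg.transform(model, df)
        assert np.allclose(scores @ model.components, Z, atol=1e-6)


class TestTransform:
    def test_training_scores_are_centered(self, random_features):
        model = eg.fit_select(random_features)
        scores = eg.transform(model, random_features)
        assert scores.shape == (len(random_features), model.n_retained)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-8)

    def test_row_of_column_means_maps_to_zero(self, random_features):
        model = eg.fit_select(random_features)
        mean_row = pd.DataFrame([model.means], columns=random_features.columns)
        assert np.allclose(eg.transform(model, mean_row), 0.0, atol=1e-9)

    def test_matches_explicit_projection_oracle(self, rng, random_features):
        """Held-out rows: equals brute-force center-scale-project."""
        model = eg.fit_select(random_features)
        held_out = _df(rng.normal(size=(100, random_features.shape[1])))
        want = naive_projection(
            held_out.to_numpy(), model.means, model.sigmas, model.components
        )
        assert np.allclose(eg.transform(model, held_out), want, atol=1e-9)

    def test_column_order_is_immaterial_but_names_must_match(self, random_features):
        model = eg.fit_select(random_features)
        reordered = random_features[list(reversed(random_features.columns))]
        assert np.allclose(
            eg.transform(model, reordered), eg.transform(model, random_features), atol=1e-12
        )
        renamed = random_features.rename(columns={"f0": "other"})
        with pytest.raises(SchemaError, match="f0"):
            eg.transform(model, renamed)


class TestLoadingReport:
    def test_cutoff_above_one_empties_every_list(self, random_features):
        model = eg.fit_select(random_features)
        report = eg.loading_report(model, cutoff=1.01)
        assert all(entries == [] for entries in report.values())

    def test_cutoff_zero_lists_every_feature(self, random_features):
        model = eg.fit_select(random_features)
        report = eg.loading_report(model, cutoff=0.0)
        d = random_features.shape[1]
        assert all(len(entries) == d for entries in report.values())
        for entries in report.values():
            mags = [abs(e["loading"]) for e in entries]
            assert mags == sorted(mags, reverse=True)

    def test_constructed_rank_one_structure_passes_cutoff(self, rng):
        """One strong latent factor: its carrier features load >= 0.71."""
        n = 400
        factor = rng.normal(size=n)
        X = np.column_stack(
            [factor + 0.1 * rng.normal(size=n) for _ in range(4)]
            + [rng.normal(size=n) for _ in range(4)]
        )
        model = eg.fit_select(_df(X))
        report = eg.loading_report(model, cutoff=0.71)
        top = {e["feature"] for e in report[0]}
        assert {"f0", "f1", "f2", "f3"} <= top

    def test_report_tags_feature_families(self, feature_table):
        model = eg.fit_select(feature_table[list(eg.FEATURE_NAMES)])
        report = eg.loading_report(model, cutoff=0.71)
        families = {e["family"] for entries in report.values() for e in entries}
        assert families <= {"temporal", "frequency", "temporal-frequency"}
        assert sel.feature_family("x_std") == "temporal"
        assert sel.feature_family("y_psd_mean") == "frequency"
        assert sel.feature_family("z_fft_07") == "temporal-frequency"
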