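"""Acoustic space PCA, mixed-model LRTs and allometric line comparison."""

import numpy as np
import pandas as pd
import pytest

from crocvoice import (
    FEATURE_COLUMNS,
    analytic_features,
    assemble_feature_matrix,
    fit_acoustic_space,
    regress_and_compare_lines,
)
from crocvoice import test_size_effect as size_effect_lrt

from conftest import make_tone


def random_features(n, seed=0, latent=False):
    """Feature frame with either i.i.d. columns or one shared latent factor."""
    rng = np.random.default_rng(seed)
    if latent:
        z = rng.standard_normal((n, 1))
        x = z @ np.ones((1, 13)) + 0.01 * rng.standard_normal((n, 13))
    else:
        x = rng.standard_normal((n, 13))
    df = pd.DataFrame(x, columns=FEATURE_COLUMNS)
    df["call_id"] = [f"c{i}" for i in range(n)]
    df["individual_id"] = [f"i{i // 3}" for i in range(n)]
    return df


class TestAssemble:
    def test_three_calls_three_rows(self):
        meta = pd.DataFrame(
            {"individual_id": ["a", "b"], "species": ["nile_crocodile"] * 2,
             "body_length_cm": [40.0, 60.0]})
        calls = [("c1", "a", make_tone(400)), ("c2", "a", make_tone(500)),
                 ("c3", "b", make_tone(300))]
        table = assemble_feature_matrix(calls, meta)
        assert len(table) == 3
        assert not table[FEATURE_COLUMNS].isna().any().any()

    def test_unvoiced_call_dropped_and_logged(self, caplog):
        import logging

        from crocvoice import Waveform

        meta = pd.DataFrame(
            {"individual_id": ["a"], "species": ["nile_crocodile"],
             "body_length_cm": [40.0]})
        calls = [("good", "a", make_tone(400)),
                 ("silent", "a", Waveform(np.zeros(44100), 44100))]
        with caplog.at_level(logging.WARNING, "crocvoice.size_coding"):
            table = assemble_feature_matrix(calls, meta)
        assert len(table) == 1
        assert any("silent" in r.message for r in caplog.records)

    def test_orphan_call_raises_with_id(self):
        meta = pd.DataFrame(
            {"individual_id": ["a"], "species": ["nile_crocodile"],
             "body_length_cm": [40.0]})
        with pytest.raises(ValueError, match="ghost"):
            assemble_feature_matrix([("c", "ghost", make_tone(400))], meta)

    def test_duplicate_metadata_raises(self):
        meta = pd.DataFrame(
            {"individual_id": ["a", "a"], "species": ["nile_crocodile"] * 2,
             "body_length_cm": [40.0, 41.0]})
        with pytest.raises(ValueError, match="duplicate"):
            assemble_feature_matrix([("c", "a", make_tone(400))], meta)


class TestAcousticSpacePCA:
    def test_single_latent_factor_dominates(self):
        space = fit_acoustic_space(random_features(60, latent=True))
        assert space.explained_variance[0] > 0.95

    def test_eigendecomposition_oracle(self):
        """Explained variance and loadings match an independent closed-form
        eigendecomposition of the sample correlation matrix (two informative
        correlated columns embedded among weak filler columns)."""
        rng = np.random.default_rng(8)
        n = 300
        a = rng.standard_normal(n)
        b = 0.6 * a + 0.8 * rng.standard_normal(n)
        filler = 1e-6 * rng.standard_normal((n, 11))
        x = np.column_stack([a, b, filler])
        df = pd.DataFrame(x, columns=FEATURE_COLUMNS)
        df["call_id"] = np.arange(n).astype(str)
        df["individual_id"] = df["call_id"]
        space = fit_acoustic_space(df)
        corr = np.corrcoef(x, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(corr)
        top2 = eigvals[::-1][:2]
        assert space.explained_variance[0] == pytest.approx(top2[0] / 13.0, rel=1e-9)
        assert space.explained_variance[1] == pytest.approx(top2[1] / 13.0, rel=1e-9)
        # the correlated pair loads the leading component; |r| sets its size
        r = abs(np.corrcoef(a, b)[0, 1])
        assert top2[0] == pytest.approx(1 + r, rel=0.1)
        lead = np.abs(eigvecs[:, -1])
        assert np.allclose(np.abs(space.loadings.to_numpy()[:, 0]), lead, atol=1e-6)

    def test_row_duplication_invariance(self):
        df = random_features(40, seed=2)
        doubled = pd.concat([df, df.assign(call_id=df["call_id"] + "x")],
                            ignore_index=True)
        a, b = fit_acoustic_space(df), fit_acoustic_space(doubled)
        assert np.allclose(a.loadings.to_numpy(), b.loadings.to_numpy(), atol=1e-9)
        assert a.explained_variance == pytest.approx(b.explained_variance)

    def test_loadings_orthonormal_and_scores_uncorrelated(self):
        space = fit_acoustic_space(random_features(80, seed=5))
        load = space.loadings.to_numpy()
        assert np.allclose(load.T @ load, np.eye(2), atol=1e-9)
        scores = space.call_scores[["AD1", "AD2"]].to_numpy()
        assert abs(np.corrcoef(scores.T)[0, 1]) < 1e-9

    def test_sign_convention(self, feature_population):
        _, ds = feature_population
        feats = analytic_features(ds.ground_truth)
        space = fit_acoustic_space(feats)
        assert space.loadings.at["centroid", "AD1"] > 0
        assert space.loadings.at["mean_pitch", "AD2"] > 0

    def test_loading_structure_on_study_like_data(self, feature_population):
        """Spectral-energy descriptors dominate the first dimension, mean
        pitch the second."""
        _, ds = feature_population
        space = fit_acoustic_space(analytic_features(ds.ground_truth))
        load = space.loadings
        assert abs(load.at["centroid", "AD1"]) > abs(load.at["centroid", "AD2"])
        assert abs(load.at["mean_pitch", "AD2"]) > abs(load.at["mean_pitch", "AD1"])

    def test_constant_column_raises_with_name(self):
        df = random_features(30)
        df["sfm"] = 0.5
        with pytest.raises(ValueError, match="sfm"):
            fit_acoustic_space(df)

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError, match="more calls"):
            fit_acoustic_space(random_features(12))


class TestSizeEffectLRT:
    @pytest.fixture(scope="class")
    def study_scores(self, request):
        feature_population = request.getfixturevalue("feature_population")
        _, ds = feature_population
        feats = analytic_features(ds.ground_truth)
        space = fit_acoustic_space(feats)
        return space.call_scores.merge(ds.metadata, on="individual_id")

    def test_detects_size_and_species_not_interaction(self, study_scores):
        res = size_effect_lrt(study_scores)
        t = res.tests.set_index(["dimension", "term"])
        assert t.loc[("AD2", "size"), "p_value"] < 1e-3
        assert t.loc[("AD1", "species"), "p_value"] < 1e-3
        # shared-slope generator: interaction stays non-significant
        assert t.loc[("AD1", "size_x_species"), "p_value"] > 0.01
        assert (t["chi_square"] >= 0).all()
        assert t.loc[("AD1", "species"), "df"] == 4

    def test_lrt_invariant_to_size_units(self, study_scores):
        res_cm = size_effect_lrt(study_scores, terms=("size",),
                                  dimensions=("AD2",))
        meters = study_scores.assign(body_length_cm=study_scores.body_length_cm / 100)
        res_m = size_effect_lrt(meters, terms=("size",), dimensions=("AD2",))
        chi_cm = res_cm.tests.chi_square.iloc[0]
        chi_m = res_m.tests.chi_square.iloc[0]
        assert chi_m == pytest.approx(chi_cm, rel=0.01)

    def test_single_species_rejected(self, study_scores):
        sub = study_scores[study_scores.species == "nile_crocodile"]
        with pytest.raises(ValueError, match="species"):
            size_effect_lrt(sub)


class TestLineComparison:
    @staticmethod
    def individual_means(ds):
        feats = analytic_features(ds.ground_truth)
        merged = feats.merge(ds.metadata, on="individual_id")
        return merged.groupby(
            ["individual_id", "species", "body_length_cm"], as_index=False
        )[["mean_pitch", "centroid"]].mean()

    def test_identical_groups_zero_slope_difference(self):
        rng = np.random.default_rng(0)
        half = pd.DataFrame(
            {
                "species": ["american_alligator"] * 8,
                "body_length_cm": np.linspace(30, 100, 8),
                "mean_pitch": 600 - 2.0 * np.linspace(30, 100, 8)
                + rng.standard_normal(8),
            }
        )
        other = half.assign(species="nile_crocodile")
        both = pd.concat([half, other], ignore_index=True)
        res = regress_and_compare_lines(
            both, "mean_pitch", ("american_alligator", "nile_crocodile"))
        comp = res.line_comparison.set_index("quantity")
        assert comp.at["slope_difference", "t"] == pytest.approx(0.0, abs=1e-9)
        assert comp.at["intercept_difference", "t"] == pytest.approx(0.0, abs=1e-9)

    def test_four_point_ols_closed_form(self):
        """Slopes and intercepts match the normal-equations solution."""
        x = np.array([30.0, 50.0, 70.0, 90.0])
        ya = np.array([600.0, 561.0, 518.0, 481.0])
        yb = np.array([500.0, 459.0, 422.0, 378.0])
        df = pd.DataFrame(
            {
                "species": ["american_alligator"] * 4 + ["nile_crocodile"] * 4,
                "body_length_cm": np.tile(x, 2),
                "mean_pitch": np.concatenate([ya, yb]),
            }
        )
        res = regress_and_compare_lines(
            df, "mean_pitch", ("american_alligator", "nile_crocodile"))
        for y, row in zip((ya, yb), res.regressions.itertuples()):
            slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
            intercept = y.mean() - slope * x.mean()
            assert row.slope == pytest.approx(slope, rel=1e-9)
            assert row.intercept == pytest.approx(intercept, rel=1e-9)

    def test_equal_slopes_different_intercepts_pattern(self, feature_population):
        """The generator shares one slope across species with distinct
        intercepts: the pooled comparison rejects the intercept difference
        but not the slope difference."""
        _, ds = feature_population
        res = regress_and_compare_lines(
            self.individual_means(ds), "mean_pitch",
            ("american_alligator", "nile_crocodile"))
        comp = res.line_comparison.set_index("quantity")
        assert comp.at["intercept_difference", "p_value"] < 0.01
        assert comp.at["slope_difference", "p_value"] > 0.05

    def test_too_few_individuals_raises(self):
        df = pd.DataFrame(
            {
                "species": ["american_alligator"] * 2 + ["nile_crocodile"] * 4,
                "body_length_cm": [30, 40, 30, 40, 50, 60],
                "mean_pitch": [600, 580, 500, 480, 460, 440.0],
            }
        )
        with pytest.raises(ValueError, match=">= 3"):
            regress_and_compare_lines(
                df, "mean_pitch", ("american_alligator", "nile_crocodile"))
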