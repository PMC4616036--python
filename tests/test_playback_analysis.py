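"""Response scoring, composite PC1, stimulus LRT and pairwise comparisons."""

import numpy as np
import pandas as pd
import pytest

from crocvoice import (
    composite_response_score,
    posthoc_pairwise,
    score_field_response,
    simulate_captive_experiment,
)
from crocvoice import test_stimulus_effect as stimulus_lrt


class TestFieldScale:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(approach_fraction=0.9), 2),
            (dict(approach_fraction=0.51), 2),
            (dict(approach_fraction=0.5), 1),  # boundary: not "more than half"
            (dict(approach_fraction=0.1), 1),
            (dict(approach_fraction=0.0), 0),
            (dict(), 0),
            (dict(retreat_m=3.0), -1),
            (dict(retreat_m=5.0), -1),  # boundary: not "more than 5 m"
            (dict(retreat_m=7.0), -2),
            (dict(retreat_m=0.0), 0),
        ],
    )
    def test_scale_mapping(self, kwargs, expected):
        assert score_field_response(**kwargs) == expected

    def test_both_directions_rejected(self):
        with pytest.raises(ValueError, match="not both"):
            score_field_response(approach_fraction=0.3, retreat_m=2.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_field_response(approach_fraction=1.5)
        with pytest.raises(ValueError):
            score_field_response(retreat_m=-1.0)


def make_trials(orientation, n_approaching, max_approach):
    return pd.DataFrame(
        {
            "orientation": orientation,
            "n_approaching": n_approaching,
            "max_approach": max_approach,
        }
    )


class TestCompositeScore:
    def test_stronger_trial_gets_maximal_score(self):
        trials = make_trials([1, 1, 1, 2], [2, 2, 2, 8], [1, 1, 1, 2])
        scores = composite_response_score(trials)
        assert scores.idxmax() == 3

    def test_rank_one_criteria_explain_everything(self):
        base = np.array([0.0, 1.0, 2.0, 3.0, 1.5])
        trials = make_trials(base, 2 * base, 3 * base)
        scores = composite_response_score(trials)
        z = (base - base.mean()) / base.std()
        # perfectly correlated criteria: PC1 carries all the variance
        assert np.allclose(scores, z * np.sqrt(3.0), atol=1e-9)

    def test_four_trial_eigen_oracle(self):
        """Scores match a direct eigendecomposition of the 3x3 correlation
        matrix."""
        trials = make_trials([0, 1, 2, 2], [0, 1, 5, 9], [0, 2, 1, 2])
        scores = composite_response_score(trials)
        x = trials.to_numpy(float)
        z = (x - x.mean(0)) / x.std(0)
        corr = np.corrcoef(z, rowvar=False)
        vals, vecs = np.linalg.eigh(corr)
        pc1 = vecs[:, np.argmax(vals)]
        if pc1[1] < 0:
            pc1 = -pc1
        assert np.allclose(scores.to_numpy(), z @ pc1, atol=1e-9)

    def test_affine_rescaling_invariance(self):
        trials = make_trials([0, 1, 2, 2, 1], [0, 1, 5, 9, 3], [0, 2, 1, 2, 1])
        rescaled = trials.copy()
        rescaled["n_approaching"] = 10.0 + 4.0 * rescaled["n_approaching"]
        a = composite_response_score(trials)
        b = composite_response_score(rescaled)
        assert np.allclose(a, b, atol=1e-9)

    def test_constant_criterion_dropped_with_warning(self):
        trials = make_trials([1, 1, 1, 1], [0, 1, 5, 9], [0, 2, 1, 2])
        with pytest.warns(UserWarning, match="orientation"):
            scores = composite_response_score(trials)
        assert scores.size == 4

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            composite_response_score(make_trials([1] * 4, [2] * 4, [1] * 4))


class TestStimulusEffect:
    def test_strong_effect_detected(self):
        trials = simulate_captive_experiment(
            {"SYNTsmall": 2.0, "SYNTlarge": 0.0, "NOFM": 0.0}, seed=5)
        scores = composite_response_score(trials)
        res = stimulus_lrt(scores, trials.stimulus, trials.unit_id,
                           trials.order_index)
        assert res["df"] == 2
        assert res["p_value"] < 0.01

    def test_single_category_rejected(self):
        trials = simulate_captive_experiment({"NOFM": 0.0}, seed=0)
        scores = pd.Series(np.arange(len(trials), dtype=float))
        with pytest.raises(ValueError, match="categories"):
            stimulus_lrt(scores, trials.stimulus, trials.unit_id,
                         trials.order_index)

    def test_too_few_units_rejected(self):
        trials = simulate_captive_experiment({"A": 0.0, "B": 0.0}, n_units=3, seed=0)
        scores = pd.Series(np.arange(len(trials), dtype=float))
        with pytest.raises(ValueError, match="units"):
            stimulus_lrt(scores, trials.stimulus, trials.unit_id,
                         trials.order_index)

    def test_order_fixed_effect_fallback(self):
        trials = simulate_captive_experiment(
            {"SYNTsmall": 2.0, "SYNTlarge": 0.0, "NOFM": 0.0}, seed=5)
        scores = composite_response_score(trials)
        res = stimulus_lrt(scores, trials.stimulus, trials.unit_id,
                           trials.order_index, order_as_fixed=True)
        assert res["p_value"] < 0.05


class TestPosthoc:
    @staticmethod
    def run(means, seed):
        trials = simulate_captive_experiment(means, seed=seed)
        scores = composite_response_score(trials)
        return posthoc_pairwise(scores, trials.stimulus, trials.unit_id,
                                trials.order_index, n_mc=50_000)

    def test_elevated_category_pattern(self):
        """One far-shifted category is significant against both others while
        the remaining pair is not."""
        table = self.run({"SYNTsmall": 2.0, "SYNTlarge": 0.0, "NOFM": 0.0},
                         seed=5).set_index("contrast")
        assert table.at["NOFM - SYNTsmall", "p_adjusted"] < 0.05
        assert table.at["SYNTlarge - SYNTsmall", "p_adjusted"] < 0.05
        assert table.at["NOFM - SYNTlarge", "p_adjusted"] > 0.05

    def test_adjusted_never_below_raw(self):
        for seed in (0, 1, 2):
            table = self.run({"A": 0.5, "B": 0.0, "C": 0.0}, seed)
            assert (table.p_adjusted >= table.p_raw - 1e-12).all()
            assert table.p_adjusted.between(0, 1).all()

    def test_deterministic(self):
        a = self.run({"A": 1.0, "B": 0.0, "C": 0.0}, seed=3)
        b = self.run({"A": 1.0, "B": 0.0, "C": 0.0}, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_two_categories_rejected(self):
        trials = simulate_captive_experiment({"A": 0.0, "B": 0.0}, seed=0)
        scores = pd.Series(np.arange(len(trials), dtype=float))
        with pytest.raises(ValueError, match=">= 3"):
            posthoc_pairwise(scores, trials.stimulus, trials.unit_id,
                             trials.order_index)


class TestSimulatedExperiment:
    def test_reproducible(self):
        a = simulate_captive_experiment({"A": 1.0, "B": 0.0}, seed=7)
        b = simulate_captive_experiment({"A": 1.0, "B": 0.0}, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_balanced_design(self):
        trials = simulate_captive_experiment({"A": 0.0, "B": 0.0, "C": 0.0},
                                             n_units=8, seed=0)
        assert len(trials) == 24
        counts = trials.groupby(["unit_id", "stimulus"]).size()
        assert (counts == 1).all()

    def test_criteria_within_coding_ranges(self):
        trials = simulate_captive_experiment({"A": 3.0, "B": -3.0}, seed=1)
        assert trials.orientation.between(0, 2).all()
        assert trials.max_approach.between(0, 2).all()
        assert (trials.n_approaching >= 0).all()
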