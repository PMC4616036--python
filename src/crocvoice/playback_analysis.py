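"""Scoring and testing of playback responses.

Two observation formats are supported.  Field trials on free-ranging females
are coded on an ordinal intensity scale from -2 (strong retreat, more than
5 m) to +2 (approach beyond half the distance to the loudspeaker).  Captive
trials on clusters of females record three correlated criteria (orientation
0-2, number of females approaching, maximal approach 0-2) that are collapsed
into a single composite score: the first principal component of the
standardized criteria, signed so that more approaching females means a
higher score.

Stimulus effects are tested with a Gaussian mixed model (maximum
likelihood): composite score ~ stimulus, with crossed random intercepts for
the experimental unit (cluster or female) and the playback order, compared
against the no-stimulus model by likelihood ratio.  Pairwise stimulus
contrasts use Tukey-style single-step multiplicity adjustment based on the
joint normal distribution of the contrast estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STIMULI",
    "score_field_response",
    "composite_response_score",
    "test_stimulus_effect",
    "posthoc_pairwise",
    "simulate_captive_experiment",
]

STIMULI = ("small_calls", "large_calls", "SYNTsmall", "SYNTlarge", "NOFM")

CRITERIA = ("orientation", "n_approaching", "max_approach")


def score_field_response(
    approach_fraction: float | None = None,
    retreat_m: float | None = None,
) -> int:
    """Ordinal intensity of a field response.

    Exactly one of ``approach_fraction`` (fraction of the initial
    female-loudspeaker distance covered) or ``retreat_m`` (meters retreated)
    may be given; neither means no movement.  The stronger codes require
    strictly more than half the distance / more than 5 m, so the boundary
    cases land on +1 and -1.
    """
    if approach_fraction is not None and retreat_m is not None:
        raise ValueError("give either an approach or a retreat, not both")
    if approach_fraction is not None:
        if not 0.0 <= approach_fraction <= 1.0:
            raise ValueError("approach_fraction must lie in [0, 1]")
        if approach_fraction == 0.0:
            return 0
        return 2 if approach_fraction > 0.5 else 1
    if retreat_m is not None:
        if retreat_m < 0:
            raise ValueError("retreat_m must be >= 0")
        if retreat_m == 0.0:
            return 0
        return -2 if retreat_m > 5.0 else -1
    return 0


def composite_response_score(trials: pd.DataFrame) -> pd.Series:
    """PC1 of the standardized captive response criteria.

    ``trials`` needs the three criterion columns.  A constant criterion is
    dropped with a warning (it carries no response information); if all three
    are constant there is nothing to score.  The sign is fixed so that
    ``n_approaching`` loads positively: higher scores mean more females
    reacting.
    """
    x = trials.loc[:, list(CRITERIA)].to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 trials to build a composite score")
    sds = x.std(axis=0, ddof=0)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all response criteria are constant; nothing to score")
    if not keep.all():
        dropped = [c for c, k in zip(CRITERIA, keep) if not k]
        warnings.warn(f"constant criterion column(s) dropped: {dropped}", stacklevel=2)
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sds[keep]
    # PC1 of the correlation matrix
    _, vecs = np.linalg.eigh(np.corrcoef(z, rowvar=False).reshape(keep.sum(), -1))
    pc1 = vecs[:, -1]
    kept = [c for c, k in zip(CRITERIA, keep) if k]
    if "n_approaching" in kept and pc1[kept.index("n_approaching")] < 0:
        pc1 = -pc1
    elif "n_approaching" not in kept and pc1.sum() < 0:
        pc1 = -pc1
    return pd.Series(z @ pc1, index=trials.index, name="composite_pc1")


def _fit_crossed_ml(data: pd.DataFrame, with_stimulus: bool,
                    order_as_fixed: bool = False) -> float:
    """ML log-likelihood of score ~ [stimulus] + (1|unit) + (1|order)."""
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    fixed = "score ~ C(stimulus)" if with_stimulus else "score ~ 1"
    if order_as_fixed:
        fixed += " + C(order_index)"
        vc = {"unit": "0 + C(unit_id)"}
    else:
        vc = {"unit": "0 + C(unit_id)", "order": "0 + C(order_index)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = smf.mixedlm(fixed, data, groups=np.ones(len(data)), vc_formula=vc)
        fit = model.fit(reml=False, method="lbfgs")
    return float(fit.llf)


def test_stimulus_effect(
    scores: pd.Series | np.ndarray,
    stimulus: pd.Series | np.ndarray,
    unit_id: pd.Series | np.ndarray,
    order_index: pd.Series | np.ndarray,
    order_as_fixed: bool = False,
) -> dict:
    """Likelihood-ratio test of the stimulus term in the crossed mixed model.

    Returns {chi_square, df, p_value}; df = number of stimulus categories - 1.
    ``order_as_fixed`` switches playback order from a random intercept (the
    default, despite its few levels) to a fixed effect.
    """
    data = pd.DataFrame(
        {
            "score": np.asarray(scores, dtype=float),
            "stimulus": np.asarray(stimulus),
            "unit_id": np.asarray(unit_id),
            "order_index": np.asarray(order_index),
        }
    )
    categories = sorted(data["stimulus"].unique())
    if len(categories) < 2:
        raise ValueError("need at least 2 stimulus categories")
    if data["unit_id"].nunique() < 4:
        raise ValueError("need at least 4 experimental units")
    counts = data.groupby("stimulus").size()
    if (counts < 2).any():
        warnings.warn(
            f"stimulus categories with a single trial: {list(counts[counts < 2].index)}",
            stacklevel=2,
        )
    ll1 = _fit_crossed_ml(data, True, order_as_fixed)
    ll0 = _fit_crossed_ml(data, False, order_as_fixed)
    chi2 = max(0.0, 2.0 * (ll1 - ll0))
    df = len(categories) - 1
    return {"chi_square": chi2, "df": df, "p_value": float(stats.chi2.sf(chi2, df))}


def _fit_contrast_model(data: pd.DataFrame, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Category means and their covariance from the crossed mixed model.

    REML fits near a variance boundary occasionally return an indefinite
    Hessian-based covariance; optimizers are tried in turn and a fit is
    accepted only with a positive-semidefinite, finite covariance.  If every
    mixed fit degenerates, the category-mean OLS covariance is used (the
    contrast estimates are identical in the balanced design; a warning is
    emitted).
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = smf.mixedlm(
            "score ~ 0 + C(stimulus)",
            data,
            groups=np.ones(len(data)),
            vc_formula={"unit": "0 + C(unit_id)", "order": "0 + C(order_index)"},
        )
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                fit = model.fit(reml=True, method=method)
            except (ValueError, np.linalg.LinAlgError):
                continue
            beta = fit.fe_params.to_numpy()[:k]
            cov = fit.cov_params().to_numpy()[:k, :k]
            if np.all(np.isfinite(cov)) and np.all(np.linalg.eigvalsh(cov) > 0):
                return beta, cov
    warnings.warn(
        "mixed-model covariance degenerate; falling back to category-mean OLS",
        stacklevel=3,
    )
    ols = smf.ols("score ~ 0 + C(stimulus)", data).fit()
    return ols.params.to_numpy()[:k], ols.cov_params().to_numpy()[:k, :k]


def posthoc_pairwise(
    scores: pd.Series | np.ndarray,
    stimulus: pd.Series | np.ndarray,
    unit_id: pd.Series | np.ndarray,
    order_index: pd.Series | np.ndarray,
    n_mc: int = 200_000,
) -> pd.DataFrame:
    """All pairwise stimulus contrasts with single-step (Tukey-style) adjustment.

    Contrast statistics come from the REML fit of the crossed mixed model
    (restricted likelihood avoids the downward ML bias in the residual
    variance); the family-wise adjusted p-value of each contrast is
    P(max_k |T_k| >= |t|) under the joint multivariate-t law of all
    contrasts at the residual degrees of freedom, evaluated by a fixed-seed
    Monte Carlo integration (deterministic).
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    data = pd.DataFrame(
        {
            "score": np.asarray(scores, dtype=float),
            "stimulus": np.asarray(stimulus),
            "unit_id": np.asarray(unit_id),
            "order_index": np.asarray(order_index),
        }
    )
    categories = sorted(data["stimulus"].unique())
    if len(categories) < 3:
        raise ValueError("post-hoc comparisons need >= 3 categories")
    k = len(categories)
    beta, cov = _fit_contrast_model(data, k)
    df_resid = max(int(len(data) - k), 2)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    contrast = np.zeros((len(pairs), k))
    for row, (i, j) in enumerate(pairs):
        contrast[row, i], contrast[row, j] = 1.0, -1.0
    est = contrast @ beta
    cmat = contrast @ cov @ contrast.T
    se = np.sqrt(np.diag(cmat))
    z = est / se
    corr = cmat / np.outer(se, se)
    # deterministic MC estimate of the max-|T| family distribution
    rng = np.random.default_rng(20121521)
    # contrasts are linearly dependent, so the correlation matrix is singular;
    # eigendecomposition-based sampling handles the rank deficiency
    draws = rng.multivariate_normal(np.zeros(len(pairs)), corr, size=n_mc,
                                    method="eigh")
    scale = np.sqrt(rng.chisquare(df_resid, size=n_mc) / df_resid)
    max_abs = np.abs(draws).max(axis=1) / scale
    raw = 2.0 * stats.t.sf(np.abs(z), df_resid)
    adjusted = np.array([np.mean(max_abs >= abs(zi)) for zi in z])
    adjusted = np.maximum(adjusted, raw)  # adjustment can never help a contrast
    return pd.DataFrame(
        {
            "contrast": [f"{categories[i]} - {categories[j]}" for i, j in pairs],
            "estimate": est,
            "z": z,
            "p_raw": raw,
            "p_adjusted": np.minimum(adjusted, 1.0),
        }
    )


def simulate_captive_experiment(
    stimulus_means: dict[str, float],
    n_units: int = 8,
    unit_sd: float = 0.5,
    order_sd: float = 0.2,
    noise_sd: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a balanced captive playback experiment.

    Each unit (cluster of females) hears every stimulus once, in a rotated
    order.  A latent response strength (stimulus mean + unit intercept +
    order intercept + noise) is mapped monotonically onto the three observed
    criteria: orientation and maximal approach threshold the latent scale at
    fixed cut points; the count of approaching females grows with it.
    """
    rng = np.random.default_rng(seed)
    stimuli = list(stimulus_means)
    k = len(stimuli)
    unit_eff = rng.normal(0.0, unit_sd, size=n_units)
    order_eff = rng.normal(0.0, order_sd, size=k)
    rows = []
    for u in range(n_units):
        for slot in range(k):
            stim = stimuli[(u + slot) % k]  # rotated presentation order
            latent = (stimulus_means[stim] + unit_eff[u] + order_eff[slot]
                      + rng.normal(0.0, noise_sd))
            rows.append(
                {
                    "unit_id": f"cluster_{u:02d}",
                    "stimulus": stim,
                    "order_index": slot,
                    "orientation": int(np.clip(np.round(latent + 1.0), 0, 2)),
                    "n_approaching": int(np.clip(np.round(3.0 * max(latent, 0.0)), 0, 20)),
                    "max_approach": int(np.clip(np.round(latent + 0.5), 0, 2)),
                }
            )
    return pd.DataFrame(rows)
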